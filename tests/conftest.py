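import numpy as np
import pytest

from elmgrade.cohort_io import CohortTable, FeatureBlock
from elmgrade.synthetic_cohort import ModalityModel, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_cohort(n_ad=3, n_nc=3, n_mci=4, seed=0, n_features=(2, 3)):
    """Tiny hand-sized cohort with random finite features."""
    r = np.random.default_rng(seed)
    n = n_ad + n_nc + n_mci
    groups = np.array(["AD"] * n_ad + ["NC"] * n_nc + ["MCI"] * n_mci)
    blocks = {}
    for b, m in enumerate(n_features):
        name = f"mod{b}"
        blocks[name] = FeatureBlock(
            name, [f"{name}_f{j}" for j in range(m)], r.standard_normal((n, m))
        )
    months = np.full(n, np.nan)
    months[n_ad + n_nc] = 24.0  # one converting MCI subject
    return CohortTable(
        subject_id=np.array([f"S{i:03d}" for i in range(n)]),
        baseline_group=groups,
        months_to_AD=months,
        months_last_followup=np.full(n, 60.0),
        reverted_to_NC=np.zeros(n, dtype=bool),
        blocks=blocks,
    )


@pytest.fixture
def tiny_cohort():
    return make_cohort()


def lean_spec(effect=0.8, mixing=1.0, n_ref=50, n_pmci=100, n_smci=200,
              n_modalities=3, m=10, n_info=5, seed=0):
    """Small multimodal spec with continuous blocks only (fast pipelines)."""
    mods = [
        ModalityModel(f"mod{i}", m, n_informative=n_info, effect_size=effect)
        for i in range(n_modalities)
    ]
    return SyntheticSpec(
        n_per_group={"AD": n_ref, "NC": n_ref, "pMCI": n_pmci, "sMCI": n_smci},
        modalities=mods,
        mci_mixing=mixing,
        seed=seed,
    )


@pytest.fixture
def lean_cohort():
    return generate(lean_spec(n_pmci=30, n_smci=50, n_ref=25, seed=3))
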