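"""Synthetic multimodal cohorts with controllable class structure.

Real MCI-conversion cohorts (clinical consortium data) are access
restricted, so every pipeline stage is exercised on generated cohorts that
mimic their shape: class-conditional Gaussian feature blocks of unequal
width (a wide morphometric block, a narrow PET block, a few CSF columns),
a binary risk-allele column, and conversion times for the progressive
subjects.

Model
-----
Continuous blocks are equicorrelated Gaussians: within a block every pair
of features shares correlation ``rho`` and unit marginal variance.  The
first ``n_informative`` features of a block carry a standardized mean
difference ``effect_size`` between AD and NC (+d/2 vs -d/2); the rest are
pure noise.  MCI groups sit between the poles: on informative features the
pMCI mean is ``mci_mixing`` times the AD mean and the sMCI mean is
``mci_mixing`` times the NC mean, so ``mci_mixing`` (a in [0, 1]) controls
how much of the AD/NC contrast survives into the prognostic task.

Binary blocks draw carrier status per group from a Bernoulli frequency.

Conversion times for pMCI are exponential, truncated at the labelling
horizon; a fraction of the stable group converts after the horizon and a
fraction reverts to NC, so the strict stable-MCI exclusion has something to
exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from elmgrade.cohort_io import CohortTable, FeatureBlock

GROUP_ORDER = ("AD", "NC", "pMCI", "sMCI")


@dataclass
class ModalityModel:
    name: str
    n_features: int
    n_informative: int = 0
    effect_size: float = 0.0  # standardized AD-vs-NC mean difference per feature
    rho: float = 0.0  # equicorrelation within the block
    binary: bool = False
    carrier_freq: dict[str, float] | None = None  # per group, binary blocks only

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError(
                f"modality {self.name!r}: n_informative exceeds n_features"
            )
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.binary:
            if self.carrier_freq is None:
                raise ValueError(
                    f"binary modality {self.name!r} needs carrier_freq per group"
                )
            bad = [g for g, p in self.carrier_freq.items() if not 0.0 <= p <= 1.0]
            if bad:
                raise ValueError(f"carrier frequencies outside [0, 1]: {bad}")


@dataclass
class SyntheticSpec:
    """Cohort recipe: group sizes, block models, MCI mixing, conversion model."""

    n_per_group: dict[str, int]
    modalities: list[ModalityModel]
    mci_mixing: float = 0.6
    conversion_scale_months: float = 22.0
    conversion_max_months: float = 36.0
    followup_months: float = 66.0
    late_conversion_frac: float = 0.15
    revert_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(GROUP_ORDER) - set(self.n_per_group)
        if missing:
            raise ValueError(f"n_per_group missing groups: {sorted(missing)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be nonnegative")
        if not 0.0 <= self.mci_mixing <= 1.0:
            raise ValueError("mci_mixing must be in [0, 1]")
        for frac in (self.late_conversion_frac, self.revert_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.late_conversion_frac + self.revert_frac > 1.0:
            raise ValueError("late_conversion_frac + revert_frac must be <= 1")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def _group_mean(model: ModalityModel, group: str, mixing: float) -> np.ndarray:
    mu = np.zeros(model.n_features)
    d = model.effect_size
    pole = {"AD": d / 2.0, "NC": -d / 2.0, "pMCI": mixing * d / 2.0,
            "sMCI": -mixing * d / 2.0}[group]
    mu[: model.n_informative] = pole
    return mu


def _continuous_block(
    model: ModalityModel, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    parts = []
    for group in GROUP_ORDER:
        n = spec.n_per_group[group]
        mu = _group_mean(model, group, spec.mci_mixing)
        z = rng.standard_normal((n, model.n_features))
        if model.rho > 0:
            shared = rng.standard_normal((n, 1))
            z = np.sqrt(model.rho) * shared + np.sqrt(1.0 - model.rho) * z
        parts.append(mu + z)
    return np.vstack(parts)


def _binary_block(
    model: ModalityModel, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    parts = []
    for group in GROUP_ORDER:
        n = spec.n_per_group[group]
        p = model.carrier_freq.get(group)
        if p is None:
            raise ValueError(
                f"binary modality {model.name!r}: no carrier_freq for {group!r}"
            )
        parts.append((rng.random((n, model.n_features)) < p).astype(float))
    return np.vstack(parts)


def generate(spec: SyntheticSpec, seed: int | None = None) -> CohortTable:
    """Draw one cohort; deterministic given the seed (``spec.seed`` unless
    overridden)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = [spec.n_per_group[g] for g in GROUP_ORDER]
    total = sum(sizes)
    width = max(4, len(str(total)))
    subject_id = np.array([f"S{i:0{width}d}" for i in range(total)])
    gen_group = np.repeat(GROUP_ORDER, sizes)  # generating group incl. pMCI/sMCI
    baseline = np.where(np.isin(gen_group, ["pMCI", "sMCI"]), "MCI", gen_group)

    blocks: dict[str, FeatureBlock] = {}
    for model in spec.modalities:
        values = (
            _binary_block(model, spec, rng)
            if model.binary
            else _continuous_block(model, spec, rng)
        )
        names = [f"{model.name}_f{j:03d}" for j in range(model.n_features)]
        blocks[model.name] = FeatureBlock(model.name, names, values)

    months_to_AD = np.full(total, np.nan)
    reverted = np.zeros(total, dtype=bool)
    pmci = np.flatnonzero(gen_group == "pMCI")
    if pmci.size:
        # exponential conversion times truncated at the labelling horizon
        u = rng.random(pmci.size)
        s, tmax = spec.conversion_scale_months, spec.conversion_max_months
        months_to_AD[pmci] = -s * np.log1p(-u * (1.0 - np.exp(-tmax / s)))
    smci = np.flatnonzero(gen_group == "sMCI")
    if smci.size:
        u = rng.random(smci.size)
        late = u < spec.late_conversion_frac
        revert = (u >= spec.late_conversion_frac) & (
            u < spec.late_conversion_frac + spec.revert_frac
        )
        months_to_AD[smci[late]] = rng.uniform(
            spec.conversion_max_months, spec.followup_months, late.sum()
        )
        reverted[smci[revert]] = True

    return CohortTable(
        subject_id=subject_id,
        baseline_group=baseline,
        months_to_AD=months_to_AD,
        months_last_followup=np.full(total, spec.followup_months),
        reverted_to_NC=reverted,
        blocks=blocks,
    )


def preset_adnilike(seed: int = 0) -> SyntheticSpec:
    """Cohort preset matching the shape of the motivating clinical study.

    Group sizes 102 AD / 200 NC / 110 pMCI / 205 sMCI and block widths
    313 (MRI) / 20 (FDG-PET) / 3 (CSF) / 1 (APOE carrier status).  Effect
    sizes are moderate and each modality carries an independent informative
    subspace, so the modalities are complementary; the conversion-time
    scale puts roughly half of the progressive conversions inside the first
    year and all inside three years, with a minority of the stable group
    converting later or reverting to NC.
    """
    return SyntheticSpec(
        n_per_group={"AD": 102, "NC": 200, "pMCI": 110, "sMCI": 205},
        modalities=[
            ModalityModel("MRI", 313, n_informative=25, effect_size=0.8, rho=0.1),
            ModalityModel("FDG-PET", 20, n_informative=8, effect_size=0.9, rho=0.1),
            ModalityModel("CSF", 3, n_informative=3, effect_size=1.0, rho=0.2),
            ModalityModel(
                "APOE",
                1,
                binary=True,
                carrier_freq={"AD": 0.65, "NC": 0.25, "pMCI": 0.60, "sMCI": 0.35},
            ),
        ],
        mci_mixing=0.6,
        conversion_scale_months=22.0,
        conversion_max_months=36.0,
        followup_months=66.0,
        late_conversion_frac=0.15,
        revert_frac=0.15,
        seed=seed,
    )
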