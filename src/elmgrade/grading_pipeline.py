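"""Orchestration: normalize, select, grade each modality, fuse the scores.

The pipeline turns a multimodal cohort into an N_MCI x K grading-score
matrix.  For each modality a kernel ELM is trained on the AD/NC reference
subjects of that modality and every MCI subject receives the grading score
s = s1 - s2, a continuous AD-vs-NC similarity.  The K per-modality scores
(default K = 3: MRI, FDG-PET, and a biological modality formed by
concatenating CSF with APOE e4 status) are then concatenated column-wise
into the fused representation fed to the downstream pMCI/sMCI classifier.

Grading models are trained once on the full AD/NC set and reused across all
cross-validation repetitions: the reference subjects are disjoint from the
MCI evaluation set, so this shares no information with the pMCI/sMCI labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from elmgrade.cohort_io import (
    CohortTable,
    FeatureBlock,
    apply_normalizer,
    fit_normalizer,
)
from elmgrade.kernel_elm import DEFAULT_C, default_gamma, elm_grade, elm_train
from elmgrade.lasso_select import (
    DEFAULT_LAMBDA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    LassoProblem,
    lasso_fit,
    select_features,
)

logger = logging.getLogger(__name__)


@dataclass
class ModalitySpec:
    """One graded modality: which cohort blocks it merges, and whether the
    L1 feature-selection step applies (only MRI by default — the wide
    morphometric block is the one containing aging-related nuisance
    features)."""

    name: str
    source_blocks: list[str]
    apply_lasso: bool = False

    def __post_init__(self) -> None:
        if not self.source_blocks:
            raise ValueError(f"modality {self.name!r} lists no source blocks")


def default_modality_specs() -> list[ModalitySpec]:
    """MRI (with feature selection), FDG-PET, and Bio = CSF + APOE."""
    return [
        ModalitySpec("MRI", ["MRI"], apply_lasso=True),
        ModalitySpec("FDG-PET", ["FDG-PET"]),
        ModalitySpec("Bio", ["CSF", "APOE"]),
    ]


@dataclass
class GradingScoreMatrix:
    """N_MCI x K fused score matrix with column names and subject ids."""

    values: np.ndarray
    column_names: list[str]
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        if self.values.shape != (len(self.subject_ids), len(self.column_names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.column_names)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite grading scores")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class ModalityData:
    """Prepared per-modality inputs: normalized (and selected) train/test."""

    spec: ModalitySpec
    train_block: FeatureBlock  # AD/NC rows
    train_labels: np.ndarray  # "AD"/"NC"
    test_block: FeatureBlock  # MCI rows
    selected_features: list[str] = field(default_factory=list)


def _merge_blocks(cohort: CohortTable, spec: ModalitySpec) -> FeatureBlock:
    parts = []
    names: list[str] = []
    for block_name in spec.source_blocks:
        if block_name not in cohort.blocks:
            raise ValueError(
                f"modality {spec.name!r} references unknown block {block_name!r}"
            )
        block = cohort.blocks[block_name]
        parts.append(block.values)
        names.extend(block.feature_names)
    return FeatureBlock(
        modality_name=spec.name, feature_names=names, values=np.hstack(parts)
    )


def build_modalities(
    cohort: CohortTable,
    specs: list[ModalitySpec] | None = None,
    lasso_lambda: float = DEFAULT_LAMBDA,
    lasso_tol: float = DEFAULT_TOL,
    lasso_max_iter: int = DEFAULT_MAX_ITER,
    lambda_scale: str = "literal",
) -> list[ModalityData]:
    """Prepare every modality: merge blocks, normalize on AD+NC, select.

    Normalization statistics come from the AD+NC reference rows and are
    applied identically to the reference and MCI partitions.  Where
    ``apply_lasso`` is set, the L1 selection is fitted on the AD/NC rows
    with +1 (AD) / -1 (NC) response and the same column subset is applied
    to the MCI block.
    """
    if specs is None:
        specs = default_modality_specs()
    ref_rows = cohort.reference_rows
    mci_rows = cohort.mci_rows
    if ref_rows.size == 0 or mci_rows.size == 0:
        raise ValueError("cohort must contain AD/NC reference rows and MCI rows")
    ref_labels = cohort.baseline_group[ref_rows]
    y = np.where(ref_labels == "AD", 1.0, -1.0)

    out: list[ModalityData] = []
    for spec in specs:
        merged = _merge_blocks(cohort, spec)
        params = fit_normalizer(merged, ref_rows)
        normed = apply_normalizer(params, merged)
        train = FeatureBlock(
            spec.name, list(normed.feature_names), normed.values[ref_rows]
        )
        test = FeatureBlock(
            spec.name, list(normed.feature_names), normed.values[mci_rows]
        )
        selected = list(train.feature_names)
        if spec.apply_lasso:
            result = lasso_fit(
                LassoProblem(train.values, y, lasso_lambda),
                tol=lasso_tol,
                max_iter=lasso_max_iter,
                lambda_scale=lambda_scale,
            )
            train = select_features(train, result)
            test = select_features(test, result)
            selected = list(train.feature_names)
            logger.info(
                "modality %s: L1 selection kept %d/%d features",
                spec.name,
                len(selected),
                merged.n_features,
            )
        logger.info(
            "modality %s: %d train (AD/NC) x %d features, %d MCI rows",
            spec.name,
            train.n_subjects,
            train.n_features,
            test.n_subjects,
        )
        out.append(
            ModalityData(
                spec=spec,
                train_block=train,
                train_labels=ref_labels.copy(),
                test_block=test,
                selected_features=selected,
            )
        )
    return out


def grade_modality(
    train_block: FeatureBlock,
    train_labels: np.ndarray,
    test_block: FeatureBlock,
    C: float = DEFAULT_C,
    gamma: float | None = None,
) -> np.ndarray:
    """Train one grading ELM on AD/NC and score every MCI row.

    Returns the grading score s = s1 - s2 per test row; higher is more
    AD-like.  ``gamma`` defaults to 10 * (feature count after selection).
    """
    train_labels = np.asarray(train_labels)
    present = set(np.unique(train_labels).tolist())
    if present != {"AD", "NC"}:
        raise ValueError(f"grading requires AD and NC training labels, got {present}")
    if gamma is None:
        gamma = default_gamma(train_block.n_features)
    model = elm_train(
        train_block.values, train_labels, C=C, gamma=gamma, class_order=("AD", "NC")
    )
    return np.asarray(elm_grade(model, test_block.values))


def fuse_scores(
    scores: dict[str, np.ndarray],
    subject_ids: np.ndarray,
    extra_covariates: pd.DataFrame | None = None,
) -> GradingScoreMatrix:
    """Concatenate per-modality score vectors column-wise (spec order).

    Optional extra covariates (e.g. neuropsychological test scores) are
    z-scored with MCI-cohort statistics before concatenation so they enter
    the classifier on the same scale as the grading scores.
    """
    subject_ids = np.asarray(subject_ids, dtype=str)
    n = subject_ids.size
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name, vec in scores.items():
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != n:
            raise ValueError(
                f"score vector {name!r} has length {vec.size}, expected {n}"
            )
        cols.append(vec)
        names.append(name)
    if extra_covariates is not None:
        if len(extra_covariates) != n:
            raise ValueError("extra covariates misaligned with subject ids")
        if "subject_id" in extra_covariates.columns:
            if not np.array_equal(
                extra_covariates["subject_id"].to_numpy(dtype=str), subject_ids
            ):
                raise ValueError("extra covariate subject ids do not match scores")
            extra_covariates = extra_covariates.drop(columns="subject_id")
        for col in extra_covariates.columns:
            v = extra_covariates[col].to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                raise ValueError(f"extra covariate {col!r} is constant")
            cols.append((v - v.mean()) / sd)
            names.append(str(col))
    return GradingScoreMatrix(
        values=np.column_stack(cols), column_names=names, subject_ids=subject_ids
    )


def run_grading(
    cohort: CohortTable,
    specs: list[ModalitySpec] | None = None,
    C: float = DEFAULT_C,
    lasso_lambda: float = DEFAULT_LAMBDA,
    lambda_scale: str = "literal",
    extra_covariates: pd.DataFrame | None = None,
) -> GradingScoreMatrix:
    """Full grading stage: cohort in, fused N_MCI x K score matrix out.

    Deterministic — every step is a closed-form computation, so repeated
    calls on the same cohort give identical matrices.
    """
    modalities = build_modalities(
        cohort, specs, lasso_lambda=lasso_lambda, lambda_scale=lambda_scale
    )
    scores = {
        md.spec.name: grade_modality(
            md.train_block, md.train_labels, md.test_block, C=C
        )
        for md in modalities
    }
    subject_ids = cohort.subject_id[cohort.mci_rows]
    return fuse_scores(scores, subject_ids, extra_covariates=extra_covariates)
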