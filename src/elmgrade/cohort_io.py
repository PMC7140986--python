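"""Cohort tables: reading, horizon labelling, and AD/NC-anchored normalization.

A cohort is a set of subjects with one feature block per modality plus a
diagnosis record (baseline group, months to AD conversion, last follow-up,
reversion to normal).  All normalization statistics are fitted on the AD and
NC reference subjects only and then applied unchanged to the MCI subjects,
so the MCI representation is expressed in reference-anchored units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("AD", "NC", "MCI")

LABEL_PMCI = "pMCI"
LABEL_SMCI = "sMCI"
LABEL_EXCLUDED = "excluded"


@dataclass
class FeatureBlock:
    """One modality's feature matrix: ``values`` is N subjects x M features."""

    modality_name: str
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"block {self.modality_name!r}: values must be 2-D, "
                f"got shape {self.values.shape}"
            )
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError(
                f"block {self.modality_name!r}: {len(self.feature_names)} feature "
                f"names but {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.modality_name!r}: non-finite value at "
                f"row {bad[0]}, column {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortTable:
    """Subjects x modality blocks plus diagnosis/conversion metadata.

    ``months_to_AD`` uses NaN for "no observed conversion".  Rows are in a
    single fixed order shared by the metadata arrays and every block.
    """

    subject_id: np.ndarray
    baseline_group: np.ndarray
    months_to_AD: np.ndarray
    months_last_followup: np.ndarray
    reverted_to_NC: np.ndarray
    blocks: dict[str, FeatureBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=str)
        self.baseline_group = np.asarray(self.baseline_group, dtype=str)
        self.months_to_AD = np.asarray(self.months_to_AD, dtype=float)
        self.months_last_followup = np.asarray(self.months_last_followup, dtype=float)
        self.reverted_to_NC = np.asarray(self.reverted_to_NC, dtype=bool)
        n = len(self.subject_id)
        for name, arr in [
            ("baseline_group", self.baseline_group),
            ("months_to_AD", self.months_to_AD),
            ("months_last_followup", self.months_last_followup),
            ("reverted_to_NC", self.reverted_to_NC),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        unknown = set(self.baseline_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown baseline groups: {sorted(unknown)}")
        for block in self.blocks.values():
            if block.n_subjects != n:
                raise ValueError(
                    f"block {block.modality_name!r} has {block.n_subjects} rows, "
                    f"cohort has {n}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def group_mask(self, *groups: str) -> np.ndarray:
        return np.isin(self.baseline_group, list(groups))

    @property
    def reference_rows(self) -> np.ndarray:
        """Row indices of the AD and NC reference subjects."""
        return np.flatnonzero(self.group_mask("AD", "NC"))

    @property
    def mci_rows(self) -> np.ndarray:
        return np.flatnonzero(self.group_mask("MCI"))


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_feature_file(path: str, modality: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_delimiter_for(path), dtype={0: str}, float_precision="round_trip"
    )
    id_col = df.columns[0]
    df = df.set_index(id_col)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"modality {modality!r}: non-numeric cell at subject {row!r}, "
                f"column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(
                f"modality {modality!r}: missing value at subject {row!r}, "
                f"column {col!r}"
            )
        df[col] = coerced
    return df


def read_cohort(feature_paths: dict[str, str], diagnosis_path: str) -> CohortTable:
    """Read one delimited file per modality plus the diagnosis file.

    Files are comma- or tab-delimited (from the ``.csv``/``.tsv`` extension)
    with a header row whose first column is the subject id.  Subject ids must
    align across all files; rows are sorted by subject id so that the
    resulting table is independent of on-disk row order.
    """
    diag = pd.read_csv(
        diagnosis_path,
        sep=_delimiter_for(diagnosis_path),
        dtype={"subject_id": str},
        float_precision="round_trip",
    )
    required = {
        "subject_id",
        "baseline_group",
        "months_to_AD",
        "months_last_followup",
        "reverted_to_NC",
    }
    missing_cols = required - set(diag.columns)
    if missing_cols:
        raise ValueError(f"diagnosis file missing columns: {sorted(missing_cols)}")
    diag = diag.set_index("subject_id").sort_index()
    if diag.index.duplicated().any():
        dup = diag.index[diag.index.duplicated()][0]
        raise ValueError(f"duplicate subject id in diagnosis file: {dup!r}")

    ids = diag.index.to_numpy(dtype=str)
    blocks: dict[str, FeatureBlock] = {}
    for modality, path in feature_paths.items():
        df = _read_feature_file(path, modality)
        absent = set(ids) - set(df.index)
        if absent:
            raise ValueError(
                f"subject {sorted(absent)[0]!r} missing from modality {modality!r}"
            )
        df = df.loc[ids]
        blocks[modality] = FeatureBlock(
            modality_name=modality,
            feature_names=list(df.columns),
            values=df.to_numpy(dtype=float),
        )

    reverted = diag["reverted_to_NC"]
    if reverted.dtype == object:
        reverted = reverted.astype(str).str.lower().isin(["true", "1", "yes"])
    return CohortTable(
        subject_id=ids,
        baseline_group=diag["baseline_group"].to_numpy(dtype=str),
        months_to_AD=pd.to_numeric(diag["months_to_AD"]).to_numpy(dtype=float),
        months_last_followup=pd.to_numeric(diag["months_last_followup"]).to_numpy(
            dtype=float
        ),
        reverted_to_NC=reverted.to_numpy(dtype=bool),
        blocks=blocks,
    )


def write_cohort(cohort: CohortTable, out_dir: str, fmt: str = "csv") -> dict[str, str]:
    """Write one feature file per block plus ``diagnosis.<fmt>``.

    Returns the mapping of written paths (``feature_paths`` plus a
    ``"diagnosis"`` entry) suitable for :func:`read_cohort`.
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError("fmt must be 'csv' or 'tsv'")
    sep = "\t" if fmt == "tsv" else ","
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for name, block in cohort.blocks.items():
        df = pd.DataFrame(block.values, columns=block.feature_names)
        df.insert(0, "subject_id", cohort.subject_id)
        path = os.path.join(out_dir, f"{name}.{fmt}")
        # %.17g keeps the write->read round trip bit-exact for doubles
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
        paths[name] = path
    diag = pd.DataFrame(
        {
            "subject_id": cohort.subject_id,
            "baseline_group": cohort.baseline_group,
            "months_to_AD": cohort.months_to_AD,
            "months_last_followup": cohort.months_last_followup,
            "reverted_to_NC": cohort.reverted_to_NC,
        }
    )
    diag_path = os.path.join(out_dir, f"diagnosis.{fmt}")
    diag.to_csv(diag_path, sep=sep, index=False, float_format="%.17g")
    paths["diagnosis"] = diag_path
    return paths


def assign_horizon_labels(
    cohort: CohortTable,
    horizon_months: float,
    strict: bool = False,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Label MCI subjects pMCI/sMCI at a conversion horizon.

    A subject is pMCI iff an AD conversion was observed at or before
    ``horizon_months`` after baseline; otherwise sMCI.  In strict mode,
    subjects who converted *after* the horizon or whose diagnosis reverted to
    NC are marked ``"excluded"`` instead of sMCI, mirroring the stricter
    stable-MCI definitions used in the conversion-prediction literature.

    ``rows`` defaults to all MCI rows of the cohort; passing non-MCI rows is
    an error.
    """
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    if rows is None:
        rows = cohort.mci_rows
    rows = np.asarray(rows, dtype=int)
    non_mci = rows[cohort.baseline_group[rows] != "MCI"]
    if non_mci.size:
        raise ValueError(
            f"assign_horizon_labels expects MCI rows only; "
            f"subject {cohort.subject_id[non_mci[0]]!r} is "
            f"{cohort.baseline_group[non_mci[0]]}"
        )
    months = cohort.months_to_AD[rows]
    converted = np.isfinite(months)
    labels = np.full(rows.shape, LABEL_SMCI, dtype=object)
    labels[converted & (months <= horizon_months)] = LABEL_PMCI
    if strict:
        late = converted & (months > horizon_months)
        labels[late | cohort.reverted_to_NC[rows]] = LABEL_EXCLUDED
        # a conversion inside the horizon outranks a recorded reversion
        labels[converted & (months <= horizon_months)] = LABEL_PMCI
    return labels.astype(str)


@dataclass
class NormalizationParams:
    """Per-feature location/scale fitted on the AD+NC reference rows.

    SD is the population standard deviation (divisor N); any consistent
    convention works, this one is fixed for reproducibility.
    """

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd <= 0):
            raise ValueError("sd entries must be strictly positive")


def fit_normalizer(
    block: FeatureBlock, reference_rows: np.ndarray
) -> NormalizationParams:
    """Fit per-column mean/SD over the reference (AD+NC) rows only."""
    reference_rows = np.asarray(reference_rows, dtype=int)
    if reference_rows.size < 2:
        raise ValueError("need at least 2 reference rows to fit a normalizer")
    ref = block.values[reference_rows]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)  # population SD, divisor N
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant feature on reference rows: "
            f"{block.feature_names[constant[0]]!r} in block {block.modality_name!r}"
        )
    return NormalizationParams(
        mean=mean, sd=sd, fitted_on=f"{block.modality_name}:{reference_rows.size} refs"
    )


def apply_normalizer(params: NormalizationParams, block: FeatureBlock) -> FeatureBlock:
    """Z-score every row of ``block`` with the reference statistics."""
    if block.n_features != params.mean.size:
        raise ValueError(
            f"block {block.modality_name!r} has {block.n_features} features, "
            f"normalizer expects {params.mean.size}"
        )
    return FeatureBlock(
        modality_name=block.modality_name,
        feature_names=list(block.feature_names),
        values=(block.values - params.mean) / params.sd,
    )


def invert_normalizer(params: NormalizationParams, block: FeatureBlock) -> FeatureBlock:
    """Undo :func:`apply_normalizer` (value * sd + mean)."""
    if block.n_features != params.mean.size:
        raise ValueError("dimension mismatch between block and normalizer")
    return FeatureBlock(
        modality_name=block.modality_name,
        feature_names=list(block.feature_names),
        values=block.values * params.sd + params.mean,
    )
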