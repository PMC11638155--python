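"""Feature engineering and cohort splitting.

Turns a cohort table into the 11-column numeric design matrix used by all
three classifiers: the six numeric instruments/demographics (age, education,
MMSE, MoCA, FAB, HDRS) standardized to zero mean and unit variance (sample SD,
``ddof=1``), Sex expanded to two indicator columns, and the three binary
management flags (comorbidity, treatment, rehabilitation) passed through as
single 0/1 indicators.

Scaling is transductive by default -- fitted on the full cohort before the
graph is built, since the population graph itself spans all subjects.  A
train-only fit is available by passing the training ids to
:func:`build_feature_matrix`; see the methods note on the leakage trade-off.

Splitting is stratified jointly by diagnosis and sex using largest-remainder
rounding inside each stratum, so both the class balance and the sex balance of
the sample carry into every partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "NUMERIC_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "PARTITIONS",
    "DEFAULT_FRACTIONS",
    "ScalerParams",
    "FeatureMatrix",
    "SplitAssignment",
    "standardize_numeric",
    "one_hot_encode",
    "build_feature_matrix",
    "stratified_split",
    "largest_remainder_counts",
]

NUMERIC_COLUMNS = ["age", "education", "mmse", "moca", "fab", "hdrs"]
CATEGORICAL_COLUMNS = ["sex", "comorbidity", "treatment", "rehabilitation"]
SEX_LEVELS = ("F", "M")
PARTITIONS = ("train", "val", "test")

# Deduced from the printed subset sex percentages (85/119, 23/30, 43/65):
# subset sizes 119/30/65 of 214.
DEFAULT_FRACTIONS = (119 / 214, 30 / 214, 65 / 214)


@dataclass
class ScalerParams:
    """Per-column mean and sample SD (ddof=1) of the scaled numeric columns."""

    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]))


@dataclass
class FeatureMatrix:
    values: np.ndarray
    column_names: list[str]
    row_ids: list[str]
    encoding_manifest: dict[str, list[str]] = field(default_factory=dict)
    scaler: ScalerParams | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "id", self.row_ids)
        return df


@dataclass
class SplitAssignment:
    partition: pd.Series  # index = patient id, values in PARTITIONS
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list[str]:
        return list(self.partition.index[self.partition == part])

    def mask(self, row_ids, part: str) -> np.ndarray:
        lookup = self.partition.to_dict()
        return np.array([lookup[i] == part for i in row_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.partition.index, "partition": self.partition.values})


def standardize_numeric(table: CohortTable, columns: list[str] | None = None,
                        scaler: ScalerParams | None = None,
                        ) -> tuple[pd.DataFrame, ScalerParams]:
    """Standardize numeric columns to mean 0, sample SD 1 (ddof=1).

    When ``scaler`` is given its stored parameters are applied instead of
    refitting, so a train-fitted transform can be reused verbatim.
    """
    if columns is None:
        columns = NUMERIC_COLUMNS
    df = table.records
    missing = set(columns) - set(df.columns)
    if missing:
        raise KeyError(f"missing numeric columns: {sorted(missing)}")
    if scaler is None:
        if len(df) < 2:
            raise ValueError("standardization needs at least 2 records")
        mean = {c: float(df[c].mean()) for c in columns}
        sd = {c: float(df[c].std(ddof=1)) for c in columns}
        for c, s in sd.items():
            if s == 0.0 or not np.isfinite(s):
                raise ValueError(f"column {c!r} is constant; cannot standardize")
        scaler = ScalerParams(mean=mean, sd=sd)
    out = pd.DataFrame({
        c: (df[c].to_numpy(dtype=float) - scaler.mean[c]) / scaler.sd[c]
        for c in columns
    })
    return out, scaler


def one_hot_encode(table: CohortTable, columns: list[str] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Encode categoricals: Sex -> two indicators, binary flags -> one each."""
    if columns is None:
        columns = CATEGORICAL_COLUMNS
    df = table.records
    frames: dict[str, np.ndarray] = {}
    manifest: dict[str, list[str]] = {}
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"missing categorical column: {col!r}")
        if col == "sex":
            vals = df[col].astype(str).to_numpy()
            unseen = set(vals) - set(SEX_LEVELS)
            if unseen:
                raise ValueError(f"unseen sex level(s): {sorted(unseen)}")
            out_cols = []
            for level in SEX_LEVELS:
                name = f"sex_{level}"
                frames[name] = (vals == level).astype(float)
                out_cols.append(name)
            manifest[col] = out_cols
        else:
            vals = df[col].to_numpy()
            bad = set(np.unique(vals)) - {0, 1}
            if bad:
                raise ValueError(f"non-binary level(s) in {col!r}: {sorted(bad)}")
            frames[col] = vals.astype(float)
            manifest[col] = [col]
    return pd.DataFrame(frames), manifest


def build_feature_matrix(table: CohortTable,
                         scaler: ScalerParams | None = None,
                         fit_ids: list[str] | None = None) -> FeatureMatrix:
    """Standardize + encode into the 11-column design matrix.

    ``fit_ids`` restricts scaler fitting to those subjects (train-only fit);
    default is the transductive full-cohort fit.
    """
    if scaler is None and fit_ids is not None:
        fit_table = CohortTable(
            records=table.records[table.records["id"].isin(set(fit_ids))])
        _, scaler = standardize_numeric(fit_table)
    numeric, scaler = standardize_numeric(table, scaler=scaler)
    categorical, manifest = one_hot_encode(table)
    manifest = {**{c: [c] for c in NUMERIC_COLUMNS}, **manifest}
    values = np.column_stack([numeric.to_numpy(), categorical.to_numpy()])
    column_names = list(numeric.columns) + list(categorical.columns)
    return FeatureMatrix(
        values=values,
        column_names=column_names,
        row_ids=list(table.records["id"]),
        encoding_manifest=manifest,
        scaler=scaler,
    )


def largest_remainder_counts(m: int, fractions) -> list[int]:
    """Integer allocation of ``m`` items to partitions by largest remainder."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ValueError("fractions must be non-negative")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    quotas = fractions * m
    base = np.floor(quotas).astype(int)
    leftover = m - int(base.sum())
    remainders = quotas - base
    # Ties broken by partition order (train, val, test): stable sort.
    order = np.argsort(-remainders, kind="stable")
    for k in order[:leftover]:
        base[k] += 1
    return base.tolist()


def stratified_split(table: CohortTable,
                     fractions=DEFAULT_FRACTIONS,
                     seed: int = 0) -> SplitAssignment:
    """Class- and sex-aware train/val/test split.

    Within each diagnosis-by-sex stratum, members are shuffled and allocated
    to partitions by largest-remainder rounding of ``fraction * stratum size``,
    so every partition count is within one subject of its exact quota inside
    each stratum.  Deterministic under a fixed seed.
    """
    df = table.records
    rng = np.random.default_rng(seed)
    n_parts = int(np.sum(np.asarray(fractions) > 0))
    assignment: dict[str, str] = {}
    # Fixed stratum order for determinism.
    strata = df.groupby(["diagnosis", "sex"], sort=True).groups
    for key in sorted(strata):
        idx = list(strata[key])
        ids = df.loc[idx, "id"].tolist()
        if len(ids) < n_parts:
            warnings.warn(
                f"stratum {key} has {len(ids)} member(s), fewer than the "
                f"{n_parts} non-empty partitions; allocating by largest remainder",
                stacklevel=2,
            )
        counts = largest_remainder_counts(len(ids), fractions)
        shuffled = [ids[k] for k in rng.permutation(len(ids))]
        pos = 0
        for part, c in zip(PARTITIONS, counts):
            for pid in shuffled[pos:pos + c]:
                assignment[pid] = part
            pos += c
    series = pd.Series({pid: assignment[pid] for pid in df["id"]}, name="partition")
    series = series.reindex(df["id"])
    return SplitAssignment(partition=series, fractions=tuple(fractions), seed=seed)
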