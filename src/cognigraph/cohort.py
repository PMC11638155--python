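"""Synthetic clinical cohort generation.

Emulates a three-group memory-clinic sample (cognitively healthy Controls,
amnesic mild cognitive impairment, probable mild Alzheimer's disease) described
only by summary statistics: per-group sizes and sex counts, age means/SDs, and
screening-score inclusion windows (patients screened with MMSE 18-28; controls
require MMSE >= 28 and MoCA > 26).  Everything the summary statistics do not
pin down (education, FAB, HDRS, comorbidity/treatment/rehabilitation rates,
the within-window shapes of MMSE/MoCA) uses configurable defaults chosen to
give a monotone severity ordering across groups -- those defaults are this
package's choice, clearly marked as such, not literature values.

The cohort is held in a pandas DataFrame with one row per subject and columns
``id, diagnosis, age, education, sex, mmse, moca, fab, hdrs, comorbidity,
treatment, rehabilitation``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DIAGNOSES",
    "COHORT_COLUMNS",
    "GroupSpec",
    "CohortConfig",
    "CohortTable",
    "default_config",
    "generate_cohort",
    "apply_inclusion_criteria",
    "write_cohort_csv",
    "read_cohort_csv",
]

DIAGNOSES = ("Control", "MCI", "AD")

COHORT_COLUMNS = [
    "id",
    "diagnosis",
    "age",
    "education",
    "sex",
    "mmse",
    "moca",
    "fab",
    "hdrs",
    "comorbidity",
    "treatment",
    "rehabilitation",
]

# Hard instrument scales (not inclusion windows).
MMSE_SCALE = (0, 30)
MOCA_SCALE = (0, 30)
FAB_SCALE = (0, 18)
HDRS_SCALE = (0, 52)
AGE_BOUNDS = (55.0, 95.0)
EDUCATION_BOUNDS = (3.0, 20.0)


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one diagnostic group.

    ``mmse_range``/``moca_range`` are the inclusive integer inclusion windows;
    scores are drawn as discretized truncated normals restricted to those
    windows.  ``hdrs_mean`` parameterizes a Poisson (clipped to the 0-52
    instrument scale), matching the right-skew of depression ratings.
    """

    label: str
    n: int
    n_female: int
    age_mean: float
    age_sd: float
    mmse_range: tuple[int, int]
    moca_range: tuple[int, int]
    mmse_mean: float
    mmse_sd: float
    moca_mean: float
    moca_sd: float
    fab_mean: float
    fab_sd: float
    hdrs_mean: float
    education_mean: float = 9.0
    education_sd: float = 4.0
    p_comorbidity: float = 0.0
    p_treatment: float = 0.0
    p_rehabilitation: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis label {self.label!r}")
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        if self.n_female > self.n:
            raise ValueError(
                f"{self.label}: n_female ({self.n_female}) exceeds n ({self.n})"
            )
        for name, (lo, hi), scale in (
            ("mmse_range", self.mmse_range, MMSE_SCALE),
            ("moca_range", self.moca_range, MOCA_SCALE),
        ):
            if lo > hi:
                raise ValueError(f"{self.label}: empty {name} ({lo}, {hi})")
            if lo < scale[0] or hi > scale[1]:
                raise ValueError(f"{self.label}: {name} outside instrument scale")
        for name in ("p_comorbidity", "p_treatment", "p_rehabilitation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.label}: {name}={p} not a probability")
        if self.age_sd <= 0 or self.mmse_sd <= 0 or self.moca_sd <= 0:
            raise ValueError(f"{self.label}: scale parameters must be positive")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


@dataclass
class CohortTable:
    """Ordered subject records plus the provenance needed to regenerate them."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)


def default_config(seed: int = 0) -> CohortConfig:
    """The default study-like cohort: 107 Controls, 77 MCI, 30 mild AD.

    Sizes, sex counts, age distributions and screening windows follow the
    study sample; the remaining distributions (education, FAB, HDRS, binary
    management flags, within-window MMSE/MoCA shapes) are this package's
    defaults, ordered by clinical severity.
    """
    control = GroupSpec(
        label="Control", n=107, n_female=78,
        age_mean=74.06, age_sd=6.8,
        mmse_range=(28, 30), moca_range=(27, 30),
        mmse_mean=29.0, mmse_sd=1.0, moca_mean=28.0, moca_sd=1.2,
        fab_mean=16.5, fab_sd=1.2, hdrs_mean=3.0,
        education_mean=9.0, education_sd=4.0,
        p_comorbidity=0.30, p_treatment=0.02, p_rehabilitation=0.00,
    )
    mci = GroupSpec(
        label="MCI", n=77, n_female=54,
        age_mean=75.53, age_sd=7.3,
        mmse_range=(18, 28), moca_range=(10, 26),
        mmse_mean=25.0, mmse_sd=2.0, moca_mean=22.0, moca_sd=3.0,
        fab_mean=13.5, fab_sd=2.0, hdrs_mean=8.0,
        education_mean=9.0, education_sd=4.0,
        p_comorbidity=0.55, p_treatment=0.40, p_rehabilitation=0.30,
    )
    ad = GroupSpec(
        label="AD", n=30, n_female=19,
        age_mean=76.33, age_sd=6.4,
        mmse_range=(18, 28), moca_range=(4, 22),
        mmse_mean=21.0, mmse_sd=2.5, moca_mean=15.0, moca_sd=4.0,
        fab_mean=10.5, fab_sd=2.5, hdrs_mean=6.0,
        education_mean=9.0, education_sd=4.0,
        p_comorbidity=0.70, p_treatment=0.80, p_rehabilitation=0.50,
    )
    return CohortConfig(groups=(control, mci, ad), seed=seed)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _discrete_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                               lo: int, hi: int, size: int) -> np.ndarray:
    """Integer scores: round a truncated normal, rejecting rounds outside [lo, hi]."""
    # Widen the continuous window by 0.5 so the boundary integers stay reachable.
    cont = _truncated_normal(rng, mean, sd, lo - 0.499, hi + 0.499, size)
    return np.clip(np.rint(cont), lo, hi).astype(int)


def _generate_group(spec: GroupSpec, rng: np.random.Generator,
                    id_offset: int) -> pd.DataFrame:
    n = spec.n
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *AGE_BOUNDS, size=n)
    education = _truncated_normal(
        rng, spec.education_mean, spec.education_sd, *EDUCATION_BOUNDS, size=n)
    # Sex by exact counts (the study reports exact per-group tallies), shuffled.
    sex = np.array(["F"] * spec.n_female + ["M"] * (n - spec.n_female))
    sex = rng.permutation(sex)
    mmse = _discrete_truncated_normal(
        rng, spec.mmse_mean, spec.mmse_sd, *spec.mmse_range, size=n)
    moca = _discrete_truncated_normal(
        rng, spec.moca_mean, spec.moca_sd, *spec.moca_range, size=n)
    fab = _discrete_truncated_normal(
        rng, spec.fab_mean, spec.fab_sd, *FAB_SCALE, size=n)
    hdrs = np.clip(rng.poisson(spec.hdrs_mean, size=n), *HDRS_SCALE).astype(int)
    return pd.DataFrame({
        "id": [f"S{id_offset + k:04d}" for k in range(n)],
        "diagnosis": spec.label,
        "age": age,
        "education": education,
        "sex": sex,
        "mmse": mmse,
        "moca": moca,
        "fab": fab,
        "hdrs": hdrs,
        "comorbidity": (rng.random(n) < spec.p_comorbidity).astype(int),
        "treatment": (rng.random(n) < spec.p_treatment).astype(int),
        "rehabilitation": (rng.random(n) < spec.p_rehabilitation).astype(int),
    })


def generate_cohort(config: CohortConfig | None = None, *,
                    seed: int | None = None) -> CohortTable:
    """Draw a full synthetic cohort.

    Deterministic under a fixed ``config.seed`` (``seed`` overrides it).  Every
    generated record satisfies :func:`apply_inclusion_criteria` by
    construction, because scores are sampled inside their inclusion windows.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for spec in config.groups:
        frames.append(_generate_group(spec, rng, id_offset=offset))
        offset += spec.n
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=COHORT_COLUMNS)
    records = records[COHORT_COLUMNS]
    provenance = {
        "seed": config.seed,
        "groups": [dataclasses.asdict(g) for g in config.groups],
    }
    return CohortTable(records=records, provenance=provenance)


def apply_inclusion_criteria(table: CohortTable) -> CohortTable:
    """Screen a cohort with the study's score-based inclusion rules.

    Patients (MCI or AD) require 18 <= MMSE <= 28; Controls require MMSE >= 28
    and MoCA > 26 (both windows deliberately admit MMSE = 28, mirroring the
    stated criteria).  Record order is preserved.
    """
    df = table.records
    required = {"diagnosis", "mmse", "moca"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"cohort table missing columns: {sorted(missing)}")
    is_control = df["diagnosis"] == "Control"
    keep_patient = ~is_control & (df["mmse"] >= 18) & (df["mmse"] <= 28)
    keep_control = is_control & (df["mmse"] >= 28) & (df["moca"] > 26)
    kept = df[keep_patient | keep_control].reset_index(drop=True)
    prov = dict(table.provenance)
    prov["screened"] = True
    return CohortTable(records=kept, provenance=prov)


def write_cohort_csv(table: CohortTable, path) -> None:
    table.records.to_csv(path, index=False)


def read_cohort_csv(path) -> CohortTable:
    df = pd.read_csv(path, dtype={"sex": str, "diagnosis": str, "id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"cohort CSV missing columns: {sorted(missing)}")
    return CohortTable(records=df[COHORT_COLUMNS], provenance={"source": str(path)})
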