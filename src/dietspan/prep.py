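"""Cohort preparation: inclusion/exclusion rules, assessment averaging,
person-years, and outcome coding.

Exclusions are conjunctive and applied in a fixed documented order
(missing sex -> under-assessed -> implausible energy -> prevalent disease
-> missing genotype when the genetic subset is requested); the retained
set is order-invariant, the per-rule counts are not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "ExclusionRules",
    "ExclusionReport",
    "apply_exclusions",
    "average_assessments",
    "person_years",
    "classify_cause",
    "alcohol_category",
    "ALCOHOL_EDGES_FINAL_MODEL",
    "ALCOHOL_EDGES_COARSE",
]

#: Alcohol covariate band edges (g/day, upper-inclusive), finer categorisation
#: used in the final mortality models: 0, 0.1-5, 5.1-10, 10.1-15, 15.1-20,
#: 20.1-30, >30.
ALCOHOL_EDGES_FINAL_MODEL = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0)
#: Coarser alternative: 0, 0.1-10, 10.1-20, 20.1-35, >=35.1.
ALCOHOL_EDGES_COARSE = (0.0, 10.0, 20.0, 35.0)

RULE_ORDER = (
    "missing_sex",
    "under_assessed",
    "implausible_energy",
    "prevalent_disease",
    "missing_genotype",
)


class ExclusionRules(BaseModel):
    """Inclusion/exclusion configuration.

    Energy plausibility bounds are sex-specific and, by default, applied to
    the mean energy across assessments (the averaged exposure); set
    ``per_assessment_energy`` to screen each assessment day instead.
    """

    min_assessments: int = Field(default=2, ge=1)
    energy_bounds: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {"male": (800.0, 4200.0), "female": (600.0, 3500.0)}
    )
    per_assessment_energy: bool = False
    exclude_prevalent: bool = True
    require_genotype: bool = False


@dataclass
class ExclusionReport:
    """Per-rule removal counts; ``retained + sum(removed) == n_input``."""

    n_input: int
    removed: Dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def __post_init__(self):
        total = self.retained + sum(self.removed.values())
        if total != self.n_input:
            raise ValueError(
                f"exclusion report does not reconcile: {self.retained} retained "
                f"+ {sum(self.removed.values())} removed != {self.n_input} input"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "retained": self.retained,
        }


def apply_exclusions(
    participants: pd.DataFrame,
    assessments: pd.DataFrame,
    rules: ExclusionRules | None = None,
    genotypes: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study's inclusion rules; return retained participants + report.

    Participants with missing sex are routed to an explicit ``missing_sex``
    bucket (never silently kept). Prevalent cardiovascular disease or cancer
    at the last assessment excludes; energy plausibility is sex-specific.
    """
    if rules is None:
        rules = ExclusionRules()
    df = participants.copy()
    n_input = len(df)
    removed: Dict[str, int] = {r: 0 for r in RULE_ORDER}

    def drop(mask: np.ndarray, rule: str):
        nonlocal df
        removed[rule] += int(mask.sum())
        df = df.loc[~mask]

    sex_missing = df["sex"].isna() | ~df["sex"].isin(["male", "female"])
    drop(sex_missing.to_numpy(), "missing_sex")

    counts = assessments.groupby("pid").size()
    n_assess = df["pid"].map(counts).fillna(0).astype(int)
    drop((n_assess < rules.min_assessments).to_numpy(), "under_assessed")

    if "energy_kcal" in assessments.columns:
        if rules.per_assessment_energy:
            grp = assessments.groupby("pid")["energy_kcal"]
            lo_e, hi_e = grp.min(), grp.max()
        else:
            mean_e = assessments.groupby("pid")["energy_kcal"].mean()
            lo_e = hi_e = mean_e
        lo = df["pid"].map(lo_e)
        hi = df["pid"].map(hi_e)
        bad = np.zeros(len(df), dtype=bool)
        for s, (b_lo, b_hi) in rules.energy_bounds.items():
            m = (df["sex"] == s).to_numpy()
            bad |= m & ((lo.to_numpy() < b_lo) | (hi.to_numpy() > b_hi))
        drop(bad, "implausible_energy")

    if rules.exclude_prevalent:
        prev = np.zeros(len(df), dtype=bool)
        for col in ("prevalent_cvd", "prevalent_cancer"):
            if col in df.columns:
                prev |= df[col].fillna(False).to_numpy(dtype=bool)
        drop(prev, "prevalent_disease")

    if rules.require_genotype:
        if genotypes is None:
            raise ValueError("require_genotype=True but no genotype table given")
        have = df["pid"].isin(genotypes["pid"]).to_numpy()
        snp_cols = [c for c in genotypes.columns if c != "pid"]
        complete = genotypes.set_index("pid")[snp_cols].notna().all(axis=1)
        ok = have & df["pid"].map(complete).fillna(False).to_numpy(dtype=bool)
        drop(~ok, "missing_genotype")

    report = ExclusionReport(
        n_input=n_input,
        removed={k: v for k, v in removed.items() if v > 0},
        retained=len(df),
    )
    return df.reset_index(drop=True), report


def average_assessments(assessments: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean intake per participant across dietary assessments.

    Requires >= 2 assessments per participant (single-assessment rows should
    have been excluded upstream). A missing nutrient value on one day is
    averaged over the non-missing days and flagged in ``any_missing``.
    """
    counts = assessments.groupby("pid").size()
    single = counts[counts < 2]
    if len(single):
        raise ValueError(
            f"{len(single)} participant(s) with <2 assessments reached averaging "
            f"(e.g. pid={single.index[0]}); apply exclusions first"
        )
    value_cols = [c for c in assessments.columns if c not in ("pid", "assessment")]
    g = assessments.groupby("pid")[value_cols]
    profile = g.mean()  # skips NaN per column
    profile["any_missing"] = assessments[value_cols].isna().groupby(
        assessments["pid"]
    ).any().any(axis=1)
    return profile.reset_index()


def person_years(
    baseline_date,
    death_date=None,
    loss_date=None,
    admin_end="2022-11-30",
) -> Tuple[float, bool]:
    """Follow-up duration (365.25-day years) and all-cause event flag.

    Follow-up runs from the most recent dietary assessment (baseline) to
    death, loss to follow-up, or the administrative censoring date,
    whichever comes first; the event flag is true iff death is earliest.
    """
    baseline = pd.Timestamp(baseline_date)
    admin = pd.Timestamp(admin_end)
    death = pd.Timestamp(death_date) if death_date is not None else None
    loss = pd.Timestamp(loss_date) if loss_date is not None else None

    if death is not None and death < baseline:
        raise ValueError(
            f"death date {death.date()} precedes baseline {baseline.date()}: "
            "corrupt record"
        )
    if baseline > admin:
        raise ValueError(
            f"baseline {baseline.date()} after administrative end {admin.date()}"
        )
    candidates = [admin]
    if death is not None:
        candidates.append(death)
    if loss is not None:
        candidates.append(loss)
    end = min(candidates)
    years = (end - baseline).days / 365.25
    event = death is not None and death == end and (loss is None or death <= loss)
    # death after admin end (or after loss) is censored, not an event
    if death is not None and death > end:
        event = False
    return years, bool(event)


_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")

_CAUSE_RANGES = {
    "I": ("CVD", (0, 99)),
    "C": ("cancer", (0, 97)),
    "G": ("neurodegenerative", (0, 99)),
    "J": ("respiratory", (0, 99)),
}


def classify_cause(icd10_code: str) -> str:
    """Map an ICD-10 underlying-cause code to a broad cause class.

    I00–I99 cardiovascular, C00–C97 cancer, G00–G99 neurodegenerative,
    J00–J99 respiratory; everything else is "other".
    """
    if not isinstance(icd10_code, str):
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    m = _ICD10_RE.match(icd10_code.strip().upper())
    if not m:
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    letter, num = m.group(1), int(m.group(2))
    if letter in _CAUSE_RANGES:
        cls, (lo, hi) = _CAUSE_RANGES[letter]
        if lo <= num <= hi:
            return cls
    return "other"


def alcohol_category(grams_per_day: float, edges=ALCOHOL_EDGES_FINAL_MODEL) -> str:
    """Alcohol consumption band label for covariate adjustment.

    ``edges`` are upper-inclusive cut points after the zero category; the
    default is the finer banding used in the fully adjusted models.
    """
    g = float(grams_per_day)
    if g < 0:
        raise ValueError(f"negative alcohol intake: {g}")
    if g == 0:
        return "0"
    prev = 0.0
    for e in edges[1:]:
        if g <= e:
            return f"{prev + 0.1:g}-{e:g}"
        prev = e
    return f">{edges[-1]:g}"
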