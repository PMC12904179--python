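"""Life-table engine: from population mortality, exposure-group hazard
ratios and exposure prevalence to group-specific life expectancy and years
of life gained.

The population table gives sex- and single-year-of-age death probabilities
q(a,s). Hazard ratios act on rates, not probabilities, so each q is first
converted to a central rate m = -ln(1-q). With group prevalences p_g(a,s)
(10-year bands expanded to single years by piecewise-constant
interpolation), the reference-group rate solves

    m_ref(a,s) = m(a,s) / sum_g p_g(a,s) * HR_g,

group rates are m_g = HR_g * m_ref, and group probabilities q_g =
1 - exp(-m_g); the prevalence-weighted group rates reproduce the population
rate exactly at every age. Life expectancy at a start age accumulates
cumulative survival with a half-year credit in the year of death, the table
closing at age 100. Confidence intervals propagate HR uncertainty by Monte
Carlo: log-HRs are drawn from the normal distributions implied by each HR's
CI (independent across groups by default; a correlation hook accepts a
log-HR covariance matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "validate_life_table",
    "validate_prevalence",
    "expand_prevalence",
    "reference_hazard",
    "group_death_probabilities",
    "life_expectancy",
    "years_gained",
    "ci_monte_carlo",
    "run_life_expectancy",
    "LifeExpectancyResult",
]

TERMINAL_AGE = 100


def validate_life_table(life_table: pd.DataFrame) -> pd.DataFrame:
    need = {"sex", "age", "qx"}
    if not need.issubset(life_table.columns):
        raise ValueError(f"life table needs columns {sorted(need)}")
    q = life_table["qx"].to_numpy(dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("life-table qx values must lie strictly in (0, 1)")
    for s, grp in life_table.groupby("sex"):
        ages = np.sort(grp["age"].to_numpy())
        if np.any(np.diff(ages) != 1):
            raise ValueError(f"life table for sex={s} has non-contiguous ages")
    return life_table


def validate_prevalence(prevalence: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    need = {"sex", "age_band", "group", "prevalence"}
    if not need.issubset(prevalence.columns):
        raise ValueError(f"prevalence table needs columns {sorted(need)}")
    sums = prevalence.groupby(["sex", "age_band"])["prevalence"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        key = bad.index[0]
        raise ValueError(
            f"prevalences do not sum to 1 for sex={key[0]}, band={key[1]} "
            f"(sum={bad.iloc[0]:.12f})"
        )
    groups = set(prevalence["group"])
    for (s, b), grp in prevalence.groupby(["sex", "age_band"]):
        missing = groups - set(grp["group"])
        if missing:
            raise ValueError(
                f"group(s) {sorted(map(str, missing))} absent from sex={s}, "
                f"band={b}; include them with prevalence 0"
            )
    return prevalence


def expand_prevalence(prevalence: pd.DataFrame, ages: np.ndarray, sex) -> pd.DataFrame:
    """Piecewise-constant expansion of banded prevalence to single years.

    ``age_band`` holds the first age of each 10-year band; each age maps to
    the band with the largest start not exceeding it.
    """
    sub = prevalence[prevalence["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no prevalence rows for sex={sex}")
    bands = np.sort(sub["age_band"].unique())
    idx = np.searchsorted(bands, ages, side="right") - 1
    if np.any(idx < 0):
        raise ValueError(
            f"age {ages[idx < 0].min()} precedes the first prevalence band "
            f"({bands[0]}) for sex={sex}"
        )
    wide = sub.pivot(index="age_band", columns="group", values="prevalence")
    out = wide.loc[bands[idx]].reset_index(drop=True)
    out.insert(0, "age", ages)
    return out


def _hr_map(hrs, sex) -> pd.Series:
    """Group -> HR for one sex, from a dict or a (sex, group, hr) frame."""
    if isinstance(hrs, dict):
        return pd.Series(hrs, dtype=float)
    df = hrs
    if "sex" in df.columns and df["sex"].nunique() > 1:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no hazard ratios for sex={sex}")
    return df.set_index("group")["hr"].astype(float)


def reference_hazard(
    life_table: pd.DataFrame,
    prevalence: pd.DataFrame,
    hrs,
    sex,
    ages: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Reference-group annual rates and per-group death probabilities.

    Returns a frame with one row per age: ``m`` (population rate), ``m_ref``,
    and one ``q_<group>`` column per exposure group. The prevalence-weighted
    group rates reproduce the population rate exactly (checked to 1e-9).
    """
    validate_life_table(life_table)
    validate_prevalence(prevalence)
    lt = life_table[life_table["sex"] == sex].set_index("age")["qx"].sort_index()
    if ages is None:
        # group-specific mortality is defined only from the first prevalence band
        first_band = int(prevalence.loc[prevalence["sex"] == sex, "age_band"].min())
        ages = lt.index.to_numpy()
        ages = ages[ages >= first_band]
    missing = np.setdiff1d(ages, lt.index.to_numpy())
    if missing.size:
        raise ValueError(f"life table for sex={sex} lacks age(s) {missing.tolist()}")
    q = lt.loc[ages].to_numpy(dtype=float)
    m = -np.log1p(-q)

    prev = expand_prevalence(prevalence, np.asarray(ages), sex)
    groups = [c for c in prev.columns if c != "age"]
    hr = _hr_map(hrs, sex)
    missing_hr = [g for g in groups if g not in hr.index]
    if missing_hr:
        raise ValueError(f"no hazard ratio for group(s) {missing_hr}")
    P = prev[groups].to_numpy(dtype=float)
    h = hr.loc[groups].to_numpy(dtype=float)

    denom = P @ h
    m_ref = m / denom
    M = np.outer(m_ref, h)  # age x group rates
    # marginal conservation: sum_g p_g m_g == m
    recon = np.einsum("ag,ag->a", P, M)
    if not np.allclose(recon, m, rtol=0, atol=1e-9 * (1 + np.abs(m).max())):
        raise AssertionError("marginal mortality not conserved")
    Q = -np.expm1(-M)
    bad = np.argwhere(Q >= 1.0)
    if bad.size:
        a_i, g_i = bad[0]
        raise ValueError(
            f"scaled death probability reaches 1 at age {ages[a_i]}, sex={sex}, "
            f"group={groups[g_i]}; hazard ratio too large for this table"
        )
    out = pd.DataFrame({"age": ages, "m": m, "m_ref": m_ref})
    for j, g in enumerate(groups):
        out[f"q_{g}"] = Q[:, j]
    return out


def group_death_probabilities(life_table, prevalence, hrs, sex) -> pd.DataFrame:
    """Per-(age, group) death probabilities in long form."""
    wide = reference_hazard(life_table, prevalence, hrs, sex)
    qcols = [c for c in wide.columns if c.startswith("q_")]
    long = wide.melt(
        id_vars="age", value_vars=qcols, var_name="group", value_name="qx"
    )
    gmap = {f"q_{g}": g for g in prevalence["group"].unique()}
    long["group"] = long["group"].map(gmap)
    return long


def life_expectancy(q_by_age: pd.Series, start_age: int) -> float:
    """Period life expectancy from single-year death probabilities.

    LE = sum_{a=start}^{100} S(a) * (1 - q(a)/2) with S(start) = 1 and
    S(a) the probability of surviving from the start age to age a; the
    half-year term credits deaths mid-year, and the table closes at 100.
    """
    q = q_by_age.sort_index()
    ages = q.index.to_numpy()
    need = np.arange(start_age, TERMINAL_AGE + 1)
    missing = np.setdiff1d(need, ages)
    if missing.size:
        raise ValueError(
            f"death probabilities missing for age(s) {missing.tolist()}"
        )
    qa = q.loc[need].to_numpy(dtype=float)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - qa[:-1])])
    return float(np.sum(surv * (1.0 - qa / 2.0)))


def years_gained(le_group: float, le_reference: float) -> float:
    """Difference in life expectancy vs the reference group."""
    return le_group - le_reference


@dataclass
class LifeExpectancyResult:
    """Life expectancy and years gained per (sex, group, start age)."""

    table: pd.DataFrame
    n_draws: int
    seed: int
    warnings: list = field(default_factory=list)


def _log_hr_se(row) -> float:
    return (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.959963984540054)


def ci_monte_carlo(
    hrs: pd.DataFrame,
    life_table: pd.DataFrame,
    prevalence: pd.DataFrame,
    sex,
    start_age: int,
    reference,
    n_draws: int = 1000,
    seed: int = 0,
    log_hr_cov: Optional[np.ndarray] = None,
):
    """Percentile CIs for group life expectancy and years gained.

    Log-HRs are drawn from normals implied by each group's CI (the reference
    group stays at HR 1). ``log_hr_cov`` optionally supplies a covariance
    matrix over the non-reference groups' log-HRs; the default is
    independence. Deterministic given ``seed``.
    """
    warnings = []
    if n_draws < 100:
        warnings.append(f"n_draws={n_draws} < 100: CI bounds will be unstable")
    hr_sex = hrs
    if "sex" in hrs.columns and hrs["sex"].nunique() > 1:
        hr_sex = hrs[hrs["sex"] == sex]
    hr_sex = hr_sex.set_index("group")
    groups = hr_sex.index.tolist()
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in HR table")
    nonref = [g for g in groups if g != reference]
    mu = np.log(hr_sex.loc[nonref, "hr"].to_numpy(dtype=float))
    se = np.array([_log_hr_se(hr_sex.loc[g]) for g in nonref])
    if np.any(~np.isfinite(se)) or np.any(se < 0):
        raise ValueError("invalid CI bounds in HR table")

    rng = np.random.default_rng(seed)
    if log_hr_cov is not None:
        draws = rng.multivariate_normal(mu, log_hr_cov, size=n_draws)
    else:
        draws = mu + se * rng.standard_normal((n_draws, len(nonref)))

    le_draws = {g: np.empty(n_draws) for g in groups}
    for d in range(n_draws):
        hr_d = {reference: 1.0}
        hr_d.update({g: float(np.exp(draws[d, j])) for j, g in enumerate(nonref)})
        wide = reference_hazard(life_table, prevalence, hr_d, sex)
        for g in groups:
            qs = pd.Series(
                wide[f"q_{g}"].to_numpy(), index=wide["age"].to_numpy()
            )
            le_draws[g][d] = life_expectancy(qs, start_age)

    rows = []
    for g in groups:
        le = le_draws[g]
        gain = le - le_draws[reference]
        rows.append(
            {
                "group": g,
                "le_ci_low": float(np.percentile(le, 2.5)),
                "le_ci_high": float(np.percentile(le, 97.5)),
                "gain_ci_low": float(np.percentile(gain, 2.5)),
                "gain_ci_high": float(np.percentile(gain, 97.5)),
            }
        )
    return pd.DataFrame(rows), warnings


def run_life_expectancy(
    life_table: pd.DataFrame,
    prevalence: pd.DataFrame,
    hrs: pd.DataFrame,
    reference,
    sexes: Sequence[str] = ("male", "female"),
    start_ages: Sequence[int] = (45, 50, 55, 60),
    n_draws: int = 1000,
    seed: int = 0,
) -> LifeExpectancyResult:
    """Life expectancy and years gained for every (sex, group, start age).

    Point estimates use the HR point estimates; CIs come from
    :func:`ci_monte_carlo`. The reference group's years gained are
    identically 0 with a zero-width CI.
    """
    all_rows = []
    all_warnings = []
    root = np.random.SeedSequence(seed)
    children = iter(root.generate_state(len(sexes) * len(start_ages) * 2))
    for sex in sexes:
        point = group_death_probabilities(life_table, prevalence, hrs, sex)
        for start_age in start_ages:
            le_point = {}
            for g, grp in point.groupby("group"):
                qs = pd.Series(grp["qx"].to_numpy(), index=grp["age"].to_numpy())
                le_point[g] = life_expectancy(qs, start_age)
            ci, warn = ci_monte_carlo(
                hrs, life_table, prevalence, sex, start_age, reference,
                n_draws=n_draws, seed=int(next(children) % (2**31 - 1)),
            )
            all_warnings.extend(warn)
            ci = ci.set_index("group")
            for g, le in le_point.items():
                gain = years_gained(le, le_point[reference])
                row = {
                    "sex": sex,
                    "group": g,
                    "start_age": start_age,
                    "life_expectancy": le,
                    "years_gained": gain,
                }
                if g == reference:
                    row.update(
                        le_ci_low=ci.loc[g, "le_ci_low"],
                        le_ci_high=ci.loc[g, "le_ci_high"],
                        gain_ci_low=0.0,
                        gain_ci_high=0.0,
                    )
                else:
                    row.update(
                        le_ci_low=ci.loc[g, "le_ci_low"],
                        le_ci_high=ci.loc[g, "le_ci_high"],
                        gain_ci_low=ci.loc[g, "gain_ci_low"],
                        gain_ci_high=ci.loc[g, "gain_ci_high"],
                    )
                all_rows.append(row)
    table = pd.DataFrame(all_rows)
    return LifeExpectancyResult(
        table=table, n_draws=n_draws, seed=seed, warnings=all_warnings
    )
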