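"""Proportional-hazards estimation of diet- and PRS-mortality associations.

Wraps lifelines' Cox partial-likelihood machinery (Efron tie handling)
behind the analysis' model vocabulary:

* quintile models with the lowest quintile as reference, with events and
  person-years per level;
* trend tests coding each participant at their quintile's median score;
* per-SD continuous effects;
* restricted-cubic-spline dose-response curves (3 knots at the 10th/50th/
  90th percentiles) with a Wald test of nonlinearity;
* multiplicative (likelihood-ratio) and additive (RERI, delta-method CI)
  diet-by-PRS interaction;
* the 15-cell joint classification (diet quintile x PRS tertile);
* stratified, food-group (per SD), leave-one-out substitution and
  cause-specific fits.

Two covariate sets are available: "model1" (age, sex) and "model2" (model1
plus ethnicity, education, deprivation quintile, assessment centre, smoking,
physical activity, BMI class, total energy, prevalent dyslipidemia/
hypertension/diabetes, PRS tertile, 10 ancestry components and genotyping
batch; alcohol bands for the indices without an alcohol component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from ._ranks import quantile_groups
from .specs import ALCOHOL_ADJUSTED_INDICES

__all__ = [
    "ModelSpec",
    "HazardRatioSet",
    "InteractionResult",
    "fit_cox",
    "trend_test",
    "quintile_medians",
    "rcs_basis",
    "spline_dose_response",
    "interaction_analysis",
    "reri_from_hrs",
    "joint_groups",
    "stratified_analysis",
    "food_group_effects",
    "leave_one_out_substitution",
    "cause_specific_fit",
    "schoenfeld_check",
]

Z95 = stats.norm.ppf(0.975)

MODEL2_CATEGORICAL = (
    "ethnicity", "education", "tdi_quintile", "centre", "smoking",
    "physical_activity", "bmi_class", "prs_tertile", "alcohol_cat",
)
MODEL2_CONTINUOUS = ("energy_kcal", "genotyping_batch") + tuple(
    f"pc{k}" for k in range(1, 11)
)
MODEL2_BINARY = ("dyslipidemia", "hypertension", "diabetes")


@dataclass
class ModelSpec:
    """Exposure and adjustment choices for one Cox fit."""

    index: Optional[str] = None
    covariates: Literal["model1", "model2"] = "model2"
    alcohol_adjust: Optional[bool] = None  # default: on iff index lacks alcohol
    exclude: Tuple[str, ...] = ()
    duration_col: str = "time_years"
    event_col: str = "event"

    def wants_alcohol(self) -> bool:
        if self.alcohol_adjust is not None:
            return self.alcohol_adjust
        return self.index in ALCOHOL_ADJUSTED_INDICES


@dataclass
class HazardRatioSet:
    """Group-labelled hazard ratios with trend and per-SD effects."""

    index: str
    levels: pd.DataFrame  # level, hr, ci_low, ci_high, n, n_events, person_years
    p_trend: Optional[float] = None
    per_sd_hr: Optional[float] = None
    per_sd_ci: Optional[Tuple[float, float]] = None
    level_medians: Dict = field(default_factory=dict)

    def hr_table(self) -> pd.DataFrame:
        t = self.levels.copy()
        t.insert(0, "index", self.index)
        return t


@dataclass
class InteractionResult:
    """Multiplicative (LRT) and additive (RERI) diet-by-PRS interaction."""

    index: str
    p_multiplicative: float
    reri: float
    reri_ci: Tuple[float, float]
    hr10: float  # high diet, low PRS
    hr01: float  # low diet, high PRS
    hr11: float  # high diet, high PRS
    stratum_hrs: Dict[str, HazardRatioSet] = field(default_factory=dict)


def reri_from_hrs(hr10: float, hr01: float, hr11: float) -> float:
    """Relative excess risk due to interaction: HR11 - HR10 - HR01 + 1."""
    return hr11 - hr10 - hr01 + 1.0


# --- design-matrix plumbing ----------------------------------------------

def covariate_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Numeric covariate columns for the requested adjustment set.

    Categorical covariates become dummy indicators (first level dropped);
    "unknown" is an ordinary level, never dropped as missing. Covariates
    absent from the cohort, constant columns and excluded names are skipped.
    """
    cols = {}
    if "age" in cohort.columns:
        cols["age"] = cohort["age"].astype(float)
    if "sex" in cohort.columns:
        cols["sex_male"] = (cohort["sex"] == "male").astype(float)
    if spec.covariates == "model2":
        for c in MODEL2_CONTINUOUS:
            if c in cohort.columns and c not in spec.exclude:
                cols[c] = cohort[c].astype(float)
        for c in MODEL2_BINARY:
            if c in cohort.columns and c not in spec.exclude:
                cols[c] = cohort[c].astype(float)
        for c in MODEL2_CATEGORICAL:
            if c == "alcohol_cat" and not spec.wants_alcohol():
                continue
            if c in cohort.columns and c not in spec.exclude:
                d = pd.get_dummies(
                    cohort[c].astype(str), prefix=c, drop_first=True, dtype=float
                )
                for name in d.columns:
                    cols[name] = d[name]
    X = pd.DataFrame(cols, index=cohort.index)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _fit(df: pd.DataFrame, spec: ModelSpec) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=spec.duration_col, event_col=spec.event_col)
    except ConvergenceError as e:
        raise RuntimeError(
            "Cox model failed to converge; check for collinear or separated "
            f"covariates. lifelines reported: {e}"
        ) from e
    return cph


def _base_frame(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = covariate_matrix(cohort, spec)
    df[spec.duration_col] = cohort[spec.duration_col].astype(float)
    df[spec.event_col] = cohort[spec.event_col].astype(float)
    return df


def _level_summary(cohort, groups, labels, spec) -> pd.DataFrame:
    rows = []
    for lab in labels:
        m = groups == lab
        rows.append(
            {
                "level": lab,
                "n": int(m.sum()),
                "n_events": int(cohort.loc[m, spec.event_col].sum()),
                "person_years": float(cohort.loc[m, spec.duration_col].sum()),
            }
        )
    return pd.DataFrame(rows)


def _check_events_per_level(summary: pd.DataFrame):
    empty = summary.loc[summary["n_events"] == 0, "level"].tolist()
    if empty:
        raise ValueError(
            f"exposure level(s) {empty} have zero events; merge levels or "
            "enlarge the cohort"
        )


def _hr_ci(cph: CoxPHFitter, term: str) -> Tuple[float, float, float]:
    b = cph.params_[term]
    se = cph.standard_errors_[term]
    return math.exp(b), math.exp(b - Z95 * se), math.exp(b + Z95 * se)


def quintile_medians(score: pd.Series, groups: np.ndarray) -> Dict[int, float]:
    """Median score within each quintile group."""
    return {
        int(q): float(np.median(score.to_numpy()[groups == q]))
        for q in np.unique(groups)
    }


# --- primary fits ---------------------------------------------------------

def fit_cox(
    cohort: pd.DataFrame,
    score,
    spec: Optional[ModelSpec] = None,
    n_groups: int = 5,
) -> HazardRatioSet:
    """Quantile-group Cox model with trend and per-SD effects.

    ``score`` is a column name or a Series aligned with ``cohort``. The
    exposure is cut into ``n_groups`` cohort quantile groups (quintiles by
    default; lowest = reference); the trend test codes each participant at
    their group's median score; the per-SD effect standardises the raw
    score by its sample SD.
    """
    spec = spec or ModelSpec()
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    name = spec.index or (score if isinstance(score, str) else "score")

    groups = quantile_groups(s.to_numpy(), n_groups)
    all_levels = list(range(1, n_groups + 1))
    summary = _level_summary(cohort, groups, all_levels, spec)
    _check_events_per_level(summary)

    df = _base_frame(cohort, spec)
    for q in all_levels[1:]:
        df[f"q{q}"] = (groups == q).astype(float)
    cph = _fit(df, spec)

    rows = [{"level": 1, "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan}]
    for q in all_levels[1:]:
        hr, lo, hi = _hr_ci(cph, f"q{q}")
        rows.append({"level": q, "hr": hr, "ci_low": lo, "ci_high": hi})
    levels = pd.DataFrame(rows).merge(summary, on="level")

    medians = quintile_medians(s, groups)
    df_tr = _base_frame(cohort, spec)
    df_tr["trend"] = np.vectorize(medians.get)(groups)
    p_trend = float(_fit(df_tr, spec).summary.loc["trend", "p"])

    df_sd = _base_frame(cohort, spec)
    df_sd["per_sd"] = (s - s.mean()) / s.std(ddof=1)
    hr_sd, lo_sd, hi_sd = _hr_ci(_fit(df_sd, spec), "per_sd")

    return HazardRatioSet(
        index=name,
        levels=levels,
        p_trend=p_trend,
        per_sd_hr=hr_sd,
        per_sd_ci=(lo_sd, hi_sd),
        level_medians=medians,
    )


def trend_test(cohort: pd.DataFrame, score, spec: Optional[ModelSpec] = None) -> float:
    """Wald p for the quintile-median-coded continuous exposure term."""
    spec = spec or ModelSpec()
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    groups = quantile_groups(s.to_numpy(), 5)
    medians = quintile_medians(s, groups)
    df = _base_frame(cohort, spec)
    df["trend"] = np.vectorize(medians.get)(groups)
    return float(_fit(df, spec).summary.loc["trend", "p"])


# --- splines --------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear in the tails).

    For knots t_1 < ... < t_k this returns k-1 columns: x itself plus k-2
    nonlinear terms

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.size < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("need at least 3 strictly increasing knots")
    k = t.size

    def plus3(u):
        return np.clip(u, 0.0, None) ** 3

    denom = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / denom
        cols.append(term)
    return np.column_stack(cols)


def spline_dose_response(
    cohort: pd.DataFrame,
    score,
    spec: Optional[ModelSpec] = None,
    n_grid: int = 60,
    reference: Optional[float] = None,
):
    """Dose-response curve on the log-HR scale with a nonlinearity test.

    Knots sit at the 10th/50th/90th score percentiles; the curve is
    referenced to ``reference`` (default: the cohort median score). Returns
    ``(curve, p_nonlinear)`` where ``curve`` has columns score, log_hr,
    ci_low, ci_high.
    """
    spec = spec or ModelSpec()
    s = cohort[score] if isinstance(score, str) else score
    s = np.asarray(s, dtype=float)
    knots = np.percentile(s, [10, 50, 90])
    if np.unique(knots).size < 3:
        raise ValueError("degenerate score distribution: knots coincide")
    basis = rcs_basis(s, knots)
    names = ["rcs_lin", "rcs_nl1"]
    df = _base_frame(cohort, spec)
    for name, col in zip(names, basis.T):
        df[name] = col
    cph = _fit(df, spec)

    p_nonlinear = float(cph.summary.loc["rcs_nl1", "p"])

    ref = float(np.median(s)) if reference is None else float(reference)
    grid = np.linspace(np.percentile(s, 1), np.percentile(s, 99), n_grid)
    B = rcs_basis(grid, knots) - rcs_basis(np.full(n_grid, ref), knots)
    beta = cph.params_[names].to_numpy()
    cov = cph.variance_matrix_.loc[names, names].to_numpy()
    log_hr = B @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", B, cov, B))
    curve = pd.DataFrame(
        {
            "score": grid,
            "log_hr": log_hr,
            "ci_low": log_hr - Z95 * se,
            "ci_high": log_hr + Z95 * se,
        }
    )
    return curve, p_nonlinear


# --- interaction, joint, stratified ---------------------------------------

def _ordinal_groups(values, k):
    return quantile_groups(np.asarray(values, dtype=float), k)


_TERTILE_ORD = {"low": 1, "intermediate": 2, "high": 3}


def _tertile_ordinal(tertiles: pd.Series) -> np.ndarray:
    t = np.asarray(tertiles)
    if np.issubdtype(t.dtype, np.number):
        return t.astype(int)
    try:
        return np.array([_TERTILE_ORD[v] for v in t])
    except KeyError as e:
        raise ValueError(f"unknown PRS tertile label {e.args[0]!r}") from None


def interaction_analysis(
    cohort: pd.DataFrame,
    score,
    prs_tertile="prs_tertile",
    spec: Optional[ModelSpec] = None,
    include_strata: bool = True,
) -> InteractionResult:
    """Multiplicative (LRT) and additive (RERI) interaction of diet with PRS.

    Multiplicative: likelihood-ratio test between the adjusted model with
    and without an ordinal(diet quintile) x ordinal(PRS tertile) product
    term. Additive: RERI computed from a joint model on the extreme 2x2
    (top vs bottom diet quintile, high vs low PRS tertile; middle categories
    excluded from the 2x2 view), with a delta-method CI from the coefficient
    covariance. PRS is removed from the covariate set (it is the modifier).
    """
    base = spec or ModelSpec()
    spec = ModelSpec(
        index=base.index, covariates=base.covariates,
        alcohol_adjust=base.alcohol_adjust,
        exclude=tuple(set(base.exclude) | {"prs_tertile"}),
        duration_col=base.duration_col, event_col=base.event_col,
    )
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    tert = cohort[prs_tertile] if isinstance(prs_tertile, str) else prs_tertile
    t_ord = _tertile_ordinal(tert)
    q = _ordinal_groups(s, 5)

    # multiplicative LRT
    df0 = _base_frame(cohort, spec)
    df0["diet_q"] = q.astype(float)
    df0["prs_t"] = t_ord.astype(float)
    ll0 = _fit(df0, spec).log_likelihood_
    df1 = df0.copy()
    df1["diet_x_prs"] = df0["diet_q"] * df0["prs_t"]
    ll1 = _fit(df1, spec).log_likelihood_
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p_mult = float(stats.chi2.sf(lr, df=1))

    # additive RERI on the extreme 2x2
    keep = ((q == 1) | (q == 5)) & ((t_ord == 1) | (t_ord == 3))
    sub = cohort.loc[keep]
    x1 = (q[keep] == 5).astype(float)  # favourable diet
    x2 = (t_ord[keep] == 3).astype(float)  # favourable PRS
    df2 = _base_frame(sub, spec)
    df2["diet_high"] = x1
    df2["prs_high"] = x2
    df2["both"] = x1 * x2
    cph = _fit(df2, spec)
    terms = ["diet_high", "prs_high", "both"]
    b = cph.params_[terms].to_numpy()
    cov = cph.variance_matrix_.loc[terms, terms].to_numpy()
    hr10 = math.exp(b[0])
    hr01 = math.exp(b[1])
    hr11 = math.exp(b.sum())
    reri = reri_from_hrs(hr10, hr01, hr11)
    grad = np.array([hr11 - hr10, hr11 - hr01, hr11])
    var = float(grad @ cov @ grad)
    half = Z95 * math.sqrt(max(var, 0.0))
    reri_ci = (reri - half, reri + half)

    strata: Dict[str, HazardRatioSet] = {}
    if include_strata:
        for label, t_val in _TERTILE_ORD.items():
            m = t_ord == t_val
            if m.sum() == 0:
                continue
            strata[label] = fit_cox(cohort.loc[m], s.loc[m], spec)

    return InteractionResult(
        index=spec.index or "score",
        p_multiplicative=p_mult,
        reri=reri,
        reri_ci=reri_ci,
        hr10=hr10,
        hr01=hr01,
        hr11=hr11,
        stratum_hrs=strata,
    )


def joint_groups(
    cohort: pd.DataFrame,
    score,
    prs_tertile="prs_tertile",
    spec: Optional[ModelSpec] = None,
) -> HazardRatioSet:
    """15-cell joint classification: diet quintile x PRS tertile.

    Reference is the highest-risk combination (lowest diet quintile, low
    PRS); PRS leaves the covariate set.
    """
    base = spec or ModelSpec()
    spec = ModelSpec(
        index=base.index, covariates=base.covariates,
        alcohol_adjust=base.alcohol_adjust,
        exclude=tuple(set(base.exclude) | {"prs_tertile"}),
        duration_col=base.duration_col, event_col=base.event_col,
    )
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    q = _ordinal_groups(s, 5)
    t_ord = _tertile_ordinal(
        cohort[prs_tertile] if isinstance(prs_tertile, str) else prs_tertile
    )
    tert_name = {1: "low", 2: "intermediate", 3: "high"}
    labels = [f"Q{qq}_{tert_name[tt]}" for tt in (1, 2, 3) for qq in (1, 2, 3, 4, 5)]
    cell = np.array([f"Q{qq}_{tert_name[tt]}" for qq, tt in zip(q, t_ord)])

    summary = _level_summary(cohort, cell, labels, spec)
    if int(summary["n"].sum()) != len(cohort):
        raise AssertionError("joint cells do not partition the cohort")
    _check_events_per_level(summary.loc[summary["n"] > 0])

    ref = "Q1_low"
    df = _base_frame(cohort, spec)
    dummy_labels = [lab for lab in labels if lab != ref]
    for lab in dummy_labels:
        df[lab] = (cell == lab).astype(float)
    cph = _fit(df, spec)

    rows = [{"level": ref, "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan}]
    for lab in dummy_labels:
        hr, lo, hi = _hr_ci(cph, lab)
        rows.append({"level": lab, "hr": hr, "ci_low": lo, "ci_high": hi})
    levels = pd.DataFrame(rows).merge(summary, on="level")
    return HazardRatioSet(index=spec.index or "score", levels=levels)


def stratified_analysis(
    cohort: pd.DataFrame,
    score,
    modifier: str,
    spec: Optional[ModelSpec] = None,
):
    """Per-stratum quintile fits plus a pooled LRT interaction p.

    The modifier leaves the covariate set inside each stratum fit; the
    pooled model adds modifier-by-trend product terms for the LRT.
    """
    base = spec or ModelSpec()
    spec = ModelSpec(
        index=base.index, covariates=base.covariates,
        alcohol_adjust=base.alcohol_adjust,
        exclude=tuple(set(base.exclude) | {modifier}),
        duration_col=base.duration_col, event_col=base.event_col,
    )
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    levels = [v for v in pd.unique(cohort[modifier])]
    results: Dict[str, HazardRatioSet] = {}
    for v in levels:
        m = (cohort[modifier] == v).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty stratum {modifier}={v!r}")
        results[str(v)] = fit_cox(cohort.loc[m], s.loc[m], spec)

    p_interaction = None
    if len(levels) > 1:
        q = _ordinal_groups(s, 5).astype(float)
        df0 = _base_frame(cohort, spec)
        df0["diet_q"] = q
        mod_d = pd.get_dummies(
            cohort[modifier].astype(str), prefix="mod", drop_first=True, dtype=float
        )
        for c in mod_d.columns:
            df0[c] = mod_d[c].to_numpy()
        ll0 = _fit(df0, spec).log_likelihood_
        df1 = df0.copy()
        for c in mod_d.columns:
            df1[f"{c}_x_diet"] = df0[c] * q
        ll1 = _fit(df1, spec).log_likelihood_
        lr = max(0.0, 2.0 * (ll1 - ll0))
        p_interaction = float(stats.chi2.sf(lr, df=len(mod_d.columns)))
    return results, p_interaction


def food_group_effects(
    cohort: pd.DataFrame,
    food_cols: Sequence[str],
    scores: Optional[pd.DataFrame] = None,
    spec: Optional[ModelSpec] = None,
):
    """Per-SD hazard ratios of individual food groups, plus the Spearman
    correlation of each food with each dietary score.

    Returns ``(hr_table, correlations)``; ``correlations`` is None when no
    score table is given.
    """
    spec = spec or ModelSpec()
    rows = []
    for col in food_cols:
        if col not in cohort.columns:
            raise KeyError(f"food group {col!r} not in cohort")
        v = cohort[col].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"food group {col!r} is constant; per-SD undefined")
        df = _base_frame(cohort, spec)
        df["food"] = (v - v.mean()) / sd
        hr, lo, hi = _hr_ci(_fit(df, spec), "food")
        rows.append(
            {"food": col, "hr_per_sd": hr, "ci_low": lo, "ci_high": hi,
             "sd": float(sd)}
        )
    hr_table = pd.DataFrame(rows)

    corr = None
    if scores is not None:
        score_cols = [c for c in scores.columns if c not in ("pid",)]
        corr = pd.DataFrame(
            index=list(food_cols), columns=score_cols, dtype=float
        )
        for f in food_cols:
            for sc in score_cols:
                corr.loc[f, sc] = float(
                    stats.spearmanr(cohort[f], scores[sc]).statistic
                )
    return hr_table, corr


def leave_one_out_substitution(
    cohort: pd.DataFrame,
    food_cols: Sequence[str],
    spec: Optional[ModelSpec] = None,
) -> pd.DataFrame:
    """Substitution hazard-ratio matrix from leave-one-out models.

    For each omitted group, the model contains every other group (per SD)
    plus the total across all groups, so the coefficient of group A is read
    as replacing the omitted group with A at constant total intake. Rows are
    the omitted (replaced) group, columns the replacement; the diagonal is
    NaN.
    """
    spec = spec or ModelSpec()
    missing = [c for c in food_cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"food group(s) not in cohort: {missing}")
    foods = list(food_cols)
    if len(foods) < 2:
        raise ValueError("substitution needs at least two food groups")
    std = {}
    for c in foods:
        v = cohort[c].astype(float)
        std[c] = (v - v.mean()) / v.std(ddof=1)
    total = sum(std.values())

    out = pd.DataFrame(np.nan, index=foods, columns=foods, dtype=float)
    for omitted in foods:
        df = _base_frame(cohort, spec)
        for c in foods:
            if c != omitted:
                df[c] = std[c]
        df["total_food"] = total
        try:
            cph = _fit(df, spec)
        except RuntimeError as e:
            raise RuntimeError(
                f"leave-one-out model omitting {omitted!r} is collinear; "
                "drop the total-intake term or reduce the food set"
            ) from e
        for c in foods:
            if c != omitted:
                out.loc[omitted, c] = math.exp(cph.params_[c])
    return out


def cause_specific_fit(
    cohort: pd.DataFrame,
    cause: str,
    score,
    spec: Optional[ModelSpec] = None,
    cause_col: str = "cause",
) -> HazardRatioSet:
    """Cause-specific hazards: deaths from other causes are censored."""
    from .simulate import CAUSE_CLASSES

    if cause not in CAUSE_CLASSES:
        raise ValueError(
            f"unknown cause class {cause!r}; known: {', '.join(CAUSE_CLASSES)}"
        )
    spec = spec or ModelSpec()
    sub = cohort.copy()
    is_cause = sub[cause_col].eq(cause) & sub[spec.event_col].astype(bool)
    sub[spec.event_col] = is_cause
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=sub.index)
    return fit_cox(sub, s, spec)


def schoenfeld_check(cohort: pd.DataFrame, score, spec: Optional[ModelSpec] = None):
    """Library-delegated proportional-hazards diagnostic (reported, not gating)."""
    from lifelines.statistics import proportional_hazard_test

    spec = spec or ModelSpec()
    s = cohort[score] if isinstance(score, str) else score
    s = pd.Series(np.asarray(s, dtype=float), index=cohort.index)
    df = _base_frame(cohort, spec)
    df["per_sd"] = (s - s.mean()) / s.std(ddof=1)
    cph = _fit(df, spec)
    res = proportional_hazard_test(cph, df, time_transform="rank")
    return res.summary
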