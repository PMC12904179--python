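"""Dietary pattern scoring engine.

:class:`DietaryPatternScorer` is a scikit-learn style transformer: ``fit``
learns any cohort-relative state a :class:`~dietspan.specs.ScoringSpec`
needs (the sorted intake distributions behind quintile components, per sex
stratum where required) and ``transform`` maps intake profiles to component
points and a total score. Absolute-anchor components carry no state, so for
purely anchor-based indices (AHEI-2010) the transformer is stateless but
keeps the same interface.

Quintile points use average ranks with the deterministic tie rule of
:mod:`dietspan._ranks`: tied intakes always earn identical points, and a new
profile is ranked against the stored fitted cohort.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin

from ._ranks import quantile_groups, rank_among
from .specs import DEFAULT_SPECS, INDEX_NAMES, Component, ScoringSpec, default_spec

__all__ = [
    "DietaryPatternScorer",
    "score_ahei",
    "score_amed",
    "score_hpdi",
    "score_dash",
    "score_drrd",
    "score_all",
    "score_without_alcohol",
    "score_correlations",
]


def _component_values(X: pd.DataFrame, comp: Component) -> np.ndarray:
    missing = [f for f in comp.fields if f not in X.columns]
    if missing:
        raise KeyError(
            f"component {comp.name!r} needs intake field(s) {missing} "
            "absent from the profile table"
        )
    return X[comp.fields].to_numpy(dtype=float).sum(axis=1)


def _sex_lookup(table: dict, sex_value: str, comp_name: str):
    if "all" in table:
        return table["all"]
    try:
        return table[sex_value]
    except KeyError:
        raise ValueError(
            f"component {comp_name!r} has sex-specific parameters but no entry "
            f"for sex={sex_value!r}"
        ) from None


class DietaryPatternScorer(BaseEstimator, TransformerMixin):
    """Score intake profiles against one dietary index specification.

    Parameters
    ----------
    spec : ScoringSpec or str
        A full specification, or the name of a shipped default
        ("AHEI", "AMED", "hPDI", "DASH", "DRRD").

    Attributes
    ----------
    spec_ : ScoringSpec
        The resolved specification.
    reference_ : dict
        For each quintile component, the sorted fitted intake values per
        stratum ("all" or a sex label).
    n_fitted_ : int
        Number of profiles seen at fit time.
    """

    def __init__(self, spec="AHEI"):
        self.spec = spec

    def _resolve_spec(self) -> ScoringSpec:
        return default_spec(self.spec) if isinstance(self.spec, str) else self.spec

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._resolve_spec()
        needs_sex = any(
            c.sex_specific or (c.rule in ("linear", "tent")
                               and "all" not in (c.anchors or c.band or {"all": 0}))
            for c in spec.components
        )
        if needs_sex and "sex" not in X.columns:
            raise KeyError(f"{spec.name} requires a 'sex' column")
        reference: Dict[str, Dict[str, np.ndarray]] = {}
        for comp in spec.components:
            if comp.rule != "quintile":
                continue
            v = _component_values(X, comp)
            ref: Dict[str, np.ndarray] = {}
            if comp.sex_specific:
                for s in np.unique(X["sex"]):
                    sv = v[(X["sex"] == s).to_numpy()]
                    self._check_stratum(sv, comp.name, s)
                    ref[str(s)] = np.sort(sv)
            else:
                self._check_stratum(v, comp.name, "all")
                ref["all"] = np.sort(v)
            reference[comp.name] = ref
        self.spec_ = spec
        self.reference_ = reference
        self.n_fitted_ = len(X)
        return self

    @staticmethod
    def _check_stratum(values: np.ndarray, comp: str, stratum: str):
        if values.size == 0:
            raise ValueError(f"component {comp!r}: empty stratum {stratum!r}")
        if np.unique(values).size < 5:
            raise ValueError(
                f"component {comp!r}, stratum {stratum!r}: fewer than 5 distinct "
                "values; quintile ranking is degenerate — use an absolute-"
                "threshold rule for this component"
            )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-component points and the total score for each profile."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "spec_")
        spec = self.spec_
        out = pd.DataFrame(index=X.index)
        for comp in spec.components:
            v = _component_values(X, comp)
            if comp.rule == "linear":
                pts = self._linear_points(v, comp, X)
            elif comp.rule == "tent":
                pts = self._tent_points(v, comp, X)
            else:
                pts = self._quintile_points(v, comp, X)
            out[comp.name] = pts
        out["total"] = out.sum(axis=1)
        lo, hi = spec.range
        assert out["total"].between(lo - 1e-9, hi + 1e-9).all()
        return out

    def score(self, X: pd.DataFrame) -> pd.Series:
        """Total score only."""
        return self.transform(X)["total"].rename(self.spec_.name)

    # --- rules ----------------------------------------------------------
    def _per_sex(self, X, v, comp, table, fn):
        pts = np.empty(len(v))
        if "all" in table:
            pts[:] = fn(v, table["all"])
        else:
            sex = X["sex"].to_numpy()
            for s in np.unique(sex):
                m = sex == s
                pts[m] = fn(v[m], _sex_lookup(table, str(s), comp.name))
        return pts

    def _linear_points(self, v, comp, X):
        def fn(vals, anchors):
            worst, best = anchors
            frac = np.clip((vals - worst) / (best - worst), 0.0, 1.0)
            return comp.min_points + frac * (comp.max_points - comp.min_points)

        return self._per_sex(X, v, comp, comp.anchors, fn)

    def _tent_points(self, v, comp, X):
        lo_pts = comp.lo_points if comp.lo_points is not None else comp.min_points

        def fn(vals, band):
            lo, p_lo, p_hi, hi = band
            pts = np.full(vals.shape, comp.max_points, dtype=float)
            left = vals < p_lo
            if p_lo > lo:
                frac = np.clip((vals - lo) / (p_lo - lo), 0.0, 1.0)
                pts = np.where(left, lo_pts + frac * (comp.max_points - lo_pts), pts)
            else:
                pts = np.where(left, lo_pts, pts)
            right = vals > p_hi
            if hi > p_hi:
                frac = np.clip((hi - vals) / (hi - p_hi), 0.0, 1.0)
                pts = np.where(
                    right, comp.min_points
                    + frac * (comp.max_points - comp.min_points), pts)
            else:
                pts = np.where(right, comp.min_points, pts)
            return pts

        pts = self._per_sex(X, v, comp, comp.band, fn)
        if comp.zero_points is not None:
            pts = np.where(v == 0.0, comp.zero_points, pts)
        return pts

    def _quintile_points(self, v, comp, X):
        ref = self.reference_[comp.name]

        def fn(vals, train_sorted):
            n = train_sorted.size
            r = rank_among(train_sorted, vals)
            q = np.clip(np.ceil(5 * r / n).astype(int), 1, 5)
            if comp.reverse:
                q = 6 - q
            step = (comp.max_points - comp.min_points) / 4.0
            return comp.min_points + (q - 1) * step

        if comp.sex_specific:
            return self._per_sex(X, v, comp, ref, fn)
        return fn(v, ref["all"])


# --- module-level convenience wrappers ----------------------------------

def _score_index(profiles: pd.DataFrame, index: str,
                 spec: Optional[ScoringSpec] = None) -> pd.Series:
    scorer = DietaryPatternScorer(spec if spec is not None else index)
    return scorer.fit(profiles).score(profiles).rename(index)


def score_ahei(profiles, spec=None):
    """AHEI-2010 totals (0-110), absolute anchors throughout."""
    return _score_index(profiles, "AHEI", spec)


def score_amed(profiles, spec=None):
    """AMED totals (10-50), sex-specific cohort quintiles."""
    return _score_index(profiles, "AMED", spec)


def score_hpdi(profiles, spec=None):
    """hPDI totals (17-85), cohort quintiles with reverse-scored non-healthy
    plant and animal foods."""
    return _score_index(profiles, "hPDI", spec)


def score_dash(profiles, spec=None):
    """DASH totals (8-40), cohort quintiles."""
    return _score_index(profiles, "DASH", spec)


def score_drrd(profiles, spec=None):
    """DRRD totals (9-45), cohort quintiles."""
    return _score_index(profiles, "DRRD", spec)


def score_all(profiles: pd.DataFrame,
              specs: Optional[Dict[str, ScoringSpec]] = None) -> pd.DataFrame:
    """All five index totals plus cohort quintile labels per index.

    Returns a table with one column per index, one ``<index>_q`` quintile
    label column (1-5, deterministic tie rule), indexed like ``profiles``.
    """
    specs = specs or DEFAULT_SPECS
    out = pd.DataFrame(index=profiles.index)
    if "pid" in profiles.columns:
        out["pid"] = profiles["pid"]
    for name in INDEX_NAMES:
        s = _score_index(profiles, name, specs.get(name))
        out[name] = s
        out[f"{name}_q"] = quantile_groups(s.to_numpy(), 5)
    return out


def score_without_alcohol(index: str, profiles: pd.DataFrame):
    """Index totals with the alcohol component removed.

    Only AHEI and AMED carry an alcohol component; the returned series'
    attrs record the shrunken attainable range (AHEI 0-100, AMED 9-45).
    """
    if index not in ("AHEI", "AMED"):
        raise KeyError(f"{index} has no alcohol component to remove")
    spec = default_spec(index).without_component("alcohol")
    s = _score_index(profiles, index, spec).rename(f"{index}_no_alcohol")
    s.attrs["range"] = spec.range
    s.attrs["removed_component"] = "alcohol"
    return s


def score_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix between the five index totals."""
    cols = [c for c in INDEX_NAMES if c in scores.columns]
    if len(cols) < 2:
        raise ValueError("need at least two index columns for a correlation matrix")
    rho = spearmanr(scores[cols].to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)
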