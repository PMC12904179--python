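"""Cohort-relative quantile-group assignment with a deterministic tie rule.

Quintile (and tertile) points are assigned from average ranks: tied values
share the mean of the ranks they occupy, and rank r out of n maps to group
ceil(k*r/n). All tied values therefore receive identical points, and group
sizes are near-equal (within one) apart from ties straddling a boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["quantile_groups", "quintile_rank"]


def quantile_groups(values, k: int, *, reverse: bool = False) -> np.ndarray:
    """Assign each value to one of ``k`` cohort-relative quantile groups.

    Parameters
    ----------
    values : array-like of float
        Cohort-wide values (one stratum).
    k : int
        Number of groups (5 for quintiles, 3 for tertiles).
    reverse : bool
        If True, group ``g`` is remapped to ``k + 1 - g`` so that larger
        values receive fewer points.

    Returns
    -------
    ndarray of int in ``1..k``.

    Raises
    ------
    ValueError
        If the stratum is empty or has fewer than ``k`` distinct values,
        in which case rank-based grouping is degenerate and an absolute
        threshold rule should be used instead.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty stratum: cannot assign quantile groups")
    if np.isnan(v).any():
        raise ValueError("NaN values in stratum: impute or drop before ranking")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct values in stratum; need at least {k} "
            f"for {k}-quantile ranking — use an absolute-threshold rule instead"
        )
    r = rankdata(v, method="average")
    g = np.ceil(k * r / v.size).astype(int)
    np.clip(g, 1, k, out=g)
    if reverse:
        g = k + 1 - g
    return g


def quintile_rank(values, *, sex=None, reverse: bool = False) -> np.ndarray:
    """Cohort quintile points (1–5), optionally within sex strata.

    With ``sex`` given, ranking is performed separately inside each sex
    stratum; permuting values within one stratum can never change points
    in the other.
    """
    v = np.asarray(values, dtype=float)
    if sex is None:
        return quantile_groups(v, 5, reverse=reverse)
    sex = np.asarray(sex)
    if sex.shape[0] != v.shape[0]:
        raise ValueError("sex and values must have equal length")
    out = np.empty(v.shape[0], dtype=int)
    for s in np.unique(sex):
        m = sex == s
        out[m] = quantile_groups(v[m], 5, reverse=reverse)
    return out


def rank_among(train_sorted: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Average rank of each ``x`` among a sorted training sample.

    For a value tied with training values, this reproduces the average-rank
    convention exactly; for a novel value it interpolates as n_less + 0.5.
    """
    lo = np.searchsorted(train_sorted, x, side="left")
    hi = np.searchsorted(train_sorted, x, side="right")
    return np.where(hi > lo, (lo + 1 + hi) / 2.0, lo + 0.5)
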