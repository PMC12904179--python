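"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorised code paths: ranks are
counted pairwise, points are accumulated per participant in plain Python.
"""

import math


def rank_points(values, k, reverse=False):
    """Average-rank quantile points by explicit pairwise counting."""
    n = len(values)
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        eq = sum(1 for u in values if u == v)
        r = less + (eq + 1) / 2.0
        q = min(max(math.ceil(k * r / n), 1), k)
        out.append(k + 1 - q if reverse else q)
    return out


def _component_value(row, fields):
    return sum(float(row[f]) for f in fields)


def _linear_points(v, comp, sex):
    worst, best = comp.anchors.get("all") or comp.anchors[sex]
    frac = (v - worst) / (best - worst)
    frac = min(max(frac, 0.0), 1.0)
    return comp.min_points + frac * (comp.max_points - comp.min_points)


def _tent_points(v, comp, sex):
    if comp.zero_points is not None and v == 0.0:
        return comp.zero_points
    lo, p_lo, p_hi, hi = comp.band.get("all") or comp.band[sex]
    lo_pts = comp.lo_points if comp.lo_points is not None else comp.min_points
    if p_lo <= v <= p_hi:
        return comp.max_points
    if v < p_lo:
        if p_lo == lo:
            return lo_pts
        frac = min(max((v - lo) / (p_lo - lo), 0.0), 1.0)
        return lo_pts + frac * (comp.max_points - lo_pts)
    if hi == p_hi:
        return comp.min_points
    frac = min(max((hi - v) / (hi - p_hi), 0.0), 1.0)
    return comp.min_points + frac * (comp.max_points - comp.min_points)


def score_cohort(profiles, spec):
    """Total index score per profile row, recomputed the slow way."""
    rows = profiles.to_dict("records")
    totals = [0.0] * len(rows)
    for comp in spec.components:
        values = [_component_value(r, comp.fields) for r in rows]
        if comp.rule == "quintile":
            if comp.sex_specific:
                pts = [None] * len(rows)
                for s in {r["sex"] for r in rows}:
                    idx = [i for i, r in enumerate(rows) if r["sex"] == s]
                    sub = [values[i] for i in idx]
                    sub_pts = rank_points(sub, 5, reverse=comp.reverse)
                    for i, p in zip(idx, sub_pts):
                        pts[i] = p
            else:
                pts = rank_points(values, 5, reverse=comp.reverse)
            step = (comp.max_points - comp.min_points) / 4.0
            pts = [comp.min_points + (p - 1) * step for p in pts]
        elif comp.rule == "linear":
            pts = [
                _linear_points(v, comp, r["sex"]) for v, r in zip(values, rows)
            ]
        else:
            pts = [_tent_points(v, comp, r["sex"]) for v, r in zip(values, rows)]
        totals = [t + p for t, p in zip(totals, pts)]
    return totals
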