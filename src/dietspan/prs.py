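"""Longevity polygenic risk score: weighted allele-dosage sum and tertiles.

PRS_i = sum_j beta_j * dosage_ij, where each beta is the years of life
gained per effect allele, so the score lives on a natural years scale and a
higher value means greater genetic predisposition to longevity. Effect-
allele orientation is the weight table's responsibility; dosages are never
flipped here.

:class:`PolygenicScore` follows the scikit-learn transformer protocol so the
score can sit inside a pipeline; ``fit`` validates the weight table against
the dosage columns and stores the fitted tertile reference distribution.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._ranks import quantile_groups, rank_among

__all__ = [
    "PolygenicScore",
    "compute_prs",
    "prs_tertiles",
    "validate_weights",
    "TERTILE_LABELS",
]

TERTILE_LABELS = {1: "low", 2: "intermediate", 3: "high"}


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a SNP weight table (columns: snp, effect_allele, weight)."""
    required = {"snp", "weight"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing column(s): {sorted(missing)}")
    if weights["snp"].duplicated().any():
        dups = weights.loc[weights["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicate SNP ids in weight table: {dups}")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite weights in weight table")
    return weights


def _dosage_matrix(dosages: pd.DataFrame, snp_ids) -> np.ndarray:
    cols = [c for c in dosages.columns if c != "pid"]
    unmatched_cols = sorted(set(cols) - set(snp_ids))
    unmatched_snps = sorted(set(snp_ids) - set(cols))
    if unmatched_cols or unmatched_snps:
        raise ValueError(
            "dosage columns and weight rows do not match; "
            f"columns without weights: {unmatched_cols}; "
            f"weights without columns: {unmatched_snps}"
        )
    D = dosages[list(snp_ids)].to_numpy(dtype=float)
    if D.size and (np.nanmin(D) < 0 or np.nanmax(D) > 2):
        raise ValueError("dosages outside [0, 2]")
    return D


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Weighted allele sum per participant (years scale), linear in dosages."""
    validate_weights(weights)
    D = _dosage_matrix(dosages, weights["snp"].tolist())
    prs = D @ weights["weight"].to_numpy(dtype=float)
    index = dosages["pid"] if "pid" in dosages.columns else dosages.index
    return pd.Series(prs, index=pd.Index(index, name="pid"), name="prs")


def prs_tertiles(prs, labels: bool = True):
    """Cut at the 1/3 and 2/3 empirical quantiles (average-rank tie rule).

    Raises on constant input, where tertiles are undefined.
    """
    v = np.asarray(prs, dtype=float)
    groups = quantile_groups(v, 3)
    if labels:
        out = np.array([TERTILE_LABELS[g] for g in groups], dtype=object)
    else:
        out = groups
    if isinstance(prs, pd.Series):
        return pd.Series(out, index=prs.index, name="prs_tertile")
    return out


class PolygenicScore(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer computing the weighted allele score.

    Parameters
    ----------
    weights : DataFrame with columns snp, effect_allele, weight, or None to
        take weights from ``fit``'s ``y``.

    Attributes
    ----------
    weights_ : validated weight table.
    reference_ : sorted fitted PRS values, used to assign tertiles to new
        participants by rank among the fitted cohort.
    """

    def __init__(self, weights: Optional[pd.DataFrame] = None):
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None):
        if self.weights is None:
            raise ValueError("PolygenicScore needs a weight table")
        self.weights_ = validate_weights(self.weights)
        prs = compute_prs(X, self.weights_)
        self.reference_ = np.sort(prs.to_numpy())
        if np.unique(self.reference_).size < 3:
            raise ValueError(
                "fewer than 3 distinct PRS values in the fitted cohort; "
                "tertiles are degenerate"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "weights_")
        prs = compute_prs(X, self.weights_)
        n = self.reference_.size
        r = rank_among(self.reference_, prs.to_numpy())
        groups = np.clip(np.ceil(3 * r / n).astype(int), 1, 3)
        out = prs.to_frame()
        out["prs_tertile"] = [TERTILE_LABELS[g] for g in groups]
        return out
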