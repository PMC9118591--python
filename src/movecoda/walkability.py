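"""One-factor PCA walkability score from six neighborhood indicators.

Six built-environment indicators measured in a 1-km street-network buffer
around each residence (three-or-more-way intersections, land-use mix, number
of parks, length of low-traffic streets, proportion of buffer area covered by
parks, and segments showing social disorder) are summarized by the first
principal component of their correlation matrix.  The component is
standardized (mean 0, sd 1), oriented so the intersection-density loading is
positive, and reported with its variance share and Spearman correlations
against the raw indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDICATOR_COLUMNS",
    "WalkabilityScores",
    "standardize_indicators",
    "first_principal_component",
    "scree_retention",
]

INDICATOR_COLUMNS = (
    "n_intersections",
    "land_use_mix",
    "n_parks",
    "low_traffic_street_length",
    "park_area_ratio",
    "social_disorder_segments",
)

#: Column whose loading fixes the sign of the component.
SIGN_ANCHOR = "n_intersections"


@dataclass
class WalkabilityScores:
    """Standardized first-PC scores with loadings and diagnostics."""

    scores: pd.Series               # indexed like the input table
    loadings: pd.Series             # first eigenvector, per indicator
    variance_explained: float       # lambda_1 / n_indicators
    spearman_rho: pd.Series         # score vs each raw indicator
    eigenvalues: np.ndarray
    n_retained_scree: int


def standardize_indicators(table: pd.DataFrame,
                           columns=INDICATOR_COLUMNS) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1 with denominator n-1)."""
    cols = [c for c in columns if c in table.columns]
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing indicator column(s): {missing}")
    z = {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"indicator {c!r} contains missing values")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"indicator {c!r} is constant")
        z[c] = (x - x.mean()) / sd
    return pd.DataFrame(z, index=table.index)


def scree_retention(eigenvalues: np.ndarray) -> int:
    """Components retained by the scree rule: count before the largest
    consecutive eigenvalue drop (1 when there is no drop at all)."""
    ev = np.asarray(eigenvalues, dtype=float)
    drops = ev[:-1] - ev[1:]
    if drops.size == 0 or np.all(drops <= 0):
        warnings.warn("scree test found no eigenvalue gap; retaining 1")
        return 1
    return int(np.argmax(drops)) + 1


def first_principal_component(table: pd.DataFrame,
                              columns=INDICATOR_COLUMNS) -> WalkabilityScores:
    """First PC of the indicator correlation matrix, standardized to
    mean 0 / sd 1 and oriented so the intersection loading is positive."""
    z = standardize_indicators(table, columns)
    n, p = z.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than indicators ({p})")
    zmat = z.to_numpy()
    corr = (zmat.T @ zmat) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    v1 = evecs[:, 0]
    anchor = SIGN_ANCHOR if SIGN_ANCHOR in z.columns else z.columns[0]
    if v1[z.columns.get_loc(anchor)] < 0:
        v1 = -v1
    raw_scores = zmat @ v1
    scores = (raw_scores - raw_scores.mean()) / raw_scores.std(ddof=1)
    rho = {}
    for c in z.columns:
        rho[c], _ = stats.spearmanr(scores, table[c].to_numpy(dtype=float))
    n_scree = scree_retention(evals)
    if n_scree != 1:
        warnings.warn(
            f"scree rule suggests {n_scree} components; "
            "proceeding with the mandated one-factor solution"
        )
    return WalkabilityScores(
        scores=pd.Series(scores, index=table.index, name="walkability"),
        loadings=pd.Series(v1, index=z.columns, name="loading"),
        variance_explained=float(evals[0] / p),
        spearman_rho=pd.Series(rho, name="spearman_rho"),
        eigenvalues=evals,
        n_retained_scree=n_scree,
    )
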