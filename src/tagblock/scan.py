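"""PCA-based genome scan for divergent selection.

Per-marker multiple regression on the leading principal components yields a
z-score vector per marker; a (robust) Mahalanobis distance of these vectors
is corrected by a genomic-inflation factor and referred to a chi-squared
distribution with K degrees of freedom.  Outliers are declared by Storey
q-values at a 5% false-discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScanResult:
    z: np.ndarray          # markers x K
    d2: np.ndarray
    p: np.ndarray
    q: np.ndarray
    outlier: np.ndarray
    K: int
    inflation: float
    marker_ids: list

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "D2": self.d2,
                "p": self.p,
                "q": self.q,
                "outlier": self.outlier,
            }
        )


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = M.std(axis=0)
    keep = sd > 0
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def pc_scores(M: np.ndarray, k: int) -> np.ndarray:
    """Score vectors (orthonormal left singular vectors) of the centred,
    standardized dosage matrix."""
    Z, _ = _standardize(M)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :k]


def choose_k(M: np.ndarray, max_k: int = 20, elbow_factor: float = 5.0):
    """Screeplot data and an elbow suggestion for the number of components.

    Returns (explained-variance proportions for components 1..max_k,
    suggested K).  The suggestion is the largest k whose drop in explained
    variance to component k+1 clearly exceeds the plateau noise scale,
    taken as ``elbow_factor`` times the median successive drop — i.e. the
    highest point before the plateau begins.  A user override is always
    allowed downstream.
    """
    Z, _ = _standardize(M)
    max_k = int(min(max_k, min(Z.shape) - 1))
    _, s, _ = np.linalg.svd(Z, full_matrices=False)
    ev = s**2 / np.sum(s**2)
    ev = ev[: max_k + 1]
    drops = ev[:-1] - ev[1:]
    med = np.median(drops)
    above = np.where(drops > elbow_factor * med)[0]
    suggested = int(above.max() + 1) if above.size else 1
    return ev[:max_k], suggested


def marker_zscores(
    M: np.ndarray, K: int, scores: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Regress each standardized marker on the first K PC scores.

    Returns (z, kept) where z[m, k] = coefficient_k / SE_k for marker m and
    ``kept`` flags markers with non-zero variance (others are excluded).
    ``scores`` allows regression against externally supplied component
    scores; by default the scores come from the markers themselves, in which
    case the z-vectors are slightly overdispersed relative to N(0,1) (the
    leading components are selected to absorb variance) — the inflation
    correction downstream accounts for this.
    """
    Z, kept = _standardize(M)
    n = Z.shape[0]
    S = pc_scores(M, K) if scores is None else scores[:, :K]
    X = np.hstack([np.ones((n, 1)) / np.sqrt(n), S])
    # X has orthonormal columns (scores are centred by construction of SVD
    # on a centred matrix), so coefficients are simple projections
    coef = X.T @ Z                           # (K+1) x m
    fitted = X @ coef
    rss = np.sum((Z - fitted) ** 2, axis=0)
    df = n - (K + 1)
    sigma2 = rss / df
    z = (coef[1:] / np.sqrt(sigma2)[None, :]).T   # m x K
    return z, kept


def mahalanobis_pvalues(
    z: np.ndarray,
    K: int,
    trim: float = 0.05,
    genomic_control: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mahalanobis D^2 of the z-vectors and chi-squared p-values.

    Location and scatter are estimated robustly: markers in the top ``trim``
    fraction of preliminary (classical) distances are excluded before the
    final mean/covariance estimate.  A genomic-inflation factor
    lambda = median(D^2) / median(chi2_K) rescales D^2 before the upper-tail
    chi-squared p-value.
    """
    def _safe_inv(cov):
        cov = np.atleast_2d(cov)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError(
                "singular z-score covariance; reduce K"
            )
        return np.linalg.inv(cov)

    mu0 = z.mean(axis=0)
    inv0 = _safe_inv(np.cov(z, rowvar=False))
    c = z - mu0
    d0 = np.einsum("ij,jk,ik->i", c, inv0, c)
    cut = np.quantile(d0, 1.0 - trim)
    core = z[d0 <= cut]
    mu = core.mean(axis=0)
    inv = _safe_inv(np.cov(core, rowvar=False))
    c = z - mu
    d2 = np.einsum("ij,jk,ik->i", c, inv, c)
    if genomic_control:
        lam = float(np.median(d2) / stats.chi2.median(K))
    else:
        lam = 1.0
    p = stats.chi2.sf(d2 / lam, K)
    return d2, p, lam


def qvalues(p: np.ndarray, fdr_level: float = 0.05) -> np.ndarray:
    """Storey q-values with smoothed pi0, falling back to Benjamini-Hochberg.

    pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95 and
    extrapolated with a cubic smoother to lambda -> 1; when the estimation
    is unstable — the smoothed value outside [0.1, 1], or any raw grid
    estimate above 1 (a non-uniform p-value tail) — plain BH adjustment
    (pi0 = 1) is used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    m = p.size
    lam_grid = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam_grid])
    coeffs = np.polyfit(lam_grid, pi0_lam, 3)
    pi0 = float(np.polyval(coeffs, lam_grid.max()))
    if pi0 > 1.0 or pi0 < 0.1 or pi0_lam.max() > 1.0:
        pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def selection_scan(
    M: np.ndarray,
    K: int,
    marker_ids: list | None = None,
    alpha: float = 0.05,
    trim: float = 0.05,
    genomic_control: bool = True,
) -> ScanResult:
    """Full scan on an imputed (no-missing) dosage matrix."""
    if np.isnan(M).any():
        raise ValueError("scan input must be imputed (no missing values)")
    z, kept = marker_zscores(M, K)
    d2, p, lam = mahalanobis_pvalues(z, K, trim=trim,
                                     genomic_control=genomic_control)
    q = qvalues(p)
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(M.shape[1])]
    ids = [mid for mid, k in zip(marker_ids, kept) if k]
    return ScanResult(z, d2, p, q, q <= alpha, K, lam, ids)
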