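"""Phenotype BLUPs, genotype imputation and RR-BLUP genomic prediction.

Phenotypic line values are shrunk across environments with a one-random-
effect mixed model (environment fixed, line random, REML).  Marker matrices
with missing calls are completed either by LD-informed k-nearest-neighbour
imputation (LD-kNNi) or by an iterative low-rank (SVD) completion.  Genomic
prediction uses ridge-regression BLUP with REML variance components via the
spectral decomposition of the marker kernel, evaluated by random-split
cross-validation and by independent validation; accuracy is the Pearson
correlation between predicted and observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from ._mixed import fit_mixed


# ---------------------------------------------------------------------------
# Phenotype BLUPs
# ---------------------------------------------------------------------------

@dataclass
class BlupResult:
    blups: pd.Series            # per line, shrunk deviation from fixed part
    sigma_line2: float
    sigma_e2: float
    env_effects: pd.Series
    mu: float


def _blup_profile(trait: pd.DataFrame):
    lines = pd.Categorical(trait["line"])
    envs = pd.Categorical(trait["env"])
    y = trait["value"].to_numpy(dtype=float)
    n = len(y)
    env_codes = envs.codes
    n_env = len(envs.categories)
    X = np.zeros((n, n_env))
    X[:, 0] = 1.0
    for e in range(1, n_env):
        X[env_codes == e, e] = 1.0
    line_codes = lines.codes
    return y, X, line_codes, lines.categories, envs.categories


def phenotype_blup(
    trait: pd.DataFrame,
    line_var: float | None = None,
    resid_var: float | None = None,
) -> BlupResult:
    """Line BLUPs from a line x environment table.

    Model: value = mu + env (fixed) + line (random) + e.  The variance ratio
    is estimated by profiled REML unless both components are supplied.
    Exploits the block structure (one random effect per line) so the fit is
    linear in the number of observations.
    """
    trait = trait.dropna(subset=["value"])
    y, X, line_codes, line_cats, env_cats = _blup_profile(trait)
    n, p = X.shape
    n_lines = len(line_cats)
    counts = np.bincount(line_codes, minlength=n_lines).astype(float)

    # per-line accumulators
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((n_lines, p))
    Sy = np.zeros(n_lines)
    np.add.at(Sx, line_codes, X)
    np.add.at(Sy, line_codes, y)

    def _solve(phi):
        c = phi / (1.0 + counts * phi)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        return beta, A, c

    def _neg_reml(log_phi):
        phi = np.exp(log_phi)
        beta, A, c = _solve(phi)
        r = y - X @ beta
        Sr = np.zeros(n_lines)
        np.add.at(Sr, line_codes, r)
        quad = float(r @ r) - float(c @ Sr**2)
        if quad <= 0:
            return 1e300
        se2 = quad / (n - p)
        logdet_v = float(np.sum(np.log1p(counts * phi)))
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e300
        return 0.5 * ((n - p) * np.log(se2) + logdet_v + logdet_a + (n - p))

    if line_var is not None and resid_var is not None:
        if resid_var <= 0:
            raise ValueError("resid_var must be positive")
        phi = line_var / resid_var
        se2 = resid_var
        beta, _, c = _solve(phi)
    else:
        res = minimize_scalar(
            _neg_reml, bounds=(np.log(1e-8), np.log(1e8)),
            method="bounded", options={"xatol": 1e-12},
        )
        phi = float(np.exp(res.x))
        beta, _, c = _solve(phi)
        r = y - X @ beta
        Sr = np.zeros(n_lines)
        np.add.at(Sr, line_codes, r)
        quad = float(r @ r) - float(c @ Sr**2)
        se2 = quad / (n - p)

    r = y - X @ beta
    Sr = np.zeros(n_lines)
    np.add.at(Sr, line_codes, r)
    shrink = counts * phi / (1.0 + counts * phi)
    with np.errstate(invalid="ignore"):
        blup = np.where(counts > 0, shrink * Sr / np.maximum(counts, 1), 0.0)
    sl2 = phi * se2
    if sl2 < 1e-10 * max(se2, 1.0):
        blup = np.zeros_like(blup)   # no line variance: all BLUPs shrink to 0
    kept = counts > 0
    return BlupResult(
        blups=pd.Series(blup[kept], index=line_cats[kept]),
        sigma_line2=float(sl2),
        sigma_e2=float(se2),
        env_effects=pd.Series(
            np.concatenate([[0.0], beta[1:]]), index=env_cats
        ),
        mu=float(beta[0]),
    )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def ld_knni_impute(
    D: np.ndarray,
    k: int = 5,
    l: int = 30,
    eps: float = 1e-6,
    hard: bool = False,
) -> np.ndarray:
    """LD-informed k-nearest-neighbour imputation of a dosage matrix.

    For each missing call (line t, marker m): take the ``l`` markers with
    highest r^2 to m; the distance from t to every other line is one minus
    the identity-by-state proportion over those markers (pairwise-complete,
    at least l/3 comparable); the imputed value is the inverse-distance-
    weighted mean dosage of the ``k`` nearest lines observed at m.  ``hard``
    rounds imputed values to the nearest dosage observed at that marker
    (so inbred 0/2 markers never receive a heterozygous 1).  Lines with no
    eligible neighbour fall back to the marker mean.
    """
    D = np.asarray(D, dtype=float)
    out = D.copy()
    miss = np.isnan(D)
    if not miss.any():
        return out
    n, m = D.shape
    obs = ~miss
    mean = np.nanmean(D, axis=0)
    sd = np.nanstd(D, axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Zs = np.where(obs, (D - mean) / sd_safe, 0.0)
    counts = obs.astype(float)
    overlap = counts.T @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Zs.T @ Zs) / np.maximum(overlap, 1)
    r2 = corr**2
    np.fill_diagonal(r2, -1.0)
    r2[:, sd == 0] = -1.0
    min_comparable = max(1, l // 3)

    for mj in np.unique(np.where(miss)[1]):
        top = np.argsort(-r2[mj])[:l]
        top = top[r2[mj, top] > 0]
        if top.size == 0:
            out[miss[:, mj], mj] = mean[mj]
            continue
        sub = D[:, top]
        sub_obs = obs[:, top]
        for t in np.where(miss[:, mj])[0]:
            comparable = sub_obs & sub_obs[t]
            n_comp = comparable.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ibs = 1.0 - np.abs(
                    np.where(comparable, sub - sub[t], np.nan)
                ) / 2.0
                sim = np.nanmean(np.where(comparable, ibs, np.nan), axis=1)
            dist = 1.0 - sim
            eligible = obs[:, mj] & (n_comp >= min_comparable)
            eligible[t] = False
            cand = np.where(eligible)[0]
            if cand.size == 0:
                out[t, mj] = mean[mj]
                continue
            order = cand[np.argsort(dist[cand], kind="stable")[:k]]
            w = 1.0 / (dist[order] + eps)
            out[t, mj] = float(np.sum(w * D[order, mj]) / np.sum(w))
    if hard:
        for mj in np.unique(np.where(miss)[1]):
            legal = np.unique(D[obs[:, mj], mj])
            if legal.size == 0:
                continue
            rows = np.where(miss[:, mj])[0]
            idx = np.argmin(np.abs(out[rows, mj][:, None] - legal), axis=1)
            out[rows, mj] = legal[idx]
        out[obs] = D[obs]
    return out


def em_impute(
    D: np.ndarray,
    rank: int = 10,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> np.ndarray:
    """Iterative low-rank (SVD) completion of a numeric dosage matrix.

    Missing entries start at marker means and are refilled from a rank-q
    reconstruction of the centred matrix until the largest change falls
    below ``tol``.  Observed entries are never altered.
    """
    D = np.asarray(D, dtype=float)
    miss = np.isnan(D)
    if not miss.any():
        return D.copy()
    mean0 = np.nanmean(D, axis=0)
    mean0 = np.where(np.isnan(mean0), 0.0, mean0)
    X = np.where(miss, mean0[None, :], D)
    rank = int(min(rank, min(D.shape) - 1)) or 1
    delta = np.inf
    for _ in range(max_iter):
        col_mean = X.mean(axis=0)
        C = X - col_mean
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        approx = U[:, :rank] * s[:rank] @ Vt[:rank] + col_mean
        new = X[miss]
        delta = float(np.max(np.abs(approx[miss] - new)))
        X[miss] = approx[miss]
        if delta < tol:
            break
    else:
        import warnings

        warnings.warn(f"em_impute: no convergence (last delta {delta:.2e})")
    return X


# ---------------------------------------------------------------------------
# RR-BLUP
# ---------------------------------------------------------------------------

@dataclass
class GSModel:
    mu: float
    effects: np.ndarray
    sigma_u2: float
    sigma_e2: float
    marker_means: np.ndarray
    training_lines: list = field(default_factory=list)

    @property
    def ratio(self) -> float:
        """lambda = sigma_e^2 / sigma_u^2."""
        return self.sigma_e2 / self.sigma_u2 if self.sigma_u2 > 0 else np.inf


def rrblup_fit(
    Z: np.ndarray,
    y: np.ndarray,
    fixed_ratio: float | None = None,
    training_lines: list | None = None,
) -> GSModel:
    """Fit y = 1 mu + Z u + e with u ~ N(0, sigma_u^2 I) by REML.

    Variance components come from a single one-dimensional REML optimization
    over the variance ratio on the spectrum of Z Z'; marker effects are the
    conditional means u = sigma_u^2 Z' V^{-1} (y - 1 mu).  ``fixed_ratio``
    bypasses REML with a known lambda = sigma_e^2 / sigma_u^2.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    means = Z.mean(axis=0)
    Zc = Z - means
    n = len(y)
    G = Zc @ Zc.T
    X = np.ones((n, 1))
    if fixed_ratio is None:
        fit = fit_mixed(y, X, G)
        delta, sg2 = fit.delta, fit.sg2
        eigvals, U = fit.eigvals, fit.U
        mu = float(fit.beta[0])
    else:
        eigvals, U = np.linalg.eigh(G)
        eigvals = np.clip(eigvals, 0.0, None)
        delta = float(fixed_ratio)
        w = eigvals + delta
        yt, Xt = U.T @ y, U.T @ X
        Xw = Xt / w[:, None]
        mu = float(np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)[0])
        r = yt - Xt[:, 0] * mu
        sg2 = float(r @ (r / w)) / (n - 1)
    # u = sigma_u^2 Z' V^{-1} (y - mu): with V = sigma_u^2 (G + delta I)
    resid = y - mu
    Vinv_r = U @ ((U.T @ resid) / (eigvals + delta))
    effects = Zc.T @ Vinv_r
    sigma_u2 = sg2
    sigma_e2 = sg2 * delta
    if sigma_u2 <= 1e-12 * max(sigma_e2, 1.0):
        import warnings

        warnings.warn("rrblup_fit: zero genetic variance; predictions "
                      "collapse to the mean")
    return GSModel(mu, effects, sigma_u2, sigma_e2, means,
                   training_lines or [])


def rrblup_predict(model: GSModel, Z_new: np.ndarray) -> np.ndarray:
    Zc = np.asarray(Z_new, dtype=float) - model.marker_means
    return model.mu + Zc @ model.effects


# ---------------------------------------------------------------------------
# Cross-validation and independent validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    fraction: float
    n_iter: int
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def cross_validate(
    Z: np.ndarray,
    y: np.ndarray,
    fractions=(0.4, 0.5, 0.6, 0.7, 0.8),
    n_iter: int = 500,
    seed: int = 0,
    min_test: int = 10,
) -> list[CVReport]:
    """Random calibration/test-split cross-validation of RR-BLUP accuracy.

    Per fraction and iteration a random calibration set of that size is
    drawn, the model fit on it, and accuracy recorded as the Pearson
    correlation between predicted and observed phenotypes on the remainder.
    Iterations whose test set would fall below ``min_test`` lines are
    skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    reports = []
    for frac in fractions:
        if not 0.0 < frac < 1.0:
            raise ValueError("calibration fractions must lie in (0, 1)")
        accs = []
        n_cal = int(round(frac * n))
        if n - n_cal < min_test:
            reports.append(CVReport(frac, 0, np.array([])))
            continue
        for _ in range(n_iter):
            perm = rng.permutation(n)
            cal, test = perm[:n_cal], perm[n_cal:]
            model = rrblup_fit(Z[cal], y[cal])
            pred = rrblup_predict(model, Z[test])
            accs.append(stats.pearsonr(pred, y[test])[0])
        reports.append(CVReport(frac, len(accs), np.asarray(accs)))
    return reports


def independent_validate(
    Z_cal: np.ndarray,
    y_cal: np.ndarray,
    Z_test: np.ndarray,
    y_test: np.ndarray,
    cal_marker_ids: list | None = None,
    test_marker_ids: list | None = None,
    min_shared: int = 100,
) -> float:
    """Fit on a calibration population, predict a disjoint test population.

    When marker-id lists are given the marker intersection (in calibration
    order) is used; fewer than ``min_shared`` shared markers is an error.
    Returns the Pearson correlation of predicted vs observed phenotype.
    """
    if cal_marker_ids is not None and test_marker_ids is not None:
        shared = [m for m in cal_marker_ids if m in set(test_marker_ids)]
        if len(shared) < min_shared:
            raise ValueError(
                f"only {len(shared)} shared markers (< {min_shared})"
            )
        cal_idx = [cal_marker_ids.index(m) for m in shared]
        test_lookup = {m: j for j, m in enumerate(test_marker_ids)}
        test_idx = [test_lookup[m] for m in shared]
        Z_cal = np.asarray(Z_cal)[:, cal_idx]
        Z_test = np.asarray(Z_test)[:, test_idx]
    model = rrblup_fit(Z_cal, y_cal)
    pred = rrblup_predict(model, Z_test)
    return float(stats.pearsonr(pred, np.asarray(y_test, dtype=float))[0])
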