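"""Mixed-linear-model association scans for SNP, TL and CL marker systems.

The scan follows the standard kinship + structure correction: a centred
identity-by-state kinship matrix (markers with MAF >= 0.2), principal-
component covariates (markers with MAF > 5% and missing < 20%), REML
variance components estimated once on the null model and held fixed for
every marker test (P3D).  Multi-allelic tag-level loci enter as allele-class
dummy columns with a joint F-test; chromosome-level haplotype-block columns
of the incidence matrix are tested one at a time as quantitative regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import MixedFit, fit_mixed
from .blocks import HaplotypeBlock
from .genotypes import GenotypeMatrix, filter_markers, het_pair, is_het


@dataclass
class KinshipMatrix:
    values: np.ndarray
    line_ids: list
    n_markers: int
    maf_floor: float


def kinship_centered_ibs(
    matrix: GenotypeMatrix, maf_min: float = 0.2
) -> KinshipMatrix:
    """Centred-IBS kinship from bi-allelic dosages, MAF >= ``maf_min``.

    With M the line x marker minor-allele dosage matrix (missing filled at
    2*p-hat), K = (M - 2P)(M - 2P)' / (2 * sum p_k (1 - p_k)).
    """
    kept, _ = filter_markers(matrix, maf_min=maf_min, maf_strict=False)
    if kept.n_loci < 50:
        import warnings

        warnings.warn(
            f"only {kept.n_loci} markers at MAF >= {maf_min} for kinship"
        )
    M = kept.dosage()
    p = np.nanmean(M, axis=0) / 2.0
    fill = np.where(np.isnan(M), (2.0 * p)[None, :], M)
    C = fill - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = C @ C.T / denom
    return KinshipMatrix(K, list(matrix.line_ids), kept.n_loci, maf_min)


def pca_covariates(
    matrix: GenotypeMatrix,
    n_pcs: int = 3,
    maf_min: float = 0.05,
    max_missing: float = 0.2,
) -> np.ndarray:
    """Principal-component scores for structure correction.

    Markers are filtered at MAF > ``maf_min`` and missing <= ``max_missing``,
    mean-filled, centred and decomposed; returns the first ``n_pcs`` score
    columns.
    """
    kept, _ = filter_markers(
        matrix, maf_min=maf_min, max_missing=max_missing, maf_strict=True
    )
    M = kept.dosage(mean_fill=True)
    C = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


# ---------------------------------------------------------------------------
# Marker design columns
# ---------------------------------------------------------------------------

def _class_dummies(matrix: GenotypeMatrix, j: int):
    """Allele-class dummy columns for a multi-allelic locus.

    The most frequent class is the reference; each remaining observed class
    contributes one column.  A heterozygote contributes 0.5 to each of its
    two classes; missing calls are filled with column means.  Returns the
    design block and the per-column class frequencies.
    """
    freqs = matrix.allele_freqs(j)
    observed = np.where(freqs > 0)[0]
    ref = observed[np.argmax(freqs[observed])]
    classes = [c for c in observed if c != ref]
    col = matrix.calls[:, j]
    n = len(col)
    X = np.zeros((n, len(classes)))
    miss = col == -1
    for k, c in enumerate(classes):
        X[col == c, k] = 1.0
    for i in np.where(is_het(col))[0]:
        a, b = het_pair(col[i])
        for k, c in enumerate(classes):
            if c in (a, b):
                X[i, k] += 0.5
    if miss.any():
        means = X[~miss].mean(axis=0) if (~miss).any() else np.zeros(len(classes))
        X[miss] = means
    return X, freqs[classes]


@dataclass
class MLMResult:
    table: pd.DataFrame
    null_fit: MixedFit
    n_pcs: int

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["neglog10p"] >= threshold]


def _p3d_scan_columns(yt, X0t, cols_t, dfs, n):
    """GLS F-tests of marker column blocks against a fixed null design."""
    p0 = X0t.shape[1]
    Q0, _ = np.linalg.qr(X0t)
    yr = yt - Q0 @ (Q0.T @ yt)
    rss0 = float(yr @ yr)
    out_F, out_p = [], []
    for C, _q in zip(cols_t, dfs):
        Cr = C - Q0 @ (Q0.T @ C)
        # drop columns absorbed by the null design (collinear markers)
        norm0 = np.linalg.norm(C, axis=0)
        normr = np.linalg.norm(Cr, axis=0)
        keep = normr > 1e-8 * (norm0 + 1e-300)
        Cr = Cr[:, keep]
        if Cr.shape[1] == 0:
            out_F.append(np.nan)
            out_p.append(np.nan)
            continue
        b, _res, rank, _sv = np.linalg.lstsq(Cr, yr, rcond=None)
        if rank == 0:
            out_F.append(np.nan)
            out_p.append(np.nan)
            continue
        fitted = Cr @ b
        explained = float(yr @ fitted)
        rss1 = rss0 - explained
        df2 = n - p0 - rank
        F = (explained / rank) / (rss1 / df2)
        out_F.append(F)
        out_p.append(float(stats.f.sf(F, rank, df2)))
    return out_F, out_p


def mlm_scan(
    markers,
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    pcs: np.ndarray | None = None,
    marker_ids: list | None = None,
    multiallelic: bool = False,
) -> MLMResult:
    """P3D mixed-linear-model association scan.

    Parameters
    ----------
    markers : GenotypeMatrix or 2-D ndarray
        A genotype matrix (bi-allelic dosage per locus, or allele-class
        dummies per locus when ``multiallelic``), or a numeric line x column
        array (e.g. a CL haplotype incidence matrix) whose columns are
        tested one at a time.
    y : per-line phenotype (single environment or BLUP)
    K : kinship matrix (polygenic covariance)
    pcs : optional fixed-effect structure covariates
    """
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K)
    n = len(y)
    X0 = np.ones((n, 1))
    n_pcs = 0
    if pcs is not None and pcs.size:
        X0 = np.hstack([X0, pcs])
        n_pcs = pcs.shape[1]
    null = fit_mixed(y, X0, Kv)
    w = null.weights
    T = w[:, None] * null.U.T          # whitening transform
    yt = T @ y
    X0t = T @ X0

    cols_t, dfs, ids, effects, driver_freq = [], [], [], [], []
    if isinstance(markers, GenotypeMatrix):
        for j, loc in enumerate(markers.loci):
            X, cfreqs = _class_dummies(markers, j)
            if X.shape[1] == 0:
                continue
            if not multiallelic and X.shape[1] > 1:
                # bi-allelic systems: single pooled-dosage column
                X = X.sum(axis=1, keepdims=True)
                cfreqs = np.array([cfreqs.sum()])
            Xc = X - X.mean(axis=0)
            cols_t.append(T @ Xc)
            dfs.append(X.shape[1])
            ids.append(loc.id)
            # effect sizes for the driving-class bookkeeping
            effects.append(Xc)
            driver_freq.append(cfreqs)
    else:
        M = np.asarray(markers, dtype=float)
        if marker_ids is None:
            marker_ids = [f"col{j}" for j in range(M.shape[1])]
        for j in range(M.shape[1]):
            X = M[:, [j]]
            Xc = X - X.mean(axis=0)
            cols_t.append(T @ Xc)
            dfs.append(1)
            ids.append(marker_ids[j])
            effects.append(Xc)
            driver_freq.append(np.array([np.mean(M[:, j] > 0.5)]))

    F, p = _p3d_scan_columns(yt, X0t, cols_t, dfs, n)

    # per-marker effect estimates and driving-class frequency
    Q0, _ = np.linalg.qr(X0t)
    yr = yt - Q0 @ (Q0.T @ yt)
    drive = []
    for Ct, cf in zip(cols_t, driver_freq):
        Cr = Ct - Q0 @ (Q0.T @ Ct)
        b = np.linalg.lstsq(Cr, yr, rcond=None)[0]
        if len(b) == 0 or np.all(np.isnan(b)):
            drive.append(np.nan)
        else:
            drive.append(float(cf[int(np.argmax(np.abs(b)))]))
    table = pd.DataFrame(
        {
            "marker": ids,
            "df": [int(d) for d in dfs],
            "F": F,
            "p": p,
            "neglog10p": [-np.log10(v) if v and v > 0 else np.nan for v in p],
            "driving_class_freq": drive,
        }
    )
    return MLMResult(table, null, n_pcs)


# ---------------------------------------------------------------------------
# CL haplotype incidence matrix
# ---------------------------------------------------------------------------

@dataclass
class IncidenceMatrix:
    """Lines x non-major block-haplotype probabilities.

    Dimension i x ((b x k) - m): every block with k observed haplotypes
    contributes k - 1 columns (the major haplotype is dropped); a line
    carrying a block's major haplotype is 0 across that block's columns.
    """

    values: np.ndarray
    line_ids: list
    columns: list = field(default_factory=list)  # (block index, haplotype)
    member_loci: list = field(default_factory=list)

    @property
    def shape(self):
        return self.values.shape


def build_incidence(
    blocks: list[HaplotypeBlock],
    matrix: GenotypeMatrix,
    knn_k: int = 10,
) -> IncidenceMatrix:
    """Populate the CL haplotype incidence matrix from detected blocks.

    Entries are 1 when the line carries the column's (non-major) haplotype,
    0 when it carries another observed haplotype of that block, and missing
    when the line is incomplete at the block; missing entries are then
    imputed by k-nearest-neighbour over lines (Euclidean distance on the
    observed columns), yielding probabilities in [0, 1].  Blocks with a
    single observed haplotype contribute no columns.
    """
    n = matrix.n_lines
    cols, registry, members = [], [], []
    for bi, block in enumerate(blocks):
        idx = [matrix.locus_index(m) for m in block.members]
        calls = matrix.calls[:, idx]
        ok = np.all((calls >= 0) & ~is_het(calls), axis=1)
        if not block.haplotypes or len(block.haplotypes) < 2:
            continue
        haplos = [h for h, _ in block.haplotypes]
        major = haplos[0]
        line_hap = {}
        for i in np.where(ok)[0]:
            line_hap[i] = tuple(int(x) for x in calls[i])
        for hap in haplos[1:]:
            col = np.full(n, np.nan)
            for i, h in line_hap.items():
                col[i] = 1.0 if h == hap else 0.0
            cols.append(col)
            registry.append((bi, hap))
        members.extend(block.members)
    if not cols:
        return IncidenceMatrix(np.zeros((n, 0)), list(matrix.line_ids), [], [])
    V = np.stack(cols, axis=1)
    V = _knn_impute_rows(V, k=knn_k)
    return IncidenceMatrix(V, list(matrix.line_ids), registry, members)


def _knn_impute_rows(V: np.ndarray, k: int = 10, eps: float = 1e-6) -> np.ndarray:
    """Impute missing entries from the k nearest lines (Euclidean on shared
    observed columns), inverse-distance weighted."""
    out = V.copy()
    obs = ~np.isnan(V)
    filled = np.where(obs, V, 0.0)
    col_means = np.nanmean(V, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    for i, j in zip(*np.where(~obs)):
        shared = obs[i] & obs
        shared[:, ~obs[i]] = False
        donors = np.where(obs[:, j] & (np.arange(len(V)) != i))[0]
        if donors.size == 0:
            out[i, j] = col_means[j]
            continue
        d = np.empty(donors.size)
        for t, dn in enumerate(donors):
            common = obs[i] & obs[dn]
            if not common.any():
                d[t] = np.inf
                continue
            diff = filled[i, common] - filled[dn, common]
            d[t] = np.sqrt(np.mean(diff**2))
        order = np.argsort(d)[:k]
        sel = donors[order]
        wts = 1.0 / (d[order] + eps)
        if not np.isfinite(wts).any():
            out[i, j] = col_means[j]
        else:
            wts = np.where(np.isfinite(wts), wts, 0.0)
            out[i, j] = float(np.sum(wts * V[sel, j]) / np.sum(wts))
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Thresholds and hit filtering
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n) significance threshold (per marker system)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def filter_hits(
    result: MLMResult,
    markers,
    y: np.ndarray,
    K,
    threshold: float,
    pcs: np.ndarray | None = None,
    min_class_freq: float = 0.01,
    multiallelic: bool = False,
) -> pd.DataFrame:
    """Discard significant hits driven by rare classes or heterozygotes.

    A hit is discarded when the allele class with the largest absolute
    effect has frequency below ``min_class_freq``, or when re-scanning the
    marker with heterozygous calls set to missing drops it below the
    threshold.
    """
    sig = result.significant(threshold).copy()
    if sig.empty:
        return sig
    keep_rare = sig["driving_class_freq"] >= min_class_freq
    sig = sig[keep_rare]
    if sig.empty or not isinstance(markers, GenotypeMatrix):
        return sig.assign(retained=True) if not sig.empty else sig
    retained = []
    het_any = is_het(markers.calls).any(axis=0)
    need_recheck = [
        mid for mid in sig["marker"]
        if het_any[markers.locus_index(mid)]
    ]
    if need_recheck:
        idx = [markers.locus_index(m) for m in need_recheck]
        sub = markers.subset(loci=idx)
        calls = sub.calls.copy()
        calls[is_het(calls)] = -1
        nohet = GenotypeMatrix(sub.line_ids, sub.loci, calls)
        res2 = mlm_scan(nohet, y, K, pcs=pcs, multiallelic=multiallelic)
        score = dict(zip(res2.table["marker"], res2.table["neglog10p"]))
        # a marker that drops out entirely (monomorphic without hets) or
        # falls below the threshold loses its hit
        lost = {
            m for m in need_recheck
            if not (score.get(m, np.nan) >= threshold)
        }
    else:
        lost = set()
    retained = [m not in lost for m in sig["marker"]]
    return sig[np.asarray(retained, dtype=bool)]


def combined_marker_set(
    matrix: GenotypeMatrix, incidence: IncidenceMatrix
) -> GenotypeMatrix:
    """Markers for a combined scan: drop the components of used blocks."""
    used = set(incidence.member_loci)
    keep = [j for j, loc in enumerate(matrix.loci) if loc.id not in used]
    return matrix.subset(loci=keep)
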