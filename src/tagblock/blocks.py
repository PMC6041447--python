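"""Chromosome-level haplotype blocks from |D'| confidence intervals.

Pairs of mapped bi-allelic markers are classified by the 95% confidence
interval of |D'| (likelihood-grid method): strong LD when the upper bound
exceeds 0.98 and the lower bound exceeds 0.7; strong evidence for historical
recombination when the upper bound is below 0.9; uninformative otherwise.
A haplotype block is a contiguous run of mapped markers whose outermost pair
is in strong LD and in which at least 95% of the informative pairs are in
strong LD.  Block haplotypes are tallied over lines complete at all member
markers and summarized with Nei's unbiased diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, is_het
from .mapping import GeneticMap

STRONG_LD = "strong_ld"
RECOMB = "recomb"
UNINFORMATIVE = "uninformative"

_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class PairClassification:
    locus_a: str
    locus_b: str
    dprime: float
    ci_low: float
    ci_high: float
    klass: str
    n_informative: int = 0


@dataclass
class HaplotypeBlock:
    group: str
    members: list            # marker ids in map order
    cm_start: float
    cm_end: float
    haplotypes: list = field(default_factory=list)   # (haplo tuple, count)
    n_complete: int = 0
    diversity: float = np.nan

    @property
    def size_cm(self) -> float:
        return self.cm_end - self.cm_start

    @property
    def n_markers(self) -> int:
        return len(self.members)


def classify_ci(ci_low: float, ci_high: float) -> str:
    """Gabriel-rule CI classification with exact printed thresholds.

    strong LD requires ci_high strictly > 0.98 AND ci_low strictly > 0.7;
    recombination requires ci_high strictly < 0.9.
    """
    if ci_high > 0.98 and ci_low > 0.7:
        return STRONG_LD
    if ci_high < 0.9:
        return RECOMB
    return UNINFORMATIVE


def haplotype_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """2x2 haplotype counts over inbred lines complete at both loci.

    Order: [AB, Ab, aB, ab] with A/B the allele-0 classes.  Missing and
    heterozygous calls are dropped pairwise (phase is known for the rest
    because the lines are inbred).
    """
    ok = (
        (calls_a >= 0) & (calls_b >= 0)
        & ~is_het(calls_a) & ~is_het(calls_b)
    )
    a, b = calls_a[ok], calls_b[ok]
    return np.array(
        [
            np.sum((a == 0) & (b == 0)),
            np.sum((a == 0) & (b == 1)),
            np.sum((a == 1) & (b == 0)),
            np.sum((a == 1) & (b == 1)),
        ],
        dtype=float,
    )


def dprime_point(counts: np.ndarray) -> float:
    """|D'| point estimate from a [AB, Ab, aB, ab] count vector."""
    n = counts.sum()
    p_ab = counts[0] / n
    p_a = (counts[0] + counts[1]) / n
    p_b = (counts[0] + counts[2]) / n
    d = p_ab - p_a * p_b
    if d > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if dmax == 0:
        return np.nan
    return abs(d) / dmax


def _grid_likelihood(counts: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of the counts on the |D'| grid.

    Allele frequencies are held at their observed values; D takes the sign
    of the observed disequilibrium and |D| = grid * Dmax.
    """
    n = counts.sum()
    p_a = (counts[0] + counts[1]) / n
    p_b = (counts[0] + counts[2]) / n
    d_obs = counts[0] / n - p_a * p_b
    sign = 1.0 if d_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d = sign * _GRID * dmax
    probs = np.empty((len(_GRID), 4))
    probs[:, 0] = p_a * p_b + d
    probs[:, 1] = p_a * (1 - p_b) - d
    probs[:, 2] = (1 - p_a) * p_b - d
    probs[:, 3] = (1 - p_a) * (1 - p_b) + d
    probs = np.clip(probs, 1e-12, None)
    return (np.log(probs) * counts).sum(axis=1)


def dprime_ci_from_counts(counts: np.ndarray) -> tuple[float, float, float]:
    """(|D'|, ci_low, ci_high) by the normalized likelihood-grid method.

    The multinomial likelihood of the observed haplotype counts is evaluated
    at |D'| in {0, 0.001, ..., 1}, normalized to sum to one; ci_low is the
    smallest grid value whose cumulative mass reaches 5% and ci_high the
    smallest reaching 95%.
    """
    loglik = _grid_likelihood(counts)
    lik = np.exp(loglik - loglik.max())
    lik /= lik.sum()
    cum = np.cumsum(lik)
    ci_low = float(_GRID[np.searchsorted(cum, 0.05)])
    ci_high = float(_GRID[np.searchsorted(cum, 0.95)])
    return float(dprime_point(counts)), ci_low, ci_high


def dprime_ci(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    locus_a: str = "a",
    locus_b: str = "b",
    min_informative: int = 10,
) -> PairClassification:
    """Classify one bi-allelic marker pair by its |D'| confidence interval."""
    counts = haplotype_counts(calls_a, calls_b)
    n = int(counts.sum())
    mono_a = (counts[0] + counts[1] == 0) or (counts[2] + counts[3] == 0)
    mono_b = (counts[0] + counts[2] == 0) or (counts[1] + counts[3] == 0)
    if n < min_informative or mono_a or mono_b:
        return PairClassification(
            locus_a, locus_b, np.nan, np.nan, np.nan, UNINFORMATIVE, n
        )
    dp, lo, hi = dprime_ci_from_counts(counts)
    return PairClassification(locus_a, locus_b, dp, lo, hi, classify_ci(lo, hi), n)


# ---------------------------------------------------------------------------
# Block detection
# ---------------------------------------------------------------------------

def _pair_class_matrix(
    calls: np.ndarray,
    window: np.ndarray,
    min_informative: int,
) -> np.ndarray:
    """Upper-triangular class codes (1 strong, 2 recomb, 0 otherwise)."""
    m = calls.shape[1]
    klass = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1, m):
            if not window[i, j]:
                continue
            pc = dprime_ci(calls[:, i], calls[:, j],
                           min_informative=min_informative)
            if pc.klass == STRONG_LD:
                klass[i, j] = klass[j, i] = 1
            elif pc.klass == RECOMB:
                klass[i, j] = klass[j, i] = 2
    return klass


def find_blocks(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    group: str,
    window_markers: int = 50,
    window_cm: float = 10.0,
    strong_fraction: float = 0.95,
    min_informative_pairs: int = 1,
    min_informative_lines: int = 10,
) -> list[HaplotypeBlock]:
    """Detect haplotype blocks on one linkage group.

    Markers are sorted by cM (ties by id).  Pair classifications are
    computed within a sliding window (``window_markers`` markers or
    ``window_cm`` cM, whichever is larger).  Candidate intervals must have a
    strong-LD outermost pair and a strong-LD fraction of at least
    ``strong_fraction`` among informative (strong + recomb) pairs; they are
    accepted greedily by descending cM length, then descending marker count,
    then leftmost start, skipping overlaps.
    """
    sub = gmap.positions(group)
    # markers on the map but absent from the genotype matrix are skipped
    present = sub["locus"].isin({loc.id for loc in matrix.loci})
    sub = sub[present]
    ids = sub["locus"].tolist()
    pos = sub["cm"].to_numpy(dtype=float)
    idx = [matrix.locus_index(lid) for lid in ids]
    calls = matrix.calls[:, idx]
    m = len(ids)
    if m < 2:
        return []

    sep = np.abs(pos[:, None] - pos[None, :])
    ordist = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
    window = (ordist <= window_markers) | (sep <= window_cm)
    klass = _pair_class_matrix(calls, window, min_informative_lines)

    strong = (klass == 1).astype(np.int64)
    inform = (klass != 0).astype(np.int64)
    cs = strong.cumsum(axis=0).cumsum(axis=1)
    ci = inform.cumsum(axis=0).cumsum(axis=1)

    def _box(csum, i, j):
        total = csum[j, j]
        if i > 0:
            total -= 2 * csum[i - 1, j] - csum[i - 1, i - 1]
        return total // 2          # symmetric, zero diagonal

    candidates = []
    for i in range(m):
        jmax = m - 1
        for j in range(i + 1, jmax + 1):
            if not window[i, j]:
                break
            if klass[i, j] != 1:
                continue
            n_strong = _box(cs, i, j)
            n_inf = _box(ci, i, j)
            if n_inf >= min_informative_pairs and n_strong >= strong_fraction * n_inf:
                candidates.append((pos[j] - pos[i], j - i + 1, i, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))

    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, _, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        block = HaplotypeBlock(
            group=group,
            members=ids[i : j + 1],
            cm_start=float(pos[i]),
            cm_end=float(pos[j]),
        )
        _tally_haplotypes(block, calls[:, i : j + 1])
        block.diversity = block_diversity(block)
        blocks.append(block)
    blocks.sort(key=lambda b: b.cm_start)
    return blocks


def _tally_haplotypes(block: HaplotypeBlock, calls: np.ndarray) -> None:
    """Tally block haplotypes over lines complete at every member marker."""
    ok = np.all((calls >= 0) & ~is_het(calls), axis=1)
    complete = calls[ok]
    block.n_complete = int(complete.shape[0])
    if block.n_complete == 0:
        block.haplotypes = []
        return
    uniq, counts = np.unique(complete, axis=0, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    block.haplotypes = [
        (tuple(int(x) for x in uniq[k]), int(counts[k])) for k in order
    ]


def block_diversity(block: HaplotypeBlock, min_freq: float = 0.02) -> float:
    """Nei's unbiased haplotype diversity H = n/(n-1) * (1 - sum p_i^2).

    ``n`` is the number of lines with complete calls at all member markers;
    the sum runs over block haplotypes with frequency >= ``min_freq``
    (frequencies keep the full complete-line denominator; they are not
    renormalized after the rare-haplotype exclusion).
    """
    n = block.n_complete
    if n < 2:
        return np.nan
    freqs = np.array([c for _, c in block.haplotypes], dtype=float) / n
    keep = freqs >= min_freq
    return float(n / (n - 1) * (1.0 - np.sum(freqs[keep] ** 2)))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_blocks(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Per-group block count and min/max/mean size, one row per group."""
    rows = []
    by_group: dict[str, list[HaplotypeBlock]] = {}
    for b in blocks:
        by_group.setdefault(b.group, []).append(b)
    for group, bs in sorted(by_group.items()):
        sizes = np.array([b.size_cm for b in bs])
        rows.append(
            {
                "group": group,
                "count": len(bs),
                "min_size_cm": float(sizes.min()),
                "max_size_cm": float(sizes.max()),
                "mean_size_cm": float(sizes.mean()),
            }
        )
    return pd.DataFrame(rows)


def summary_totals(summary: pd.DataFrame) -> dict:
    """Panel totals from a per-group summary table.

    Covered cM is the sum over groups of count x mean size, which equals the
    direct sum of block sizes.
    """
    if summary.empty:
        return {"n_blocks": 0, "covered_cm": 0.0}
    covered = float((summary["count"] * summary["mean_size_cm"]).sum())
    return {"n_blocks": int(summary["count"].sum()), "covered_cm": covered}


def blocks_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": b.group,
                "start_cM": b.cm_start,
                "end_cM": b.cm_end,
                "size_cM": b.size_cm,
                "n_markers": b.n_markers,
                "n_haplotypes": len(b.haplotypes),
                "diversity": b.diversity,
                "member_ids": ",".join(b.members),
            }
            for b in blocks
        ]
    )
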