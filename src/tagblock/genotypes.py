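"""Genotype data model, HapMap-dialect I/O, marker encodings and filtering.

Inbred panels are stored one allele per call: each entry of the call matrix
is a non-negative allele-class index, ``MISSING`` (-1) for a failed call, or
a packed negative heterozygote code carrying both class indices (rare calls
surviving the upstream heterozygosity filter).  Allele-frequency tallies
count a heterozygote as half an observation of each of its two classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1
#: allele symbols legal in the HapMap dialect, in canonical rank order
HAPMAP_CODES = ("A", "C", "G", "T", "+", "-")
_HET_BASE = 2
_HET_STRIDE = 64


def het_code(a: int, b: int) -> int:
    """Pack an unordered heterozygote of allele classes ``a`` and ``b``."""
    if a == b:
        raise ValueError("heterozygote requires two distinct allele classes")
    a, b = sorted((a, b))
    return -(_HET_BASE + a * _HET_STRIDE + b)


def het_pair(code: int) -> tuple[int, int]:
    v = -code - _HET_BASE
    return v // _HET_STRIDE, v % _HET_STRIDE


def is_het(calls: np.ndarray) -> np.ndarray:
    return calls <= -_HET_BASE


@dataclass
class Locus:
    """A marker locus: multi-allelic tag-level haplotype or bi-allelic SNP.

    Tag-level loci use ids with a single decimal suffix (``avgbs2_123.1``);
    their component SNPs carry two-decimal ids (``avgbs2_123.1.2``).
    ``group``/``cm`` hold the linkage-map position when the locus is placed.
    """

    id: str
    alleles: list[str]
    group: str | None = None
    cm: float | None = None
    snp_children: list[str] = field(default_factory=list)
    monomorphic: bool = False

    @property
    def is_tl(self) -> bool:
        return bool(re.search(r"\.\d+$", self.id)) and not re.search(
            r"\.\d+\.\d+$", self.id
        )


class GenotypeMatrix:
    """Lines x loci call matrix with per-locus summary statistics.

    Parameters
    ----------
    line_ids : sequence of str
    loci : sequence of Locus
    calls : int ndarray, shape (n_lines, n_loci)
        Allele indices; ``MISSING`` or packed heterozygote codes allowed.
    """

    def __init__(self, line_ids, loci, calls):
        self.line_ids = list(line_ids)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.line_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.loci)} loci"
            )
        self.calls = calls

    # -- shape ------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        try:
            return self._locus_lookup[locus_id]
        except AttributeError:
            self._locus_lookup = {loc.id: j for j, loc in enumerate(self.loci)}
            return self._locus_lookup[locus_id]

    # -- per-locus statistics ---------------------------------------------
    def allele_counts(self, j: int) -> np.ndarray:
        """Class counts at locus ``j``; heterozygotes add 0.5 to each class."""
        n_alleles = len(self.loci[j].alleles)
        col = self.calls[:, j]
        counts = np.zeros(n_alleles)
        hom = col >= 0
        if hom.any():
            counts += np.bincount(col[hom], minlength=n_alleles)[:n_alleles]
        for code in col[is_het(col)]:
            a, b = het_pair(code)
            counts[a] += 0.5
            counts[b] += 0.5
        return counts

    def allele_freqs(self, j: int) -> np.ndarray:
        counts = self.allele_counts(j)
        total = counts.sum()
        return counts / total if total > 0 else counts

    def maf(self) -> np.ndarray:
        """Minor-allele-class frequency: 1 - major-class frequency.

        Equals the usual minor-allele frequency for bi-allelic loci and the
        frequency of the pooled alternate allele after bi-allelic compression
        of a multi-allelic locus.
        """
        out = np.zeros(self.n_loci)
        for j in range(self.n_loci):
            freqs = self.allele_freqs(j)
            out[j] = 1.0 - freqs.max() if freqs.size else 0.0
        return out

    def missing_frac(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def het_frac(self) -> np.ndarray:
        return is_het(self.calls).mean(axis=0)

    # -- views -------------------------------------------------------------
    def subset(self, lines=None, loci=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        lj = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            [self.line_ids[i] for i in li],
            [self.loci[j] for j in lj],
            self.calls[np.ix_(li, lj)],
        )

    def dosage(self, mean_fill: bool = False) -> np.ndarray:
        """Minor-allele dosage on a 0..2 scale for bi-allelic loci.

        Homozygote for class 0 (major) -> 0, heterozygote -> 1, homozygote
        for class 1 -> 2; missing -> NaN, or the locus mean when
        ``mean_fill`` is set.
        """
        d = np.full(self.calls.shape, np.nan)
        d[self.calls == 0] = 0.0
        d[self.calls == 1] = 2.0
        d[is_het(self.calls)] = 1.0
        if mean_fill:
            means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[1]]
        return d


# ---------------------------------------------------------------------------
# HapMap-dialect I/O
# ---------------------------------------------------------------------------

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]
#: cM positions are stored as integer pos = round(cM * 1e4); the consensus
#: map has no physical coordinates, so the linkage group fills ``chrom``.
_POS_SCALE = 1e4


def write_hapmap(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as HapMap-dialect text (one marker per row)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + matrix.line_ids) + "\n")
        for j, loc in enumerate(matrix.loci):
            codes = loc.alleles
            bad = [c for c in codes if c not in HAPMAP_CODES]
            if bad:
                raise ValueError(f"locus {loc.id}: non-HapMap allele symbols {bad}")
            col = matrix.calls[:, j]
            cells = []
            for code in col:
                if code == MISSING:
                    cells.append("NN")
                elif code >= 0:
                    cells.append(codes[code] * 2)
                else:
                    a, b = het_pair(code)
                    cells.append(codes[a] + codes[b])
            chrom = loc.group if loc.group is not None else "NA"
            pos = int(round(loc.cm * _POS_SCALE)) if loc.cm is not None else 0
            row = [loc.id, "/".join(codes), chrom, str(pos)] + ["NA"] * 7 + cells
            fh.write("\t".join(row) + "\n")


def read_hapmap(path) -> GenotypeMatrix:
    """Read a HapMap-dialect file written by :func:`write_hapmap`.

    Allele symbols are restricted to A, C, G, T, +, - (N only inside the
    missing call ``NN``); heterozygotes are two-letter cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_HAPMAP_HEADER)] != _HAPMAP_HEADER:
            raise ValueError(
                f"{path}: line 1: malformed HapMap header "
                f"(expected columns {_HAPMAP_HEADER})"
            )
        line_ids = header[len(_HAPMAP_HEADER):]
        loci: list[Locus] = []
        columns: list[np.ndarray] = []
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(_HAPMAP_HEADER) + len(line_ids):
                raise ValueError(f"{path}: line {lineno}: wrong field count")
            locus_id, allele_field, chrom, pos = parts[0], parts[1], parts[2], parts[3]
            codes = allele_field.split("/")
            unknown = [c for c in codes if c not in HAPMAP_CODES]
            if unknown:
                raise ValueError(
                    f"{path}: locus {locus_id}: unknown allele symbol(s) {unknown}"
                )
            lookup = {c: k for k, c in enumerate(codes)}
            col = np.empty(len(line_ids), dtype=np.int32)
            for i, cell in enumerate(parts[len(_HAPMAP_HEADER):]):
                if cell == "NN":
                    col[i] = MISSING
                elif len(cell) == 2 and cell[0] == cell[1]:
                    col[i] = lookup[cell[0]]
                elif len(cell) == 2:
                    col[i] = het_code(lookup[cell[0]], lookup[cell[1]])
                else:
                    raise ValueError(
                        f"{path}: locus {locus_id}: bad call {cell!r}"
                    )
            cm = None if pos == "0" and chrom == "NA" else int(pos) / _POS_SCALE
            group = None if chrom == "NA" else chrom
            loci.append(Locus(locus_id, codes, group=group, cm=cm))
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(line_ids), 0), dtype=np.int32)
    )
    return GenotypeMatrix(line_ids, loci, calls)


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    """Plain tabular matrix: line rows x locus columns, -1 = missing."""
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(loc.id for loc in matrix.loci) + "\n")
        for i, lid in enumerate(matrix.line_ids):
            fh.write(lid + "\t" + "\t".join(map(str, matrix.calls[i])) + "\n")


def write_map_tsv(loci, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tgroup\tcM\n")
        for loc in loci:
            g = loc.group if loc.group is not None else "NA"
            c = f"{loc.cm:.4f}" if loc.cm is not None else "NA"
            fh.write(f"{loc.id}\t{g}\t{c}\n")


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

def rank_alleles(freqs: np.ndarray) -> np.ndarray:
    """Allele classes ordered by descending frequency, ties by input order."""
    order = np.argsort(-np.asarray(freqs), kind="stable")
    return order


def encode_six_allele(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Recode every locus onto the six HapMap symbols by frequency rank.

    Classes are ranked by descending observed frequency (ties keep input
    order); ranks 1..6 map to A, C, G, T, +, - and any classes ranked 7th or
    later are pooled into the sixth symbol.  Ranking happens once; the pooled
    tail is not re-ranked.
    """
    new_cols = []
    new_loci = []
    for j, loc in enumerate(matrix.loci):
        freqs = matrix.allele_freqs(j)
        if freqs.sum() == 0:
            raise ValueError(f"locus {loc.id}: all calls missing")
        order = rank_alleles(freqs)
        # old class -> new rank index, tail pooled into index 5
        remap = np.empty(len(order), dtype=np.int32)
        for rank, old in enumerate(order):
            remap[old] = min(rank, len(HAPMAP_CODES) - 1)
        col = matrix.calls[:, j].copy()
        hom = col >= 0
        col[hom] = remap[col[hom]]
        for i in np.where(is_het(col))[0]:
            a, b = het_pair(col[i])
            na, nb = remap[a], remap[b]
            col[i] = na if na == nb else het_code(na, nb)
        n_codes = min(len(order), len(HAPMAP_CODES))
        new_loci.append(replace(loc, alleles=list(HAPMAP_CODES[:n_codes])))
        new_cols.append(col)
    calls = np.stack(new_cols, axis=1) if new_cols else matrix.calls.copy()
    return GenotypeMatrix(matrix.line_ids, new_loci, calls)


def compress_to_biallelic(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse every multi-allelic locus to major vs pooled-alternate.

    For loci with more than two allele classes the most frequent class
    becomes allele 0 and all other classes pool into the single alternate
    allele 1.  Missing calls are preserved; a heterozygote whose two classes
    fall in the same compressed class becomes homozygous.  Loci that are
    already bi-allelic pass through unchanged (so the operation is
    idempotent); monomorphic loci pass through flagged.  Note the pooled
    alternate allele can be the more frequent class when no single original
    class reaches 50%.
    """
    new_cols = []
    new_loci = []
    for j, loc in enumerate(matrix.loci):
        freqs = matrix.allele_freqs(j)
        poly = (freqs > 0).sum() > 1
        if len(loc.alleles) <= 2:
            new_loci.append(replace(loc, monomorphic=not poly))
            new_cols.append(matrix.calls[:, j].copy())
            continue
        major = int(rank_alleles(freqs)[0]) if freqs.size else 0
        col = matrix.calls[:, j].copy()
        hom = col >= 0
        col[hom] = (col[hom] != major).astype(np.int32)
        for i in np.where(is_het(col))[0]:
            a, b = het_pair(col[i])
            na, nb = int(a != major), int(b != major)
            col[i] = na if na == nb else het_code(0, 1)
        new_loci.append(
            replace(loc, alleles=["A", "C"], monomorphic=not poly)
        )
        new_cols.append(col)
    calls = np.stack(new_cols, axis=1) if new_cols else matrix.calls.copy()
    return GenotypeMatrix(matrix.line_ids, new_loci, calls)


def filter_markers(
    matrix: GenotypeMatrix,
    maf_min: float = 0.0,
    max_missing: float = 1.0,
    max_het: float = 1.0,
    maf_strict: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Drop loci failing MAF / missing-fraction / heterozygosity thresholds.

    ``maf_strict`` selects MAF > maf_min (strict, the ">15%" and ">5%"
    placement/PCA rules) vs MAF >= maf_min (the kinship "MAF >= 0.2" rule).
    Missing fraction is kept at <= ``max_missing``; het fraction at
    < ``max_het``.  Returns the filtered matrix and a removal report.
    """
    for t in (maf_min, max_missing, max_het):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    maf = matrix.maf()
    miss = matrix.missing_frac()
    het = matrix.het_frac()
    ok_maf = maf > maf_min if maf_strict else maf >= maf_min
    ok_miss = miss <= max_missing
    ok_het = het < max_het if max_het < 1.0 else np.ones_like(het, dtype=bool)
    keep = ok_maf & ok_miss & ok_het
    report = {
        "n_input": matrix.n_loci,
        "n_kept": int(keep.sum()),
        "removed_maf": int((~ok_maf).sum()),
        "removed_missing": int((~ok_miss).sum()),
        "removed_het": int((~ok_het).sum()),
    }
    return matrix.subset(loci=np.where(keep)[0]), report
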