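"""Placement of new markers on a fixed framework consensus map.

New markers are positioned by two-point recombination against framework
markers across one or more biparental (RIL) populations: recombination
fractions are pooled over populations by summing recombinant and informative
counts, the candidate is placed between the two least-recombining framework
markers, and its position is interpolated so that framework positions are
never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, is_het


class GeneticMap:
    """An ordered framework map plus placed markers.

    Framework marker positions are immutable; placed markers receive
    interpolated positions between framework flanks.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        cols = ["locus", "group", "cm", "framework"]
        if df is None:
            df = pd.DataFrame(columns=cols)
        self.df = df[cols].copy()
        self._sort()

    def _sort(self) -> None:
        self.df = self.df.sort_values(
            ["group", "cm", "locus"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_loci(cls, loci, framework: bool = True) -> "GeneticMap":
        rows = [
            {"locus": loc.id, "group": loc.group, "cm": loc.cm,
             "framework": framework}
            for loc in loci
            if loc.group is not None and loc.cm is not None
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_tsv(cls, path, framework: bool = True) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={"locus_id": "locus", "cM": "cm"})
        if "framework" not in df.columns:
            df["framework"] = framework
        return cls(df)

    def write_tsv(self, path) -> None:
        out = self.df.rename(columns={"locus": "locus_id", "cm": "cM"})
        out.to_csv(path, sep="\t", index=False)

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def positions(self, group: str) -> pd.DataFrame:
        sub = self.df[self.df["group"] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} not on map")
        return sub

    def position_of(self, locus: str) -> tuple[str, float]:
        row = self.df[self.df["locus"] == locus]
        if row.empty:
            raise KeyError(f"locus {locus!r} not on map")
        return row.iloc[0]["group"], float(row.iloc[0]["cm"])

    def add_placed(self, locus: str, group: str, cm: float) -> None:
        self.df = pd.concat(
            [self.df, pd.DataFrame([{"locus": locus, "group": group,
                                     "cm": cm, "framework": False}])],
            ignore_index=True,
        )
        self._sort()

    def framework_view(self) -> pd.DataFrame:
        return self.df[self.df["framework"]].reset_index(drop=True)


@dataclass
class RecombEstimate:
    """Pooled two-point recombination between a candidate and one marker."""

    candidate: str
    framework: str
    group: str
    framework_cm: float
    recombinant: int = 0
    informative: int = 0
    per_population: list = field(default_factory=list)

    @property
    def r_hat(self) -> float:
        if self.informative == 0:
            return np.nan
        return self.recombinant / self.informative


@dataclass
class Placement:
    candidate: str
    status: str                     # placed | unplaceable | ambiguous
    group: str | None = None
    cm: float | None = None
    flank1: str | None = None
    flank2: str | None = None
    r1: float = np.nan
    r2: float = np.nan


def two_point_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[int, int]:
    """Recombinant and informative line counts for one marker pair.

    Operates on bi-allelic inbred calls (0/1); lines missing or heterozygous
    at either locus are excluded.  Parental phase is fixed per population as
    the more frequent coupling, so recombinants = min(n00+n11, n01+n10).
    """
    ok = (
        (calls_a >= 0) & (calls_b >= 0)
        & ~is_het(calls_a) & ~is_het(calls_b)
    )
    a, b = calls_a[ok], calls_b[ok]
    # a pair is informative only if both markers segregate among the
    # jointly-called lines
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0, 0
    same = int(np.sum(a == b))
    diff = int(np.sum(a != b))
    return min(same, diff), same + diff


def pairwise_recomb(
    candidate: str,
    populations: list[GenotypeMatrix],
    framework_map: GeneticMap,
    min_informative: int = 10,
) -> list[RecombEstimate]:
    """Pool two-point recombination of ``candidate`` vs every framework marker.

    Each population contributes recombinant/informative counts with its own
    parental phase; counts (not fractions) are summed, weighting populations
    by information content.  Framework markers absent from a population are
    skipped there.
    """
    fw = framework_map.framework_view()
    estimates: dict[str, RecombEstimate] = {}
    for _, row in fw.iterrows():
        estimates[row["locus"]] = RecombEstimate(
            candidate, row["locus"], row["group"], float(row["cm"])
        )
    for pop in populations:
        try:
            cj = pop.locus_index(candidate)
        except KeyError:
            continue
        cand_calls = pop.calls[:, cj]
        for fid, est in estimates.items():
            try:
                fj = pop.locus_index(fid)
            except KeyError:
                continue
            rec, inf = two_point_counts(cand_calls, pop.calls[:, fj])
            if inf < min_informative:
                continue
            est.recombinant += rec
            est.informative += inf
            est.per_population.append((rec, inf))
    return [e for e in estimates.values() if e.informative > 0]


def place_marker(
    candidate: str,
    gmap: GeneticMap,
    estimates: list[RecombEstimate],
) -> Placement:
    """Place a candidate between its two least-recombining framework markers.

    The two flanks with lowest pooled r-hat are selected (ties broken by
    smaller cM gap between the two, then lexicographic id); the position is
    a linear interpolation between the flank positions weighted inversely by
    the two r-hat values: cm1 + gap * r1 / (r1 + r2).  If both are zero the
    candidate snaps to the shared lowest position.  Flanks on different
    groups leave the marker unplaced with an ambiguity flag.
    """
    informative = [e for e in estimates if e.informative > 0]
    if not informative:
        return Placement(candidate, "unplaceable")
    ranked = sorted(informative, key=lambda e: (e.r_hat, e.framework))
    if len(ranked) < 2:
        return Placement(candidate, "unplaceable")
    best = ranked[0]
    # candidates for the second flank: next-lowest r-hat; ties resolved by
    # the smaller cM gap to the first flank, then id
    rest = ranked[1:]
    low_r = min(e.r_hat for e in rest)
    tied = [e for e in rest if e.r_hat == low_r]
    second = min(
        tied, key=lambda e: (abs(e.framework_cm - best.framework_cm), e.framework)
    )
    if best.group != second.group:
        return Placement(
            candidate, "ambiguous", flank1=best.framework,
            flank2=second.framework, r1=best.r_hat, r2=second.r_hat,
        )
    r1, r2 = best.r_hat, second.r_hat
    cm1, cm2 = best.framework_cm, second.framework_cm
    if r1 + r2 == 0:
        cm = cm1
    else:
        cm = cm1 + (cm2 - cm1) * r1 / (r1 + r2)
    return Placement(
        candidate, "placed", group=best.group, cm=float(cm),
        flank1=best.framework, flank2=second.framework, r1=r1, r2=r2,
    )


def place_markers(
    candidates: list[str],
    populations: list[GenotypeMatrix],
    gmap: GeneticMap,
    min_informative: int = 10,
) -> list[Placement]:
    """Place a batch of candidates; placed positions are added to the map."""
    out = []
    for cand in candidates:
        est = pairwise_recomb(cand, populations, gmap, min_informative)
        placement = place_marker(cand, gmap, est)
        if placement.status == "placed":
            gmap.add_placed(cand, placement.group, placement.cm)
        out.append(placement)
    return out


def placement_report(placements: list[Placement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": p.candidate, "group": p.group, "position": p.cm,
                "flank1": p.flank1, "flank2": p.flank2,
                "r1": p.r1, "r2": p.r2, "status": p.status,
            }
            for p in placements
        ]
    )


def map_span(gmap: GeneticMap, group: str) -> float:
    """Map length of a group: max position - min position (negatives legal)."""
    sub = gmap.positions(group)
    if sub.empty:
        raise ValueError(f"group {group!r} has no markers")
    return float(sub["cm"].max() - sub["cm"].min())


def bin_map(gmap: GeneticMap, group: str, width: float = 1.0) -> pd.DataFrame:
    """Per-bin marker counts with half-open bins [k, k+width).

    Bins are anchored at floor(min position); returns one row per non-empty
    bin with its start position and marker count.
    """
    sub = gmap.positions(group)
    pos = sub["cm"].to_numpy()
    anchor = np.floor(pos.min())
    idx = np.floor((pos - anchor) / width).astype(int)
    counts = np.bincount(idx)
    rows = [
        {"group": group, "bin_start": anchor + k * width, "count": int(c)}
        for k, c in enumerate(counts)
        if c > 0
    ]
    return pd.DataFrame(rows)


def bin_count_vector(gmap: GeneticMap, group: str, width: float = 1.0) -> np.ndarray:
    """Dense bin-count vector (including empty bins) for map comparisons."""
    sub = gmap.positions(group)
    pos = sub["cm"].to_numpy()
    anchor = np.floor(pos.min())
    idx = np.floor((pos - anchor) / width).astype(int)
    return np.bincount(idx)
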