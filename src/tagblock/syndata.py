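"""Synthetic inbred GBS panels, RIL populations and quantitative traits.

The generator emulates a structured, near-homozygous crop diversity panel of
the kind produced by tag-level haplotype GBS pipelines: two (or more)
subpopulations with admixture, multi-allelic tag-level (TL) loci whose
alleles expand deterministically into 1-3 component SNPs, genetic-map-
structured LD with cosegregating marker clusters, loci under divergent
selection, configurable missing-data and residual-heterozygosity rates, and
an additive multi-environment trait.

Lines are built by a founder-mosaic (copying) model: a small set of founder
haplotypes is simulated per linkage group and every line is a recombination
mosaic of founders, with subpopulation-specific founder-usage weights
providing drift.  This produces blockwise LD that decays with cM distance
without the cost of a full coalescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Locus, het_code

#: founder haplotypes per linkage group
_N_FOUNDERS = 8


@dataclass
class TraitConfig:
    """Additive trait with QTL, polygenic background and environment effects.

    ``h2`` is the across-environment line-mean heritability; the residual
    variance is solved from it.  The default 16 environments mirror a
    multi-location-year heading-date trial series.
    """

    n_qtl: int = 10
    qtl_effect_sd: float = 1.0
    h2: float = 0.5
    n_env: int = 16
    env_effect_sd: float = 1.0
    mu: float = 100.0


@dataclass
class SimConfig:
    """Panel-simulation settings.

    Defaults emulate a two-subpopulation elite oat diversity panel: 497
    spring + 123 southern lines, mostly bi-allelic TL loci with a tail of
    higher allele counts, moderate drift and admixture, ~1% residual
    heterozygosity and 20% missing calls.
    """

    seed: int = 0
    n_groups: int = 5
    group_length_cm: float = 150.0
    n_tl_loci: int = 1000
    n_snp_loci: int = 0
    #: weights over 2..6 tag alleles per TL locus
    allele_count_distribution: tuple = (0.55, 0.25, 0.12, 0.05, 0.03)
    subpop_sizes: tuple = (497, 123)
    admixture: float = 0.2
    fst_drift: float = 0.15
    n_selected_loci: int = 0
    selection_displacement: float = 0.4
    missing_rate: float = 0.2
    het_rate: float = 0.01
    coseg_frac: float = 0.1
    #: effective mosaic-switch generations; sets the LD decay scale.  The
    #: default emulates a diversity panel with many breeding generations,
    #: giving sub-cM haplotype blocks.
    ld_generations: float = 40.0
    trait: TraitConfig = field(default_factory=TraitConfig)

    def validate(self) -> None:
        if not 0.0 <= self.trait.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if len(self.subpop_sizes) < 1:
            raise ValueError("at least one subpopulation required")
        if any(s < 2 for s in self.subpop_sizes):
            raise ValueError("subpopulation sizes must be >= 2")
        if not 0.0 <= self.admixture <= 1.0:
            raise ValueError("admixture must lie in [0, 1]")
        if self.trait.n_env < 1:
            raise ValueError("n_env must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    founder_states: dict          # locus id -> founder allele indices
    positions: dict               # locus id -> (group, cM)
    selected_loci: list           # TL locus ids under divergent selection
    qtl: dict                     # locus id -> per-allele effect vector
    tbv: np.ndarray               # per-line true breeding value
    subpop: np.ndarray            # per-line subpopulation index
    true_calls: np.ndarray        # TL calls before missing/het injection
    coseg_clusters: list          # lists of cosegregating TL locus ids


def _founder_weights(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subpopulation founder-usage weights (drift via Dirichlet)."""
    n_sub = len(cfg.subpop_sizes)
    if cfg.fst_drift <= 0:
        w = np.full((n_sub, _N_FOUNDERS), 1.0 / _N_FOUNDERS)
    else:
        conc = (1.0 - cfg.fst_drift) / cfg.fst_drift
        w = rng.dirichlet(np.full(_N_FOUNDERS, conc), size=n_sub)
    mean = w.mean(axis=0)
    return (1.0 - cfg.admixture) * w + cfg.admixture * mean


def simulate_panel(cfg: SimConfig):
    """Simulate an inbred diversity panel.

    Returns
    -------
    tl : GenotypeMatrix
        Multi-allelic tag-level loci (single-decimal ids), map positions set.
    snp : GenotypeMatrix
        Component SNPs of every TL allele (two-decimal ids) plus any extra
        independent bi-allelic loci, on the same lines.
    truth : SimTruth
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_lines = int(sum(cfg.subpop_sizes))
    subpop = np.repeat(np.arange(len(cfg.subpop_sizes)), cfg.subpop_sizes)
    line_ids = [f"L{i:04d}" for i in range(n_lines)]

    # --- map: positions per group, with cosegregating clusters -----------
    per_group = np.full(cfg.n_groups, cfg.n_tl_loci // cfg.n_groups)
    per_group[: cfg.n_tl_loci % cfg.n_groups] += 1
    groups, cms, coseg_head = [], [], []
    for g in range(cfg.n_groups):
        m = per_group[g]
        pos = np.sort(rng.uniform(0.0, cfg.group_length_cm, size=m))
        head = np.ones(m, dtype=bool)
        for j in range(1, m):
            if rng.random() < cfg.coseg_frac:
                pos[j] = pos[j - 1]
                head[j] = False
        groups.extend([f"Mrg{g + 1:02d}"] * m)
        cms.extend(pos)
        coseg_head.extend(head)
    cms = np.asarray(cms)
    coseg_head = np.asarray(coseg_head)

    # --- TL loci: allele counts, frequencies, founder states -------------
    k_choices = np.arange(2, 2 + len(cfg.allele_count_distribution))
    p = np.asarray(cfg.allele_count_distribution, dtype=float)
    allele_counts = rng.choice(k_choices, size=cfg.n_tl_loci, p=p / p.sum())
    founder_states = np.zeros((cfg.n_tl_loci, _N_FOUNDERS), dtype=np.int32)
    tl_loci = []
    clusters: list[list[str]] = []
    for j in range(cfg.n_tl_loci):
        k = int(allele_counts[j])
        lid = f"synt_{j + 1}.1"
        if not coseg_head[j]:
            # cluster member: identical founder pattern (and allele count)
            founder_states[j] = founder_states[j - 1]
            k = len(tl_loci[-1].alleles)
            clusters[-1].append(lid)
        else:
            freqs = rng.dirichlet(np.full(k, 1.5))
            states = rng.choice(k, size=_N_FOUNDERS, p=freqs)
            while len(np.unique(states)) < 2:  # founders must segregate
                states = rng.choice(k, size=_N_FOUNDERS, p=freqs)
            founder_states[j] = states
            clusters.append([lid])
        codes = [chr(ord("a") + c) for c in range(k)]
        tl_loci.append(Locus(lid, codes, group=groups[j], cm=cms[j]))

    # --- lines as founder mosaics -----------------------------------------
    weights = _founder_weights(cfg, rng)
    n_sub = len(cfg.subpop_sizes)
    cum_w = np.cumsum(weights, axis=1)

    def _draw_founders(sel: np.ndarray, f: np.ndarray) -> None:
        # inverse-CDF draw from each line's subpopulation founder weights
        u = rng.random(int(sel.sum()))
        rows = cum_w[subpop[sel]]
        f[sel] = (u[:, None] > rows).sum(axis=1)

    calls = np.zeros((n_lines, cfg.n_tl_loci), dtype=np.int32)
    group_arr = np.asarray(groups)
    for gname in dict.fromkeys(groups):
        idx = np.where(group_arr == gname)[0]
        gaps = np.diff(cms[idx])
        p_switch = 1.0 - np.exp(-cfg.ld_generations * gaps / 100.0)
        f = np.zeros(n_lines, dtype=np.int64)
        _draw_founders(np.ones(n_lines, dtype=bool), f)
        calls[:, idx[0]] = founder_states[idx[0], f]
        for step, j in enumerate(idx[1:]):
            switch = rng.random(n_lines) < p_switch[step]
            if switch.any():
                _draw_founders(switch, f)
            calls[:, j] = founder_states[j, f]

    # --- divergent selection ----------------------------------------------
    # selected loci receive a direct between-subpopulation allele-frequency
    # displacement: calls are redrawn per line with the favoured allele at
    # frequency 0.5 +/- displacement/2 depending on the subpopulation.
    # Only singleton loci are eligible so cosegregation clusters stay intact.
    singleton = coseg_head.copy()
    for j in range(cfg.n_tl_loci - 1):
        if j + 1 < cfg.n_tl_loci and not coseg_head[j + 1]:
            singleton[j] = False
    eligible = np.where(singleton)[0]
    n_sel = min(cfg.n_selected_loci, len(eligible))
    selected = (
        rng.choice(eligible, size=n_sel, replace=False) if n_sel else []
    )
    selected_ids = []
    delta = cfg.selection_displacement
    for j in np.sort(np.asarray(selected, dtype=int)):
        k = len(tl_loci[j].alleles)
        fav = int(rng.integers(k))
        others = np.array([c for c in range(k) if c != fav])
        for s in range(len(cfg.subpop_sizes)):
            sign = 1.0 if s % 2 == 0 else -1.0
            f_s = np.clip(0.5 + sign * delta / 2.0, 0.0, 1.0)
            sel_lines = np.where(subpop == s)[0]
            take = rng.random(len(sel_lines)) < f_s
            calls[sel_lines[take], j] = fav
            if (~take).any():
                calls[sel_lines[~take], j] = rng.choice(
                    others, size=int((~take).sum())
                )
        selected_ids.append(tl_loci[j].id)

    true_calls = calls.copy()

    # --- QTL and true breeding values --------------------------------------
    tc = cfg.trait
    qtl: dict[str, np.ndarray] = {}
    if tc.n_qtl > 0:
        qtl_idx = rng.choice(cfg.n_tl_loci, size=min(tc.n_qtl, cfg.n_tl_loci),
                             replace=False)
        for j in np.sort(qtl_idx):
            k = len(tl_loci[j].alleles)
            eff = rng.normal(0.0, tc.qtl_effect_sd, size=k)
            qtl[tl_loci[j].id] = eff
    poly_idx = np.array([j for j in range(cfg.n_tl_loci)
                         if tl_loci[j].id not in qtl])
    poly_sd = (tc.qtl_effect_sd / max(np.sqrt(len(poly_idx)), 1.0)) * 0.5
    id_to_idx = {loc.id: j for j, loc in enumerate(tl_loci)}
    tbv = np.zeros(n_lines)
    for lid, eff in qtl.items():
        tbv += eff[true_calls[:, id_to_idx[lid]]]
    for j in poly_idx:
        k = len(tl_loci[j].alleles)
        eff = rng.normal(0.0, poly_sd, size=k)
        tbv += eff[true_calls[:, j]]

    # --- TL allele -> component-SNP expansion -------------------------------
    snp_loci, snp_cols = [], []
    for j, loc in enumerate(tl_loci):
        k = len(loc.alleles)
        n_snp = int(rng.integers(1, 4))
        # each TL allele is a short haplotype over n_snp SNP positions
        haplos = rng.integers(0, 2, size=(k, n_snp))
        while any(len(np.unique(haplos[:, s])) < 2 for s in range(n_snp)):
            haplos = rng.integers(0, 2, size=(k, n_snp))
        for s in range(n_snp):
            sid = f"{loc.id}.{s + 1}"
            loc.snp_children.append(sid)
            snp_loci.append(Locus(sid, ["A", "C"], group=loc.group, cm=loc.cm))
            snp_cols.append(haplos[calls[:, j], s].astype(np.int32))
    for j in range(cfg.n_snp_loci):
        sid = f"synsnp_{j + 1}.1.1"
        g = int(rng.integers(cfg.n_groups))
        cm = float(rng.uniform(0.0, cfg.group_length_cm))
        snp_loci.append(Locus(sid, ["A", "C"], group=f"Mrg{g + 1:02d}", cm=cm))
        f = rng.uniform(0.1, 0.9)
        snp_cols.append((rng.random(n_lines) < f).astype(np.int32))
    snp_calls = np.stack(snp_cols, axis=1)

    # --- missing and heterozygous calls -------------------------------------
    def _inject(mat_calls, loci):
        if cfg.het_rate > 0:
            mask = rng.random(mat_calls.shape) < cfg.het_rate
            for i, j in zip(*np.where(mask)):
                k = len(loci[j].alleles)
                if k < 2:
                    continue
                other = int(rng.integers(k - 1))
                if other >= mat_calls[i, j]:
                    other += 1
                mat_calls[i, j] = het_code(int(mat_calls[i, j]), other)
        if cfg.missing_rate > 0:
            mask = rng.random(mat_calls.shape) < cfg.missing_rate
            mat_calls[mask] = MISSING
        return mat_calls

    calls = _inject(calls, tl_loci)
    snp_calls = _inject(snp_calls, snp_loci)

    tl = GenotypeMatrix(line_ids, tl_loci, calls)
    snp = GenotypeMatrix(line_ids, snp_loci, snp_calls)
    truth = SimTruth(
        founder_states={loc.id: founder_states[j] for j, loc in enumerate(tl_loci)},
        positions={loc.id: (loc.group, loc.cm) for loc in tl_loci + snp_loci},
        selected_loci=selected_ids,
        qtl=qtl,
        tbv=tbv,
        subpop=subpop,
        true_calls=true_calls,
        coseg_clusters=[c for c in clusters if len(c) > 1],
    )
    return tl, snp, truth


# ---------------------------------------------------------------------------
# RIL populations
# ---------------------------------------------------------------------------

def haldane_r(d_cm: float) -> float:
    """Two-point recombination fraction at map distance ``d_cm`` (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def ril_r(d_cm: float) -> float:
    """Observed recombinant fraction between F-infinity RILs: 2r/(1+2r)."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril(
    matrix: GenotypeMatrix,
    parent_a: int,
    parent_b: int,
    n_lines: int,
    seed: int,
) -> GenotypeMatrix:
    """Simulate fully inbred RILs from two homozygous parents of ``matrix``.

    Per line and linkage group the parental origin follows a Markov chain
    whose switch probability between adjacent markers at distance ``d`` is
    the RIL-adjusted Haldane fraction 2r/(1+2r), r = (1-exp(-2d/100))/2, so
    two-point recombinant fractions match the F-infinity expectation.
    Unplaced markers and different groups segregate independently.
    """
    if n_lines < 10:
        raise ValueError("n_lines must be >= 10")
    pa, pb = matrix.calls[parent_a], matrix.calls[parent_b]
    if np.any(pa < MISSING) or np.any(pb < MISSING):
        raise ValueError("parents must be fully homozygous")
    if not np.any((pa != pb) & (pa != MISSING) & (pb != MISSING)):
        raise ValueError("parents share every non-missing call")
    rng = np.random.default_rng(seed)
    n_loci = matrix.n_loci
    groups = np.asarray([loc.group or "_unplaced" for loc in matrix.loci])
    cms = np.asarray([loc.cm if loc.cm is not None else np.nan
                      for loc in matrix.loci])
    origin = np.zeros((n_lines, n_loci), dtype=np.int8)
    for gname in dict.fromkeys(groups):
        idx = np.where(groups == gname)[0]
        order = idx[np.argsort(cms[idx], kind="stable")]
        if gname == "_unplaced" or np.isnan(cms[order]).any():
            origin[:, order] = rng.integers(0, 2, size=(n_lines, len(order)))
            continue
        gaps = np.diff(cms[order])
        p_switch = np.array([ril_r(d) for d in gaps])
        state = rng.integers(0, 2, size=n_lines)
        origin[:, order[0]] = state
        for step, j in enumerate(order[1:]):
            flip = rng.random(n_lines) < p_switch[step]
            state = np.where(flip, 1 - state, state)
            origin[:, j] = state
    calls = np.where(origin == 0, pa[None, :], pb[None, :]).astype(np.int32)
    line_ids = [f"RIL{i:04d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids, list(matrix.loci), calls)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_trait(
    matrix: GenotypeMatrix,
    truth: SimTruth,
    trait: TraitConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate a line x environment phenotype table from true breeding values.

    y[line, env] = mu + g[line] + env[env] + e, with Var(e) solved so the
    across-environment line-mean heritability equals ``trait.h2``:
    sigma_e^2 = n_env * sigma_g^2 * (1 - h2) / h2.  At h2 = 0 the genetic
    term is dropped (pure noise); at h2 = 1 the residual is zero.
    """
    if trait.n_env < 1:
        raise ValueError("n_env must be >= 1")
    if not 0.0 <= trait.h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = truth.tbv
    var_g = float(np.var(g))
    if trait.h2 == 0.0 or var_g == 0.0:
        g_used = np.zeros_like(g)
        sd_e = 1.0
    else:
        g_used = g
        var_e = trait.n_env * var_g * (1.0 - trait.h2) / trait.h2
        sd_e = float(np.sqrt(var_e))
    env_eff = rng.normal(0.0, trait.env_effect_sd, size=trait.n_env)
    records = []
    for e in range(trait.n_env):
        noise = rng.normal(0.0, sd_e, size=len(g)) if sd_e > 0 else np.zeros(len(g))
        vals = trait.mu + g_used + env_eff[e] + noise
        for i, lid in enumerate(matrix.line_ids):
            records.append((lid, f"env{e + 1:02d}", float(vals[i])))
    return pd.DataFrame(records, columns=["line", "env", "value"])
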