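"""Synthetic data generators with controllable planted ground truth.

Every input the pipeline consumes can be generated here: a genome of
non-overlapping genes with 16 phylostratigraphic age classes, a
promoter-fragment contact network with a planted same-category edge
preference, H3K27me3 peak sets with category-biased promoter coverage, LAD
intervals with category-biased gene overlap, Pol II coverage tracks with
planted promoter/body density ratios, expression/variability tables with a
planted age trend, and differential-expression tables with category-specific
up/down proportions.

Generator defaults mirror the magnitudes the analyses target: category
shares 38/45/17% (UC/EM/MM), Polycomb promoter rates 16/34/14%, LAD gene
overlap 7/13/15%, pausing strongest for the oldest genes, age-expression
trend |rho| = 0.95.  Determinism: one master seed; each generator draws from
an independent stream keyed by (seed, generator name), so adding a generator
never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin_network import ChromatinNetwork, write_ibed
from .genome_features import (
    CATEGORIES,
    DEFAULT_CATEGORY_BOUNDS,
    N_AGE_CLASSES,
    AgeTable,
    DETable,
    GeneModel,
    GenomicInterval,
    PeakSet,
    write_genes_tsv,
    write_lads_bed,
    _write_commented_tsv,
)
from .pol2_pausing import body_region, promoter_region
from .tracks import SignalTrack

__all__ = [
    "SyntheticConfig",
    "ScenarioBundle",
    "default_class_weights",
    "make_genome",
    "make_network",
    "make_peaks",
    "make_lads",
    "make_coverage",
    "make_expression",
    "make_de",
    "make_cpg_sites",
    "make_methylation",
    "make_scenario",
    "write_dataset",
]

_MIN_GENE_SPACING = 2000


def default_class_weights() -> tuple[float, ...]:
    """16 class weights whose category sums match the published shares.

    UC : EM : MM = 7397 : 8682 : 3325 of 19404 genes, spread uniformly over
    the classes inside each category at the default (3, 9) bounds.
    """
    uc, em, mm = 7397 / 19404, 8682 / 19404, 3325 / 19404
    w = [uc / 3] * 3 + [em / 6] * 6 + [mm / 7] * 7
    total = sum(w)
    return tuple(x / total for x in w)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study system; defaults ARE the study conditions."""

    n_genes: int = 1000
    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    class_weights: tuple[float, ...] = field(default_factory=default_class_weights)
    category_bounds: tuple[int, int] = DEFAULT_CATEGORY_BOUNDS
    n_edges: int = 3000
    p_within: float = 0.3
    trans_fraction: float = 0.05
    multi_gene_fraction: float = 0.0
    peak_prob_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 0.16, "EM": 0.34, "MM": 0.14}
    )
    lad_fraction: float = 0.12
    lad_enrichment_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 0.583, "EM": 1.083, "MM": 1.25}
    )
    pi_mean_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 2.5, "EM": 1.8, "MM": 1.2}
    )
    cell_states: tuple[str, ...] = ("hESC", "B-cell", "B-CLL")
    cell_pi_scale: Mapping[str, float] = field(
        default_factory=lambda: {"hESC": 1.2, "B-cell": 1.0, "B-CLL": 1.4}
    )
    coverage_binsize: int = 10
    noise_sd: float = 0.1
    rho_target: float = 0.95
    cpg_rate_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 5.0, "EM": 3.0, "MM": 1.0}
    )
    meth_mean_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 0.2, "EM": 0.5, "MM": 0.8}
    )
    de_up_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 0.14, "EM": 0.32, "MM": 0.59}
    )
    de_down_by_category: Mapping[str, float] = field(
        default_factory=lambda: {"UC": 0.05, "EM": 0.03, "MM": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_weights) != N_AGE_CLASSES:
            raise ValueError("class_weights must have 16 entries")
        if any(w < 0 for w in self.class_weights):
            raise ValueError("class_weights must be non-negative")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1 within 1e-9")
        b1, b2 = self.category_bounds
        if not (1 <= b1 < b2 < N_AGE_CLASSES):
            raise ValueError("category_bounds must be strictly increasing within 1..16")
        for name, probs in (
            ("peak_prob_by_category", self.peak_prob_by_category),
            ("de_up_by_category", self.de_up_by_category),
            ("de_down_by_category", self.de_down_by_category),
        ):
            for cat, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{cat}] must be in [0, 1]")
        if not (0.0 <= self.p_within <= 1.0):
            raise ValueError("p_within must be in [0, 1]")
        if not (0.0 <= self.trans_fraction <= 1.0):
            raise ValueError("trans_fraction must be in [0, 1]")
        if not (0.0 <= self.lad_fraction <= 1.0):
            raise ValueError("lad_fraction must be in [0, 1]")
        if any(v <= 0 for v in self.pi_mean_by_category.values()):
            raise ValueError("pi_mean_by_category must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.rho_target) > 1:
            raise ValueError("rho_target must be in [-1, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream keyed by (seed, stream name)."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# genome and ages
# ---------------------------------------------------------------------------


def make_genome(config: SyntheticConfig) -> tuple[list[GeneModel], AgeTable]:
    """Non-overlapping, jittered-grid genes with random strands and ages.

    Gene lengths are log-normal (median ~2.2 kb, sigma 1.0), so roughly a
    fifth of genes fall under 1 kb and exercise the pausing length filter.
    """
    rng = config.rng("genome")
    per_chrom = _split_even(config.n_genes, config.n_chromosomes)
    genes: list[GeneModel] = []
    idx = 0
    for c, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        spacing = config.chrom_length // n_c
        if spacing < _MIN_GENE_SPACING:
            raise ValueError(
                f"{config.n_genes} genes at minimum spacing {_MIN_GENE_SPACING} bp "
                f"exceed the genome: chr{c + 1} would space genes {spacing} bp apart"
            )
        chrom = f"chr{c + 1}"
        for i in range(n_c):
            jitter = int(rng.integers(0, max(1, spacing // 5)))
            start = i * spacing + jitter
            length = int(np.clip(rng.lognormal(math.log(2200), 1.0), 200, int(spacing * 0.7)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{idx:05d}", chrom, start, start + length, strand))
            idx += 1
    counts = rng.multinomial(config.n_genes, np.asarray(config.class_weights))
    classes = np.repeat(np.arange(1, N_AGE_CLASSES + 1), counts)
    rng.shuffle(classes)
    ages = AgeTable(
        {g.gene_id: int(k) for g, k in zip(genes, classes)}, bounds=config.category_bounds
    )
    return genes, ages


def _split_even(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


# ---------------------------------------------------------------------------
# contact network
# ---------------------------------------------------------------------------


def _promoter_fragments(
    genes: Sequence[GeneModel], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[GenomicInterval], list[tuple[str, ...]], np.ndarray]:
    """One promoter fragment per gene; optionally co-host ~2 genes per
    fragment on a fraction of fragments (multi-gene-node aggregation)."""
    host = np.arange(len(genes))
    if config.multi_gene_fraction > 0:
        by_chrom: dict[str, list[int]] = {}
        for i, g in enumerate(genes):
            by_chrom.setdefault(g.chrom, []).append(i)
        n_pairs = int(round(config.multi_gene_fraction * len(genes) / 2))
        candidates = []
        for idxs in by_chrom.values():
            candidates.extend((idxs[j], idxs[j + 1]) for j in range(0, len(idxs) - 1, 2))
        rng.shuffle(candidates)
        for a, b in candidates[:n_pairs]:
            host[b] = a
    fragments: list[GenomicInterval] = []
    node_genes: list[tuple[str, ...]] = []
    node_of = np.full(len(genes), -1, dtype=np.int64)
    for i, g in enumerate(genes):
        if host[i] != i:
            continue
        members = [j for j in range(len(genes)) if host[j] == i]
        tss = [genes[j].tss for j in members]
        frag = GenomicInterval(g.chrom, max(0, min(tss) - 500), max(tss) + 500)
        node_idx = len(fragments)
        fragments.append(frag)
        node_genes.append(tuple(sorted(genes[j].gene_id for j in members)))
        for j in members:
            node_of[j] = node_idx
    return fragments, node_genes, node_of


def make_network(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> ChromatinNetwork:
    """Contact network with a planted same-category edge preference.

    With probability ``p_within`` an edge joins two genes of the same
    category, otherwise two genes at random — so the same-category edge
    fraction is ~ ``p_within + (1 - p_within) * q`` with q the random-pairing
    same-category rate.  A ``trans_fraction`` of edges is inter-chromosomal;
    cis edges carry |fragment-midpoint difference| as distance.
    """
    n = len(genes)
    if config.n_edges > n * (n - 1) // 2:
        raise ValueError(f"cannot place {config.n_edges} edges among {n} genes")
    rng = config.rng("network")
    fragments, node_genes, node_of = _promoter_fragments(genes, config, rng)

    chroms = sorted({g.chrom for g in genes})
    by_chrom = {c: np.array([i for i, g in enumerate(genes) if g.chrom == c]) for c in chroms}
    cat_of = np.array([CATEGORIES.index(ages.category(g.gene_id)) for g in genes])
    by_cat = {k: np.flatnonzero(cat_of == k) for k in range(len(CATEGORIES))}
    by_chrom_cat = {
        (c, k): by_chrom[c][cat_of[by_chrom[c]] == k] for c in chroms for k in range(3)
    }
    chrom_w = np.array([len(by_chrom[c]) * (len(by_chrom[c]) - 1) for c in chroms], float)
    chrom_w /= chrom_w.sum()
    cat_w = np.array([len(by_cat[k]) * (len(by_cat[k]) - 1) for k in range(3)], float)
    cat_w = cat_w / cat_w.sum() if cat_w.sum() else cat_w

    def draw_pair() -> tuple[int, int]:
        trans = config.n_chromosomes > 1 and rng.random() < config.trans_fraction
        within = rng.random() < config.p_within
        for _ in range(1000):
            if trans:
                pool = by_cat[_choice(rng, cat_w)] if within else np.arange(n)
                if len(pool) < 2:
                    within = False
                    continue
                i, j = pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]
                if i == j or genes[i].chrom == genes[j].chrom:
                    continue
                return int(i), int(j)
            c = chroms[_choice(rng, chrom_w)]
            if within:
                weights = np.array(
                    [max(0, len(by_chrom_cat[(c, k)]) - 1) * len(by_chrom_cat[(c, k)]) for k in range(3)],
                    float,
                )
                if weights.sum() == 0:
                    within = False
                    continue
                pool = by_chrom_cat[(c, _choice(rng, weights / weights.sum()))]
            else:
                pool = by_chrom[c]
            if len(pool) < 2:
                continue
            i, j = pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]
            if i != j:
                return int(i), int(j)
        raise RuntimeError("could not draw an edge pair")

    edges, dists = _collect_edges(
        config.n_edges, draw_pair, node_of, fragments, rng
    )
    return ChromatinNetwork(fragments, node_genes, edges, dists)


def _choice(rng: np.random.Generator, w: np.ndarray) -> int:
    return int(rng.choice(len(w), p=w))


def _collect_edges(n_edges, draw_pair, node_of, fragments, rng):
    """Draw gene pairs, map to nodes, dedupe; returns (edges, distances)."""
    n_nodes = len(fragments)
    used: set[int] = set()
    ea, eb, dd = [], [], []
    guard = 0
    while len(ea) < n_edges:
        guard += 1
        if guard > 200 * n_edges:
            raise RuntimeError("edge budget infeasible after many attempts")
        i, j = draw_pair()
        a, b = int(node_of[i]), int(node_of[j])
        if a == b:
            continue
        if a > b:
            a, b = b, a
        key = a * n_nodes + b
        if key in used:
            continue
        used.add(key)
        ea.append(a)
        eb.append(b)
        fa, fb = fragments[a], fragments[b]
        dd.append(abs(fa.midpoint - fb.midpoint) if fa.chrom == fb.chrom else np.nan)
    return np.c_[np.array(ea, dtype=np.int64), np.array(eb, dtype=np.int64)], np.array(dd)


# ---------------------------------------------------------------------------
# peaks, LADs
# ---------------------------------------------------------------------------


def make_peaks(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> PeakSet:
    """H3K27me3-like peaks: category-biased TSS coverage plus background.

    For each gene, with probability ``peak_prob_by_category[category]`` emit
    one peak (500-3000 bp) containing the TSS; background peaks avoid every
    TSS so they never create extra Polycomb targets.
    """
    rng = config.rng("peaks")
    intervals: list[GenomicInterval] = []
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}

    for g in genes:
        p = config.peak_prob_by_category.get(ages.category(g.gene_id), 0.0)
        if rng.random() >= p:
            continue
        width = int(rng.integers(500, 3001))
        offset = int(rng.integers(0, width))
        start = max(0, g.tss - offset)
        intervals.append(GenomicInterval(g.chrom, start, start + width))

    chroms = sorted(tss_by_chrom)
    n_background = max(10, len(genes) // 2)
    placed = 0
    attempts = 0
    while chroms and placed < n_background and attempts < 50 * max(1, n_background):
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(500, 3001))
        start = int(rng.integers(0, max(1, config.chrom_length - width)))
        tss = tss_by_chrom[chrom]
        lo = np.searchsorted(tss, start, "left")
        hi = np.searchsorted(tss, start + width, "left")
        if hi > lo:  # would cover a TSS
            continue
        intervals.append(GenomicInterval(chrom, start, start + width))
        placed += 1
    return PeakSet(intervals)


def make_lads(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> tuple[list[GenomicInterval], list[str]]:
    """LAD intervals covering ~``lad_fraction`` of the genome with
    category-biased gene overlap.

    Each gene is wrapped in a LAD with probability
    ``min(1, lad_fraction * enrichment[category])``; gene-free filler
    intervals (and, if still short, any uncovered region) top coverage up to
    the target.  Intervals get random constitutive/facultative labels.
    Internally a 1 kb occupancy mask keeps the union arithmetic exact.
    """
    res = 1000
    rng = config.rng("lads")
    if config.lad_fraction == 0:
        return [], []
    nb = config.chrom_length // res
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    lad_mask = {c: np.zeros(nb, dtype=bool) for c in chroms}
    gene_mask = {c: np.zeros(nb, dtype=bool) for c in chroms}
    for g in genes:
        gene_mask[g.chrom][g.start // res : min(nb, -(-g.end // res))] = True

    for g in genes:
        enrich = config.lad_enrichment_by_category.get(ages.category(g.gene_id), 1.0)
        p = min(1.0, config.lad_fraction * enrich)
        if rng.random() >= p:
            continue
        pad = int(rng.integers(2, 10)) * res
        lo = max(0, (g.start - pad) // res)
        hi = min(nb, -(-(g.end + pad) // res))
        lad_mask[g.chrom][lo:hi] = True

    total_bins = nb * len(chroms)
    target = int(round(config.lad_fraction * total_bins))

    def covered() -> int:
        return int(sum(m.sum() for m in lad_mask.values()))

    # fill with gene-free runs first, then anywhere
    for allow_genes in (False, True):
        attempts = 0
        while covered() < target and attempts < 20000:
            attempts += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            run = int(rng.integers(20, 200))
            start = int(rng.integers(0, max(1, nb - run)))
            sel = np.arange(start, min(nb, start + run))
            free = ~lad_mask[chrom][sel]
            if not allow_genes:
                free &= ~gene_mask[chrom][sel]
            take = sel[free][: max(0, target - covered())]
            lad_mask[chrom][take] = True
        if covered() >= target:
            break

    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    for chrom in chroms:
        mask = lad_mask[chrom]
        edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
        for lo, hi in zip(edges[::2], edges[1::2]):
            intervals.append(GenomicInterval(chrom, int(lo) * res, int(hi) * res))
            labels.append("constitutive" if rng.random() < 0.5 else "facultative")
    return intervals, labels


# ---------------------------------------------------------------------------
# coverage, expression, DE, methylation
# ---------------------------------------------------------------------------


def make_coverage(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> dict[str, SignalTrack]:
    """Pol II-like coverage per cell state with planted pausing ratios.

    Each gene gets a base body level b ~ U(0.5, 2); promoter bins sit at
    b * PI(category) * cell scale, body bins at b, with truncated-Gaussian
    noise (sd = ``noise_sd``).  Bins are chopped from each region's start so
    no bin straddles the promoter/body boundary — in the noiseless limit the
    measured PI equals the planted ratio exactly.  Sparse intergenic bins sit
    near zero.
    """
    tracks: dict[str, SignalTrack] = {}
    bs = config.coverage_binsize
    for cell in config.cell_states:
        rng = config.rng(f"coverage:{cell}")
        scale = config.cell_pi_scale.get(cell, 1.0)
        rows: list[tuple[str, int, int, float]] = []
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            for g in gs:
                base = float(rng.uniform(0.5, 2.0))
                pi = config.pi_mean_by_category[ages.category(g.gene_id)] * scale
                for region, level in (
                    (promoter_region(g), base * pi),
                    (body_region(g), base),
                ):
                    if region is None:
                        continue
                    pos = region.start
                    while pos < region.end:
                        end = min(pos + bs, region.end)
                        v = level + (rng.normal(0, config.noise_sd) if config.noise_sd else 0.0)
                        rows.append((chrom, pos, end, max(0.0, v)))
                        pos = end
            # intergenic bins at gap centres, near zero
            for g_prev, g_next in zip(gs, gs[1:]):
                mid = (g_prev.end + g_next.start) // 2
                if g_next.start - g_prev.end < 120:
                    continue
                for k in range(-1, 2):
                    s = mid + k * bs
                    v = rng.normal(0, config.noise_sd) if config.noise_sd else 0.0
                    rows.append((chrom, s, s + bs, max(0.0, v)))
        tracks[cell] = SignalTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        )
    return tracks


def make_expression(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> pd.DataFrame:
    """Per-gene expression and expression variability with planted age trends.

    Class-mean expression decreases strictly with age class index and EV
    increases, before noise.  Class-level jitter is scaled so the realized
    class-mean Spearman against class index lands near -rho_target
    (expression) and +rho_target (EV): for x vs x + noise the Pearson is
    1 / sqrt(1 + s^2/var(x)), inverted for the jitter scale s.
    """
    rng = config.rng("expression")
    expr_step, ev_step = 0.5, 0.05
    k_idx = np.arange(1, N_AGE_CLASSES + 1)
    expr_means = 12.0 - expr_step * (k_idx - 1)
    ev_means = 0.2 + ev_step * (k_idx - 1)
    rho = abs(config.rho_target)
    if config.noise_sd > 0 and 0 < rho < 1:
        jitter = math.sqrt(1.0 / rho**2 - 1.0) * float(np.std(k_idx))
        expr_means = expr_means + rng.normal(0, expr_step * jitter, N_AGE_CLASSES)
        ev_means = ev_means + rng.normal(0, ev_step * jitter, N_AGE_CLASSES)
    rows = []
    for g in genes:
        k = ages.age_class(g.gene_id)
        expr = expr_means[k - 1] + (rng.normal(0, config.noise_sd) if config.noise_sd else 0.0)
        ev = ev_means[k - 1] + (rng.normal(0, config.noise_sd * ev_step) if config.noise_sd else 0.0)
        rows.append((g.gene_id, expr, max(0.0, ev)))
    return pd.DataFrame(rows, columns=["gene_id", "expression", "ev"])


def make_de(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> DETable:
    """DE table with planted per-category up/down proportions."""
    rng = config.rng("de")
    records: dict[str, tuple[float, float]] = {}
    for g in genes:
        cat = ages.category(g.gene_id)
        u = rng.random()
        up = config.de_up_by_category.get(cat, 0.0)
        down = config.de_down_by_category.get(cat, 0.0)
        if u < up:
            records[g.gene_id] = (float(rng.uniform(2.2, 6.0)), float(rng.uniform(0.0, 0.09)))
        elif u < up + down:
            records[g.gene_id] = (float(rng.uniform(-6.0, -2.2)), float(rng.uniform(0.0, 0.09)))
        elif rng.random() < 0.02:
            records[g.gene_id] = (float(rng.normal(0, 0.5)), math.nan)
        else:
            records[g.gene_id] = (float(rng.normal(0, 0.5)), float(rng.uniform(0.1, 1.0)))
    return DETable(records)


def make_cpg_sites(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> pd.DataFrame:
    """CpG site positions: Poisson counts per promoter, category-biased."""
    rng = config.rng("cpg")
    rows = []
    for g in genes:
        lam = config.cpg_rate_by_category.get(ages.category(g.gene_id), 1.0)
        for _ in range(int(rng.poisson(lam))):
            pos = int(np.clip(g.tss + rng.integers(-900, 901), 0, config.chrom_length - 1))
            rows.append((g.chrom, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def make_methylation(
    genes: Sequence[GeneModel], ages: AgeTable, config: SyntheticConfig
) -> pd.DataFrame:
    """Promoter methylation scores in [0, 1] around category-planted means."""
    rng = config.rng("methylation")
    rows = []
    for g in genes:
        mu = config.meth_mean_by_category.get(ages.category(g.gene_id), 0.5)
        for _ in range(int(rng.integers(2, 6))):
            pos = int(np.clip(g.tss + rng.integers(-900, 901), 0, config.chrom_length - 1))
            score = float(np.clip(rng.normal(mu, config.noise_sd * 0.5), 0.0, 1.0))
            rows.append((g.chrom, pos, score))
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


# ---------------------------------------------------------------------------
# planted cell-state scenarios
# ---------------------------------------------------------------------------

# fraction of the planted (within-category) edge budget per category
SCENARIO_STRENGTHS: dict[str, dict[str, float]] = {
    "differentiated": {"UC": 0.64, "EM": 0.26, "MM": 0.06},
    "oncogenesis": {"UC": 0.56, "EM": 0.05, "MM": 0.38},
}
# chromatin feature whose positive genes carry each category's clustering
SCENARIO_COUPLING = {"UC": "pol2", "EM": "polycomb", "MM": "lad"}
SCENARIO_FEATURE_RATES: dict[str, dict[str, float]] = {
    "pol2": {"UC": 0.40, "EM": 0.30, "MM": 0.25},
    "polycomb": {"UC": 0.16, "EM": 0.34, "MM": 0.14},
    "lad": {"UC": 0.10, "EM": 0.18, "MM": 0.45},
}
SCENARIO_WITHIN_FRACTION = 0.5


@dataclass
class ScenarioBundle:
    """A cell-state scenario: genes, ages, network and gene-level features."""

    name: str
    genes: list[GeneModel]
    ages: AgeTable
    network: ChromatinNetwork
    features: dict[str, dict[str, int]]
    config: SyntheticConfig


def make_scenario(name: str, config: SyntheticConfig) -> ScenarioBundle:
    """Build a planted cell-state network ("differentiated" or "oncogenesis").

    Both scenarios share the genome, ages and chromatin features drawn from
    the same seed; they differ only in how the planted within-category edge
    budget is split.  Within-category edges for a category are drawn only
    among its feature-positive genes (UC <- Pol II, EM <- Polycomb,
    MM <- LAD), so the features genuinely mediate the clustering:
    "differentiated" plants the strongest clustering for the oldest genes;
    "oncogenesis" collapses the EM share and inflates MM.
    """
    if name not in SCENARIO_STRENGTHS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIO_STRENGTHS)}")
    genes, ages = make_genome(config)
    feat_rng = config.rng("scenario-features")
    features: dict[str, dict[str, int]] = {}
    for feat, rates in SCENARIO_FEATURE_RATES.items():
        features[feat] = {
            g.gene_id: int(feat_rng.random() < rates[ages.category(g.gene_id)]) for g in genes
        }

    rng = config.rng(f"scenario-edges:{name}")
    frag_rng = config.rng("scenario-fragments")
    fragments, node_genes, node_of = _promoter_fragments(genes, config, frag_rng)
    n = len(genes)
    cat_of = [ages.category(g.gene_id) for g in genes]
    pools: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        feat = SCENARIO_COUPLING[cat]
        pool = np.array(
            [i for i in range(n) if cat_of[i] == cat and features[feat][genes[i].gene_id]]
        )
        if len(pool) < 2:  # degenerate plant: fall back to the whole category
            pool = np.array([i for i in range(n) if cat_of[i] == cat])
        pools[cat] = pool

    total_within = int(round(SCENARIO_WITHIN_FRACTION * config.n_edges))
    strengths = SCENARIO_STRENGTHS[name]
    budget = {cat: int(round(strengths[cat] * total_within)) for cat in CATEGORIES}
    chroms = sorted({g.chrom for g in genes})
    by_chrom = {c: np.array([i for i, g in enumerate(genes) if g.chrom == c]) for c in chroms}
    chrom_w = np.array([len(by_chrom[c]) * (len(by_chrom[c]) - 1) for c in chroms], float)
    chrom_w /= chrom_w.sum()

    plan: list[str | None] = []
    for cat in CATEGORIES:
        plan.extend([cat] * budget[cat])
    plan.extend([None] * (config.n_edges - len(plan)))

    n_nodes = len(fragments)
    used: set[int] = set()
    ea: list[int] = []
    eb: list[int] = []
    dd: list[float] = []

    def try_add(i: int, j: int) -> bool:
        a, b = int(node_of[i]), int(node_of[j])
        if a == b:
            return False
        if a > b:
            a, b = b, a
        key = a * n_nodes + b
        if key in used:
            return False
        used.add(key)
        ea.append(a)
        eb.append(b)
        fa, fb = fragments[a], fragments[b]
        dd.append(abs(fa.midpoint - fb.midpoint) if fa.chrom == fb.chrom else np.nan)
        return True

    for cat in plan:
        placed = False
        if cat is not None:
            pool = pools[cat]
            max_pairs = len(pool) * (len(pool) - 1) // 2
            for _ in range(1000):
                i, j = pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]
                if i != j and try_add(int(i), int(j)):
                    placed = True
                    break
                if len(used) >= max_pairs and max_pairs > 0:
                    break  # pool saturated; spill to background
        while not placed:
            if len(chroms) > 1 and rng.random() < config.trans_fraction:
                i, j = int(rng.integers(n)), int(rng.integers(n))
                if i == j or genes[i].chrom == genes[j].chrom:
                    continue
            else:
                pool_bg = by_chrom[chroms[_choice(rng, chrom_w)]]
                if len(pool_bg) < 2:
                    continue
                i, j = int(pool_bg[rng.integers(len(pool_bg))]), int(
                    pool_bg[rng.integers(len(pool_bg))]
                )
                if i == j:
                    continue
            placed = try_add(i, j)

    edges = np.c_[np.array(ea, dtype=np.int64), np.array(eb, dtype=np.int64)]
    net = ChromatinNetwork(fragments, node_genes, edges, np.array(dd))
    return ScenarioBundle(name, genes, ages, net, features, config)


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the path map.

    All outputs are plain text: TSV with '#' headers, BED, bedGraph, and the
    ibed interaction dialect.  Identical config + seed gives byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, ages = make_genome(config)
    net = make_network(genes, ages, config)
    peaks = make_peaks(genes, ages, config)
    lads, lad_labels = make_lads(genes, ages, config)
    coverage = make_coverage(genes, ages, config)
    expression = make_expression(genes, ages, config)
    de = make_de(genes, ages, config)
    cpg = make_cpg_sites(genes, ages, config)
    meth = make_methylation(genes, ages, config)

    paths: dict[str, Path] = {}
    paths["genes"] = out / "genes.tsv"
    write_genes_tsv(genes, paths["genes"])
    paths["ages"] = out / "ages.tsv"
    ages.write_tsv(paths["ages"])
    paths["interactions"] = out / "interactions.ibed"
    write_ibed(net, paths["interactions"], seed=int(config.rng("ibed-scores").integers(2**31)))
    paths["peaks"] = out / "peaks.bed"
    peaks.write_bed(paths["peaks"])
    paths["lads"] = out / "lads.bed"
    write_lads_bed(lads, paths["lads"], lad_labels)
    for cell, track in coverage.items():
        key = f"coverage:{cell}"
        paths[key] = out / f"pol2_{cell.replace(' ', '_')}.bedgraph"
        track.to_bedgraph(paths[key])
    paths["expression"] = out / "expression.tsv"
    _write_commented_tsv(expression, paths["expression"])
    paths["de"] = out / "de.tsv"
    de.write_tsv(paths["de"])
    paths["cpg_sites"] = out / "cpg_sites.tsv"
    _write_commented_tsv(cpg, paths["cpg_sites"])
    paths["methylation"] = out / "methylation.tsv"
    _write_commented_tsv(meth, paths["methylation"])
    return paths
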