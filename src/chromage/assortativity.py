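"""Chromatin assortativity (ChAs), distance-matched nulls, z-scores, ΔChAs.

ChAs is the Pearson correlation of a node feature across the two endpoints of
every edge of a chromatin-contact network, computed on the symmetrized
(oriented-both-ways) edge list.  Because genomically close fragments contact
each other trivially, significance is assessed against a null that rewires
edges while preserving each edge's genomic-distance bin: z = (observed -
null mean) / null sd over ``n_rand`` rewired networks, with feature values
held fixed on the nodes.

ΔChAs asks whether a chromatin feature (Pol II, Polycomb, LAD, ...) drives
the 3D clustering of a gene group: within the group, the ChAs z-score of the
feature-positive subgroup minus that of the feature-negative subgroup,
computed against a shared stream of null networks.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin_network import ChromatinNetwork, NodeFeature, map_feature

__all__ = [
    "DegenerateFeatureError",
    "DistanceBinning",
    "ChAsResult",
    "DeltaChAsResult",
    "chas",
    "chas_categorical",
    "randomize_distmatch",
    "permute_feature",
    "chas_zscore",
    "chas_zscore_multi",
    "chas_categorical_zscores",
    "delta_chas",
    "write_chas_tsv",
    "write_delta_chas_tsv",
]


class DegenerateFeatureError(ValueError):
    """Feature constant on the usable nodes, or too few usable edges."""


@dataclass(frozen=True)
class DistanceBinning:
    """log10 genomic-distance bins of fixed width; short range pooled.

    Distances below ``pool_below`` base pairs share bin 0; otherwise the bin
    is ``floor(log10(d) / width)``, which is >= 30 for d >= 1 kb at the
    default width, so pooled and logarithmic bins never collide.
    """

    width: float = 0.1
    pool_below: float = 1000.0

    def bin_of(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        out = np.zeros(d.shape, dtype=np.int64)
        big = d >= self.pool_below
        with np.errstate(divide="ignore"):
            out[big] = np.floor(np.log10(d[big]) / self.width).astype(np.int64)
        return out


@dataclass
class ChAsResult:
    feature: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_rand: int
    n_nodes_used: int
    n_edges_used: int
    degenerate: bool = False
    null_samples: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass
class DeltaChAsResult:
    group: str
    feature: str
    z_with: float
    z_without: float
    delta: float
    n_with: int
    n_without: int
    with_result: ChAsResult = field(repr=False, default=None)
    without_result: ChAsResult = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# observed ChAs
# ---------------------------------------------------------------------------


def _usable_edge_values(net: ChromatinNetwork, values: np.ndarray):
    """Endpoint value pairs over edges whose both endpoints are defined."""
    x = values[net.edge_a]
    y = values[net.edge_b]
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok], ok


def _chas_from_pairs(x: np.ndarray, y: np.ndarray) -> float:
    # Pearson over the symmetrized oriented list {(x,y)} ∪ {(y,x)}.
    m = (x.mean() + y.mean()) / 2.0
    dx = x - m
    dy = y - m
    var = float(np.sum(dx * dx) + np.sum(dy * dy))
    if var <= 0:
        raise DegenerateFeatureError("feature constant on usable nodes")
    cov = float(2.0 * np.sum(dx * dy))
    return cov / var


def chas(net: ChromatinNetwork, f: NodeFeature) -> float:
    """Observed chromatin assortativity of a node feature.

    Pearson correlation of endpoint values over the symmetrized edge list;
    edges with an undefined endpoint are excluded.  Raises
    :class:`DegenerateFeatureError` when fewer than two usable edges remain
    or the feature is constant on the nodes those edges touch.
    """
    values = f.as_array(net)
    x, y, _ = _usable_edge_values(net, values)
    if len(x) < 2:
        raise DegenerateFeatureError(
            f"feature {f.name!r}: only {len(x)} usable edges (need >= 2)"
        )
    return _chas_from_pairs(x, y)


def chas_categorical(
    net: ChromatinNetwork, category_assignment: Mapping[str, Set[str]]
) -> dict[str, float]:
    """Per-category ChAs from multi-label node categories.

    For each category c, ChAs of the binary indicator (node carries c).
    Nodes absent from the assignment stay undefined; a node with several
    categories contributes 1 to each of its indicators.  Degenerate
    categories come back as NaN with a warning, never silently dropped.
    """
    cats = sorted({c for s in category_assignment.values() for c in s})
    out: dict[str, float] = {}
    for cat in cats:
        f = NodeFeature(
            name=cat,
            kind="binary",
            values={nid: float(cat in s) for nid, s in category_assignment.items()},
        )
        try:
            out[cat] = chas(net, f)
        except DegenerateFeatureError as exc:
            warnings.warn(f"category {cat!r}: {exc}", stacklevel=2)
            out[cat] = float("nan")
    return out


# ---------------------------------------------------------------------------
# distance-matched randomization null
# ---------------------------------------------------------------------------

_POOL_PAIR_LIMIT = 5_000_000
_MAX_ATTEMPTS = 1000


def _pair_pools(net: ChromatinNetwork, binning: DistanceBinning):
    """All same-chromosome node pairs grouped by distance bin.

    Enumerating pairs once lets every draw be an exact uniform sample from a
    bin's pair population.  Cached on the network; above ``_POOL_PAIR_LIMIT``
    pairs the randomizer falls back to per-edge rejection sampling.
    """
    key = (binning.width, binning.pool_below)
    cache = getattr(net, "_distmatch_pools", None)
    if cache is not None and key in cache:
        return cache[key]
    n_pairs = 0
    for c in range(len(net.chrom_names)):
        nc = int(np.sum(net.node_chrom == c))
        n_pairs += nc * (nc - 1) // 2
    if n_pairs > _POOL_PAIR_LIMIT:
        pools = None
    else:
        acc_a: dict[int, list[np.ndarray]] = {}
        acc_b: dict[int, list[np.ndarray]] = {}
        for c in range(len(net.chrom_names)):
            idx = np.flatnonzero(net.node_chrom == c)
            if len(idx) < 2:
                continue
            ii, jj = np.triu_indices(len(idx), k=1)
            gi, gj = idx[ii], idx[jj]
            d = np.abs(net.node_mid[gi] - net.node_mid[gj])
            bins = binning.bin_of(d)
            for b in np.unique(bins):
                sel = bins == b
                acc_a.setdefault(int(b), []).append(gi[sel])
                acc_b.setdefault(int(b), []).append(gj[sel])
        pools = {
            b: (np.concatenate(acc_a[b]), np.concatenate(acc_b[b])) for b in acc_a
        }
    if cache is None:
        cache = {}
        net._distmatch_pools = cache
    cache[key] = pools
    return pools


def _chrom_sorted_positions(net: ChromatinNetwork):
    out = {}
    for c in range(len(net.chrom_names)):
        idx = np.flatnonzero(net.node_chrom == c)
        order = np.argsort(net.node_mid[idx])
        out[c] = (idx[order], net.node_mid[idx][order])
    return out


def _bin_bounds(b: int, binning: DistanceBinning) -> tuple[float, float]:
    if b == 0:
        return 0.0, binning.pool_below
    return 10 ** (b * binning.width), 10 ** ((b + 1) * binning.width)


def randomize_distmatch(
    net: ChromatinNetwork,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    binning: DistanceBinning = DistanceBinning(),
) -> ChromatinNetwork:
    """Rewire edges while preserving each edge's genomic-distance bin.

    The returned network has the identical node set and edge count; every cis
    edge is replaced by a uniformly sampled same-chromosome node pair from
    the same log-distance bin, every trans edge by a uniform
    inter-chromosomal pair; no self-loops or duplicates.  When a bin offers
    no unused alternative within the attempt cap, the original edge is kept
    and counted in ``n_fallback_edges`` — the per-bin distance histogram is
    preserved exactly either way.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if net.n_edges == 0 or not np.any(net.is_cis()):
        raise ValueError("network must have at least one cis edge")
    pools = _pair_pools(net, binning)
    sorted_pos = None if pools is not None else _chrom_sorted_positions(net)
    n = net.n_nodes
    cis = net.is_cis()
    orig_bins = binning.bin_of(np.where(cis, net.edge_distance, 0.0))
    used: set[int] = set()
    new_a = np.empty(net.n_edges, dtype=np.int64)
    new_b = np.empty(net.n_edges, dtype=np.int64)
    new_d = np.empty(net.n_edges, dtype=float)
    n_fallback = 0

    for e in range(net.n_edges):
        oa, ob = int(net.edge_a[e]), int(net.edge_b[e])
        if not cis[e]:
            # trans: uniform inter-chromosomal pair
            for _ in range(_MAX_ATTEMPTS):
                i = int(rng.integers(n))
                j = int(rng.integers(n))
                if i == j or net.node_chrom[i] == net.node_chrom[j]:
                    continue
                a, b = (i, j) if i < j else (j, i)
                if a * n + b in used:
                    continue
                break
            else:
                a, b = oa, ob
                n_fallback += 1
            if a * n + b in used:
                a, b = _first_unused_trans(net, used)
            used.add(a * n + b)
            new_a[e], new_b[e], new_d[e] = a, b, np.nan
            continue

        bb = int(orig_bins[e])
        a = b = -1
        if pools is not None:
            pool = pools.get(bb)
            if pool is not None and len(pool[0]):
                pa, pb = pool
                m = len(pa)
                for _ in range(min(_MAX_ATTEMPTS, 4 * m + 8)):
                    k = int(rng.integers(m))
                    i, j = int(pa[k]), int(pb[k])
                    a_, b_ = (i, j) if i < j else (j, i)
                    if a_ * n + b_ in used:
                        continue
                    a, b = a_, b_
                    break
        else:
            d_lo, d_hi = _bin_bounds(bb, binning)
            chrom_nodes = sorted_pos
            for _ in range(_MAX_ATTEMPTS):
                i = int(rng.integers(n))
                c = int(net.node_chrom[i])
                idx, pos = chrom_nodes[c]
                p = net.node_mid[i]
                lo_r = np.searchsorted(pos, p + d_lo, "left")
                hi_r = np.searchsorted(pos, p + d_hi, "left")
                lo_l = np.searchsorted(pos, p - d_hi, "right")
                hi_l = np.searchsorted(pos, p - d_lo, "right")
                cands = np.concatenate([idx[lo_l:hi_l], idx[lo_r:hi_r]])
                cands = cands[cands != i]
                if len(cands) == 0:
                    continue
                j = int(cands[rng.integers(len(cands))])
                a_, b_ = (i, j) if i < j else (j, i)
                if a_ * n + b_ in used:
                    continue
                d_ij = abs(net.node_mid[i] - net.node_mid[j])
                if binning.bin_of(np.array([d_ij]))[0] != bb:
                    continue
                a, b = a_, b_
                break
        if a < 0:
            # bin exhausted: keep the original edge (same bin by definition)
            a, b = oa, ob
            n_fallback += 1
            if a * n + b in used and pools is not None:
                pa, pb = pools[bb]
                for k in range(len(pa)):
                    i, j = int(pa[k]), int(pb[k])
                    a_, b_ = (i, j) if i < j else (j, i)
                    if a_ * n + b_ not in used:
                        a, b = a_, b_
                        break
                else:
                    raise RuntimeError(f"distance bin {bb} has no unused pair left")
        used.add(a * n + b)
        new_a[e], new_b[e] = a, b
        new_d[e] = abs(net.node_mid[a] - net.node_mid[b])

    out = net.with_edges(np.c_[new_a, new_b], new_d)
    out.n_fallback_edges = n_fallback
    # nulls share the parent's pair pools (same node set)
    out._distmatch_pools = getattr(net, "_distmatch_pools", None)
    return out


def _first_unused_trans(net: ChromatinNetwork, used: set[int]) -> tuple[int, int]:
    n = net.n_nodes
    for a in range(n):
        for b in range(a + 1, n):
            if net.node_chrom[a] != net.node_chrom[b] and a * n + b not in used:
                return a, b
    raise RuntimeError("no unused trans pair left")


def permute_feature(
    f: NodeFeature, rng: np.random.Generator
) -> NodeFeature:
    """Plain feature-permutation null: shuffle values over defined nodes."""
    nids = list(f.values)
    vals = np.array([f.values[n] for n in nids], dtype=float)
    rng.shuffle(vals)
    return NodeFeature(f.name, f.kind, dict(zip(nids, vals.tolist())))


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


def chas_zscore(
    net: ChromatinNetwork,
    f: NodeFeature,
    n_rand: int = 100,
    seed: int | None = None,
    null: str = "distmatch",
    binning: DistanceBinning = DistanceBinning(),
) -> ChAsResult:
    """ChAs z-score of one feature against the distance-matched null.

    The observed ChAs is compared with its distribution over ``n_rand``
    rewired networks (feature values fixed to nodes); z uses the sample
    (n-1) standard deviation.  ``null="permute"`` swaps in the plain
    feature-shuffle null for comparison.
    """
    return chas_zscore_multi(net, {f.name: f}, n_rand, seed, null, binning)[f.name]


def chas_zscore_multi(
    net: ChromatinNetwork,
    features: Mapping[str, NodeFeature],
    n_rand: int = 100,
    seed: int | None = None,
    null: str = "distmatch",
    binning: DistanceBinning = DistanceBinning(),
) -> dict[str, ChAsResult]:
    """z-scores for several features sharing one stream of null networks.

    Sharing nulls both saves the dominant cost (rewiring) and gives common
    random numbers to statistics that are later differenced (ΔChAs).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if null not in ("distmatch", "permute"):
        raise ValueError(f"unknown null {null!r}")
    arrays = {name: f.as_array(net) for name, f in features.items()}
    observed: dict[str, float] = {}
    used_counts: dict[str, tuple[int, int]] = {}
    for name, arr in arrays.items():
        x, y, ok = _usable_edge_values(net, arr)
        if len(x) < 2:
            raise DegenerateFeatureError(f"feature {name!r}: fewer than 2 usable edges")
        observed[name] = _chas_from_pairs(x, y)
        nodes_used = np.unique(np.r_[net.edge_a[ok], net.edge_b[ok]])
        used_counts[name] = (len(nodes_used), int(ok.sum()))

    rng = np.random.default_rng(seed)
    nulls = {name: np.empty(n_rand) for name in features}
    for r in range(n_rand):
        if null == "distmatch":
            rnet = randomize_distmatch(net, rng=rng, binning=binning)
            for name, arr in arrays.items():
                x, y, _ = _usable_edge_values(rnet, arr)
                nulls[name][r] = _chas_from_pairs(x, y) if len(x) >= 2 else np.nan
        else:
            for name, f in features.items():
                pf = permute_feature(f, rng)
                arr = pf.as_array(net)
                x, y, _ = _usable_edge_values(net, arr)
                nulls[name][r] = _chas_from_pairs(x, y) if len(x) >= 2 else np.nan

    out: dict[str, ChAsResult] = {}
    for name in features:
        sample = nulls[name][~np.isnan(nulls[name])]
        mean = float(np.mean(sample)) if len(sample) else float("nan")
        sd = float(np.std(sample, ddof=1)) if len(sample) > 1 else 0.0
        degenerate = sd == 0.0 or len(sample) < 2
        z = float("nan") if degenerate else (observed[name] - mean) / sd
        out[name] = ChAsResult(
            feature=name,
            observed=observed[name],
            null_mean=mean,
            null_sd=sd,
            z=z,
            n_rand=n_rand,
            n_nodes_used=used_counts[name][0],
            n_edges_used=used_counts[name][1],
            degenerate=degenerate,
            null_samples=sample,
        )
    return out


def chas_categorical_zscores(
    net: ChromatinNetwork,
    category_assignment: Mapping[str, Set[str]],
    n_rand: int = 100,
    seed: int | None = None,
    null: str = "distmatch",
) -> dict[str, ChAsResult]:
    """Per-category indicator z-scores against one shared null stream."""
    cats = sorted({c for s in category_assignment.values() for c in s})
    features = {
        cat: NodeFeature(
            name=cat,
            kind="binary",
            values={nid: float(cat in s) for nid, s in category_assignment.items()},
        )
        for cat in cats
    }
    return chas_zscore_multi(net, features, n_rand, seed, null)


def delta_chas(
    net: ChromatinNetwork,
    group: Set[str],
    feature: Set[str],
    n_rand: int = 100,
    seed: int | None = None,
    group_name: str = "group",
    feature_name: str = "feature",
    null: str = "distmatch",
) -> DeltaChAsResult:
    """ΔChAs: does a chromatin feature drive a gene group's 3D clustering?

    Splits ``group`` into feature-positive (group ∩ feature) and
    feature-negative (group − feature) gene subgroups, computes the ChAs
    z-score of each subgroup's binary node indicator against a *shared*
    stream of distance-matched nulls, and reports
    ``delta = z_with - z_without``.  Positive delta implicates the feature in
    holding the group together in 3D.
    """
    with_genes = set(group) & set(feature)
    without_genes = set(group) - set(feature)
    net_genes = net.genes
    if not (with_genes & net_genes):
        raise ValueError(f"subgroup '{group_name} with {feature_name}' is empty on the network")
    if not (without_genes & net_genes):
        raise ValueError(
            f"subgroup '{group_name} without {feature_name}' is empty on the network"
        )
    indicators = {}
    for label, subset in (("with", with_genes), ("without", without_genes)):
        gene_feature = {g: float(g in subset) for g in net_genes}
        indicators[label] = map_feature(net, gene_feature, "binary", name=label)
    results = chas_zscore_multi(net, indicators, n_rand=n_rand, seed=seed, null=null)
    zw, zo = results["with"].z, results["without"].z
    return DeltaChAsResult(
        group=group_name,
        feature=feature_name,
        z_with=zw,
        z_without=zo,
        delta=zw - zo,
        n_with=len(with_genes & net_genes),
        n_without=len(without_genes & net_genes),
        with_result=results["with"],
        without_result=results["without"],
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def write_chas_tsv(results: Mapping[str, ChAsResult], path: str | Path) -> None:
    from .genome_features import _write_commented_tsv

    frame = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "n_rand": r.n_rand,
                "nodes": r.n_nodes_used,
                "edges": r.n_edges_used,
            }
            for r in results.values()
        ]
    )
    _write_commented_tsv(frame, path)


def write_delta_chas_tsv(results: Sequence[DeltaChAsResult], path: str | Path) -> None:
    from .genome_features import _write_commented_tsv

    frame = pd.DataFrame(
        [
            {
                "group": r.group,
                "feature": r.feature,
                "z_with": r.z_with,
                "z_without": r.z_without,
                "delta": r.delta,
                "n_with": r.n_with,
                "n_without": r.n_without,
            }
            for r in results
        ]
    )
    _write_commented_tsv(frame, path)
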