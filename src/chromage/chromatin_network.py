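"""Promoter-capture Hi-C interaction parsing and chromatin-network construction.

Significant PCHi-C interaction calls (CHiCAGO score > 5) become an undirected
graph whose nodes are restriction fragments and whose edges are contacts.
Each edge carries its genomic distance (absolute difference of fragment
midpoints) when cis, or a trans flag.  Gene-level features are lifted onto
nodes (OR for binary features, mean for continuous), which is the substrate
for chromatin assortativity.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_features import GeneModel, GenomicInterval

__all__ = [
    "InteractionRecord",
    "ParseReport",
    "ChromatinNetwork",
    "NodeFeature",
    "load_interactions",
    "build_network",
    "promoter_subnetwork",
    "map_feature",
    "assign_genes_to_fragments",
    "write_ibed",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One filtered PCHi-C call: bait fragment, other end, CHiCAGO score."""

    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    other_end: GenomicInterval
    oe_genes: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("CHiCAGO score must be >= 0")

    @property
    def is_trans(self) -> bool:
        return self.bait.chrom != self.other_end.chrom

    @property
    def distance(self) -> float | None:
        """|midpoint difference| for cis pairs, None for trans."""
        if self.is_trans:
            return None
        return abs(self.bait.midpoint - self.other_end.midpoint)


@dataclass
class ParseReport:
    n_rows: int = 0
    n_kept: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_rows - self.n_kept


_IBED_COLUMNS = (
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "otherEnd_chr",
    "otherEnd_start",
    "otherEnd_end",
    "otherEnd_name",
    "N_reads",
    "score",
)


def _parse_names(field_value: str) -> tuple[str, ...]:
    if field_value in (".", "", "-", "NA"):
        return ()
    return tuple(n for n in field_value.replace(",", ";").split(";") if n and n != ".")


def load_interactions(
    path: str | Path, score_threshold: float = 5.0
) -> tuple[list[InteractionRecord], ParseReport]:
    """Read an ibed interaction table, keeping scores strictly above threshold.

    The ibed dialect is tab-separated with columns
    ``bait_chr bait_start bait_end bait_name oe_chr oe_start oe_end oe_name
    N_reads score`` and an optional header line.  Input coordinates are
    1-based inclusive and converted to 0-based half-open here, nowhere else.
    """
    records: list[InteractionRecord] = []
    report = ParseReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts and parts[0] in ("bait_chr", "bait_chrom"):
                continue  # header
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: expected 10 ibed columns, got {len(parts)}")
            try:
                bait = GenomicInterval(parts[0], int(parts[1]) - 1, int(parts[2]))
                oe = GenomicInterval(parts[4], int(parts[5]) - 1, int(parts[6]))
                score = float(parts[9])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed ibed row ({exc})") from None
            report.n_rows += 1
            if score <= score_threshold:
                continue
            report.n_kept += 1
            records.append(
                InteractionRecord(bait, _parse_names(parts[3]), oe, _parse_names(parts[7]), score)
            )
    if report.n_rows and not records:
        warnings.warn(
            f"no interactions above CHiCAGO score {score_threshold} in {path}", stacklevel=2
        )
    return records, report


class ChromatinNetwork:
    """Fragment-contact graph: fragments as nodes, filtered calls as edges.

    Nodes are keyed ``chrom:start-end``; a node is a promoter node iff it has
    at least one resident gene.  Edges are undirected, deduplicated,
    self-loop-free, and carry genomic distance (NaN marks trans contacts).
    """

    def __init__(
        self,
        fragments: Sequence[GenomicInterval],
        genes_per_node: Sequence[tuple[str, ...]],
        edges: np.ndarray,
        distances: np.ndarray,
    ) -> None:
        if len(fragments) != len(genes_per_node):
            raise ValueError("fragments and genes_per_node must be parallel")
        self.fragments = list(fragments)
        self.node_genes = [tuple(g) for g in genes_per_node]
        self.node_ids = [f"{f.chrom}:{f.start}-{f.end}" for f in self.fragments]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate fragments must be merged before construction")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        distances = np.asarray(distances, dtype=float).reshape(-1)
        if len(edges) != len(distances):
            raise ValueError("edges and distances must be parallel")
        if len(edges):
            if edges.min() < 0 or edges.max() >= len(self.fragments):
                raise ValueError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
        a = np.minimum(edges[:, 0], edges[:, 1]) if len(edges) else edges[:, 0]
        b = np.maximum(edges[:, 0], edges[:, 1]) if len(edges) else edges[:, 1]
        keys = a * len(self.fragments) + b
        if len(keys) != len(set(keys.tolist())):
            raise ValueError("duplicate edges are not allowed")
        self.edge_a = a
        self.edge_b = b
        self.edge_distance = distances
        self.n_fallback_edges = 0  # set by randomization when bins run dry
        self._chrom_names = sorted({f.chrom for f in self.fragments})
        chrom_code = {c: i for i, c in enumerate(self._chrom_names)}
        self.node_chrom = np.array([chrom_code[f.chrom] for f in self.fragments], dtype=np.int64)
        self.node_mid = np.array([f.midpoint for f in self.fragments], dtype=float)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.fragments)

    @property
    def n_edges(self) -> int:
        return len(self.edge_a)

    @property
    def is_promoter(self) -> np.ndarray:
        return np.array([len(g) > 0 for g in self.node_genes], dtype=bool)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chrom_names)

    def node_index(self, node_id: str) -> int:
        return self._index[node_id]

    @property
    def genes(self) -> set[str]:
        return {g for gs in self.node_genes for g in gs}

    def edge_keys(self) -> set[int]:
        n = self.n_nodes
        return set((self.edge_a * n + self.edge_b).tolist())

    def is_cis(self) -> np.ndarray:
        return ~np.isnan(self.edge_distance)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edge_a, 1)
        np.add.at(deg, self.edge_b, 1)
        return deg

    def with_edges(self, edges: np.ndarray, distances: np.ndarray) -> "ChromatinNetwork":
        """Same node set, new edge set (used by randomization nulls)."""
        out = ChromatinNetwork.__new__(ChromatinNetwork)
        out.fragments = self.fragments
        out.node_genes = self.node_genes
        out.node_ids = self.node_ids
        out._index = self._index
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        out.edge_a = np.minimum(edges[:, 0], edges[:, 1])
        out.edge_b = np.maximum(edges[:, 0], edges[:, 1])
        out.edge_distance = np.asarray(distances, dtype=float).reshape(-1)
        out.n_fallback_edges = 0
        out._chrom_names = self._chrom_names
        out.node_chrom = self.node_chrom
        out.node_mid = self.node_mid
        return out

    # -- exports -----------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for nid, frag, genes in zip(self.node_ids, self.fragments, self.node_genes):
            g.add_node(nid, chrom=frag.chrom, start=frag.start, end=frag.end,
                       genes=";".join(genes), is_promoter=len(genes) > 0)
        for a, b, d in zip(self.edge_a, self.edge_b, self.edge_distance):
            g.add_edge(self.node_ids[a], self.node_ids[b],
                       distance=float(d) if not np.isnan(d) else -1.0,
                       trans=bool(np.isnan(d)))
        return g

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "chrom": [f.chrom for f in self.fragments],
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "genes": [";".join(g) for g in self.node_genes],
                "is_promoter": self.is_promoter.astype(int),
            }
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": [self.node_ids[i] for i in self.edge_a],
                "node_b": [self.node_ids[i] for i in self.edge_b],
                "distance_or_trans": [
                    "trans" if np.isnan(d) else f"{d:g}" for d in self.edge_distance
                ],
            }
        )

    def write_tsv(self, node_path: str | Path, edge_path: str | Path) -> None:
        from .genome_features import _write_commented_tsv

        _write_commented_tsv(self.node_table(), node_path)
        _write_commented_tsv(self.edge_table(), edge_path)

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


@dataclass
class NodeFeature:
    """A feature value per node; nodes absent from ``values`` are undefined.

    Undefined nodes are excluded edgewise from assortativity, never imputed.
    """

    name: str
    kind: str  # "binary" | "continuous"
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"kind must be binary or continuous, got {self.kind!r}")

    def as_array(self, net: ChromatinNetwork) -> np.ndarray:
        arr = np.full(net.n_nodes, np.nan)
        for nid, v in self.values.items():
            idx = net._index.get(nid)
            if idx is not None:
                arr[idx] = v
        return arr


def build_network(records: Iterable[InteractionRecord]) -> ChromatinNetwork:
    """Merge fragments and calls into the deduplicated contact graph.

    Identical fragments (chrom, start, end) become one node carrying the
    union of gene labels; duplicate contacts collapse to one edge; bait ==
    other-end rows are dropped (no self-loops).
    """
    frag_index: dict[tuple[str, int, int], int] = {}
    fragments: list[GenomicInterval] = []
    gene_sets: list[set[str]] = []

    def node_of(iv: GenomicInterval, genes: tuple[str, ...]) -> int:
        key = (iv.chrom, iv.start, iv.end)
        idx = frag_index.get(key)
        if idx is None:
            idx = len(fragments)
            frag_index[key] = idx
            fragments.append(GenomicInterval(iv.chrom, iv.start, iv.end))
            gene_sets.append(set())
        gene_sets[idx].update(genes)
        return idx

    edge_map: dict[tuple[int, int], float] = {}
    for rec in records:
        a = node_of(rec.bait, rec.bait_genes)
        b = node_of(rec.other_end, rec.oe_genes)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key not in edge_map:
            d = rec.distance
            edge_map[key] = float("nan") if d is None else float(d)
    edges = np.array(list(edge_map.keys()), dtype=np.int64).reshape(-1, 2)
    dists = np.array(list(edge_map.values()), dtype=float)
    genes_per_node = [tuple(sorted(s)) for s in gene_sets]
    return ChromatinNetwork(fragments, genes_per_node, edges, dists)


def assign_genes_to_fragments(
    net: ChromatinNetwork, genes: Sequence[GeneModel]
) -> ChromatinNetwork:
    """Re-derive promoter labels from coordinates: gene g lives on a fragment
    iff the fragment contains g's TSS.  Coordinates win over any annotation
    carried in the interaction file."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    new_gene_sets: list[tuple[str, ...]] = []
    for frag in net.fragments:
        res = [
            g.gene_id
            for g in by_chrom.get(frag.chrom, [])
            if frag.start <= g.tss < frag.end
        ]
        new_gene_sets.append(tuple(sorted(res)))
    return ChromatinNetwork(
        net.fragments, new_gene_sets, np.c_[net.edge_a, net.edge_b], net.edge_distance
    )


def promoter_subnetwork(net: ChromatinNetwork, mode: str = "strict") -> ChromatinNetwork:
    """Induced subgraph on promoter nodes.

    "strict" (default) keeps only promoter-promoter edges — the
    promoter-promoter interaction network.  "inclusive" keeps every edge with
    at least one promoter endpoint, plus the non-promoter partners it touches.
    """
    if mode not in ("strict", "inclusive"):
        raise ValueError(f"unknown promoter subnetwork mode {mode!r}")
    promoter = net.is_promoter
    if mode == "strict":
        keep_nodes = np.flatnonzero(promoter)
        keep_edge = promoter[net.edge_a] & promoter[net.edge_b]
    else:
        keep_edge = promoter[net.edge_a] | promoter[net.edge_b]
        touched = np.zeros(net.n_nodes, dtype=bool)
        touched[net.edge_a[keep_edge]] = True
        touched[net.edge_b[keep_edge]] = True
        keep_nodes = np.flatnonzero(promoter | touched)
    remap = -np.ones(net.n_nodes, dtype=np.int64)
    remap[keep_nodes] = np.arange(len(keep_nodes))
    edges = np.c_[remap[net.edge_a[keep_edge]], remap[net.edge_b[keep_edge]]]
    return ChromatinNetwork(
        [net.fragments[i] for i in keep_nodes],
        [net.node_genes[i] for i in keep_nodes],
        edges,
        net.edge_distance[keep_edge],
    )


def map_feature(
    net: ChromatinNetwork,
    gene_feature: Mapping[str, float],
    kind: str,
    name: str = "feature",
) -> NodeFeature:
    """Lift a gene-level feature onto nodes.

    Binary: OR (max) over the node's annotated genes.  Continuous: arithmetic
    mean.  Nodes none of whose genes carry a value stay undefined and are
    excluded edgewise downstream.
    """
    if not gene_feature:
        warnings.warn("empty gene feature: all nodes undefined", stacklevel=2)
    values: dict[str, float] = {}
    for nid, gs in zip(net.node_ids, net.node_genes):
        vals = [float(gene_feature[g]) for g in gs if g in gene_feature]
        if not vals:
            continue
        values[nid] = max(vals) if kind == "binary" else float(np.mean(vals))
    return NodeFeature(name=name, kind=kind, values=values)


def write_ibed(
    net: ChromatinNetwork,
    path: str | Path,
    seed: int = 0,
    header: bool = True,
) -> None:
    """Export edges in the ibed dialect (1-based inclusive coordinates).

    Scores are deterministic draws from Uniform(5.01, 30) so every row passes
    the CHiCAGO > 5 filter on re-import; read counts are a monotone
    transformation of the score.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(_IBED_COLUMNS) + "\n")
        for a, b in zip(net.edge_a, net.edge_b):
            fa, fb = net.fragments[a], net.fragments[b]
            na = ";".join(net.node_genes[a]) or "."
            nb = ";".join(net.node_genes[b]) or "."
            score = rng.uniform(5.01, 30.0)
            n_reads = int(round(score * 3)) + 1
            fh.write(
                f"{fa.chrom}\t{fa.start + 1}\t{fa.end}\t{na}\t"
                f"{fb.chrom}\t{fb.start + 1}\t{fb.end}\t{nb}\t{n_reads}\t{score:.4f}\n"
            )
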