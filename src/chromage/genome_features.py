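"""Gene-centric annotation against evolutionary age classes.

Genes dated by phylostratigraphy fall into 16 age classes, grouped into three
broad categories: unicellular-ancestor (UC), early-metazoan (EM) and
mammal-specific (MM).  This module carries the coordinate types shared by the
whole package and the annotation rules that stratify genes by category:
Polycomb targets (H3K27me3 peak over the TSS), lamina-associated-domain (LAD)
genes, promoter CpG-site counts, promoter methylation aggregates, TSS-centred
metagene profiles and differential-expression classification.

All coordinates are 0-based, half-open.  1-based input dialects are converted
at parse time, never downstream.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .tracks import SignalTrack

CATEGORIES = ("UC", "EM", "MM")
DEFAULT_CATEGORY_BOUNDS = (3, 9)
N_AGE_CLASSES = 16

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATEGORY_BOUNDS",
    "N_AGE_CLASSES",
    "GenomicInterval",
    "GeneModel",
    "AgeTable",
    "PeakSet",
    "DETable",
    "age_category",
    "polycomb_targets",
    "lad_genes",
    "promoter_window",
    "count_promoter_sites",
    "promoter_methylation",
    "metagene_profile",
    "classify_de",
    "build_annotation_table",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_lads_bed",
    "write_lads_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene as a single stranded interval with one TSS and one TES."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty interval")
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start")

    @property
    def location(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def age_category(age_class: int, bounds: tuple[int, int] = DEFAULT_CATEGORY_BOUNDS) -> str:
    """Map an age class (1..16) onto UC / EM / MM.

    ``bounds = (b1, b2)`` puts classes ``<= b1`` in UC, ``b1 < class <= b2``
    in EM, and the rest in MM.  The 16-to-3 boundary is not uniquely fixed by
    the published class counts, so it stays configurable.
    """
    if not (1 <= age_class <= N_AGE_CLASSES):
        raise ValueError(f"age class must be in 1..{N_AGE_CLASSES}, got {age_class}")
    b1, b2 = bounds
    if not (1 <= b1 < b2 < N_AGE_CLASSES):
        raise ValueError(f"category bounds must satisfy 1 <= b1 < b2 < 16, got {bounds}")
    if age_class <= b1:
        return "UC"
    if age_class <= b2:
        return "EM"
    return "MM"


class AgeTable:
    """gene_id -> (age_class 1..16, category UC/EM/MM)."""

    def __init__(
        self,
        classes: Mapping[str, int],
        bounds: tuple[int, int] = DEFAULT_CATEGORY_BOUNDS,
    ) -> None:
        self.bounds = (int(bounds[0]), int(bounds[1]))
        self._classes: dict[str, int] = {}
        for gene_id, cls in classes.items():
            cls = int(cls)
            if not (1 <= cls <= N_AGE_CLASSES):
                raise ValueError(f"gene {gene_id}: age class {cls} outside 1..16")
            self._classes[str(gene_id)] = cls
        # validate bounds once
        age_category(1, self.bounds)

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._classes

    @property
    def genes(self) -> list[str]:
        return list(self._classes)

    def age_class(self, gene_id: str) -> int:
        return self._classes[gene_id]

    def category(self, gene_id: str) -> str:
        return age_category(self._classes[gene_id], self.bounds)

    def categories(self) -> dict[str, str]:
        return {g: self.category(g) for g in self._classes}

    def genes_in_category(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return {g for g in self._classes if self.category(g) == category}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self._classes),
                "age_class": list(self._classes.values()),
                "category": [self.category(g) for g in self._classes],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bounds=DEFAULT_CATEGORY_BOUNDS) -> "AgeTable":
        return cls(dict(zip(frame["gene_id"].astype(str), frame["age_class"].astype(int))), bounds)

    def write_tsv(self, path: str | Path) -> None:
        _write_commented_tsv(self.to_frame()[["gene_id", "age_class"]], path)

    @classmethod
    def read_tsv(cls, path: str | Path, bounds=DEFAULT_CATEGORY_BOUNDS) -> "AgeTable":
        frame = _read_commented_tsv(path, ["gene_id", "age_class"])
        return cls.from_frame(frame, bounds)


class PeakSet:
    """Unstranded peak intervals with point- and interval-overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos)) if tree is not None else False

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in sorted(self.intervals, key=lambda p: (p.chrom, p.start, p.end)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "PeakSet":
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                out.append(GenomicInterval(chrom, int(start), int(end)))
        return cls(out)


@dataclass
class DETable:
    """Differential-expression results: gene -> (log2FC, adjusted p or NaN)."""

    records: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DETable":
        recs = {}
        for gene_id, lfc, padj in zip(frame["gene_id"], frame["log2FC"], frame["padj"]):
            recs[str(gene_id)] = (float(lfc), float(padj) if pd.notna(padj) else math.nan)
        return cls(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.records),
                "log2FC": [v[0] for v in self.records.values()],
                "padj": [v[1] for v in self.records.values()],
            }
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DETable":
        return cls.from_frame(_read_commented_tsv(path, ["gene_id", "log2FC", "padj"]))

    def write_tsv(self, path: str | Path) -> None:
        _write_commented_tsv(self.to_frame(), path)


# ---------------------------------------------------------------------------
# annotation rules
# ---------------------------------------------------------------------------


def polycomb_targets(genes: Sequence[GeneModel], peaks: PeakSet) -> dict[str, int]:
    """Flag genes whose TSS base lies inside an H3K27me3 peak.

    The TSS is treated as a single base under half-open semantics
    (``peak.start <= tss < peak.end``); gene bodies are ignored.  Genes on
    chromosomes absent from the peak set get 0.
    """
    return {g.gene_id: int(peaks.contains_point(g.chrom, g.tss)) for g in genes}


def lad_genes(
    genes: Sequence[GeneModel],
    lads: Sequence[GenomicInterval],
    mode: str = "all",
    labels: Sequence[str | None] | None = None,
) -> dict[str, int]:
    """Flag genes whose body overlaps a lamina-associated domain by >= 1 base.

    ``mode`` selects which LADs count: "all", "constitutive" or "facultative"
    (labels taken from ``labels``, parallel to ``lads``; unlabeled intervals
    only match mode "all").
    """
    if mode not in ("all", "constitutive", "facultative"):
        raise ValueError(f"unknown LAD mode {mode!r}")
    if labels is None:
        labels = [None] * len(lads)
    trees: dict[str, IntervalTree] = {}
    for iv, label in zip(lads, labels):
        if mode != "all" and label != mode:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = {}
    for g in genes:
        tree = trees.get(g.chrom)
        out[g.gene_id] = int(bool(tree.overlap(g.start, g.end))) if tree is not None else 0
    return out


def promoter_window(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0.

    On '+': ``[tss - upstream, tss + downstream)``.  On '-', the mirror image:
    ``[tss - downstream + 1, tss + upstream + 1)``, so that the window covers
    the same transcript-relative positions on either strand.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    start = max(0, start)
    if end <= start:  # zero-width or fully clipped -> the single TSS base
        start, end = gene.tss, gene.tss + 1
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def _sites_by_chrom(sites) -> dict[str, np.ndarray]:
    """Normalize a site collection to chrom -> sorted positions."""
    if isinstance(sites, pd.DataFrame):
        pairs = zip(sites["chrom"].astype(str), sites["pos"].astype(int))
    else:
        pairs = ((str(c), int(p)) for c, p in sites)
    acc: dict[str, list[int]] = {}
    for chrom, pos in pairs:
        acc.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in acc.items()}


def count_promoter_sites(
    genes: Sequence[GeneModel],
    sites,
    window: tuple[int, int] = (1000, 1000),
    ages: AgeTable | None = None,
) -> tuple[dict[str, int], dict[str, float] | None]:
    """Count point sites (e.g. CpGs) in each gene's promoter window.

    Returns per-gene counts and, when an age table is given, per-category
    arithmetic means of those counts.
    """
    by_chrom = _sites_by_chrom(sites)
    counts: dict[str, int] = {}
    for g in genes:
        win = promoter_window(g, *window)
        pos = by_chrom.get(g.chrom)
        if pos is None:
            counts[g.gene_id] = 0
        else:
            counts[g.gene_id] = int(
                np.searchsorted(pos, win.end, "left") - np.searchsorted(pos, win.start, "left")
            )
    means = _category_means(counts, ages, default=0.0) if ages is not None else None
    return counts, means


def promoter_methylation(
    genes: Sequence[GeneModel],
    scores,
    window: tuple[int, int] = (1000, 1000),
    ages: AgeTable | None = None,
) -> tuple[dict[str, float], dict[str, float] | None]:
    """Unweighted mean methylation score over sites in the promoter window.

    ``scores`` is a DataFrame (chrom, pos, score) or a mapping
    ``(chrom, pos) -> score`` with scores in [0, 1].  Genes with no site in
    their window get NaN and are excluded from category means.
    """
    if isinstance(scores, pd.DataFrame):
        frame = scores
    else:
        frame = pd.DataFrame(
            {
                "chrom": [c for c, _ in scores],
                "pos": [p for _, p in scores],
                "score": list(scores.values()),
            }
        )
    vals = frame["score"].to_numpy(float)
    if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("methylation scores must lie in [0, 1]")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in frame.groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy())
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy(np.int64)[order],
            sub["score"].to_numpy(float)[order],
        )
    out: dict[str, float] = {}
    for g in genes:
        win = promoter_window(g, *window)
        hit = by_chrom.get(g.chrom)
        if hit is None:
            out[g.gene_id] = math.nan
            continue
        pos, sc = hit
        lo = np.searchsorted(pos, win.start, "left")
        hi = np.searchsorted(pos, win.end, "left")
        out[g.gene_id] = float(np.mean(sc[lo:hi])) if hi > lo else math.nan
    means = _category_means(out, ages, default=math.nan) if ages is not None else None
    return out, means


def _category_means(values: Mapping[str, float], ages: AgeTable, default: float) -> dict[str, float]:
    acc: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for gene_id, v in values.items():
        if gene_id in ages and not (isinstance(v, float) and math.isnan(v)):
            acc[ages.category(gene_id)].append(v)
    return {c: (float(np.mean(v)) if v else default) for c, v in acc.items()}


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int,
    binsize: int,
    group_by: AgeTable,
) -> dict[str, np.ndarray]:
    """Average TSS-centred signal profile per age category.

    Each gene contributes a vector of ``2*flank/binsize`` bins spanning
    TSS-flank .. TSS+flank in transcript orientation (minus-strand genes are
    flipped).  Bin values are coverage-weighted means over the positions the
    track covers; bins with no covered position are NaN and drop out of the
    category mean.
    """
    if flank <= 0 or binsize <= 0 or (2 * flank) % binsize != 0:
        raise ValueError("binsize must divide 2*flank")
    n_bins = 2 * flank // binsize
    acc: dict[str, list[np.ndarray]] = {c: [] for c in CATEGORIES}
    for g in genes:
        if g.gene_id not in group_by:
            continue
        prof = np.full(n_bins, np.nan)
        for b in range(n_bins):
            lo = g.tss - flank + b * binsize
            hi = lo + binsize
            mean, covered = track.weighted_mean(g.chrom, max(0, lo), max(0, hi))
            if covered > 0:
                prof[b] = mean
        if g.strand == "-":
            prof = prof[::-1]
        acc[group_by.category(g.gene_id)].append(prof)
    out = {}
    for cat, rows in acc.items():
        if rows:
            with np.errstate(invalid="ignore"):
                out[cat] = np.nanmean(np.vstack(rows), axis=0)
        else:
            out[cat] = np.full(n_bins, np.nan)
    return out


def classify_de(
    de: DETable,
    lfc_threshold: float = 2.0,
    padj_threshold: float = 0.1,
    ages: AgeTable | None = None,
) -> tuple[dict[str, str], pd.DataFrame | None]:
    """Label genes up / down / none from a DE result table.

    up: log2FC > lfc_threshold and padj < padj_threshold; down: log2FC <
    -lfc_threshold with the same padj rule; everything else (including
    missing padj) none.  With an age table, also report the per-category
    label proportions.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be positive")
    labels: dict[str, str] = {}
    for gene_id, (lfc, padj) in de.records.items():
        if not math.isnan(padj) and padj < padj_threshold:
            if lfc > lfc_threshold:
                labels[gene_id] = "up"
                continue
            if lfc < -lfc_threshold:
                labels[gene_id] = "down"
                continue
        labels[gene_id] = "none"
    props = None
    if ages is not None:
        rows = []
        for cat in CATEGORIES:
            members = [g for g in labels if g in ages and ages.category(g) == cat]
            n = len(members)
            row = {"category": cat, "n": n}
            for lab in ("up", "down", "none"):
                row[lab] = (sum(labels[g] == lab for g in members) / n) if n else math.nan
            rows.append(row)
        props = pd.DataFrame(rows)
    return labels, props


def build_annotation_table(
    genes: Sequence[GeneModel],
    ages: AgeTable,
    polycomb: Mapping[str, int] | None = None,
    lad: Mapping[str, int] | None = None,
    cpg_counts: Mapping[str, int] | None = None,
    meth_means: Mapping[str, float] | None = None,
    de_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join all per-gene annotations into one table."""
    rows = []
    for g in genes:
        if g.gene_id not in ages:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "age_class": ages.age_class(g.gene_id),
                "category": ages.category(g.gene_id),
                "polycomb": (polycomb or {}).get(g.gene_id, math.nan),
                "lad": (lad or {}).get(g.gene_id, math.nan),
                "cpg_count": (cpg_counts or {}).get(g.gene_id, math.nan),
                "meth_mean": (meth_means or {}).get(g.gene_id, math.nan),
                "de_label": (de_labels or {}).get(g.gene_id, "none"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV / BED IO (tab-separated, '#'-prefixed header)
# ---------------------------------------------------------------------------


def _write_commented_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def _read_commented_tsv(path: str | Path, default_names: list[str]) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        names = first[1:].strip().split("\t")
        return pd.read_csv(path, sep="\t", skiprows=1, names=names)
    return pd.read_csv(path, sep="\t", names=default_names)


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    _write_commented_tsv(frame, path)


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    frame = _read_commented_tsv(path, ["gene_id", "chrom", "start", "end", "strand"])
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in frame.itertuples()
    ]


def write_lads_bed(
    lads: Sequence[GenomicInterval],
    path: str | Path,
    labels: Sequence[str | None] | None = None,
) -> None:
    if labels is None:
        labels = [None] * len(lads)
    with open(path, "w") as fh:
        for iv, label in zip(lads, labels):
            if label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_lads_bed(path: str | Path) -> tuple[list[GenomicInterval], list[str | None]]:
    lads: list[GenomicInterval] = []
    labels: list[str | None] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            lads.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            labels.append(parts[3] if len(parts) > 3 else None)
    return lads, labels
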