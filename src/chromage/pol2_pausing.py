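"""RNA Pol II pausing-index pipeline.

The pausing index (PI) of a gene is the ratio of Pol II signal density in the
promoter window (TSS-30 .. TSS+300, transcript orientation) to the density in
the gene body (TSS+300 .. TES).  The pipeline mirrors the standard filtering
chain: genes shorter than 1 kb are discarded; per cell state, PI outliers are
removed by Tukey fences on the interquartile range; genes whose surviving PIs
sum to less than 0.2 across cell states are treated as unexpressed; remaining
PIs are min-max rescaled to [0, 1] within each cell state.  Every exclusion is
recorded with its reason, and the accounting always balances.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome_features import CATEGORIES, AgeTable, GeneModel, GenomicInterval
from .tracks import SignalTrack

__all__ = [
    "SignalTrack",
    "PausingParams",
    "PausingTable",
    "promoter_region",
    "body_region",
    "region_density",
    "pausing_pipeline",
    "compare_pi_distributions",
]

EXCLUSION_REASONS = ("none", "short_gene", "outlier", "unexpressed", "undefined")


@dataclass(frozen=True)
class PausingParams:
    min_gene_length: int = 1000
    expression_floor: float = 0.2
    iqr_k: float = 1.5
    weighted_density: bool = False
    # default order: outlier fences first, then the cross-cell sum filter
    sum_filter_first: bool = False


def promoter_region(gene: GeneModel) -> GenomicInterval:
    """Promoter window TSS-30 .. TSS+300 in transcript orientation.

    Genome coordinates: '+' -> [tss-30, tss+300); '-' -> [tss-300+1, tss+30+1),
    clipped at 0.
    """
    if gene.strand == "+":
        start, end = gene.tss - 30, gene.tss + 300
    else:
        start, end = gene.tss - 300 + 1, gene.tss + 30 + 1
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def body_region(gene: GeneModel) -> GenomicInterval | None:
    """Gene body TSS+300 .. TES (inclusive of the TES base); None if empty.

    Genes of length <= 300 have no body — their PI is undefined.
    """
    if gene.length <= 300:
        return None
    if gene.strand == "+":
        start, end = gene.tss + 300, gene.tes + 1
    else:
        start, end = gene.tes, gene.tss - 300 + 1
    if end <= start:
        return None
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def region_density(track: SignalTrack, region: GenomicInterval, weighted: bool = False) -> float:
    """Mean signal of all bins overlapping the region by >= 1 base; 0 if none.

    Unweighted by default — the plain average of overlapping-bin values; a
    length-weighted variant is available.
    """
    return track.mean_value(region.chrom, region.start, region.end, weighted=weighted)


@dataclass
class PausingTable:
    """Per-gene, per-cell-state pausing indices through every filter stage."""

    frame: pd.DataFrame
    params: PausingParams = field(default_factory=PausingParams)

    def surviving(self, cell: str) -> pd.DataFrame:
        sub = self.frame[(self.frame["cell"] == cell) & (self.frame["excluded_reason"] == "none")]
        return sub

    def exclusion_counts(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["cell", "excluded_reason"]).size().rename("n").reset_index()
        )

    def write_tsv(self, path: str | Path) -> None:
        from .genome_features import _write_commented_tsv

        _write_commented_tsv(self.frame, path)


def _tukey_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    """Fences from linear-interpolation quartiles: [Q1 - k*IQR, Q3 + k*IQR]."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def pausing_pipeline(
    tracks: Mapping[str, SignalTrack],
    genes: Sequence[GeneModel],
    params: PausingParams = PausingParams(),
) -> PausingTable:
    """Run the full PI pipeline over all cell states.

    Stages, in order: (1) drop genes shorter than ``min_gene_length``;
    (2) PI = promoter density / body density per gene and cell, undefined when
    the body is empty or has zero density; (3) per cell, remove PIs outside
    the Tukey fences; (4) drop genes whose surviving PIs sum to less than
    ``expression_floor`` across cell states; (5) per cell, min-max rescale the
    survivors to [0, 1].  ``sum_filter_first=True`` swaps stages 3 and 4.
    """
    if not tracks:
        raise ValueError("need at least one cell state track")
    rows = []
    for gene in genes:
        short = gene.length < params.min_gene_length
        prom = promoter_region(gene)
        body = body_region(gene)
        for cell, track in tracks.items():
            if short:
                rows.append((gene.gene_id, cell, np.nan, np.nan, np.nan, "short_gene"))
                continue
            pd_ = region_density(track, prom, weighted=params.weighted_density)
            if body is None:
                rows.append((gene.gene_id, cell, pd_, np.nan, np.nan, "undefined"))
                continue
            bd = region_density(track, body, weighted=params.weighted_density)
            if bd == 0:
                rows.append((gene.gene_id, cell, pd_, bd, np.nan, "undefined"))
                continue
            rows.append((gene.gene_id, cell, pd_, bd, pd_ / bd, "none"))
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "cell", "promoter_density", "body_density", "pi_raw", "excluded_reason"],
    )

    def outlier_stage(fr: pd.DataFrame) -> None:
        for cell in tracks:
            mask = (fr["cell"] == cell) & (fr["excluded_reason"] == "none")
            vals = fr.loc[mask, "pi_raw"].to_numpy()
            if len(vals) == 0:
                continue
            lo, hi = _tukey_fences(vals, params.iqr_k)
            out = mask & ((fr["pi_raw"] < lo) | (fr["pi_raw"] > hi))
            fr.loc[out, "excluded_reason"] = "outlier"

    def sum_stage(fr: pd.DataFrame) -> None:
        ok = fr["excluded_reason"] == "none"
        sums = fr[ok].groupby("gene_id")["pi_raw"].sum()
        weak = set(sums[sums < params.expression_floor].index)
        fr.loc[ok & fr["gene_id"].isin(weak), "excluded_reason"] = "unexpressed"

    if params.sum_filter_first:
        sum_stage(frame)
        outlier_stage(frame)
    else:
        outlier_stage(frame)
        sum_stage(frame)

    frame["pi_norm"] = np.nan
    for cell in tracks:
        mask = (frame["cell"] == cell) & (frame["excluded_reason"] == "none")
        vals = frame.loc[mask, "pi_raw"].to_numpy()
        if len(vals) == 0:
            continue
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if hi > lo:
            frame.loc[mask, "pi_norm"] = (frame.loc[mask, "pi_raw"] - lo) / (hi - lo)
        else:
            # all survivors identical: midpoint of the unit interval
            frame.loc[mask, "pi_norm"] = 0.5
    if not np.any(frame["excluded_reason"] == "none"):
        counts = frame.groupby(["cell", "excluded_reason"]).size().to_dict()
        raise ValueError(f"all genes excluded; stage counts: {counts}")
    return PausingTable(frame=frame, params=params)


def compare_pi_distributions(pt: PausingTable, ages: AgeTable) -> pd.DataFrame:
    """Two-sided Wilcoxon-Mann-Whitney tests on normalized PIs.

    Compares age categories within each cell state and cell states within
    each age category.  SciPy picks the exact distribution for small,
    tie-free samples and the tie-corrected normal approximation otherwise.
    Empty groups yield a warning and no row.
    """
    frame = pt.frame[pt.frame["excluded_reason"] == "none"].copy()
    frame["category"] = [
        ages.category(g) if g in ages else None for g in frame["gene_id"]
    ]
    frame = frame[frame["category"].notna()]
    cells = sorted(frame["cell"].unique())
    rows = []

    def one_test(scope: str, scope_value: str, a_name: str, b_name: str, a, b) -> None:
        if len(a) == 0 or len(b) == 0:
            warnings.warn(
                f"empty group in comparison {a_name} vs {b_name} ({scope}={scope_value})",
                stacklevel=3,
            )
            return
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append(
            {
                "scope": scope,
                "scope_value": scope_value,
                "group_a": a_name,
                "group_b": b_name,
                "n_a": len(a),
                "n_b": len(b),
                "U": float(res.statistic),
                "p": float(res.pvalue),
            }
        )

    for cell in cells:
        sub = frame[frame["cell"] == cell]
        for ca, cb in itertools.combinations(CATEGORIES, 2):
            one_test(
                "cell",
                cell,
                ca,
                cb,
                sub.loc[sub["category"] == ca, "pi_norm"].to_numpy(),
                sub.loc[sub["category"] == cb, "pi_norm"].to_numpy(),
            )
    for cat in CATEGORIES:
        sub = frame[frame["category"] == cat]
        for ca, cb in itertools.combinations(cells, 2):
            one_test(
                "category",
                cat,
                ca,
                cb,
                sub.loc[sub["cell"] == ca, "pi_norm"].to_numpy(),
                sub.loc[sub["cell"] == cb, "pi_norm"].to_numpy(),
            )
    return pd.DataFrame(rows)
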