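"""Cross-cutting statistics and end-to-end report orchestration.

Spearman age trends (class-mean or gene level), Fisher exact gene-set
enrichment, variability decile grouping, and ``run_report`` — the driver
that takes a declarative config naming input files, executes annotation,
network construction, ChAs / ΔChAs, the pausing pipeline and the summary
statistics, and writes one TSV per analysis plus a structured JSON summary.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import genome_features as gf
from .assortativity import (
    chas_categorical_zscores,
    delta_chas,
    write_chas_tsv,
    write_delta_chas_tsv,
)
from .chromatin_network import (
    assign_genes_to_fragments,
    build_network,
    load_interactions,
    promoter_subnetwork,
)
from .genome_features import AgeTable, CATEGORIES, DETable, PeakSet
from .pol2_pausing import PausingParams, compare_pi_distributions, pausing_pipeline
from .tracks import SignalTrack

__all__ = [
    "EnrichmentResult",
    "spearman_age_trend",
    "fisher_enrichment",
    "decile_groups",
    "benjamini_hochberg",
    "run_report",
]


@dataclass
class EnrichmentResult:
    """2x2 gene-set overlap: counts, odds ratio, two-sided Fisher p."""

    n_a: int
    n_b: int
    n_universe: int
    overlap: int
    odds_ratio: float
    p_value: float
    infinite: bool = False
    continuity: bool = False

    @property
    def table(self) -> list[list[int]]:
        a = self.overlap
        return [
            [a, self.n_a - a],
            [self.n_b - a, self.n_universe - self.n_a - self.n_b + a],
        ]


def spearman_age_trend(
    ages: AgeTable,
    values: Mapping[str, float],
    level: str = "class-mean",
) -> tuple[float, float]:
    """Spearman correlation of a per-gene quantity against age class.

    ``level="class-mean"`` correlates the 16 class indices with per-class
    mean values (the design behind class-wise trend figures);
    ``level="gene"`` correlates per-gene class index against per-gene values.
    Average ranks break ties.
    """
    if level not in ("class-mean", "gene"):
        raise ValueError(f"unknown level {level!r}")
    pairs = [
        (ages.age_class(g), v)
        for g, v in values.items()
        if g in ages and not (isinstance(v, float) and math.isnan(v))
    ]
    if level == "class-mean":
        acc: dict[int, list[float]] = {}
        for k, v in pairs:
            acc.setdefault(k, []).append(v)
        pairs = [(k, float(np.mean(vs))) for k, vs in sorted(acc.items())]
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if np.all(y == y[0]):
        raise ValueError("values are constant; Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_enrichment(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> EnrichmentResult:
    """Two-sided Fisher exact test on the overlap of two gene sets.

    The 2x2 table is [[k, |A|-k], [|B|-k, |U|-|A|-|B|+k]] with k the overlap.
    The odds ratio is the sample (cross-product) ratio; a 0.5 continuity
    correction is applied — and flagged — only when a zero cell would
    otherwise make it 0/0, and a clean zero denominator is flagged infinite.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a_set, b_set = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    k = len(a_set & b_set)
    t11, t12 = k, len(a_set) - k
    t21 = len(b_set) - k
    t22 = len(universe) - len(a_set) - len(b_set) + k
    _, p = stats.fisher_exact([[t11, t12], [t21, t22]], alternative="two-sided")
    infinite = continuity = False
    if t12 * t21 == 0:
        if t11 * t22 == 0:
            continuity = True
            odds = ((t11 + 0.5) * (t22 + 0.5)) / ((t12 + 0.5) * (t21 + 0.5))
        else:
            infinite = True
            odds = math.inf
    else:
        odds = (t11 * t22) / (t12 * t21)
    return EnrichmentResult(
        n_a=len(a_set),
        n_b=len(b_set),
        n_universe=len(universe),
        overlap=k,
        odds_ratio=float(odds),
        p_value=float(p),
        infinite=infinite,
        continuity=continuity,
    )


def decile_groups(values: Mapping[str, float]) -> dict[str, int]:
    """Rank genes into 10 near-equal groups (1 = lowest values).

    Ties are broken by gene id (stable lexicographic order), so the
    assignment is deterministic for any input.
    """
    if len(values) < 10:
        raise ValueError("need at least 10 values for decile grouping")
    order = sorted(values, key=lambda g: (values[g], g))
    n = len(order)
    return {g: int(i * 10 // n) + 1 for i, g in enumerate(order)}


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------


def _require(config: Mapping, key: str, analysis: str) -> str:
    path = config.get("inputs", {}).get(key)
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            f"input {key!r} ({path}) is required for analysis {analysis!r}"
        )
    return str(path)


def run_report(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a declarative config; return the summary.

    ``config`` maps ``inputs`` (paths: genes, ages, interactions, peaks,
    lads, tracks {cell: path}, de, expression, methylation, cpg_sites),
    ``params`` (score_threshold, n_rand, seed, lfc/padj thresholds, pausing
    settings) and optionally ``out_dir``.  Analyses whose optional inputs are
    missing are skipped with a recorded reason; missing required inputs
    raise, naming the file and the analysis.  Same config + seed gives an
    identical summary.
    """
    params = dict(config.get("params", {}))
    seed = int(params.get("seed", 0))
    n_rand = int(params.get("n_rand", 100))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(config), "skipped": {}, "filters": {}}
    inputs = config.get("inputs", {})

    genes = gf.read_genes_tsv(_require(config, "genes", "annotation"))
    bounds = tuple(params.get("category_bounds", gf.DEFAULT_CATEGORY_BOUNDS))
    ages = AgeTable.read_tsv(_require(config, "ages", "annotation"), bounds=bounds)

    def have(key: str) -> bool:
        p = inputs.get(key)
        if isinstance(p, Mapping):
            return bool(p)
        return p is not None and Path(p).exists()

    # ---- annotation -----------------------------------------------------
    polycomb = lad = None
    if have("peaks"):
        peaks = PeakSet.read_bed(inputs["peaks"])
        polycomb = gf.polycomb_targets(genes, peaks)
    else:
        summary["skipped"]["polycomb"] = "no peaks input"
    if have("lads"):
        lads, labels = gf.read_lads_bed(inputs["lads"])
        lad = gf.lad_genes(genes, lads, mode=params.get("lad_mode", "all"), labels=labels)
    else:
        summary["skipped"]["lad"] = "no lads input"
    cpg_counts = meth_means = None
    if have("cpg_sites"):
        sites = gf._read_commented_tsv(inputs["cpg_sites"], ["chrom", "pos"])
        cpg_counts, cpg_cat = gf.count_promoter_sites(genes, sites, ages=ages)
        summary["cpg_category_means"] = cpg_cat
    if have("methylation"):
        meth = gf._read_commented_tsv(inputs["methylation"], ["chrom", "pos", "score"])
        meth_means, meth_cat = gf.promoter_methylation(genes, meth, ages=ages)
        summary["methylation_category_means"] = meth_cat
    de_labels = None
    if have("de"):
        de = DETable.read_tsv(inputs["de"])
        de_labels, de_props = gf.classify_de(
            de,
            lfc_threshold=float(params.get("lfc_threshold", 2.0)),
            padj_threshold=float(params.get("padj_threshold", 0.1)),
            ages=ages,
        )
        summary["de_proportions"] = de_props.to_dict(orient="records")
    else:
        summary["skipped"]["de"] = "no de input"
    annotation = gf.build_annotation_table(
        genes, ages, polycomb, lad, cpg_counts, meth_means, de_labels
    )
    gf._write_commented_tsv(annotation, out / "annotation.tsv")

    # ---- network + ChAs -------------------------------------------------
    chas_summary = None
    if have("interactions"):
        records, report = load_interactions(
            inputs["interactions"], score_threshold=float(params.get("score_threshold", 5.0))
        )
        summary["filters"]["interactions"] = {
            "rows": report.n_rows,
            "kept": report.n_kept,
            "dropped": report.n_dropped,
        }
        net = assign_genes_to_fragments(build_network(records), genes)
        sub = promoter_subnetwork(net, mode=params.get("promoter_mode", "strict"))
        summary["filters"]["network"] = {
            "nodes": net.n_nodes,
            "edges": net.n_edges,
            "promoter_nodes": sub.n_nodes,
            "promoter_edges": sub.n_edges,
        }
        sub.write_tsv(out / "network_nodes.tsv", out / "network_edges.tsv")
        assignment = {
            nid: {ages.category(g) for g in gs if g in ages}
            for nid, gs in zip(sub.node_ids, sub.node_genes)
            if any(g in ages for g in gs)
        }
        cat_results = chas_categorical_zscores(sub, assignment, n_rand=n_rand, seed=seed)
        write_chas_tsv(cat_results, out / "chas_age_categories.tsv")
        chas_summary = {
            c: {"observed": r.observed, "z": r.z, "null_mean": r.null_mean, "null_sd": r.null_sd}
            for c, r in cat_results.items()
        }
        summary["chas_age_categories"] = chas_summary

        # ΔChAs per category for each available binary feature
        deltas = []
        feature_sets: dict[str, set[str]] = {}
        if polycomb is not None:
            feature_sets["polycomb"] = {g for g, v in polycomb.items() if v}
        if lad is not None:
            feature_sets["lad"] = {g for g, v in lad.items() if v}
        for feat_name, feat_genes in feature_sets.items():
            for cat in CATEGORIES:
                group = ages.genes_in_category(cat)
                try:
                    deltas.append(
                        delta_chas(
                            sub,
                            group,
                            feat_genes,
                            n_rand=n_rand,
                            seed=seed,
                            group_name=cat,
                            feature_name=feat_name,
                        )
                    )
                except ValueError as exc:
                    summary["skipped"][f"delta_{feat_name}_{cat}"] = str(exc)
        if deltas:
            write_delta_chas_tsv(deltas, out / "delta_chas.tsv")
            summary["delta_chas"] = [
                {
                    "group": d.group,
                    "feature": d.feature,
                    "z_with": d.z_with,
                    "z_without": d.z_without,
                    "delta": d.delta,
                }
                for d in deltas
            ]
    else:
        summary["skipped"]["chas"] = "no interactions input"

    # ---- pausing --------------------------------------------------------
    tracks_cfg = inputs.get("tracks") or {}
    if tracks_cfg:
        tracks = {cell: SignalTrack.from_bedgraph(p) for cell, p in tracks_cfg.items()}
        pp = PausingParams(
            min_gene_length=int(params.get("min_gene_length", 1000)),
            expression_floor=float(params.get("expression_floor", 0.2)),
            iqr_k=float(params.get("iqr_k", 1.5)),
            weighted_density=bool(params.get("weighted_density", False)),
        )
        table = pausing_pipeline(tracks, genes, pp)
        table.write_tsv(out / "pausing.tsv")
        summary["filters"]["pausing"] = table.exclusion_counts().to_dict(orient="records")
        comparisons = compare_pi_distributions(table, ages)
        if len(comparisons):
            comparisons["p_adj"] = benjamini_hochberg(comparisons["p"].to_numpy())
        gf._write_commented_tsv(comparisons, out / "pausing_comparisons.tsv")
        pi_summ = []
        frame = table.frame[table.frame["excluded_reason"] == "none"].copy()
        frame["category"] = [ages.category(g) if g in ages else None for g in frame["gene_id"]]
        for (cell, cat), sub_ in frame.groupby(["cell", "category"]):
            pi_summ.append(
                {
                    "cell": cell,
                    "category": cat,
                    "n": len(sub_),
                    "pi_norm_median": float(sub_["pi_norm"].median()),
                    "pi_raw_mean": float(sub_["pi_raw"].mean()),
                }
            )
        summary["pausing"] = pi_summ
    else:
        summary["skipped"]["pausing"] = "no coverage tracks input"

    # ---- trends and enrichments ----------------------------------------
    if have("expression"):
        expr = gf._read_commented_tsv(inputs["expression"], ["gene_id", "expression", "ev"])
        expr_map = dict(zip(expr["gene_id"].astype(str), expr["expression"].astype(float)))
        ev_map = dict(zip(expr["gene_id"].astype(str), expr["ev"].astype(float)))
        rho_e, p_e = spearman_age_trend(ages, expr_map, level="class-mean")
        rho_v, p_v = spearman_age_trend(ages, ev_map, level="class-mean")
        summary["age_trends"] = {
            "expression": {"rho": rho_e, "p": p_e},
            "ev": {"rho": rho_v, "p": p_v},
        }
        universe = set(ev_map) & set(ages.genes)
        groups = decile_groups({g: ev_map[g] for g in universe})
        low = {g for g, grp in groups.items() if grp <= 6}
        high = {g for g, grp in groups.items() if grp >= 8}
        enr_rows = []
        for cat in CATEGORIES:
            cat_genes = ages.genes_in_category(cat) & universe
            for set_name, subset in (("low_1_6", low), ("high_8_10", high)):
                r = fisher_enrichment(cat_genes, subset, universe)
                enr_rows.append(
                    {
                        "category": cat,
                        "ev_groups": set_name,
                        "overlap": r.overlap,
                        "odds_ratio": r.odds_ratio,
                        "p": r.p_value,
                    }
                )
        enr = pd.DataFrame(enr_rows)
        enr["p_adj"] = benjamini_hochberg(enr["p"].to_numpy())
        gf._write_commented_tsv(enr, out / "ev_enrichment.tsv")
        summary["ev_enrichment"] = enr_rows
    else:
        summary["skipped"]["expression"] = "no expression input"

    summary["seed"] = seed
    summary["n_rand"] = n_rand
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
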