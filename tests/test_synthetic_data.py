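"""Generator contracts: determinism, planted-parameter recovery, round-trips."""

import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from chromage.genome_features import (
    AgeTable,
    PeakSet,
    lad_genes,
    polycomb_targets,
    read_genes_tsv,
    read_lads_bed,
)
from chromage.chromatin_network import build_network, load_interactions
from chromage.synthetic_data import (
    SyntheticConfig,
    make_coverage,
    make_expression,
    make_genome,
    make_lads,
    make_network,
    make_peaks,
    make_scenario,
    write_dataset,
)
from chromage.pol2_pausing import PausingParams, pausing_pipeline
from chromage.tracks import SignalTrack


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(class_weights=(0.5,) + (0.0,) * 15)

    def test_bounds_must_increase(self):
        with pytest.raises(ValueError):
            SyntheticConfig(category_bounds=(9, 3))

    @pytest.mark.parametrize("field,value", [
        ("p_within", 1.5),
        ("lad_fraction", -0.1),
        ("noise_sd", -1.0),
        ("rho_target", 2.0),
    ])
    def test_scalar_ranges(self, field, value):
        with pytest.raises(ValueError):
            SyntheticConfig(**{field: value})


class TestMakeGenome:
    def test_counts_and_class_assignment(self):
        cfg = SyntheticConfig(n_genes=100, class_weights=(1 / 16,) * 16, seed=1)
        genes, ages = make_genome(cfg)
        assert len(genes) == 100
        assert all(g.gene_id in ages for g in genes)
        counts = np.bincount([ages.age_class(g.gene_id) for g in genes], minlength=17)[1:]
        # uniform multinomial, n=100: each count within 5 SD of 6.25
        assert np.all(np.abs(counts - 100 / 16) <= 5 * math.sqrt(100 * (1 / 16) * (15 / 16)))

    def test_category_bounds_mapping(self):
        cfg = SyntheticConfig(n_genes=300, category_bounds=(3, 9), seed=2)
        _, ages = make_genome(cfg)
        for g in ages.genes:
            k = ages.age_class(g)
            expected = "UC" if k <= 3 else ("EM" if k <= 9 else "MM")
            assert ages.category(g) == expected

    def test_genes_do_not_overlap(self, small_genome):
        genes, _ = small_genome
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_short_gene_fraction_exercises_length_filter(self, small_genome):
        genes, _ = small_genome
        assert sum(g.length < 1000 for g in genes) / len(genes) >= 0.10

    def test_sizing_error_when_genome_too_small(self):
        with pytest.raises(ValueError, match="spacing"):
            make_genome(SyntheticConfig(n_genes=2000, n_chromosomes=1, chrom_length=1_000_000))

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_genes=150, seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(cfg, d1)
        write_dataset(cfg, d2)
        for f1 in sorted(d1.iterdir()):
            assert filecmp.cmp(f1, d2 / f1.name, shallow=False), f1.name


class TestMakeNetwork:
    def test_p_within_one_only_same_category_edges(self):
        cfg = SyntheticConfig(n_genes=150, n_edges=300, p_within=1.0, seed=4)
        genes, ages = make_genome(cfg)
        net = make_network(genes, ages, cfg)
        for a, b in zip(net.edge_a, net.edge_b):
            cats_a = {ages.category(g) for g in net.node_genes[a]}
            cats_b = {ages.category(g) for g in net.node_genes[b]}
            assert cats_a & cats_b

    def test_p_within_zero_matches_random_pairing_rate(self):
        cfg = SyntheticConfig(n_genes=600, n_edges=10_000, p_within=0.0, seed=5)
        genes, ages = make_genome(cfg)
        net = make_network(genes, ages, cfg)
        cats = [ages.category(g.gene_id) for g in genes]
        freqs = np.array([cats.count(c) for c in ("UC", "EM", "MM")]) / len(cats)
        q = float(np.sum(freqs**2))
        same = np.mean([
            bool({ages.category(g) for g in net.node_genes[a]}
                 & {ages.category(g) for g in net.node_genes[b]})
            for a, b in zip(net.edge_a, net.edge_b)
        ])
        sd = math.sqrt(q * (1 - q) / net.n_edges)
        assert abs(same - q) <= 3 * sd

    def test_p_within_recovered_by_moment_inversion(self):
        # sparse relative to the pair pools, so dedupe cannot bias the mix
        cfg = SyntheticConfig(n_genes=2000, n_edges=10_000, p_within=0.8,
                              n_chromosomes=6, seed=6)
        genes, ages = make_genome(cfg)
        net = make_network(genes, ages, cfg)
        cats = [ages.category(g.gene_id) for g in genes]
        freqs = np.array([cats.count(c) for c in ("UC", "EM", "MM")]) / len(cats)
        q = float(np.sum(freqs**2))
        same = np.mean([
            bool({ages.category(g) for g in net.node_genes[a]}
                 & {ages.category(g) for g in net.node_genes[b]})
            for a, b in zip(net.edge_a, net.edge_b)
        ])
        p_hat = (same - q) / (1 - q)
        assert p_hat == pytest.approx(0.8, abs=0.05)

    def test_edge_budget_sizing_error(self):
        cfg = SyntheticConfig(n_genes=10, n_edges=3000, chrom_length=2_000_000,
                              n_chromosomes=1)
        genes, ages = make_genome(cfg)
        with pytest.raises(ValueError, match="edges"):
            make_network(genes, ages, cfg)

    def test_trans_fraction_and_scores_pass_filter(self, tmp_path, small_genome, small_config):
        genes, ages = small_genome
        net = make_network(genes, ages, small_config)
        trans_frac = float(np.isnan(net.edge_distance).mean())
        assert trans_frac == pytest.approx(0.05, abs=0.03)
        from chromage.chromatin_network import write_ibed

        p = tmp_path / "net.ibed"
        write_ibed(net, p)
        records, report = load_interactions(p, score_threshold=5)
        assert report.n_dropped == 0
        assert build_network(records).n_edges == net.n_edges

    def test_multi_gene_fragment_option(self):
        cfg = SyntheticConfig(n_genes=200, n_edges=300, multi_gene_fraction=0.1, seed=8)
        genes, ages = make_genome(cfg)
        net = make_network(genes, ages, cfg)
        multi = sum(len(g) > 1 for g in net.node_genes)
        assert net.n_nodes < len(genes)
        assert multi == pytest.approx(0.05 * len(genes), rel=0.5)


class TestMakePeaks:
    def test_limit_case_selects_exactly_em_genes(self):
        cfg = SyntheticConfig(
            n_genes=300, seed=9, peak_prob_by_category={"UC": 0.0, "EM": 1.0, "MM": 0.0}
        )
        genes, ages = make_genome(cfg)
        peaks = make_peaks(genes, ages, cfg)
        targets = polycomb_targets(genes, peaks)
        em = ages.genes_in_category("EM")
        assert {g for g, v in targets.items() if v} == em

    def test_planted_rate_within_binomial_bounds(self):
        cfg = SyntheticConfig(n_genes=3000, n_chromosomes=8, seed=10)
        genes, ages = make_genome(cfg)
        peaks = make_peaks(genes, ages, cfg)
        targets = polycomb_targets(genes, peaks)
        em = ages.genes_in_category("EM")
        rate = sum(targets[g] for g in em) / len(em)
        sd = math.sqrt(0.34 * 0.66 / len(em))
        assert abs(rate - 0.34) <= 3 * sd

    def test_empty_gene_list_background_only(self):
        cfg = SyntheticConfig(n_genes=50, seed=11)
        peaks = make_peaks([], AgeTable({}), cfg)
        assert len(peaks) > 0  # background peaks on config chromosomes


class TestMakeLads:
    def test_zero_fraction_empty(self, small_genome, small_config):
        genes, ages = small_genome
        import dataclasses

        cfg = dataclasses.replace(small_config, lad_fraction=0.0)
        lads, labels = make_lads(genes, ages, cfg)
        assert lads == [] and labels == []

    def test_full_fraction_covers_every_gene(self, small_genome, small_config):
        genes, ages = small_genome
        import dataclasses

        cfg = dataclasses.replace(small_config, lad_fraction=1.0)
        lads, _ = make_lads(genes, ages, cfg)
        flags = lad_genes(genes, lads)
        assert all(flags.values())

    def test_coverage_near_target(self, small_genome, small_config):
        import dataclasses

        genes, ages = small_genome
        cfg = dataclasses.replace(small_config, lad_fraction=0.3)
        lads, labels = make_lads(genes, ages, cfg)
        total = cfg.n_chromosomes * cfg.chrom_length
        covered = sum(iv.length for iv in lads)  # construction yields disjoint runs
        assert covered / total == pytest.approx(0.3, abs=0.02)
        assert set(labels) <= {"constitutive", "facultative"}

    def test_enrichment_ratio_recovered_over_seeds(self):
        ratios = []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_genes=400,
                seed=seed,
                lad_fraction=0.3,
                lad_enrichment_by_category={"UC": 1.0, "EM": 1.0, "MM": 2.0},
            )
            genes, ages = make_genome(cfg)
            lads, _ = make_lads(genes, ages, cfg)
            flags = lad_genes(genes, lads)
            uc = ages.genes_in_category("UC")
            mm = ages.genes_in_category("MM")
            rate_uc = sum(flags[g] for g in uc) / len(uc)
            rate_mm = sum(flags[g] for g in mm) / len(mm)
            ratios.append(rate_mm / rate_uc)
        assert 1.5 <= float(np.mean(ratios)) <= 2.5


class TestMakeCoverage:
    def test_noiseless_pi_exact(self):
        cfg = SyntheticConfig(
            n_genes=120,
            seed=12,
            noise_sd=0.0,
            cell_states=("c",),
            cell_pi_scale={"c": 1.0},
            pi_mean_by_category={"UC": 2.0, "EM": 2.0, "MM": 1.0},
        )
        genes, ages = make_genome(cfg)
        tracks = make_coverage(genes, ages, cfg)
        table = pausing_pipeline(tracks, genes, PausingParams(expression_floor=0.0, iqr_k=1e9))
        ok = table.frame[table.frame["pi_raw"].notna()]
        for gid, pi in zip(ok["gene_id"], ok["pi_raw"]):
            planted = cfg.pi_mean_by_category[ages.category(gid)]
            assert abs(pi - planted) <= 1e-12

    def test_noisy_recovery_of_category_means(self):
        cfg = SyntheticConfig(
            n_genes=900,
            n_chromosomes=6,
            seed=13,
            noise_sd=0.1,
            cell_states=("c",),
            cell_pi_scale={"c": 1.0},
        )
        genes, ages = make_genome(cfg)
        tracks = make_coverage(genes, ages, cfg)
        table = pausing_pipeline(tracks, genes, PausingParams(expression_floor=0.0))
        frame = table.frame[table.frame["excluded_reason"] == "none"]
        for cat, planted in cfg.pi_mean_by_category.items():
            vals = [
                pi for gid, pi in zip(frame["gene_id"], frame["pi_raw"])
                if ages.category(gid) == cat
            ]
            assert np.mean(vals) == pytest.approx(planted, abs=0.05)


class TestMakeExpression:
    def test_noiseless_trend_is_perfectly_monotone(self, small_genome):
        genes, ages = small_genome
        cfg = SyntheticConfig(n_genes=200, seed=11, noise_sd=0.0)
        table = make_expression(genes, ages, cfg)
        from chromage.stats_report import spearman_age_trend

        rho_e, _ = spearman_age_trend(ages, dict(zip(table["gene_id"], table["expression"])))
        rho_v, _ = spearman_age_trend(ages, dict(zip(table["gene_id"], table["ev"])))
        assert rho_e == pytest.approx(-1.0)
        assert rho_v == pytest.approx(1.0)

    def test_rho_target_calibration_over_seeds(self):
        from chromage.stats_report import spearman_age_trend

        rhos = []
        for seed in range(20):
            cfg = SyntheticConfig(n_genes=400, seed=seed, rho_target=0.95)
            genes, ages = make_genome(cfg)
            table = make_expression(genes, ages, cfg)
            rho, _ = spearman_age_trend(ages, dict(zip(table["gene_id"], table["expression"])))
            rhos.append(abs(rho))
        assert float(np.mean(rhos)) >= 0.85


class TestRoundTrips:
    def test_files_roundtrip_through_module_readers(self, tmp_path):
        cfg = SyntheticConfig(n_genes=150, seed=33)
        paths = write_dataset(cfg, tmp_path)
        genes, ages = make_genome(cfg)
        genes_back = read_genes_tsv(paths["genes"])
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes_back] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes
        ]
        ages_back = AgeTable.read_tsv(paths["ages"])
        assert {g: ages_back.age_class(g) for g in ages_back.genes} == {
            g: ages.age_class(g) for g in ages.genes
        }
        records, _ = load_interactions(paths["interactions"])
        net_back = build_network(records)
        net = make_network(genes, ages, cfg)
        assert net_back.n_edges == net.n_edges and set(net_back.node_ids) == set(net.node_ids)
        peaks_back = PeakSet.read_bed(paths["peaks"])
        assert len(peaks_back) == len(make_peaks(genes, ages, cfg))
        lads, labels = make_lads(genes, ages, cfg)
        lads_back, labels_back = read_lads_bed(paths["lads"])
        assert [(l.chrom, l.start, l.end) for l in lads_back] == [
            (l.chrom, l.start, l.end) for l in lads
        ]
        assert labels_back == labels
        tracks = make_coverage(genes, ages, cfg)
        for cell, track in tracks.items():
            back = SignalTrack.from_bedgraph(paths[f"coverage:{cell}"])
            assert np.allclose(back.frame["value"], track.frame["value"])


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            make_scenario("bogus", SyntheticConfig())

    def test_scenarios_share_genome_and_features(self):
        cfg = SyntheticConfig(n_genes=200, n_edges=400, seed=14)
        a = make_scenario("differentiated", cfg)
        b = make_scenario("oncogenesis", cfg)
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]
        assert a.features == b.features
        assert a.network.edge_keys() != b.network.edge_keys()

    def test_differentiated_scenario_realizes_planted_order(self):
        """z(UC) > z(EM) > z(MM) > 2 and positive Polycomb ΔChAs for EM."""
        from chromage.assortativity import chas_categorical_zscores, delta_chas

        cfg = SyntheticConfig(n_genes=500, n_edges=1500, seed=104)
        b = make_scenario("differentiated", cfg)
        assignment = {
            nid: {b.ages.category(g) for g in gs}
            for nid, gs in zip(b.network.node_ids, b.network.node_genes)
        }
        res = chas_categorical_zscores(b.network, assignment, n_rand=60, seed=504)
        assert res["UC"].z > res["EM"].z > res["MM"].z > 2
        polycomb = {g for g, v in b.features["polycomb"].items() if v}
        d = delta_chas(
            b.network, b.ages.genes_in_category("EM"), polycomb,
            n_rand=40, seed=7, group_name="EM", feature_name="polycomb",
        )
        assert d.delta > 0
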