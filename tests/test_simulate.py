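"""Synthetic-study generator: determinism, truth structure, recovery limits."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from trchip.assign import assign_peaks, bound_gene_set, build_windows
from trchip.consensus import intersect_replicates
from trchip.motif import scan_dr4
from trchip.simulate import (
    SAMPLES,
    SimulationConfig,
    evaluate_recovery,
    fragments_for_sites,
    simulate,
    simulate_terms,
)

SMALL = dict(
    n_chroms=1,
    chrom_length=700_000,
    n_genes=40,
    n_true_sites=50,
    gene_length_range=(2000, 4000),
)


def run_consensus(result):
    return {
        s: intersect_replicates(result.peaks[s], sample_id=s)
        for s in result.peaks
    }


def tree_digest(root):
    return {
        p.relative_to(root): hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(Path(root).rglob("*"))
        if p.is_file()
    }


class TestSimulate:
    def test_same_seed_byte_identical_trees(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        simulate(cfg, outdir=tmp_path / "a")
        simulate(SimulationConfig(seed=7, **SMALL), outdir=tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate(SimulationConfig(seed=1, **SMALL), outdir=tmp_path / "a")
        simulate(SimulationConfig(seed=2, **SMALL), outdir=tmp_path / "b")
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")

    def test_genic_site_allocation_is_deterministic(self):
        cfg = SimulationConfig(
            seed=0,
            n_true_sites=100,
            fraction_sites_in_windows=0.6,
            n_genes=120,
            chrom_length=1_200_000,
        )
        result = simulate(cfg)
        genic = [s for s in result.sites if s.gene_id is not None]
        assert len(genic) == 60
        assert len(result.sites) == 100

    def test_planted_sites_carry_dr4_elements(self):
        result = simulate(SimulationConfig(seed=3, **SMALL))
        for site in result.sites[:10]:
            window = result.genome[site.chrom][site.start : site.end]
            assert len(scan_dr4(window)) >= 1

    def test_genic_sites_map_to_their_gene_window(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        result = simulate(cfg)
        windows = {w.gene_id: w for w in build_windows(result.genes, cfg.flank)}
        for site in result.sites:
            if site.gene_id is None:
                continue
            w = windows[site.gene_id]
            assert site.interval.overlaps(w.interval)

    def test_intergenic_sites_outside_all_windows(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        result = simulate(cfg)
        windows = build_windows(result.genes, cfg.flank)
        for site in result.sites:
            if site.gene_id is not None:
                continue
            assert not any(site.interval.overlaps(w.interval) for w in windows)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            SimulationConfig(
                n_genes=100, chrom_length=50_000, n_chroms=1, n_true_sites=10
            ).validate()

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(seed=9, jitter_sd=10.0, **SMALL)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg

    def test_ko_samples_detect_subset_of_wt(self):
        result = simulate(SimulationConfig(seed=11, **SMALL))
        det = result.truth["detectable"]
        assert set(det["ko_plusT3"]) <= set(det["wt_plusT3"])
        assert set(det["ko_minusT3"]) <= set(det["ko_plusT3"])
        assert set(det["wt_minusT3"]) <= set(det["wt_plusT3"])


class TestRecovery:
    def test_noiseless_limit_recovers_exactly(self):
        cfg = SimulationConfig(
            seed=2, jitter_sd=0.0, fp_rate=0.0, dropout_rate=0.0, **SMALL
        )
        result = simulate(cfg)
        report = evaluate_recovery(result.truth, run_consensus(result))
        for sample in SAMPLES:
            assert report[sample]["site_precision"] == 1.0
            assert report[sample]["site_recall"] == 1.0

    def test_noiseless_bound_genes_match_truth(self):
        cfg = SimulationConfig(
            seed=2, jitter_sd=0.0, fp_rate=0.0, dropout_rate=0.0, **SMALL
        )
        result = simulate(cfg)
        windows = build_windows(result.genes, cfg.flank)
        for sample, cons in run_consensus(result).items():
            called = bound_gene_set(assign_peaks(cons, windows))
            assert called == set(result.truth["bound_genes"][sample])

    def test_false_peaks_rarely_survive_intersection(self):
        """Independent false peaks must co-occur in all replicates to pass.

        At fp_rate 0.5 on a ~1 Mb genome, nearly all consensus peaks match
        true sites: pooled precision ≥ 0.99 over seeded runs.
        """
        matched = called = 0
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, fp_rate=0.5, dropout_rate=0.0, **SMALL
            )
            result = simulate(cfg)
            report = evaluate_recovery(result.truth, run_consensus(result))
            for sample in SAMPLES:
                called += report[sample]["n_called"]
                matched += round(
                    report[sample]["site_precision"] * report[sample]["n_called"]
                )
        assert called > 0
        assert matched / called >= 0.99

    def test_total_dropout_in_one_replicate_kills_recall(self):
        cfg = SimulationConfig(seed=4, fp_rate=0.0, dropout_rate=0.0, **SMALL)
        result = simulate(cfg)
        sample = "wt_plusT3"
        peaks = dict(result.peaks[sample])
        peaks["rep3"] = []  # every site dropped in one replicate
        cons = intersect_replicates(peaks, sample_id=sample)
        report = evaluate_recovery(result.truth, {sample: cons})
        assert report[sample]["site_recall"] == 0.0


class TestExpressionTruth:
    def test_regulated_genes_are_bound_in_truth(self):
        result = simulate(SimulationConfig(seed=6, **SMALL))
        wt_bound = set(result.truth["bound_genes_union"]["wt"])
        for key in ("wt_up", "wt_down"):
            assert set(result.truth["regulated"][key]) <= wt_bound

    def test_ko_regulation_attenuated(self):
        cfg = SimulationConfig(seed=8, n_true_sites=120, n_genes=120)
        result = simulate(cfg)
        by_gene = {r.gene_id: r for r in result.expression}
        for gid in result.truth["regulated"]["wt_up"]:
            r = by_gene[gid]
            if gid in result.truth["regulated"]["ko_up"]:
                assert r.log2fc_ko == pytest.approx(
                    cfg.ko_attenuation * r.log2fc_wt
                )


class TestSimulateTerms:
    def test_sizes_and_determinism(self):
        genes = [f"g{i}" for i in range(100)]
        t1 = simulate_terms(genes, 20, (5, 15), seed=3)
        t2 = simulate_terms(genes, 20, (5, 15), seed=3)
        assert t1 == t2
        assert len(t1) == 20
        assert all(5 <= len(t.gene_ids) <= 15 for t in t1)


class TestFragmentMode:
    def test_fragments_feed_pileup_caller(self):
        """End-to-end fragment mode: stacked site fragments become peaks."""
        from trchip.consensus import pileup_call

        cfg = SimulationConfig(seed=12, **SMALL)
        result = simulate(cfg)
        sites = result.sites[:5]
        chrom_lengths = {c: len(s) for c, s in result.genome.items()}
        frags = fragments_for_sites(
            sites, chrom_lengths, site_depth=60, background_rate=0.0001, seed=1
        )
        peaks = pileup_call(frags, chrom_lengths, background_rate=0.0001)
        for site in sites:
            assert any(p.interval.overlaps(site.interval) for p in peaks)
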