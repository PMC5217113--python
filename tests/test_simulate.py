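"""Generative model: determinism, selection arithmetic, noise structure,
and end-to-end recovery through the real pipeline."""

import numpy as np
import pytest

from shscreen import (
    SequencingLibrary,
    build_matcher,
    count_reads,
    make_null_config,
    make_pilot_like_config,
    run_count_pipeline,
    simulate_reads,
    simulate_screen,
)
from shscreen.simulate import SimulationConfig, make_graded_config


class TestSimulateScreen:
    def test_same_seed_identical_screen(self):
        cfg = make_null_config(seed=4)
        s1, s2 = simulate_screen(cfg), simulate_screen(cfg)
        assert s1.input_pool_counts.counts == s2.input_pool_counts.counts
        for key in s1.replicate_counts:
            assert (
                s1.replicate_counts[key].counts
                == s2.replicate_counts[key].counts
            )

    def test_different_seed_differs(self):
        base = make_null_config(seed=4)
        cfg2 = SimulationConfig(
            manifest=base.manifest, seed=5
        )
        s1, s2 = simulate_screen(base), simulate_screen(cfg2)
        assert s1.input_pool_counts.counts != s2.input_pool_counts.counts

    def test_neutral_screen_tracks_input_weights(self):
        # no selection, no biological noise, jackpotting switched off:
        # read fractions stay within 3 multinomial SEs of the input weights
        base = make_null_config(seed=6)
        cfg = SimulationConfig(
            manifest=base.manifest, bio_sd=0.0, jackpot_shape=float("inf"),
            seed=6,
        )
        screen = simulate_screen(cfg)
        w = cfg.weights()
        for tab in screen.replicate_counts.values():
            n = tab.n_reads_total
            frac = np.array(list(tab.counts.values())) / n
            se = np.sqrt(w * (1 - w) / n)
            assert (np.abs(frac - w) < 3 * se + 1e-12).mean() > 0.95

    def test_strong_depletion_arithmetic(self):
        # s_c = -10 means 2^-10 survival: testis counts below 0.1% of input
        base = make_null_config(seed=7)
        victim = base.manifest.construct_ids[0]
        sel = {victim: -10.0}
        cfg = SimulationConfig(
            manifest=base.manifest, selection_log2=sel, bio_sd=0.0, seed=7,
        )
        screen = simulate_screen(cfg)
        input_frac = (
            screen.input_pool_counts.counts[victim]
            / screen.input_pool_counts.n_reads_total
        )
        testis = sum(
            t.counts[victim] for t in screen.replicate_counts.values()
        )
        total = sum(t.n_reads_total for t in screen.replicate_counts.values())
        assert testis / total < 0.001 * max(input_frac, 1e-9) + 1e-4

    def test_truth_covers_every_construct(self):
        cfg = make_pilot_like_config(seed=8)
        screen = simulate_screen(cfg)
        assert set(screen.truth_selection) == set(cfg.manifest.construct_ids)
        assert set(screen.truth_gene_essential) == set(cfg.manifest.genes)

    def test_jackpot_shape_controls_technical_variance(self):
        # heavier jackpotting (smaller gamma shape) inflates the spread of
        # technical-replicate counts for the same biology
        base = make_null_config(seed=9)

        def tech_cv(shape, seed):
            cfg = SimulationConfig(
                manifest=base.manifest, jackpot_shape=shape, bio_sd=0.0,
                n_bio_reps=1, n_tech_reps=100, seed=seed,
            )
            screen = simulate_screen(cfg)
            counts = np.array(
                [list(t.counts.values()) for t in screen.replicate_counts.values()]
            )
            return (counts.std(axis=0) / counts.mean(axis=0)).mean()

        assert tech_cv(0.5, 10) > tech_cv(50.0, 10)

    def test_invalid_efficiency_rejected(self):
        base = make_null_config(seed=1)
        with pytest.raises(ValueError):
            SimulationConfig(manifest=base.manifest, transfection_efficiency=0.0)


class TestSimulateReads:
    def test_round_trip_recovers_counts_exactly(self, tmp_path):
        cfg = make_null_config(
            seed=12, n_test_genes=2, n_negative_genes=1, mean_coverage=20,
            n_bio_reps=1, n_tech_reps=1,
        )
        screen = simulate_screen(cfg)
        paths = simulate_reads(screen, cfg.manifest, seed=12, out_dir=tmp_path)
        matcher = build_matcher(cfg.manifest)
        for lib_id, tab in [
            ("input_pool", screen.input_pool_counts),
            ("rep1_tech1", screen.replicate_counts[(1, 1)]),
        ]:
            counted = count_reads(
                SequencingLibrary(library_id=lib_id, reads=paths[lib_id]),
                matcher, cfg.manifest,
            )
            assert counted.counts == tab.counts
            assert counted.n_unmapped == 0

    def test_sequencing_errors_lose_reads_at_expected_rate(self, tmp_path):
        cfg = make_null_config(
            seed=13, n_test_genes=2, n_negative_genes=1, mean_coverage=200,
            n_bio_reps=1, n_tech_reps=1,
        )
        screen = simulate_screen(cfg)
        err = 0.01
        paths = simulate_reads(
            screen, cfg.manifest, seed=13, out_dir=tmp_path, error_rate=err
        )
        matcher = build_matcher(cfg.manifest)
        tab = screen.replicate_counts[(1, 1)]
        counted = count_reads(
            SequencingLibrary(library_id="x", reads=paths["rep1_tech1"]),
            matcher, cfg.manifest,
        )
        n = tab.n_reads_total
        seq_len = 21
        expect = (1 - err) ** seq_len
        frac = counted.n_mapped / n
        sd = np.sqrt(expect * (1 - expect) / n)
        assert frac == pytest.approx(expect, abs=4 * sd)

    def test_empty_counts_give_empty_fastq(self, tmp_path):
        cfg = make_null_config(
            seed=14, n_test_genes=1, n_negative_genes=1, mean_coverage=5,
            n_bio_reps=1, n_tech_reps=1,
        )
        screen = simulate_screen(cfg)
        for cid in screen.input_pool_counts.counts:
            screen.input_pool_counts.counts[cid] = 0
        paths = simulate_reads(screen, cfg.manifest, seed=14, out_dir=tmp_path)
        assert paths["input_pool"].read_text() == ""

    def test_read_length_too_short(self, tmp_path):
        cfg = make_null_config(seed=15, n_test_genes=1, n_negative_genes=1)
        screen = simulate_screen(cfg)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(screen, cfg.manifest, read_length=22, out_dir=tmp_path)


class TestPilotLikeDesign:
    def test_ground_truth_matches_intended_error_structure(self):
        cfg = make_pilot_like_config(seed=21)
        truth = simulate_screen(cfg).truth_gene_essential
        pos = cfg.manifest.genes_in_class("positive")
        neg = cfg.manifest.genes_in_class("negative")
        assert sum(truth[g] for g in pos) == 14  # 3 refractory genes
        assert sum(truth[g] for g in neg) == 0

    def test_all_inert_pool_has_no_essential_truth(self):
        cfg = make_pilot_like_config(seed=22, effective_fraction=0.0,
                                     n_refractory_positive=17)
        # every positive gene refractory -> at most one effective construct
        truth = simulate_screen(cfg).truth_gene_essential
        assert not any(truth.values())

    def test_parameter_recovery_correlation(self, pilot_screen, pilot_groups):
        # mean per-construct log2fc across replicates tracks the true
        # selection coefficients
        cfg = pilot_screen.config
        _, _, fc = run_count_pipeline(
            pilot_groups, pilot_screen.input_pool_counts, cfg.manifest
        )
        s = np.array(
            [pilot_screen.truth_selection[c] for c in cfg.manifest.construct_ids]
        )
        est = fc.log2fc.reindex(cfg.manifest.construct_ids).mean(axis=1)
        r = np.corrcoef(s, est)[0, 1]
        assert r >= 0.8

    def test_end_to_end_recovers_strongly_essential_genes(
        self, pilot_screen, pilot_groups
    ):
        # >= 80% of genes whose every effective pair is strong (s <= -2 twice)
        # are called by the full pipeline at alpha 0.01 / two-hit
        cfg = pilot_screen.config
        _, genes, _ = run_count_pipeline(
            pilot_groups, pilot_screen.input_pool_counts, cfg.manifest
        )
        called = {g.gene for g in genes if g.essential_call}
        strong = [
            g
            for g in cfg.manifest.genes
            if sum(
                pilot_screen.truth_selection[c.construct_id] <= -2.0
                for c in cfg.manifest.constructs_for_gene(g)
            )
            >= 2
        ]
        assert strong, "design should contain strongly essential genes"
        recovered = sum(g in called for g in strong) / len(strong)
        assert recovered >= 0.8

    def test_graded_pool_spans_small_effects(self):
        cfg = make_graded_config(seed=23)
        sel = [v for v in simulate_screen(cfg).truth_selection.values() if v < 0]
        assert min(sel) < -3.0
        assert max(sel) > -0.25
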