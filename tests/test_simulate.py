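"""Generator checks: planted truth, count structure, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from m6akit import (
    SimulationConfig,
    generate_truth,
    simulate_calibration_run,
    simulate_decay_series,
    simulate_expression,
    simulate_merip_windows,
)
from m6akit.kinetics import CHANNEL_A, CHANNEL_M6A


class TestGenerateTruth:
    def test_transcript_count_and_lengths(self, small_cohort):
        tx = small_cohort["transcripts"]
        assert len(tx) == small_cohort["config"].n_transcripts
        assert (tx["total_len"] == tx["utr5_len"] + tx["cds_len"] + tx["utr3_len"]).all()
        assert (tx["cds_len"] > 0).all()

    def test_methylated_fraction_matches_binomial_draw(self):
        cfg = SimulationConfig(n_transcripts=2000, frac_methylated=0.5, seed=3)
        _, truth = generate_truth(cfg)
        n_meth = int(truth["is_methylated"].sum())  # direct count oracle
        sd = math.sqrt(2000 * 0.5 * 0.5)
        assert abs(n_meth - 1000) <= 3 * sd

    def test_no_methylation_means_no_peaks(self):
        cfg = SimulationConfig(n_transcripts=150, frac_methylated=0.0, seed=1)
        _, truth = generate_truth(cfg)
        assert truth["peak_start"].isna().all()
        assert (truth["true_quadrant"] == "none").all()

    def test_quadrant_mix_frequencies(self):
        cfg = SimulationConfig(
            n_transcripts=5000, frac_methylated=0.6, frac_diff_methylated=0.8,
            quadrant_mix=(0.7, 0.1, 0.1, 0.1), seed=7,
        )
        _, truth = generate_truth(cfg)
        labeled = truth[truth["true_quadrant"] != "none"]
        share = (labeled["true_quadrant"] == "hyper-up").mean()
        sd = math.sqrt(0.7 * 0.3 / len(labeled))
        assert abs(share - 0.7) <= 3 * sd

    def test_quadrant_defined_iff_both_directions(self, small_cohort):
        truth = small_cohort["truth"]
        both = (truth["meth_direction"] != "none") & (truth["expr_direction"] != "none")
        assert ((truth["true_quadrant"] != "none") == both).all()

    def test_peak_interval_inside_transcript(self, small_cohort):
        t = small_cohort["truth"].merge(small_cohort["transcripts"], on=["transcript_id", "gene_id"])
        meth = t[t["is_methylated"]]
        assert (meth["peak_start"] >= 0).all()
        assert (meth["peak_end"] <= meth["total_len"]).all()
        assert (meth["peak_start"] < meth["peak_end"]).all()

    def test_empty_configuration(self):
        tx, truth = generate_truth(SimulationConfig(n_transcripts=0, seed=0))
        assert len(tx) == 0 and len(truth) == 0

    @pytest.mark.parametrize("bad", [
        {"frac_methylated": 1.5},
        {"dispersion": 0.0},
        {"quadrant_mix": (-1.0, 1.0, 0.0, 0.0)},
        {"expr_fc": 0.5},
        {"window_size": 0},
    ])
    def test_invalid_configuration_raises(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad).validate()


class TestMeripWindows:
    def test_windows_tile_each_transcript(self, small_cohort):
        tx = small_cohort["transcripts"].set_index("transcript_id")
        w = small_cohort["windows"]
        one_sample = w[w["sample"] == w["sample"].iloc[0]]
        for tid, grp in one_sample.groupby("transcript_id"):
            grp = grp.sort_values("window_start")
            assert grp["window_start"].iloc[0] == 0
            assert grp["window_end"].iloc[-1] == tx.loc[tid, "total_len"]
            assert (grp["window_end"].to_numpy()[:-1] == grp["window_start"].to_numpy()[1:]).all()
            assert (grp["window_start"] < grp["window_end"]).all()

    def test_counts_are_nonnegative_integers(self, small_cohort):
        w = small_cohort["windows"]
        for col in ("ip_count", "input_count"):
            assert w[col].dtype.kind in "iu"
            assert (w[col] >= 0).all()

    def test_single_window_when_transcript_shorter_than_window(self):
        cfg = SimulationConfig(n_transcripts=10, window_size=100_000,
                               n_patients=1, seed=2)
        tx, truth = generate_truth(cfg)
        w = simulate_merip_windows(truth, tx, cfg)
        per = w.groupby(["transcript_id", "sample"]).size()
        assert (per == 1).all()
        one = w[w["sample"] == w["sample"].iloc[0]].set_index("transcript_id")
        assert (one["window_end"] == tx.set_index("transcript_id")["total_len"]).all()

    def test_null_configuration_ip_input_ratio_near_one(self):
        cfg = SimulationConfig(n_transcripts=300, n_patients=2,
                               frac_methylated=0.0, seed=5)
        tx, truth = generate_truth(cfg)
        w = simulate_merip_windows(truth, tx, cfg)
        assert len(w) >= 4 * 10_000
        ratio = w["ip_count"].sum() / w["input_count"].sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_planted_peak_enrichment_recovered_by_averaging(self):
        cfg = SimulationConfig(n_transcripts=400, n_patients=2, frac_methylated=0.5,
                               frac_diff_methylated=0.0, peak_enrichment=4.0, seed=9)
        tx, truth = generate_truth(cfg)
        w = simulate_merip_windows(truth, tx, cfg)
        merged = w.merge(truth[["transcript_id", "peak_start", "peak_end"]], on="transcript_id")
        inside = (
            merged["peak_start"].notna()
            & (merged["window_start"] < merged["peak_end"].fillna(-1).astype(int))
            & (merged["window_end"] > merged["peak_start"].fillna(-1).astype(int))
        )
        # brute-force averaging oracle over pooled counts
        r_in = merged.loc[inside, "ip_count"].sum() / merged.loc[inside, "input_count"].sum()
        r_out = merged.loc[~inside, "ip_count"].sum() / merged.loc[~inside, "input_count"].sum()
        assert r_in / r_out == pytest.approx(4.0, rel=0.15)

    def test_peak_placement_biased_toward_utr3(self):
        cfg = SimulationConfig(n_transcripts=2000, frac_methylated=1.0,
                               peak_segment_bias=(0.1, 0.35, 0.55), seed=13)
        tx, truth = generate_truth(cfg)
        merged = truth.merge(tx, on=["transcript_id", "gene_id"])
        mid = (merged["peak_start"] + merged["peak_end"]) // 2
        in_utr5 = (mid < merged["utr5_len"]).sum()
        in_utr3 = (mid >= merged["utr5_len"] + merged["cds_len"]).sum()
        assert in_utr3 > in_utr5

    def test_seeded_outputs_bit_identical(self, small_config):
        a_tx, a_truth = generate_truth(small_config)
        b_tx, b_truth = generate_truth(small_config)
        pd.testing.assert_frame_equal(a_tx, b_tx)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        w1 = simulate_merip_windows(a_truth, a_tx, small_config)
        w2 = simulate_merip_windows(b_truth, b_tx, small_config)
        pd.testing.assert_frame_equal(w1, w2)
        e1 = simulate_expression(a_truth, small_config)
        e2 = simulate_expression(b_truth, small_config)
        pd.testing.assert_frame_equal(e1, e2)


class TestExpression:
    def test_no_effect_gives_zero_mean_log2fc(self):
        cfg = SimulationConfig(n_transcripts=200, n_patients=4, expr_fc=1.0,
                               quadrant_mix=(0.5, 0.0, 0.5, 0.0), seed=21)
        _, truth = generate_truth(cfg)
        counts = simulate_expression(truth, cfg)
        cols_a = [c for c in counts.columns if c.endswith("_N")]
        cols_b = [c for c in counts.columns if c.endswith("_T")]
        lfc = np.log2((counts[cols_b].mean(axis=1) + 0.5) / (counts[cols_a].mean(axis=1) + 0.5))
        up = truth.set_index("gene_id")["expr_direction"] == "up"
        assert abs(float(lfc[up.to_numpy()].mean())) < 0.1

    def test_planted_up_genes_mostly_positive_log2fc(self):
        cfg = SimulationConfig(n_transcripts=300, n_patients=4, expr_fc=2.0,
                               seq_depth=500, frac_methylated=0.8,
                               frac_diff_methylated=0.9,
                               quadrant_mix=(0.5, 0.0, 0.5, 0.0), seed=22)
        _, truth = generate_truth(cfg)
        counts = simulate_expression(truth, cfg)
        cols_a = [c for c in counts.columns if c.endswith("_N")]
        cols_b = [c for c in counts.columns if c.endswith("_T")]
        lfc = np.log2((counts[cols_b].mean(axis=1) + 0.5) / (counts[cols_a].mean(axis=1) + 0.5))
        up = (truth["expr_direction"] == "up").to_numpy()
        assert up.sum() >= 100
        assert float((lfc.to_numpy()[up] > 0).mean()) >= 0.95


class TestDecayAndCalibration:
    def test_noiseless_series_is_exact_exponential(self):
        s = simulate_decay_series(math.log(2), [0, 1, 2], cv=0.0)
        assert np.allclose(s.abundances, [1.0, 0.5, 0.25])

    def test_t0_abundance_is_one(self):
        s = simulate_decay_series(1.7, [0, 1, 2, 4], cv=0.3, seed=4)
        assert s.abundances[s.timepoints == 0][0] == 1.0

    @pytest.mark.parametrize("kwargs", [
        {"k": 0.0, "timepoints": [0, 1, 2]},
        {"k": 0.5, "timepoints": []},
        {"k": 0.5, "timepoints": [1, 2, 3]},   # missing t = 0
        {"k": 0.5, "timepoints": [0, 1], "cv": -0.1},
    ])
    def test_decay_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            simulate_decay_series(**kwargs)

    def test_calibration_channels_carry_mass_transitions(self):
        standards, responses = simulate_calibration_run(0.01, [1, 2, 5], noise=0.0)
        channels = set(standards["channel"])
        assert channels == {CHANNEL_M6A, CHANNEL_A}
        assert "282" in CHANNEL_M6A and "150" in CHANNEL_M6A
        assert "268" in CHANNEL_A and "136" in CHANNEL_A
        assert set(responses) == channels

    def test_noiseless_standards_lie_on_configured_line(self):
        standards, _ = simulate_calibration_run(
            0.01, [1.0, 2.0, 4.0], noise=0.0, slopes=(2.0, 1.0), intercepts=(0.0, 0.0))
        m6a = standards[standards["channel"] == CHANNEL_M6A]
        assert np.allclose(m6a["response"], 2.0 * m6a["concentration"])

    @pytest.mark.parametrize("bad", [
        {"true_ratio": 0.01, "standards": [1.0]},
        {"true_ratio": 0.01, "standards": [1.0, 1.0, 2.0]},
        {"true_ratio": 1.5, "standards": [1.0, 2.0]},
        {"true_ratio": 0.01, "standards": [-1.0, 2.0]},
    ])
    def test_calibration_domain_errors(self, bad):
        with pytest.raises(ValueError):
            simulate_calibration_run(**bad)
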