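"""Quadrant classification, summaries, high-frequency rule and the screen."""

import math

import numpy as np
import pandas as pd
import pytest

from m6akit.integrate import (
    QuadrantCall,
    classify_quadrants,
    expression_changes,
    high_frequency_hyperup,
    quadrant_percentages,
    screen_candidates,
)
from m6akit.peaks import DifferentialPeak, Peak


def _diff_peak(tid, q, lfc, direction, start=0):
    pk = Peak(transcript_id=tid, start=start, end=start + 100,
              enrichment=2.0, p_value=q / 2)
    return DifferentialPeak(peak=pk, log2_meth_fc=lfc, p_value=q / 2,
                            q_value=q, direction=direction)


def _tx(pairs):
    return pd.DataFrame({
        "transcript_id": [t for t, _ in pairs],
        "gene_id": [g for _, g in pairs],
        "utr5_len": 100, "cds_len": 200, "utr3_len": 100, "total_len": 400,
    })


class TestExpressionChanges:
    def test_identical_conditions_give_zero_and_none(self):
        counts = pd.DataFrame({"s1": [100, 900], "s2": [100, 900]},
                              index=pd.Index(["g1", "g2"], name="gene_id"))
        changes = expression_changes(counts, {"s1": "A", "s2": "B"})
        assert all(c.log2_fc == 0.0 and c.direction == "none" for c in changes)

    def test_pseudocounted_fold_change_at_cpm_100_vs_25(self):
        # gene g at CPM 100 in A and 25 in B-reversed orientation:
        # log2((100+0.5)/(25+0.5)) with the 0.5-CPM pseudocount
        counts = pd.DataFrame(
            {"a": [100, 999_900], "b": [25, 999_975]},
            index=pd.Index(["g", "filler"], name="gene_id"))
        changes = expression_changes(counts, {"a": "A", "b": "B"})
        g = next(c for c in changes if c.gene_id == "g")
        assert g.log2_fc == pytest.approx(math.log2(25.5 / 100.5), abs=1e-9)
        assert g.direction == "down"

    def test_direction_threshold(self):
        counts = pd.DataFrame({"a": [100, 200], "b": [150, 150]},
                              index=pd.Index(["g1", "g2"], name="gene_id"))
        strict = expression_changes(counts, {"a": "A", "b": "B"}, min_abs_log2fc=2.0)
        assert all(c.direction == "none" for c in strict)

    def test_missing_condition_raises(self):
        counts = pd.DataFrame({"a": [1]}, index=pd.Index(["g"], name="gene_id"))
        with pytest.raises(ValueError):
            expression_changes(counts, {"a": "A"})


class TestClassifyQuadrants:
    def _changes(self, mapping):
        from m6akit.integrate import ExpressionChange
        return [ExpressionChange(g, 1.0 if d == "up" else -1.0 if d == "down" else 0.0, d)
                for g, d in mapping.items()]

    def test_quadrant_vocabulary(self):
        tx = _tx([("T1", "G1"), ("T2", "G2"), ("T3", "G3"), ("T4", "G4")])
        dps = [_diff_peak("T1", 0.01, 1.0, "hyper"),
               _diff_peak("T2", 0.01, 1.0, "hyper"),
               _diff_peak("T3", 0.01, -1.0, "hypo"),
               _diff_peak("T4", 0.01, -1.0, "hypo")]
        changes = self._changes({"G1": "up", "G2": "down", "G3": "up", "G4": "down"})
        calls = {c.gene_id: c.quadrant for c in classify_quadrants(dps, changes, tx)}
        assert calls == {"G1": "hyper-up", "G2": "hyper-down",
                         "G3": "hypo-up", "G4": "hypo-down"}

    def test_gene_without_expression_direction_is_excluded(self):
        tx = _tx([("T1", "G1")])
        dps = [_diff_peak("T1", 0.01, 1.0, "hyper")]
        assert classify_quadrants(dps, self._changes({"G1": "none"}), tx) == []

    def test_gene_without_directional_peak_is_excluded(self):
        tx = _tx([("T1", "G1")])
        dps = [_diff_peak("T1", 0.5, 0.2, "none")]
        assert classify_quadrants(dps, self._changes({"G1": "up"}), tx) == []

    def test_multi_peak_gene_takes_smallest_q(self):
        tx = _tx([("T1", "G1"), ("T2", "G1")])
        dps = [_diff_peak("T1", 0.01, 1.0, "hyper"),
               _diff_peak("T2", 0.04, -2.0, "hypo")]
        calls = classify_quadrants(dps, self._changes({"G1": "up"}), tx)
        assert len(calls) == 1 and calls[0].meth_direction == "hyper"

    def test_q_tie_broken_by_larger_effect_then_position(self):
        tx = _tx([("T1", "G1"), ("T2", "G1")])
        dps = [_diff_peak("T1", 0.01, 1.0, "hyper"),
               _diff_peak("T2", 0.01, -3.0, "hypo")]
        calls = classify_quadrants(dps, self._changes({"G1": "up"}), tx)
        assert calls[0].meth_direction == "hypo"


class TestQuadrantPercentages:
    def _call(self, quadrant, gene="G1"):
        m, e = quadrant.split("-")
        return QuadrantCall(gene_id=gene, meth_direction=m, expr_direction=e)

    def test_single_class_patient(self):
        s = quadrant_percentages({"P1": [self._call("hyper-up", f"G{i}") for i in range(5)]})
        assert s.per_patient_pct.loc["P1", "hyper-up"] == 100.0
        assert s.cohort_mean_pct["hyper-up"] == 100.0

    def test_direct_division(self):
        calls = ([self._call("hyper-up", f"G{i}") for i in range(7)]
                 + [self._call("hyper-down", "Ga"), self._call("hypo-up", "Gb"),
                    self._call("hypo-down", "Gc")])
        s = quadrant_percentages({"P1": calls})
        row = s.per_patient_pct.loc["P1"]
        assert list(row[["hyper-up", "hyper-down", "hypo-up", "hypo-down"]]) == [70, 10, 10, 10]

    def test_cohort_mean_is_unweighted(self):
        def patient(counts):
            out = []
            for q, k in zip(("hyper-up", "hyper-down", "hypo-up", "hypo-down"), counts):
                out += [self._call(q, f"G{q}{i}") for i in range(k)]
            return out
        s = quadrant_percentages({"P1": patient((16, 2, 1, 1)),
                                  "P2": patient((6, 2, 1, 1))})
        assert s.cohort_mean_pct["hyper-up"] == pytest.approx((80 + 60) / 2)

    def test_percentages_sum_to_100_per_patient(self):
        s = quadrant_percentages({"P1": [self._call("hyper-up"), self._call("hypo-down", "G2")],
                                  "P2": [self._call("hypo-up", "G3")]})
        assert np.allclose(s.per_patient_pct.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_call_patient_excluded_from_mean(self):
        s = quadrant_percentages({"P1": [self._call("hyper-up")], "P2": []})
        assert s.cohort_mean_pct["hyper-up"] == 100.0
        assert "P2" not in s.per_patient_pct.index

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            quadrant_percentages({"P1": []})


class TestHighFrequencyRule:
    def test_shared_by_three_is_included(self):
        sets = [{"g"}, {"g"}, {"g"}, set(), set(), set(), set(), set()]
        assert high_frequency_hyperup(sets, min_share=3) == ["g"]

    def test_shared_by_two_is_excluded(self):
        sets = [{"g"}, {"g"}, set(), set(), set(), set(), set(), set()]
        assert high_frequency_hyperup(sets, min_share=3) == []

    def test_hand_counted_example_with_ordering(self):
        sets = [{"a", "b"}, {"a"}, {"a", "c"}]
        assert high_frequency_hyperup(sets, min_share=2) == ["a"]

    def test_sorted_by_share_then_name(self):
        sets = [{"a", "b"}, {"a", "b"}, {"b"}]
        assert high_frequency_hyperup(sets, min_share=2) == ["b", "a"]

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            high_frequency_hyperup([{"a"}] * 3, min_share=0)
        with pytest.raises(ValueError):
            high_frequency_hyperup([{"a"}], min_share=3)


class TestScreen:
    def _frame(self, fc, hyper=None):
        df = pd.DataFrame({"gene_id": list(fc), "fold_change": list(fc.values())})
        if hyper is not None:
            df["hyper"] = [g in hyper for g in fc]
        return df

    def test_disjoint_lists_give_empty_candidates(self):
        a = self._frame({"x": 3.0})
        b = self._frame({"y": 3.0}, hyper={"y"})
        r = screen_candidates(a, b)
        assert r.candidates == ()

    def test_named_intersection(self):
        a = self._frame({"IL11": 4.0, "SERPINE2": 3.0, "X": 5.0})
        b = self._frame({"IL11": 2.5, "SERPINE2": 2.1, "Y": 9.0},
                        hyper={"IL11", "SERPINE2", "Y"})
        r = screen_candidates(a, b, fc_threshold=2.0)
        assert r.candidates == ("IL11", "SERPINE2")
        assert r.n_candidates <= min(r.n_list_a, r.n_list_b)

    def test_threshold_is_strict_and_hyper_flag_required(self):
        a = self._frame({"g": 2.0, "h": 2.01})
        b = self._frame({"g": 5.0, "h": 5.0, "k": 5.0}, hyper={"h", "g"})
        r = screen_candidates(a, b, fc_threshold=2.0)
        assert r.list_a == {"h"}           # fold change must strictly exceed 2
        assert "k" not in r.list_b         # above threshold but not hyper-flagged
        assert r.candidates == ("h",)

    def test_candidates_subset_of_both_lists(self):
        a = self._frame({"a": 3.0, "b": 3.0})
        b = self._frame({"b": 3.0, "c": 3.0}, hyper={"b", "c"})
        r = screen_candidates(a, b)
        assert set(r.candidates) <= r.list_a and set(r.candidates) <= r.list_b

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            screen_candidates(self._frame({"a": 3.0}),
                              self._frame({"a": 3.0}, hyper={"a"}), fc_threshold=0)

    def test_planted_overlap_recovered_exactly_under_noiseless_effects(self):
        # fold changes taken directly from a planted truth: 4x for planted
        # genes, 1x otherwise -> the screen must return exactly the overlap
        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(200)]
        kd_up = set(rng.choice(genes, 40, replace=False))
        hyper_up = set(rng.choice(genes, 50, replace=False))
        a = self._frame({g: (4.0 if g in kd_up else 1.0) for g in genes})
        b = self._frame({g: (4.0 if g in hyper_up else 1.0) for g in genes},
                        hyper=hyper_up)
        r = screen_candidates(a, b, fc_threshold=2.0)
        assert set(r.candidates) == (kd_up & hyper_up)
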