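import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import pooled_t_p
from vigormet.heterosis import (
    HybridStats,
    classify_combination,
    compute_bpv,
    compute_mpv,
    evaluate_combination,
    heterosis_percent,
    summarize_population,
)
from vigormet.heterosis import test_vs_bpv as bpv_t_test
from vigormet.synthetic_data import CrossConfig, simulate_trait_table


class TestMpvBpv:
    def test_mpv_is_mean_of_parental_means(self):
        assert compute_mpv([10, 12, 14], [6, 8, 10]) == pytest.approx(10.0)
        assert compute_mpv([12], [8]) == pytest.approx(10.0)
        assert compute_mpv([5, 5], [5, 5]) == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "p1, p2, bpv, better",
        [([12], [8], 12.0, "parent1"), ([8], [12], 12.0, "parent2")],
    )
    def test_bpv_is_larger_parental_mean(self, p1, p2, bpv, better):
        res = compute_bpv(p1, p2)
        assert (res.bpv, res.better_parent) == (bpv, better)
        assert not res.tie

    def test_parental_tie_defaults_to_parent1_with_flag(self):
        res = compute_bpv([7, 9], [8, 8])
        assert res.better_parent == "parent1"
        assert res.tie

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_mpv([], [1.0])
        with pytest.raises(ValueError):
            compute_bpv([1.0], [])

    @given(
        p1=st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=8),
        p2=st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=8),
    )
    @settings(deadline=None)
    def test_mpv_never_exceeds_bpv(self, p1, p2):
        assert compute_mpv(p1, p2) <= compute_bpv(p1, p2).bpv + 1e-12


class TestHeterosisPercent:
    @pytest.mark.parametrize(
        "f1, ref, expected", [(13.2, 12.0, 10.0), (12.0, 12.0, 0.0), (14.4, 10.0, 44.0)]
    )
    def test_percent_arithmetic(self, f1, ref, expected):
        assert heterosis_percent(f1, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            heterosis_percent(10.0, 0.0)

    def test_bph_below_mph_when_parents_differ(self):
        p1, p2 = [10.0, 11.0], [6.0, 7.0]
        mpv = compute_mpv(p1, p2)
        bpv = compute_bpv(p1, p2).bpv
        f1 = 12.0
        assert heterosis_percent(f1, bpv) < heterosis_percent(f1, mpv)


class TestTestVsBpv:
    def test_identical_samples_give_p_one(self):
        res = bpv_t_test([5, 5, 5], [5, 5, 5])
        assert res.p == 1.0
        assert not res.significant_above and not res.significant_below

    def test_p_matches_independent_t_cdf_evaluation(self):
        f1, bp = [10, 11, 12], [7, 8, 9]
        res = bpv_t_test(f1, bp)
        assert res.p == pytest.approx(pooled_t_p(f1, bp), abs=1e-12)
        assert res.p == pytest.approx(0.0214, abs=5e-4)
        assert res.significant_above and not res.significant_below

    def test_two_sided_symmetry_flips_direction_flag(self):
        up = bpv_t_test([10, 11, 12], [7, 8, 9])
        down = bpv_t_test([7, 8, 9], [10, 11, 12])
        assert up.p == pytest.approx(down.p)
        assert down.significant_below and not down.significant_above

    def test_zero_variance_unequal_means_is_degenerate(self):
        res = bpv_t_test([5, 5, 5], [4, 4, 4])
        assert res.degenerate
        assert res.p < 1e-300
        assert res.significant_above


def _stats(bph, above, below=False, line="h"):
    return HybridStats(line, 100.0, bph, bph + 5, 0.01 if (above or below) else 0.5, above, below)


class TestClassification:
    def test_high_when_both_significant_and_one_exceeds_threshold(self):
        # the anchor pattern: reciprocals 32.9% and 11.6% above BPV
        assert classify_combination(_stats(32.9, True), _stats(11.6, True)) == "high"

    def test_weak_when_effects_sit_between_zero_and_threshold(self):
        # the anchor pattern: 8.9% and 1.8% with one significant
        assert classify_combination(_stats(8.9, True), _stats(1.8, False)) == "weak"

    def test_none_when_neither_significant(self):
        assert classify_combination(_stats(3.0, False), _stats(-2.0, False)) == "none"

    def test_opposite_significant_trends_unclassifiable(self):
        up = _stats(15.0, True)
        down = HybridStats("h", 80.0, -12.0, -5.0, 0.01, False, True)
        assert classify_combination(up, down) == "unclassifiable"

    def test_mixed_pattern_falls_through_to_unclassifiable(self):
        # one reciprocal strongly above, the other nonsignificantly below
        up = _stats(15.0, True)
        below_ns = HybridStats("h", 95.0, -3.0, 1.0, 0.4, False, False)
        assert classify_combination(up, below_ns) == "unclassifiable"

    def test_both_significant_but_small_is_weak(self):
        assert classify_combination(_stats(6.0, True), _stats(4.0, True)) == "weak"

    def test_missing_reciprocal_rejected(self):
        with pytest.raises(ValueError):
            classify_combination(_stats(5.0, True), None)

    @given(
        bph1=st.floats(min_value=-30, max_value=40),
        bph2=st.floats(min_value=-30, max_value=40),
        sig1=st.booleans(),
        sig2=st.booleans(),
    )
    @settings(deadline=None)
    def test_partition_exactly_one_label(self, bph1, bph2, sig1, sig2):
        h1 = HybridStats("a", 1, bph1, bph1, 0.01 if sig1 else 0.5, sig1 and bph1 > 0, sig1 and bph1 < 0)
        h2 = HybridStats("b", 1, bph2, bph2, 0.01 if sig2 else 0.5, sig2 and bph2 > 0, sig2 and bph2 < 0)
        assert classify_combination(h1, h2) in {"high", "weak", "none", "unclassifiable"}


class TestEvaluateCombination:
    def test_scale_invariance_of_percentages_pvalues_and_label(self):
        config = CrossConfig(heterosis_bph_pct=(25.0, 12.0), cv=0.08, n_reps=6, seed=5)
        table = simulate_trait_table(config)
        scaled = table.assign(value=table["value"] * 1000.0)
        a = evaluate_combination(table)
        b = evaluate_combination(scaled)
        assert a.class_label == b.class_label
        for role in ("F1", "F1rec"):
            assert a.hybrids[role].bph_pct == pytest.approx(b.hybrids[role].bph_pct)
            assert a.hybrids[role].mph_pct == pytest.approx(b.hybrids[role].mph_pct)
            assert a.hybrids[role].p_vs_bpv == pytest.approx(b.hybrids[role].p_vs_bpv)

    def test_missing_role_rejected(self):
        table = simulate_trait_table(CrossConfig(seed=1))
        with pytest.raises(ValueError, match="F1rec"):
            evaluate_combination(table[table["role"] != "F1rec"])

    def test_welch_flag_changes_test_but_not_structure(self):
        table = simulate_trait_table(CrossConfig(heterosis_bph_pct=(20.0, 20.0), seed=2))
        pooled = evaluate_combination(table)
        welch = evaluate_combination(table, welch=True)
        assert set(pooled.hybrids) == set(welch.hybrids)


class TestSummarizePopulation:
    def _population(self, labels):
        results = []
        for i, label in enumerate(labels):
            bph = {"high": (32.0, 12.0), "weak": (8.0, 2.0), "none": (1.0, -2.0)}.get(
                label, (15.0, -12.0)
            )
            sig = label == "high"
            table = None
            results.append(
                type(
                    "R",
                    (),
                    {
                        "class_label": label,
                        "hybrids": {
                            "F1": _stats(bph[0], sig, line=f"c{i}"),
                            "F1rec": _stats(bph[1], sig, line=f"c{i}r"),
                        },
                    },
                )()
            )
        return results

    def test_counts_and_percentages(self):
        labels = ["high"] * 9 + ["none"] * 11 + ["weak"] * 2 + ["unclassifiable"] * 6
        summary = summarize_population(self._population(labels))
        assert summary.loc["high", "count"] == 9
        assert summary["count"].sum() == 28
        assert summary.loc["high", "pct_of_total"] == pytest.approx(100 * 9 / 28)

    def test_empty_class_reports_absent_range(self):
        summary = summarize_population(self._population(["high", "high"]))
        assert summary.loc["weak", "count"] == 0
        assert np.isnan(summary.loc["weak", "bph_min"])
        assert summary.loc["high", "pct_of_total"] == pytest.approx(100.0)
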