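import itertools

import numpy as np
import pytest
from scipy.stats import studentized_range

from vigormet.preprocess import is_normalize
from vigormet.synthetic_data import MetabolomeConfig, simulate_metabolome
from vigormet.tca import (
    analyze_ratios,
    anova_tukey,
    fold_vs_mpv_ratio,
    mpv_area_ratio_fold,
    ratio_table,
    sample_ratio,
)


class TestSampleRatio:
    @pytest.mark.parametrize("fum, mal, expected", [(2, 1, 2.0), (1, 1, 1.0), (0.5, 2, 0.25)])
    def test_ratio_arithmetic(self, fum, mal, expected):
        assert sample_ratio(fum, mal) == pytest.approx(expected)

    def test_nonpositive_malate_rejected(self):
        with pytest.raises(ValueError):
            sample_ratio(1.0, 0.0)

    def test_missing_fumarate_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(sample_ratio(float("nan"), 2.0))


class TestFoldVsMpv:
    def test_headline_arithmetic(self):
        fold = fold_vs_mpv_ratio([4.4, 4.4], [2.5, 2.5], [1.5, 1.5])
        assert fold == pytest.approx(2.2)

    def test_hybrid_equal_to_mpv_gives_unit_fold(self):
        assert fold_vs_mpv_ratio([2.0, 2.0], [2.5, 2.5], [1.5, 1.5]) == pytest.approx(1.0)

    def test_injected_fumarate_effect_recovered_over_seeds(self):
        """A x2.2 fumarate shift is recovered as fold 2.2 +/- 5% (mean over 100 seeds)."""
        folds = []
        for seed in range(100):
            config = MetabolomeConfig(
                n_peaks=30, n_known=20, n_is=4,
                line_effects={"ColxC24": {"Fumarate": 2.2}},
                noise_sd_log2=0.1, seed=seed,
            )
            matrix, _ = simulate_metabolome(config)
            normalized, _ = is_normalize(matrix)
            table = ratio_table(
                normalized,
                normalized.peaks.index[normalized.peaks["annotation"] == "Fumarate"][0],
                normalized.peaks.index[normalized.peaks["annotation"] == "Malate"][0],
            )
            groups = {
                line: table.loc[table["line_id"] == line, "ratio"].to_numpy()
                for line in ("ColxC24", "Col", "C24")
            }
            folds.append(fold_vs_mpv_ratio(groups["ColxC24"], groups["Col"], groups["C24"]))
        assert np.mean(folds) == pytest.approx(2.2, rel=0.05)

    def test_no_effect_config_concentrates_at_unity(self):
        folds = []
        for seed in range(100):
            config = MetabolomeConfig(n_peaks=20, n_known=15, n_is=3, seed=seed)
            matrix, _ = simulate_metabolome(config)
            fum = matrix.peaks.index[matrix.peaks["annotation"] == "Fumarate"][0]
            mal = matrix.peaks.index[matrix.peaks["annotation"] == "Malate"][0]
            table = ratio_table(matrix, fum, mal)
            groups = {
                line: table.loc[table["line_id"] == line, "ratio"].to_numpy()
                for line in ("ColxC24", "Col", "C24")
            }
            folds.append(fold_vs_mpv_ratio(groups["ColxC24"], groups["Col"], groups["C24"]))
        assert np.mean(folds) == pytest.approx(1.0, abs=0.02)


class TestScaleInvariance:
    def test_common_rescale_leaves_everything_unchanged(self, default_metabolome):
        _, matrix, _ = default_metabolome
        fum = matrix.peaks.index[matrix.peaks["annotation"] == "Fumarate"][0]
        mal = matrix.peaks.index[matrix.peaks["annotation"] == "Malate"][0]
        base = analyze_ratios(matrix, fum, mal, ("Col", "C24"), ("ColxC24", "C24xCol"))
        scaled = matrix.copy()
        scaled.data.loc[[fum, mal]] *= 13.0
        after = analyze_ratios(scaled, fum, mal, ("Col", "C24"), ("ColxC24", "C24xCol"))
        for h in ("ColxC24", "C24xCol"):
            assert after.fold_vs_mpv[h] == pytest.approx(base.fold_vs_mpv[h])
        assert after.tukey_letters == base.tukey_letters

    def test_fumarate_only_rescale_multiplies_ratios(self, default_metabolome):
        _, matrix, _ = default_metabolome
        fum = matrix.peaks.index[matrix.peaks["annotation"] == "Fumarate"][0]
        mal = matrix.peaks.index[matrix.peaks["annotation"] == "Malate"][0]
        base = ratio_table(matrix, fum, mal)["ratio"].to_numpy()
        scaled = matrix.copy()
        scaled.data.loc[fum] *= 3.0
        after = ratio_table(scaled, fum, mal)["ratio"].to_numpy()
        assert np.allclose(after, 3.0 * base)


class TestAnovaTukey:
    def test_identical_groups_share_single_letter(self):
        groups = {name: np.array([5.0, 5.0, 5.0]) for name in "ABCD"}
        res = anova_tukey(groups)
        assert res.anova_p == 1.0
        assert set(res.letters.values()) == {"a"}

    def test_outlier_group_gets_unique_letter(self):
        rng = np.random.default_rng(0)
        groups = {name: rng.normal(0, 1, 6) for name in "ABC"}
        groups["D"] = rng.normal(100, 1, 6)
        res = anova_tukey(groups)
        d_letters = set(res.letters["D"])
        others = set("".join(res.letters[g] for g in "ABC"))
        assert d_letters.isdisjoint(others)
        # verify against the studentized-range critical value by brute force
        all_values = np.concatenate(list(groups.values()))
        k, n = 4, 6
        df = all_values.size - k
        mse = sum((v - v.mean()) @ (v - v.mean()) for v in groups.values()) / df
        q_crit = studentized_range.ppf(0.95, k, df)
        for a, b in itertools.combinations(groups, 2):
            q_stat = abs(groups[a].mean() - groups[b].mean()) / np.sqrt(mse / n)
            significant = q_stat > q_crit
            shares = bool(set(res.letters[a]) & set(res.letters[b]))
            assert shares == (not significant)

    def test_two_groups_reduce_to_pairwise_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(5, 1, 6)
        res = anova_tukey({"A": a, "B": b})
        assert res.letters["A"] != res.letters["B"]
        same = anova_tukey({"A": a, "B": a + 0.01 * rng.normal(size=6)})
        assert set(same.letters["A"]) & set(same.letters["B"])

    def test_letter_display_valid_for_random_six_group_data(self):
        """Shared letter <=> Tukey-adjusted p >= alpha, exhaustively for 6 groups."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            k = int(rng.integers(3, 7))
            spread = rng.uniform(0, 4)
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, spread), 1, 5) for i in range(k)
            }
            res = anova_tukey(groups)
            for row in res.pairwise.itertuples():
                shares = bool(set(res.letters[row.group1]) & set(res.letters[row.group2]))
                assert shares == (row.p_adj >= 0.05), (
                    f"trial {trial}: {row.group1}/{row.group2} "
                    f"p_adj={row.p_adj} letters={res.letters}"
                )

    def test_group_sizes_validated(self):
        with pytest.raises(ValueError):
            anova_tukey({"A": np.ones(3)})
        with pytest.raises(ValueError):
            anova_tukey({"A": np.ones(3), "B": np.array([1.0])})


class TestAnalyzeRatios:
    def test_full_analysis_reports_both_mpv_conventions(self, default_metabolome):
        config, matrix, truth = default_metabolome
        normalized, _ = is_normalize(matrix)
        fum = matrix.peaks.index[matrix.peaks["annotation"] == "Fumarate"][0]
        mal = matrix.peaks.index[matrix.peaks["annotation"] == "Malate"][0]
        result = analyze_ratios(
            normalized, fum, mal, parents=("Col", "C24"), hybrids=("ColxC24", "C24xCol")
        )
        for hybrid in ("ColxC24", "C24xCol"):
            assert result.fold_vs_mpv[hybrid] == pytest.approx(
                truth.true_ratio_fold[hybrid], rel=0.15
            )
            alt = mpv_area_ratio_fold(normalized, fum, mal, hybrid, "Col", "C24")
            assert result.fold_vs_mpv_area_convention[hybrid] == pytest.approx(alt)
        frame = result.to_frame()
        assert set(frame["line_id"]) == {"Col", "C24", "ColxC24", "C24xCol"}
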