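import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phagoquant import study_tables
from phagoquant.stats import (
    baseline_contrasts,
    bonferroni_posthoc,
    combined_average,
    group_densities,
    normalize_to_max,
    one_way_anova,
    shapiro_wilk,
    stacked_profile,
    subtype_report,
    two_way_anova,
)
from phagoquant.synthetic import CountModel, generate_timecourse

# frozen n=12 sample with its R shapiro.test() result (cross-implementation oracle)
R_SAMPLE = [
    2.617314, 2.985152, 2.688032, 1.416092, 1.16432, 2.040318,
    2.516811, 2.305512, 3.086171, 2.450506, 2.383856, 1.561206,
]
R_SHAPIRO_W = 0.9316409565
R_SHAPIRO_P = 0.3978303132


class TestShapiroWilk:
    def test_matches_r_reference_implementation(self):
        w, p = shapiro_wilk(R_SAMPLE)
        assert w == pytest.approx(R_SHAPIRO_W, abs=1e-6)
        assert p == pytest.approx(R_SHAPIRO_P, abs=1e-6)

    def test_ordered_normal_scores_give_high_w(self):
        scores = sps.norm.ppf((np.arange(1, 21) - 0.375) / (20 + 0.25))
        w, _ = shapiro_wilk(scores)
        assert w > 0.99

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_error(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])


class TestOneWayAnova:
    def test_hand_computed_sums_of_squares(self):
        result = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert result.F == pytest.approx(3.0)
        assert (result.df_between, result.df_within) == (2, 6)

    def test_identical_groups_give_zero_f(self):
        result = one_way_anova([[1, 2, 3], [3, 1, 2], [2, 3, 1]])
        assert result.F == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_zero_within_variance_flagged_infinite(self):
        result = one_way_anova([[1, 1, 1], [2, 2, 2]])
        assert np.isinf(result.F)
        assert result.p == 0.0

    def test_matches_scipy_on_unbalanced_groups(self, rng):
        groups = [rng.normal(i * 0.3, 1, size=n) for i, n in enumerate((4, 7, 5, 9))]
        mine = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert mine.F == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        result = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert result.F == pytest.approx(t.statistic**2)
        assert result.p == pytest.approx(t.pvalue)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])


class TestBonferroniPosthoc:
    def test_seven_groups_give_21_comparisons(self, rng):
        groups = {zt: rng.normal(2, 0.5, 6) for zt in study_tables.ZT_POINTS}
        table = bonferroni_posthoc(groups)
        assert len(table) == 21

    def test_adjustment_never_lowers_p_and_caps_at_one(self, rng):
        groups = {i: rng.normal(0, 1, 5) for i in range(5)}
        table = bonferroni_posthoc(groups)
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()
        order_raw = table.sort_values("p_raw").index
        order_adj = table.sort_values("p_adjusted", kind="stable").index
        # order-preserving up to the cap at 1
        uncapped = table["p_adjusted"] < 1.0
        assert list(table.loc[uncapped].sort_values("p_raw").index) == list(
            table.loc[uncapped].sort_values("p_adjusted").index
        )

    def test_identical_groups_adjusted_to_one(self):
        groups = {1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0], 3: [5.0, 6.0, 7.0]}
        table = bonferroni_posthoc(groups)
        row = table[(table.group_a == 1) & (table.group_b == 2)].iloc[0]
        assert row["p_adjusted"] == 1.0

    def test_separated_pair_detected_with_power(self, rng):
        hits = 0
        for _ in range(100):
            groups = {i: rng.normal(0, 0.5, 8) for i in range(6)}
            groups[6] = rng.normal(2.0, 0.5, 8)
            table = bonferroni_posthoc(groups)
            worst = table[
                ((table.group_a == 0) & (table.group_b == 6))
            ]["p_adjusted"].iloc[0]
            hits += worst < 0.05
        assert hits >= 95

    def test_baseline_contrasts_against_zt10(self, rng):
        groups = {zt: rng.normal(2, 0.5, 6) for zt in study_tables.ZT_POINTS}
        table = baseline_contrasts(groups)
        assert len(table) == 6
        assert (table["baseline"] == 10).all()
        with pytest.raises(ValueError):
            baseline_contrasts({1: [1, 2, 3], 3: [2, 3, 4]})


class TestTwoWayAnova:
    @staticmethod
    def _frame(rng, shift=0.0, n=4):
        rows = []
        for condition in ("LD", "DD"):
            for zt in study_tables.ZT_POINTS:
                mu = 2.0 + (shift if condition == "DD" else 0.0)
                for value in rng.normal(mu, 0.5, n):
                    rows.append({"condition": condition, "zt": zt, "density": value})
        return pd.DataFrame(rows)

    def test_pure_condition_shift_detected(self, rng):
        result = two_way_anova(self._frame(rng, shift=1.0))
        assert result["condition"].p < 0.05

    def test_duplicated_condition_gives_zero_f(self, rng):
        df = self._frame(rng, shift=0.0)
        ld = df[df.condition == "LD"].copy()
        dd = ld.copy()
        dd["condition"] = "DD"
        result = two_way_anova(pd.concat([ld, dd], ignore_index=True))
        assert result["condition"].F == pytest.approx(0.0, abs=1e-20)

    def test_matches_r_car_type_iii(self):
        # frozen unbalanced dataset checked against R car::Anova(type=3)
        rng = np.random.default_rng(123)
        rows = []
        for i, condition in enumerate(("LD", "DD")):
            for j, zt in enumerate((1, 3, 5)):
                n = 4 + (i + j) % 3
                for value in rng.normal(2 + 0.5 * i - 0.2 * j, 0.5, n):
                    rows.append(
                        {"condition": condition, "zt": zt, "density": round(value, 6)}
                    )
        result = two_way_anova(pd.DataFrame(rows))
        assert result["condition"].F == pytest.approx(13.6033, abs=1e-4)
        assert result["zt"].F == pytest.approx(0.8645, abs=1e-4)
        assert result["interaction"].F == pytest.approx(0.3018, abs=1e-4)
        assert result["condition"].p == pytest.approx(0.001154, abs=1e-6)

    def test_per_zt_contrasts_shape(self, rng):
        result = two_way_anova(self._frame(rng, shift=1.0))
        contrasts = result["condition_by_zt"]
        assert len(contrasts) == 7
        assert (contrasts["p_adjusted"] >= contrasts["p_raw"] - 1e-15).all()

    def test_empty_cell_errors(self, rng):
        df = self._frame(rng)
        df = df[~((df.condition == "DD") & (df.zt == 5))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df)


class TestProfiles:
    def test_uv_profile_peaks_at_zt5(self):
        prof = normalize_to_max(study_tables.LD_MEAN_DENSITY["UV"])
        assert prof[5] == 1.0
        assert max(prof.values()) == 1.0
        assert all(0 <= v <= 1 for v in prof.values())

    def test_constant_profile_all_ones(self):
        prof = normalize_to_max({zt: 2.5 for zt in study_tables.ZT_POINTS})
        assert all(v == 1.0 for v in prof.values())

    def test_normalization_idempotent(self):
        prof = normalize_to_max(study_tables.LD_MEAN_DENSITY["blue"])
        assert normalize_to_max(prof) == prof

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValueError):
            normalize_to_max({1: 0.0, 3: 0.0})

    def test_stack_of_constant_profiles(self):
        ones = {zt: 1.0 for zt in study_tables.ZT_POINTS}
        stacked = stacked_profile({"UV": ones, "blue": ones, "green": ones})
        assert all(v == pytest.approx(3.0) for v in stacked.values())

    def test_stacked_ld_profiles_peak_at_zt3_and_zt16(self):
        profiles = {
            s: normalize_to_max(study_tables.LD_MEAN_DENSITY[s])
            for s in ("UV", "blue", "green")
        }
        stacked = stacked_profile(profiles)
        top_two = sorted(stacked, key=stacked.get, reverse=True)[:2]
        assert sorted(top_two) == [3, 16]

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            stacked_profile({"a": {1: 1.0}, "b": {3: 1.0}})

    def test_combined_average_weighted_vs_unweighted(self):
        profiles = {"a": {1: 1.0, 3: 2.0}, "b": {1: 3.0, 3: 4.0}}
        plain = combined_average(profiles)
        assert plain == {1: 2.0, 3: 3.0}
        weighted = combined_average(
            profiles, weights={"a": {1: 3, 3: 1}, "b": {1: 1, 3: 3}}
        )
        assert weighted[1] == pytest.approx(1.5)
        assert weighted[3] == pytest.approx(3.5)


class TestSubtypeReport:
    def test_report_structure_from_generated_dataset(self):
        df = generate_timecourse(CountModel(seed=6))
        report = subtype_report(df, "UV", "LD")
        assert report["anova"].df_between == 6
        assert len(report["posthoc"]) == 21
        assert len(report["baseline_contrasts"]) == 6
        assert report["normalized_profile"][
            max(report["group_means"], key=report["group_means"].get)
        ] == pytest.approx(1.0)

    def test_group_accessor(self):
        df = generate_timecourse(CountModel(seed=6))
        groups = group_densities(df, "blue", "DD")
        assert set(groups) == set(study_tables.ZT_POINTS)
        assert all(len(v) == 8 for v in groups.values())
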