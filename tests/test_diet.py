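"""FFQ conversion, nutrients, dietary patterns, clinical formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oaprs.diet import (DAYS_PER_MONTH, FREQUENCY_LEVELS, PORTION_LEVELS,
                        alcohol_category, categorical_codings,
                        daily_food_intake, egfr, exercise_flag,
                        extract_patterns, frequency_to_daily, group_intakes,
                        homa_b, homa_ir, lookup_eer, mets_flag,
                        nutrient_intake, obesity_flag)
from oaprs.synthetic import generate_ffq


class TestFrequency:
    def test_five_six_per_week_is_point_seven_nine(self):
        assert frequency_to_daily("5-6/week") == pytest.approx(5.5 / 7)
        assert round(frequency_to_daily("5-6/week"), 2) == 0.79

    def test_never_is_zero_and_max_is_three(self):
        assert frequency_to_daily("never or seldom") == 0.0
        assert frequency_to_daily(">=3/day") == 3.0

    def test_two_three_per_month_midpoint(self):
        assert frequency_to_daily("2-3/month") == pytest.approx(
            2.5 / DAYS_PER_MONTH)

    def test_monotone_over_ordered_categories(self):
        vals = [frequency_to_daily(c) for c in FREQUENCY_LEVELS]
        assert vals == sorted(vals)
        assert all(b > a for a, b in zip(vals, vals[1:]) if b != a)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown frequency"):
            frequency_to_daily("fortnightly")


def _ffq_row(freq, portion):
    return pd.DataFrame({"sample": ["s1"], "itemA_freq": [freq],
                         "itemA_portion": [portion]})


class TestDailyIntake:
    def test_once_daily_equal_portion(self):
        out = daily_food_intake(_ffq_row("1/day", "equal"),
                                pd.Series({"itemA": 100.0}))
        assert out["itemA"].iloc[0] == pytest.approx(100.0)

    def test_five_six_week_more_portion(self):
        out = daily_food_intake(_ffq_row("5-6/week", "more"),
                                pd.Series({"itemA": 70.0}))
        assert out["itemA"].iloc[0] == pytest.approx(5.5 / 7 * 1.5 * 70)

    def test_all_never_gives_zero_vector(self):
        df = pd.DataFrame({"sample": ["a", "b"],
                           "x_freq": ["never or seldom"] * 2,
                           "x_portion": ["equal"] * 2})
        out = daily_food_intake(df, pd.Series({"x": 50.0}))
        assert (out.to_numpy() == 0).all()

    def test_missing_portion_reference_rejected(self):
        with pytest.raises(ValueError, match="portion size"):
            daily_food_intake(_ffq_row("1/day", "equal"), pd.Series(dtype=float))


class TestNutrients:
    def test_single_food_energy(self):
        foods = pd.DataFrame({"a": [100.0]})
        comp = pd.DataFrame({"energy_kcal": [2.0]}, index=["a"])
        out = nutrient_intake(foods, comp)
        assert out["energy_kcal"].iloc[0] == pytest.approx(2.0)

    def test_macronutrient_energy_shares_4_9_4(self):
        # protein 65 g, fat 32.2 g, CHO 349.8 g, energy 1952 kcal ->
        # 13.3 / 14.8 / 71.7 en%
        foods = pd.DataFrame({"a": [100.0]})
        comp = pd.DataFrame({"energy_kcal": [1952.0], "protein_g": [65.0],
                             "fat_g": [32.2], "carbohydrate_g": [349.8]},
                            index=["a"])
        out = nutrient_intake(foods, comp)
        assert out["protein_en_pct"].iloc[0] == pytest.approx(13.3, abs=0.05)
        assert out["fat_en_pct"].iloc[0] == pytest.approx(14.8, abs=0.05)
        assert out["carbohydrate_en_pct"].iloc[0] == pytest.approx(71.7, abs=0.05)

    def test_zero_intake_zero_nutrients(self):
        foods = pd.DataFrame({"a": [0.0, 0.0]})
        comp = pd.DataFrame({"energy_kcal": [500.0]}, index=["a"])
        assert (nutrient_intake(foods, comp).to_numpy() == 0).all()

    def test_linearity(self, rng):
        comp = pd.DataFrame(rng.uniform(0, 50, (4, 3)),
                            index=list("abcd"),
                            columns=["n1", "n2", "n3"])
        fa = pd.DataFrame(rng.uniform(0, 200, (5, 4)), columns=list("abcd"))
        fb = pd.DataFrame(rng.uniform(0, 200, (5, 4)), columns=list("abcd"))
        lhs = nutrient_intake(fa + fb, comp)
        rhs = nutrient_intake(fa, comp) + nutrient_intake(fb, comp)
        pd.testing.assert_frame_equal(lhs, rhs)

    def test_composition_gap_listed(self):
        foods = pd.DataFrame({"a": [1.0], "zz": [1.0]})
        comp = pd.DataFrame({"energy_kcal": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="zz"):
            nutrient_intake(foods, comp)

    def test_percent_eer(self):
        foods = pd.DataFrame({"a": [100.0]})
        comp = pd.DataFrame({"energy_kcal": [1900.0]}, index=["a"])
        cohort = pd.DataFrame({"age": [45.0], "sex": [1]})  # female 30-49
        out = nutrient_intake(foods, comp, cohort)
        assert out["energy_pct_eer"].iloc[0] == pytest.approx(100.0)

    def test_eer_lookup_bands(self):
        eer = lookup_eer(pd.Series([25.0, 70.0]), pd.Series([0, 1]))
        assert eer.tolist() == [2600.0, 1600.0]


class TestPatterns:
    def test_recovers_planted_orthogonal_patterns(self, small_cohort):
        cohort = pd.DataFrame({"sample": [f"S{i}" for i in range(2000)]})
        ffq, item_map, planted = generate_ffq(cohort, n_items=58,
                                              n_groups=29, n_patterns=2,
                                              seed=11)
        portions = pd.Series(100.0, index=item_map["item"])
        intake = daily_food_intake(ffq, portions)
        gi = group_intakes(intake, item_map)
        pat = extract_patterns(gi)
        assert pat.loadings.shape[1] >= 2
        L = pat.loadings.to_numpy()
        cong = np.abs(L.T @ planted) / (
            np.linalg.norm(L, axis=0)[:, None]
            * np.linalg.norm(planted, axis=0))
        assert (cong.max(axis=0) > 0.9).all()

    def test_pattern_scores_nearly_uncorrelated(self):
        cohort = pd.DataFrame({"sample": [f"S{i}" for i in range(2000)]})
        ffq, item_map, _ = generate_ffq(cohort, n_items=58, n_patterns=2,
                                        seed=12)
        portions = pd.Series(100.0, index=item_map["item"])
        gi = group_intakes(daily_food_intake(ffq, portions), item_map)
        pat = extract_patterns(gi)
        r = np.corrcoef(pat.scores.to_numpy(), rowvar=False)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert (np.abs(off) < 0.1).all()

    def test_pure_noise_retains_nothing(self, rng):
        # iid columns: eigenvalues concentrate near 1, none above 1.5
        X = pd.DataFrame(rng.standard_normal((3000, 20)))
        with pytest.raises(ValueError, match="eigenvalue"):
            extract_patterns(X)

    def test_high_flag_at_seventieth_percentile(self, rng):
        cohort = pd.DataFrame({"sample": [f"S{i}" for i in range(1000)]})
        ffq, item_map, _ = generate_ffq(cohort, n_items=58, seed=13)
        portions = pd.Series(100.0, index=item_map["item"])
        gi = group_intakes(daily_food_intake(ffq, portions), item_map)
        pat = extract_patterns(gi)
        frac = pat.high.mean(axis=0)
        assert ((frac > 0.25) & (frac < 0.35)).all()

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 5)))
        X[5] = 1.0
        with pytest.raises(ValueError, match="constant"):
            extract_patterns(X)


class TestClinicalFormulas:
    def test_homa_ir_worked_value(self):
        assert homa_ir(10.0, 5.0) == pytest.approx(2.2222, abs=1e-4)
        assert homa_ir(0.0, 5.0) == 0.0

    def test_homa_b_worked_value(self):
        assert homa_b(7.5, 4.5) == pytest.approx(150.0)
        with pytest.raises(ValueError, match="undefined"):
            homa_b(10.0, 3.5)

    def test_egfr_values(self):
        male = egfr(1.0, 50.0, female=False)
        assert male == pytest.approx(175.0 * 50.0 ** -0.203, rel=1e-9)
        assert male == pytest.approx(79.10, abs=0.01)
        assert egfr(1.0, 50.0, female=True) == pytest.approx(male * 0.742)
        # age exponent of 1: the age term vanishes
        assert egfr(1.0, 1.0, female=False) == pytest.approx(175.0)
        with pytest.raises(ValueError):
            egfr(0.0, 50.0, False)

    @pytest.mark.parametrize("grams,cat", [
        (0.0, "non"), (10.0, "light"), (15.0, "light"), (20.0, "moderate"),
        (30.0, "moderate"), (31.0, "heavy")])
    def test_alcohol_bands(self, grams, cat):
        assert alcohol_category(grams) == cat

    def test_obesity_inclusive_at_25(self):
        assert obesity_flag(25.0)
        assert not obesity_flag(24.9)

    def test_mets_three_of_five(self):
        # TG 160 + low HDL (35, male) + waist 92 -> 3 criteria met
        assert mets_flag(92.0, 160.0, 35.0, 120.0, 78.0, 90.0, female=False)
        # only two criteria -> no
        assert not mets_flag(92.0, 160.0, 45.0, 120.0, 78.0, 90.0,
                             female=False)
        # female thresholds: waist 85 and HDL 50 both bind
        assert mets_flag(86.0, 160.0, 45.0, 120.0, 78.0, 90.0, female=True)
        assert not mets_flag(86.0, 160.0, 55.0, 120.0, 78.0, 90.0,
                             female=True)

    def test_exercise_flag(self):
        assert exercise_flag(150.0) and not exercise_flag(149.0)

    def test_categorical_codings_frame(self):
        df = pd.DataFrame({"sample": ["a"], "alcohol_g_day": [20.0],
                           "bmi": [25.0], "exercise_min_week": [200.0]})
        out = categorical_codings(df)
        assert out.loc[0, "alcohol_cat"] == "moderate"
        assert bool(out.loc[0, "obese"])
        assert bool(out.loc[0, "regular_exercise"])
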