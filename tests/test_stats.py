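"""Normality-gated statistical battery."""

import numpy as np
import pytest

from atriakit.stats import (ConditionTriplet, compare_df_groups,
                            compare_three_conditions, compare_two_groups,
                            delta_from_uas, normality_gate,
                            summary_stat_ttest)


def _triplets(values, sex="male"):
    return [ConditionTriplet(f"a{i}", sex,
                             {"UAS": u, "ISO": s, "PEN": p})
            for i, (u, s, p) in enumerate(values)]


def _random_triplets(rng, n=13, shift_pen=0.0):
    out = []
    for i in range(n):
        b = rng.normal(0, 1.0)
        out.append(ConditionTriplet(f"a{i}", "male", {
            "UAS": b + rng.normal(0, 0.5),
            "ISO": b + rng.normal(0, 0.5),
            "PEN": b + shift_pen + rng.normal(0, 0.5)}))
    return out


class TestNormalityGate:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(normality_gate({"g": rng.normal(0, 1, 16)})["passed"]
                     for _ in range(200))
        assert passes / 200 == pytest.approx(0.95, abs=0.05)

    def test_heavy_skew_usually_fails(self):
        rng = np.random.default_rng(1)
        fails = sum(not normality_gate(
            {"g": rng.lognormal(0, 1.5, 16)})["passed"] for _ in range(100))
        assert fails / 100 >= 0.8

    def test_constant_sample_fails_with_flag(self):
        out = normality_gate({"g": np.full(10, 3.0)})
        assert not out["passed"]
        assert out["degenerate"] == ["g"]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate({"g": [1.0, 2.0]})


class TestThreeConditions:
    def test_identical_conditions_null(self):
        tr = _triplets([(10.0, 10.0, 10.0)] * 8)
        rep = compare_three_conditions(tr)
        assert rep.p_value == pytest.approx(1.0)
        assert all(p >= 0.99 for _, p in rep.pairwise) or not rep.pairwise

    def test_pen_shift_detected_parametrically(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(30):
            tr = _random_triplets(rng, shift_pen=1.0)
            rep = compare_three_conditions(tr, force_parametric=True)
            hits += rep.p_value < 0.05
        assert hits / 30 >= 0.7          # strong effect: usually detected
        # and the PEN contrasts carry the signal
        pen_ps = [p for c, p in rep.pairwise if "PEN" in c]
        other = [p for c, p in rep.pairwise if "PEN" not in c]
        assert min(pen_ps) <= min(other) or rep.p_value < 0.05

    def test_force_nonparametric_takes_friedman_path(self):
        rng = np.random.default_rng(3)
        rep = compare_three_conditions(_random_triplets(rng),
                                       force_nonparametric=True)
        assert rep.test_name == "friedman + dunn"

    def test_gate_routes_skewed_data_to_friedman(self):
        rng = np.random.default_rng(4)
        tr = [ConditionTriplet(f"a{i}", "male",
                               {c: rng.lognormal(0, 1.8)
                                for c in ("UAS", "ISO", "PEN")})
              for i in range(16)]
        rep = compare_three_conditions(tr)
        assert rep.test_name == "friedman + dunn"
        assert rep.normality_passed is False

    def test_incomplete_triplets_dropped_with_warning(self):
        tr = _random_triplets(np.random.default_rng(5))
        tr[0].values.pop("PEN")
        with pytest.warns(UserWarning, match="incomplete"):
            rep = compare_three_conditions(tr)
        assert 0 <= rep.p_value <= 1

    def test_dunn_adjustment_never_below_unadjusted(self):
        rng = np.random.default_rng(6)
        tr = _random_triplets(rng, shift_pen=0.8)
        rep = compare_three_conditions(tr, force_nonparametric=True)
        # Bonferroni-type family correction multiplies by the number of
        # contrasts, so each adjusted p is >= the raw z-test p
        from scipy import stats as st
        data = np.array([[t.values[c] for c in ("UAS", "ISO", "PEN")]
                         for t in tr])
        ranks = st.rankdata(data, axis=1).sum(axis=0)
        se = np.sqrt(len(tr) * 3 * 4 / 6.0)
        raw = {}
        names = ("UAS", "ISO", "PEN")
        for i in range(3):
            for j in range(i + 1, 3):
                z = abs(ranks[i] - ranks[j]) / se
                raw[f"{names[i]} vs {names[j]}"] = 2 * st.norm.sf(z)
        for contrast, p_adj in rep.pairwise:
            assert p_adj >= raw[contrast] - 1e-12

    def test_too_few_triplets_rejected(self):
        with pytest.raises(ValueError):
            compare_three_conditions(_triplets([(1.0, 2.0, 3.0)] * 2))


class TestTwoGroups:
    def test_identical_samples_t_path_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = compare_two_groups(x, x.copy(), force="t")
        assert rep.p_value == pytest.approx(1.0)

    def test_rejection_rate_matches_t_test_power(self):
        # two-sample t with delta = 1 SD, n = 13/16: closed-form power
        from scipy import stats as st
        delta, n1, n2 = 1.0, 13, 16
        df = n1 + n2 - 2
        nc = delta / np.sqrt(1 / n1 + 1 / n2)
        tcrit = st.t.ppf(0.975, df)
        power = 1 - st.nct.cdf(tcrit, df, nc) + st.nct.cdf(-tcrit, df, nc)
        rng = np.random.default_rng(7)
        hits = sum(compare_two_groups(rng.normal(0, 1, n1),
                                      rng.normal(delta, 1, n2),
                                      force="t").p_value < 0.05
                   for _ in range(500))
        assert hits / 500 == pytest.approx(power, abs=0.05)

    def test_constant_vs_constant_degenerate_mannwhitney(self):
        rep = compare_two_groups(np.full(5, 2.0), np.full(6, 2.0),
                                 force="mannwhitney")
        assert rep.p_value == pytest.approx(1.0)
        assert rep.notes

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSummaryStatTTest:
    def test_printed_table_comparisons(self):
        rr = summary_stat_ttest(182.2, 4.21, 13, 168.6, 3.48, 16)
        assert rr["p"] == pytest.approx(0.019, abs=0.01)
        pr = summary_stat_ttest(49.96, 1.15, 13, 46.99, 0.90, 16)
        assert pr["p"] == pytest.approx(0.049, abs=0.01)
        assert rr["p"] < 0.05 and pr["p"] < 0.05

    def test_equal_means_null(self):
        out = summary_stat_ttest(10.0, 1.0, 10, 10.0, 1.0, 10)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_agrees_with_raw_data_ttest(self):
        from scipy import stats as st
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 13), rng.normal(0.4, 1.2, 16)
        raw = st.ttest_ind(x, y, equal_var=True)
        out = summary_stat_ttest(x.mean(), x.std(ddof=1) / np.sqrt(13), 13,
                                 y.mean(), y.std(ddof=1) / np.sqrt(16), 16)
        assert out["t"] == pytest.approx(raw.statistic, abs=1e-9)
        assert out["p"] == pytest.approx(raw.pvalue, abs=1e-9)

    def test_bad_sem_rejected(self):
        with pytest.raises(ValueError):
            summary_stat_ttest(1.0, 0.0, 5, 2.0, 1.0, 5)


class TestDelta:
    def test_per_animal_differences(self):
        tr = _triplets([(180.0, 180.0, 194.0)])
        df = delta_from_uas(tr)
        iso = df[df.condition == "ISO"]["delta"].iloc[0]
        pen = df[df.condition == "PEN"]["delta"].iloc[0]
        assert iso == 0.0 and pen == 14.0

    def test_all_equal_gives_zero_deltas(self):
        df = delta_from_uas(_triplets([(5.0, 5.0, 5.0)] * 4))
        assert (df["delta"] == 0.0).all()

    def test_missing_baseline_dropped_with_warning(self):
        tr = _triplets([(1.0, 2.0, 3.0)] * 3)
        tr[0].values.pop("UAS")
        with pytest.warns(UserWarning, match="without UAS"):
            df = delta_from_uas(tr)
        assert df["animal_id"].nunique() == 2

    def test_sex_specific_effect_detected_downstream(self):
        # males get an ISO effect, females do not; the delta contrast picks
        # it up via the two-group path in most replicates
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50):
            males = [ConditionTriplet(f"m{i}", "male",
                     {"UAS": rng.normal(30, 7), "ISO": rng.normal(20, 7),
                      "PEN": rng.normal(30, 7)}) for i in range(13)]
            females = [ConditionTriplet(f"f{i}", "female",
                       {"UAS": rng.normal(10, 3), "ISO": rng.normal(10, 3),
                        "PEN": rng.normal(10, 3)}) for i in range(16)]
            df = delta_from_uas(males + females)
            iso = df[df.condition == "ISO"]
            rep = compare_two_groups(
                iso[iso.sex == "male"]["delta"],
                iso[iso.sex == "female"]["delta"], force="mannwhitney")
            hits += rep.p_value < 0.05
        assert hits / 50 >= 0.6


class TestDFGroups:
    def test_identical_groups_null(self):
        g = {"UAS": np.full(5, 20.0), "ISO": np.full(5, 20.0)}
        rep = compare_df_groups(g)
        assert rep.p_value == pytest.approx(1.0)

    def test_df_shift_detected_in_majority_of_seeds(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            g = {"UAS": rng.normal(22.0, 4.0, 50),
                 "ISO": rng.normal(17.0, 4.0, 33),
                 "PEN": rng.normal(18.0, 4.0, 40)}
            rep = compare_df_groups(g)
            pair = dict(rep.pairwise)
            hits += pair["UAS vs ISO"] < 0.05
        assert hits / 30 >= 0.6

    def test_two_group_decision_tracks_mannwhitney(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)
        kw = compare_df_groups({"a": x, "b": y}).p_value
        mw = compare_two_groups(x, y, force="mannwhitney").p_value
        assert (kw < 0.05) == (mw < 0.05)
        x2, y2 = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        kw2 = compare_df_groups({"a": x2, "b": y2}).p_value
        mw2 = compare_two_groups(x2, y2, force="mannwhitney").p_value
        assert (kw2 < 0.05) == (mw2 < 0.05)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_df_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
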