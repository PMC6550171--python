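import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from scipy import stats

from manuka import (
    DriftModel,
    ImputationScheme,
    bh_adjust,
    generate_stability_dataset,
    habitat_analysis,
    heteroscedastic_anova,
    impute_below_lor,
    regional_temporal_model,
    run_censored_anova,
    stability_analysis,
    tukey_hsd,
    winsorised_mean_variance,
)
from manuka.samples import censor_col

from oracles import hand_bh


class TestImputation:
    def test_mixed_rule_uniform_on_0_lor(self):
        rng = np.random.default_rng(0)
        scheme = ImputationScheme(lor=1.0)
        vals = np.array([np.nan, 5.0, 7.2])
        out = impute_below_lor(vals, [True, False, False], scheme, rng)
        assert 0.0 < out[0] < 1.0
        assert out[1] == 5.0 and out[2] == 7.2

    def test_all_below_rule_beta_mean(self):
        # Beta(1, 40) has mean 1/41; scaled by the LOR
        rng = np.random.default_rng(1)
        scheme = ImputationScheme(lor=1.0)
        n = 100_000
        out = impute_below_lor(np.full(n, np.nan), np.ones(n, bool), scheme, rng)
        mean, sd = 1 / 41, np.sqrt(40 / (41**2 * 42))
        assert abs(out.mean() - mean) < 3 * sd / np.sqrt(n)
        assert out.min() > 0 and out.max() < 1

    def test_mixed_rule_uniform_by_ks(self):
        rng = np.random.default_rng(2)
        scheme = ImputationScheme(lor=2.0)
        n = 20_000
        vals = np.concatenate([[5.0], np.full(n, np.nan)])
        cens = np.concatenate([[False], np.ones(n, bool)])
        out = impute_below_lor(vals, cens, scheme, rng)[1:]
        p = stats.kstest(out / 2.0, "uniform").pvalue
        assert p > 0.01

    def test_no_censoring_is_identity(self):
        rng = np.random.default_rng(3)
        vals = np.array([1.5, 2.5])
        out = impute_below_lor(vals, [False, False], ImputationScheme(), rng)
        assert np.array_equal(out, vals)

    def test_invalid_lor_rejected(self):
        with pytest.raises(ValueError):
            ImputationScheme(lor=0.0)


class TestTukey:
    def test_identical_groups_give_p_one(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in "abc"}
        res = tukey_hsd(g)
        assert np.allclose(res["p"], 1.0)
        assert np.allclose(res["q"], 0.0)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0.8, 1, 9),
            "c": rng.normal(-0.5, 1, 15),
        }
        ours = tukey_hsd(groups).set_index(["group1", "group2"])
        data = np.concatenate(list(groups.values()))
        labels = sum([[k] * len(v) for k, v in groups.items()], [])
        sm_res = pairwise_tukeyhsd(data, labels)
        table = sm_res._results_table.data[1:]
        for row, p in zip(table, sm_res.pvalues):
            g1, g2 = str(row[0]), str(row[1])
            assert ours.loc[(g1, g2), "p"] == pytest.approx(p, abs=1e-6)

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
        p_tukey = tukey_hsd({"a": a, "b": b})["p"].iloc[0]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": np.arange(3.0)})


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_matches_hand_step_up_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, hand_bh(pvals))
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestWinsorised:
    def test_trim_zero_is_ordinary_moments(self):
        x = [1.0, 4.0, 2.0, 9.0]
        m, v = winsorised_mean_variance(x, 0.0)
        assert m == pytest.approx(np.mean(x))
        assert v == pytest.approx(np.var(x, ddof=1))

    def test_hand_winsorisation(self):
        # [1,2,3,4,100] trimmed 20% each side -> [2,2,3,4,4]
        m, v = winsorised_mean_variance([1, 2, 3, 4, 100], 0.2)
        assert m == pytest.approx(3.0)
        assert v == pytest.approx(np.var([2, 2, 3, 4, 4], ddof=1))

    def test_symmetric_data_keeps_mean(self):
        x = np.array([-3, -1, 0, 1, 3], dtype=float)
        m, _ = winsorised_mean_variance(x, 0.2)
        assert m == pytest.approx(x.mean())

    def test_rejects_large_trim(self):
        with pytest.raises(ValueError):
            winsorised_mean_variance([1.0, 2.0], 0.5)


def _two_group_table(delta, n=20, censor_frac=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in (("a", 0.0), ("b", delta)):
        vals = np.exp(rng.normal(np.log(10) + mu, 0.4, n))
        cens = rng.random(n) < censor_frac
        for v, c in zip(vals, cens):
            rows.append({"group": g, "3-PA": np.nan if c else v,
                         censor_col("3-PA"): c})
    return pd.DataFrame(rows)


class TestCensoredAnova:
    def test_planted_large_separation_always_significant(self):
        table = _two_group_table(delta=2.0, censor_frac=0.1, seed=1)  # 5 sd on logs
        res = run_censored_anova(
            table, "group", "3-PA", ImputationScheme(n_simulations=50, seed=2)
        )
        assert res.pairwise["proportion_significant"].iloc[0] == 1.0

    def test_deterministic_given_seed(self):
        table = _two_group_table(delta=0.5, censor_frac=0.3, seed=3)
        runs = [
            run_censored_anova(
                table, "group", "3-PA", ImputationScheme(n_simulations=5, seed=9)
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0].pairwise, runs[1].pairwise)
        pd.testing.assert_frame_equal(runs[0].group_means, runs[1].group_means)

    def test_degenerate_group_reported_not_dropped(self):
        table = pd.concat(
            [
                _two_group_table(0.0, n=10, seed=4),
                pd.DataFrame(
                    [{"group": "c", "3-PA": 12.0, censor_col("3-PA"): False}]
                ),
            ],
            ignore_index=True,
        )
        res = run_censored_anova(
            table, "group", "3-PA", ImputationScheme(n_simulations=3, seed=5)
        )
        assert any("'c'" in w for w in res.warnings)
        pairs = set(map(tuple, res.pairwise[["group1", "group2"]].to_numpy()))
        assert ("a", "c") in pairs and ("b", "c") in pairs


class TestHeteroscedasticAnova:
    def test_variance_ratio_recovery(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "g": ["a"] * 2000 + ["b"] * 2000,
                "y": np.concatenate(
                    [rng.normal(0, 1, 2000), rng.normal(0, 5, 2000)]
                ),
            }
        )
        res = heteroscedastic_anova(df, "g", "y")
        ratio = res.group_variances["b"] / res.group_variances["a"]
        assert ratio == pytest.approx(25.0, rel=0.2)
        assert res.p_variance < 1e-10

    def test_equal_variances_small_lr(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "g": np.repeat(list("abc"), 200),
                "y": rng.normal(0, 1, 600),
            }
        )
        res = heteroscedastic_anova(df, "g", "y")
        vs = list(res.group_variances.values())
        assert max(vs) / min(vs) < 1.5
        assert res.p_variance > 0.01

    def test_mean_effect_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            df = pd.DataFrame(
                {"g": np.repeat(list("abc"), 40), "y": rng.normal(0, 1, 120)}
            )
            if heteroscedastic_anova(df, "g", "y").p_mean < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.02

    def test_detects_planted_mean_shift(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b"], 100),
                "y": np.concatenate(
                    [rng.normal(0, 1, 100), rng.normal(1.5, 3, 100)]
                ),
            }
        )
        assert heteroscedastic_anova(df, "g", "y").p_mean < 0.01

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            heteroscedastic_anova(df, "g", "y")


class TestStabilityAnalysis:
    def test_null_data_mostly_non_significant(self):
        hits = 0
        n_seeds = 30
        for s in range(n_seeds):
            df = generate_stability_dataset(seed=100 + s)
            res = stability_analysis(df, ["3-PA"])["3-PA"]
            if res["temperature_p"] > 0.05 and res["date_p"] > 0.05:
                hits += 1
        assert hits >= int(0.75 * n_seeds)

    def test_planted_temperature_effect_detected(self):
        # halve concentrations at 35 C by the final timepoint
        effects = {"3-PA": DriftModel(temp_slope=np.log(0.5) / 31.0)}
        df = generate_stability_dataset(effects=effects, seed=11)
        res = stability_analysis(df, ["3-PA"])["3-PA"]
        assert res["temperature_p"] < 0.05

    def test_planted_time_effect_detected(self):
        effects = {"3-PA": DriftModel(time_slope=np.log(0.6) / 68.0)}
        df = generate_stability_dataset(effects=effects, seed=12)
        res = stability_analysis(df, ["3-PA"])["3-PA"]
        assert res["date_p"] < 0.05

    def test_single_sample_flagged(self):
        df = generate_stability_dataset(seed=13)
        with pytest.raises(ValueError):
            stability_analysis(df[df["sample"] == "S1"], ["3-PA"])


class TestRegionalTemporal:
    def _table(self, shift, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for year, mu in (("2014/15", np.log(300) + shift), ("2015/16", np.log(300))):
            for v in np.exp(rng.normal(mu, 0.5, 60)):
                rows.append({"year": year, "3-PA": v, censor_col("3-PA"): False})
        return pd.DataFrame(rows)

    def test_planted_year_effect_detected(self):
        res = regional_temporal_model(self._table(0.5, 14), "3-PA", "year")
        assert res.p_value < 0.01
        assert res.group_means["2014/15"] > res.group_means["2015/16"]

    def test_null_type_one_error(self):
        hits = sum(
            regional_temporal_model(self._table(0.0, 200 + s), "3-PA", "year").p_value
            < 0.05
            for s in range(100)
        )
        assert hits <= 12  # ~alpha with Monte-Carlo slack

    def test_single_level_rejected(self):
        df = self._table(0.0, 15)
        with pytest.raises(ValueError):
            regional_temporal_model(df[df["year"] == "2014/15"], "3-PA", "year")


class TestHabitatAnalysis:
    def _nectar(self, shift=0.0, censor_all=False, seed=16):
        rng = np.random.default_rng(seed)
        rows = []
        habitats = ["calcareous soil", "coastal sand/headland", "dry ridge",
                    "low-altitude bog", "montane"]
        for h in habitats:
            mu = np.log(2.0) + (shift if h == "low-altitude bog" else 0.0)
            vals = np.exp(rng.normal(mu, 0.4, 15))
            for v in vals:
                rows.append(
                    {
                        "habitat": h,
                        "sugar_content": rng.uniform(30, 60),
                        "DHA": np.nan if censor_all else v,
                        censor_col("DHA"): censor_all,
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_habitat_shift_detected(self):
        res = habitat_analysis(self._nectar(shift=1.5), ["DHA"])["DHA"]
        assert res["method"] == "linear_model"
        assert res["p"] < 0.01

    def test_all_censored_routes_through_beta_rule(self):
        from manuka import ImputationScheme

        res = habitat_analysis(
            self._nectar(censor_all=True),
            ["DHA"],
            scheme=ImputationScheme(lor=0.01, n_simulations=20, seed=1),
        )["DHA"]
        assert res["method"] == "simulation"
        assert 0.0 <= res["proportion_significant"] <= 0.3
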