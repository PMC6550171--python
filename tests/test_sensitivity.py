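import numpy as np
import pandas as pd
import pytest

from manuka import (
    ImputationScheme,
    Scenario,
    TreeConfig,
    bias_assessment,
    bootstrap_cart,
    inject_bias,
    lor_sim_cart,
    rounding_assessment,
    round_option,
    run_scenarios,
    stratified_resample,
    load_option,
    classify_table,
)
from manuka.samples import censor_col

from conftest import planted_tree_data
from test_criteria import sample

PLANTED_MARKERS = ["3-PA", "manuka_dna", "kanuka_dna"]


class TestStratifiedBootstrap:
    def test_class_counts_preserved(self):
        df = planted_tree_data(n_per_class=25, seed=0)
        rng = np.random.default_rng(1)
        boot = stratified_resample(df, rng)
        assert (
            boot["supplier_label"].value_counts().sort_index()
            == df["supplier_label"].value_counts().sort_index()
        ).all()

    def test_planted_marker_dominates_first_split(self):
        df = planted_tree_data(n_per_class=40, seed=2)
        res = bootstrap_cart(
            df, TreeConfig(markers=PLANTED_MARKERS), n_replicates=50, seed=3
        )
        assert res.first_split_frequency["3-PA"] == 1.0

    def test_fixed_seed_reproducible(self):
        df = planted_tree_data(n_per_class=25, seed=4)
        r1 = bootstrap_cart(df, TreeConfig(markers=PLANTED_MARKERS),
                            n_replicates=10, seed=5)
        r2 = bootstrap_cart(df, TreeConfig(markers=PLANTED_MARKERS),
                            n_replicates=10, seed=5)
        assert r1.inclusion_frequency == r2.inclusion_frequency
        pd.testing.assert_frame_equal(r1.statistics, r2.statistics)

    def test_pure_noise_markers_nondominant(self):
        rng = np.random.default_rng(6)

        def null_table(n):
            return pd.DataFrame(
                {
                    "3-PA": rng.uniform(0, 100, n),
                    "manuka_dna": rng.uniform(20, 40, n),
                    "supplier_label": rng.choice(["M", "NM"], n),
                }
            )

        res = bootstrap_cart(
            null_table(300),
            TreeConfig(markers=["3-PA", "manuka_dna"]),
            n_replicates=40,
            seed=7,
            test=null_table(300),
        )
        # neither noise marker should dominate the first split, and the
        # out-of-sample correct-rate interval should cover chance level
        assert max(res.first_split_frequency.values()) < 0.95
        row = res.statistics.set_index("statistic").loc["correct"]
        assert row["lo95"] <= 0.5 <= row["hi95"]

    def test_rejects_empty(self):
        df = planted_tree_data(n_per_class=10, seed=8)
        with pytest.raises(ValueError):
            bootstrap_cart(df, TreeConfig(markers=PLANTED_MARKERS), n_replicates=0)


class TestLorSimCart:
    def _censored_table(self, seed=0):
        df = planted_tree_data(n_per_class=30, seed=seed)
        rng = np.random.default_rng(seed + 100)
        cens = (df["3-PA"] < 150) & (rng.random(len(df)) < 0.8)
        df[censor_col("3-PA")] = cens
        df.loc[cens, "3-PA"] = np.nan
        return df

    def test_no_censoring_gives_identical_fits(self):
        df = planted_tree_data(n_per_class=25, seed=9)
        df[censor_col("3-PA")] = False
        with pytest.warns(UserWarning, match="no censored values"):
            res = lor_sim_cart(
                df, TreeConfig(markers=PLANTED_MARKERS),
                ImputationScheme(seed=1), n_simulations=5,
            )
        assert (res.paired_differences["mean_diff"] == 0).all()

    def test_censored_data_reports_paired_intervals(self):
        df = self._censored_table(seed=10)
        res = lor_sim_cart(
            df, TreeConfig(markers=PLANTED_MARKERS),
            ImputationScheme(seed=2), n_simulations=10,
        )
        assert len(res.simulated) == 10
        d = res.paired_differences
        assert (d["lo95"] <= d["hi95"]).all()

    def test_single_simulation_reproducible(self):
        df = self._censored_table(seed=11)
        runs = [
            lor_sim_cart(
                df, TreeConfig(markers=PLANTED_MARKERS),
                ImputationScheme(seed=3), n_simulations=1,
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0].simulated, runs[1].simulated)


class TestCqRecode:
    def test_reports_both_treatments(self, honey):
        from manuka.sensitivity import cq_recode_comparison

        train = honey[honey["year"] == "2014/15"]
        test = honey[honey["year"] == "2015/16"]
        out = cq_recode_comparison(
            train, TreeConfig(markers=PLANTED_MARKERS), test=test
        )
        assert list(out["dna_treatment"]) == ["raw", "recoded"]
        assert out["correct"].between(0, 1).all()

    def test_recode_noop_when_all_cq_below_lor(self):
        from manuka.sensitivity import cq_recode_comparison

        rng = np.random.default_rng(20)
        df = pd.DataFrame(
            {
                "3-PA": np.concatenate(
                    [rng.uniform(420, 900, 40), rng.uniform(1, 380, 40)]
                ),
                "manuka_dna": rng.uniform(20, 35, 80),  # all below Cq 36
                "kanuka_dna": rng.uniform(20, 35, 80),
                "supplier_label": ["M"] * 40 + ["NM"] * 40,
            }
        )
        out = cq_recode_comparison(df, TreeConfig(markers=PLANTED_MARKERS))
        raw = out[out["dna_treatment"] == "raw"].drop(columns="dna_treatment")
        rec = out[out["dna_treatment"] == "recoded"].drop(columns="dna_treatment")
        assert np.allclose(raw.to_numpy(float), rec.to_numpy(float))


class TestBias:
    def test_multiplicative_arithmetic(self):
        df = pd.DataFrame([{**sample(pa=100.0), "supplier_label": "M"}])
        out = inject_bias(df, "chemical", 0.20)
        assert out["3-PA"].iloc[0] == pytest.approx(120.0)
        assert out["manuka_dna"].iloc[0] == df["manuka_dna"].iloc[0]

    def test_dna_bias_separate(self):
        df = pd.DataFrame([{**sample(md=30.0), "supplier_label": "M"}])
        out = inject_bias(df, "dna", -0.10)
        assert out["manuka_dna"].iloc[0] == pytest.approx(27.0)
        assert out["3-PA"].iloc[0] == df["3-PA"].iloc[0]

    def test_zero_level_is_classification_noop(self):
        df = pd.DataFrame(
            [{**sample(pa=pa), "supplier_label": "M"} for pa in (10, 100, 500)]
        )
        res = bias_assessment(df, "final", levels=[0.0])
        assert (res["fraction_reclassified"] == 0.0).all()

    def test_unlisted_level_rejected_without_override(self):
        df = pd.DataFrame([{**sample(), "supplier_label": "M"}])
        with pytest.raises(ValueError):
            inject_bias(df, "chemical", 0.33)
        inject_bias(df, "chemical", 0.33, allow_any_level=True)

    def test_reclassification_monotone_in_bias_magnitude(self):
        # margins placed so progressively larger bias crosses more samples
        # over the 400 mg/kg monofloral boundary
        pas = [404, 412, 428, 444, 460, 476, 1000]
        df = pd.DataFrame(
            [{**sample(pa=pa), "supplier_label": "M"} for pa in pas]
        )
        counts = []
        for level in (-0.05, -0.10, -0.15, -0.20):
            biased = inject_bias(df, "chemical", level)
            labels = classify_table(biased, "final")
            base = classify_table(df, "final")
            counts.append(int(np.sum(labels != base)))
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]


class TestRounding:
    def test_identity_map_reclassifies_nothing(self, honey):
        from manuka.sensitivity import identity_rounding_map

        option = load_option("final")
        res = rounding_assessment(
            option, identity_rounding_map(option), {"honey": honey}
        )
        assert res["fraction_reclassified"].iloc[0] == 0.0

    def test_samples_outside_rounding_window_unaffected(self):
        # exact Option 1 uses 435/18.5; rounded uses 400/20. Samples with
        # 3-PA outside [18.5, 20] u [400, 435] cannot change label.
        exact = load_option("option1_exact")
        rmap = {435.0: 400.0, 18.5: 20.0, 50.0: 50.0, 1.0: 1.0,
                30.0: 30.0, 36.0: 36.0, 25.0: 25.0}
        df = pd.DataFrame(
            [{**sample(pa=pa, md=33.0, kd=28.0), "supplier_label": "M"}
             for pa in (5, 25, 100, 390, 500, 900)]
        )
        res = rounding_assessment(exact, rmap, {"margin": df})
        assert res["fraction_reclassified"].iloc[0] == 0.0

    def test_sample_inside_window_reclassified(self):
        exact = load_option("option1_exact")
        rmap = {435.0: 400.0, 18.5: 20.0, 50.0: 50.0, 1.0: 1.0,
                30.0: 30.0, 36.0: 36.0, 25.0: 25.0}
        df = pd.DataFrame(
            [
                {**sample(pa=420.0, md=33.0, kd=28.0), "supplier_label": "M"},
                {**sample(pa=600.0, md=33.0, kd=28.0), "supplier_label": "M"},
            ]
        )
        res = rounding_assessment(exact, rmap, {"window": df})
        # exactly the 3-PA = 420 sample flips (multifloral under 435, monofloral under 400)
        assert res["fraction_reclassified"].iloc[0] == pytest.approx(0.5)

    def test_unmapped_threshold_rejected(self):
        option = load_option("final")
        with pytest.raises(ValueError, match="rounding map"):
            round_option(option, {400.0: 400.0})


class TestScenarios:
    def test_grid_runs_and_reports_tidy_rows(self, honey):
        scenarios = [
            Scenario(name="y1415_6class", train_year="2014/15", n_classes=6,
                     markers=tuple(PLANTED_MARKERS)),
            Scenario(name="y1415_4class", train_year="2014/15", n_classes=4,
                     markers=tuple(PLANTED_MARKERS)),
        ]
        out = run_scenarios(scenarios, honey, n_replicates=5, seed=0)
        assert set(out["scenario"]) == {"y1415_6class", "y1415_4class"}
        assert {"within_sample", "2015/16", "archive"} <= set(out["test_set"])
        assert (out["lo95"] <= out["hi95"]).all()

    def test_coarsening_cannot_reduce_correct_rate(self, honey):
        from manuka import collapse_to_four, grow_tree, report

        train = honey[honey["year"] == "2014/15"]
        cfg = TreeConfig(markers=PLANTED_MARKERS)
        tree = grow_tree(train, cfg)
        preds = tree.predict(train)
        six = report(train["supplier_label"].to_numpy(), preds)
        sup4 = [collapse_to_four(s) for s in train["supplier_label"]]
        pred4 = [collapse_to_four(p) for p in preds]
        four = report(sup4, pred4)
        assert four.correct >= six.correct

    def test_island_scenario_restricts_nz_training_only(self, honey):
        from manuka.sensitivity import _scenario_tables

        sc = Scenario(name="north", islands=("North",))
        train, _ = _scenario_tables(honey, sc, "supplier_label")
        nz = train[train["country"] == "NZ"]
        assert (nz["island"] == "North").all()
        assert {"AU", "NN"} <= set(train["supplier_label"])

    def test_empty_stratum_skipped_with_warning(self, honey):
        sc = Scenario(name="ghost", train_year="1999/00")
        with pytest.warns(UserWarning, match="skipped"):
            out = run_scenarios([sc], honey, n_replicates=2, seed=1)
        assert out.empty
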