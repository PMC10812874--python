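"""Comparison statistics and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from drpcurves import (
    ExperimentConfig,
    SyntheticConfig,
    average_ranking,
    build_pairs,
    comparison_table,
    curves_from_results,
    drug_variability_association,
    error_normality_summary,
    fit_drug_average,
    per_drug_error,
    percent_mse_reduction,
    run_experiment,
    simulate_dataset,
    summarize_comparison,
)
from drpcurves.splitting import cancer_blind_split, split_pairs


class TestAverageRanking:
    def test_clean_sweep(self):
        table = pd.DataFrame({"A": np.full(30, 1.0), "B": np.full(30, 2.0)})
        assert average_ranking(table) == {"A": 1.0, "B": 2.0}

    def test_midranks_on_tie(self):
        table = pd.DataFrame({"A": [1.0], "B": [1.0]})
        assert average_ranking(table) == {"A": 1.5, "B": 1.5}

    def test_partial_wins_closed_form(self):
        # A wins 24/30 splits -> mean ranks 0.8*1+0.2*2 = 1.2 and 1.8
        a = np.where(np.arange(30) < 24, 1.0, 2.0)
        b = np.where(np.arange(30) < 24, 2.0, 1.0)
        table = pd.DataFrame({"A": a, "B": b})
        ranking = average_ranking(table)
        assert ranking["A"] == pytest.approx(1.2)
        assert ranking["B"] == pytest.approx(1.8)

    def test_condition_subset(self):
        table = pd.DataFrame({"A": [1.0], "B": [2.0], "C": [3.0]})
        assert average_ranking(table, ["A", "C"]) == {"A": 1.0, "C": 2.0}

    def test_needs_two_conditions(self):
        with pytest.raises(ValueError):
            average_ranking(pd.DataFrame({"A": [1.0]}))


class TestPercentReduction:
    def test_halving_is_fifty_percent(self):
        assert percent_mse_reduction(2.0, 1.0) == 50.0

    def test_equal_inputs_zero(self):
        assert percent_mse_reduction(1.3, 1.3) == 0.0

    def test_matches_recompute(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ref, cmp_ = rng.uniform(0.5, 3.0, size=2)
            expected = 100.0 * (ref - cmp_) / ref
            assert percent_mse_reduction(ref, cmp_) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_reference(self):
        with pytest.raises(ValueError):
            percent_mse_reduction(0.0, 1.0)

    def test_antisymmetric_after_rescaling(self):
        a, b = 1.7, 0.9
        forward = percent_mse_reduction(a, b)
        backward = percent_mse_reduction(b, a)
        # rescaling each direction by its own reference recovers +/-(a-b)
        assert forward * a == pytest.approx(-backward * b)


def _benchmark_setup(seed=31, **cfg_kw):
    cfg = SyntheticConfig(
        n_cell_lines=60,
        n_drugs=10,
        n_features_per_modality={"rnaseq": 20},
        sparsity_of_response=0.0,
        seed=seed,
        **cfg_kw,
    )
    profiles, table, truth = simulate_dataset(cfg)
    pairs = build_pairs(profiles["rnaseq"], table)
    cells = sorted({c for c, _ in pairs.pair_index})
    split = cancer_blind_split(cells, seed=seed)
    tr, _, te = split_pairs(split, pairs.pair_index)
    train, test = pairs.subset(tr), pairs.subset(te)
    return fit_drug_average(train), train, test, truth


class TestPerDrugError:
    def test_perfect_predictions_zero_mse(self):
        model, _, test, _ = _benchmark_setup()
        sub = test.subset([i for i, (_, d) in enumerate(test.pair_index) if d == "D000"])
        from drpcurves.models import TrainedModel

        class Oracle:
            def predict(self, X):
                return sub.targets

        per_drug = per_drug_error(TrainedModel("gbt", Oracle()), sub)
        assert per_drug.loc["D000", "mse"] == 0.0

    def test_partition_additivity(self):
        model, _, test, _ = _benchmark_setup()
        per_drug = per_drug_error(model, test)
        for drug in per_drug.index:
            sub = test.subset([i for i, (_, d) in enumerate(test.pair_index) if d == drug])
            assert per_drug.loc[drug, "mse"] == pytest.approx(model.test_mse(sub))

    def test_benchmark_per_drug_mse_tracks_target_variance(self):
        model, _, test, _ = _benchmark_setup()
        per_drug = per_drug_error(model, test)
        # mean predictor: per-drug MSE ~ that drug's within-test variance
        # (plus the train-mean offset), so the two must correlate strongly
        variances = per_drug["target_sd"] ** 2
        assert np.corrcoef(per_drug["mse"], variances)[0, 1] > 0.7

    def test_single_pair_drugs_flagged(self):
        model, _, test, _ = _benchmark_setup()
        sub = test.subset([0])
        per_drug = per_drug_error(model, sub)
        assert bool(per_drug["flagged"].iloc[0])


class TestDrugVariabilityAssociation:
    def test_monotone_association_is_one(self):
        per_drug = pd.DataFrame(
            {"mse": np.arange(1.0, 9.0), "target_sd": np.arange(2.0, 10.0)}
        )
        rho, _ = drug_variability_association(per_drug, n_permutations=99)
        assert rho == pytest.approx(1.0)

    def test_constant_mse_zero_correlation(self):
        per_drug = pd.DataFrame({"mse": np.ones(8), "target_sd": np.arange(8.0)})
        rho, p = drug_variability_association(per_drug, n_permutations=99)
        assert rho == 0.0 and p == 1.0

    def test_needs_five_drugs(self):
        per_drug = pd.DataFrame({"mse": [1.0, 2.0], "target_sd": [1.0, 2.0]})
        with pytest.raises(ValueError):
            drug_variability_association(per_drug)

    def test_tenfold_noise_spread_detected(self):
        detections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_drugs, n_test = 12, 40
            noise_sd = np.geomspace(0.1, 1.0, n_drugs)  # 10-fold spread
            rows = []
            for j, sd in enumerate(noise_sd):
                y = rng.normal(0.0, sd, size=n_test)
                rows.append((np.mean(y**2), np.std(y, ddof=1)))
            per_drug = pd.DataFrame(rows, columns=["mse", "target_sd"])
            rho, p = drug_variability_association(per_drug, seed=seed)
            detections += (rho > 0) and (p < 0.05)
        assert detections >= 8


class TestErrorNormality:
    def test_gaussian_residuals_pass(self):
        passes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            out = error_normality_summary({"cond": rng.normal(size=500)})
            passes += out.loc["cond", "p_value"] > 0.01
        assert passes >= 9

    def test_skewed_residuals_fail(self):
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            out = error_normality_summary({"cond": rng.exponential(size=500)})
            rejections += out.loc["cond", "p_value"] < 0.01
        assert rejections >= 9

    def test_constant_residuals_flagged(self):
        out = error_normality_summary({"cond": np.ones(50)})
        assert bool(out.loc["cond", "degenerate"])
        assert np.isnan(out.loc["cond", "p_value"])

    def test_too_few_residuals(self):
        with pytest.raises(ValueError):
            error_normality_summary({"cond": np.ones(5)})


def test_planted_modality_advantage_ranks_and_mse_agree():
    """With one modality's read-out distorted, the clean modality attains both
    the lower mean test MSE and the lower mean rank in most seeds."""
    from drpcurves import fit_gbt

    agreements = 0
    for seed in range(10):
        cfg = SyntheticConfig(
            n_cell_lines=100,
            n_drugs=15,
            n_features_per_modality={"rnaseq": 60, "proteomics": 60},
            n_informative_features=15,
            cell_effect_sd=0.8,
            noise_sd=0.3,
            sparsity_of_response=0.0,
            missing_rate=0.0,
            modality_distortion_sd={"proteomics": 1.0},
            seed=1300 + seed,
        )
        profiles, table, _ = simulate_dataset(cfg)
        mses = {}
        for modality in ("rnaseq", "proteomics"):
            pairs = build_pairs(profiles[modality], table)
            cells = sorted({c for c, _ in pairs.pair_index})
            rows = []
            for rep in range(3):
                split = cancer_blind_split(cells, seed=97 * seed + rep)
                tr, va, te = split_pairs(split, pairs.pair_index)
                model = fit_gbt(
                    pairs.subset(tr),
                    pairs.subset(va),
                    params={"n_estimators": 120, "max_depth": 4},
                    seed=seed,
                )
                rows.append(model.test_mse(pairs.subset(te)))
            mses[modality] = rows
        table_mse = pd.DataFrame(mses)
        ranking = average_ranking(table_mse)
        mse_better = table_mse.mean().idxmin()
        rank_better = min(ranking, key=ranking.get)
        agreements += (mse_better == "rnaseq") and (rank_better == "rnaseq")
    assert agreements >= 8


TINY = ExperimentConfig(
    synthetic=SyntheticConfig(
        n_cell_lines=20,
        n_drugs=5,
        n_features_per_modality={"rnaseq": 15},
        n_informative_features=5,
        sparsity_of_response=0.0,
        seed=17,
    ),
    modalities=["rnaseq"],
    learners=["benchmark"],
    n_repeats=2,
    n_sizes=2,
    min_size=10,
    base_seed=17,
)


class TestRunExperiment:
    def test_smoke_emits_all_artifacts(self, tmp_path):
        results = run_experiment(TINY, tmp_path / "exp")
        expected = {"benchmark"}
        assert set(results["learner"]) == expected
        assert (tmp_path / "exp" / "results.csv").exists()
        assert (tmp_path / "exp" / "comparison.csv").exists()
        assert (tmp_path / "exp" / "comparison_summary.csv").exists()
        assert (tmp_path / "exp" / "splits.json").exists()
        assert (tmp_path / "exp" / "manifest.json").exists()
        assert list((tmp_path / "exp" / "curves").glob("*_summary.csv"))
        # 2 repeats x 2 sizes x 1 condition
        assert len(results) == 4

    def test_rerun_identical_bytes(self, tmp_path):
        run_experiment(TINY, tmp_path / "a")
        run_experiment(TINY, tmp_path / "b")
        for name in ("results.csv", "comparison.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_mismatched_config_refused(self, tmp_path):
        run_experiment(TINY, tmp_path / "exp")
        import dataclasses

        other = dataclasses.replace(TINY, n_repeats=3)
        with pytest.raises(ValueError, match="refusing"):
            run_experiment(other, tmp_path / "exp")

    def test_benchmark_row_matches_recomputation(self, tmp_path):
        results = run_experiment(TINY, tmp_path / "exp")
        profiles, table, _ = simulate_dataset(TINY.synthetic)
        pairs = build_pairs(profiles["rnaseq"], table)
        from drpcurves.splitting import load_split_manifest

        splits = load_split_manifest(tmp_path / "exp" / "splits.json")
        full = results[results["size"] == results["size"].max()]
        for split in splits:
            tr, _, te = split_pairs(split, pairs.pair_index)
            expected_max = results["size"].max()
            # recompute the benchmark at the full subset for this repeat
            from drpcurves.splitting import make_subset_schedule

            schedule = make_subset_schedule(
                tr, seed=split.seed, sizes=sorted(results["size"].unique())
            )
            model = fit_drug_average(pairs.subset(schedule.subsets[-1]))
            got = full[(full["repeat"] == split.repeat_index)]["test_mse"].iloc[0]
            assert got == pytest.approx(model.test_mse(pairs.subset(te)), abs=1e-12)

    def test_comparison_cells_equal_curve_entries(self, tmp_path):
        results = run_experiment(TINY, tmp_path / "exp")
        table = comparison_table(results)
        curves = curves_from_results(results)
        curve = curves[("-", "benchmark")]
        np.testing.assert_allclose(
            np.sort(table["-/benchmark"].to_numpy()),
            np.sort(curve.per_repeat_error[:, -1]),
        )

    def test_summary_contains_rankings_with_two_conditions(self, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(
            TINY,
            learners=["benchmark", "gbt"],
            learner_params={"gbt": {"n_estimators": 20, "max_depth": 3}},
        )
        run_experiment(cfg, tmp_path / "exp2")
        results = pd.read_csv(tmp_path / "exp2" / "results.csv")
        summary = summarize_comparison(comparison_table(results))
        assert "average_ranking" in summary.columns
        assert summary["average_ranking"].sum() == pytest.approx(3.0)  # ranks 1+2
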