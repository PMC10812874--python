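"""Benchmark arithmetic, learner contracts, and random search."""

import numpy as np
import pandas as pd
import pytest

from drpcurves import (
    HyperparameterSpace,
    SyntheticConfig,
    build_pairs,
    fit_drug_average,
    fit_gbt,
    fit_nn,
    mse,
    predict_drug_average,
    random_search,
    simulate_dataset,
)
from drpcurves.models import ParamRange
from drpcurves.splitting import cancer_blind_split, split_pairs

from conftest import matrix_from


def paired_from_rows(rows):
    cells = sorted({c for c, _, _ in rows})
    omics = matrix_from(np.zeros((len(cells), 2)), cells=cells)
    responses = pd.DataFrame(rows, columns=["cell_line", "drug", "ln_ic50"])
    return build_pairs(omics, responses)


class TestDrugAverageBenchmark:
    ROWS = [("c1", "dA", 2.0), ("c2", "dA", 4.0), ("c1", "dB", 1.0)]

    def test_printed_rule_arithmetic(self):
        model = fit_drug_average(paired_from_rows(self.ROWS))
        assert model.estimator.per_drug_mean_ == {"dA": 3.0, "dB": 1.0}
        assert model.estimator.global_mean_ == pytest.approx(7 / 3)

    def test_single_pair(self):
        model = fit_drug_average(paired_from_rows([("c1", "dA", 2.5)]))
        assert model.estimator.per_drug_mean_ == {"dA": 2.5}
        assert model.estimator.global_mean_ == 2.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fit_drug_average(paired_from_rows(self.ROWS).subset([]))

    def test_known_and_unseen_drug_predictions(self):
        model = fit_drug_average(paired_from_rows(self.ROWS))
        preds = predict_drug_average(model, [("c9", "dA"), ("c9", "dZ")])
        assert preds[0] == 3.0
        assert preds[1] == pytest.approx(7 / 3)  # fallback: global training mean

    def test_prediction_ignores_cell_line(self):
        model = fit_drug_average(paired_from_rows(self.ROWS))
        pairs = [(f"c{i}", "dA") for i in range(10)]
        assert len(set(predict_drug_average(model, pairs))) == 1

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"c{i}", f"d{rng.integers(6)}", float(rng.normal()))
            for i in range(40)
        ]
        rows = list({(c, d): (c, d, y) for c, d, y in rows}.values())
        train = paired_from_rows(rows)
        model = fit_drug_average(train)
        frame = pd.DataFrame(rows, columns=["cell_line", "drug", "ln_ic50"])
        expected = frame.groupby("drug")["ln_ic50"].mean()
        for drug, mean in expected.items():
            assert model.estimator.per_drug_mean_[drug] == pytest.approx(mean)

    def test_unseen_drug_in_paired_dataset(self):
        # drug vocabulary fixed before splitting: a test-only drug one-hots to
        # a column with no training support and falls back to the global mean
        all_rows = self.ROWS + [("c3", "dC", 9.0)]
        full = paired_from_rows(all_rows)
        train = full.subset([i for i, (_, d) in enumerate(full.pair_index) if d != "dC"])
        test = full.subset([i for i, (_, d) in enumerate(full.pair_index) if d == "dC"])
        model = fit_drug_average(train)
        assert predict_drug_average(model, test)[0] == pytest.approx(7 / 3)


class TestMSE:
    def test_identical_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_known_value(self):
        assert mse([0.0, 0.0], [1.0, 3.0]) == 5.0

    def test_matches_loop(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=50), rng.normal(size=50)
        total = sum((a - b) ** 2 for a, b in zip(p, t)) / 50
        assert mse(p, t) == pytest.approx(total, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def learnable_splits():
    """Synthetic data with drug-level + cell-level signal, split cancer-blind."""
    cfg = SyntheticConfig(
        n_cell_lines=80,
        n_drugs=12,
        n_features_per_modality={"rnaseq": 60},
        n_informative_features=10,
        cell_effect_sd=0.8,
        noise_sd=0.3,
        sparsity_of_response=0.0,
        seed=21,
    )
    profiles, table, _ = simulate_dataset(cfg)
    pairs = build_pairs(profiles["rnaseq"], table)
    cells = sorted({c for c, _ in pairs.pair_index})
    split = cancer_blind_split(cells, seed=21)
    tr, va, te = split_pairs(split, pairs.pair_index)
    return pairs.subset(tr), pairs.subset(va), pairs.subset(te)


@pytest.fixture(scope="module")
def drug_only_splits():
    """No cell effect, no noise: the drug one-hots carry the whole signal."""
    cfg = SyntheticConfig(
        n_cell_lines=40,
        n_drugs=8,
        n_features_per_modality={"rnaseq": 20},
        cell_effect_sd=0.0,
        noise_sd=0.0,
        sparsity_of_response=0.0,
        seed=5,
    )
    profiles, table, _ = simulate_dataset(cfg)
    pairs = build_pairs(profiles["rnaseq"], table)
    cells = sorted({c for c, _ in pairs.pair_index})
    split = cancer_blind_split(cells, seed=5)
    tr, va, te = split_pairs(split, pairs.pair_index)
    return pairs.subset(tr), pairs.subset(va), pairs.subset(te)


GBT_FAST = {"n_estimators": 150, "max_depth": 4}
# small weight decay: the drug-only contract needs near-interpolation
NN_FAST = {"hidden_layer_sizes": (64,), "alpha": 1e-3, "max_epochs": 100, "patience": 10}


class TestLearners:
    @pytest.mark.parametrize(
        "fitter,params,slack",
        [
            # trees reproduce the per-drug means essentially exactly
            (fit_gbt, GBT_FAST, 1e-6),
            # SGD nets carry a small optimization gap at this data size
            (fit_nn, {"hidden_layer_sizes": (64,), "alpha": 10.0, "max_epochs": 150, "patience": 15}, 0.1),
        ],
    )
    def test_matches_benchmark_on_drug_only_signal(self, drug_only_splits, fitter, params, slack):
        train, val, test = drug_only_splits
        bench = fit_drug_average(train).test_mse(test)  # 0 by construction
        model = fitter(train, val, params=params, seed=1)
        assert model.test_mse(test) <= bench + slack

    @pytest.mark.parametrize("fitter,params", [(fit_gbt, GBT_FAST), (fit_nn, NN_FAST)])
    def test_seeded_fit_repeatable(self, learnable_splits, fitter, params):
        train, val, test = learnable_splits
        a = fitter(train, val, params=params, seed=3)
        b = fitter(train, val, params=params, seed=3)
        assert a.validation_mse == pytest.approx(b.validation_mse, abs=1e-6)

    @pytest.mark.parametrize("fitter,params", [(fit_gbt, GBT_FAST), (fit_nn, {})])
    def test_beats_benchmark_with_cell_effect(self, learnable_splits, fitter, params):
        train, val, test = learnable_splits
        bench = fit_drug_average(train).test_mse(test)
        model = fitter(train, val, params=params, seed=2)
        assert model.test_mse(test) < bench

    def test_non_finite_features_rejected(self, learnable_splits):
        train, val, _ = learnable_splits
        bad = train.subset(range(10))
        bad.cell_inputs[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_gbt(bad, val, params=GBT_FAST)

    def test_early_stopping_returns_best_validation(self, learnable_splits):
        train, val, _ = learnable_splits
        model = fit_nn(train, val, params=NN_FAST, seed=4)
        refit_val = mse(model.predict(val), val.targets)
        assert refit_val == pytest.approx(model.validation_mse, abs=1e-9)


class TestRandomSearch:
    def test_single_point_space_returns_it(self, drug_only_splits):
        train, val, _ = drug_only_splits
        space = HyperparameterSpace(
            params={"n_estimators": [30], "max_depth": [3]}, trial_count=1
        )
        model = random_search("gbt", space, train, val, seed=0)
        assert model.params["n_estimators"] == 30
        assert model.params["max_depth"] == 3

    def test_executes_exactly_trial_count_fits(self, drug_only_splits):
        train, val, _ = drug_only_splits
        space = HyperparameterSpace(
            params={"n_estimators": [20], "max_depth": ParamRange(2, 4, dtype=int)},
            trial_count=15,
        )
        model = random_search("gbt", space, train, val, seed=1)
        assert len(model.trial_log) == 15

    def test_returns_minimum_of_trial_log(self, drug_only_splits):
        train, val, _ = drug_only_splits
        space = HyperparameterSpace(
            params={"n_estimators": [20], "max_depth": ParamRange(2, 5, dtype=int)},
            trial_count=6,
        )
        model = random_search("gbt", space, train, val, seed=2)
        assert model.validation_mse == min(t["validation_mse"] for t in model.trial_log)

    def test_benchmark_has_no_search(self, drug_only_splits):
        train, val, _ = drug_only_splits
        with pytest.raises(ValueError):
            random_search("benchmark", HyperparameterSpace(params={"x": [1]}), train, val)
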