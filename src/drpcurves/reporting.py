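"""Max-training-size comparison statistics and the experiment driver.

The driver runs the full protocol end-to-end on synthetic data: simulate
omics + responses, preprocess, pair, split cancer-blind with repeats, train
every (learner, modality) condition across the subset schedule, and emit
learning curves plus a comparison table at the largest training size.  The
statistics here summarise that table: average rankings across splits,
percentage MSE reductions between conditions, per-drug error against IC50
variability, and a residual-normality check.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import models as mdl
from .datatypes import PairedDataset
from .learning_curves import LearningCurve, assemble_curve, plot_curves, write_curve_csvs
from .pairing import build_pairs, drop_cell_lines_without_targets, intersect_cell_line_sets
from .preprocess import prepare_modality
from .splitting import (
    log_spaced_sizes,
    make_subset_schedule,
    repeat_splits,
    save_split_manifest,
    split_pairs,
)
from .synthetic import SyntheticConfig, simulate_dataset

BENCHMARK_MODALITY = "-"  # the benchmark uses no omics input


def average_ranking(
    table: pd.DataFrame, conditions: list[str] | None = None
) -> dict[str, float]:
    """Mean rank of each condition across splits (1 = lowest MSE; midranks).

    ``table`` is splits x conditions of test MSE.  A condition that wins 24
    of 30 splits against one other gets 0.8*1 + 0.2*2 = 1.2.
    """
    if conditions is not None:
        table = table.loc[:, conditions]
    if table.shape[1] < 2 or table.shape[0] < 1:
        raise ValueError("need >=2 conditions and >=1 split")
    ranks = table.apply(lambda row: stats.rankdata(row.to_numpy()), axis=1, result_type="expand")
    ranks.columns = table.columns
    return {c: float(ranks[c].mean()) for c in table.columns}


def percent_mse_reduction(reference: float, comparison: float) -> float:
    """100 * (reference - comparison) / reference; positive = comparison better."""
    if reference <= 0:
        raise ValueError("reference MSE must be positive")
    return 100.0 * (reference - comparison) / reference


def per_drug_error(
    model: mdl.TrainedModel, test: PairedDataset
) -> pd.DataFrame:
    """Per-drug test MSE, pair count and target SD.

    Drugs with fewer than 2 test pairs are flagged (their SD is undefined
    and their MSE rests on a single pair).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    predictions = model.predict(test)
    frame = pd.DataFrame(
        {
            "drug": test.drugs,
            "sq_err": (predictions - test.targets) ** 2,
            "target": test.targets,
        }
    )
    grouped = frame.groupby("drug", sort=True)
    out = pd.DataFrame(
        {
            "mse": grouped["sq_err"].mean(),
            "n_pairs": grouped.size(),
            "target_sd": grouped["target"].std(ddof=1),
        }
    )
    out["flagged"] = out["n_pairs"] < 2
    return out


def drug_variability_association(
    per_drug: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Rank correlation between per-drug MSE and per-drug target SD.

    Tests whether drugs with more variable IC50 values are harder to
    predict.  Returns (Spearman rho, one-sided permutation p-value for
    positive association); midranks handle ties, and a constant MSE column
    yields rho = 0.
    """
    usable = per_drug.dropna(subset=["target_sd"])
    if len(usable) < 5:
        raise ValueError("need >= 5 drugs with defined target SD")
    x = stats.rankdata(usable["mse"].to_numpy())
    y = stats.rankdata(usable["target_sd"].to_numpy())
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0
    rho = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if np.corrcoef(x, perm)[0, 1] >= rho:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return rho, float(p)


def error_normality_summary(
    residuals: dict[str, np.ndarray]
) -> pd.DataFrame:
    """D'Agostino-Pearson normality statistic per condition (reported, not gated)."""
    rows = []
    for condition, res in residuals.items():
        res = np.asarray(res, dtype=float)
        if res.size < 20:
            raise ValueError(f"condition {condition!r}: need >= 20 residuals")
        if np.std(res) == 0:
            rows.append((condition, np.nan, np.nan, True))
            continue
        stat, p = stats.normaltest(res)
        rows.append((condition, float(stat), float(p), False))
    return pd.DataFrame(
        rows, columns=["condition", "statistic", "p_value", "degenerate"]
    ).set_index("condition")


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class ExperimentConfig:
    """Everything needed to re-run an experiment exactly."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    modalities: list[str] = field(default_factory=lambda: ["rnaseq"])
    learners: list[str] = field(default_factory=lambda: ["benchmark", "gbt"])
    n_repeats: int = 30
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_sizes: int = 8
    min_size: int = 32
    base_seed: int = 0
    hyperparameter_search: bool = False
    trial_count: int = 15
    learner_params: dict[str, dict] = field(default_factory=dict)

    def content_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _model_seed(base_seed: int, repeat: int, size: int, modality: str, kind: str) -> int:
    tag = zlib.crc32(f"{repeat}:{size}:{modality}:{kind}".encode()) & 0xFFFF
    return int((base_seed * 131071 + tag) % (2**31))


def _fit_condition(
    kind: str,
    train: PairedDataset,
    val: PairedDataset,
    config: ExperimentConfig,
    seed: int,
) -> mdl.TrainedModel:
    if kind == "benchmark":
        return mdl.fit_drug_average(train)
    if config.hyperparameter_search:
        space = mdl.DEFAULT_GBT_SPACE if kind == "gbt" else mdl.DEFAULT_NN_SPACE
        space = mdl.HyperparameterSpace(params=space.params, trial_count=config.trial_count)
        return mdl.random_search(kind, space, train, val, seed=seed)
    params = dict(config.learner_params.get(kind, {}))
    fitter = mdl.fit_gbt if kind == "gbt" else mdl.fit_nn
    return fitter(train, val, params=params, seed=seed)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run the full protocol; returns the long results table.

    Emits, under ``out_dir``: ``manifest.json`` (config + hash),
    ``splits.json``, ``results.csv`` (repeat, size, modality, learner,
    test MSE), per-condition learning-curve CSVs, ``comparison.csv`` (the
    max-size table with mean, standard error and average ranking) and a
    log-log curve plot.  Re-running over an existing directory resumes,
    skipping finished (repeat, size, condition) cells; a directory produced
    under a different config is refused.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.content_hash()
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("config_hash") != chash:
            raise ValueError(
                f"{out} holds results for a different config "
                f"({prior.get('config_hash')} != {chash}); refusing to merge"
            )
    else:
        manifest_path.write_text(
            json.dumps(
                {"config_hash": chash, "config": asdict(config)},
                indent=1,
                sort_keys=True,
                default=str,
            )
        )

    # --- data
    profiles, responses, _truth = simulate_dataset(config.synthetic)
    profiles = {m: profiles[m] for m in config.modalities}
    profiles = drop_cell_lines_without_targets(profiles, responses)
    prepared = {m: prepare_modality(mat) for m, mat in profiles.items()}
    cells = intersect_cell_line_sets(list(prepared.values()))
    responses = responses[responses["cell_line"].isin(cells)]
    vocabulary = sorted(responses["drug"].unique())
    paired = {
        m: build_pairs(mat, responses, cells, vocabulary)
        for m, mat in prepared.items()
    }
    pair_index = next(iter(paired.values())).pair_index

    # --- splits
    splits = repeat_splits(cells, config.fractions, config.n_repeats, config.base_seed)
    save_split_manifest(
        splits, out / "splits.json", fractions=config.fractions, base_seed=config.base_seed
    )

    results_path = out / "results.csv"
    done: set[tuple] = set()
    rows: list[dict] = []
    if results_path.exists():
        prior_rows = pd.read_csv(results_path)
        rows = prior_rows.to_dict("records")
        done = {
            (r["repeat"], r["size"], r["modality"], r["learner"]) for r in rows
        }

    # one size grid shared by all repeats, capped at the smallest repeat's
    # training pair count so every curve point is averaged over every repeat
    n_common = min(len(split_pairs(s, pair_index)[0]) for s in splits)
    grid = log_spaced_sizes(min(config.min_size, n_common), n_common, config.n_sizes)

    for split in splits:
        train_idx, val_idx, test_idx = split_pairs(split, pair_index)
        schedule = make_subset_schedule(train_idx, seed=split.seed, sizes=grid)
        for size, subset in zip(schedule.sizes, schedule.subsets):
            for modality in sorted(paired):
                data = paired[modality]
                train = data.subset(subset)
                val = data.subset(val_idx)
                test = data.subset(test_idx)
                for kind in config.learners:
                    cond_modality = BENCHMARK_MODALITY if kind == "benchmark" else modality
                    key = (split.repeat_index, size, cond_modality, kind)
                    if key in done:
                        continue
                    done.add(key)
                    seed = _model_seed(
                        config.base_seed, split.repeat_index, size, cond_modality, kind
                    )
                    model = _fit_condition(kind, train, val, config, seed)
                    rows.append(
                        {
                            "repeat": split.repeat_index,
                            "size": size,
                            "modality": cond_modality,
                            "learner": kind,
                            "test_mse": model.test_mse(test),
                            "validation_mse": model.validation_mse,
                            "n_train_cells": len({c for c, _ in train.pair_index}),
                        }
                    )
            frame = pd.DataFrame(rows).sort_values(
                ["repeat", "size", "modality", "learner"], kind="mergesort"
            )
            frame.to_csv(results_path, index=False)

    results = pd.read_csv(results_path)
    _emit_curves_and_comparison(results, out)
    return results


def curves_from_results(results: pd.DataFrame) -> dict[tuple[str, str], LearningCurve]:
    """One learning curve per (modality, learner) condition."""
    curves = {}
    for (modality, learner), group in results.groupby(["modality", "learner"]):
        wide = group.pivot(index="repeat", columns="size", values="test_mse")
        wide = wide.sort_index(axis=1).dropna(axis=1)
        curves[(modality, learner)] = assemble_curve(
            wide.to_numpy(), [int(s) for s in wide.columns], labels=(modality, learner)
        )
    return curves


def comparison_table(results: pd.DataFrame) -> pd.DataFrame:
    """Splits x conditions test-MSE table at the largest training size."""
    n_max = results["size"].max()
    at_max = results[results["size"] == n_max].copy()
    at_max["condition"] = at_max["modality"] + "/" + at_max["learner"]
    return at_max.pivot(index="repeat", columns="condition", values="test_mse")


def summarize_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Mean MSE, standard error over splits, and average ranking per condition."""
    n_splits = table.shape[0]
    summary = pd.DataFrame(
        {
            "mean_mse": table.mean(axis=0),
            "stderr": table.std(axis=0, ddof=1) / np.sqrt(n_splits)
            if n_splits > 1
            else 0.0,
        }
    )
    if table.shape[1] >= 2:
        ranking = average_ranking(table)
        summary["average_ranking"] = pd.Series(ranking)
    return summary.sort_index()


def _emit_curves_and_comparison(results: pd.DataFrame, out: Path) -> None:
    curves = curves_from_results(results)
    curve_dir = out / "curves"
    for (modality, learner), curve in sorted(curves.items()):
        write_curve_csvs(curve, curve_dir, f"{modality}_{learner}".replace("/", "_"))
    try:
        plot_curves(list(curves.values()), out / "learning_curves.png")
    except Exception:  # plotting must never sink the run
        pass
    table = comparison_table(results)
    table.to_csv(out / "comparison.csv")
    summarize_comparison(table).to_csv(out / "comparison_summary.csv")
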