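"""Cancer-blind splits and the training-subset schedule for learning curves.

Cancer-blind evaluation partitions *cell lines* — not pairs — into train /
validation / test sets, so every pair of a held-out cell line is unseen at
training time.  This simulates predicting responses for a new patient or
sample.  Each repeat reshuffles the cell lines before partitioning; within a
repeat the training pairs are cut into K nested, log-spaced subsets whose
prefix structure means the difference between adjacent curve points reflects
added data rather than resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class CancerBlindSplit:
    """Disjoint train/validation/test cell-line partition."""

    train_cells: list[str]
    val_cells: list[str]
    test_cells: list[str]
    repeat_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        t, v, e = map(set, (self.train_cells, self.val_cells, self.test_cells))
        if t & v or t & e or v & e:
            raise ValueError("train/val/test cell-line sets must be disjoint")

    @property
    def all_cells(self) -> set[str]:
        return set(self.train_cells) | set(self.val_cells) | set(self.test_cells)


@dataclass
class SubsetSchedule:
    """Nested training subsets of strictly increasing size."""

    sizes: list[int]
    subsets: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        for size, sub in zip(self.sizes, self.subsets):
            if len(sub) != size:
                raise ValueError("subset length disagrees with its size")
        for small, big in zip(self.subsets, self.subsets[1:]):
            if not set(small) <= set(big):
                raise ValueError("subsets must be nested")


def cancer_blind_split(
    cell_lines: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    repeat_index: int = 0,
) -> CancerBlindSplit:
    """Shuffle cell lines by ``seed`` and partition by ``fractions``.

    Validation and test sizes are rounded; the remainder goes to train, so
    train is never starved by rounding.  All pairs of a cell line inherit its
    partition downstream.
    """
    if len(cell_lines) < 3:
        raise ValueError("need at least 3 cell lines for a 3-way split")
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    order = list(np.array(cell_lines)[rng.permutation(len(cell_lines))])
    n = len(order)
    n_val = max(1, round(f_val * n))
    n_test = max(1, round(f_test * n))
    if n_val + n_test >= n:
        raise ValueError("fractions leave no training cell lines")
    return CancerBlindSplit(
        train_cells=order[: n - n_val - n_test],
        val_cells=order[n - n_val - n_test : n - n_test],
        test_cells=order[n - n_test :],
        repeat_index=repeat_index,
        seed=seed,
    )


def log_spaced_sizes(min_size: int, full: int, k: int) -> list[int]:
    """K log-spaced integer sizes from ``min_size`` to ``full`` inclusive."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if min_size < 1 or full < min_size:
        raise ValueError(f"need 1 <= min_size <= full size (got {min_size}, {full})")
    raw = np.geomspace(min_size, full, num=k)
    sizes = sorted(set(int(round(s)) for s in raw) | {min_size, full})
    if len(sizes) < 2:
        raise ValueError(
            f"cannot place {k} distinct log-spaced sizes between {min_size} and {full}"
        )
    return sizes


def make_subset_schedule(
    train_pairs: list[int] | int,
    k: int = 8,
    min_size: int = 32,
    seed: int = 0,
    sizes: list[int] | None = None,
) -> SubsetSchedule:
    """Log-spaced nested subsets of the training pairs.

    ``train_pairs`` may be an explicit pair-index list or a pair count (then
    indices 0..n-1 are used).  Sizes run from ``min_size`` to the full pair
    count inclusive; subsets are prefixes of one seeded shuffle.  An explicit
    ``sizes`` grid (e.g. a grid shared across repeats, capped at the smallest
    repeat's training size) overrides the log spacing.
    """
    if isinstance(train_pairs, int):
        train_pairs = list(range(train_pairs))
    full = len(train_pairs)
    if sizes is None:
        sizes = log_spaced_sizes(min_size, full, k)
    else:
        sizes = sorted(set(int(s) for s in sizes))
        if not sizes or sizes[0] < 1 or sizes[-1] > full:
            raise ValueError(f"explicit sizes must lie in [1, {full}]")
    rng = np.random.default_rng(seed)
    order = [train_pairs[i] for i in rng.permutation(full)]
    subsets = [order[:s] for s in sizes]
    return SubsetSchedule(sizes=sizes, subsets=subsets)


def repeat_splits(
    cell_lines: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_repeats: int = 30,
    base_seed: int = 0,
) -> list[CancerBlindSplit]:
    """``n_repeats`` reshuffled cancer-blind splits with derived seeds."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seeds = derive_seeds(base_seed, n_repeats)
    return [
        cancer_blind_split(cell_lines, fractions, seed=s, repeat_index=i)
        for i, s in enumerate(seeds)
    ]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Reproducible distinct child seeds (below 2^31) from one base seed."""
    if n == 1:
        return [base_seed]
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def split_pairs(
    split: CancerBlindSplit, pair_index: list[tuple[str, str]]
) -> tuple[list[int], list[int], list[int]]:
    """Route pair rows to train/val/test by their cell line's partition."""
    t, v, e = set(split.train_cells), set(split.val_cells), set(split.test_cells)
    train, val, test = [], [], []
    for i, (cell, _) in enumerate(pair_index):
        if cell in t:
            train.append(i)
        elif cell in v:
            val.append(i)
        elif cell in e:
            test.append(i)
        else:
            raise KeyError(f"cell line {cell!r} missing from the split")
    return train, val, test


def save_split_manifest(
    splits: list[CancerBlindSplit],
    path: str | Path,
    fractions: tuple[float, float, float] | None = None,
    base_seed: int | None = None,
) -> None:
    """Serialize splits to a JSON manifest for audit and exact re-runs."""
    payload = {
        "fractions": fractions,
        "base_seed": base_seed,
        "repeats": [
            {
                "repeat_index": s.repeat_index,
                "seed": s.seed,
                "train_cells": s.train_cells,
                "val_cells": s.val_cells,
                "test_cells": s.test_cells,
            }
            for s in splits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_split_manifest(path: str | Path) -> list[CancerBlindSplit]:
    payload = json.loads(Path(path).read_text())
    return [
        CancerBlindSplit(
            train_cells=r["train_cells"],
            val_cells=r["val_cells"],
            test_cells=r["test_cells"],
            repeat_index=r["repeat_index"],
            seed=r["seed"],
        )
        for r in payload["repeats"]
    ]
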