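"""Learning-curve assembly, power-law fitting, regions, and crossings.

A learning curve plots generalization error eps against training-set size n,
averaged over repeated cancer-blind splits.  Its middle segment typically
follows the power law

    eps(n) = alpha * n**beta          (beta < 0 when data helps)

which is a straight line in log-log coordinates:
log(eps) = beta*log(n) + log(alpha).  The small-data region (flat, near
random-guess error) precedes it and the irreducible-error/diminishing-returns
region (slope magnitude shrinking toward an error floor) follows it.
Extrapolating the fitted line predicts how error would shrink with more data
— with the caveat that nothing in the observed curve reveals when the
power-law region will end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

REGIONS = ("small_data", "power_law", "diminishing_returns")


@dataclass
class LearningCurve:
    """Per-size mean generalization error with standard errors over repeats."""

    sizes: list[int]
    per_repeat_error: np.ndarray  # repeats x sizes
    labels: tuple[str, str] = ("", "")  # (modality, learner)

    def __post_init__(self) -> None:
        self.per_repeat_error = np.asarray(self.per_repeat_error, dtype=float)
        if self.per_repeat_error.ndim != 2:
            raise ValueError("per_repeat_error must be repeats x sizes")
        if self.per_repeat_error.shape[1] != len(self.sizes):
            raise ValueError("size list length != error matrix width")
        if np.isnan(self.per_repeat_error).any():
            raise ValueError("per_repeat_error contains missing cells")

    @property
    def n_repeats(self) -> int:
        return self.per_repeat_error.shape[0]

    @property
    def mean_error(self) -> np.ndarray:
        return self.per_repeat_error.mean(axis=0)

    @property
    def stderr(self) -> np.ndarray:
        if self.n_repeats < 2:
            return np.zeros(len(self.sizes))
        return self.per_repeat_error.std(axis=0, ddof=1) / np.sqrt(self.n_repeats)

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long (size, repeat, error) table."""
        rows = [
            (size, k, self.per_repeat_error[k, j])
            for j, size in enumerate(self.sizes)
            for k in range(self.n_repeats)
        ]
        return pd.DataFrame(rows, columns=["size", "repeat", "error"])

    def to_summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mean_error": self.mean_error, "stderr": self.stderr}
        )


def assemble_curve(
    per_repeat_error: np.ndarray,
    sizes: list[int],
    labels: tuple[str, str] = ("", ""),
) -> LearningCurve:
    """Build a curve from the repeats x sizes error matrix."""
    return LearningCurve(sizes=list(sizes), per_repeat_error=per_repeat_error, labels=labels)


@dataclass
class PowerLawFit:
    """eps(n) = alpha * n**beta fitted over a window of curve sizes."""

    alpha: float
    beta: float
    fit_window: tuple[int, int]  # [start, stop) size indices
    residual_sum: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.residual_sum < 0:
            raise ValueError("residual_sum must be non-negative")


class PowerLawModel(RegressorMixin, BaseEstimator):
    """Least-squares power law in log-log space, scikit-learn style.

    ``fit(n, eps)`` regresses log(eps) on log(n); ``predict(n)`` returns
    alpha * n**beta.
    """

    def fit(self, X, y):
        n = np.asarray(X, dtype=float).reshape(-1)
        eps = np.asarray(y, dtype=float).reshape(-1)
        if n.size < 2:
            raise ValueError("power-law fit needs at least 2 points")
        if (eps <= 0).any() or (n <= 0).any():
            raise ValueError("power-law fit requires positive sizes and errors")
        slope, intercept = np.polyfit(np.log(n), np.log(eps), deg=1)
        self.beta_ = float(slope)
        self.alpha_ = float(np.exp(intercept))
        resid = np.log(eps) - (slope * np.log(n) + intercept)
        self.residual_sum_ = float(np.sum(resid**2))
        self.fit_sizes_ = (float(n.min()), float(n.max()))
        return self

    def predict(self, X):
        n = np.asarray(X, dtype=float)
        return self.alpha_ * n**self.beta_


def default_fit_window(n_sizes: int) -> tuple[int, int]:
    """Interior sizes (drop smallest and largest) when there is room.

    The power law holds in the middle region of the curve; the extreme sizes
    are the most likely to sit in the small-data or diminishing-returns
    regions.
    """
    if n_sizes >= 4:
        return (1, n_sizes - 1)
    return (0, n_sizes)


def fit_power_law(
    curve: LearningCurve, window: tuple[int, int] | None = None
) -> PowerLawFit:
    """Fit eps(n)=alpha*n^beta to the mean curve over a size-index window."""
    if window is None:
        window = default_fit_window(len(curve.sizes))
    start, stop = window
    if not (0 <= start < stop <= len(curve.sizes)) or stop - start < 2:
        raise ValueError(f"invalid fit window {window} for {len(curve.sizes)} sizes")
    n = np.asarray(curve.sizes[start:stop], dtype=float)
    eps = curve.mean_error[start:stop]
    if (eps <= 0).any():
        raise ValueError("non-positive mean error inside the fit window")
    model = PowerLawModel().fit(n, eps)
    return PowerLawFit(
        alpha=model.alpha_,
        beta=model.beta_,
        fit_window=(start, stop),
        residual_sum=model.residual_sum_,
    )


def _local_slopes(sizes: np.ndarray, log_eps: np.ndarray) -> np.ndarray:
    """Per-point slope in log-log coordinates.

    Forward differences (backward for the last point) so a region change at
    size j shows up at j, not smeared across its neighbours.
    """
    log_n = np.log(sizes)
    fwd = np.diff(log_eps) / np.diff(log_n)
    return np.append(fwd, fwd[-1])


def classify_regions(
    curve: LearningCurve,
    fit: PowerLawFit | None = None,
    slope_rel_tol: float = 0.25,
    diminishing_frac: float = 0.5,
) -> list[str]:
    """Label each curve size as small_data / power_law / diminishing_returns.

    Sizes whose local log-log slope magnitude falls below
    ``diminishing_frac * |beta|`` are flat: flat points before the curve's
    steepest descent are small_data, flat points after it are
    diminishing_returns.  The remaining (declining) points are power_law;
    points within ``slope_rel_tol`` relative tolerance of beta always
    qualify.
    """
    if len(curve.sizes) < 4:
        raise ValueError("region classification needs >= 4 sizes")
    eps = curve.mean_error
    if (eps <= 0).any():
        raise ValueError("region classification requires positive errors")
    if fit is None:
        fit = fit_power_law(curve)
    slopes = _local_slopes(np.asarray(curve.sizes, float), np.log(eps))
    beta = fit.beta
    flat_cut = diminishing_frac * abs(beta)
    steepest = int(np.argmax(np.abs(slopes)))
    labels = []
    for j, s in enumerate(slopes):
        if abs(s - beta) <= slope_rel_tol * abs(beta):
            labels.append("power_law")
        elif abs(s) < flat_cut:
            labels.append("small_data" if j < steepest else "diminishing_returns")
        else:
            labels.append("power_law")
    return labels


def extrapolate(fit: PowerLawFit, n_target: int, curve: LearningCurve | None = None):
    """Predicted error alpha * n_target**beta at a (possibly unseen) size.

    Returns ``(prediction, flagged)`` where ``flagged`` is True when
    ``n_target`` lies beyond the sizes the fit was computed on (an
    extrapolation, trustworthy only while the power-law region lasts).
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    prediction = fit.alpha * float(n_target) ** fit.beta
    flagged = False
    if curve is not None:
        start, stop = fit.fit_window
        flagged = n_target > curve.sizes[stop - 1] or n_target < curve.sizes[start]
    return prediction, flagged


def find_crossing(a: LearningCurve, b: LearningCurve) -> float | None:
    """Smallest size where (b - a) changes sign and keeps the new sign.

    Detects where one learner's curve overtakes the other *persistently*
    (the sign must hold to the final grid size), ignoring single flips.  The
    crossing is refined by linear interpolation in log(n) between the
    bracketing grid points; returns None when no persistent change exists.
    """
    if list(a.sizes) != list(b.sizes):
        raise ValueError("curves must share one size grid")
    diff = b.mean_error - a.mean_error
    sign = np.sign(diff)
    for j in range(1, len(diff)):
        if sign[j] != 0 and sign[j] != sign[j - 1] and sign[j - 1] != 0:
            if np.all(sign[j:] == sign[j]):
                # linear interpolation of the zero of diff in log n
                x0, x1 = np.log(a.sizes[j - 1]), np.log(a.sizes[j])
                y0, y1 = diff[j - 1], diff[j]
                x_star = x0 - y0 * (x1 - x0) / (y1 - y0)
                return float(np.exp(x_star))
    return None


def pooled_standard_error(curve: LearningCurve, j: int, k: int) -> float:
    """Pooled SE of the difference between the means at two sizes."""
    se = curve.stderr
    return float(np.sqrt(se[j] ** 2 + se[k] ** 2))


def is_monotone_within_error(curve: LearningCurve, n_se: float = 1.0) -> bool:
    """Non-increasing mean error within ``n_se`` pooled SEs per step."""
    eps = curve.mean_error
    for j in range(1, len(eps)):
        slack = n_se * pooled_standard_error(curve, j - 1, j)
        if eps[j] > eps[j - 1] + slack:
            return False
    return True


def write_curve_csvs(curve: LearningCurve, out_dir: str | Path, stem: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_tidy_frame().to_csv(out / f"{stem}_tidy.csv", index=False)
    curve.to_summary_frame().to_csv(out / f"{stem}_summary.csv", index=False)


def plot_curves(
    curves: list[LearningCurve],
    path: str | Path,
    title: str = "Learning curves",
) -> None:
    """Log-log plot with standard-error shading, one line per curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in curves:
        label = " / ".join(x for x in curve.labels if x) or None
        mean, se = curve.mean_error, curve.stderr
        ax.plot(curve.sizes, mean, marker="o", label=label)
        ax.fill_between(curve.sizes, mean - se, mean + se, alpha=0.25)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("training set size (pairs)")
    ax.set_ylabel("test MSE")
    ax.set_title(title)
    if any(any(c.labels) for c in curves):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
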