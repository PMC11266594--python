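"""Goodness-of-fit statistics and multi-run aggregation.

Per prediction/reference pair: mean squared error (MSE), mean absolute
deviation (MAD), Theil's inequality coefficient (TIC, 0 = perfect and
bounded by 1), Nash-Sutcliffe efficiency (NSE, 1 = perfect) and its
complement ENSE = 1 - NSE.  Because the surrogate trainer is stochastic,
runs are repeated and summarized by per-metric minimum, mean and sample
standard deviation.

Notation note: the point count within one run and the number of
independent runs are distinct quantities (both conventionally written M);
here they are ``n_points`` and ``n_runs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricReport",
    "RunStatistics",
    "mse",
    "mad",
    "tic",
    "nse_ense",
    "evaluate",
    "aggregate_runs",
]


def _paired(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size == 0 or p.size != t.size:
        raise ValueError(
            f"pred and truth must have equal nonzero lengths ({p.size} vs {t.size})"
        )
    return p, t


def mse(pred, truth) -> float:
    """Mean squared error."""
    p, t = _paired(pred, truth)
    return float(np.mean((p - t) ** 2))


def mad(pred, truth) -> float:
    """Mean absolute deviation, (1/n) sum |pred_j - truth_j|."""
    p, t = _paired(pred, truth)
    return float(np.mean(np.abs(p - t)))


def tic(pred, truth) -> float:
    """Theil inequality coefficient.

    RMS of the difference over the sum of the RMS norms of the two
    series; scale-invariant and confined to [0, 1], with 0 for identical
    series.  Undefined (error) when both series are identically zero.
    """
    p, t = _paired(pred, truth)
    denom = math.sqrt(np.mean(p**2)) + math.sqrt(np.mean(t**2))
    if denom == 0.0:
        raise ValueError("TIC undefined: both series are identically zero")
    return float(math.sqrt(np.mean((p - t) ** 2)) / denom)


def nse_ense(pred, truth, variant: str = "classical") -> tuple[float, float]:
    """Nash-Sutcliffe efficiency and its complement ENSE = 1 - NSE.

    ``variant="classical"`` (default) is the standard definition:
    ``1 - sum((pred-truth)^2) / sum((truth - mean(truth))^2)`` -- 1 for a
    perfect prediction, 0 for the mean-of-reference predictor.
    ``variant="as_printed"`` is an alternative pairing sometimes seen in
    the soft-computing literature, with the denominator built from the
    *prediction's* deviation about the reference mean and a 1/n factor on
    the numerator only; it is provided for comparison but is degenerate
    when the prediction is constant at the reference mean.
    """
    p, t = _paired(pred, truth)
    t_mean = float(np.mean(t))
    if variant == "classical":
        denom = float(np.sum((t - t_mean) ** 2))
        if denom == 0.0:
            raise ValueError("NSE undefined for a constant reference series")
        nse = 1.0 - float(np.sum((p - t) ** 2)) / denom
    elif variant == "as_printed":
        denom = float(np.sum((p - t_mean) ** 2))
        if denom == 0.0:
            raise ValueError("NSE (as_printed) undefined: prediction equals the reference mean")
        nse = 1.0 - float(np.mean((p - t) ** 2)) / denom
    else:
        raise ValueError(f"unknown NSE variant {variant!r}")
    return nse, 1.0 - nse


@dataclass(frozen=True)
class MetricReport:
    """All scalar statistics for one prediction/reference pair."""

    mse: float
    mad: float
    tic: float
    nse: float
    ense: float
    n_points: int
    label: str = ""


def evaluate(pred, truth, label: str = "", variant: str = "classical") -> MetricReport:
    """Compute every statistic for one prediction/reference pair."""
    p, t = _paired(pred, truth)
    n, e = nse_ense(p, t, variant=variant)
    return MetricReport(
        mse=mse(p, t), mad=mad(p, t), tic=tic(p, t), nse=n, ense=e,
        n_points=p.size, label=label,
    )


@dataclass(frozen=True)
class RunStatistics:
    """Minimum / mean / sample standard deviation per metric over runs."""

    scenario: str
    n_runs: int
    minimum: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)


_AGG_METRICS = ("mse", "mad", "tic", "nse", "ense")


def aggregate_runs(reports: list[MetricReport], scenario: str = "") -> RunStatistics:
    """Summarize repeated stochastic runs metric by metric.

    Uses the sample (ddof=1) standard deviation, hence at least two
    reports are required.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to aggregate")
    minimum, mean_, std = {}, {}, {}
    for name in _AGG_METRICS:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        minimum[name] = float(np.min(vals))
        mean_[name] = float(np.mean(vals))
        std[name] = float(np.std(vals, ddof=1))
    return RunStatistics(
        scenario=scenario, n_runs=len(reports), minimum=minimum, mean=mean_, std=std
    )
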