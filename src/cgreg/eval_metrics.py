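"""Accuracy statistics for genome-proportion estimates.

All metrics compare an individuals-by-populations table of true
proportions ``b`` against an equally shaped table of estimates ``b_hat``,
flattened over all L x N cells:

* MAX — largest absolute difference;
* bias — signed mean difference (truth minus estimate);
* MSE — mean squared difference;
* R — Pearson correlation of the flattened vectors, centred at the grand
  means of truth and estimate respectively;
* MAE — mean absolute difference (handier for plots than MSE).

Individuals can additionally be grouped into six categories by their true
proportion of a chosen population (0%, four quarter bins, 100%) to study
how accuracy degrades as that population's contribution grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORY_LABELS = (
    "0%",
    ">0%-<=25%",
    ">25%-<=50%",
    ">50%-<=75%",
    ">75%-<100%",
    "100%",
)


@dataclass
class MetricsReport:
    max_abs_error: float
    bias: float
    mse: float
    correlation: float  # NaN when undefined (zero variance)
    mae: float
    n_individuals: int
    n_populations: int

    def to_dict(self) -> dict:
        return {
            "max_abs_error": self.max_abs_error,
            "bias": self.bias,
            "mse": self.mse,
            "correlation": self.correlation,
            "mae": self.mae,
            "n_individuals": self.n_individuals,
            "n_populations": self.n_populations,
        }


def _check_aligned(truth: pd.DataFrame, estimates: pd.DataFrame) -> None:
    if list(truth.index) != list(estimates.index):
        raise ValueError("truth and estimate tables list different individuals (or order)")
    if list(truth.columns) != list(estimates.columns):
        raise ValueError("truth and estimate tables list different populations (or order)")


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    """Grand-mean-centred Pearson correlation of two flattened tables."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    va, vb = a @ a, b @ b
    if va <= 0 or vb <= 0:
        warnings.warn("correlation undefined: zero variance in a flattened table", stacklevel=3)
        return float("nan")
    return float((a @ b) / np.sqrt(va * vb))


def compute_metrics(truth: pd.DataFrame, estimates: pd.DataFrame) -> MetricsReport:
    """MAX, bias, MSE, correlation and MAE over all individual-population cells."""
    _check_aligned(truth, estimates)
    t = truth.to_numpy(float)
    e = estimates.to_numpy(float)
    d = t - e
    return MetricsReport(
        max_abs_error=float(np.abs(d).max()),
        bias=float(d.mean()),
        mse=float((d * d).mean()),
        correlation=_pearson_flat(t, e),
        mae=float(np.abs(d).mean()),
        n_individuals=t.shape[0],
        n_populations=t.shape[1],
    )


def compute_metrics_subset(
    truth: pd.DataFrame, estimates: pd.DataFrame, populations: list[str]
) -> MetricsReport:
    """Metrics restricted to the given population columns.

    Used when a population was deliberately left out of the design (its
    cells are not scored) or when only one focal population is of
    interest.
    """
    if not populations:
        raise ValueError("population restriction must be non-empty")
    missing = [p for p in populations if p not in truth.columns or p not in estimates.columns]
    if missing:
        raise ValueError(f"populations absent from tables: {missing}")
    return compute_metrics(truth[populations], estimates[populations])


def categorise_by_truth(values: np.ndarray | pd.Series) -> np.ndarray:
    """Assign each true proportion to one of the six standard categories.

    Boundaries exactly as printed: 0 and 1 are their own categories; the
    quarter bins are upper-inclusive (0.25 belongs to ">0%-<=25%").
    Simulated truths are rationals, so the exact-endpoint tests are safe.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any() or (v > 1).any():
        raise ValueError("true proportions must lie in [0, 1]")
    out = np.empty(v.shape, dtype=object)
    out[v == 0.0] = CATEGORY_LABELS[0]
    out[(v > 0.0) & (v <= 0.25)] = CATEGORY_LABELS[1]
    out[(v > 0.25) & (v <= 0.50)] = CATEGORY_LABELS[2]
    out[(v > 0.50) & (v <= 0.75)] = CATEGORY_LABELS[3]
    out[(v > 0.75) & (v < 1.0)] = CATEGORY_LABELS[4]
    out[v == 1.0] = CATEGORY_LABELS[5]
    return out


def metrics_by_category(
    truth: pd.DataFrame,
    estimates: pd.DataFrame,
    category_population: str,
    scored_populations: list[str] | None = None,
) -> dict[str, MetricsReport]:
    """Per-category metrics, grouping individuals by their true share of one population.

    ``scored_populations`` restricts the scored columns (e.g. to the
    populations kept in an under-specified design); the grouping always
    uses the full truth table's ``category_population`` column.
    """
    if category_population not in truth.columns:
        raise ValueError(f"population {category_population!r} absent from truth table")
    cats = categorise_by_truth(truth[category_population].to_numpy())
    cols = scored_populations if scored_populations is not None else list(estimates.columns)
    out: dict[str, MetricsReport] = {}
    for label in CATEGORY_LABELS:
        mask = cats == label
        if not mask.any():
            continue
        out[label] = compute_metrics_subset(truth.loc[mask], estimates.loc[mask], cols)
    return out


def error_correlation(
    estimates_a: pd.DataFrame, estimates_b: pd.DataFrame, truth: pd.DataFrame
) -> float:
    """Pearson correlation between the estimation errors of two estimate sets."""
    _check_aligned(truth, estimates_a)
    _check_aligned(truth, estimates_b)
    t = truth.to_numpy(float)
    return _pearson_flat(t - estimates_a.to_numpy(float), t - estimates_b.to_numpy(float))
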