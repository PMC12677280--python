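"""Quantile categorization, the conventional baseline AMC is compared against."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amc import Categorization

__all__ = ["QuantileConfig", "quantile_fit"]


@dataclass(frozen=True)
class QuantileConfig:
    """Number of equal-probability bins (quartiles by default)."""

    n_bins: int = 4

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def quantile_fit(
    values: np.ndarray,
    config: QuantileConfig = QuantileConfig(),
    predictor_name: str = "",
) -> Categorization:
    """Bin a predictor at its empirical quantiles.

    Thresholds sit at the order-statistic quantiles i/n_bins (inverted-CDF
    definition, so cuts land on observed values) and are inclusive upper
    bounds, matching AMC's assignment convention.  Under zero inflation
    several quantiles coincide; duplicated edges are collapsed, so the fitted
    k may be smaller than n_bins.  A constant predictor yields a degenerate
    single-category fit.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.unique(x).size < 2:
        return Categorization(
            predictor_name=predictor_name,
            thresholds=(),
            category_counts=(x.size,),
            method="quantile",
            degenerate=True,
        )
    probs = np.arange(1, config.n_bins) / config.n_bins
    edges = np.quantile(x, probs, method="inverted_cdf")
    edges = np.unique(edges)
    # an edge at the maximum would leave the top category empty
    edges = edges[edges < x.max()]
    codes = np.searchsorted(edges, x, side="left")
    counts = np.bincount(codes, minlength=edges.size + 1)
    return Categorization(
        predictor_name=predictor_name,
        thresholds=tuple(float(e) for e in edges),
        category_counts=tuple(int(c) for c in counts),
        method="quantile",
        degenerate=edges.size == 0,
    )
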