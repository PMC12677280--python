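"""Cohort-wide comparison of the five association methods.

For every non-degenerate predictor the battery fits AMC and quantile
categorizations and produces five association results (chi-square and
linear trend on each categorization, plus the trend test on the raw
values).  Degenerate predictors — constant, or collapsing to a single
category under either categorizer — are excluded from all five methods
symmetrically, so per-method summaries average over identical predictor
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amc import AMCConfig, DegeneratePredictorError, amc_fit, assign
from .baselines import QuantileConfig, quantile_fit
from .stats import AssociationResult, associate
from .synthetic import CohortTable

__all__ = [
    "ComparisonSummary",
    "run_five_methods",
    "aggregate_by_dictionary",
    "risk_profile",
    "results_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-method and per-dictionary summaries of an association battery."""

    method_means: pd.DataFrame  # index method; columns mean_minus_log10_p, n
    dictionary_means: pd.DataFrame  # (dictionary, method) rows with mean p / effects
    excluded: tuple[str, ...]  # predictors dropped as degenerate


def run_five_methods(
    cohort: CohortTable,
    amc_config: AMCConfig = AMCConfig(),
    quantile_config: QuantileConfig = QuantileConfig(),
) -> list[AssociationResult]:
    """Run all five association methods on every testable predictor.

    Returns exactly five AssociationResults per non-degenerate predictor, in
    predictor order.  Raises if no predictor is testable.
    """
    results: list[AssociationResult] = []
    tested = 0
    for name in cohort.predictor_names:
        x = cohort.predictor(name)
        try:
            amc_cat = amc_fit(x, amc_config, predictor_name=name)
            q_cat = quantile_fit(x, quantile_config, predictor_name=name)
            if amc_cat.degenerate or q_cat.degenerate:
                raise DegeneratePredictorError(name)
            batch = [
                associate(x, cohort.outcome, "amc_chi", amc_cat),
                associate(x, cohort.outcome, "amc_linear", amc_cat),
                associate(x, cohort.outcome, "quantile_chi", q_cat),
                associate(x, cohort.outcome, "quantile_linear", q_cat),
                associate(x, cohort.outcome, "untransformed_linear", None, name),
            ]
        except DegeneratePredictorError:
            log.warning("predictor %s is degenerate; excluded from all methods", name)
            continue
        results.extend(batch)
        tested += 1
    if tested == 0:
        raise DegeneratePredictorError("no testable predictor in cohort")
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy frame of association results (one row per predictor x method)."""
    return pd.DataFrame(
        {
            "predictor": [r.predictor_name for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "minus_log10_p": [r.minus_log10_p for r in results],
            "effect_size": [r.effect_size for r in results],
            "effect_type": [r.effect_type for r in results],
            "flag": [r.flag for r in results],
        }
    )


def aggregate_by_dictionary(
    results: list[AssociationResult],
    dictionary_map: dict[str, str] | None,
) -> ComparisonSummary:
    """Mean significance and effect sizes per method, overall and by
    text-category dictionary; unmapped predictors fall in "unassigned"."""
    df = results_frame(results)
    mapping = dictionary_map or {}
    df["dictionary"] = [mapping.get(p, "unassigned") for p in df["predictor"]]

    method_means = (
        df.groupby("method")
        .agg(mean_minus_log10_p=("minus_log10_p", "mean"), n=("predictor", "count"))
        .sort_values("mean_minus_log10_p", ascending=False)
    )
    dictionary_means = (
        df.groupby(["dictionary", "method"])
        .agg(
            n=("predictor", "count"),
            mean_minus_log10_p=("minus_log10_p", "mean"),
            mean_effect_size=("effect_size", "mean"),
        )
        .reset_index()
    )
    tested = set(df["predictor"])
    excluded = tuple(sorted(set(mapping) - tested)) if mapping else ()
    return ComparisonSummary(method_means, dictionary_means, excluded)


def risk_profile(codes: np.ndarray, outcome: np.ndarray) -> np.ndarray:
    """Observed case proportion per ordered category (codes 1..k)."""
    codes = np.asarray(codes)
    y = np.asarray(outcome)
    if codes.shape != y.shape:
        raise ValueError("codes and outcome must have equal length")
    k = int(codes.max())
    totals = np.bincount(codes, minlength=k + 1)[1:]
    cases = np.bincount(codes[y == 1], minlength=k + 1)[1:]
    if np.any(totals == 0):
        raise ValueError("codes must be dense 1..k")
    return cases / totals
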