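"""Undersampling sensitivity analysis: AMC vs quantile at small sample sizes.

Repeatedly draws smaller case/control subsets without replacement, re-fits
both categorizations inside each subsample, chi-squares both against the
outcome, and records per-iteration the fraction of predictors on which AMC
attains the more significant p-value ("win fraction") and the mean phi of
each arm.  Defaults follow the emulated study: scenarios of 500 cases /
2000 controls and 1000 cases / 4000 controls, 100 iterations, restricted to
the top-20 predictors by full-cohort AMC chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amc import AMCConfig, DegeneratePredictorError, amc_fit, assign
from .baselines import QuantileConfig, quantile_fit
from .stats import chi_square, contingency, phi
from .synthetic import CohortTable

__all__ = ["SubsampleConfig", "SubsampleReport", "subsample_cohort", "run_experiment", "top_predictors"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsampleConfig:
    scenarios: tuple[tuple[int, int], ...] = ((500, 2000), (1000, 4000))
    n_iterations: int = 100
    predictor_subset: tuple[str, ...] = ()  # empty -> top 20 by AMC chi-square
    n_top: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class SubsampleReport:
    """Per-scenario aggregates across iterations (win fraction in [0, 1])."""

    table: pd.DataFrame
    # columns: n_cases, n_controls, n_iterations, mean_win_fraction,
    # sd_win_fraction, amc_mean_phi, amc_sd_phi, quantile_mean_phi,
    # quantile_sd_phi


def subsample_cohort(
    cohort: CohortTable, n_cases: int, n_controls: int, seed: int
) -> CohortTable:
    """Uniform within-class sampling without replacement, seeded."""
    if n_cases > cohort.n_cases or n_controls > cohort.n_controls:
        raise ValueError(
            f"requested {n_cases}/{n_controls} but cohort has "
            f"{cohort.n_cases} cases / {cohort.n_controls} controls"
        )
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(cohort.outcome == 1)
    control_idx = np.flatnonzero(cohort.outcome == 0)
    keep = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    keep.sort()
    return CohortTable(
        subject_id=cohort.subject_id[keep],
        outcome=cohort.outcome[keep],
        values=cohort.values[keep],
        predictor_names=cohort.predictor_names,
        dictionary_map=cohort.dictionary_map,
    )


def top_predictors(
    cohort: CohortTable, n_top: int, amc_config: AMCConfig = AMCConfig()
) -> tuple[str, ...]:
    """The n_top predictors ranked by full-cohort AMC chi-square -log10 p."""
    scored: list[tuple[float, str]] = []
    for name in cohort.predictor_names:
        x = cohort.predictor(name)
        cat = amc_fit(x, amc_config, predictor_name=name)
        if cat.degenerate:
            continue
        codes = assign(x, cat)
        _, _, mlp = chi_square(contingency(codes, cohort.outcome))
        scored.append((mlp, name))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return tuple(name for _, name in scored[:n_top])


def run_experiment(
    cohort: CohortTable,
    config: SubsampleConfig = SubsampleConfig(),
    amc_config: AMCConfig = AMCConfig(),
    quantile_config: QuantileConfig = QuantileConfig(),
    fit_amc: "callable | None" = None,
    fit_quantile: "callable | None" = None,
) -> SubsampleReport:
    """Run the undersampling comparison for every configured scenario.

    Within each iteration both categorizers are re-fit on the subsample; a
    predictor degenerate in that subsample is dropped from the iteration's
    denominator.  Ties in -log10 p are broken by a fair coin so that two
    identical arms average to a 0.5 win fraction.  ``fit_amc`` /
    ``fit_quantile`` override the arm categorizers (signature
    ``(values, predictor_name) -> Categorization``), e.g. to run a
    same-categorizer symmetry control.
    """
    if fit_amc is None:
        fit_amc = lambda x, name: amc_fit(x, amc_config, predictor_name=name)
    if fit_quantile is None:
        fit_quantile = lambda x, name: quantile_fit(x, quantile_config, predictor_name=name)
    subset = config.predictor_subset or top_predictors(cohort, config.n_top, amc_config)
    rows = []
    for n_cases, n_controls in config.scenarios:
        seed_seq = np.random.SeedSequence([config.seed, n_cases, n_controls])
        iter_seeds = seed_seq.generate_state(config.n_iterations)
        tie_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_777_777]))
        win_fracs, amc_phis, q_phis = [], [], []
        for it in range(config.n_iterations):
            sub = subsample_cohort(
                cohort, n_cases, n_controls, int(iter_seeds[it]) & 0x7FFFFFFF
            )
            wins, denom = 0, 0
            amc_iter, q_iter = [], []
            for name in subset:
                x = sub.predictor(name)
                amc_cat = fit_amc(x, name)
                q_cat = fit_quantile(x, name)
                if amc_cat.degenerate or q_cat.degenerate:
                    log.info("iteration %d: predictor %s degenerate, dropped", it, name)
                    continue
                t_amc = contingency(assign(x, amc_cat), sub.outcome)
                t_q = contingency(assign(x, q_cat), sub.outcome)
                _, _, mlp_amc = chi_square(t_amc)
                _, _, mlp_q = chi_square(t_q)
                if mlp_amc > mlp_q:
                    wins += 1
                elif mlp_amc == mlp_q and tie_rng.random() < 0.5:
                    wins += 1
                denom += 1
                amc_iter.append(phi(t_amc))
                q_iter.append(phi(t_q))
            if denom == 0:
                raise DegeneratePredictorError(
                    f"iteration {it}: every subset predictor degenerate"
                )
            win_fracs.append(wins / denom)
            amc_phis.append(float(np.mean(amc_iter)))
            q_phis.append(float(np.mean(q_iter)))
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            {
                "n_cases": n_cases,
                "n_controls": n_controls,
                "n_iterations": config.n_iterations,
                "mean_win_fraction": float(np.mean(win_fracs)),
                "sd_win_fraction": sd(win_fracs),
                "amc_mean_phi": float(np.mean(amc_phis)),
                "amc_sd_phi": sd(amc_phis),
                "quantile_mean_phi": float(np.mean(q_phis)),
                "quantile_sd_phi": sd(q_phis),
            }
        )
    return SubsampleReport(pd.DataFrame(rows))
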