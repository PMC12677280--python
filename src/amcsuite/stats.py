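"""Association tests and effect sizes for case-control predictors.

Five methods are compared throughout the package, named by how the predictor
enters the test:

* ``amc_chi`` / ``quantile_chi`` — Pearson chi-square of the k x 2
  category-by-outcome table (effect size: phi = sqrt(chi2 / N), which equals
  Cramer's V for two-column tables);
* ``amc_linear`` / ``quantile_linear`` — logistic-regression linear-trend
  test on the integer category codes 1..k, i.e. assuming equal risk steps
  between adjacent categories (effect size: Cohen's d on the codes);
* ``untransformed_linear`` — the same trend test on the raw values.

All p-values are carried as -log10(p); zero-inflated predictors reach
significance levels far beyond double-precision underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._pvalues import chi2_minus_log10_sf, normal_two_sided_minus_log10_p
from .amc import Categorization, DegeneratePredictorError, assign

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "contingency",
    "chi_square",
    "phi",
    "logistic_trend",
    "cohens_d",
    "associate",
    "METHODS",
]

METHODS = (
    "amc_chi",
    "amc_linear",
    "quantile_chi",
    "quantile_linear",
    "untransformed_linear",
)


@dataclass(frozen=True)
class ContingencyTable:
    """k x 2 cross-tabulation; rows are ordered categories, columns are
    (case, control)."""

    counts: np.ndarray  # shape (k, 2), nonnegative integers
    name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("counts must be a k x 2 matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class AssociationResult:
    predictor_name: str
    method: str
    statistic: float
    df: int
    minus_log10_p: float
    effect_size: float
    effect_type: str  # "phi" | "cohens_d"
    flag: str = ""  # e.g. "separation" when the score fallback was used


def contingency(codes: np.ndarray, outcome: np.ndarray, name: str = "") -> ContingencyTable:
    """Cross-tabulate integer category codes 1..k against a binary outcome."""
    codes = np.asarray(codes)
    y = np.asarray(outcome)
    if codes.shape != y.shape:
        raise ValueError("codes and outcome must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    k = int(codes.max())
    cases = np.bincount(codes[y == 1], minlength=k + 1)[1:]
    controls = np.bincount(codes[y == 0], minlength=k + 1)[1:]
    return ContingencyTable(np.column_stack([cases, controls]), name=name)


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) with log-scale tail.

    Returns (statistic, df, -log10 p).  df = k - 1 for a k x 2 table.
    """
    obs = table.counts.astype(float)
    if obs.shape[0] < 2:
        raise DegeneratePredictorError("chi-square needs at least two categories")
    if np.any(table.row_totals == 0) or np.any(table.column_totals == 0):
        raise ValueError("chi-square undefined with an empty row or column")
    expected = np.outer(table.row_totals, table.column_totals) / table.n
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.shape[0] - 1
    return stat, df, chi2_minus_log10_sf(stat, df)


def phi(table: ContingencyTable) -> float:
    """Phi coefficient sqrt(chi2 / N); Cramer's V for a k x 2 table."""
    stat, _, _ = chi_square(table)
    return float(np.sqrt(stat / table.n))


def logistic_trend(
    x: np.ndarray, outcome: np.ndarray, test: str = "wald"
) -> tuple[float, float, float, str]:
    """Univariate logistic regression trend test of a binary outcome on x.

    Returns (slope, statistic, -log10 p, flag).  ``test`` selects the Wald z
    (default) or likelihood-ratio statistic.  Under (quasi-)complete
    separation the MLE diverges; the slope is reported as fitted and the
    p-value falls back to the score test, flagged "separation".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor has no trend")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(fit.params[1])
        se = float(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        separated = (not converged) or not np.isfinite(se) or se > 1e6 or abs(slope) > 50
    except Exception:
        slope, separated = np.nan, True
    if separated:
        z = _score_z(x, y)
        return slope, float(z), normal_two_sided_minus_log10_p(z), "separation"
    if test == "wald":
        z = slope / se
        return slope, float(z), normal_two_sided_minus_log10_p(z), ""
    if test == "lr":
        llr = 2.0 * (fit.llf - fit.llnull)
        return slope, float(llr), chi2_minus_log10_sf(llr, 1), ""
    raise ValueError(f"unknown test {test!r}")


def _score_z(x: np.ndarray, y: np.ndarray) -> float:
    """Score (Rao) z statistic for the logistic slope at beta = 0.

    Equivalent to the Cochran-Armitage trend statistic when x holds ordinal
    scores; finite even under complete separation.
    """
    p0 = y.mean()
    u = float(np.sum(x * (y - p0)))
    v = p0 * (1 - p0) * float(np.sum((x - x.mean()) ** 2))
    return u / np.sqrt(v)


def cohens_d(x: np.ndarray, outcome: np.ndarray) -> float:
    """|mean(case) - mean(control)| over the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(outcome)
    g1, g0 = x[y == 1], x[y == 0]
    if g1.size < 2 or g0.size < 2:
        raise ValueError("both groups need at least two observations")
    s1, s0 = g1.var(ddof=1), g0.var(ddof=1)
    pooled = np.sqrt(((g1.size - 1) * s1 + (g0.size - 1) * s0) / (g1.size + g0.size - 2))
    if pooled == 0:
        raise DegeneratePredictorError("pooled standard deviation is zero")
    return float(abs(g1.mean() - g0.mean()) / pooled)


def associate(
    values: np.ndarray,
    outcome: np.ndarray,
    method: str,
    categorization: Categorization | None = None,
    predictor_name: str | None = None,
) -> AssociationResult:
    """Run one of the five association methods on one predictor.

    Categorical methods take the fitted categorization's codes through the
    chi-square test with phi; linear methods take the codes (or the raw
    values for ``untransformed_linear``) through the logistic trend test with
    Cohen's d.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    name = predictor_name if predictor_name is not None else (
        categorization.predictor_name if categorization is not None else ""
    )
    if method == "untransformed_linear":
        x = np.asarray(values, dtype=float)
    else:
        if categorization is None:
            raise ValueError(f"method {method!r} requires a categorization")
        if categorization.degenerate or categorization.k < 2:
            raise DegeneratePredictorError(
                f"{name or 'predictor'}: single-category fit cannot be tested"
            )
        x = assign(values, categorization).astype(float)
    if method.endswith("_chi"):
        table = contingency(x.astype(int), np.asarray(outcome), name=name)
        stat, df, mlp = chi_square(table)
        return AssociationResult(name, method, stat, df, mlp, phi(table), "phi")
    slope, stat, mlp, flag = logistic_trend(x, outcome)
    d = cohens_d(x, outcome)
    return AssociationResult(name, method, stat, 1, mlp, d, "cohens_d", flag)
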