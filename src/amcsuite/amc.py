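"""Adaptive-mixture-categorization (AMC) of continuous predictors.

AMC converts a continuous, typically zero-inflated and right-skewed variable
into ordered categories by a greedy threshold search.  The loss for a
candidate set of thresholds is the reciprocal of the one-way ANOVA F
statistic of the induced grouping — i.e. the ratio of within-category to
between-category variation — so each step picks the cut that best preserves
variance after discretisation.  The number of categories k is chosen by the
F-test p-value (not the raw loss, which always improves with k), and sparse
tail categories are merged leftward afterwards so every category keeps a
minimum occupancy.

Thresholds are *inclusive upper bounds* placed at observed data values:
category i is ``t_{i-1} < x <= t_i`` with t_0 = -inf and t_k = +inf.  The
search considers only cuts at the lower edge of the largest gaps between
adjacent distinct values, which preserves the solution in practice while
making the search linear in the number of candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pvalues import f_minus_log10_sf

__all__ = [
    "AMCConfig",
    "FResult",
    "Categorization",
    "DegeneratePredictorError",
    "anova_f",
    "loss",
    "candidate_gaps",
    "greedy_step",
    "amc_fit",
    "merge_sparse",
    "assign",
]


class DegeneratePredictorError(ValueError):
    """Raised when a predictor cannot support the requested operation
    (constant values, empty categories, undefined variance)."""


@dataclass(frozen=True)
class AMCConfig:
    """Tuning knobs of the AMC search.

    k_max: largest number of categories tried by the linear search.
    min_category_size: occupancy floor; sparser categories are merged left.
    max_gap_candidates: number of largest data gaps kept as cut candidates.
    """

    k_max: int = 10
    min_category_size: int = 20
    max_gap_candidates: int = 1000

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.min_category_size < 1:
            raise ValueError("min_category_size must be >= 1")
        if self.max_gap_candidates < 1:
            raise ValueError("max_gap_candidates must be >= 1")


@dataclass(frozen=True)
class FResult:
    """One-way ANOVA decomposition driving the AMC loss."""

    between_ss: float
    within_ss: float
    df_between: int
    df_within: int
    f_stat: float
    minus_log10_p: float

    @property
    def loss(self) -> float:
        """Reciprocal of F: within-to-between variation ratio (0 when F is inf)."""
        if np.isinf(self.f_stat):
            return 0.0
        if self.f_stat == 0.0:
            return np.inf
        return 1.0 / self.f_stat


@dataclass(frozen=True)
class Categorization:
    """A fitted binning of one predictor.

    ``thresholds`` are strictly increasing inclusive upper bounds; the number
    of categories is ``k = len(thresholds) + 1``.  ``category_counts`` are the
    training-data occupancies.  ``selection_minus_log10_p`` is the F-test
    significance at the selected k (AMC only; NaN for quantile fits).
    ``degenerate`` marks constant predictors (k = 1), which downstream
    association tests must exclude.
    """

    predictor_name: str
    thresholds: tuple[float, ...]
    category_counts: tuple[int, ...]
    method: str  # "amc" | "quantile"
    selection_minus_log10_p: float = float("nan")
    degenerate: bool = False

    @property
    def k(self) -> int:
        return len(self.thresholds) + 1

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.category_counts) != len(self.thresholds) + 1:
            raise ValueError("category_counts must have len(thresholds)+1 entries")


# ---------------------------------------------------------------------------
# ANOVA primitives
# ---------------------------------------------------------------------------

def anova_f(values: np.ndarray, category_codes: np.ndarray) -> FResult:
    """One-way ANOVA of ``values`` grouped by integer ``category_codes``.

    Codes may be any integers; every distinct code present defines one group
    and every group must be nonempty by construction.  Requires at least two
    groups and n >= k + 1 so both degrees of freedom are positive.
    """
    x = np.asarray(values, dtype=float)
    codes = np.asarray(category_codes)
    if x.shape != codes.shape:
        raise ValueError("values and category_codes must have equal length")
    _, inv = np.unique(codes, return_inverse=True)
    k = int(inv.max()) + 1
    n = x.size
    if k < 2:
        raise DegeneratePredictorError("ANOVA needs at least two categories")
    if n < k + 1:
        raise ValueError(f"need n >= k+1 observations (n={n}, k={k})")
    counts = np.bincount(inv, minlength=k).astype(float)
    sums = np.bincount(inv, weights=x, minlength=k)
    grand_mean = x.mean()
    total_ss = float(np.sum((x - grand_mean) ** 2))
    between_ss = float(np.sum(sums**2 / counts) - x.sum() ** 2 / n)
    between_ss = max(between_ss, 0.0)
    within_ss = max(total_ss - between_ss, 0.0)
    return _f_from_ss(between_ss, within_ss, k, n)


def _f_from_ss(between_ss: float, within_ss: float, k: int, n: int) -> FResult:
    df_between = k - 1
    df_within = n - k
    # relative zero guard: SS differences below machine noise count as zero
    scale = between_ss + within_ss
    if within_ss <= 1e-12 * scale or within_ss == 0.0:
        return FResult(between_ss, 0.0, df_between, df_within, np.inf, np.inf)
    f_stat = (between_ss / df_between) / (within_ss / df_within)
    return FResult(
        between_ss,
        within_ss,
        df_between,
        df_within,
        f_stat,
        f_minus_log10_sf(f_stat, df_between, df_within),
    )


def loss(values: np.ndarray, thresholds: np.ndarray) -> float:
    """AMC loss of a threshold set: within-SS / between-SS scaled by dfs (1/F).

    Thresholds are inclusive upper bounds; every induced category must be
    nonempty and the grouping non-constant.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant vector has no valid split")
    codes = np.searchsorted(t, x, side="left")  # code i iff t_{i-1} < x <= t_i
    counts = np.bincount(codes, minlength=t.size + 1)
    if np.any(counts == 0):
        raise ValueError("thresholds induce an empty category")
    return anova_f(x, codes).loss


# ---------------------------------------------------------------------------
# Gap candidates
# ---------------------------------------------------------------------------

def candidate_gaps(values: np.ndarray, max_candidates: int) -> np.ndarray:
    """Thresholds at the lower edges of the ``max_candidates`` largest gaps.

    A gap is the difference between adjacent *distinct* sorted values; its
    candidate threshold is the smaller of the two values, so the cut
    ``x <= t`` severs exactly that gap.  Returned sorted ascending.  Equal
    gap sizes are broken toward the smaller threshold.
    """
    distinct = np.unique(np.asarray(values, dtype=float))
    if distinct.size < 2:
        return np.empty(0, dtype=float)
    gaps = np.diff(distinct)
    lower = distinct[:-1]
    if max_candidates < gaps.size:
        # stable sort on -gap keeps ties in ascending-threshold order
        order = np.argsort(-gaps, kind="stable")[:max_candidates]
        lower = lower[order]
    return np.sort(lower)


# ---------------------------------------------------------------------------
# Greedy search over sorted-data prefix sums
# ---------------------------------------------------------------------------

class _SortedView:
    """Prefix-sum machinery over the sorted sample.

    Because thresholds live on the value axis, every category is a contiguous
    block of the sorted sample; group sums (and hence the full ANOVA
    decomposition) for any boundary set come from two prefix-sum lookups per
    category, making each greedy sweep O(#candidates * k) instead of
    O(#candidates * n).
    """

    def __init__(self, values: np.ndarray):
        x = np.sort(np.asarray(values, dtype=float))
        self.x = x
        self.n = x.size
        self.cum = np.concatenate(([0.0], np.cumsum(x)))
        self.total = self.cum[-1]
        grand_mean = self.total / self.n
        self.total_ss = float(np.sum((x - grand_mean) ** 2))
        self.mean_sq_total = self.total**2 / self.n

    def positions(self, thresholds: np.ndarray) -> np.ndarray:
        """Boundary positions: #values <= t for each threshold."""
        return np.searchsorted(self.x, thresholds, side="right")

    def between_ss(self, bounds: np.ndarray) -> float:
        """Between-group SS for boundary positions (excluding 0 and n)."""
        edges = np.concatenate(([0], bounds, [self.n]))
        cnt = np.diff(edges).astype(float)
        seg = np.diff(self.cum[edges])
        return float(np.sum(seg**2 / cnt) - self.mean_sq_total)

    def f_result(self, bounds: np.ndarray) -> FResult:
        k = bounds.size + 1
        between = max(self.between_ss(bounds), 0.0)
        within = max(self.total_ss - between, 0.0)
        return _f_from_ss(between, within, k, self.n)


def greedy_step(
    values: np.ndarray,
    fixed_thresholds: np.ndarray,
    candidates: np.ndarray,
) -> tuple[float, FResult]:
    """Best single threshold to add to ``fixed_thresholds``.

    Evaluates every candidate cut jointly with the fixed cuts and returns the
    one minimising the loss (equivalently maximising F), ties broken toward
    the smaller threshold.  Raises DegeneratePredictorError when no candidate
    yields a valid refinement (search exhaustion).
    """
    sv = _SortedView(values)
    return _greedy_step_sv(sv, np.asarray(fixed_thresholds, float), np.asarray(candidates, float))


def _greedy_step_sv(
    sv: _SortedView, fixed: np.ndarray, candidates: np.ndarray
) -> tuple[float, FResult]:
    if candidates.size == 0:
        raise DegeneratePredictorError("no remaining candidate thresholds")
    fixed_pos = sv.positions(np.sort(fixed)) if fixed.size else np.empty(0, dtype=int)
    cand_pos = sv.positions(candidates)
    # drop candidates duplicating a fixed boundary or cutting nothing
    ok = (cand_pos > 0) & (cand_pos < sv.n)
    if fixed_pos.size:
        ok &= ~np.isin(cand_pos, fixed_pos)
    if not np.any(ok):
        raise DegeneratePredictorError("candidate set exhausted")
    candidates = candidates[ok]
    cand_pos = cand_pos[ok]

    base_between = sv.between_ss(fixed_pos) if fixed_pos.size else 0.0
    # segment of the fixed partition containing each candidate
    edges = np.concatenate(([0], fixed_pos, [sv.n]))
    seg_idx = np.searchsorted(edges, cand_pos, side="right") - 1
    lo = edges[seg_idx]
    hi = edges[seg_idx + 1]
    seg_sum = sv.cum[hi] - sv.cum[lo]
    seg_cnt = (hi - lo).astype(float)
    left_sum = sv.cum[cand_pos] - sv.cum[lo]
    left_cnt = (cand_pos - lo).astype(float)
    right_sum = seg_sum - left_sum
    right_cnt = seg_cnt - left_cnt
    between = (
        base_between
        - seg_sum**2 / seg_cnt
        + left_sum**2 / left_cnt
        + right_sum**2 / right_cnt
    )
    # maximise between-SS == maximise F at fixed k; ties -> smaller threshold
    best = int(np.argmax(between))
    if np.isclose(between[best], between, rtol=1e-12, atol=0.0).sum() > 1:
        tied = np.isclose(between, between[best], rtol=1e-12, atol=0.0)
        best = int(np.flatnonzero(tied)[0])
    new_t = float(candidates[best])
    bounds = np.sort(np.append(fixed_pos, cand_pos[best]))
    return new_t, sv.f_result(bounds)


def amc_fit(
    values: np.ndarray,
    config: AMCConfig = AMCConfig(),
    predictor_name: str = "",
) -> Categorization:
    """Fit an AMC categorization to one predictor.

    The linear search starts at k = 2 and adds one threshold per step, each
    chosen greedily with earlier thresholds held fixed; the selected k
    maximises the F-test -log10 p along the path (ties toward smaller k).
    Sparse categories (below ``config.min_category_size``) are then merged
    into their left neighbour.  A constant predictor yields a degenerate
    single-category result.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        return Categorization(
            predictor_name=predictor_name,
            thresholds=(),
            category_counts=(x.size,),
            method="amc",
            degenerate=True,
        )
    sv = _SortedView(x)
    pool = list(candidate_gaps(x, config.max_gap_candidates))
    chosen: list[float] = []
    path_p: list[float] = []  # minus_log10_p at k = 2, 3, ...
    k_cap = min(config.k_max, x.size - 1)
    while len(chosen) + 2 <= k_cap and pool:
        remaining = np.array([c for c in pool if c not in chosen], dtype=float)
        try:
            new_t, fres = _greedy_step_sv(sv, np.array(chosen, dtype=float), remaining)
        except DegeneratePredictorError:
            break
        chosen.append(new_t)
        path_p.append(fres.minus_log10_p)
        if np.isinf(fres.minus_log10_p):
            break  # perfect separation: no further split can beat it
    if not chosen:
        return Categorization(
            predictor_name=predictor_name,
            thresholds=(),
            category_counts=(x.size,),
            method="amc",
            degenerate=True,
        )
    best_step = int(np.argmax(path_p))  # argmax takes the first max: smaller k
    thresholds = np.sort(np.array(chosen[: best_step + 1], dtype=float))
    counts = np.diff(np.concatenate(([0], sv.positions(thresholds), [sv.n])))
    cat = Categorization(
        predictor_name=predictor_name,
        thresholds=tuple(thresholds),
        category_counts=tuple(int(c) for c in counts),
        method="amc",
        selection_minus_log10_p=float(path_p[best_step]),
    )
    return merge_sparse(cat, config.min_category_size)


def merge_sparse(cat: Categorization, min_size: int) -> Categorization:
    """Merge categories with fewer than ``min_size`` members into their left
    neighbour (the leftmost category, lacking one, merges right), repeating
    until every category meets the floor or a single category remains."""
    counts = list(cat.category_counts)
    thresholds = list(cat.thresholds)
    while len(counts) > 1:
        sparse = [i for i, c in enumerate(counts) if c < min_size]
        if not sparse:
            break
        i = sparse[0]
        if i == 0:
            counts[1] += counts[0]
            del counts[0]
            del thresholds[0]
        else:
            counts[i - 1] += counts[i]
            del counts[i]
            del thresholds[i - 1]
    return Categorization(
        predictor_name=cat.predictor_name,
        thresholds=tuple(thresholds),
        category_counts=tuple(counts),
        method=cat.method,
        selection_minus_log10_p=cat.selection_minus_log10_p,
        degenerate=len(counts) == 1,
    )


def assign(values: np.ndarray, cat: Categorization) -> np.ndarray:
    """Integer codes 1..k: code i iff t_{i-1} < x <= t_i (open-ended tails)."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(cat.thresholds, dtype=float)
    return np.searchsorted(t, x, side="left") + 1
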