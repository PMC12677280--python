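"""AMC core: ANOVA decomposition, gap candidates, greedy search, merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amcsuite import (
    AMCConfig,
    Categorization,
    DegeneratePredictorError,
    amc_fit,
    anova_f,
    assign,
    candidate_gaps,
    greedy_step,
    loss,
    merge_sparse,
)


# --- independent brute-force oracles -------------------------------------

def oracle_anova(values, codes):
    """Plain group-by ANOVA, no prefix sums."""
    values = np.asarray(values, float)
    groups = [values[codes == c] for c in np.unique(codes)]
    grand = values.mean()
    between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return between, within


def oracle_loss(values, thresholds):
    """1/F via the plain decomposition."""
    values = np.asarray(values, float)
    codes = np.searchsorted(np.sort(thresholds), values, side="left")
    b, w = oracle_anova(values, codes)
    k, n = len(thresholds) + 1, values.size
    if w == 0:
        return 0.0
    return (w / (n - k)) / (b / (k - 1))


# --- anova_f --------------------------------------------------------------

def test_anova_hand_example():
    """Two groups {1,2,3} and {10,11,12}: means 2 and 11, grand mean 6.5."""
    fr = anova_f(np.array([1, 2, 3, 10, 11, 12.0]), np.array([1, 1, 1, 2, 2, 2]))
    assert fr.between_ss == pytest.approx(121.5)
    assert fr.within_ss == pytest.approx(4.0)
    assert fr.f_stat == pytest.approx(121.5)
    assert fr.df_between == 1 and fr.df_within == 4
    assert fr.loss == pytest.approx(1 / 121.5)


def test_anova_ss_partition_random(rng):
    """between + within equals total SS on random groupings."""
    x = rng.gamma(2, 1, size=300)
    codes = rng.integers(0, 4, size=300)
    fr = anova_f(x, codes)
    total = ((x - x.mean()) ** 2).sum()
    assert fr.between_ss + fr.within_ss == pytest.approx(total, rel=1e-9)
    b, w = oracle_anova(x, codes)
    assert fr.between_ss == pytest.approx(b, rel=1e-9)
    assert fr.within_ss == pytest.approx(w, rel=1e-9)


def test_anova_zero_within_is_infinite_f():
    fr = anova_f(np.array([2.0, 2, 2, 7, 7, 7]), np.array([0, 0, 0, 1, 1, 1]))
    assert fr.within_ss == 0.0
    assert np.isinf(fr.f_stat)
    assert fr.loss == 0.0
    assert np.isinf(fr.minus_log10_p)


def test_anova_single_group_errors():
    with pytest.raises(DegeneratePredictorError):
        anova_f(np.array([1.0, 2, 3]), np.array([1, 1, 1]))


# --- loss -----------------------------------------------------------------

def test_loss_examples():
    x = np.array([1, 2, 3, 10, 11, 12.0])
    assert loss(x, np.array([3.0])) == pytest.approx(1 / 121.5)
    two_point = np.array([0.0] * 10 + [5.0] * 10)
    assert loss(two_point, np.array([0.0])) == 0.0
    with pytest.raises(DegeneratePredictorError):
        loss(np.full(10, 3.0), np.array([3.0]))


def test_loss_empty_category_errors():
    with pytest.raises(ValueError):
        loss(np.array([1.0, 2, 3]), np.array([5.0, 6.0]))


# --- candidate_gaps -------------------------------------------------------

@pytest.mark.parametrize(
    "values,max_c,expected",
    [
        ([0, 0, 0, 1, 5, 100], 2, [1.0, 5.0]),  # gaps 1, 4, 95 -> keep 5 and 1
        ([0, 0, 7, 7], 10, [0.0]),
        ([0, 0, 0, 1, 5, 100], 99, [0.0, 1.0, 5.0]),  # no truncation
        ([3, 3, 3], 5, []),  # constant -> no candidates
    ],
)
def test_candidate_gaps(values, max_c, expected):
    got = candidate_gaps(np.array(values, float), max_c)
    assert got.tolist() == expected


# --- greedy_step ----------------------------------------------------------

def test_greedy_first_split_exhaustive():
    """On two well-separated clusters the first cut severs the big gap."""
    x = np.array([1, 2, 3, 10, 11, 12.0])
    cands = candidate_gaps(x, 100)
    t, fres = greedy_step(x, np.array([]), cands)
    assert t == 3.0
    best = min(oracle_loss(x, [c]) for c in cands)
    assert fres.loss == pytest.approx(best, rel=1e-9)


def test_greedy_second_step_exhaustive(rng):
    """With one threshold fixed between two clusters, the second step picks
    the exhaustive-best intra-cluster split."""
    x = np.concatenate([rng.normal(0, 1, 40), rng.normal(20, 3, 40)])
    cands = candidate_gaps(x, 1000)
    t1, _ = greedy_step(x, np.array([]), cands)
    rest = cands[cands != t1]
    t2, fres = greedy_step(x, np.array([t1]), rest)
    losses = [oracle_loss(x, sorted([t1, c])) for c in rest]
    assert fres.loss == pytest.approx(min(losses), rel=1e-9)


def test_greedy_single_candidate():
    x = np.array([0.0, 0, 0, 5, 5, 5])
    t, _ = greedy_step(x, np.array([]), np.array([0.0]))
    assert t == 0.0


def test_greedy_exhaustion_errors():
    x = np.array([0.0, 0, 5, 5])
    with pytest.raises(DegeneratePredictorError):
        greedy_step(x, np.array([0.0]), np.array([0.0]))


# --- amc_fit --------------------------------------------------------------

def test_fit_perfect_two_point_mixture():
    """30 zeros + 30 fives: the only cut is 0.0 and it separates perfectly."""
    x = np.array([0.0] * 30 + [5.0] * 30)
    cat = amc_fit(x)
    assert cat.thresholds == (0.0,)
    assert cat.k == 2
    assert cat.category_counts == (30, 30)
    assert not cat.degenerate
    assert np.isinf(cat.selection_minus_log10_p)


def test_fit_constant_predictor_degenerate():
    cat = amc_fit(np.full(100, 2.5))
    assert cat.degenerate and cat.k == 1
    assert cat.category_counts == (100,)


def test_fit_greedy_path_matches_exhaustive(rng):
    """At every k along the linear search the chosen cut achieves the
    exhaustive minimum loss over the same candidate set."""
    for _ in range(10):
        x = np.concatenate(
            [
                np.zeros(rng.integers(10, 30)),
                rng.lognormal(0, 1, rng.integers(20, 40)),
                rng.lognormal(2.5, 0.3, rng.integers(10, 30)),
            ]
        )
        cands = candidate_gaps(x, 1000)
        fixed = []
        for _k in range(2, 5):
            rest = np.array([c for c in cands if c not in fixed])
            if rest.size == 0:
                break
            t, fres = greedy_step(x, np.array(fixed), rest)
            best = min(oracle_loss(x, sorted(fixed + [c])) for c in rest)
            assert fres.loss == pytest.approx(best, rel=1e-9, abs=1e-12)
            fixed.append(t)


def test_fit_gap_restriction_consistency(rng):
    """With the candidate cap at least the number of distinct gaps, the
    restricted search equals the unrestricted one."""
    for _ in range(5):
        x = np.round(rng.lognormal(0, 1.2, 300), 2)
        full = amc_fit(x, AMCConfig(max_gap_candidates=10**6))
        capped = amc_fit(x, AMCConfig(max_gap_candidates=len(np.unique(x))))
        assert full.thresholds == capped.thresholds
        assert full.category_counts == capped.category_counts


def test_fit_ratio_monotone_along_path(rng):
    """The unscaled within/between ratio is non-increasing as k grows."""
    x = rng.lognormal(0, 1.5, 400)
    cands = candidate_gaps(x, 1000)
    fixed, ratios = [], []
    for _k in range(2, 8):
        rest = np.array([c for c in cands if c not in fixed])
        t, fres = greedy_step(x, np.array(fixed), rest)
        fixed.append(t)
        ratios.append(fres.within_ss / fres.between_ss)
    assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(ratios, ratios[1:]))


def test_fit_respects_min_category_size(rng):
    x = np.concatenate([np.zeros(200), rng.lognormal(1, 2, 300)])
    cat = amc_fit(x, AMCConfig(min_category_size=20))
    assert all(c >= 20 for c in cat.category_counts)
    assert sum(cat.category_counts) == x.size


# --- merge_sparse ---------------------------------------------------------

def _cat(counts, thresholds):
    return Categorization("p", tuple(thresholds), tuple(counts), "amc")


def test_merge_into_left_neighbour():
    out = merge_sparse(_cat([30, 5, 40], [1.0, 2.0]), 20)
    assert out.category_counts == (35, 40)
    assert out.thresholds == (2.0,)


def test_merge_leftmost_goes_right():
    out = merge_sparse(_cat([10, 300], [1.0]), 20)
    assert out.category_counts == (310,)
    assert out.thresholds == ()
    assert out.degenerate


def test_merge_cascades():
    out = merge_sparse(_cat([30, 5, 5, 5, 40], [1, 2, 3, 4.0]), 20)
    assert out.category_counts == (45, 40)
    assert sum(out.category_counts) == 85


# --- assign ---------------------------------------------------------------

def test_assign_inclusive_upper_bounds():
    cat = _cat([1, 1, 1], [0.0, 2.01])
    codes = assign(np.array([0.0, 1.5, 3.0]), cat)
    assert codes.tolist() == [1, 2, 3]
    # values beyond the training range fall in the last category
    assert assign(np.array([99.0]), cat).tolist() == [3]


def test_assign_no_thresholds_all_one():
    cat = Categorization("p", (), (5,), "amc", degenerate=True)
    assert assign(np.arange(5.0), cat).tolist() == [1] * 5


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_assign_roundtrip_reproduces_counts(seed):
    """assign(training data) reproduces the fitted category counts, and the
    codes partition the sample."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([np.zeros(rng.integers(5, 40)), rng.lognormal(0, 1.3, 60)])
    cat = amc_fit(x, AMCConfig(min_category_size=5))
    codes = assign(x, cat)
    counts = np.bincount(codes, minlength=cat.k + 1)[1:]
    assert counts.tolist() == list(cat.category_counts)
    assert codes.min() >= 1 and codes.max() <= cat.k
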