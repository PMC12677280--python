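"""Association tests: chi-square, phi, logistic trend, Cohen's d."""

import numpy as np
import pytest

from amcsuite import (
    ContingencyTable,
    DegeneratePredictorError,
    associate,
    chi_square,
    cohens_d,
    contingency,
    phi,
    quantile_fit,
)
from amcsuite.amc import Categorization
from amcsuite.stats import logistic_trend


def brute_chi2(counts):
    """Textbook sum over cells of (O - E)^2 / E."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    rows, cols = counts.sum(1), counts.sum(0)
    return sum(
        (counts[i, j] - rows[i] * cols[j] / n) ** 2 / (rows[i] * cols[j] / n)
        for i in range(counts.shape[0])
        for j in range(counts.shape[1])
    )


def test_contingency_basic():
    t = contingency(np.array([1, 1, 2]), np.array([1, 0, 1]))
    assert t.counts.tolist() == [[1, 1], [1, 0]]


def test_contingency_length_mismatch():
    with pytest.raises(ValueError):
        contingency(np.array([1, 2]), np.array([1]))


def test_chi_square_2x2_hand_formula():
    """[[10,90],[30,70]]: N(ad-bc)^2/(r1 r2 c1 c2) = 12.5 with df 1."""
    stat, df, mlp = chi_square(ContingencyTable(np.array([[10, 90], [30, 70]])))
    assert stat == pytest.approx(12.5)
    assert df == 1
    assert mlp == pytest.approx(-np.log10(4.07e-4), rel=1e-2)


def test_chi_square_independence_is_zero():
    stat, _, mlp = chi_square(ContingencyTable(np.array([[10, 20], [30, 60], [5, 10]])))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert mlp == pytest.approx(0.0, abs=1e-12)


def test_chi_square_matches_brute_force(rng):
    for _ in range(20):
        counts = rng.integers(1, 500, size=(rng.integers(2, 8), 2))
        stat, df, _ = chi_square(ContingencyTable(counts))
        assert stat == pytest.approx(brute_chi2(counts), rel=1e-12)
        assert df == counts.shape[0] - 1


def test_phi_identity_and_example(rng):
    t = ContingencyTable(np.array([[10, 90], [30, 70]]))
    assert phi(t) == pytest.approx(0.25)
    for _ in range(10):
        counts = rng.integers(1, 300, size=(rng.integers(2, 6), 2))
        table = ContingencyTable(counts)
        stat, _, _ = chi_square(table)
        assert phi(table) ** 2 * table.n == pytest.approx(stat, rel=1e-12)


def test_logistic_trend_closed_form_two_level():
    """Binary x: the fitted slope is the log odds ratio
    ln((30/70)/(10/90)) ~ 1.3499."""
    x = np.repeat([0.0, 1.0], 100)
    y = np.concatenate([np.repeat([1, 0], [10, 90]), np.repeat([1, 0], [30, 70])])
    slope, stat, mlp, flag = logistic_trend(x, y)
    assert slope == pytest.approx(np.log((30 / 70) / (10 / 90)), rel=1e-5)
    assert flag == ""
    assert mlp > -np.log10(0.05)


def test_logistic_trend_null_slope():
    """Equal case fractions at every level of a 3-level x give slope ~ 0."""
    x = np.repeat([1.0, 2.0, 3.0], 40)
    y = np.tile(np.repeat([1, 0], [10, 30]), 3)
    slope, _, mlp, _ = logistic_trend(x, y)
    assert slope == pytest.approx(0.0, abs=1e-8)
    assert mlp == pytest.approx(0.0, abs=1e-6)


def test_logistic_trend_constant_x_errors():
    with pytest.raises(DegeneratePredictorError):
        logistic_trend(np.ones(20), np.tile([0, 1], 10))


def test_logistic_trend_separation_falls_back_to_score():
    """Complete separation: Wald collapses, the score test still reports."""
    x = np.concatenate([np.zeros(30), np.ones(30)])
    y = np.concatenate([np.zeros(30), np.ones(30)]).astype(int)
    slope, stat, mlp, flag = logistic_trend(x, y)
    assert flag == "separation"
    assert np.isfinite(mlp) and mlp > 2


def test_logistic_trend_lr_close_to_wald(rng):
    x = rng.integers(1, 5, 500).astype(float)
    y = (rng.random(500) < 0.2 + 0.1 * (x - 1) / 3).astype(int)
    _, _, mlp_w, _ = logistic_trend(x, y, test="wald")
    _, _, mlp_lr, _ = logistic_trend(x, y, test="lr")
    assert mlp_w == pytest.approx(mlp_lr, rel=0.25, abs=0.3)


def test_cohens_d():
    x = np.array([0.0, 2.0, 1.0, 3.0])
    y = np.array([1, 1, 0, 0])
    assert cohens_d(x, y) == pytest.approx(1 / np.sqrt(2))
    # identical groups
    assert cohens_d(np.array([1.0, 2, 1, 2]), np.array([1, 1, 0, 0])) == 0.0
    # invariant under positive affine rescaling
    assert cohens_d(5 + 3 * x, y) == pytest.approx(cohens_d(x, y))
    with pytest.raises(DegeneratePredictorError):
        cohens_d(np.array([1.0, 1, 1, 1]), np.array([1, 1, 0, 0]))


def test_associate_dispatch(rng):
    x = np.concatenate([np.zeros(100), rng.lognormal(0, 1, 100)])
    y = rng.integers(0, 2, 200)
    y[:3] = [0, 1, 0]  # both classes guaranteed
    cat = quantile_fit(x)
    r_chi = associate(x, y, "quantile_chi", cat)
    assert r_chi.effect_type == "phi" and r_chi.df == cat.k - 1
    r_lin = associate(x, y, "quantile_linear", cat)
    assert r_lin.effect_type == "cohens_d"
    r_raw = associate(x, y, "untransformed_linear", None, "x")
    assert r_raw.predictor_name == "x"
    with pytest.raises(ValueError):
        associate(x, y, "nonsense", cat)


def test_associate_degenerate_categorization_errors():
    x = np.ones(50)
    y = np.tile([0, 1], 25)
    cat = Categorization("p", (), (50,), "amc", degenerate=True)
    with pytest.raises(DegeneratePredictorError):
        associate(x, y, "amc_linear", cat)
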