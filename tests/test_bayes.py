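import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from emofmri.bayes import (DEFAULT_CAUCHY_SCALE, bayes_correlation_bf,
                           binomial_bf, contingency_bf, grade_evidence,
                           jzs_one_sample_bf, jzs_two_sample_bf)


# ------------------------------------------------------------ JZS t-tests

def test_two_sample_from_summaries_matches_printed_cohort_values():
    """Printed group summaries of the study cohort reproduce the published
    common-log Bayes factors within rounding of the summaries."""
    rows = {
        (32.63, 9.13, 28.44, 7.95): -0.159,   # age
        (29.93, 0.26, 29.69, 0.60): -0.121,   # MMSE
        (1.75, 1.65, 1.63, 1.78): -0.466,     # HADS depression
        (13.31, 12.97, 11.93, 9.48): -0.450,  # MFIS fatigue
    }
    for (m1, s1, m2, s2), expected in rows.items():
        res = jzs_two_sample_bf((m1, s1, 16), (m2, s2, 16))
        assert res.log10_bf10 == pytest.approx(expected, abs=0.05)


def test_null_t_gives_equal_one_sided_factors():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    two = jzs_two_sample_bf(x, y)
    plus = jzs_two_sample_bf(x, y, direction="greater")
    minus = jzs_two_sample_bf(x, y, direction="less")
    assert plus.log10_bf10 == pytest.approx(minus.log10_bf10, abs=1e-8)
    assert two.bf10 < 1.0


def test_prior_splitting_identity_holds():
    """BF10 = (BF+0 + BF-0) / 2: the Cauchy prior splits its mass evenly."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        v = rng.normal(rng.normal(0, 1), 1.0, size=rng.integers(4, 20))
        two = jzs_one_sample_bf(v).bf10
        plus = jzs_one_sample_bf(v, direction="greater").bf10
        minus = jzs_one_sample_bf(v, direction="less").bf10
        assert math.log10((plus + minus) / 2) == pytest.approx(
            math.log10(two), abs=1e-6)


def test_affine_invariance_of_bf():
    rng = np.random.default_rng(6)
    x, y = rng.normal(1.0, 2.0, 10), rng.normal(0.0, 2.0, 12)
    base = jzs_two_sample_bf(x, y).log10_bf10
    shifted = jzs_two_sample_bf(3.0 * x - 5.0, 3.0 * y - 5.0).log10_bf10
    assert shifted == pytest.approx(base, abs=1e-7)


def test_one_sided_bf_grows_as_variance_shrinks():
    """All-positive samples: BF+0 increases monotonically as the sample
    spread shrinks toward a point mass."""
    base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    bfs = [jzs_one_sample_bf(2.0 + s * base, direction="greater").log10_bf10
           for s in (2.0, 1.0, 0.5, 0.1, 0.02)]
    assert all(b > a for a, b in zip(bfs, bfs[1:]))
    assert bfs[-1] > 3.0


def test_quadrature_matches_monte_carlo_prior_averaging():
    """The quadrature BF agrees with brute-force Monte-Carlo averaging of
    the noncentral-t likelihood over Cauchy prior draws (3 MC-SE)."""
    rng = np.random.default_rng(7)
    for _ in range(3):
        x = rng.normal(0.4, 1.0, 8)
        y = rng.normal(0.0, 1.0, 8)
        res = jzs_two_sample_bf(x, y)
        t = stats.ttest_ind(x, y).statistic
        df, n_eff = 14, 4.0
        deltas = DEFAULT_CAUCHY_SCALE * rng.standard_cauchy(10 ** 6)
        like = stats.nct.pdf(t, df, deltas * math.sqrt(n_eff))
        bf_mc = like.mean() / stats.t.pdf(t, df)
        se = like.std(ddof=1) / math.sqrt(like.size) / stats.t.pdf(t, df)
        assert abs(res.bf10 - bf_mc) < 3 * se


def test_pingouin_agrees_with_two_sample_bf():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    x, y = rng.normal(0.5, 1, 14), rng.normal(0, 1, 11)
    t = stats.ttest_ind(x, y).statistic
    ours = jzs_two_sample_bf(x, y).bf10
    theirs = float(pg.bayesfactor_ttest(t, nx=14, ny=11, r=DEFAULT_CAUCHY_SCALE))
    assert ours == pytest.approx(theirs, rel=1e-3)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        jzs_two_sample_bf((1.0, 0.0, 16), (1.0, 0.0, 16))
    with pytest.raises(ValueError):
        jzs_one_sample_bf([1.0])
    with pytest.raises(ValueError):
        jzs_one_sample_bf([2.0, 2.0, 2.0])


# ---------------------------------------------------------------- binomial

def test_binomial_group_allocation_value():
    assert binomial_bf(16, 32).log10_bf10 == pytest.approx(-0.664, abs=5e-4)


def test_binomial_no_data_is_indifferent():
    assert binomial_bf(0, 0).bf10 == pytest.approx(1.0)


def test_binomial_two_of_two_closed_form():
    # B(3,1)/B(1,1) / 0.25 = (1/3)/(1/4) = 4/3
    assert binomial_bf(2, 2).bf10 == pytest.approx(4.0 / 3.0, abs=1e-12)


def test_binomial_bounds_checked():
    with pytest.raises(ValueError):
        binomial_bf(3, 2)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(k=st.integers(0, 40), n_extra=st.integers(0, 40))
def test_binomial_matches_direct_beta_integral(k, n_extra):
    n = k + n_extra
    # numerical integral of the Beta(1,1)-averaged likelihood over p
    grid = np.linspace(1e-9, 1 - 1e-9, 20001)
    log_like = k * np.log(grid) + (n - k) * np.log1p(-grid)
    m1 = np.trapezoid(np.exp(log_like), grid)
    m0 = 0.5 ** n
    expected = math.log10(m1) - math.log10(m0)
    assert binomial_bf(k, n).log10_bf10 == pytest.approx(expected, abs=1e-4)


# ------------------------------------------------------------- contingency

def test_contingency_balanced_sex_table_value():
    assert contingency_bf([[8, 8], [8, 8]]).log10_bf10 == pytest.approx(
        -0.383, abs=0.005)


def test_contingency_perfect_association_grows():
    vals = [contingency_bf([[n, 0], [0, n]]).log10_bf10 for n in (2, 5, 10, 20)]
    assert vals[0] > 0
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_contingency_matches_monte_carlo_marginals():
    """Closed form within 3 MC-SE of Dirichlet prior-averaging of the two
    marginal likelihoods."""
    rng = np.random.default_rng(9)
    table = np.array([[5, 3], [2, 7]])
    n_draws = 10 ** 6

    def mc_marginal(counts_rows):
        # average the (coefficient-free) likelihood over Dirichlet(1,1) rows
        like = np.ones(n_draws)
        for row in counts_rows:
            p = rng.dirichlet([1.0, 1.0], size=n_draws)
            like = like * np.prod(p ** np.asarray(row), axis=1)
        return like

    l1 = mc_marginal(table)
    l0 = mc_marginal([table.sum(axis=0)])
    bf_mc = l1.mean() / l0.mean()
    # delta-method SE of the ratio
    se = bf_mc * math.sqrt((l1.std() / l1.mean()) ** 2
                           + (l0.std() / l0.mean()) ** 2) / math.sqrt(n_draws)
    assert abs(contingency_bf(table).bf10 - bf_mc) < 3 * se


def test_contingency_rejects_bad_tables():
    with pytest.raises(ValueError):
        contingency_bf(np.empty((0, 2)))
    with pytest.raises(ValueError):
        contingency_bf([[1.5, 2.0], [1.0, 1.0]])


# ------------------------------------------------------------- correlation

def test_correlation_null_sample_favors_h0():
    x = np.arange(20.0)
    y = np.array([1.0, -1.0] * 10)  # r == 0 by construction
    assert abs(np.corrcoef(x, y)[0, 1]) < 0.1
    assert bayes_correlation_bf(x, y).bf10 < 1.0


def test_correlation_bf_increases_with_r():
    n = 25
    rng = np.random.default_rng(10)
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    bfs = []
    for w in (0.0, 0.5, 1.0, 2.0, 5.0):
        y = w * x + noise
        bfs.append(bayes_correlation_bf(x, y).log10_bf10)
    assert all(b > a for a, b in zip(bfs, bfs[1:]))


def test_correlation_matches_pingouin_exact_form():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    x = rng.normal(size=20)
    y = 0.6 * x + rng.normal(size=20)
    r = float(np.corrcoef(x, y)[0, 1])
    ours = bayes_correlation_bf(x, y).bf10
    theirs = float(pg.bayesfactor_pearson(r, 20))
    assert ours == pytest.approx(theirs, rel=1e-6)


def test_correlation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        bayes_correlation_bf([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------------ grading

@pytest.mark.parametrize("value,label", [
    (1.70, "strong_H1"),       # strong group difference (DLPFC-scale)
    (0.66, "moderate_H1"),
    (0.0, "anecdotal"),
    (-0.512, "moderate_H0"),   # amygdala-scale similarity
    (-1.3, "strong_H0"),
])
def test_evidence_grades(value, label):
    assert grade_evidence(value).label == label


def test_grade_rejects_non_finite():
    with pytest.raises(ValueError):
        grade_evidence(float("nan"))
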