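"""Bayes factors for group inference on behavioral and parcel-level endpoints.

All evidence is reported on the common-log scale, ``log10 BF10``: positive
values favor the alternative, negative values favor the null.  The t-test
family uses the Jeffreys–Zellner–Siow (JZS) setup — a Cauchy prior with
scale ``r`` (default sqrt(2)/2) on the standardized effect size — evaluated
by adaptive quadrature of the noncentral-t likelihood over the prior.
Binomial and 2xK contingency tests have closed forms; the Pearson
correlation test integrates the exact sampling density of r over a
stretched-beta prior on rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "BFResult",
    "EvidenceGrade",
    "jzs_two_sample_bf",
    "jzs_one_sample_bf",
    "binomial_bf",
    "contingency_bf",
    "bayes_correlation_bf",
    "grade_evidence",
    "DEFAULT_CAUCHY_SCALE",
]

#: Default Cauchy prior scale on the standardized effect size.
DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0

Direction = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class BFResult:
    """A single Bayes factor on the common-log scale.

    Attributes
    ----------
    log10_bf10 : float
        log10 of BF10 (alternative over null).  For one-sided tests this
        is log10 BF+0 or log10 BF-0 according to ``direction``.
    direction : {"two_sided", "greater", "less"}
    prior_scale_r : float
        Scale of the Cauchy (or width of the stretched-beta) prior.
    method : {"quadrature", "closed_form", "mcmc", "importance"}
    mc_error : float
        Monte-Carlo SE of log10 BF; 0 for deterministic methods.
    """

    log10_bf10: float
    direction: Direction = "two_sided"
    prior_scale_r: float = DEFAULT_CAUCHY_SCALE
    method: str = "quadrature"
    mc_error: float = 0.0

    @property
    def bf10(self) -> float:
        return 10.0 ** self.log10_bf10

    def __float__(self) -> float:  # convenient in comparisons
        return self.log10_bf10


@dataclass(frozen=True)
class EvidenceGrade:
    """Discrete evidence label with the 0.5 / 1.0 common-log thresholds.

    |log10 BF| >= 1.0 -> strong (>= 10x more probable), >= 0.5 -> moderate
    (>= 10^0.5 ~ 3.16x), otherwise anecdotal; the sign decides which
    hypothesis the grade refers to.
    """

    label: Literal["strong_H1", "moderate_H1", "anecdotal", "moderate_H0", "strong_H0"]
    log10_bf10: float
    thresholds: tuple[float, float] = (0.5, 1.0)


def grade_evidence(log10_bf10: float) -> EvidenceGrade:
    """Grade a common-log Bayes factor into the conventional evidence bands."""
    if not np.isfinite(log10_bf10):
        raise ValueError("log10_bf10 must be finite")
    b = float(log10_bf10)
    if b >= 1.0:
        label = "strong_H1"
    elif b >= 0.5:
        label = "moderate_H1"
    elif b > -0.5:
        label = "anecdotal"
    elif b > -1.0:
        label = "moderate_H0"
    else:
        label = "strong_H0"
    return EvidenceGrade(label=label, log10_bf10=b)


# ---------------------------------------------------------------------------
# JZS t-test Bayes factors
# ---------------------------------------------------------------------------

def _jzs_bf_from_t(t: float, df: float, n_eff: float, r: float,
                   direction: Direction) -> float:
    """log10 BF for the JZS t test, by quadrature over the Cauchy prior.

    The marginal likelihood under H1 is the noncentral-t density averaged
    over delta ~ Cauchy(0, r) (truncated and renormalized for one-sided
    tests); H0 is the central t.  The substitution delta = r tan(theta)
    absorbs the Cauchy weight, leaving a bounded smooth integrand on
    (-pi/2, pi/2).
    """
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not np.isfinite(t) or abs(t) > 1e8:
        raise ValueError("t statistic is not finite (degenerate data?)")
    sqrt_n = math.sqrt(n_eff)

    def integrand(theta: float) -> float:
        delta = r * math.tan(theta)
        nc = delta * sqrt_n
        # the likelihood underflows long before this bound; skipping the
        # evaluation also avoids nct.pdf convergence failures at extreme
        # noncentrality
        if abs(nc) > abs(t) + 40.0:
            return 0.0
        # Cauchy(0,r) density times d(delta)/d(theta) equals 1/pi exactly.
        return stats.nct.pdf(t, df, nc) / math.pi

    if direction == "two_sided":
        lo, hi, renorm = -math.pi / 2, math.pi / 2, 1.0
    elif direction == "greater":
        lo, hi, renorm = 0.0, math.pi / 2, 2.0
    elif direction == "less":
        lo, hi, renorm = -math.pi / 2, 0.0, 2.0
    else:  # pragma: no cover - guarded by typing
        raise ValueError(f"unknown direction {direction!r}")

    m1, _ = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-8, limit=200)
    m1 *= renorm
    m0 = stats.t.pdf(t, df)
    if m1 <= 0.0 or m0 <= 0.0:
        raise FloatingPointError("quadrature underflow in JZS Bayes factor")
    return math.log10(m1) - math.log10(m0)


def _pooled_t(mean1: float, sd1: float, n1: int,
              mean2: float, sd2: float, n2: int) -> tuple[float, float, float]:
    """Pooled-variance two-sample t statistic, df, and effective n."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    scale = mean1 ** 2 + mean2 ** 2 + sd1 ** 2 + sd2 ** 2
    if sp2 <= 0.0 or sp2 <= 1e-24 * max(scale, 1e-300):
        raise ValueError("zero pooled variance")
    n_eff = n1 * n2 / (n1 + n2)
    t = (mean1 - mean2) / math.sqrt(sp2 / n_eff)
    return t, df, n_eff


def jzs_two_sample_bf(x, y, r: float = DEFAULT_CAUCHY_SCALE,
                      direction: Direction = "two_sided") -> BFResult:
    """JZS independent-samples t-test Bayes factor.

    Parameters
    ----------
    x, y : array-like of raw samples, or (mean, sd, n) summary triples.
        Summaries use the pooled-variance Student t, matching the equal-
        variance assumption of the JZS derivation.
    r : Cauchy prior scale on the standardized difference (default sqrt2/2).
    direction : "two_sided", or "greater"/"less" for x - y one-sided tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape == (3,) and y.shape == (3,) and x[2] == round(x[2]) and x[2] >= 2:
        m1, s1, n1 = x
        m2, s2, n2 = y
        t, df, n_eff = _pooled_t(m1, s1, int(n1), m2, s2, int(n2))
    else:
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("raw samples must be one-dimensional")
        t, df, n_eff = _pooled_t(float(np.mean(x)), float(np.std(x, ddof=1)), x.size,
                                 float(np.mean(y)), float(np.std(y, ddof=1)), y.size)
    lb = _jzs_bf_from_t(t, df, n_eff, r, direction)
    return BFResult(lb, direction=direction, prior_scale_r=r, method="quadrature")


def jzs_one_sample_bf(values: Sequence[float], r: float = DEFAULT_CAUCHY_SCALE,
                      direction: Direction = "two_sided",
                      mu0: float = 0.0) -> BFResult:
    """JZS one-sample t-test Bayes factor against ``mu0``."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 one-dimensional observations")
    sd = float(np.std(v, ddof=1))
    if sd <= 0.0 or sd <= 1e-12 * max(abs(float(np.mean(v))), 1e-300):
        raise ValueError("zero sample variance")
    n = v.size
    t = (float(np.mean(v)) - mu0) / (sd / math.sqrt(n))
    lb = _jzs_bf_from_t(t, n - 1, float(n), r, direction)
    return BFResult(lb, direction=direction, prior_scale_r=r, method="quadrature")


# ---------------------------------------------------------------------------
# Closed-form discrete tests
# ---------------------------------------------------------------------------

def binomial_bf(k: int, n: int, p0: float = 0.5,
                a: float = 1.0, b: float = 1.0) -> BFResult:
    """Bayes factor for a binomial rate against the point null ``p0``.

    Marginal likelihoods of the same data under p ~ Beta(a, b) versus the
    point mass at p0; the binomial coefficient is common to both and
    cancels, so BF10 = B(k+a, n-k+b) / [B(a, b) * p0^k (1-p0)^(n-k)].
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    log_m1 = special.betaln(k + a, n - k + b) - special.betaln(a, b)
    log_m0 = k * math.log(p0) + (n - k) * math.log1p(-p0)
    return BFResult((log_m1 - log_m0) / math.log(10.0),
                    direction="two_sided", prior_scale_r=float("nan"),
                    method="closed_form")


def contingency_bf(table, a: float = 1.0) -> BFResult:
    """Gunel–Dickey Bayes factor for a 2xK (or RxK) contingency table.

    Independent-multinomial sampling with the group (row) margins fixed:
    under H1 each row has its own cell-probability vector with a symmetric
    Dirichlet(a) prior; under H0 all rows share one vector with the same
    Dirichlet(a) prior.  The multinomial coefficients are identical under
    both hypotheses and cancel, leaving a ratio of Dirichlet normalizers.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2 or y.size == 0:
        raise ValueError("table must be a non-empty 2-D array of counts")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if a <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    n_rows, n_cols = y.shape

    def log_multibeta(alpha: np.ndarray) -> float:
        return float(np.sum(special.gammaln(alpha)) - special.gammaln(np.sum(alpha)))

    prior = np.full(n_cols, a)
    log_m1 = sum(log_multibeta(y[i] + prior) - log_multibeta(prior)
                 for i in range(n_rows))
    col_totals = y.sum(axis=0)
    log_m0 = log_multibeta(col_totals + prior) - log_multibeta(prior)
    return BFResult((log_m1 - log_m0) / math.log(10.0),
                    direction="two_sided", prior_scale_r=float("nan"),
                    method="closed_form")


# ---------------------------------------------------------------------------
# Bayesian Pearson correlation
# ---------------------------------------------------------------------------

def _log_corr_likelihood_ratio(rho: np.ndarray, r_obs: float, n: int) -> np.ndarray:
    """log p(r_obs | rho) - log p(r_obs | 0) from the exact sampling density.

    Only the rho-dependent factors of the density of the sample correlation
    are needed: (1-rho^2)^((n-1)/2) (1-rho*r)^((3-2n)/2)
    2F1(1/2, 1/2; (2n-1)/2; (rho*r+1)/2), normalized at rho = 0.
    """
    rho = np.asarray(rho, dtype=float)
    c = (2.0 * n - 1.0) / 2.0
    h = special.hyp2f1(0.5, 0.5, c, (rho * r_obs + 1.0) / 2.0)
    h0 = special.hyp2f1(0.5, 0.5, c, 0.5)
    return ((n - 1) / 2.0 * np.log1p(-rho ** 2)
            + (3.0 - 2.0 * n) / 2.0 * np.log1p(-rho * r_obs)
            + np.log(h) - np.log(h0))


def bayes_correlation_bf(x, y, stretched_beta_width: float = 1.0) -> BFResult:
    """Bayes factor for a nonzero Pearson correlation.

    The prior on rho is a stretched beta on (-1, 1): (rho+1)/2 ~
    Beta(1/k, 1/k) with width ``k`` (k = 1 is uniform).  The marginal
    likelihood is integrated numerically through the sample correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired one-dimensional samples with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in x or y")
    k = stretched_beta_width
    if k <= 0:
        raise ValueError("stretched_beta_width must be positive")
    n = x.size
    r_obs = float(np.corrcoef(x, y)[0, 1])
    alpha = 1.0 / k

    def integrand(rho: float) -> float:
        # Beta density of (rho+1)/2 with Jacobian 1/2, written on (-1, 1):
        log_prior = (-special.betaln(alpha, alpha)
                     + (alpha - 1.0) * (math.log1p(rho) - math.log(2.0))
                     + (alpha - 1.0) * (math.log1p(-rho) - math.log(2.0))
                     - math.log(2.0))
        return math.exp(_log_corr_likelihood_ratio(rho, r_obs, n) + log_prior)

    bf10, _ = integrate.quad(integrand, -1.0, 1.0, epsabs=0.0, epsrel=1e-8,
                             limit=200)
    return BFResult(math.log10(bf10), direction="two_sided",
                    prior_scale_r=k, method="quadrature")
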