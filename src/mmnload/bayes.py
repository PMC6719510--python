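"""Bayes factors with uniform priors, credible intervals, correlation BFs.

The evidence layer follows the Dienes-calculator convention: the
population mean difference delta has likelihood given by a scaled,
shifted central t distribution -- the observed mean m with standard
error se and df = n - 1, so p(data | delta) = f_t((m - delta)/se; df)/se
-- and the alternative hypothesis puts a uniform prior on delta, by
default over [-1.5, +1.5] microvolts (directional variants use [0, b] or
[-b, 0]). BF10 is the ratio of the marginal likelihood under that prior
to the point-null likelihood at delta = 0.

Far-tail cases (|m/se| large) are computed in log space: the visual-P3
BF is a ratio of two quantities around 1e-13.

Correlation BFs use the exact sampling density of the Pearson r under
bivariate normality with a flat (stretched beta, beta = 1) prior on rho
over (-1, 1), integrated on a dense grid; the posterior over rho yields
central credible intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

DEFAULT_PRIOR_BOUND_UV = 1.5
FAR_TAIL_T = 8.0


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior on the mean difference, in microvolts."""

    lower: float
    upper: float
    directional: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise StatsError("prior requires lower < upper")
        if self.directional and not (
            (self.lower == 0.0) ^ (self.upper == 0.0)
        ):
            raise StatsError("directional prior must have one bound at 0")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def two_sided_prior(bound: float = DEFAULT_PRIOR_BOUND_UV) -> PriorSpec:
    return PriorSpec(-bound, bound)


def directional_prior(direction: str, bound: float = DEFAULT_PRIOR_BOUND_UV) -> PriorSpec:
    if direction == "positive":
        return PriorSpec(0.0, bound, directional=True)
    if direction == "negative":
        return PriorSpec(-bound, 0.0, directional=True)
    raise StatsError(f"unknown direction {direction!r}")


@dataclass
class GroupSummary:
    mean: float
    ci_lower: float
    ci_upper: float
    n: int
    se: float

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.mean <= self.ci_upper:
            raise StatsError("CI must bracket the mean")

    @property
    def df(self) -> int:
        return self.n - 1


@dataclass
class BFResult:
    bf10: float
    prior: PriorSpec
    log_bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def label(self) -> str:
        return interpret_bf(self.bf10)


@dataclass
class CorrelationResult:
    r: float
    n: int
    bf10: float
    ci_lower: float
    ci_upper: float
    prior_beta: float = 1.0

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def label(self) -> str:
        return interpret_bf(self.bf10)


# ---------------------------------------------------------------------------
# group summaries


def group_summary(values: np.ndarray) -> GroupSummary:
    """Mean, SE and two-sided 95% t interval of per-subject measures."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("need at least 2 values")
    n = x.size
    se = float(x.std(ddof=1) / math.sqrt(n))
    m = float(x.mean())
    if se == 0.0:
        return GroupSummary(m, m, m, n, 0.0)  # degenerate: zero-width CI
    half = stats.t.ppf(0.975, n - 1) * se
    return GroupSummary(m, m - half, m + half, n, se)


def se_from_ci(ci_lower: float, ci_upper: float, df: int) -> float:
    """Recover the SE from a printed two-sided 95% t interval."""
    if ci_upper <= ci_lower:
        raise StatsError("CI width must be positive")
    if df < 1:
        raise StatsError("df must be >= 1")
    return (ci_upper - ci_lower) / (2.0 * stats.t.ppf(0.975, df))


def summary_from_printed(mean: float, ci_lower: float, ci_upper: float,
                         n: int) -> GroupSummary:
    return GroupSummary(mean, ci_lower, ci_upper, n, se_from_ci(ci_lower, ci_upper, n - 1))


def credible_interval_mean(m: float, se: float, df: int) -> tuple[float, float]:
    """Central 95% posterior interval under the improper flat prior on the
    mean; coincides with the frequentist t interval."""
    if se <= 0:
        raise StatsError("se must be positive")
    half = stats.t.ppf(0.975, df) * se
    return (m - half, m + half)


# ---------------------------------------------------------------------------
# uniform-prior Bayes factor


def _log_marginal_uniform(m: float, se: float, df: int, prior: PriorSpec) -> float:
    """log of (1/width) * integral over delta of f_t((m-delta)/se; df)/se.

    Substituting t = (m - delta)/se turns the integral into the t mass on
    [(m-upper)/se, (m-lower)/se]; the quadrature runs on the t scale with
    the integrand rescaled by its in-range peak so far tails stay finite.
    """
    t_lo = (m - prior.upper) / se
    t_hi = (m - prior.lower) / se
    peak = min(max(0.0, t_lo), t_hi)  # pdf argmax clipped into range
    log_scale = stats.t.logpdf(peak, df)
    val, err = integrate.quad(
        lambda t: np.exp(stats.t.logpdf(t, df) - log_scale),
        t_lo, t_hi, epsrel=1e-10, limit=400,
    )
    if val <= 0 or not np.isfinite(val):
        raise StatsError(f"quadrature failed on [{t_lo:.3g}, {t_hi:.3g}]: {val}")
    if err > 1e-6 * val:
        raise StatsError(f"quadrature did not converge: rel err {err / val:.2e}")
    return log_scale + math.log(val) - math.log(prior.width)


def bf_uniform(m: float, se: float, df: int, prior: PriorSpec | None = None) -> BFResult:
    """Uniform-prior Bayes factor with t likelihood (BF10 and BF01)."""
    if se <= 0:
        raise StatsError("se must be positive")
    if df < 1:
        raise StatsError("df must be >= 1")
    prior = prior or two_sided_prior()
    log_m1 = _log_marginal_uniform(m, se, df, prior)
    log_m0 = stats.t.logpdf(m / se, df) - math.log(se)
    log_bf10 = log_m1 - log_m0
    return BFResult(math.exp(log_bf10), prior, log_bf10)


def bf_uniform_from_summary(s: GroupSummary, prior: PriorSpec | None = None) -> BFResult:
    return bf_uniform(s.mean, s.se, s.df, prior)


def bf_directional(m: float, se: float, df: int, bound: float = DEFAULT_PRIOR_BOUND_UV,
                   direction: str = "positive") -> BFResult:
    """One-sided uniform prior oriented along the hypothesized direction."""
    return bf_uniform(m, se, df, directional_prior(direction, bound))


# ---------------------------------------------------------------------------
# correlation Bayes factor

RHO_GRID_POINTS = 4001


def _log_r_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """log sampling density of Pearson r given rho (terms in rho only).

    Exact bivariate-normal form: p(r | rho, n) is proportional to
    (1-rho^2)^((n-1)/2) (1-rho r)^((3-2n)/2) 2F1(1/2, 1/2; n-1/2; (1+rho r)/2);
    r-only factors cancel in the Bayes factor and posterior.
    """
    x = rho * r
    return (
        0.5 * (n - 1) * np.log1p(-rho**2)
        + 0.5 * (3 - 2 * n) * np.log1p(-x)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + x) / 2))
    )


def correlation_bf(r: float, n: int, beta: float = 1.0,
                   grid_points: int = RHO_GRID_POINTS) -> CorrelationResult:
    """Two-sided correlation BF with a stretched-beta prior on rho.

    beta = 1 is the flat prior over (-1, 1). The posterior over rho on
    the grid provides the central 95% credible interval.
    """
    if not abs(r) < 1:
        raise StatsError("|r| must be < 1 (degenerate likelihood at |r|=1)")
    if n < 4:
        raise StatsError("need n >= 4")
    eps = 1e-12
    rho = np.linspace(-1 + eps, 1 - eps, grid_points)
    # symmetric stretched beta: density proportional to (1-rho^2)^(1/beta - 1)
    log_prior = (1.0 / beta - 1.0) * np.log1p(-rho**2)
    log_prior -= _log_trapz(log_prior, rho)  # normalise the prior on the grid
    log_post_unnorm = _log_r_density(r, rho, n) + log_prior
    log_marginal = _log_trapz(log_post_unnorm, rho)
    log_null = float(_log_r_density(r, np.array([0.0]), n)[0])
    bf10 = math.exp(log_marginal - log_null)

    post = np.exp(log_post_unnorm - log_post_unnorm.max())
    cdf = integrate.cumulative_trapezoid(post, rho, initial=0.0)
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, rho))
    hi = float(np.interp(0.975, cdf, rho))
    return CorrelationResult(r, n, bf10, lo, hi, beta)


def _log_trapz(log_y: np.ndarray, x: np.ndarray) -> float:
    """log of the trapezoid integral of exp(log_y) over x, overflow-safe."""
    c = log_y.max()
    return float(c + np.log(np.trapezoid(np.exp(log_y - c), x)))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise StatsError("need equal-length samples, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# evidence labels and OSPAN scoring

_THRESHOLDS = ((100.0, "extreme"), (30.0, "very strong"), (10.0, "strong"),
               (3.0, "moderate"), (1.0, "anecdotal"))


def interpret_bf(bf10: float) -> str:
    """Verbal evidence category on the dominant direction of the BF."""
    if bf10 <= 0:
        raise StatsError("BF must be positive")
    if bf10 == 1.0:
        return "no evidence"
    favored = "H1" if bf10 > 1 else "H0"
    b = bf10 if bf10 > 1 else 1.0 / bf10
    for cut, name in _THRESHOLDS:
        if b > cut:
            return f"{name} ({favored})"
    return f"anecdotal ({favored})"


def pcu_score(trials: list[tuple[int, int]]) -> float:
    """Operation-span partial credit unit: mean per-sequence proportion of
    letters recalled in the correct serial position."""
    if not trials:
        raise StatsError("no OSPAN trials")
    props = []
    for length, n_correct in trials:
        if not 0 <= n_correct <= length or length <= 0:
            raise StatsError(f"invalid trial ({length}, {n_correct})")
        props.append(n_correct / length)
    return float(np.mean(props))
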