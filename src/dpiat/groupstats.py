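"""Group-level inference on D-scores.

One-sample t against zero with Cohen's d and a t-based confidence interval;
the default (JZS) Bayes factor for the one-sample t, obtained by integrating
the marginal likelihood ratio over a Cauchy(0, r) effect-size prior; a
sequential version of that Bayes factor accumulating participants in
presentation order; and Spearman rank correlation.

The JZS integral uses the inverse-gamma mixture representation of the Cauchy
prior: with nu = n - 1 degrees of freedom and g the mixing variable,

    BF10 = int_0^inf (1 + n g r^2)^(-1/2)
                     (1 + t^2 / ((1 + n g r^2) nu))^(-(nu+1)/2)
                     (2 pi)^(-1/2) g^(-3/2) exp(-1/(2g)) dg
           / (1 + t^2 / nu)^(-(nu+1)/2)

evaluated by adaptive quadrature on the log-transformed axis u = log g
(the integrand is heavy-tailed in g but well behaved in u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .exceptions import DegenerateDataError, NumericError, ValidationError

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "GroupTestResult",
    "BayesResult",
    "one_sample_test",
    "cohens_d_from_t",
    "jzs_bf10",
    "sequential_bf",
    "spearman_rho",
]

#: Default Cauchy prior scale r = sqrt(2)/2, the "medium" default of common
#: Bayes-factor software.
DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class GroupTestResult:
    n: int
    mean: float
    sd: float
    t: float
    df: int
    p_two_tailed: float
    cohens_d: float
    ci_level: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    prior_scale: float
    t: float
    n: int

    def __post_init__(self) -> None:
        if not self.bf10 > 0:
            raise ValidationError(f"bf10 must be positive, got {self.bf10}")


def one_sample_test(values: Sequence[float], mu0: float = 0.0,
                    ci_level: float = 0.95) -> GroupTestResult:
    """One-sample t-test of ``values`` against ``mu0`` with a t-based CI.

    Cohen's d is (mean - mu0)/sd, identically t/sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError(f"need >= 2 values, got {x.size}")
    if not 0 < ci_level < 1:
        raise ValidationError(f"ci_level must be in (0, 1), got {ci_level}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("constant sample: sd = 0, t undefined")
    res = stats.ttest_1samp(x, popmean=mu0)
    ci = res.confidence_interval(confidence_level=ci_level)
    mean = float(x.mean())
    return GroupTestResult(
        n=int(x.size),
        mean=mean,
        sd=sd,
        t=float(res.statistic),
        df=int(x.size) - 1,
        p_two_tailed=float(res.pvalue),
        cohens_d=(mean - mu0) / sd,
        ci_level=ci_level,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def ci_from_summary(mean: float, sd: float, n: int,
                    ci_level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a mean from printed summary statistics."""
    if n < 2 or sd <= 0:
        raise ValidationError("need n >= 2 and sd > 0")
    half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def cohens_d_from_t(t: float, n: int) -> float:
    """Cohen's d recovered from a one-sample t: d = t / sqrt(n)."""
    if n < 2:
        raise ValidationError(f"need n >= 2, got {n}")
    return t / math.sqrt(n)


def jzs_bf10(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesResult:
    """Default Bayes factor BF10 for a one-sample t statistic.

    Quadrature is run on u = log g; a relative error estimate above 1e-6
    raises :class:`NumericError` with the integrator diagnostics.
    """
    if n < 2:
        raise ValidationError(f"need n >= 2, got {n}")
    if not prior_scale > 0:
        raise ValidationError(f"prior_scale must be > 0, got {prior_scale}")
    nu = n - 1
    r2 = prior_scale * prior_scale

    def integrand_logg(u: float) -> float:
        # tails vanish: g^(-1/2) decay as u -> inf, exp(-1/(2g)) as u -> -inf
        if abs(u) > 690.0:
            return 0.0
        g = math.exp(u)
        a = 1.0 + n * g * r2
        logval = (
            -0.5 * math.log(a)
            - (nu + 1) / 2.0 * math.log1p(t * t / (a * nu))
            - 0.5 * math.log(2.0 * math.pi)
            - 1.5 * math.log(g)
            - 1.0 / (2.0 * g)
            + u  # Jacobian dg = g du
        )
        return math.exp(logval)

    num, err = integrate.quad(integrand_logg, -np.inf, np.inf, limit=400,
                              epsabs=0.0, epsrel=1e-10)
    if num <= 0 or err > 1e-6 * num:
        raise NumericError(
            f"JZS quadrature did not converge: integral={num}, abs err={err}"
        )
    log_den = -(nu + 1) / 2.0 * math.log1p(t * t / nu)
    return BayesResult(bf10=num / math.exp(log_den),
                       prior_scale=prior_scale, t=t, n=n)


def sequential_bf(values: Sequence[float],
                  prior_scale: float = DEFAULT_PRIOR_SCALE) -> list[tuple[int, float]]:
    """BF10 after each prefix of the sample, in presentation order.

    Returns (k, bf10) for k = 2..n; the final element equals the full-sample
    Bayes factor exactly.
    """
    x = list(map(float, values))
    if len(x) < 2:
        raise ValidationError(f"need >= 2 values, got {len(x)}")
    out = []
    for k in range(2, len(x) + 1):
        res = one_sample_test(x[:k])
        out.append((k, jzs_bf10(res.t, k, prior_scale).bf10))
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need >= 3 pairs, got {x.size}")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
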