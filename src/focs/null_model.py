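"""Community-conditional hypergeometric null and the uniformizing correction.

The null model fixes a community ``C`` and treats the tested node ``u`` as
external: the edges leaving ``C`` and the edges internal to the external set
are broken into stubs, and the ``d_u`` stubs of ``u`` are re-assigned
uniformly without replacement.  The in-degree of ``u`` with respect to ``C``
is then hypergeometric.  Because that law is discrete, its CDF evaluated at
the observed in-degree is not uniform; :func:`corrected_quantile` draws a
uniform deviate on the CDF step containing the observation, which *is*
exactly Uniform[0,1] under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import ImpossibleObservationError, InfeasibleNullError

__all__ = [
    "NullParams",
    "CorrectedQuantile",
    "null_pmf",
    "null_cdf",
    "corrected_quantile",
    "sample_null_indegree",
    "simulate_corrected_quantiles",
]


@dataclass(frozen=True)
class NullParams:
    """Hypergeometric parameters for one tested node against one community.

    Attributes
    ----------
    draws
        Number of stubs of the tested node to re-assign (its degree).
    successes
        Stubs available on the community side of the broken-edge pool.
    failures
        Stubs available in the external-external part of the pool.
    """

    draws: int
    successes: int
    failures: int

    def __post_init__(self):
        for name in ("draws", "successes", "failures"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def population(self) -> int:
        return self.successes + self.failures

    @property
    def support(self) -> tuple[int, int]:
        """Inclusive (min, max) of the in-degree support."""
        return (max(0, self.draws - self.failures), min(self.draws, self.successes))

    def check_feasible(self) -> None:
        if self.draws > self.population:
            raise InfeasibleNullError(
                f"tested node has {self.draws} stubs but the external pool "
                f"only holds {self.population}"
            )


@dataclass(frozen=True)
class CorrectedQuantile:
    """One realization of the uniformized CDF value, with its step bounds."""

    value: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.value <= self.upper <= 1.0):
            raise ValueError(f"inconsistent quantile bounds: {self}")


def _dist(params: NullParams):
    return hypergeom(M=params.population, n=params.successes, N=params.draws)


def null_pmf(params: NullParams, a: int) -> float:
    """P(in-degree = a) under the null; 0 outside the support."""
    params.check_feasible()
    if params.draws == 0:
        return 1.0 if a == 0 else 0.0
    lo, hi = params.support
    if a < lo or a > hi:
        return 0.0
    return float(_dist(params).pmf(a))


def null_cdf(params: NullParams, a: int) -> float:
    """P(in-degree <= a) under the null; nondecreasing, 1 at the support max."""
    params.check_feasible()
    if params.draws == 0:
        return 1.0 if a >= 0 else 0.0
    lo, hi = params.support
    if a < lo:
        return 0.0
    if a >= hi:
        return 1.0
    return float(_dist(params).cdf(a))


def corrected_quantile(
    params: NullParams,
    a: int,
    rng: np.random.Generator,
    *,
    deviate: float | None = None,
) -> CorrectedQuantile:
    """Uniform draw on the CDF step [g(a-1), g(a)] containing ``a``.

    ``deviate`` optionally supplies the unit-uniform variate instead of
    drawing from ``rng`` (used for common random numbers across iterations).
    At the support minimum the lower bound is 0 by convention.
    """
    params.check_feasible()
    lo, hi = params.support
    if a < lo or a > hi:
        raise ImpossibleObservationError(
            f"observed in-degree {a} outside null support [{lo}, {hi}] "
            f"for {params}"
        )
    lower = null_cdf(params, a - 1)
    upper = null_cdf(params, a)
    if deviate is None:
        deviate = rng.random()
    value = lower + deviate * (upper - lower)
    return CorrectedQuantile(value=value, lower=lower, upper=upper)


def sample_null_indegree(params: NullParams, rng: np.random.Generator) -> int:
    """One draw of the in-degree from the null (for oracle testing)."""
    params.check_feasible()
    if params.draws == 0:
        return 0
    return int(rng.hypergeometric(params.successes, params.failures, params.draws))


def simulate_corrected_quantiles(
    params: NullParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized two-stage simulation: in-degree from the null, then the
    corrected quantile.  Under the null the result is exactly Uniform[0,1];
    this is the Monte-Carlo witness for that property.
    """
    params.check_feasible()
    if params.draws == 0:
        return rng.random(n)
    lo, hi = params.support
    grid = np.arange(lo - 1, hi + 1)
    cdf = _dist(params).cdf(grid)
    cdf[0] = 0.0  # g at one below the support minimum
    cdf[-1] = 1.0
    draws = rng.hypergeometric(params.successes, params.failures, params.draws, size=n)
    idx = draws - (lo - 1)
    lower = cdf[idx - 1]
    upper = cdf[idx]
    return lower + rng.random(n) * (upper - lower)
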