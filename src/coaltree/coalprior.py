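"""Predata coalescent model: waiting times, moments, and the mutation law.

Under Kingman's coalescent a sample of ``n`` sequences from a large
constant-size Wright-Fisher population has TMRCA

    t_n = sum_{j=2}^{n} w_j,

in units of ``N`` generations, where the waiting times ``w_j`` (the time
during which the sample has exactly ``j`` ancestral lineages) are
independent Exp(j(j-1)/2).  The total tree length is
``l_n = sum_{j=2}^{n} j * w_j``, and conditional on ``l_n = l`` the number
of mutations in the sample is Poisson(theta * l / 2), with
``theta = 2 N mu`` the scaled per-sequence mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class WaitingTimes:
    """Coalescent waiting times ``w_2 .. w_n`` (units of N generations)."""

    n: int
    w: np.ndarray  # w[i] is w_{i+2}, i.e. index 0 holds w_2

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if w.shape != (self.n - 1,):
            raise ValueError("need exactly n - 1 waiting times (w_2 .. w_n)")
        if not (w > 0).all():
            raise ValueError("waiting times must be positive")

    def w_of(self, j: int) -> float:
        """``w_j`` for ``2 <= j <= n``."""
        return float(self.w[j - 2])

    @property
    def t_n(self) -> float:
        """Time to the MRCA: sum of the waiting times."""
        return float(self.w.sum())

    @property
    def l_n(self) -> float:
        """Total tree length: sum of j * w_j."""
        j = np.arange(2, self.n + 1)
        return float((j * self.w).sum())


@dataclass(frozen=True)
class PredataMoments:
    """Closed-form predata mean/variance of ``t_n`` and ``l_n``."""

    n: int
    mean_t: float
    var_t: float
    mean_l: float
    var_l: float


def sample_waiting_times(n: int, rng: np.random.Generator) -> WaitingTimes:
    """Draw ``w_j ~ Exp(j(j-1)/2)`` independently for ``j = 2..n``.

    Uses the inverse-CDF transform ``w_j = -2/(j(j-1)) * ln(1 - u)`` with a
    fresh ``u ~ U(0, 1)`` per ``j``, drawn in the fixed order
    ``j = 2, ..., n``; ``u`` is taken on the open interval so ``log`` never
    sees zero.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    j = np.arange(2, n + 1, dtype=float)
    # rng.random() is in [0, 1); clamp away from 0 so every w_j is > 0
    u = np.clip(rng.random(n - 1), np.finfo(float).tiny, None)
    w = -2.0 / (j * (j - 1.0)) * np.log1p(-u)
    return WaitingTimes(n=n, w=w)


def predata_moments(n: int) -> PredataMoments:
    """Closed-form predata moments of ``t_n`` and ``l_n``.

    mean_t = 2(1 - 1/n)
    var_t  = 8 * sum_{j=2}^{n} 1/j^2 - 4(1 - 1/n)^2
    mean_l = 2 * sum_{j=1}^{n-1} 1/j
    var_l  = 4 * sum_{j=1}^{n-1} 1/j^2
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    j2 = np.arange(2, n + 1, dtype=float)
    j1 = np.arange(1, n, dtype=float)
    mean_t = 2.0 * (1.0 - 1.0 / n)
    var_t = 8.0 * float((1.0 / j2**2).sum()) - 4.0 * (1.0 - 1.0 / n) ** 2
    mean_l = 2.0 * float((1.0 / j1).sum())
    var_l = 4.0 * float((1.0 / j1**2).sum())
    return PredataMoments(n=n, mean_t=mean_t, var_t=var_t, mean_l=mean_l, var_l=var_l)


def ancestor_probability(n: int, N: int) -> float:
    """Probability that the whole population of size ``N`` has a single
    ancestor at the sample's TMRCA:

        P(A_N(t_n) = 1) = (n - 1)(N + 1) / ((n + 1)(N - 1)).

    Valid for a random sample of size ``n <= N`` from the population; it is
    why the sample TMRCA is usually a good proxy for the population TMRCA.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if n > N:
        raise ValueError("sample size n cannot exceed population size N")
    return (n - 1) * (N + 1) / ((n + 1) * (N - 1))


def mutation_count_pmf(k: int, l: float, theta: float) -> float:
    """P(s_n = k | l_n = l): Poisson(theta * l / 2) mass at ``k``."""
    if k < 0 or k != int(k):
        raise ValueError("mutation count k must be a nonnegative integer")
    if l <= 0:
        raise ValueError("tree length l must be positive")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    return float(stats.poisson.pmf(int(k), theta * l / 2.0))


def to_years(t: float, N: float, Y: float) -> float:
    """Convert a time in units of ``N`` generations to years: ``t * N * Y``.

    ``Y`` is the average generation span in years (commonly 20-25 for
    humans); no default is applied — the conversion is always explicit.
    """
    if N <= 0 or Y <= 0:
        raise ValueError("N and Y must be positive")
    return t * N * Y
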