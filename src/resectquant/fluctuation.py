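"""Luria-Delbruck fluctuation analysis by MSS maximum likelihood.

Estimates the expected number of mutations per culture, m, from the
distribution of mutant (recombinant) counts across parallel cultures, and
converts it to a per-cell-per-division rate m / Nt. The likelihood uses
the Ma-Sandri-Sarkar recursion for the Luria-Delbruck probability mass
function:

    p_0 = exp(-m)
    p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1),   r >= 1

Counts above a truncation bound are pooled into a tail term P(R >= r_max)
so that jackpot cultures do not force unbounded recursions. Confidence
intervals come from the likelihood-ratio bound (delta logL = 1.92, the
chi-square_1 95% quantile / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LR_BOUND = 1.92  # chi2(1) 95% quantile / 2
_TINY = 1e-300


@dataclass
class FluctuationExperiment:
    """Per-culture mutant counts and the final population size per culture."""

    counts: np.ndarray
    nt: float
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("need at least 2 cultures for estimation")
        if (self.counts < 0).any():
            raise ValueError("mutant counts must be non-negative")
        if self.nt <= 0:
            raise ValueError("final population size must be positive")


@dataclass
class RateEstimate:
    m: float
    log_likelihood: float
    ci_low: float
    ci_high: float
    rate: float = math.nan
    rate_ci_low: float = math.nan
    rate_ci_high: float = math.nan


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbruck probabilities p_0 .. p_r_max via the MSS recursion.

    The distribution has a 1/(r (r+1)) tail, so the truncated mass is
    1 - O(m / r_max); callers needing a proper likelihood over all counts
    pool the remainder into a tail term (see :func:`estimate_m`).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if r_max < 0:
        raise ValueError("r_max must be non-negative")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if m == 0:
        return p
    # inv[k] = 1/(k + 1); term i of p_r uses 1/(r - i + 1) = inv[r - i]
    inv = 1.0 / (1.0 + np.arange(r_max + 1))
    for r in range(1, r_max + 1):
        p[r] = (m / r) * float(np.dot(p[:r], inv[r:0:-1]))
    return p


def _log_likelihood(
    m: float, uniq: np.ndarray, mult: np.ndarray, r_cap: int, has_tail: bool
) -> float:
    """Sum of log LD probabilities over observed counts (tail-pooled)."""
    if m == 0:
        return 0.0 if uniq.max(initial=0) == 0 else -math.inf
    pmf = ld_pmf(m, r_cap)
    probs = pmf[np.minimum(uniq, r_cap)].copy()
    if has_tail:
        tail = max(1.0 - float(pmf.sum()), _TINY)
        probs[uniq >= r_cap] = tail
    return float(np.dot(mult, np.log(np.maximum(probs, _TINY))))


def estimate_m(
    exp: FluctuationExperiment,
    r_max: int = 10_000,
    m_bounds: tuple[float, float] = (1e-6, 1e4),
) -> RateEstimate:
    """Maximum-likelihood m with a 95% likelihood-ratio confidence interval.

    The likelihood is maximized over log m by bounded scalar optimization.
    All-zero counts put the maximum on the m = 0 boundary; the one-sided
    interval then follows from n * m = 1.92.
    """
    counts = exp.counts
    n = len(counts)
    if (counts == 0).all():
        # L(m) = exp(-n m): monotone, maximized at the boundary
        upper = _LR_BOUND / n
        return RateEstimate(m=0.0, log_likelihood=0.0, ci_low=0.0, ci_high=upper)
    capped = np.minimum(counts, r_max)
    has_tail = bool((counts >= r_max).any())
    r_cap = int(capped.max())
    uniq, mult = np.unique(capped, return_counts=True)

    def neg_ll(log_m: float) -> float:
        return -_log_likelihood(math.exp(log_m), uniq, mult, r_cap, has_tail)

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(math.log(m_bounds[0]), math.log(m_bounds[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    m_hat = math.exp(res.x)
    ll_hat = -res.fun

    def deficit(log_m: float) -> float:
        return (-neg_ll(log_m)) - (ll_hat - _LR_BOUND)

    lo_bracket = math.log(m_bounds[0])
    hi_bracket = math.log(m_bounds[1])
    ci_low = m_bounds[0]
    if deficit(lo_bracket) < 0:
        ci_low = math.exp(optimize.brentq(deficit, lo_bracket, math.log(m_hat)))
    ci_high = m_bounds[1]
    if deficit(hi_bracket) < 0:
        ci_high = math.exp(optimize.brentq(deficit, math.log(m_hat), hi_bracket))
    return RateEstimate(m=m_hat, log_likelihood=ll_hat, ci_low=ci_low, ci_high=ci_high)


def mutation_rate(
    estimate: RateEstimate, nt: float, plating_fraction: float = 1.0
) -> RateEstimate:
    """Convert m to a per-cell-per-division rate m / Nt (CI scaled alike).

    ``plating_fraction`` optionally corrects for plating only a dilution of
    each culture (observed counts underestimate m by that factor); the
    default of 1 applies no correction.
    """
    if nt <= 0:
        raise ValueError("Nt must be positive")
    if not 0 < plating_fraction <= 1:
        raise ValueError("plating_fraction must lie in (0, 1]")
    scale = 1.0 / (nt * plating_fraction)
    return RateEstimate(
        m=estimate.m,
        log_likelihood=estimate.log_likelihood,
        ci_low=estimate.ci_low,
        ci_high=estimate.ci_high,
        rate=estimate.m * scale,
        rate_ci_low=estimate.ci_low * scale,
        rate_ci_high=estimate.ci_high * scale,
    )


def analyze_experiment(
    exp: FluctuationExperiment, r_max: int = 10_000, plating_fraction: float = 1.0
) -> RateEstimate:
    """estimate_m followed by the rate conversion, in one call."""
    return mutation_rate(estimate_m(exp, r_max=r_max), exp.nt, plating_fraction)
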