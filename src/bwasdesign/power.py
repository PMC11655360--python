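"""Power, replicability and sample size from the non-central F distribution.

For an effect of size ``S`` tested on ``m`` coefficients in a model with
``df_model`` total mean parameters, the Wald statistic at sample size ``N``
is approximately non-central F with degrees of freedom ``(m, N - df_model)``
and non-centrality ``lambda = N * S**2``.  Power at level ``alpha`` is the
upper tail beyond the central-F critical value; replicability — the chance
that two independent identically designed studies both reject — is power
squared.  With ``m = 1`` this reduces to the single-parameter formula the
index was defined with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "power_ncf",
    "replicability_from_power",
    "n_for_power",
    "n_for_replicability",
    "empirical_power",
    "wilson_interval",
]


@dataclass
class PowerQuery:
    S: float
    alpha: float = 0.05
    df_model: int = 1
    m: int = 1

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1 or self.df_model < 1:
            raise ValueError("m and df_model must be >= 1")


def power_ncf(query: PowerQuery, N: int) -> float:
    """Power of the level-``alpha`` Wald/F test at sample size ``N``."""
    df2 = N - query.df_model
    if df2 <= 0:
        raise ValueError(
            f"N={N} leaves no residual degrees of freedom (df_model={query.df_model})"
        )
    crit = stats.f.ppf(1.0 - query.alpha, query.m, df2)
    lam = N * query.S**2
    if lam == 0.0:
        return float(query.alpha)  # central case: power equals the test level
    return float(stats.ncf.sf(crit, query.m, df2, lam))


def replicability_from_power(p: float) -> float:
    """Probability that two independent identical studies both reject: p^2."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("power must be in [0, 1]")
    return p * p


def n_for_power(query: PowerQuery, gamma: float) -> int:
    """Smallest integer N with ``power_ncf(N) >= gamma``.

    Exponential bracketing followed by integer bisection; power is monotone
    increasing in N so the solver is exact.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    if query.S <= 0:
        raise ValueError(
            "target power unattainable at S = 0 (power never exceeds alpha)"
        )
    lo = query.df_model + 1  # smallest N with positive df2 is df_model + 1
    hi = lo + 1
    while power_ncf(query, hi) < gamma:
        hi *= 2
        if hi > 10**9:
            raise RuntimeError("sample size search exceeded 1e9")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_ncf(query, mid) >= gamma:
            hi = mid
        else:
            lo = mid
    return hi


def n_for_replicability(query: PowerQuery, r: float) -> int:
    """Smallest N achieving replicability ``r``; solves power >= sqrt(r)."""
    if not 0 < r < 1:
        raise ValueError("replicability target must be in (0, 1)")
    return n_for_power(query, float(np.sqrt(r)))


def empirical_power(pvalues, alpha: float = 0.05) -> dict:
    """Share of replicates rejecting at ``alpha``, with its replicability.

    Returns ``{"estimate", "k", "n", "replicability"}`` where ``k`` counts
    p-values at or below ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    k = int(np.sum(p <= alpha))
    est = k / p.size
    return {"estimate": est, "k": k, "n": int(p.size), "replicability": est**2}


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return float(max(0.0, centre - half)), float(min(1.0, centre + half))
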