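"""Driver-gene recurrence statistics.

The significance framework is an exact binomial one: under the null, each
of the ``n`` tumours independently acquires a non-synonymous mutation in a
given gene with probability ``p_bg``, obtained by compounding the cohort's
per-base background mutation rate over the gene's coding footprint.  The
cohort's power to detect a driver mutated in a fraction ``f`` of tumours is
then the probability that the observed count reaches the smallest count
significant at the genome-wide threshold.  Independent experiments are
combined with Fisher's method (-2 * sum(ln p) ~ chi-square on 2k df).

All binomial tails are exact (log-space sums); with n = 42 and thresholds
of 5e-6 the relevant probabilities live far in the tail, where a normal
approximation would be off by orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "DriverTestConfig",
    "PowerResult",
    "MetaResult",
    "gene_background_probability",
    "binomial_recurrence_test",
    "detection_power",
    "fisher_combine",
]


@dataclass(frozen=True)
class DriverTestConfig:
    """Background model and significance thresholds.

    ``background_rate_per_mb`` is the cohort's non-synonymous mutation rate
    mu (per Mb); ``gene_footprint_bp`` the assumed coding footprint of a
    typical gene (1,500 bp default); the two alpha levels are the nominal
    and genome-wide significance thresholds.
    """

    background_rate_per_mb: float = 0.51
    gene_footprint_bp: int = 1500
    alpha_nominal: float = 0.05
    alpha_genomewide: float = 5e-6

    def __post_init__(self):
        if self.background_rate_per_mb < 0:
            raise ValueError("background rate must be >= 0")
        if self.gene_footprint_bp <= 0:
            raise ValueError("gene footprint must be positive")
        if not 0 < self.alpha_genomewide < self.alpha_nominal < 1:
            raise ValueError("require 0 < alpha_genomewide < alpha_nominal < 1")


def gene_background_probability(config: DriverTestConfig) -> float:
    """Per-sample probability of >= 1 background mutation in one gene.

    ``p_bg = 1 - (1 - mu * 1e-6) ** L`` for per-base rate ``mu * 1e-6``
    compounded over the ``L``-bp footprint, evaluated as ``-expm1(L *
    log1p(-mu*1e-6))`` so tiny rates do not underflow.
    """
    per_base = config.background_rate_per_mb * 1e-6
    if per_base >= 1.0:
        raise ValueError("per-base background rate must be < 1")
    if per_base == 0.0:
        return 0.0
    return -math.expm1(config.gene_footprint_bp * math.log1p(-per_base))


def binomial_recurrence_test(mutated_samples: int, n: int, p_bg: float) -> float:
    """Exact upper-tail binomial p-value P(X >= observed | n, p_bg).

    Summed in log-space over the upper tail; observed = 0 gives 1.
    """
    if not 0 <= mutated_samples <= n:
        raise ValueError("mutated_samples must be in [0, n]")
    if not 0.0 <= p_bg < 1.0:
        raise ValueError("p_bg must be in [0, 1)")
    if mutated_samples == 0:
        return 1.0
    ks = np.arange(mutated_samples, n + 1)
    logp = stats.binom.logpmf(ks, n, p_bg)
    return float(min(1.0, math.exp(logsumexp(logp))))


@dataclass(frozen=True)
class PowerResult:
    """Detection power of a cohort of ``n`` for a driver at frequency ``f``.

    ``k_min`` is the smallest mutated-sample count significant at the
    genome-wide threshold under the background ``p_bg``; ``power`` is the
    probability a true driver at frequency ``f`` reaches it.  ``k_min =
    n + 1`` (power 0) when no achievable count is significant.
    """

    n: int
    f: float
    p_bg: float
    k_min: int
    power: float


def detection_power(n: int, f: float,
                    config: DriverTestConfig | None = None) -> PowerResult:
    config = config or DriverTestConfig()
    if not 0 < f <= 1:
        raise ValueError("driver frequency f must be in (0, 1]")
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    p_bg = gene_background_probability(config)
    k_min = n + 1
    for k in range(1, n + 1):
        if binomial_recurrence_test(k, n, p_bg) <= config.alpha_genomewide:
            k_min = k
            break
    if k_min > n:
        power = 0.0
    else:
        # exact upper tail of Binom(n, f) at k_min
        ks = np.arange(k_min, n + 1)
        power = float(min(1.0, math.exp(logsumexp(stats.binom.logpmf(ks, n, f)))))
    return PowerResult(n=n, f=f, p_bg=p_bg, k_min=k_min, power=power)


@dataclass(frozen=True)
class MetaResult:
    component_p: tuple[float, ...]
    statistic: float          # -2 * sum(ln p)
    df: int                   # 2k
    combined_p: float


def fisher_combine(pvalues: list[float]) -> MetaResult:
    """Fisher's combined-probability test over independent p-values."""
    if not pvalues:
        raise ValueError("fisher_combine requires at least one p-value")
    for p in pvalues:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must be in (0, 1]; got {p}")
    statistic = -2.0 * sum(math.log(p) for p in pvalues)
    df = 2 * len(pvalues)
    combined = float(stats.chi2.sf(statistic, df))
    return MetaResult(tuple(pvalues), statistic, df, combined)
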