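"""Hill-number diversity and its multiplicative alpha/beta/gamma partition.

The effective species number of order ``q`` of a relative-abundance vector
``p`` is ``(Σ p_i^q)^(1/(1−q))`` (the Shannon limit ``exp(−Σ p ln p)`` at
q = 1).  Richness is q = 0 and the reciprocal of Simpson's concentration is
q = 2.  For a set of N sites weighted equally, gamma is the Hill number of
the pooled assemblage, alpha is the equal-weight Hill mean across sites

    alpha_q = ( Σ_i Σ_s p_is^q / N )^(1/(1−q)),   p_is within-site proportions,

and beta = gamma / alpha, so the partition is multiplicative by
construction.  At q = 0 alpha reduces to mean site richness and gamma to
pooled richness.  Uncertainty comes from resampling sites with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import AbundanceTable

__all__ = [
    "hill_number",
    "simpson_reciprocal",
    "DiversityPartition",
    "partition_diversity",
    "bootstrap_diversity",
]


def hill_number(counts, q: float = 0.0) -> float:
    """Effective species number of order ``q`` of a single assemblage."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty assemblage")
    p = c[c > 0] / total
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


def simpson_reciprocal(counts) -> float:
    """Simpson's reciprocal diversity ``1 / Σ p_i²`` (Hill number, q = 2)."""
    return hill_number(counts, q=2.0)


@dataclass
class DiversityPartition:
    """Point estimates (and, after bootstrapping, SEs) of the partition."""

    period: str
    q: float
    alpha: float
    beta: float
    gamma: float
    n_sites: int
    se_alpha: float | None = None
    se_beta: float | None = None
    se_gamma: float | None = None
    B_div: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _alpha_gamma(m: np.ndarray, q: float) -> tuple[float, float]:
    """Equal-weight Hill alpha and gamma for a site × species count matrix."""
    totals = m.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a site row has zero total abundance")
    p = m / totals
    n = m.shape[0]
    if q == 0:
        alpha = float((m > 0).sum(axis=1).mean())
    elif q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        alpha = float(np.exp(-plogp.sum(axis=1).mean()))
    else:
        alpha = float((np.sum(p ** q) / n) ** (1.0 / (1.0 - q)))
    gamma = hill_number(m.sum(axis=0), q=q)
    return alpha, gamma


def partition_diversity(table: AbundanceTable, period: str, q: float = 0.0
                        ) -> DiversityPartition:
    """Plug-in alpha/beta/gamma for one period, equal site weights."""
    m = table.subset_period(period).to_numpy(dtype=float)
    alpha, gamma = _alpha_gamma(m, q)
    return DiversityPartition(period=period, q=q, alpha=alpha,
                              beta=gamma / alpha, gamma=gamma,
                              n_sites=m.shape[0])


def bootstrap_diversity(table: AbundanceTable, period: str, q: float = 0.0,
                        B_div: int = 10_000, seed: int | None = None
                        ) -> DiversityPartition:
    """Partition with bootstrap SEs from resampling sites with replacement.

    Point estimates are the plug-in values; the SE of each component is the
    standard deviation of its ``B_div`` bootstrap replicates.  Resampling a
    site k times is equivalent to giving it weight k, which lets all
    replicates be computed from one ``(B_div × N) @ (N × S)`` product.
    """
    m = table.subset_period(period).to_numpy(dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 sites")
    part = partition_diversity(table, period, q)

    rng = np.random.default_rng(seed)
    w = rng.multinomial(n, np.full(n, 1.0 / n), size=B_div).astype(float)  # B×N
    pooled = w @ m                                                         # B×S

    # gamma replicates
    tot = pooled.sum(axis=1, keepdims=True)
    pg = pooled / tot
    if q == 0:
        gam = (pooled > 0).sum(axis=1).astype(float)
    elif q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pg > 0, pg * np.log(pg), 0.0)
        gam = np.exp(-plogp.sum(axis=1))
    else:
        gam = np.sum(pg ** q, axis=1) ** (1.0 / (1.0 - q))

    # alpha replicates from per-site sufficient statistics
    p_site = m / m.sum(axis=1, keepdims=True)
    if q == 0:
        site_stat = (m > 0).sum(axis=1).astype(float)       # richness
        alp = (w @ site_stat) / n
    elif q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p_site > 0, p_site * np.log(p_site), 0.0)
        site_stat = -plogp.sum(axis=1)                      # entropy
        alp = np.exp((w @ site_stat) / n)
    else:
        site_stat = np.sum(p_site ** q, axis=1)
        alp = ((w @ site_stat) / n) ** (1.0 / (1.0 - q))

    bet = gam / alp
    part.se_alpha = float(np.std(alp, ddof=1))
    part.se_beta = float(np.std(bet, ddof=1))
    part.se_gamma = float(np.std(gam, ddof=1))
    part.B_div = B_div
    part.seed = seed
    return part
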