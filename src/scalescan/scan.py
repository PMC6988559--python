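"""Per-grain pooled temporal dissimilarity and the bootstrap discontinuity test.

The scan pools the N matched site pairs into K spatial clusters for every
grain K = N (local) down to K = 1 (global), recomputes the between-period
dissimilarity of each pooled assemblage, and summarizes the K per-cluster
values.  A candidate "domain of scale" boundary at some K is then tested by
resampling: draw K of the N local (K = N) values with replacement, record
their mean, repeat B times, and report the probability that a resampled mean
is ≤ the observed mean at K — a one-sided bootstrap p-value with no
continuity correction, by direct count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import AbundanceTable, pool_sites
from .clustering import MergeTree
from .dissimilarity import morisita_horn_dissimilarity, jaccard_dissimilarity

logger = logging.getLogger("scalescan")

__all__ = [
    "build_pair_table",
    "cluster_temporal_change",
    "ScaleScanResult",
    "scan_all_scales",
    "recovered_domain",
    "BootstrapTestResult",
    "discontinuity_bootstrap_test",
]


def _scalar_index(index: str):
    if index in ("morisita_horn", "morisita"):
        variant = "horn" if index == "morisita_horn" else "morisita"
        return lambda x, y: morisita_horn_dissimilarity(x, y, variant=variant)
    if index == "jaccard":
        return jaccard_dissimilarity
    raise ValueError(f"unknown index {index!r}")


def build_pair_table(table: AbundanceTable, pairs,
                     periods: tuple[str, str] = ("T1", "T2")) -> AbundanceTable:
    """Re-key a site table by matched pair: row (pair, T1) is the first-period
    assemblage of the pair's historical site, row (pair, T2) the second-period
    assemblage of its resurvey site.

    The pair identifier is the historical site id (unique in one-to-one
    matching), or ``"t1~t2"`` when historical ids repeat.
    """
    pa, pb = periods
    ids_t1 = [p.site_t1 for p in pairs]
    use_compound = len(set(ids_t1)) != len(ids_t1)
    rows = {}
    for p in pairs:
        pid = f"{p.site_t1}~{p.site_t2}" if use_compound else p.site_t1
        rows[(pid, pa)] = table.data.loc[(p.site_t1, pa)]
        rows[(pid, pb)] = table.data.loc[(p.site_t2, pb)]
    df = pd.DataFrame(rows).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["site_id", "period"])
    return AbundanceTable(df)


def cluster_temporal_change(table: AbundanceTable,
                            clusters: Mapping[str, int],
                            index: str = "morisita_horn",
                            periods: tuple[str, str] = ("T1", "T2")
                            ) -> np.ndarray:
    """Pool pairs by cluster and return one temporal dissimilarity per cluster.

    Output is ordered by cluster id.  A cluster with no individuals in one
    of the two periods is an error (its change is undefined).
    """
    pa, pb = periods
    dissim = _scalar_index(index)
    pooled = pool_sites(table, clusters)
    out = []
    for cid in sorted(set(clusters.values())):
        key_a, key_b = (str(cid), pa), (str(cid), pb)
        for key in (key_a, key_b):
            if key not in pooled.data.index:
                raise ValueError(f"cluster {cid} has no assemblage in "
                                 f"period {key[1]!r}")
        out.append(dissim(pooled.data.loc[key_a].to_numpy(),
                          pooled.data.loc[key_b].to_numpy()))
    return np.asarray(out, dtype=float)


@dataclass
class ScaleScanResult:
    """Per-grain temporal dissimilarities: ``per_K[K]`` has length K."""

    per_K: dict[int, np.ndarray]
    index_name: str
    n_pairs: int
    cluster_maps: dict[int, dict[str, int]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Boxplot-ready per-K summary (linear-interpolation quartiles)."""
        rows = []
        for K in sorted(self.per_K):
            v = self.per_K[K]
            rows.append({
                "K": K, "n": len(v), "mean": float(np.mean(v)),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q3": float(np.percentile(v, 75)),
                "min": float(np.min(v)), "max": float(np.max(v)),
            })
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [{"K": K, "cluster_id": i + 1, "dissimilarity": float(v)}
                for K in sorted(self.per_K)
                for i, v in enumerate(self.per_K[K])]
        return pd.DataFrame(rows)


def scan_all_scales(table: AbundanceTable, tree: MergeTree,
                    K_range: Iterable[int] | None = None,
                    index: str = "morisita_horn",
                    periods: tuple[str, str] = ("T1", "T2")
                    ) -> ScaleScanResult:
    """Run the scan over every grain in ``K_range`` (default 1..N).

    ``table`` must be keyed by pair (see :func:`build_pair_table`) with the
    tree's leaf labels as its site ids; ``per_K[N]`` then reproduces the
    local paired dissimilarities exactly.
    """
    n = tree.n_leaves
    table_sites = set(table.sites)
    if table_sites != set(tree.labels):
        raise ValueError("tree leaves and table pair ids disagree: "
                         f"{sorted(table_sites ^ set(tree.labels))}")
    Ks = sorted(set(K_range)) if K_range is not None else list(range(1, n + 1))
    per_K: dict[int, np.ndarray] = {}
    cluster_maps: dict[int, dict[str, int]] = {}
    for K in Ks:
        clusters = tree.cut(K)
        cluster_maps[K] = clusters
        per_K[K] = cluster_temporal_change(table, clusters, index, periods)
    return ScaleScanResult(per_K=per_K, index_name=index, n_pairs=n,
                           cluster_maps=cluster_maps)


def recovered_domain(result: ScaleScanResult) -> int:
    """Grain K minimizing the median per-cluster dissimilarity.

    Ties (exactly equal medians) resolve to the smallest K.
    """
    Ks = sorted(result.per_K)
    medians = np.array([np.median(result.per_K[K]) for K in Ks])
    return int(Ks[int(np.argmin(medians))])


@dataclass
class BootstrapTestResult:
    K_tested: int
    observed_mean: float
    B: int
    p_value: float
    seed: int | None
    boot_summary: dict[str, float]
    alternative: str = "less"

    def to_dict(self) -> dict:
        return asdict(self)


def discontinuity_bootstrap_test(local_values: Sequence[float], K_tested: int,
                                 observed_mean: float, B: int = 100_000,
                                 seed: int | None = None,
                                 alternative: str = "less"
                                 ) -> BootstrapTestResult:
    """Bootstrap test of a grain's mean against the local distribution.

    Each of ``B`` iterations draws ``K_tested`` values with replacement from
    the N local dissimilarities and records the mean; the one-sided p-value
    is the exact count fraction of iteration means ≤ ``observed_mean``
    ("less", the default).  ``alternative="two-sided"`` doubles the smaller
    tail (capped at 1).  The summary quantiles of the bootstrap distribution
    use linear interpolation.
    """
    local = np.asarray(local_values, dtype=float)
    if local.size == 0:
        raise ValueError("local_values is empty")
    if not 1 <= K_tested <= local.size:
        raise ValueError(f"K_tested={K_tested} outside 1..{local.size}")
    if B < 1:
        raise ValueError("B must be >= 1")
    if alternative not in ("less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, local.size, size=(B, K_tested))
    means = local[draws].mean(axis=1)
    p_le = np.count_nonzero(means <= observed_mean) / B
    if alternative == "less":
        p = p_le
    else:
        p_ge = np.count_nonzero(means >= observed_mean) / B
        p = min(1.0, 2.0 * min(p_le, p_ge))
    q = np.percentile(means, [0, 25, 50, 75, 100])
    return BootstrapTestResult(
        K_tested=K_tested, observed_mean=float(observed_mean), B=B,
        p_value=float(p), seed=seed, alternative=alternative,
        boot_summary={"min": float(q[0]), "q1": float(q[1]),
                      "median": float(q[2]), "q3": float(q[3]),
                      "max": float(q[4])})
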