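"""End-to-end orchestration: harmonize → pair → dissimilarity → diversity
→ cluster → scan → discontinuity test(s), with a single summary report.

All stochastic stages (the two bootstraps) derive their streams from the
config seed, so a run is a pure function of its inputs and config; the
summary JSON records config, seed, and software version for replay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (AbundanceTable, harmonize_taxa, read_abundance_table,
                        read_sites, TaxonMergeMap)
from .clustering import ward_dendrogram
from .dissimilarity import (jaccard_dissimilarity,
                            morisita_horn_dissimilarity, pairwise_matrix)
from .diversity import bootstrap_diversity, hill_number, simpson_reciprocal
from .pairing import match_sites, read_fluvial_matrix, SitePairSet
from .scan import (build_pair_table, discontinuity_bootstrap_test,
                   scan_all_scales)

logger = logging.getLogger("scalescan")

__all__ = ["PipelineConfig", "PersistenceSummary", "species_persistence",
           "run_pipeline", "run_on_dataset"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and iteration counts of one analysis run.

    The defaults are the study settings: 8 km straight-line pairing cutoff,
    same stream order required, 100,000 bootstrap iterations for the
    discontinuity test, 10,000 for the diversity partition, q = 0, α = 0.05.
    """

    abundance: str | None = None
    sites: str | None = None
    fluvial: str | None = None
    taxon_map: str | None = None
    out_dir: str | None = None
    index_name: str = "morisita_horn"
    max_straight_km: float = 8.0
    require_same_order: bool = True
    one_to_one: bool = True
    K_test: list[int] = field(default_factory=list)
    B: int = 100_000
    B_div: int = 10_000
    q: float = 0.0
    alpha_level: float = 0.05
    periods: tuple[str, str] = ("T1", "T2")
    third_period: str | None = "T3"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "periods" in raw:
            raw["periods"] = tuple(raw["periods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["periods"] = list(self.periods)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PersistenceSummary:
    """Species persistence between two periods, with the rarity breakdown
    of the non-shared species (single-site occurrences, and multi-site
    species never exceeding one individual per site)."""

    n_shared: int
    n_only_a: int
    n_only_b: int
    n_transient_one_site: int
    n_transient_one_individual: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def species_persistence(table: AbundanceTable, period_a: str, period_b: str
                        ) -> PersistenceSummary:
    """Count species shared between two periods vs unique to one.

    A species counts as present in a period if its pooled abundance over all
    sites of that period is positive.  Non-shared (transient) species are
    broken down by rarity: those occurring at exactly one site in their only
    period, and those at several sites but never with more than one
    individual per site.
    """
    a = table.subset_period(period_a)
    b = table.subset_period(period_b)
    pooled_a, pooled_b = a.sum(axis=0), b.sum(axis=0)
    in_a, in_b = pooled_a > 0, pooled_b > 0
    shared = in_a & in_b
    only_a, only_b = in_a & ~in_b, in_b & ~in_a

    one_site = one_ind = 0
    for sp in table.species:
        if shared.get(sp, False) or not (in_a.get(sp, False)
                                         or in_b.get(sp, False)):
            continue
        sub = a[sp] if only_a.get(sp, False) else b[sp]
        n_sites = int((sub > 0).sum())
        if n_sites == 1:
            one_site += 1
        elif int(sub.max()) == 1:
            one_ind += 1
    return PersistenceSummary(
        n_shared=int(shared.sum()), n_only_a=int(only_a.sum()),
        n_only_b=int(only_b.sum()), n_transient_one_site=one_site,
        n_transient_one_individual=one_ind)


def _summary_stats(values: np.ndarray) -> dict:
    return {"n": int(len(values)), "mean": float(np.mean(values)),
            "min": float(np.min(values)),
            "median": float(np.median(values)),
            "max": float(np.max(values))}


def run_on_dataset(table: AbundanceTable, sites: pd.DataFrame,
                   fluvial: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run the full analysis on in-memory inputs; returns the summary dict.

    See :func:`run_pipeline` for the file-based entry point.
    """
    pa, pb = config.periods
    seq = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(["diversity_a", "diversity_b", "tests"],
                                seq.spawn(3))}

    table = harmonize_taxa(table, TaxonMergeMap.from_csv(config.taxon_map)
                           if config.taxon_map else None)

    sites_a = sites[sites.period == pa]
    sites_b = sites[sites.period == pb]
    if sites_a.empty or sites_b.empty:
        raise ValueError(f"site records missing for period {pa!r} or {pb!r}")
    pairs = match_sites(sites_a, sites_b, fluvial,
                        max_straight_km=config.max_straight_km,
                        require_same_order=config.require_same_order,
                        one_to_one=config.one_to_one)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 site pairs retained; cannot scan")
    logger.info("retained %d pairs (%d exact matches)", len(pairs),
                pairs.n_exact)

    pair_table = build_pair_table(table, pairs, periods=(pa, pb))
    matrix = pairwise_matrix(pair_table, index=config.index_name)
    # with the pair table re-keyed so both periods share the pair id, the
    # local values are just the within-pair temporal entries
    local = np.array([matrix[f"{pid}@{pa}", f"{pid}@{pb}"]
                      for pid in pair_table.sites])

    # spatial hierarchy over pairs: fluvial distance between historical sites
    pair_ids = pair_table.sites
    t1_of = {(f"{p.site_t1}~{p.site_t2}"
              if "~" in pair_ids[0] else p.site_t1): p.site_t1 for p in pairs}
    fl = fluvial.loc[[t1_of[pid] for pid in pair_ids],
                     [t1_of[pid] for pid in pair_ids]].to_numpy(dtype=float)
    tree = ward_dendrogram(fl, labels=pair_ids)
    scan = scan_all_scales(pair_table, tree, index=config.index_name,
                           periods=(pa, pb))
    global_value = float(scan.per_K[1][0])

    diversity = {}
    for period, seed_key in ((pa, "diversity_a"), (pb, "diversity_b")):
        part = bootstrap_diversity(table, period, q=config.q,
                                   B_div=config.B_div, seed=seeds[seed_key])
        pooled = table.pooled(period).to_numpy()
        diversity[period] = {**part.to_dict(),
                             "richness": hill_number(pooled, 0),
                             "simpson_reciprocal": simpson_reciprocal(pooled)}

    persistence = species_persistence(table, pa, pb)

    tests = {}
    for i, K in enumerate(config.K_test):
        res = discontinuity_bootstrap_test(
            local, K, float(np.mean(scan.per_K[K])), B=config.B,
            seed=seeds["tests"] + i)
        tests[int(K)] = {**res.to_dict(),
                         "significant": res.p_value < config.alpha_level}

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_pairs": len(pairs),
        "n_exact_pairs": pairs.n_exact,
        "local": _summary_stats(local),
        "global_k1": global_value,
        "persistence": persistence.to_dict(),
        "diversity": diversity,
        "tests": tests,
    }

    # optional third-period (one-year) comparison on the resurveyed subset
    if config.third_period and config.third_period in table.periods:
        pc = config.third_period
        resurvey = sorted(table.subset_period(pc).index)
        scalar = (jaccard_dissimilarity if config.index_name == "jaccard"
                  else morisita_horn_dissimilarity)
        one_year = np.array([scalar(table.counts(s, pb), table.counts(s, pc))
                             for s in resurvey])
        summary["one_year"] = _summary_stats(one_year)

    if config.out_dir:
        _write_outputs(Path(config.out_dir), summary, scan, pairs, tree)
    return summary


def _write_outputs(outdir: Path, summary: dict, scan, pairs: SitePairSet,
                   tree) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    scan.summary().to_csv(outdir / "scan_summary.tsv", sep="\t", index=False)
    scan.to_long_frame().to_csv(outdir / "scan_long.tsv", sep="\t", index=False)
    pairs.write_tsv(outdir / "pairs.tsv")
    (outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    logger.info("wrote results to %s", outdir)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: read the three inputs named in the config and
    run the full analysis."""
    for name in ("abundance", "sites", "fluvial"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config.{name}: {path!r} does not exist")
    table = read_abundance_table(config.abundance, dialect="long")
    sites = read_sites(config.sites)
    fluvial = read_fluvial_matrix(config.fluvial)
    logger.info("run %s: %s", config.digest(), config.to_dict())
    return run_on_dataset(table, sites, fluvial, config)
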