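"""Synthetic dendritic riverscapes and two/three-period metacommunities.

The generator emulates the statistical structure the analysis assumes so
every stage of the pipeline runs offline: ~33 resurveyed sites on a
dendritic network spanning Strahler orders, a ~50-species regional pool
with a long-tailed (lognormal) abundance distribution including rare
near-singleton species, spatially structured occupancy (a species occupies
a contiguous river neighborhood around a focal reach, with probability
decaying in fluvial distance), and temporal turnover that is high at the
site level while the regional pool persists — the local-instability /
global-stability contrast the scale scan is designed to detect.

Two turnover modes exist:

* the default identity-turnover mode: at each site every occupied species
  is independently dropped with probability τ and replaced by a redraw from
  the species available there, after which abundances are redrawn
  multinomially (sites with no identity change keep their counts exactly,
  so τ = 0 reproduces the first period bit-for-bit);
* a planted-domain mode that homogenizes turnover at the tributary scale:
  second-period assemblages within a tributary are a cyclic permutation of
  its first-period assemblages (every site changes; every pooled tributary
  barely does), tributary total abundances drift by lognormal factors (so
  pooling across tributaries mixes stable but different compositions with
  shifted weights and change rises again below the tributary grain), and
  residual site-level abundance jitter grows with tributary isolation
  (rescue-effect reading: well-connected tributaries fluctuate least).
  This plants a recoverable dissimilarity minimum at K = n_tributaries.

Geometry: tributary subtrees are compact (edges ~0.5–4 km) relative to
mainstem junction spacing (~8–20 km), the proportions of headwater
drainages feeding a mainstem, which makes the tributary grain a well-posed
spatial cluster level.  The planar embedding walks each edge with a bounded
turning angle, so straight-line distance never exceeds fluvial distance;
pseudo lat/lon coordinates scale the embedding onto a ~1° box (a 113 × 48
km study extent) with a 3% contraction so the great-circle approximation
stays below the river distance too.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .community import AbundanceTable
from .pairing import haversine_km

logger = logging.getLogger("scalescan")

__all__ = [
    "SyntheticConfig",
    "RiverNetwork",
    "SpeciesPool",
    "SyntheticDataset",
    "generate_network",
    "simulate_metacommunity",
    "apply_turnover",
    "apply_planted_turnover",
    "generate_dataset",
]

_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320
_LATLON_CONTRACTION = 0.97  # keeps haversine <= planar <= fluvial


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic riverscape resurvey."""

    n_sites: int = 33
    n_species: int = 50
    mean_log: float = 2.0          # lognormal regional abundance, log-mean
    sd_log: float = 1.2            # lognormal regional abundance, log-sd
    occupancy_decay: float = 0.03  # per river-km decline of occupancy prob
    local_dominance_sd: float = 1.2  # lognormal sd of site-level dominance
    turnover: float = 0.5          # site-level identity turnover τ, T1→T2
    one_year_turnover: float = 0.15  # τ₂ for the one-year resurvey T2→T3
    n_tributaries: int = 15
    sample_size: int = 150         # individuals collected per site visit
    n_resurvey_t3: int = 8         # sites revisited one year after T2
    planted_domain: bool = False
    trib_edge_km: tuple[float, float] = (0.5, 4.0)
    mainstem_edge_km: tuple[float, float] = (8.0, 20.0)
    weight_shift_sd: float = 1.0   # lognormal sd of tributary abundance drift
    site_jitter_sd: float = 0.25   # isolation-scaled site weight jitter sd
    origin_latlon: tuple[float, float] = (34.2, -96.3)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover must be in [0, 1]")
        if not 0.0 <= self.one_year_turnover <= 1.0:
            raise ValueError("one_year_turnover must be in [0, 1]")
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if self.n_tributaries > self.n_sites:
            raise ValueError("n_tributaries cannot exceed n_sites")
        if self.n_tributaries < 1:
            raise ValueError("need at least 1 tributary")
        if min(self.n_species, self.sample_size) < 1:
            raise ValueError("n_species and sample_size must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RiverNetwork:
    """Dendritic river tree with site placements.

    ``graph`` is an undirected tree whose edges carry ``length`` (km);
    ``root`` is the single outlet.  ``site_nodes`` maps site_id → node,
    ``tributary`` maps site_id → tributary index (the planted truth), and
    ``strahler`` holds the stream order of every node.
    """

    graph: nx.Graph
    root: object
    pos: dict
    site_nodes: dict[str, object]
    strahler: dict[object, int]
    tributary: dict[str, int]
    junctions: dict[int, object]  # tributary index -> mainstem junction node

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.site_nodes)

    def fluvial_distance_matrix(self) -> pd.DataFrame:
        """Pairwise along-network distance (river-km) between sites."""
        ids = self.site_ids
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph,
                                                         weight="length"))
        d = np.zeros((len(ids), len(ids)))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                d[i, j] = lengths[self.site_nodes[a]][self.site_nodes[b]]
        return pd.DataFrame(d, index=ids, columns=ids)

    def node_distance(self, a, b) -> float:
        return nx.dijkstra_path_length(self.graph, a, b, weight="length")

    def latlon(self) -> pd.DataFrame:
        """Pseudo WGS84 coordinates of the sites (contracted embedding)."""
        lat0, lon0 = (34.2, -96.3) if not hasattr(self, "_origin") else self._origin
        rows = []
        coslat = math.cos(math.radians(lat0))
        for sid in self.site_ids:
            x, y = self.pos[self.site_nodes[sid]]
            rows.append({
                "site_id": sid,
                "latitude": lat0 + _LATLON_CONTRACTION * y / _KM_PER_DEG_LAT,
                "longitude": lon0 + _LATLON_CONTRACTION * x
                / (_KM_PER_DEG_LON_EQ * coslat),
            })
        return pd.DataFrame(rows)

    def site_frame(self, periods: list[str]) -> pd.DataFrame:
        """Site metadata records, one row per (site, period)."""
        ll = self.latlon().set_index("site_id")
        rows = []
        for period in periods:
            for sid in self.site_ids:
                rows.append({
                    "site_id": sid, "period": period,
                    "latitude": float(ll.loc[sid, "latitude"]),
                    "longitude": float(ll.loc[sid, "longitude"]),
                    "stream_order": int(self.strahler[self.site_nodes[sid]]),
                })
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick rendering of the tree rooted at the outlet."""
        tree = nx.bfs_tree(self.graph, self.root)
        node_site = {v: k for k, v in self.site_nodes.items()}

        def render(node) -> str:
            kids = list(tree.successors(node))
            label = node_site.get(node, f"n{node}")
            if not kids:
                return label
            inner = ",".join(
                f"{render(c)}:{self.graph[node][c]['length']:.4f}"
                for c in kids)
            return f"({inner}){label}"

        return render(self.root) + ";"


@dataclass
class SpeciesPool:
    """Regional pool and its realized occupancy field.

    ``weights`` are regional relative abundances; ``availability`` is a
    site × species boolean DataFrame saying which species can occur where
    (shared between periods, since the pool persists).  ``local_factors``
    holds, per period, the site × species lognormal dominance factors that
    modulate regional weights locally (lottery/environmental filtering);
    turnover redraws a factor only when the species itself is replaced, so
    local dominance is persistent for persisting species.
    """

    names: list[str]
    weights: np.ndarray
    focal_sites: list[str]
    availability: pd.DataFrame
    local_factors: dict[str, pd.DataFrame] = field(default_factory=dict)


def _strahler_orders(graph: nx.Graph, root) -> dict:
    order: dict = {}
    tree = nx.bfs_tree(graph, root)
    for node in reversed(list(nx.topological_sort(tree))):
        kids = list(tree.successors(node))
        if not kids:
            order[node] = 1
        else:
            k = max(order[c] for c in kids)
            order[node] = k + 1 if sum(order[c] == k for c in kids) >= 2 else k
    return order


def generate_network(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> RiverNetwork:
    """Random dendritic riverscape: a mainstem joined by compact tributary
    subtrees, one site per tributary node."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_tributaries
    g = nx.Graph()

    # mainstem: outlet at the downstream end, junctions upstream of it
    junctions = {}
    prev = "outlet"
    g.add_node(prev)
    x, y = 0.0, 0.0
    pos = {prev: (x, y)}
    for t in range(m):
        node = f"J{t}"
        step = rng.uniform(*config.mainstem_edge_km)
        ang = rng.uniform(-0.35, 0.35)  # radians off the +y axis: meander
        x += step * math.sin(ang)
        y += step * math.cos(ang)
        g.add_edge(prev, node, length=step)
        pos[node] = (x, y)
        junctions[t] = node
        prev = node

    # site allocation across tributaries: as even as possible, remainder
    # spread over rng-chosen tributaries
    base = config.n_sites // m
    extra = config.n_sites - base * m
    sizes = np.full(m, base, dtype=int)
    if extra:
        sizes[rng.choice(m, size=extra, replace=False)] += 1
    if base == 0:
        sizes = np.maximum(sizes, 0)
        if (sizes == 0).any():
            keep = sizes > 0
            logger.info("more tributaries than sites; %d tributaries empty",
                        int((~keep).sum()))

    site_nodes: dict[str, object] = {}
    tributary: dict[str, int] = {}
    counter = 0
    for t in range(m):
        attachables = [junctions[t]]
        child_count = {junctions[t]: 0}
        side = 1 if rng.random() < 0.5 else -1
        # the tributary's first site sits at its mouth on the mainstem, so
        # site stream orders span the drainage hierarchy (headwaters to
        # mainstem) and the same-order pairing filter is meaningful
        if sizes[t] > 0:
            sid = f"S{counter:02d}"
            site_nodes[sid] = junctions[t]
            tributary[sid] = t
            counter += 1
        for _ in range(max(int(sizes[t]) - 1, 0)):
            parents = [a for a in attachables if child_count[a] < 2]
            parent = parents[int(rng.integers(len(parents)))]
            node = f"T{t}n{counter}"
            length = rng.uniform(*config.trib_edge_km)
            px, py = pos[parent]
            ang = side * rng.uniform(0.6, 1.3) + rng.uniform(-0.3, 0.3)
            # unit displacement of exactly the edge length keeps the planar
            # embedding a contraction of the tree metric
            pos[node] = (px + length * math.sin(ang),
                         py + length * math.cos(ang))
            g.add_edge(parent, node, length=length)
            child_count[parent] = child_count.get(parent, 0) + 1
            child_count[node] = 0
            attachables.append(node)
            sid = f"S{counter:02d}"
            site_nodes[sid] = node
            tributary[sid] = t
            counter += 1

    strahler = _strahler_orders(g, "outlet")
    net = RiverNetwork(graph=g, root="outlet", pos=pos, site_nodes=site_nodes,
                       strahler=strahler, tributary=tributary,
                       junctions=junctions)
    net._origin = config.origin_latlon
    return net


def simulate_metacommunity(network: RiverNetwork, config: SyntheticConfig,
                           rng: np.random.Generator | None = None,
                           period: str = "T1"
                           ) -> tuple[AbundanceTable, SpeciesPool]:
    """First-period assemblages: lognormal regional pool, distance-decay
    occupancy around species-specific focal reaches, multinomial sampling."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = network.site_ids
    names = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    weights = rng.lognormal(config.mean_log, config.sd_log, config.n_species)
    focal_idx = rng.integers(0, len(ids), size=config.n_species)
    focal_sites = [ids[i] for i in focal_idx]

    dmat = network.fluvial_distance_matrix().to_numpy()
    # occupancy: Bernoulli with probability exp(-decay * fluvial distance
    # from the species' focal reach); the focal reach itself is certain
    prob = np.exp(-config.occupancy_decay * dmat[:, focal_idx])  # site×species
    avail = rng.random(prob.shape) < prob
    for s in range(config.n_species):
        avail[focal_idx[s], s] = True
    # a site left with nothing available adopts its single best candidate
    for i in range(len(ids)):
        if not avail[i].any():
            avail[i, int(np.argmax(prob[i] * weights))] = True

    # site-level dominance: local lottery/filtering modulates the regional
    # weight of each available species by a persistent lognormal factor
    factors = rng.lognormal(0.0, config.local_dominance_sd,
                            size=(len(ids), config.n_species))
    counts = np.zeros((len(ids), config.n_species), dtype=np.int64)
    for i in range(len(ids)):
        w = np.where(avail[i], weights * factors[i], 0.0)
        counts[i] = rng.multinomial(config.sample_size, w / w.sum())

    pooled = counts.sum(axis=0)
    realized = pooled > 0
    singletons = int(np.sum(pooled == 1))
    if singletons == 0:
        logger.warning("no singleton species realized in the regional sample")
    logger.info("simulated %d sites, %d/%d species realized, %d singletons",
                len(ids), int(realized.sum()), config.n_species, singletons)

    df = pd.DataFrame(counts, columns=names,
                      index=pd.MultiIndex.from_product(
                          [ids, [period]], names=["site_id", "period"]))
    # MultiIndex.from_product pairs every site with the single period label
    table = AbundanceTable(df)
    pool = SpeciesPool(names=names, weights=weights, focal_sites=focal_sites,
                       availability=pd.DataFrame(avail, index=ids,
                                                 columns=names),
                       local_factors={period: pd.DataFrame(
                           factors, index=ids, columns=names)})
    return table, pool


def apply_turnover(table: AbundanceTable, pool: SpeciesPool, tau: float,
                   config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   period: str = "T2", source_period: str | None = None,
                   sites: list[str] | None = None) -> AbundanceTable:
    """Identity turnover within a fixed regional pool (default mode).

    Per site: each occupied species is dropped with probability ``tau`` and
    replaced by a redraw (regional-abundance weighted) from the species
    available there and not already present — a replacement is a different
    species, never the one just lost.  Abundances of changed sites are
    redrawn multinomially over the new set with the site's dominance
    factors, redrawing a factor only for incoming species; sites whose
    species set is unchanged keep their counts exactly, so ``tau = 0``
    reproduces the source period bit-for-bit.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if source_period is None:
        source_period = table.periods[-1]
    src = table.subset_period(source_period)
    if sites is None:
        sites = list(src.index)
    names = list(src.columns)
    weights = np.array([pool.weights[pool.names.index(n)] if n in pool.names
                        else 0.0 for n in names])
    src_factors = pool.local_factors.get(source_period)

    new_rows = {}
    new_factors = {}
    for sid in sites:
        counts = src.loc[sid].to_numpy().copy()
        if src_factors is not None and sid in src_factors.index:
            factors = src_factors.loc[sid].to_numpy().copy()
        else:
            factors = np.ones(len(names))
        occupied = np.flatnonzero(counts > 0)
        drop = occupied[rng.random(len(occupied)) < tau]
        if len(drop) == 0:
            new_rows[(sid, period)] = counts
            new_factors[sid] = factors
            continue
        keep = set(int(i) for i in occupied) - set(int(i) for i in drop)
        if sid in pool.availability.index:
            avail = pool.availability.loc[sid].to_numpy()
        else:
            avail = np.ones(len(names), bool)
        excluded = set(int(i) for i in occupied)  # no self-replacement
        for _ in drop:
            cand = np.flatnonzero(avail)
            cand = np.array([c for c in cand
                             if c not in excluded and c not in keep])
            if len(cand) == 0:
                continue
            w = weights[cand]
            w = w / w.sum() if w.sum() > 0 else np.full(len(cand),
                                                        1.0 / len(cand))
            incoming = int(rng.choice(cand, p=w))
            keep.add(incoming)
            factors[incoming] = rng.lognormal(0.0, config.local_dominance_sd)
        new = np.zeros(len(names))
        if not keep:
            # everything lost and no eligible colonist: the reach is
            # recolonized from whatever the occupancy field allows
            keep = {int(i) for i in np.flatnonzero(avail)} or \
                   {int(i) for i in occupied}
        idx = sorted(keep)
        w = weights[idx] * factors[idx]
        w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
        new[idx] = rng.multinomial(int(counts.sum()), w)
        new_rows[(sid, period)] = new.astype(np.int64)
        new_factors[sid] = factors

    pool.local_factors[period] = pd.DataFrame.from_dict(
        new_factors, orient="index", columns=names)
    df = pd.DataFrame.from_dict(new_rows, orient="index", columns=names)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["site_id", "period"])
    return AbundanceTable(df)


def _tributary_isolation(network: RiverNetwork) -> dict[int, float]:
    """Rescue-effect covariate: each tributary's fluvial distance to its
    nearest neighboring junction, as excess over the best-connected
    tributary (normalized to mean 1).

    The least-isolated tributaries get an excess of ~0: communities that
    exchange migrants most freely fluctuate least, so their pooled
    composition is the most stable.
    """
    tribs = sorted(network.junctions)
    iso = {}
    for t in tribs:
        others = [network.node_distance(network.junctions[t],
                                        network.junctions[u])
                  for u in tribs if u != t]
        iso[t] = min(others) if others else 1.0
    lo = min(iso.values())
    excess = {t: v - lo for t, v in iso.items()}
    mean = np.mean(list(excess.values())) or 1.0
    return {t: v / mean for t, v in excess.items()}


def apply_planted_turnover(table: AbundanceTable, network: RiverNetwork,
                           config: SyntheticConfig,
                           rng: np.random.Generator | None = None,
                           period: str = "T2",
                           source_period: str | None = None) -> AbundanceTable:
    """Tributary-homogenized turnover: plants a change minimum at
    K = n_tributaries (see module docstring for the three ingredients)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if source_period is None:
        source_period = table.periods[-1]
    src = table.subset_period(source_period)
    names = list(src.columns)
    iso = _tributary_isolation(network)

    by_trib: dict[int, list[str]] = {}
    for sid in src.index:
        by_trib.setdefault(network.tributary[sid], []).append(sid)

    new_rows = {}
    for t, members in sorted(by_trib.items()):
        members = sorted(members)
        f_t = rng.lognormal(0.0, config.weight_shift_sd)
        jitter_sd = config.site_jitter_sd * iso.get(t, 1.0)
        # cyclic permutation: no fixed points, no invariant proper subsets,
        # so any split of the tributary exhibits change while the whole does not
        sources = members[1:] + members[:1] if len(members) > 1 else members
        for sid, src_sid in zip(members, sources):
            comp = src.loc[src_sid].to_numpy().astype(float)
            g_i = rng.lognormal(0.0, jitter_sd)
            # deterministic rescaled copy (rounded to whole individuals):
            # population sizes drift, relative composition is carried over,
            # so residual within-tributary change is weight-driven, not
            # resampling noise
            new = np.round(comp * f_t * g_i).astype(np.int64)
            if new.sum() == 0:
                new[int(np.argmax(comp))] = 1
            new_rows[(sid, period)] = new

    df = pd.DataFrame.from_dict(new_rows, orient="index", columns=names)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["site_id", "period"])
    return AbundanceTable(df)


@dataclass
class SyntheticDataset:
    """A complete synthetic study: network, tables, pool, and provenance."""

    config: SyntheticConfig
    network: RiverNetwork
    table: AbundanceTable
    pool: SpeciesPool
    periods: list[str]
    resurvey_sites: list[str]

    def manifest(self) -> dict:
        return {"config": self.config.to_dict(), "periods": self.periods,
                "resurvey_sites": self.resurvey_sites,
                "n_sites": len(self.network.site_ids),
                "tributary": dict(sorted(self.network.tributary.items()))}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .community import write_abundance_table
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundance": outdir / "abundance.csv",
            "sites": outdir / "sites.csv",
            "fluvial": outdir / "fluvial_km.csv",
            "network": outdir / "network.nwk",
            "manifest": outdir / "manifest.json",
        }
        write_abundance_table(self.table, paths["abundance"], dialect="long")
        frame = self.network.site_frame(self.periods[:2])
        if len(self.periods) > 2:
            t3 = self.network.site_frame([self.periods[2]])
            t3 = t3[t3.site_id.isin(self.resurvey_sites)]
            frame = pd.concat([frame, t3], ignore_index=True)
        frame.to_csv(paths["sites"], index=False)
        self.network.fluvial_distance_matrix().to_csv(paths["fluvial"])
        paths["network"].write_text(self.network.to_newick() + "\n")
        paths["manifest"].write_text(json.dumps(self.manifest(), indent=2,
                                                sort_keys=True) + "\n")
        return paths


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministic end-to-end generation: the whole dataset is a pure
    function of the config (all randomness derives from ``config.seed``)."""
    seq = np.random.SeedSequence(config.seed)
    rng_net, rng_meta, rng_turn, rng_t3 = (np.random.default_rng(s)
                                           for s in seq.spawn(4))
    network = generate_network(config, rng_net)
    t1, pool = simulate_metacommunity(network, config, rng_meta, period="T1")
    if config.planted_domain:
        t2 = apply_planted_turnover(t1, network, config, rng_turn,
                                    period="T2", source_period="T1")
    else:
        t2 = apply_turnover(t1, pool, config.turnover, config, rng_turn,
                            period="T2", source_period="T1")
    tables = [t1.data, t2.data]
    periods = ["T1", "T2"]
    resurvey: list[str] = []
    if config.n_resurvey_t3 > 0:
        resurvey = network.site_ids[: config.n_resurvey_t3]
        t3 = apply_turnover(t2, pool, config.one_year_turnover, config,
                            rng_t3, period="T3", source_period="T2",
                            sites=resurvey)
        tables.append(t3.data)
        periods.append("T3")
    table = AbundanceTable(pd.concat(tables))
    return SyntheticDataset(config=config, network=network, table=table,
                            pool=pool, periods=periods,
                            resurvey_sites=resurvey)
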