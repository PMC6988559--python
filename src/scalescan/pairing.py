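"""Matching resurvey sites to historical sites.

Each second-period site is matched to its fluvially nearest first-period
site; a candidate pair is retained only if the straight-line (great-circle)
distance between the two locations is below a threshold (default 8 km) and
both sites lie on stream reaches of the same Strahler order.  In one-to-one
mode (the default) conflicts over a shared historical site are resolved
greedily along a single globally ascending queue of fluvial distances, so
losers fall through to their next-nearest eligible site and no site is used
twice; this prevents pseudo-replication at the cost of not always realizing
the literal per-site "nearest" assignment (``one_to_one=False`` gives that
reading instead, without re-matching filtered-out proposals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("scalescan")

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "SitePair", "SitePairSet",
           "match_sites", "read_fluvial_matrix"]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees (WGS84)."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float)
                              for v in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class SitePair:
    site_t1: str
    site_t2: str
    straight_km: float
    fluvial_km: float
    exact_match: bool  # fluvial distance exactly zero: same location


@dataclass
class SitePairSet:
    pairs: list[SitePair] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    @property
    def n_exact(self) -> int:
        return sum(p.exact_match for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.pairs],
                            columns=["site_t1", "site_t2", "straight_km",
                                     "fluvial_km", "exact_match"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SitePairSet":
        df = pd.read_csv(Path(path), sep="\t",
                         dtype={"site_t1": str, "site_t2": str})
        return cls([SitePair(r.site_t1, r.site_t2, float(r.straight_km),
                             float(r.fluvial_km), bool(r.exact_match))
                    for r in df.itertuples()])


def read_fluvial_matrix(path: str | Path) -> pd.DataFrame:
    """Square river-km distance matrix CSV with site_id header row/column."""
    df = pd.read_csv(Path(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("fluvial matrix rows and columns disagree")
    return df


def _site_lookup(sites: pd.DataFrame) -> pd.DataFrame:
    df = sites.copy()
    df["site_id"] = df["site_id"].astype(str)
    missing = df[["latitude", "longitude", "stream_order"]].isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"sites with missing coordinates/order: "
            f"{df.loc[missing, 'site_id'].tolist()}")
    return df.set_index("site_id")


def match_sites(sites_t1: pd.DataFrame, sites_t2: pd.DataFrame,
                fluvial: pd.DataFrame, *, max_straight_km: float = 8.0,
                require_same_order: bool = True, one_to_one: bool = True
                ) -> SitePairSet:
    """Pair each second-period site with a first-period site.

    Parameters
    ----------
    sites_t1, sites_t2 :
        Site metadata frames (``site_id, latitude, longitude, stream_order``)
        for the two periods.
    fluvial :
        Square river-km distance DataFrame covering all sites of both periods.
    max_straight_km, require_same_order :
        The retention filters; ``numpy.inf`` / ``False`` disable them.
    one_to_one :
        Resolve shared-nearest conflicts greedily (see module docstring).

    The result is deterministic: candidates are processed in ascending
    ``(fluvial_km, site_t2, site_t1)`` order regardless of input row order.
    """
    t1 = _site_lookup(sites_t1)
    t2 = _site_lookup(sites_t2)
    for sid in list(t1.index) + list(t2.index):
        if sid not in fluvial.index:
            raise KeyError(f"site {sid!r} missing from fluvial matrix")

    # eligible candidate pairs after the two retention filters
    candidates: list[tuple[float, str, str, float]] = []
    for s2, r2 in t2.iterrows():
        for s1, r1 in t1.iterrows():
            straight = haversine_km(r1.latitude, r1.longitude,
                                    r2.latitude, r2.longitude)
            if straight >= max_straight_km:
                continue
            if require_same_order and int(r1.stream_order) != int(r2.stream_order):
                continue
            candidates.append((float(fluvial.loc[s1, s2]), s2, s1, float(straight)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    pairs: list[SitePair] = []
    used_t2: set[str] = set()
    used_t1: set[str] = set()
    if one_to_one:
        for fkm, s2, s1, straight in candidates:
            if s2 in used_t2 or s1 in used_t1:
                continue
            used_t2.add(s2)
            used_t1.add(s1)
            pairs.append(SitePair(s1, s2, straight, fkm, fkm == 0.0))
    else:
        # literal reading: each t2 proposes its fluvially nearest t1 site
        # (over all t1, not just eligible ones), and the proposal is dropped
        # if it fails a filter -- no re-matching.
        for s2, r2 in t2.iterrows():
            d = fluvial.loc[list(t1.index), s2].astype(float)
            order = sorted(zip(d.to_numpy(), d.index))
            fkm, s1 = order[0]
            r1 = t1.loc[s1]
            straight = haversine_km(r1.latitude, r1.longitude,
                                    r2.latitude, r2.longitude)
            if straight >= max_straight_km:
                continue
            if require_same_order and int(r1.stream_order) != int(r2.stream_order):
                continue
            pairs.append(SitePair(s1, s2, float(straight), float(fkm), fkm == 0.0))
        pairs.sort(key=lambda p: (p.fluvial_km, p.site_t2, p.site_t1))

    if not pairs:
        logger.warning("site matching produced no pairs")
    unpaired = sorted(set(t2.index) - {p.site_t2 for p in pairs})
    if unpaired:
        logger.info("unpaired second-period sites: %s", unpaired)
    return SitePairSet(pairs)
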