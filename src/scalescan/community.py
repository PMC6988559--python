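"""Site-by-species abundance tables: reading, validation, harmonization, pooling.

The central container is :class:`AbundanceTable`, a thin wrapper around a
pandas DataFrame whose rows are keyed by ``(site_id, period)`` and whose
columns are species names, holding non-negative integer counts of
individuals collected.  Everything downstream (dissimilarity, diversity,
the scale scan) consumes this object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("scalescan")

__all__ = [
    "AbundanceTable",
    "MergeEntry",
    "TaxonMergeMap",
    "DEFAULT_TAXON_MAP",
    "read_abundance_table",
    "write_abundance_table",
    "read_sites",
    "harmonize_taxa",
    "pool_sites",
    "to_presence_absence",
]

LONG_COLUMNS = ("site_id", "period", "species", "count")
SITE_COLUMNS = ("site_id", "period", "latitude", "longitude", "stream_order")


class ValidationError(ValueError):
    """Raised when an input table violates the abundance-table contract."""


class AbundanceTable:
    """Integer community matrix indexed by ``(site_id, period)``.

    Parameters
    ----------
    data :
        DataFrame with a two-level index ``(site_id, period)`` (strings) and
        one column per species, containing non-negative integers.
    drop_empty :
        Rows whose counts are all zero are dropped (with a log message)
        rather than rejected; an assemblage with nothing in it carries no
        information for any index computed here.
    """

    def __init__(self, data: pd.DataFrame, *, drop_empty: bool = True):
        if not isinstance(data.index, pd.MultiIndex) or data.index.nlevels != 2:
            raise ValidationError("index must be a (site_id, period) MultiIndex")
        data = data.copy()
        data.index = data.index.set_names(["site_id", "period"])
        data.index = pd.MultiIndex.from_arrays(
            [data.index.get_level_values(0).astype(str),
             data.index.get_level_values(1).astype(str)],
            names=["site_id", "period"],
        )
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate (site_id, period) row keys: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species columns: {dups}")
        data.columns = data.columns.astype(str)

        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size:
            if np.any(~np.isfinite(values.astype(float))):
                raise ValidationError("counts must be finite")
            if np.any(values < 0):
                bad = data.index[np.any(values < 0, axis=1)].tolist()
                raise ValidationError(f"negative counts in rows: {bad}")
            if np.any(values != np.floor(values)):
                bad = data.index[np.any(values != np.floor(values), axis=1)].tolist()
                raise ValidationError(f"non-integer counts in rows: {bad}")
        data = data.astype(np.int64)

        empty = data.sum(axis=1) == 0
        if empty.any():
            if drop_empty:
                logger.warning("dropping %d all-zero rows: %s",
                               int(empty.sum()), data.index[empty].tolist())
                data = data.loc[~empty]
            else:
                raise ValidationError(
                    f"all-zero rows: {data.index[empty].tolist()}")
        self.data = data

    # -- basic introspection -------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(self.data.index)

    @property
    def periods(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.data.index.get_level_values("period"):
            seen.setdefault(p, None)
        return list(seen)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.index.get_level_values("site_id"):
            seen.setdefault(s, None)
        return list(seen)

    def counts(self, site_id: str, period: str) -> np.ndarray:
        """Abundance vector of one assemblage, in species-column order."""
        return self.data.loc[(str(site_id), str(period))].to_numpy()

    def subset_period(self, period: str) -> pd.DataFrame:
        """Site × species counts for one period (plain DataFrame, site index)."""
        if period not in self.periods:
            raise KeyError(f"period {period!r} not present (have {self.periods})")
        sub = self.data.xs(period, level="period")
        return sub

    def pooled(self, period: str) -> pd.Series:
        """Column sums over all sites of one period: the global assemblage."""
        return self.subset_period(period).sum(axis=0)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, AbundanceTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return (f"AbundanceTable({len(self.data)} assemblages × "
                f"{len(self.data.columns)} species, periods={self.periods})")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def read_abundance_table(path: str | Path, dialect: str = "long") -> AbundanceTable:
    """Read an abundance table from CSV/TSV.

    ``long`` files carry columns ``site_id, period, species, count`` (one row
    per nonzero cell; duplicates of the same triple are an error, not summed).
    ``wide`` files carry one row per ``(site_id, period)`` and one column per
    species; absent cells become zero.
    """
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "long":
        df = pd.read_csv(path, sep=sep, dtype={c: str for c in LONG_COLUMNS[:3]})
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"long file missing columns: {sorted(missing)}")
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts < 0) | (counts != np.floor(counts.fillna(-1)))
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise ValidationError(
                "invalid count "
                f"{row['count']!r} for (site={row['site_id']}, period={row['period']}, "
                f"species={row['species']})")
        keys = df[["site_id", "period", "species"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate record for (site={dup['site_id']}, "
                f"period={dup['period']}, species={dup['species']})")
        wide = df.pivot_table(index=["site_id", "period"], columns="species",
                              values="count", fill_value=0, aggfunc="sum")
        wide.columns.name = None
        return AbundanceTable(wide)
    elif dialect == "wide":
        df = pd.read_csv(path, sep=sep, dtype={"site_id": str, "period": str})
        for col in ("site_id", "period"):
            if col not in df.columns:
                raise ValidationError(f"wide file missing column {col!r}")
        df = df.set_index(["site_id", "period"]).fillna(0)
        return AbundanceTable(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          dialect: str = "long") -> None:
    """Write a table to CSV/TSV; ``long`` (the canonical on-disk form) emits
    only nonzero cells."""
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "long":
        long = (table.data.stack().rename("count").reset_index()
                .rename(columns={"level_2": "species"}))
        long.columns = list(LONG_COLUMNS)
        long = long[long["count"] > 0]
        long = long.sort_values(list(LONG_COLUMNS[:3]), kind="stable")
        long.to_csv(path, sep=sep, index=False)
    elif dialect == "wide":
        table.data.reset_index().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read site metadata (``site_id, period, latitude, longitude, stream_order``)."""
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)),
                     dtype={"site_id": str, "period": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sites file missing columns: {sorted(missing)}")
    if ((df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any()):
        raise ValidationError("latitude/longitude out of range")
    if (df["stream_order"] < 1).any():
        raise ValidationError("stream_order must be >= 1")
    return df


# ---------------------------------------------------------------------------
# Taxon harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeEntry:
    source: str
    target: str
    kind: str = "merge"  # "merge" (sum counts) or "rename" (relabel)

    def __post_init__(self):
        if self.kind not in {"merge", "rename"}:
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass
class TaxonMergeMap:
    """Set of taxon merge/rename operations applied before any analysis.

    A target never appears as a source (no chained mappings), so application
    order cannot matter.
    """

    entries: list[MergeEntry] = field(default_factory=list)

    def __post_init__(self):
        sources = {e.source for e in self.entries}
        targets = {e.target for e in self.entries}
        chained = sources & targets
        if chained:
            raise ValidationError(f"chained taxon mappings via: {sorted(chained)}")
        if len(sources) != len(self.entries):
            raise ValidationError("a source species is mapped twice")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonMergeMap":
        df = pd.read_csv(Path(path))
        kind = df["kind"] if "kind" in df.columns else ["merge"] * len(df)
        return cls([MergeEntry(str(s), str(t), str(k))
                    for s, t, k in zip(df["source"], df["target"], kind)])


#: The three harmonization operations applied to the 1974/2014 fish data:
#: the two Campostoma species and the two Fundulus species were not
#: distinguished in the historical collections, and Notropis rubellus records
#: from this drainage are now referred to N. suttkusi.
DEFAULT_TAXON_MAP = TaxonMergeMap([
    MergeEntry("Campostoma anomalum", "Campostoma spp.", "merge"),
    MergeEntry("Campostoma spadiceum", "Campostoma spp.", "merge"),
    MergeEntry("Fundulus notatus", "Fundulus spp.", "merge"),
    MergeEntry("Fundulus olivaceus", "Fundulus spp.", "merge"),
    MergeEntry("Notropis rubellus", "Notropis suttkusi", "rename"),
])


def harmonize_taxa(table: AbundanceTable, taxon_map: TaxonMergeMap | None = None
                   ) -> AbundanceTable:
    """Apply merge/rename operations; row totals are conserved exactly.

    Sources absent from the table are skipped with a log message.  A rename
    whose target already exists becomes an implicit merge (forced by column
    uniqueness) and is logged as such.
    """
    if taxon_map is None:
        taxon_map = DEFAULT_TAXON_MAP
    df = table.data.copy()
    for entry in taxon_map.entries:
        if entry.source not in df.columns:
            logger.info("taxon map source %r absent; skipped", entry.source)
            continue
        if entry.target in df.columns:
            if entry.kind == "rename":
                logger.warning("rename %r -> %r collides with existing column; "
                               "merging counts", entry.source, entry.target)
            df[entry.target] = df[entry.target] + df[entry.source]
            df = df.drop(columns=[entry.source])
        else:
            df = df.rename(columns={entry.source: entry.target})
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# Pooling and transforms
# ---------------------------------------------------------------------------

def pool_sites(table: AbundanceTable, groups: Mapping[str, object]) -> AbundanceTable:
    """Pool member sites of each cluster, per period.

    ``groups`` maps every site_id in the table to a cluster identifier; output
    rows are keyed ``(cluster_id, period)`` and cells are sums over member
    sites, so the grand total per period is conserved exactly.
    """
    sites = set(table.data.index.get_level_values("site_id"))
    orphans = sorted(sites - {str(s) for s in groups})
    if orphans:
        raise KeyError(f"sites missing from grouping: {orphans}")
    mapped = [str(groups[s]) for s in table.data.index.get_level_values("site_id")]
    pooled = table.data.groupby(
        [pd.Index(mapped, name="site_id"),
         table.data.index.get_level_values("period")]).sum()
    return AbundanceTable(pooled)


def to_presence_absence(table: AbundanceTable) -> AbundanceTable:
    """Binary (0/1) transform; idempotent."""
    return AbundanceTable((table.data > 0).astype(np.int64))
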