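"""Compositional dissimilarity between assemblages.

Two indices are provided, matching the two data resolutions of the analysis:

* ``morisita_horn`` — the abundance-based Horn (1966) form of the
  Morisita index, ``C = 2 Σ x_i y_i / ((d_x + d_y) X Y)`` with
  ``X = Σ x_i``, ``d_x = Σ x_i² / X²`` (and likewise for y);
  dissimilarity is ``1 − C``.  This is the form community-ecology software
  ships under the name "horn"; it is invariant to rescaling either vector,
  so differences in sampling effort between surveys cancel.
* ``morisita`` — the classic Morisita index with the small-sample
  correction ``d_x = Σ x_i (x_i − 1) / (X (X − 1))``; offered as an
  alternative, not the default.
* ``jaccard`` — presence/absence ``1 − a / (a + b + c)``.

Empty assemblages are hard errors rather than NaN: a silent NaN would
propagate through the scale scan and corrupt every downstream summary.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import AbundanceTable, to_presence_absence

__all__ = [
    "EmptyAssemblageError",
    "morisita_horn_dissimilarity",
    "jaccard_dissimilarity",
    "pairwise_matrix",
    "paired_temporal_dissimilarity",
    "row_id",
]

INDICES = ("morisita_horn", "morisita", "jaccard")


class EmptyAssemblageError(ValueError):
    """An assemblage with zero total abundance has no defined composition."""


def _as_counts(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(a < 0):
        raise ValueError(f"{name} contains negative counts")
    return a


def morisita_horn_dissimilarity(x: Sequence[float], y: Sequence[float],
                                *, variant: str = "horn") -> float:
    """Morisita–Horn dissimilarity ``1 − C`` between two count vectors.

    ``variant="horn"`` (default) uses the relative-abundance form;
    ``variant="morisita"`` the classic count form (requires X, Y > 1).
    The result is clamped to [0, 1] against floating-point overshoot.
    """
    x = _as_counts(x, "x")
    y = _as_counts(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise EmptyAssemblageError("empty assemblage (zero total abundance)")
    if variant == "horn":
        dx = (x * x).sum() / X**2
        dy = (y * y).sum() / Y**2
    elif variant == "morisita":
        if X <= 1 or Y <= 1:
            raise EmptyAssemblageError(
                "classic Morisita needs > 1 individual per assemblage")
        dx = (x * (x - 1)).sum() / (X * (X - 1))
        dy = (y * (y - 1)).sum() / (Y * (Y - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    c = 2.0 * (x * y).sum() / ((dx + dy) * X * Y)
    return float(np.clip(1.0 - c, 0.0, 1.0))


def jaccard_dissimilarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Jaccard dissimilarity ``1 − a/(a+b+c)`` on presence/absence.

    Abundance vectors are binarized (> 0) first; an all-absent vector is an
    error, as for the abundance index.
    """
    bx = _as_counts(x, "x") > 0
    by = _as_counts(y, "y") > 0
    if bx.shape != by.shape:
        raise ValueError("x and y must have the same length")
    if not bx.any() or not by.any():
        raise EmptyAssemblageError("empty assemblage (no presences)")
    a = np.count_nonzero(bx & by)
    union = np.count_nonzero(bx | by)
    return float(np.clip(1.0 - a / union, 0.0, 1.0))


def row_id(site_id: str, period: str) -> str:
    """Label of one assemblage row inside a :class:`skbio.DistanceMatrix`."""
    return f"{site_id}@{period}"


def _check_nonempty_rows(table: AbundanceTable) -> None:
    totals = table.data.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise EmptyAssemblageError(f"empty assemblage rows: {list(empty.index)}")


def pairwise_matrix(table: AbundanceTable, index: str = "morisita_horn"
                    ) -> DistanceMatrix:
    """All-pairs dissimilarity over the rows of an abundance table.

    Rows are labelled ``"site@period"``.  The Jaccard matrix of an abundance
    table equals that of its presence/absence transform by construction.
    """
    if index not in INDICES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")
    if len(table.data) < 2:
        raise ValueError("need at least 2 assemblage rows")
    _check_nonempty_rows(table)
    ids = [row_id(s, p) for s, p in table.data.index]
    if len(set(ids)) != len(ids):  # pragma: no cover - index uniqueness upstream
        raise ValueError("non-unique row labels")

    m = table.data.to_numpy(dtype=float)
    if index == "jaccard":
        d = squareform(pdist(m > 0, metric="jaccard"))
    elif index == "morisita_horn":
        p = m / m.sum(axis=1, keepdims=True)
        g = p @ p.T
        s = np.diag(g)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 1.0 - 2.0 * g / (s[:, None] + s[None, :])
    else:  # classic morisita: scalar loop (alternative path, small N)
        n = len(m)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = morisita_horn_dissimilarity(
                    m[i], m[j], variant="morisita")
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    return DistanceMatrix(d, ids=ids)


def paired_temporal_dissimilarity(matrix: DistanceMatrix, pairs,
                                  period_a: str = "T1", period_b: str = "T2"
                                  ) -> np.ndarray:
    """Extract the temporal dissimilarity of each matched site pair.

    ``pairs`` is a :class:`scalescan.pairing.SitePairSet` (or any iterable of
    objects with ``site_t1``/``site_t2``); the value returned for a pair is
    the matrix entry between ``site_t1@period_a`` and ``site_t2@period_b``,
    in pair order.
    """
    out = []
    for pair in pairs:
        ia, ib = row_id(pair.site_t1, period_a), row_id(pair.site_t2, period_b)
        try:
            out.append(matrix[ia, ib])
        except Exception as exc:
            raise KeyError(
                f"pair ({pair.site_t1}, {pair.site_t2}): row {ia!r} or {ib!r} "
                f"missing from matrix") from exc
    return np.asarray(out, dtype=float)
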