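"""Morisita–Horn and Jaccard dissimilarity: exact values and invariances."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scalescan import (jaccard_dissimilarity, morisita_horn_dissimilarity,
                       paired_temporal_dissimilarity, pairwise_matrix,
                       to_presence_absence)
from scalescan.dissimilarity import EmptyAssemblageError

from conftest import identity_pairs, make_table

counts = st.lists(st.integers(0, 100), min_size=3, max_size=8)


def nonempty(v):
    return sum(v) > 0


# ------------------------------------------------------------ scalar values

@pytest.mark.parametrize("x,y,expected", [
    ((5, 3, 2), (5, 3, 2), 0.0),          # identical assemblages
    ((2, 0), (0, 2), 1.0),                # disjoint assemblages
    ((1, 0), (1, 1), 1.0 / 3.0),          # C = 2·1/((1+0.5)·1·2) = 2/3
])
def test_morisita_horn_exact_values(x, y, expected):
    assert morisita_horn_dissimilarity(x, y) == pytest.approx(expected,
                                                              abs=1e-12)


@pytest.mark.parametrize("x,y,expected", [
    ((1, 1, 1, 0), (1, 1, 1, 0), 0.0),
    ((1, 1, 1, 0), (0, 1, 1, 1), 0.5),    # |{B,C}| / |{A,B,C,D}|
    ((1, 1, 0, 0), (0, 0, 1, 1), 1.0),
])
def test_jaccard_exact_values(x, y, expected):
    assert jaccard_dissimilarity(x, y) == pytest.approx(expected, abs=1e-12)


def test_empty_assemblage_is_an_error():
    with pytest.raises(EmptyAssemblageError):
        morisita_horn_dissimilarity([0, 0], [1, 2])
    with pytest.raises(EmptyAssemblageError):
        jaccard_dissimilarity([1, 1], [0, 0])


# ------------------------------------------------------------- invariances

@settings(deadline=None, derandomize=True, max_examples=50)
@given(counts.filter(nonempty), counts.filter(nonempty),
       st.integers(1, 1000))
def test_morisita_horn_scale_invariance(x, y, k):
    if len(x) != len(y):
        y = (y + x)[: len(x)]
    if not nonempty(y):
        return
    base = morisita_horn_dissimilarity(x, y)
    scaled = morisita_horn_dissimilarity(np.array(x) * k, y)
    assert scaled == pytest.approx(base, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(counts.filter(nonempty), counts.filter(nonempty), st.randoms())
def test_permutation_and_zero_column_invariance(x, y, rnd):
    if len(x) != len(y):
        y = (y + x)[: len(x)]
    if not nonempty(y):
        return
    x, y = np.array(x), np.array(y)
    perm = list(range(len(x)))
    rnd.shuffle(perm)
    for f in (morisita_horn_dissimilarity, jaccard_dissimilarity):
        assert f(x[perm], y[perm]) == pytest.approx(f(x, y), abs=1e-12)
        assert f(np.append(x, 0), np.append(y, 0)) == pytest.approx(
            f(x, y), abs=1e-12)


def test_values_stay_in_unit_interval(dataset):
    for index in ("morisita_horn", "jaccard"):
        d = pairwise_matrix(dataset.table, index=index).data
        assert d.min() >= 0.0 and d.max() <= 1.0


# --------------------------------------------------------- pairwise matrix

def test_pairwise_matrix_matches_scalar_calls(dataset):
    sub = make_table({("a", "T1"): {"x": 3, "y": 1, "z": 0},
                      ("b", "T1"): {"x": 0, "y": 2, "z": 5},
                      ("c", "T2"): {"x": 1, "y": 1, "z": 1}})
    for index, scalar in [("morisita_horn", morisita_horn_dissimilarity),
                          ("jaccard", jaccard_dissimilarity)]:
        dm = pairwise_matrix(sub, index=index)
        rows = list(sub.data.index)
        for i, (si, pi) in enumerate(rows):
            for j, (sj, pj) in enumerate(rows):
                expected = 0.0 if i == j else scalar(sub.data.iloc[i],
                                                     sub.data.iloc[j])
                assert dm[f"{si}@{pi}", f"{sj}@{pj}"] == pytest.approx(
                    expected, abs=1e-12)


def test_duplicated_row_has_zero_distance():
    t = make_table({("a", "T1"): {"x": 3, "y": 1},
                    ("b", "T1"): {"x": 3, "y": 1}})
    dm = pairwise_matrix(t)
    assert dm["a@T1", "b@T1"] == 0.0


def test_jaccard_matrix_equal_on_abundance_and_binary(dataset):
    d1 = pairwise_matrix(dataset.table, index="jaccard")
    d2 = pairwise_matrix(to_presence_absence(dataset.table), index="jaccard")
    np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)


def test_paired_extraction_order_and_length(dataset):
    pairs = identity_pairs(dataset.network.site_ids)
    dm = pairwise_matrix(dataset.table)
    v = paired_temporal_dissimilarity(dm, pairs)
    assert len(v) == 33
    first = pairs.pairs[0]
    assert v[0] == dm[f"{first.site_t1}@T1", f"{first.site_t2}@T2"]


def test_paired_extraction_names_missing_pair(dataset):
    dm = pairwise_matrix(dataset.table)
    pairs = identity_pairs(["nope"])
    with pytest.raises(KeyError, match="nope"):
        paired_temporal_dissimilarity(dm, pairs)


# -------------------------------------------- independent oracle (R vegan)

def test_scalar_indices_agree_with_vegan():
    """Cross-check both indices against vegan's vegdist on a fixed matrix."""
    m = np.array([[10, 4, 0, 1, 0],
                  [3, 3, 2, 0, 1],
                  [0, 0, 7, 7, 7]])
    script = textwrap.dedent("""
        suppressMessages(library(vegan))
        m <- matrix(c(10,4,0,1,0, 3,3,2,0,1, 0,0,7,7,7),
                    nrow=3, byrow=TRUE)
        cat(as.vector(vegdist(m, method="horn")), "\\n")
        cat(as.vector(vegdist(m, method="jaccard", binary=TRUE)), "\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True, timeout=120)
    horn_line, jac_line = [l for l in out.stdout.splitlines() if l.strip()]
    ref_horn = [float(v) for v in horn_line.split()]
    ref_jac = [float(v) for v in jac_line.split()]
    ours_horn = [morisita_horn_dissimilarity(m[i], m[j])
                 for i, j in [(0, 1), (0, 2), (1, 2)]]
    ours_jac = [jaccard_dissimilarity(m[i], m[j])
                for i, j in [(0, 1), (0, 2), (1, 2)]]
    np.testing.assert_allclose(ours_horn, ref_horn, atol=1e-6)
    np.testing.assert_allclose(ours_jac, ref_jac, atol=1e-6)
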