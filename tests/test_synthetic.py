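"""The dendritic riverscape generator and its statistical guarantees."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import networkx as nx

from scalescan import (SyntheticConfig, apply_turnover, generate_dataset,
                       generate_network, morisita_horn_dissimilarity,
                       simulate_metacommunity)
from scalescan.synthetic import _strahler_orders


def test_same_seed_reproduces_everything():
    a = generate_dataset(SyntheticConfig(seed=5))
    b = generate_dataset(SyntheticConfig(seed=5))
    pd.testing.assert_frame_equal(a.table.data, b.table.data)
    pd.testing.assert_frame_equal(a.network.fluvial_distance_matrix(),
                                  b.network.fluvial_distance_matrix())


def test_different_seed_changes_edge_lengths():
    a = generate_network(SyntheticConfig(seed=1))
    b = generate_network(SyntheticConfig(seed=2))
    assert not np.allclose(a.fluvial_distance_matrix().to_numpy(),
                           b.fluvial_distance_matrix().to_numpy())


def test_network_is_a_tree_with_one_outlet(dataset):
    g = dataset.network.graph
    assert nx.is_tree(g)
    assert dataset.network.root in g


def test_two_site_network_distance_is_path_length():
    net = generate_network(SyntheticConfig(seed=0, n_sites=2,
                                           n_tributaries=2))
    d = net.fluvial_distance_matrix()
    ids = net.site_ids
    assert d.loc[ids[0], ids[1]] == pytest.approx(
        net.node_distance(net.site_nodes[ids[0]], net.site_nodes[ids[1]]))


def test_strahler_orders_follow_the_standard_recursion():
    # balanced binary tree of depth 3: root order 4
    g = nx.balanced_tree(2, 3)
    orders = _strahler_orders(g, 0)
    assert orders[0] == 4
    assert all(orders[leaf] == 1 for leaf in range(7, 15))
    # joining unequal orders keeps the larger: a chain stays order 1
    chain = nx.path_graph(4)
    assert _strahler_orders(chain, 0)[0] == 1


def test_fluvial_matrix_is_a_tree_metric(dataset):
    """Four-point condition on random quadruples."""
    d = dataset.network.fluvial_distance_matrix().to_numpy()
    rng = np.random.default_rng(0)
    for _ in range(200):
        i, j, k, l = rng.choice(len(d), size=4, replace=False)
        sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l],
                       d[i, l] + d[j, k]])
        assert sums[2] - sums[1] < 1e-8


def test_straight_line_distances_bounded_by_fluvial(dataset):
    net = dataset.network
    fluvial = net.fluvial_distance_matrix()
    ll = net.latlon().set_index("site_id")
    from scalescan import haversine_km
    for a in net.site_ids[::3]:
        for b in net.site_ids[::3]:
            straight = haversine_km(ll.loc[a, "latitude"],
                                    ll.loc[a, "longitude"],
                                    ll.loc[b, "latitude"],
                                    ll.loc[b, "longitude"])
            assert straight <= fluvial.loc[a, b] + 1e-9


def test_sites_span_stream_orders(dataset):
    orders = {dataset.network.strahler[n]
              for n in dataset.network.site_nodes.values()}
    assert min(orders) == 1 and len(orders) >= 2


def test_zero_decay_makes_every_species_available():
    cfg = SyntheticConfig(seed=3, occupancy_decay=0.0)
    net = generate_network(cfg)
    _, pool = simulate_metacommunity(net, cfg,
                                     np.random.default_rng(3))
    assert pool.availability.to_numpy().all()


def test_extreme_decay_confines_species_to_few_sites():
    cfg = SyntheticConfig(seed=3, occupancy_decay=50.0)
    net = generate_network(cfg)
    _, pool = simulate_metacommunity(net, cfg, np.random.default_rng(3))
    sites_per_species = pool.availability.to_numpy().sum(axis=0)
    assert np.median(sites_per_species) <= 2


def test_pooled_abundance_tracks_regional_ranking():
    """Spearman correlation between regional weights and realized pooled
    counts, averaged over 20 seeds."""
    rhos = []
    for seed in range(20):
        ds = generate_dataset(SyntheticConfig(seed=seed, n_resurvey_t3=0))
        pooled = ds.table.pooled("T1").to_numpy()
        rho = spearmanr(ds.pool.weights, pooled).statistic
        rhos.append(rho)
    assert np.mean(rhos) > 0.8


def test_zero_turnover_copies_period_exactly():
    ds = generate_dataset(SyntheticConfig(seed=9, turnover=0.0,
                                          n_resurvey_t3=0))
    t1 = ds.table.subset_period("T1")
    t2 = ds.table.subset_period("T2")
    pd.testing.assert_frame_equal(t1, t2)


def test_full_turnover_with_disjoint_pools_gives_total_change():
    ds = generate_dataset(SyntheticConfig(seed=9, n_resurvey_t3=0))
    t1 = ds.table.subset_period("T1")
    t2 = apply_turnover(ds.table, ds.pool, 1.0, ds.config,
                        np.random.default_rng(0), period="X",
                        source_period="T1").subset_period("X")
    # τ=1 replaces every occupied species with a different one, so local
    # Morisita-Horn change is exactly 1 wherever replacements existed
    mh = [morisita_horn_dissimilarity(t1.loc[s], t2.loc[s])
          for s in t1.index]
    assert np.median(mh) == pytest.approx(1.0, abs=1e-9)


def test_mean_local_change_is_monotone_in_turnover():
    """Averaged over 20 seeds, mean local MH is nondecreasing in τ."""
    taus = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    for tau in taus:
        vals = []
        for seed in range(20):
            ds = generate_dataset(SyntheticConfig(seed=seed, turnover=tau,
                                                  n_resurvey_t3=0))
            t1 = ds.table.subset_period("T1")
            t2 = ds.table.subset_period("T2")
            vals.append(np.mean([morisita_horn_dissimilarity(t1.loc[s],
                                                             t2.loc[s])
                                 for s in t1.index]))
        means.append(np.mean(vals))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_regional_pool_persists_under_turnover(dataset):
    """Identity turnover preserves most of the pooled species list."""
    in_t1 = dataset.table.pooled("T1") > 0
    in_t2 = dataset.table.pooled("T2") > 0
    shared = (in_t1 & in_t2).sum()
    assert shared >= 0.8 * in_t1.sum()


def test_third_period_covers_requested_resurvey_subset(dataset):
    t3 = dataset.table.subset_period("T3")
    assert len(t3) == 8
    assert set(t3.index) == set(dataset.resurvey_sites)


def test_dataset_files_round_trip(tmp_path, dataset):
    from scalescan import read_abundance_table, read_sites
    from scalescan.pairing import read_fluvial_matrix
    paths = dataset.write(tmp_path)
    table = read_abundance_table(paths["abundance"])
    assert set(table.periods) == {"T1", "T2", "T3"}
    sites = read_sites(paths["sites"])
    assert set(sites.period) == {"T1", "T2", "T3"}
    fl = read_fluvial_matrix(paths["fluvial"])
    assert list(fl.index) == dataset.network.site_ids
    manifest = paths["manifest"].read_text()
    assert '"seed": 42' in manifest
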