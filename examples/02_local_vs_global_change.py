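"""Quantify 40-year compositional change locally and for the pooled drainage.

Pairs the two survey periods site by site, computes Morisita-Horn
dissimilarity for each pair, and contrasts the local values with the single
global (all sites pooled) value — the local-instability / global-stability
signature.
"""

import numpy as np

from scalescan import (SyntheticConfig, build_pair_table, generate_dataset,
                       match_sites, morisita_horn_dissimilarity,
                       paired_temporal_dissimilarity, pairwise_matrix)

ds = generate_dataset(SyntheticConfig(seed=7))
sites = ds.network.site_frame(["T1", "T2"])

# pairing applies the retention rules: straight-line distance < 8 km and
# equal Strahler order; here resurveys are at the original reaches, so all
# pairs are exact (fluvial distance 0)
pairs = match_sites(sites[sites.period == "T1"], sites[sites.period == "T2"],
                    ds.network.fluvial_distance_matrix())
print(f"{len(pairs)} retained pairs, {pairs.n_exact} exact matches")

table = build_pair_table(ds.table, pairs)
local = paired_temporal_dissimilarity(pairwise_matrix(table), pairs)
print(f"local MH dissimilarity: mean {local.mean():.2f}, "
      f"range {local.min():.2f}-{local.max():.2f}")

global_mh = morisita_horn_dissimilarity(ds.table.pooled("T1"),
                                        ds.table.pooled("T2"))
print(f"global MH dissimilarity (drainage pooled): {global_mh:.2f}")

# Individual reaches turn over substantially while the pooled drainage
# changes far less: species lost from one reach persist elsewhere.
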