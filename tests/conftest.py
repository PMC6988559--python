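import numpy as np
import pandas as pd
import pytest

from scalescan import (AbundanceTable, SitePair, SitePairSet, SyntheticConfig,
                       generate_dataset)


def make_table(rows: dict[tuple[str, str], dict[str, int]]) -> AbundanceTable:
    """Small abundance tables from literal dicts, for focused unit tests."""
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["site_id", "period"])
    return AbundanceTable(df)


def identity_pairs(site_ids) -> SitePairSet:
    """Each site resurveyed at the same location (all exact matches)."""
    return SitePairSet([SitePair(s, s, 0.0, 0.0, True) for s in site_ids])


@pytest.fixture(scope="session")
def dataset():
    """One default-mode synthetic study, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def planted_dataset():
    """One planted-domain synthetic study, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=42, planted_domain=True,
                                            n_resurvey_t3=0))
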