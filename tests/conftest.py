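import numpy as np
import pandas as pd
import pytest

from gutweb.tabular_io import FeatureTable, SampleMetadata


def make_table(counts, sample_ids=None, feature_ids=None, marker=None, domain=None):
    """Build a FeatureTable from a plain array with sensible defaults."""
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    marker = marker or ["16S"] * p
    domain = domain or ["Bacteria"] * p
    return FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=feature_ids, dtype=np.int64),
        pd.Series(marker, index=feature_ids),
        pd.Series(domain, index=feature_ids),
    )


def make_metadata(sample_ids, host_group="salamander", conc=10.0, is_ntc=False,
                  state="TN", ecoregion="eco1"):
    n = len(sample_ids)
    as_list = lambda v: list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n
    return SampleMetadata(pd.DataFrame(
        {
            "host_group": as_list(host_group),
            "host_genus": ["Plethodon"] * n,
            "state": as_list(state),
            "ecoregion3": as_list(ecoregion),
            "dna_concentration": as_list(conc),
            "is_ntc": as_list(is_ntc),
        },
        index=list(sample_ids),
    ))


@pytest.fixture
def tiny_table():
    return make_table([[1, 2], [3, 4], [5, 6]])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
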