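import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microprot import SpectralCountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_table(counts: dict, lengths: dict, genes: dict | None = None,
               isoforms: dict | None = None, contaminants: set | None = None,
               groups: dict | None = None) -> SpectralCountTable:
    """Build a small count table from plain dicts (accession-keyed)."""
    accs = list(lengths)
    proteins = pd.DataFrame(
        {
            "gene": [genes.get(a, a.lower()) if genes else a.lower() for a in accs],
            "isoform": [isoforms.get(a, "") if isoforms else "" for a in accs],
            "length": [lengths[a] for a in accs],
            "is_contaminant": [a in (contaminants or set()) for a in accs],
        },
        index=pd.Index(accs, name="accession"),
    )
    count_df = pd.DataFrame(counts, index=proteins.index)
    return SpectralCountTable(proteins, count_df, groups or {})


@pytest.fixture
def toy_table() -> SpectralCountTable:
    """3 proteins x 2 samples with unequal lengths."""
    return make_table(
        counts={"s1": [10, 10, 0], "s2": [4, 0, 6]},
        lengths={"A": 100, "B": 50, "C": 200},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
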