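import numpy as np
import pandas as pd
import pytest

from clonescape import LocusAlignment, MultilocusDataset, SimulationConfig, simulate


def make_aln(seqs, name="locus", ids=None):
    """Build a LocusAlignment from a list of equal-length sequences."""
    if ids is None:
        ids = [f"s{i + 1}" for i in range(len(seqs))]
    return LocusAlignment(name, len(seqs[0]), dict(zip(ids, seqs)))


def random_aln(rng, n, L, alphabet="ACGT", p_missing=0.0, name="rand"):
    """Random alignment with a common template plus noise, so sites segregate."""
    template = rng.choice(list(alphabet), size=L)
    rows = []
    for _ in range(n):
        row = template.copy()
        k = rng.integers(0, max(2, L // 8))
        pos = rng.integers(0, L, size=k)
        row[pos] = rng.choice(list(alphabet), size=k)
        if p_missing:
            miss = rng.random(L) < p_missing
            row[miss] = "N"
        rows.append("".join(row))
    return make_aln(rows, name=name)


@pytest.fixture(scope="session")
def sim_default():
    """Default three-lineage clonal simulation with its truth record."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture()
def meta_two_chemotypes():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "population": ["A"] * 4,
            "chemotype": ["UVplus", "UVminus", "UVplus", "UVplus"],
            "morphotype": ["cylindrical_hollow"] * 3 + ["flat_wide"],
            "locality": ["x"] * 4,
            "lat": [np.nan] * 4,
            "lon": [np.nan] * 4,
        }
    )
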