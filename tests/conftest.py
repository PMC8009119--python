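import numpy as np
import pandas as pd
import pytest

from physofrac import simdata


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig.small(seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simdata.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale cohort at the generator's default study conditions."""
    return simdata.simulate_cohort(simdata.SimConfig(seed=7))


@pytest.fixture(scope="session")
def random_tree():
    return simdata.simulate_tree(30, seed=2)


@pytest.fixture(scope="session")
def random_counts(random_tree):
    rng = np.random.default_rng(0)
    taxa = [t.name for t in random_tree.tips()]
    counts = rng.integers(0, 500, size=(20, len(taxa)))
    counts[0] += 1  # no all-zero row
    return pd.DataFrame(counts, index=[f"s{i}" for i in range(20)], columns=taxa)


@pytest.fixture(scope="session")
def random_abundance(random_counts):
    df = random_counts.astype(float)
    return df.div(df.sum(axis=1), axis=0)


def make_count_table(counts: np.ndarray, fractions, individuals=None,
                     treatments=None, asv_prefix="ASV"):
    """Tiny CountTable builder used across test modules."""
    from physofrac.io_formats import CountTable

    n, m = counts.shape
    ids = [f"s{i}" for i in range(n)]
    if individuals is None:
        individuals = [f"I{i + 1:02d}" for i in range(n)]
    if treatments is None:
        treatments = ["NA"] * n
    meta = pd.DataFrame({"individual": individuals, "fraction": list(fractions),
                         "treatment": treatments, "replicate": 1}, index=ids)
    cols = [f"{asv_prefix}{j + 1:03d}" for j in range(m)]
    return CountTable(pd.DataFrame(counts, index=ids, columns=cols), meta)
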