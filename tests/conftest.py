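import numpy as np
import pandas as pd
import pytest

from methylaging import MethylationDataset, SimulationConfig, simulate_aging_cohort
from methylaging.preprocess import preprocess_chain


def make_dataset(percent, ages, coverage=50, groups=None, batches=None, strand="+"):
    """Dataset with exact percent values at uniform coverage.

    ``percent`` is (n_sites, n_samples); counts are chosen so that
    meth/(meth+unmeth) equals percent exactly when percent*coverage/100 is
    integral.
    """
    percent = np.asarray(percent, dtype=float)
    n_sites, n_samples = percent.shape
    meth = percent * coverage / 100.0
    unmeth = coverage - meth
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 1000,
            "strand": [strand] * n_sites,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n_samples)],
            "age_days": np.asarray(ages, dtype=float),
            "batch": batches if batches is not None else ["b1"] * n_samples,
            "dose": np.nan,
            "group": groups if groups is not None else [f"g{a}" for a in ages],
        }
    )
    return MethylationDataset(sites, samples, meth, unmeth)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, n_sites=1200)


@pytest.fixture(scope="session")
def aging_small(small_cfg):
    return simulate_aging_cohort(small_cfg)


@pytest.fixture(scope="session")
def preprocessed_small(aging_small):
    ds, _ = aging_small
    return preprocess_chain(ds)
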