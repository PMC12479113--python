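import numpy as np
import pandas as pd
import pytest

from tfcoverage import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale world used by several suites (kept small for speed)."""
    return WorldConfig(n_tfs=20, n_cell_types=12, n_classes=4,
                       n_experiments=150, n_tss=80, n_snps=120,
                       peaks_per_experiment=25, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def sharp_world():
    """World with an essentially separated expression mixture (16 sigma), so
    StepMiner calls recover the ground truth exactly."""
    cfg = WorldConfig(n_tfs=20, n_cell_types=12, n_classes=4,
                      n_experiments=150, n_tss=80, n_snps=120,
                      peaks_per_experiment=25,
                      mu_low=-1.0, mu_high=3.0, sigma=0.25, seed=7)
    return generate_world(cfg)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame({
        "experiment_id": ["E1", "E2", "E3", "E4"],
        "antigen": ["A", "A", "B", "C"],
        "cell_type": ["X", "X", "Y", "X"],
        "cell_type_class": ["CX", "CX", "CY", "CX"],
        "deposit_date": pd.to_datetime(
            ["2010-05-01", "2012-06-01", "2011-01-15", "2015-09-30"]),
    })


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=2000,
                     max_len=120):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
    })
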