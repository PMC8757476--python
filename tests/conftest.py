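import numpy as np
import pandas as pd
import pytest

from fmtengraft import OtuTable, SimConfig, simulate_trial


@pytest.fixture()
def small_table() -> OtuTable:
    counts = pd.DataFrame(
        [[30, 50, 20], [0, 10, 5], [7, 0, 3]],
        index=["s1", "s2", "s3"],
        columns=["otuA", "otuB", "otuC"],
    )
    taxonomy = {
        "otuA": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales"),
        "otuB": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales"),
        "otuC": ("Bacteria",),
    }
    return OtuTable(counts, taxonomy)


@pytest.fixture(scope="session")
def trial():
    """One default synthetic trial, shared across tests (seed 42)."""
    return simulate_trial(SimConfig(seed=42))


def random_table(rng: np.random.Generator, n_samples: int = 20,
                 n_otus: int = 50) -> OtuTable:
    """A sparse random count table for property tests."""
    counts = rng.poisson(1.5, size=(n_samples, n_otus))
    counts[rng.random(counts.shape) < 0.6] = 0
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"otu{j}" for j in range(n_otus)],
    ))
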