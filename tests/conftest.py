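import numpy as np
import pandas as pd
import pytest

from plasmidome.synthdata import (
    SimulationConfig,
    detect,
    make_source_pool,
    simulate_neutral_abundances,
)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    shift = rng.integers(1, 4, int(hit.sum()))
    codes = np.searchsorted(BASES, arr[hit])
    arr[hit] = BASES[(codes + shift) % 4]
    return "".join(arr)


@pytest.fixture(scope="session")
def neutral_dataset():
    """A small neutral cohort: 200 samples x 300 entities, Nm = 500."""
    pool = make_source_pool(300, seed=11, prefix="E")
    cfg = SimulationConfig(n_samples=200, Nm=500.0, d=1e-3, seed=11)
    abund = simulate_neutral_abundances(pool, cfg)
    presence = detect(abund, cfg.d)
    return {"pool": pool, "cfg": cfg, "abund": abund, "presence": presence}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_metadata(neutral_dataset):
    cfg = neutral_dataset["cfg"]
    g = np.random.default_rng(99)
    idx = neutral_dataset["abund"].sample_ids
    return pd.DataFrame(
        {
            "disease": g.choice(list(cfg.disease_proportions),
                                len(idx), p=list(cfg.disease_proportions.values())),
            "continent": g.choice(["Europe", "NorthAmerica"], len(idx)),
        },
        index=idx,
    )
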