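import numpy as np
import pandas as pd
import pytest

import limnoblot as lb


@pytest.fixture(scope="session")
def builtin_probes():
    return lb.load_builtin_probes()


@pytest.fixture(scope="session")
def builtin_primers():
    return lb.load_builtin_primer_pairs()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic survey shared by read-only tests."""
    return lb.generate_dataset(n_habitats=80, seed=11, with_sequences=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_score_matrix(rng, n_habitats=20, n_probes=5):
    df = pd.DataFrame(
        rng.integers(0, 4, size=(n_habitats, n_probes)),
        index=[f"H{i}" for i in range(n_habitats)],
        columns=[f"P{j}" for j in range(n_probes)],
    )
    return lb.ScoreMatrix(df)


def random_habitats(rng, ids, ph_range=(3.8, 9.1)):
    ph = rng.uniform(*ph_range, size=len(ids))
    return lb.HabitatTable(pd.DataFrame({"pH": ph}, index=pd.Index(ids, name="habitat_id")))
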