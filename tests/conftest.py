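import numpy as np
import pandas as pd
import pytest

from cerna import fixtures


@pytest.fixture(scope="session")
def ovarian_pairs():
    return fixtures.ovarian_pairs()


@pytest.fixture(scope="session")
def ovarian_sites():
    return fixtures.ovarian_sites()


@pytest.fixture
def rng():
    return np.random.default_rng(20240824)


def make_pair_table(rows, class_a, class_b, pair_type):
    """Build a screened-pair table from (id_a, id_b, rho) tuples."""
    return pd.DataFrame(
        [
            {
                "id_a": a,
                "class_a": class_a,
                "id_b": b,
                "class_b": class_b,
                "rho": rho,
                "p": 0.001,
                "q": 0.01,
                "pair_type": pair_type,
                "n_samples": 46,
            }
            for a, b, rho in rows
        ]
    )
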