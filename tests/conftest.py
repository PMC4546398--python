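import numpy as np
import pandas as pd
import pytest

from dualsage import SimConfig, TagCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, fully featured simulation: both species, errors, artifacts."""
    return SimConfig(
        n_host_transcripts=60,
        n_symbiont_transcripts=15,
        depth_ctl=20_000,
        depth_inf=40_000,
        seed=11,
    )


def make_table(rows, n_ctl=None, n_inf=None):
    df = pd.DataFrame(rows, columns=["tag", "count_ctl", "count_inf"])
    return TagCountTable(
        df,
        n_ctl if n_ctl is not None else int(df["count_ctl"].sum()),
        n_inf if n_inf is not None else int(df["count_inf"].sum()),
    )


@pytest.fixture
def random_tags(rng):
    def _make(n, length=26):
        return [
            "".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)
        ]

    return _make
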