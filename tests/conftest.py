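import numpy as np
import pytest

from dms2func import encoding as enc
from dms2func.sequence_data import WildType
from dms2func import synthetic_data as syn


@pytest.fixture(scope="session")
def props():
    return enc.load_property_matrix()


@pytest.fixture(scope="session")
def proj(props):
    return enc.fit_property_projection(props)


@pytest.fixture(scope="session")
def gb1_like_wt():
    """A 56-residue wild type with E at 19 and A at 24 (GB1-style notation)."""
    rng = np.random.default_rng(56)
    seq = list(rng.choice(list("ACDFGHIKLMNPQRSTVWY"), size=56))
    seq[18] = "E"
    seq[23] = "A"
    return WildType(id="wt56", sequence="".join(seq))


@pytest.fixture(scope="session")
def tiny_wt():
    return WildType(id="tiny", sequence="MKTAYIAK")


@pytest.fixture(scope="session")
def small_landscape():
    return syn.build_landscape(syn.LandscapeSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_landscape):
    return syn.sample_dataset(small_landscape, 400, 2, seed=11)
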