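import numpy as np
import pandas as pd
import pytest

from fdshift.data import TRAIT_NAMES, CommunityMatrix, TraitTable
from fdshift.simulate import SyntheticScenario, generate_scenario


@pytest.fixture(scope="session")
def default_survey():
    """One study-scale synthetic survey shared by read-only tests."""
    return generate_scenario(SyntheticScenario(rng_seed=42))


@pytest.fixture(scope="session")
def shared_space(default_survey):
    from fdshift.decomposition import build_shared_space

    pair, _, _ = default_survey
    return build_shared_space(pair, k_use=4)


def make_trait_table(values: np.ndarray, period: str = "P1990",
                     status: str = "native", prefix: str = "sp") -> TraitTable:
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=pd.Index(ids, name="species_id"),
                      columns=list(TRAIT_NAMES))
    st = pd.Series([status] * len(ids), index=df.index, name="status")
    return TraitTable(df, st, period)


def make_community(abund: np.ndarray, species: list[str],
                   period: str = "P1990") -> CommunityMatrix:
    abund = np.atleast_2d(np.asarray(abund, dtype=float))
    sites = [f"S{i}" for i in range(abund.shape[0])]
    df = pd.DataFrame(abund, index=pd.Index(sites, name="site_id"), columns=species)
    return CommunityMatrix(df, period)
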