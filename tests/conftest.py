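import numpy as np
import pandas as pd
import pytest

from oligofish.concordance import PairedCalls
from oligofish.fixtures import load_fixture


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    return load_fixture("cohort")


def _pairs(name: str) -> PairedCalls:
    df = load_fixture(name)
    return PairedCalls(
        df["case_id"].tolist(), df["manual"].tolist(),
        df["automated"].tolist(), df["interpretable"].astype(bool).tolist())


@pytest.fixture(scope="session")
def chr9_pairs() -> PairedCalls:
    return _pairs("concordance_chr9")


@pytest.fixture(scope="session")
def chr10_pairs() -> PairedCalls:
    return _pairs("concordance_chr10")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160)
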