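from pathlib import Path

import pandas as pd
import pytest

from hehprofile.classifier import RiskRule

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def corpus() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "fixture_corpus.csv")


@pytest.fixture(scope="session")
def rule() -> RiskRule:
    return RiskRule.default()
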