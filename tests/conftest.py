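import pandas as pd
import pytest
from hypothesis import settings

from peprt import load_fixture
from peprt.peptides import AMINO_ACIDS

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

#: alphabet string for hypothesis peptide strategies
ALPHABET = "".join(sorted(AMINO_ACIDS))


@pytest.fixture(scope="session")
def calibration() -> pd.DataFrame:
    """The bundled 50-peptide calibration table."""
    return load_fixture("calibration_model_proteins")


@pytest.fixture(scope="session")
def sasp_dprpe() -> pd.DataFrame:
    return load_fixture("sasp_dprpe")


@pytest.fixture(scope="session")
def sasp_168() -> pd.DataFrame:
    return load_fixture("sasp_168")


@pytest.fixture(scope="session")
def pooled_sasp(sasp_dprpe, sasp_168) -> pd.DataFrame:
    """Both strain tables pooled, input order preserved."""
    return pd.concat([sasp_dprpe, sasp_168], ignore_index=True)


@pytest.fixture(scope="session")
def all_rows(calibration, sasp_dprpe, sasp_168) -> pd.DataFrame:
    return pd.concat([calibration, sasp_dprpe, sasp_168], ignore_index=True)
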