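import warnings

import pytest

from hdxmap import cd160
from hdxmap.peptide_chem import ProteinSequence


@pytest.fixture(scope="session")
def parent() -> ProteinSequence:
    return cd160.CD160


@pytest.fixture(scope="session")
def panel():
    return cd160.panel_peptides()


@pytest.fixture(autouse=True)
def _quiet_exposure_flags():
    """Silence the informational relative-SASA flags from toy fixtures.

    The synthetic ring/cage fixtures intentionally have super-exposed
    residues; the >1.2 relative-SASA warning is expected there and would
    otherwise drown real warnings.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="relative SASA above 1.2")
        yield
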