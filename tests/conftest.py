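import numpy as np
import pytest

from crtkit import protein, simulate


@pytest.fixture(scope="session")
def default_cdna():
    """Synthetic cDNA with the PhCRT3a-style default geometry (seed 11)."""
    return simulate.make_cdna(seed=11)


@pytest.fixture(scope="session")
def default_protein(default_cdna):
    record, truth = default_cdna
    return protein.translate(truth.orf.slice(record.sequence), record.id)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
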