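import numpy as np
import pytest

from qsrrkit.molecules import parse_smiles
from qsrrkit.synthetic import (PlantedSignalSpec, gen_descriptor_dataset,
                               gen_molecules)


@pytest.fixture(scope="session")
def probe_smiles():
    """50-molecule C/N/O probe library for descriptor checks."""
    return gen_molecules(50, seed=1)


@pytest.fixture(scope="session")
def probe_molecules(probe_smiles):
    return [parse_smiles(s) for s in probe_smiles]


@pytest.fixture(scope="session")
def planted_small():
    """Low-noise planted-signal dataset for validation-machinery tests."""
    spec = PlantedSignalSpec(n=60, coefficients=(10.0, 3.0, -2.0),
                             k_decoy=5, noise_sd=0.5, seed=7)
    mat, y = gen_descriptor_dataset(spec)
    return mat, y


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
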