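import numpy as np
import pytest

from ccs_propspace import GeneratorConfig, MoleculeRecord, PropertyDataset, generate


@pytest.fixture(scope="session")
def default_dataset() -> PropertyDataset:
    """Moderate synthetic dataset under generator defaults (shared, read-only)."""
    return generate(GeneratorConfig(n_molecules=4000, seed=20231))


@pytest.fixture()
def tiny_dataset() -> PropertyDataset:
    """Hand-built four-molecule dataset with known fields."""
    return PropertyDataset(
        [
            MoleculeRecord("m1", {"C": 6, "H": 8, "O": 1}, "ketone", 6.3, 72.1),
            MoleculeRecord("m2", {"C": 1, "H": 4}, None, 10.5, 17.5),
            MoleculeRecord("m3", {"C": 2, "H": 6, "O": 1}, "primary_alcohol", 7.6, 28.9),
            MoleculeRecord(
                "m4",
                {"C": 3, "H": 6, "O": 1},
                "aldehyde",
                6.5,
                40.0,
                alpha_tensor=np.diag([38.0, 40.0, 42.0]),
            ),
        ],
        provenance="tiny",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
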