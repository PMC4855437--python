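import numpy as np
import pytest

from chemspace3d import chem_io, fixtures


@pytest.fixture
def smiles_file(tmp_path):
    def write(lines, name="lib.smi"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture(scope="session")
def small_library():
    """60 distinct standardized molecules (fast, deterministic)."""
    spec = fixtures.FixtureSpec(n_molecules=60, seed=11)
    records = chem_io.parse_smiles_lines(
        f"{smi} {name}" for smi, name in fixtures.make_library(spec)
    )
    mols, _ = chem_io.standardize_library(records)
    return mols


@pytest.fixture(scope="session")
def library_500():
    """500 distinct standardized molecules for resolution statistics."""
    spec = fixtures.FixtureSpec(n_molecules=500, seed=7)
    records = chem_io.parse_smiles_lines(
        f"{smi} {name}" for smi, name in fixtures.make_library(spec)
    )
    mols, _ = chem_io.standardize_library(records)
    return mols


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
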