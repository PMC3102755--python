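from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from e2dyn.structio import ConformerSet

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = REPO_ROOT / "data"


def make_conformers(
    frames,
    residue_numbers=None,
    atom_names=None,
    elements=None,
    frame_spacing=0.0,
) -> ConformerSet:
    """Build a ConformerSet from raw coordinates with minimal metadata."""
    frames = np.asarray(frames, dtype=float)
    A = frames.shape[1]
    if residue_numbers is None:
        residue_numbers = np.arange(1, A + 1)
    if atom_names is None:
        atom_names = ["CA"] * A
    if elements is None:
        elements = ["C"] * A
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, A + 1),
            "atom_name": atom_names,
            "residue_name": ["ALA"] * A,
            "residue_number": residue_numbers,
            "chain_id": ["A"] * A,
            "element": elements,
        }
    )
    return ConformerSet(atoms=atoms, frames=frames, frame_spacing=frame_spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR
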