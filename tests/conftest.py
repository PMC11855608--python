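import numpy as np
import pytest

from scpermeate.model import AtomRecord, LabeledFrame, SimulationBox


def make_frame(positions, residue_names=None, atom_names=None, box=(10.0, 10.0, 10.0), time=0.0):
    """Build a LabeledFrame from raw coordinates with optional names."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    residue_names = residue_names or ["MOL"] * n
    atom_names = atom_names or ["X"] * n
    atoms = [
        AtomRecord(residue_names[i], atom_names[i], i + 1, positions[i])
        for i in range(n)
    ]
    return LabeledFrame(atoms=atoms, box=SimulationBox(*box), time=time)


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
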