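import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for worked_example

from mdcontacts import ComplexModel, generate_complex


@pytest.fixture
def two_residue_complex():
    """Two single-residue chains whose closest heavy atoms sit 4.0 Å apart."""
    from mdcontacts import Atom

    atoms = [
        Atom(1, "N", "N", 1, "GLY", "A", (0.0, 0.0, 0.0)),
        Atom(2, "CA", "C", 1, "GLY", "A", (1.458, 0.0, 0.0)),
        Atom(3, "N", "N", 1, "ALA", "B", (0.0, 0.0, 4.0)),
        Atom(4, "CA", "C", 1, "ALA", "B", (1.458, 0.0, 4.0)),
    ]
    return ComplexModel(model_id="pair", atoms=atoms)


def random_complex(seed: int, n_per_chain: int = 10) -> ComplexModel:
    """A seeded random two-chain fixture with varying inter-chain separation."""
    rng = np.random.default_rng(seed)
    separation = float(rng.uniform(2.5, 8.0))
    return generate_complex(n_per_chain, separation, seed=seed)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
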