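"""Core containers: atoms, two-chain complex models, trajectories.

A :class:`ComplexModel` is an ordered atom list with cached numpy views
(coordinates, masses, residue grouping) so that distance-heavy operations
stay vectorized while the per-atom record interface remains simple.
Residue identity is the triple ``(chain_id, residue_number, residue_name)``
with author numbering preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .elements import mass_of
from .errors import MassError, ResidueNotFoundError, TopologyError


class ResidueId(NamedTuple):
    """Identity of a residue: chain, author number, 3-letter name."""

    chain_id: str
    number: int
    name: str

    @property
    def label(self) -> str:
        """Compact ``NAME###`` label, e.g. ``GLY256``."""
        return f"{self.name}{self.number}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chain_id}/{self.label}"


@dataclass(frozen=True)
class Atom:
    """One atom record in author (PDB) conventions, coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: tuple[float, float, float]
    mass: float = 0.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinate on atom {self.serial} {self.name}")
        if self.mass <= 0.0:
            object.__setattr__(
                self, "mass", mass_of(self.element, atom_label=f"{self.serial} {self.name}")
            )
        object.__setattr__(self, "is_hydrogen", self.element.strip().upper() == "H")

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_number, self.residue_name)


class Residue(NamedTuple):
    """A contiguous residue: identity plus indices into the atom list."""

    identity: ResidueId
    atom_indices: np.ndarray  # int indices into ComplexModel.atoms


@dataclass
class ComplexModel:
    """A protein-complex structure: ordered atoms grouped into residues.

    Interface operations require exactly two chains; the container itself
    accepts any number so that generators can build structures piecewise.
    """

    model_id: str | int
    atoms: list[Atom]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- cached numpy views ------------------------------------------------
    def _build_cache(self) -> None:
        c = self._cache
        c["coords"] = np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)
        c["masses"] = np.array([a.mass for a in self.atoms], dtype=float)
        c["heavy"] = np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)
        c["chains"] = np.array([a.chain_id for a in self.atoms])
        residues: list[Residue] = []
        current: ResidueId | None = None
        start = 0
        for i, a in enumerate(self.atoms):
            rid = a.residue_id
            if rid != current:
                if current is not None:
                    residues.append(Residue(current, np.arange(start, i)))
                current = rid
                start = i
        if current is not None:
            residues.append(Residue(current, np.arange(start, len(self.atoms))))
        c["residues"] = residues
        c["residue_index"] = {r.identity: r for r in residues}

    def _cached(self, key: str):
        if key not in self._cache:
            self._build_cache()
        return self._cache[key]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å."""
        return self._cached("coords")

    @property
    def masses(self) -> np.ndarray:
        return self._cached("masses")

    @property
    def heavy_mask(self) -> np.ndarray:
        return self._cached("heavy")

    @property
    def chain_array(self) -> np.ndarray:
        return self._cached("chains")

    @property
    def residues(self) -> list[Residue]:
        return self._cached("residues")

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue(self, identity: ResidueId) -> Residue:
        try:
            return self._cached("residue_index")[identity]
        except KeyError:
            raise ResidueNotFoundError(f"residue {identity} not in model {self.model_id}")

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.identity.chain_id == chain_id]

    def topology_key(self) -> tuple[tuple[str, int, str, str], ...]:
        """Canonical per-atom topology tuple, order-sensitive."""
        return tuple(
            (a.chain_id, a.residue_number, a.residue_name, a.name) for a in self.atoms
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexModel":
        """Return a rigid-body transformed copy (rotation then translation)."""
        new_xyz = self.coords @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        atoms = [
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_number=a.residue_number,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                position=tuple(new_xyz[i]),
                mass=a.mass,
            )
            for i, a in enumerate(self.atoms)
        ]
        return ComplexModel(model_id=self.model_id, atoms=atoms)


@dataclass
class Trajectory:
    """Ordered frames of one MD replicate with constant topology."""

    replicate_id: str
    frames: list[ComplexModel]

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError(f"trajectory {self.replicate_id!r} has no frames")
        ref = self.frames[0].topology_key()
        for i, frame in enumerate(self.frames[1:], start=2):
            if frame.topology_key() != ref:
                raise TopologyError(
                    f"trajectory {self.replicate_id!r}: frame {i} topology differs "
                    f"from frame 1"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology_key(self) -> tuple[tuple[str, int, str, str], ...]:
        return self.frames[0].topology_key()


def residue_center_of_mass(
    atoms: Sequence[Atom] | Iterable[Atom], *, heavy_only: bool = False
) -> np.ndarray:
    """Mass-weighted mean position of a set of atoms, in Å.

    Hydrogens are included when present (physical center of mass); pass
    ``heavy_only=True`` to drop them, e.g. when comparing hydrogen-free
    and protonated inputs. Raises MassError if the total mass is zero.
    """
    atoms = list(atoms)
    if heavy_only:
        atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        raise MassError("cannot compute center of mass of zero atoms")
    masses = np.array([a.mass for a in atoms], dtype=float)
    total = masses.sum()
    if total <= 0:
        raise MassError("zero total mass")
    xyz = np.array([a.position for a in atoms], dtype=float)
    return masses @ xyz / total
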