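"""Seeded synthetic fixtures: two-chain complexes, docking ensembles with
planted interface hydrogen bonds, and trajectory replicates with planted
contact persistence and COM-distance distributions.

These generators stand in for undeposited docking ensembles and MD
trajectories. They make no attempt at physical realism (no force field,
no solvent); what they control exactly is the *statistical* structure the
analysis measures:

* per-frame contact with the partner chain is an independent Bernoulli
  event with probability ``p`` (optionally a two-state Markov chain for
  stress tests — the persistence statistic is ordering-insensitive);
* the per-frame COM distance to the closest partner residue is drawn
  from a normal distribution ``N(mu, sigma^2)`` truncated below at 0.1 Å
  and realised geometrically to well within 0.05 Å.

Planted residues are two-equal-mass-atom dumbbells so their center of
mass is controlled in closed form: contact frames align the dumbbells
along the separation axis leaving a heavy-atom gap below the 4.5 Å
contact cutoff, non-contact frames split both dumbbells perpendicular to
it so every heavy-atom pair sits at >= 6 Å whatever the COM distance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .errors import CapacityError, ParameterError
from .interface import HBondCriteria, detect_interface_hbonds
from .io import write_pdb, write_trajectory
from .structures import Atom, ComplexModel, Trajectory

__all__ = [
    "PlantedResidue",
    "TrajectorySpec",
    "EnsembleSpec",
    "generate_complex",
    "generate_ensemble",
    "generate_trajectory",
]

#: COM distance draws are truncated below at this value (Å)
DISTANCE_FLOOR = 0.1
#: heavy-atom gap realised in contact frames (strictly below the 4.5 Å cutoff)
CONTACT_GAP = 3.5
#: minimum heavy-atom separation realised in non-contact frames
NONCONTACT_GAP = 6.5

# idealised glycine backbone, Å (N, CA, C, O in the xy-plane)
_GLY_TEMPLATE = (
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.458, 0.000, 0.000)),
    ("C", "C", (2.009, 1.420, 0.000)),
    ("O", "O", (1.251, 2.390, 0.000)),
)
_RESIDUE_SPACING = 4.0  # Å between consecutive residues along the strand


@dataclass(frozen=True)
class PlantedResidue:
    """A ligand-chain residue with controlled contact statistics."""

    number: int
    contact_probability: float
    distance_mean: float
    distance_sd: float
    name: str = "ALA"

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_probability <= 1.0:
            raise ParameterError(f"contact probability must be in [0, 1]")
        if self.distance_mean <= 0:
            raise ParameterError("distance_mean must be > 0")
        if self.distance_sd < 0:
            raise ParameterError("distance_sd must be >= 0")


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int
    seed: int
    ligand_residues: tuple[PlantedResidue, ...]
    background_residues: int = 0
    frame_jitter: float = 0.0
    ligand_chain: str = "A"
    partner_chain: str = "B"
    #: 1.0 -> i.i.d. Bernoulli contacts; smaller values mix a two-state
    #: Markov chain with the same stationary contact probability
    markov_mixing: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_residues", tuple(self.ligand_residues))
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.background_residues < 0:
            raise ParameterError("background_residues must be >= 0")
        if self.frame_jitter < 0:
            raise ParameterError("frame_jitter must be >= 0")
        if not 0.0 < self.markov_mixing <= 1.0:
            raise ParameterError("markov_mixing must be in (0, 1]")


@dataclass(frozen=True)
class EnsembleSpec:
    seed: int
    planted_counts: tuple[tuple[str | int, int], ...]
    n_per_chain: int = 25
    with_hydrogens: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_counts", tuple(self.planted_counts))
        for model_id, count in self.planted_counts:
            if count < 0:
                raise ParameterError(f"planted count for model {model_id} is negative")


def _strand_atoms(
    chain_id: str,
    n_residues: int,
    origin: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
    serial_start: int,
    res_number_start: int = 1,
) -> list[Atom]:
    atoms: list[Atom] = []
    serial = serial_start
    for i in range(n_residues):
        base = origin + np.array([i * _RESIDUE_SPACING, 0.0, 0.0])
        for name, element, offset in _GLY_TEMPLATE:
            pos = base + np.array(offset)
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, size=3)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_number=res_number_start + i,
                    residue_name="GLY",
                    chain_id=chain_id,
                    position=tuple(pos),
                )
            )
            serial += 1
    return atoms


def generate_complex(
    n_per_chain: int, separation: float, seed: int, *, model_id: str | int = "synthetic"
) -> ComplexModel:
    """Two glycine strands whose closest heavy-atom approach equals
    ``separation`` (adjusted exactly after jitter); deterministic per seed."""
    if n_per_chain < 1:
        raise ParameterError("n_per_chain must be >= 1")
    if separation <= 0:
        raise ParameterError("separation must be > 0")
    rng = np.random.default_rng(seed)
    atoms_a = _strand_atoms("A", n_per_chain, np.zeros(3), rng, 0.02, 1)
    atoms_b = _strand_atoms(
        "B", n_per_chain, np.array([0.0, 0.0, 10.0]), rng, 0.02, len(atoms_a) + 1
    )
    xyz_a = np.array([a.position for a in atoms_a])
    xyz_b = np.array([a.position for a in atoms_b])
    # shift chain B along z so the minimal inter-chain distance is exact
    diff = xyz_a[:, None, :] - xyz_b[None, :, :]
    current = float(np.sqrt((diff**2).sum(-1)).min())
    # move along z; the closest pair is near-vertical so a z-shift changes
    # the minimum near-linearly — iterate to convergence
    shift = 0.0
    for _ in range(50):
        delta = separation - current
        if abs(delta) < 1e-9:
            break
        shift -= delta
        moved = xyz_b + np.array([0.0, 0.0, -shift + 10.0]) - np.array([0.0, 0.0, 10.0])
        diff = xyz_a[:, None, :] - moved[None, :, :]
        current = float(np.sqrt((diff**2).sum(-1)).min())
    atoms_b = [
        Atom(
            serial=a.serial,
            name=a.name,
            element=a.element,
            residue_number=a.residue_number,
            residue_name=a.residue_name,
            chain_id=a.chain_id,
            position=(a.position[0], a.position[1], a.position[2] - shift),
        )
        for a in atoms_b
    ]
    return ComplexModel(model_id=model_id, atoms=atoms_a + atoms_b)


def _planted_model(
    model_id: str | int,
    count: int,
    n_per_chain: int,
    rng: np.random.Generator,
    with_hydrogens: bool,
) -> ComplexModel:
    capacity = (n_per_chain + 1) // 2
    if count > capacity:
        raise CapacityError(
            f"model {model_id}: cannot plant {count} hydrogen bonds in a "
            f"{n_per_chain}-residue chain (capacity {capacity})"
        )
    atoms_a = _strand_atoms("A", n_per_chain, np.zeros(3), rng, 0.02, 1)
    atoms_b = _strand_atoms(
        "B", n_per_chain, np.array([0.0, 20.0, 0.0]), rng, 0.02, len(atoms_a) + 1
    )
    # donor N of every second chain-A residue; move the matching chain-B
    # residue's carbonyl O to 2.9 A along +z (perpendicular to the strand
    # plane, clear of every other polar atom)
    serial = len(atoms_a) + len(atoms_b) + 1
    hydrogens: list[Atom] = []
    for j in range(count):
        donor_res = 2 * j  # residue index on chain A
        donor = atoms_a[donor_res * 4]  # the N atom
        target = np.array(donor.position) + np.array([0.0, 0.0, 2.9])
        o_index = donor_res * 4 + 3  # matching chain-B residue's O
        old = atoms_b[o_index]
        atoms_b[o_index] = Atom(
            serial=old.serial,
            name=old.name,
            element=old.element,
            residue_number=old.residue_number,
            residue_name=old.residue_name,
            chain_id=old.chain_id,
            position=tuple(target),
        )
        if with_hydrogens:
            hpos = np.array(donor.position) + np.array([0.0, 0.0, 1.0])
            hydrogens.append(
                Atom(
                    serial=serial,
                    name="H",
                    element="H",
                    residue_number=donor.residue_number,
                    residue_name=donor.residue_name,
                    chain_id=donor.chain_id,
                    position=tuple(hpos),
                )
            )
            serial += 1
    # keep residues contiguous: splice hydrogens right after their donor N
    if hydrogens:
        merged: list[Atom] = []
        hmap = {(h.chain_id, h.residue_number): h for h in hydrogens}
        for a in atoms_a:
            merged.append(a)
            if a.name == "N" and (a.chain_id, a.residue_number) in hmap:
                merged.append(hmap.pop((a.chain_id, a.residue_number)))
        atoms_a = merged
    return ComplexModel(model_id=model_id, atoms=atoms_a + atoms_b)


def generate_ensemble(spec: EnsembleSpec) -> list[ComplexModel]:
    """Docking-ensemble stand-in with an exact planted number of interface
    hydrogen bonds per model, verified internally with the detector."""
    rng = np.random.default_rng(spec.seed)
    models = []
    for model_id, count in spec.planted_counts:
        model = _planted_model(model_id, count, spec.n_per_chain, rng, spec.with_hydrogens)
        detected = len(detect_interface_hbonds(model, HBondCriteria()))
        if detected != count:  # pragma: no cover - generator self-check
            raise CapacityError(
                f"model {model_id}: planted {count} bonds but detector found {detected}"
            )
        models.append(model)
    return models


_PARTNER_SPACING = 30.0  # Å between dedicated partner residues


def _dumbbell(
    chain: str,
    number: int,
    name: str,
    com: np.ndarray,
    half_offset: np.ndarray,
    serial: int,
) -> list[Atom]:
    """Two equal-mass carbons symmetric about ``com`` (exact COM control)."""
    return [
        Atom(
            serial=serial,
            name="CA",
            element="C",
            residue_number=number,
            residue_name=name,
            chain_id=chain,
            position=tuple(com + half_offset),
        ),
        Atom(
            serial=serial + 1,
            name="CB",
            element="C",
            residue_number=number,
            residue_name=name,
            chain_id=chain,
            position=tuple(com - half_offset),
        ),
    ]


def _contact_states(
    rng: np.random.Generator, p: float, n: int, mixing: float
) -> np.ndarray:
    if mixing >= 1.0:
        return rng.random(n) < p
    # two-state Markov chain with stationary P(contact)=p;
    # mixing -> 1 recovers independence
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p
    p_on = p * mixing  # P(off -> on)
    p_off = (1.0 - p) * mixing  # P(on -> off)
    u = rng.random(n)
    for k in range(1, n):
        states[k] = (u[k] >= p_off) if states[k - 1] else (u[k] < p_on)
    return states


def _draw_distances(
    rng: np.random.Generator, mu: float, sigma: float, n: int
) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, mu)
    a = (DISTANCE_FLOOR - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_trajectory(
    spec: TrajectorySpec,
    path: str | os.PathLike | None = None,
    *,
    replicate_id: str = "rep1",
) -> Trajectory:
    """Trajectory replicate with planted per-residue contact probability
    and COM-distance distribution; optionally written as multi-model PDB.

    Each planted ligand residue faces a dedicated partner residue 30 Å
    from its neighbours, so the closest partner is unambiguous. Background
    residues sit > 10 Å from the partner chain in every frame.
    """
    if not spec.ligand_residues and spec.background_residues == 0:
        raise ParameterError("spec defines no ligand residues at all")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    planted = spec.ligand_residues
    k = len(planted)

    contacts = {
        pr.number: _contact_states(rng, pr.contact_probability, n, spec.markov_mixing)
        for pr in planted
    }
    distances = {
        pr.number: _draw_distances(rng, pr.distance_mean, pr.distance_sd, n)
        for pr in planted
    }
    # rigid per-frame translation of each residue/partner pair keeps the
    # planted geometry exact while still moving coordinates between frames
    jitters = (
        rng.normal(0.0, spec.frame_jitter, size=(n, max(k, 1), 3))
        if spec.frame_jitter > 0
        else np.zeros((n, max(k, 1), 3))
    )
    bg_jitters = (
        rng.normal(0.0, spec.frame_jitter, size=(n, spec.background_residues, 3))
        if spec.frame_jitter > 0
        else np.zeros((n, spec.background_residues, 3))
    )

    frames: list[ComplexModel] = []
    eps = np.array([0.1, 0.0, 0.0])
    for f in range(n):
        atoms: list[Atom] = []
        serial = 1
        # ligand chain first: planted residues in number order
        for i, pr in enumerate(sorted(planted, key=lambda r: r.number)):
            base = np.array([_PARTNER_SPACING * i, 0.0, 0.0]) + jitters[f, i]
            d = float(distances[pr.number][f])
            com_l = base + np.array([d, 0.0, 0.0])
            if contacts[pr.number][f]:
                half = (d - CONTACT_GAP) / 2.0
                off_l = np.array([-max(half, 0.1), 0.0, 0.0])
            else:
                s2 = (NONCONTACT_GAP**2 - d**2) / 2.0
                s = float(np.sqrt(s2)) if s2 > 0 else 0.1
                off_l = np.array([0.0, s, 0.0])
            atoms.extend(
                _dumbbell(spec.ligand_chain, pr.number, pr.name, com_l, off_l, serial)
            )
            serial += 2
        # background residues: far from the partner chain in every frame
        for b in range(spec.background_residues):
            pos = np.array([5.0 * b, 60.0, 0.0]) + bg_jitters[f, b]
            atoms.append(
                Atom(
                    serial=serial,
                    name="CA",
                    element="C",
                    residue_number=1000 + b,
                    residue_name="GLY",
                    chain_id=spec.ligand_chain,
                    position=tuple(pos),
                )
            )
            serial += 1
        # partner chain: one dumbbell per planted residue (or one lone
        # residue when nothing is planted, so the chain exists)
        if planted:
            for i, pr in enumerate(sorted(planted, key=lambda r: r.number)):
                base = np.array([_PARTNER_SPACING * i, 0.0, 0.0]) + jitters[f, i]
                d = float(distances[pr.number][f])
                if contacts[pr.number][f]:
                    half = (d - CONTACT_GAP) / 2.0
                    off_p = np.array([max(half, 0.1), 0.0, 0.0])
                else:
                    s2 = (NONCONTACT_GAP**2 - d**2) / 2.0
                    s = float(np.sqrt(s2)) if s2 > 0 else 0.1
                    off_p = np.array([0.0, 0.0, s])
                atoms.extend(
                    _dumbbell(spec.partner_chain, i + 1, "GLY", base, off_p, serial)
                )
                serial += 2
        else:
            atoms.extend(
                _dumbbell(
                    spec.partner_chain, 1, "GLY", np.array([0.0, 0.0, 0.0]), eps, serial
                )
            )
            serial += 2
        frames.append(ComplexModel(model_id=f"{replicate_id}:{f + 1}", atoms=atoms))

    traj = Trajectory(replicate_id=replicate_id, frames=frames)
    if path is not None:
        write_trajectory(traj, path)
    return traj
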