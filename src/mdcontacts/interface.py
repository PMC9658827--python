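"""Interface residues, inter-chain hydrogen bonds, and docking-model
ranking by interface hydrogen-bond count.

Hydrogen bonds are detected with conventional geometric criteria: a
donor-element heavy atom (N/O/S) and an acceptor-element heavy atom on
opposite chains within a distance cutoff (default 3.5 Å), with an optional
D-H···A angle gate (default 120°) applied only when explicit hydrogens are
present in the structure. Heavy-atom pairs closer than 1.8 Å are treated
as covalent and never counted. Docking ensembles are ranked by descending
bond count with stable (input-order) tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ChainCountError, EmptyInputError, ParameterError
from .structures import Atom, ComplexModel, ResidueId

__all__ = [
    "HBondCriteria",
    "HydrogenBond",
    "RankEntry",
    "ModelRanking",
    "interface_residues",
    "detect_interface_hbonds",
    "rank_models",
    "rank_counts",
]

#: heavy-atom pairs closer than this are considered covalently bonded
COVALENT_CUTOFF = 1.8
#: a hydrogen within this distance of a heavy atom is bonded to it
H_COVALENT_CUTOFF = 1.2


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    The angle gate applies only when an explicit hydrogen bonded to the
    donor is present; hydrogen-free (heavy-atom) structures are judged on
    donor-acceptor distance alone.
    """

    max_donor_acceptor_distance: float = 3.5
    min_dha_angle: float = 120.0
    donor_elements: frozenset[str] = frozenset({"N", "O", "S"})
    acceptor_elements: frozenset[str] = frozenset({"N", "O", "S"})

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ParameterError("max_donor_acceptor_distance must be > 0")
        if not 0.0 <= self.min_dha_angle <= 180.0:
            raise ParameterError("min_dha_angle must be in [0, 180]")


@dataclass(frozen=True)
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float
    hydrogen: Atom | None = None
    angle: float | None = None

    @property
    def atom_pair(self) -> frozenset[int]:
        """Unordered pair key: (chain, serial) of donor and acceptor."""
        return frozenset(
            [(self.donor.chain_id, self.donor.serial), (self.acceptor.chain_id, self.acceptor.serial)]
        )


@dataclass(frozen=True)
class RankEntry:
    rank: int
    model_id: str | int
    hbond_count: int


@dataclass
class ModelRanking:
    entries: list[RankEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = [e.hbond_count for e in self.entries]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("hbond_count must be non-increasing with rank")
        if [e.rank for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be consecutive from 1")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def top(self) -> RankEntry:
        return self.entries[0]


def _two_chains(model: ComplexModel) -> tuple[str, str]:
    chains = model.chain_ids
    if len(chains) != 2:
        raise ChainCountError(
            f"model {model.model_id}: interface operations need exactly 2 chains, "
            f"found {len(chains)} ({chains})"
        )
    return chains[0], chains[1]


def interface_residues(
    model: ComplexModel, cutoff: float = 5.0
) -> dict[str, set[ResidueId]]:
    """Interface residue sets per chain.

    A residue is an interface residue iff any of its heavy atoms lies
    within ``cutoff`` (strictly) of any heavy atom of the other chain.
    Returns ``{chain_id: set of ResidueId}`` for both chains.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    chain_a, chain_b = _two_chains(model)
    heavy = model.heavy_mask
    in_a = (model.chain_array == chain_a) & heavy
    in_b = (model.chain_array == chain_b) & heavy
    idx_a = np.flatnonzero(in_a)
    idx_b = np.flatnonzero(in_b)
    result: dict[str, set[ResidueId]] = {chain_a: set(), chain_b: set()}
    if len(idx_a) == 0 or len(idx_b) == 0:
        return result
    dist = cdist(model.coords[idx_a], model.coords[idx_b])
    close = dist < cutoff
    atoms = model.atoms
    for local_i in np.flatnonzero(close.any(axis=1)):
        result[chain_a].add(atoms[idx_a[local_i]].residue_id)
    for local_j in np.flatnonzero(close.any(axis=0)):
        result[chain_b].add(atoms[idx_b[local_j]].residue_id)
    return result


def _bonded_hydrogens(model: ComplexModel, donor_index: int) -> list[int]:
    """Indices of hydrogens covalently bonded to the donor atom."""
    h_idx = np.flatnonzero(~model.heavy_mask)
    if len(h_idx) == 0:
        return []
    d = np.linalg.norm(model.coords[h_idx] - model.coords[donor_index], axis=1)
    return [int(i) for i in h_idx[d < H_COVALENT_CUTOFF]]


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_interface_hbonds(
    model: ComplexModel, criteria: HBondCriteria | None = None
) -> list[HydrogenBond]:
    """Detect hydrogen bonds crossing the two-chain interface.

    Heavy-atom mode (no hydrogens in the model): a bond is any
    donor-element / acceptor-element heavy-atom pair on opposite chains
    within the distance cutoff and beyond the covalent cutoff.
    Explicit-hydrogen mode (hydrogens present): additionally requires a
    hydrogen bonded to the donor with D-H···A angle >= the minimum; the
    best-angle hydrogen is reported. Each atom pair appears at most once.
    """
    if criteria is None:
        criteria = HBondCriteria()
    chain_a, chain_b = _two_chains(model)
    has_hydrogens = bool((~model.heavy_mask).any())
    polar = criteria.donor_elements | criteria.acceptor_elements

    atoms = model.atoms
    cand_a = [
        i
        for i, a in enumerate(atoms)
        if a.chain_id == chain_a and not a.is_hydrogen and a.element.upper() in polar
    ]
    cand_b = [
        i
        for i, a in enumerate(atoms)
        if a.chain_id == chain_b and not a.is_hydrogen and a.element.upper() in polar
    ]
    if not cand_a or not cand_b:
        return []
    dist = cdist(model.coords[cand_a], model.coords[cand_b])
    bonds: list[HydrogenBond] = []
    seen: set[frozenset] = set()
    for ii, i in enumerate(cand_a):
        for jj, j in enumerate(cand_b):
            d = float(dist[ii, jj])
            if d > criteria.max_donor_acceptor_distance or d < COVALENT_CUTOFF:
                continue
            bond = _classify_pair(model, i, j, d, criteria, has_hydrogens)
            if bond is None:
                continue
            key = bond.atom_pair
            if key in seen:
                continue
            seen.add(key)
            bonds.append(bond)
    return bonds


def _classify_pair(
    model: ComplexModel,
    i: int,
    j: int,
    d: float,
    criteria: HBondCriteria,
    has_hydrogens: bool,
) -> HydrogenBond | None:
    """Try both donor/acceptor orientations of a cross-chain pair."""
    atoms = model.atoms
    for di, ai in ((i, j), (j, i)):
        donor, acceptor = atoms[di], atoms[ai]
        if donor.element.upper() not in criteria.donor_elements:
            continue
        if acceptor.element.upper() not in criteria.acceptor_elements:
            continue
        if not has_hydrogens:
            return HydrogenBond(donor=donor, acceptor=acceptor, distance=d)
        best: tuple[float, int] | None = None
        for h in _bonded_hydrogens(model, di):
            ang = _dha_angle(model.coords[di], model.coords[h], model.coords[ai])
            if ang >= criteria.min_dha_angle and (best is None or ang > best[0]):
                best = (ang, h)
        if best is not None:
            return HydrogenBond(
                donor=donor,
                acceptor=acceptor,
                distance=d,
                hydrogen=atoms[best[1]],
                angle=best[0],
            )
    return None


def rank_counts(
    counts: Iterable[tuple[str | int, int]], top_n: int | None = None
) -> ModelRanking:
    """Rank (model_id, hbond_count) pairs.

    Descending by count; ties keep the input order (stable sort); the
    list is truncated to ``top_n`` when given.
    """
    pairs = list(counts)
    if not pairs:
        raise EmptyInputError("cannot rank an empty ensemble")
    ordered = sorted(pairs, key=lambda mc: -mc[1])
    if top_n is not None:
        if top_n < 1:
            raise ParameterError("top_n must be >= 1")
        ordered = ordered[:top_n]
    return ModelRanking(
        [RankEntry(rank=r, model_id=m, hbond_count=c) for r, (m, c) in enumerate(ordered, 1)]
    )


def rank_models(
    models: Sequence[ComplexModel],
    criteria: HBondCriteria | None = None,
    top_n: int | None = None,
) -> ModelRanking:
    """Rank a docking ensemble by interface hydrogen-bond count."""
    if not models:
        raise EmptyInputError("cannot rank an empty ensemble")
    counts = [(m.model_id, len(detect_interface_hbonds(m, criteria))) for m in models]
    return rank_counts(counts, top_n=top_n)
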