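"""Per-residue contact persistence and center-of-mass distance statistics
over MD trajectory replicates.

Two separate, configurable gates realise the residue-relevance criteria:

* **persistence** — the fraction of frames in which any heavy atom of the
  ligand-chain residue lies within an atomic cutoff (default 4.5 Å,
  strict ``<``) of any heavy atom of the partner chain must exceed a
  threshold (default 0.80, strict ``>``);
* **COM distance** — the mean over frames of the distance between the
  residue's center of mass and the center of mass of the closest
  partner-chain residue must fall below a cutoff (default 5.0 Å, strict
  ``<``).

The two metrics are deliberately distinct: a residue can be in persistent
atomic contact while its COM sits beyond 5 Å, so ``criteria_mode``
chooses whether selection uses persistence alone (default) or the
conjunction of both gates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ParameterError, ResidueNotFoundError
from .structures import ComplexModel, ResidueId, Trajectory, residue_center_of_mass

__all__ = [
    "ContactCriteria",
    "DistanceSeries",
    "ResidueContactSummary",
    "AggregateRecord",
    "residue_center_of_mass",
    "per_frame_min_com_distance",
    "atomic_contact",
    "analyze_replicate",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Thresholds for nominating interface-relevant residues."""

    persistence_threshold: float = 0.80
    com_distance_threshold: float = 5.0
    atomic_contact_cutoff: float = 4.5
    criteria_mode: Literal["persistence_and_com", "persistence_only"] = "persistence_only"

    def __post_init__(self) -> None:
        if not 0.0 < self.persistence_threshold <= 1.0:
            raise ParameterError("persistence_threshold must be in (0, 1]")
        if self.com_distance_threshold <= 0 or self.atomic_contact_cutoff <= 0:
            raise ParameterError("distance thresholds must be > 0")
        if self.criteria_mode not in ("persistence_and_com", "persistence_only"):
            raise ParameterError(f"unknown criteria_mode {self.criteria_mode!r}")


@dataclass
class DistanceSeries:
    """Per-frame COM distance of one residue to its closest partner residue."""

    residue: ResidueId
    replicate_id: str
    values: np.ndarray  # (n_frames,) Å
    closest_partner_per_frame: list[ResidueId]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"invalid distance series for {self.residue}")


@dataclass(frozen=True)
class ResidueContactSummary:
    residue: ResidueId
    replicate_id: str
    persistence_fraction: float
    mean_distance: float
    sd_distance: float
    passes_criteria: bool


@dataclass
class AggregateRecord:
    """Cross-replicate aggregate for one residue."""

    residue: ResidueId
    pooled_mean: float
    pooled_sd: float
    n_frames: int
    pass_flags: dict[str, bool]  # replicate_id -> passed criteria

    @property
    def n_replicates_passed(self) -> int:
        return sum(self.pass_flags.values())


def _residue_heavy_coords(frame: ComplexModel, residue: ResidueId) -> np.ndarray:
    res = frame.residue(residue)
    idx = res.atom_indices[frame.heavy_mask[res.atom_indices]]
    return frame.coords[idx]


def per_frame_min_com_distance(
    frame: ComplexModel, residue: ResidueId, partner_chain: str
) -> tuple[float, ResidueId]:
    """COM distance from a residue to the closest partner-chain residue.

    Returns ``(distance, partner_residue)`` where the partner minimises
    the COM-COM distance; ties break to the lowest partner residue number.
    """
    res = frame.residue(residue)  # raises ResidueNotFoundError if absent
    com = residue_center_of_mass(frame.atoms[i] for i in res.atom_indices)
    partners = frame.chain_residues(partner_chain)
    if not partners:
        raise ResidueNotFoundError(f"partner chain {partner_chain!r} is empty")
    best: tuple[float, int, ResidueId] | None = None
    for p in partners:
        pcom = residue_center_of_mass(frame.atoms[i] for i in p.atom_indices)
        d = float(np.linalg.norm(com - pcom))
        key = (d, p.identity.number)
        if best is None or key < (best[0], best[1]):
            best = (d, p.identity.number, p.identity)
    return best[0], best[2]


def atomic_contact(
    frame: ComplexModel, residue: ResidueId, partner_chain: str, cutoff: float = 4.5
) -> bool:
    """True iff any heavy atom of the residue is strictly within ``cutoff``
    of any heavy atom of the partner chain."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    res_xyz = _residue_heavy_coords(frame, residue)
    partner_mask = (frame.chain_array == partner_chain) & frame.heavy_mask
    partner_xyz = frame.coords[partner_mask]
    if len(res_xyz) == 0 or len(partner_xyz) == 0:
        return False
    return bool(cdist(res_xyz, partner_xyz).min() < cutoff)


def analyze_replicate(
    traj: Trajectory,
    ligand_chain: str,
    partner_chain: str,
    criteria: ContactCriteria | None = None,
) -> tuple[list[ResidueContactSummary], list[DistanceSeries]]:
    """Contact persistence and COM-distance statistics for every
    ligand-chain residue of one replicate.

    For each residue: ``persistence_fraction`` is the fraction of frames
    in atomic contact with the partner chain; the distance series holds
    the per-frame COM distance to the closest partner residue; mean and
    SD (population, divide-by-N) are over the full series. Pass/fail
    follows the criteria mode.
    """
    if criteria is None:
        criteria = ContactCriteria()
    if traj.n_frames < 1:
        raise EmptyInputError("trajectory has no frames")
    first = traj.frames[0]
    ligand_residues = [r.identity for r in first.chain_residues(ligand_chain)]
    if not ligand_residues:
        raise ResidueNotFoundError(f"no residues on ligand chain {ligand_chain!r}")
    if not first.chain_residues(partner_chain):
        raise ResidueNotFoundError(f"no residues on partner chain {partner_chain!r}")

    summaries: list[ResidueContactSummary] = []
    series_out: list[DistanceSeries] = []
    for rid in ligand_residues:
        dists = np.empty(traj.n_frames)
        partners: list[ResidueId] = []
        n_contact = 0
        for k, frame in enumerate(traj.frames):
            d, partner = per_frame_min_com_distance(frame, rid, partner_chain)
            dists[k] = d
            partners.append(partner)
            if atomic_contact(frame, rid, partner_chain, criteria.atomic_contact_cutoff):
                n_contact += 1
        persistence = n_contact / traj.n_frames
        mean = float(dists.mean())
        sd = float(dists.std(ddof=0))
        passes = persistence > criteria.persistence_threshold
        if criteria.criteria_mode == "persistence_and_com":
            passes = passes and mean < criteria.com_distance_threshold
        summaries.append(
            ResidueContactSummary(
                residue=rid,
                replicate_id=traj.replicate_id,
                persistence_fraction=persistence,
                mean_distance=mean,
                sd_distance=sd,
                passes_criteria=passes,
            )
        )
        series_out.append(
            DistanceSeries(
                residue=rid,
                replicate_id=traj.replicate_id,
                values=dists,
                closest_partner_per_frame=partners,
            )
        )
    return summaries, series_out


def aggregate_replicates(
    summaries: Iterable[ResidueContactSummary],
    series: Iterable[DistanceSeries],
    *,
    pooling: Literal["frames", "replicate_means"] = "frames",
) -> list[AggregateRecord]:
    """Pool per-replicate results into per-residue aggregates.

    ``pooling="frames"`` (default) concatenates the per-frame distances of
    every replicate in which the residue appears and takes mean and
    population SD over the pool. ``pooling="replicate_means"`` instead
    averages the per-replicate means and takes the population SD across
    those means (0 for a single replicate). Per-replicate pass flags are
    preserved for the prevalence stage. Output is sorted ascending by
    pooled mean.
    """
    summaries = list(summaries)
    series = list(series)
    if not summaries:
        raise EmptyInputError("no replicate summaries to aggregate")
    by_residue_series: dict[ResidueId, list[DistanceSeries]] = {}
    for s in series:
        by_residue_series.setdefault(s.residue, []).append(s)
    by_residue_flags: dict[ResidueId, dict[str, bool]] = {}
    for summ in summaries:
        by_residue_flags.setdefault(summ.residue, {})[summ.replicate_id] = (
            summ.passes_criteria
        )

    records: list[AggregateRecord] = []
    for rid, slist in by_residue_series.items():
        if pooling == "frames":
            pool = np.concatenate([s.values for s in slist])
            mean = float(pool.mean())
            sd = float(pool.std(ddof=0))
            n = int(pool.size)
        elif pooling == "replicate_means":
            means = np.array([s.values.mean() for s in slist])
            mean = float(means.mean())
            sd = float(means.std(ddof=0))
            n = int(sum(s.values.size for s in slist))
        else:
            raise ParameterError(f"unknown pooling {pooling!r}")
        records.append(
            AggregateRecord(
                residue=rid,
                pooled_mean=mean,
                pooled_sd=sd,
                n_frames=n,
                pass_flags=by_residue_flags.get(rid, {}),
            )
        )
    records.sort(key=lambda r: (r.pooled_mean, r.residue.number))
    return records
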