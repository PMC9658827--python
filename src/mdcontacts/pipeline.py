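"""End-to-end orchestration: rank a docking ensemble, analyze MD
replicates, aggregate distances, and compute residue prevalence.

Outputs are four TSV tables shaped like the study deliverables:
``ranking.tsv`` (model rank by interface H-bond count), per-replicate
``selection_<id>.tsv`` (persistence / distance summaries with pass
flags), ``distances.tsv`` (pooled per-residue mean/SD sorted ascending)
and ``prevalence.tsv`` (replicate counts and tiers), plus a
``provenance.json`` echoing configuration and versions. Tables carry no
timestamps so identical inputs reproduce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .contacts import (
    AggregateRecord,
    ContactCriteria,
    ResidueContactSummary,
    aggregate_replicates,
    analyze_replicate,
)
from .errors import MDContactsError, ParameterError, PipelineError
from .interface import HBondCriteria, ModelRanking, rank_models
from .io import read_pdb, read_trajectory, write_table
from .prevalence import PrevalenceRecord, compute_prevalence, unique_top_residue

logger = logging.getLogger("mdcontacts")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    trajectory_files: dict[str, str]  # replicate_id -> multi-model PDB path
    ligand_chain: str
    partner_chain: str
    ensemble_dir: str | None = None
    top_n: int = 10
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ligand_chain == self.partner_chain:
            raise ParameterError("ligand and partner chain IDs must differ")


@dataclass
class RunReport:
    ranking: ModelRanking | None
    summaries: dict[str, list[ResidueContactSummary]]  # per replicate
    aggregates: list[AggregateRecord]
    prevalence: list[PrevalenceRecord]
    top_residue: object | None
    provenance: dict


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MDContactsError as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run ranking (optional), replicate analysis, aggregation and
    prevalence; write all tables under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ranking: ModelRanking | None = None
    if config.ensemble_dir is not None:
        paths = sorted(
            p for p in Path(config.ensemble_dir).iterdir() if p.suffix == ".pdb"
        )
        if not paths:
            raise PipelineError(f"stage 'ranking' failed: no .pdb files in {config.ensemble_dir}")
        logger.info("ranking %d docking models", len(paths))
        models = [_stage(f"read {p.name}", read_pdb, p) for p in paths]
        ranking = _stage(
            "ranking", rank_models, models, config.hbond_criteria, config.top_n
        )
        write_table(
            [
                {"rank": e.rank, "model_id": e.model_id, "hbond_count": e.hbond_count}
                for e in ranking
            ],
            out / "ranking.tsv",
        )

    all_summaries: dict[str, list[ResidueContactSummary]] = {}
    all_series = []
    for rep_id, path in config.trajectory_files.items():
        logger.info("analyzing replicate %s (%s)", rep_id, path)
        traj = _stage(f"read trajectory {rep_id}", read_trajectory, path, rep_id)
        summaries, series = _stage(
            f"analyze {rep_id}",
            analyze_replicate,
            traj,
            config.ligand_chain,
            config.partner_chain,
            config.contact_criteria,
        )
        all_summaries[rep_id] = summaries
        all_series.extend(series)
        write_table(
            [
                {
                    "residue": s.residue.label,
                    "persistence": round(s.persistence_fraction, 4),
                    "mean_distance": s.mean_distance,
                    "sd_distance": s.sd_distance,
                    "passes": s.passes_criteria,
                }
                for s in summaries
            ],
            out / f"selection_{rep_id}.tsv",
            float_decimals=4,
        )

    flat_summaries = [s for lst in all_summaries.values() for s in lst]
    aggregates = _stage(
        "aggregate", aggregate_replicates, flat_summaries, all_series
    )
    write_table(
        [
            {
                "residue": a.residue.label,
                "pooled_mean": a.pooled_mean,
                "pooled_sd": a.pooled_sd,
                "n_frames": a.n_frames,
                "n_replicates_passed": a.n_replicates_passed,
            }
            for a in aggregates
        ],
        out / "distances.tsv",
    )

    selections = [
        {s.residue for s in summaries if s.passes_criteria}
        for summaries in all_summaries.values()
    ]
    pooled_means = {a.residue: a.pooled_mean for a in aggregates}
    prevalence = _stage("prevalence", compute_prevalence, selections, pooled_means)
    top = unique_top_residue(prevalence) if prevalence else None
    write_table(
        [
            {
                "residue": r.residue.label,
                "count": r.count,
                "tier": r.tier,
                "pooled_mean_distance": r.pooled_mean_distance,
            }
            for r in prevalence
        ],
        out / "prevalence.tsv",
    )

    provenance = {
        "package": "mdcontacts",
        "version": __version__,
        "seed": config.seed,
        "ligand_chain": config.ligand_chain,
        "partner_chain": config.partner_chain,
        "trajectory_files": {k: str(v) for k, v in config.trajectory_files.items()},
        "ensemble_dir": str(config.ensemble_dir) if config.ensemble_dir else None,
        "hbond_criteria": {
            "max_donor_acceptor_distance": config.hbond_criteria.max_donor_acceptor_distance,
            "min_dha_angle": config.hbond_criteria.min_dha_angle,
        },
        "contact_criteria": {
            "persistence_threshold": config.contact_criteria.persistence_threshold,
            "com_distance_threshold": config.contact_criteria.com_distance_threshold,
            "atomic_contact_cutoff": config.contact_criteria.atomic_contact_cutoff,
            "criteria_mode": config.contact_criteria.criteria_mode,
        },
        "unique_top_residue": top.label if top is not None else None,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write(os.linesep)

    # report consistency: every prevalent residue came from some selection
    selected_union = set().union(*selections) if selections else set()
    assert all(r.residue in selected_union for r in prevalence)

    return RunReport(
        ranking=ranking,
        summaries=all_summaries,
        aggregates=aggregates,
        prevalence=prevalence,
        top_residue=top,
        provenance=provenance,
    )
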