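"""Cross-replicate prevalence of selected residues.

A residue's prevalence is the number of independent MD replicates in
which it satisfied the contact criteria. Residues present in every
replicate are the strongest interface candidates; a residue that is the
*unique* maximum is reported as the top candidate, ties yield none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

from .errors import EmptyInputError

__all__ = ["PrevalenceRecord", "compute_prevalence", "unique_top_residue", "tier_for"]


def tier_for(count: int, n_replicates: int) -> str:
    """Tier label from a prevalence count.

    ``all_replicates`` when the residue passed in every replicate,
    ``single`` when in exactly one, ``majority`` in between.
    """
    if count == n_replicates:
        return "all_replicates"
    if count == 1:
        return "single"
    return "majority"


@dataclass(frozen=True)
class PrevalenceRecord:
    residue: Hashable
    count: int
    tier: str
    pooled_mean_distance: float | None = None


def compute_prevalence(
    per_replicate_selected: Sequence[set],
    pooled_mean_distance: Mapping[Hashable, float] | None = None,
) -> list[PrevalenceRecord]:
    """Tally how many replicate selections contain each residue.

    ``per_replicate_selected`` is one set of residue identities per
    replicate. Residues absent from every set are omitted. Records are
    sorted by count descending, then pooled mean distance ascending when
    provided (unknown means sort last), then by a stable string key.
    """
    if not per_replicate_selected:
        raise EmptyInputError("no replicate selections given")
    n_rep = len(per_replicate_selected)
    counts: dict[Hashable, int] = {}
    for selected in per_replicate_selected:
        for residue in selected:
            counts[residue] = counts.get(residue, 0) + 1
    means = pooled_mean_distance or {}
    records = [
        PrevalenceRecord(
            residue=residue,
            count=count,
            tier=tier_for(count, n_rep),
            pooled_mean_distance=means.get(residue),
        )
        for residue, count in counts.items()
    ]
    records.sort(
        key=lambda r: (
            -r.count,
            r.pooled_mean_distance if r.pooled_mean_distance is not None else float("inf"),
            str(r.residue),
        )
    )
    return records


def unique_top_residue(records: Sequence[PrevalenceRecord]) -> Hashable | None:
    """The residue with the strictly maximal prevalence count, or None.

    Returns None when two or more residues tie for the maximum: a tied
    top is not an arbitrary pick.
    """
    if not records:
        raise EmptyInputError("no prevalence records")
    top_count = max(r.count for r in records)
    top = [r.residue for r in records if r.count == top_count]
    return top[0] if len(top) == 1 else None
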