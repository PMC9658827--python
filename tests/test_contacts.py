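"""Center-of-mass distances, atomic contact, per-replicate analysis and
cross-replicate aggregation."""

import numpy as np
import pytest
from scipy.stats import binom

from conftest import random_complex

from mdcontacts import (
    Atom,
    ComplexModel,
    ContactCriteria,
    DistanceSeries,
    ResidueContactSummary,
    ResidueId,
    Trajectory,
    aggregate_replicates,
    analyze_replicate,
    atomic_contact,
    generate_trajectory,
    per_frame_min_com_distance,
    residue_center_of_mass,
    PlantedResidue,
    TrajectorySpec,
)
from mdcontacts.errors import EmptyInputError, MassError, ResidueNotFoundError


class TestCenterOfMass:
    def test_single_atom_identity(self):
        a = Atom(1, "CA", "C", 1, "GLY", "A", (1.0, 2.0, 3.0))
        assert residue_center_of_mass([a]) == pytest.approx([1.0, 2.0, 3.0])

    def test_equal_masses_midpoint(self):
        atoms = [
            Atom(1, "CA", "C", 1, "GLY", "A", (0.0, 0.0, 0.0)),
            Atom(2, "CB", "C", 1, "GLY", "A", (2.0, 0.0, 0.0)),
        ]
        assert residue_center_of_mass(atoms) == pytest.approx([1.0, 0.0, 0.0])

    def test_glycine_against_scalar_loop_oracle(self):
        atoms = [
            Atom(1, "N", "N", 1, "GLY", "A", (0.0, 0.0, 0.0)),
            Atom(2, "CA", "C", 1, "GLY", "A", (1.458, 0.0, 0.0)),
            Atom(3, "C", "C", 1, "GLY", "A", (2.009, 1.420, 0.0)),
            Atom(4, "O", "O", 1, "GLY", "A", (1.251, 2.390, 0.0)),
        ]
        # independent scalar accumulation
        sx = sy = sz = sm = 0.0
        for a in atoms:
            sx += a.mass * a.position[0]
            sy += a.mass * a.position[1]
            sz += a.mass * a.position[2]
            sm += a.mass
        assert residue_center_of_mass(atoms) == pytest.approx([sx / sm, sy / sm, sz / sm])

    def test_zero_atoms_raises(self):
        with pytest.raises(MassError):
            residue_center_of_mass([])


def com_of(model, residue):
    res = model.residue(residue)
    return residue_center_of_mass(model.atoms[i] for i in res.atom_indices)


class TestMinComDistance:
    def test_single_partner_residue(self, two_residue_complex):
        rid = ResidueId("A", 1, "GLY")
        d, partner = per_frame_min_com_distance(two_residue_complex, rid, "B")
        expected = float(
            np.linalg.norm(
                com_of(two_residue_complex, rid)
                - com_of(two_residue_complex, ResidueId("B", 1, "ALA"))
            )
        )
        assert d == pytest.approx(expected)
        assert partner == ResidueId("B", 1, "ALA")

    def test_matches_exhaustive_partner_scan(self):
        for seed in range(25):
            model = random_complex(seed)
            rid = model.chain_residues("A")[0].identity
            d, partner = per_frame_min_com_distance(model, rid, "B")
            com = com_of(model, rid)
            expected = min(
                (float(np.linalg.norm(com - com_of(model, p.identity))), p.identity.number, p.identity)
                for p in model.chain_residues("B")
            )
            assert d == pytest.approx(expected[0])
            assert partner == expected[2]

    def test_unknown_residue_raises(self, two_residue_complex):
        with pytest.raises(ResidueNotFoundError):
            per_frame_min_com_distance(two_residue_complex, ResidueId("A", 99, "GLY"), "B")


def _pair_at(gap):
    atoms = [
        Atom(1, "CA", "C", 1, "GLY", "A", (0.0, 0.0, 0.0)),
        Atom(2, "CA", "C", 1, "GLY", "B", (gap, 0.0, 0.0)),
    ]
    return ComplexModel("pair", atoms)


class TestAtomicContact:
    def test_inside_cutoff(self):
        assert atomic_contact(_pair_at(4.4), ResidueId("A", 1, "GLY"), "B", 4.5)

    def test_boundary_is_strict(self):
        assert not atomic_contact(_pair_at(4.5), ResidueId("A", 1, "GLY"), "B", 4.5)

    def test_matches_all_pairs_scan(self):
        for seed in range(25):
            model = random_complex(seed)
            for res in model.chain_residues("A"):
                expected = any(
                    float(np.linalg.norm(np.array(a.position) - np.array(b.position))) < 4.5
                    for a in (model.atoms[i] for i in res.atom_indices)
                    for b in model.atoms
                    if b.chain_id == "B" and not b.is_hydrogen
                )
                assert atomic_contact(model, res.identity, "B", 4.5) == expected


def constant_distance_trajectory(d, n_frames=10, contact=True):
    """A ligand residue pinned at COM distance d; in/out of atomic contact."""
    frames = []
    for f in range(n_frames):
        x = 0.5 if contact else 10.0
        atoms = [
            Atom(1, "CA", "C", 5, "GLY", "A", (d - x, 0.0, 0.0)),
            Atom(2, "CB", "C", 5, "GLY", "A", (d + x, 0.0, 0.0)),
            Atom(3, "CA", "C", 1, "GLY", "B", (-x, 0.0, 0.0)),
            Atom(4, "CB", "C", 1, "GLY", "B", (x, 0.0, 0.0)),
        ]
        frames.append(ComplexModel(f"f{f}", atoms))
    return Trajectory(replicate_id="rep1", frames=frames)


class TestAnalyzeReplicate:
    def test_pinned_contact_residue(self):
        traj = constant_distance_trajectory(3.0, contact=True)
        summaries, series = analyze_replicate(traj, "A", "B")
        (s,) = summaries
        assert s.persistence_fraction == 1.0
        assert s.mean_distance == pytest.approx(3.0)
        assert s.sd_distance == pytest.approx(0.0)
        assert s.passes_criteria
        assert series[0].values.shape == (10,)

    def test_never_in_contact_fails(self):
        traj = constant_distance_trajectory(30.0, contact=False)
        (s,), _ = analyze_replicate(traj, "A", "B")
        assert s.persistence_fraction == 0.0
        assert not s.passes_criteria

    def test_planted_parameter_recovery_seed42(self):
        """Recover p=0.90, mu=4.44, sigma=0.21 from 200 generated frames
        within closed-form sampling bands."""
        n = 200
        traj = generate_trajectory(
            TrajectorySpec(
                n_frames=n,
                seed=42,
                ligand_residues=(
                    PlantedResidue(number=256, name="GLY", contact_probability=0.90,
                                   distance_mean=4.44, distance_sd=0.21),
                ),
            )
        )
        (s,), _ = analyze_replicate(traj, "A", "B")
        lo = binom.ppf(0.005, n, 0.9) / n
        hi = binom.ppf(0.995, n, 0.9) / n
        assert lo <= s.persistence_fraction <= hi
        assert abs(s.mean_distance - 4.44) <= 3 * 0.21 / np.sqrt(n)
        assert 0.15 <= s.sd_distance <= 0.29

    def test_duplicated_frames_leave_statistics_unchanged(self):
        traj = generate_trajectory(
            TrajectorySpec(
                n_frames=50,
                seed=3,
                ligand_residues=(
                    PlantedResidue(number=1, contact_probability=0.6,
                                   distance_mean=5.0, distance_sd=0.5),
                ),
            )
        )
        (s1,), _ = analyze_replicate(traj, "A", "B")
        tripled = Trajectory(replicate_id="rep1", frames=traj.frames * 3)
        (s3,), _ = analyze_replicate(tripled, "A", "B")
        assert s3.persistence_fraction == pytest.approx(s1.persistence_fraction)
        assert s3.mean_distance == pytest.approx(s1.mean_distance)
        assert s3.sd_distance == pytest.approx(s1.sd_distance)

    def test_conjunctive_mode_selects_subset(self):
        traj = generate_trajectory(
            TrajectorySpec(
                n_frames=100,
                seed=8,
                ligand_residues=(
                    PlantedResidue(number=1, contact_probability=0.95,
                                   distance_mean=4.0, distance_sd=0.3),
                    PlantedResidue(number=2, contact_probability=0.95,
                                   distance_mean=7.0, distance_sd=0.3),
                    PlantedResidue(number=3, contact_probability=0.3,
                                   distance_mean=4.0, distance_sd=0.3),
                ),
            )
        )
        only, _ = analyze_replicate(traj, "A", "B", ContactCriteria(criteria_mode="persistence_only"))
        both, _ = analyze_replicate(traj, "A", "B", ContactCriteria(criteria_mode="persistence_and_com"))
        sel_only = {s.residue for s in only if s.passes_criteria}
        sel_both = {s.residue for s in both if s.passes_criteria}
        assert sel_both <= sel_only
        assert ResidueId("A", 2, "ALA") in sel_only - sel_both  # far COM, high persistence


class TestAggregate:
    def _summary(self, rid, rep, mean, sd=0.0, passes=True):
        return ResidueContactSummary(rid, rep, 1.0, mean, sd, passes)

    def _series(self, rid, rep, values):
        partner = ResidueId("B", 1, "GLY")
        return DistanceSeries(rid, rep, np.asarray(values, dtype=float),
                              [partner] * len(values))

    def test_single_replicate_identity(self):
        rid = ResidueId("A", 1, "GLY")
        recs = aggregate_replicates(
            [self._summary(rid, "r1", 4.0, 0.5)], [self._series(rid, "r1", [3.5, 4.5])]
        )
        (rec,) = recs
        assert rec.pooled_mean == pytest.approx(4.0)
        assert rec.pooled_sd == pytest.approx(0.5)
        assert rec.pass_flags == {"r1": True}

    def test_two_constant_replicates_closed_form(self):
        """Constant series at 4 and 6 Å pool to mean 5.0, population SD 1.0."""
        rid = ResidueId("A", 1, "GLY")
        recs = aggregate_replicates(
            [self._summary(rid, "r1", 4.0), self._summary(rid, "r2", 6.0)],
            [self._series(rid, "r1", [4.0] * 5), self._series(rid, "r2", [6.0] * 5)],
        )
        assert recs[0].pooled_mean == pytest.approx(5.0)
        assert recs[0].pooled_sd == pytest.approx(1.0)

    def test_replicate_means_pooling_variant(self):
        rid = ResidueId("A", 1, "GLY")
        recs = aggregate_replicates(
            [self._summary(rid, "r1", 4.0), self._summary(rid, "r2", 6.0)],
            [self._series(rid, "r1", [3.0, 5.0]), self._series(rid, "r2", [6.0, 6.0])],
            pooling="replicate_means",
        )
        assert recs[0].pooled_mean == pytest.approx(5.0)
        assert recs[0].pooled_sd == pytest.approx(1.0)  # sd across {4, 6}

    def test_sorted_ascending_by_pooled_mean(self):
        r1, r2 = ResidueId("A", 1, "GLY"), ResidueId("A", 2, "ALA")
        recs = aggregate_replicates(
            [self._summary(r1, "r1", 7.0), self._summary(r2, "r1", 3.0)],
            [self._series(r1, "r1", [7.0]), self._series(r2, "r1", [3.0])],
        )
        assert [r.residue for r in recs] == [r2, r1]

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            aggregate_replicates([], [])
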