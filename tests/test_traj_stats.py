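"""Tests for contact, hydration, distance, pore and RMSD statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from pipfep.traj_stats import (
    ATOM_COLUMNS,
    ContactTable,
    Selection,
    Trajectory,
    atomic_contact_probability,
    contact_diff,
    desolvation_count,
    hydration_count,
    min_heavy_distance,
    pore_profile,
    residue_contact_ratio,
    rmsd_rmsf,
)


def make_traj(rows, frames):
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return Trajectory(coords=np.asarray(frames, dtype=float), atoms=atoms)


def atom(serial, name, resname, chain, resid, element):
    return {
        "serial": serial,
        "name": name,
        "resname": resname,
        "chain": chain,
        "resid": resid,
        "element": element,
        "is_heavy": element != "H",
        "is_water": resname == "HOH",
    }


@pytest.fixture
def ten_frame_contact_traj():
    """One ligand atom at origin, one protein atom inside 5 A in 4/10 frames."""
    rows = [
        atom(1, "P1", "PIP", "A", 500, "P"),
        atom(2, "CZ", "ARG", "A", 78, "C"),
    ]
    frames = []
    for f in range(10):
        prot = [3.0, 0.0, 0.0] if f < 4 else [20.0, 0.0, 0.0]
        frames.append([[0.0, 0.0, 0.0], prot])
    return make_traj(rows, frames)


class TestAtomicContactProbability:
    def test_never_in_contact(self, ten_frame_contact_traj):
        t = ten_frame_contact_traj
        t.coords[:, 1] = [50.0, 0.0, 0.0]
        p = atomic_contact_probability(
            t, Selection(name="CZ"), Selection(resname="PIP")
        )
        assert p == 0.0

    def test_always_in_contact(self, ten_frame_contact_traj):
        t = ten_frame_contact_traj
        t.coords[:, 1] = [2.0, 0.0, 0.0]
        assert atomic_contact_probability(
            t, Selection(name="CZ"), Selection(resname="PIP")
        ) == 1.0

    def test_four_of_ten_frames_counted(self, ten_frame_contact_traj):
        p = atomic_contact_probability(
            ten_frame_contact_traj, Selection(name="CZ"), Selection(resname="PIP")
        )
        assert p == pytest.approx(0.4)

    def test_boundary_distance_counts_as_contact(self, ten_frame_contact_traj):
        t = ten_frame_contact_traj
        t.coords[:, 1] = [5.0, 0.0, 0.0]
        assert atomic_contact_probability(
            t, Selection(name="CZ"), Selection(resname="PIP")
        ) == 1.0

    def test_empty_selection_rejected(self, ten_frame_contact_traj):
        with pytest.raises(ValueError):
            atomic_contact_probability(
                ten_frame_contact_traj, Selection(name="XX"), Selection(resname="PIP")
            )


class TestResidueContactRatio:
    def test_residue_out_of_range_gives_zero(self):
        rows = [atom(1, "P1", "PIP", "A", 500, "P"), atom(2, "CZ", "ARG", "A", 78, "C")]
        frames = [[[0, 0, 0], [40, 0, 0]]] * 5
        t = make_traj(rows, frames)
        assert residue_contact_ratio(t, Selection(resid=78), Selection(resname="PIP")) == 0.0

    def test_three_atoms_always_in_contact_sum_to_three(self):
        rows = [atom(1, "P1", "PIP", "A", 500, "P")] + [
            atom(2 + k, n, "ARG", "A", 78, "C") for k, n in enumerate(["CZ", "CD", "CG"])
        ]
        frames = [[[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]]] * 5
        t = make_traj(rows, frames)
        assert residue_contact_ratio(t, Selection(resid=78), Selection(resname="PIP")) == 3.0

    def test_hydrogens_excluded_from_ratio(self):
        rows = [
            atom(1, "P1", "PIP", "A", 500, "P"),
            atom(2, "CZ", "ARG", "A", 78, "C"),
            atom(3, "HZ", "ARG", "A", 78, "H"),
        ]
        frames = [[[0, 0, 0], [2, 0, 0], [2.5, 0, 0]]] * 4
        t = make_traj(rows, frames)
        assert residue_contact_ratio(t, Selection(resid=78), Selection(resname="PIP")) == 1.0

    def test_multi_chain_average(self):
        # chain A copy always in contact, chain B copy never
        rows = [
            atom(1, "P1", "PIP", "A", 500, "P"),
            atom(2, "CZ", "ARG", "A", 78, "C"),
            atom(3, "P1", "PIP", "B", 500, "P"),
            atom(4, "CZ", "ARG", "B", 78, "C"),
        ]
        frames = [[[0, 0, 0], [2, 0, 0], [100, 0, 0], [140, 0, 0]]] * 6
        t = make_traj(rows, frames)
        q = residue_contact_ratio(t, Selection(resid=78), Selection(resname="PIP"))
        assert q == pytest.approx(0.5)


class TestContactDiff:
    def test_published_aggregate_identities(self):
        wt = ContactTable({"R78": 1.0, "K189": 2.0})
        mut = ContactTable({"R78": 3.5, "K189": 0.75})
        diff = contact_diff(wt, mut)
        assert diff.dq_pos == pytest.approx(2.5)
        assert diff.dq_neg == pytest.approx(-1.25)
        assert diff.dq_all == pytest.approx(diff.dq_pos + diff.dq_neg)

    def test_identical_tables_give_empty_highlight(self):
        t = ContactTable({"R78": 1.0, "K189": 2.0})
        diff = contact_diff(t, ContactTable(dict(t.entries)))
        assert all(v == 0.0 for v in diff.deltas.values())
        assert diff.highlighted == []
        assert diff.dq_all == 0.0

    def test_missing_residues_treated_as_zero(self):
        wt = ContactTable({"R78": 1.0})
        mut = ContactTable({"K189": 0.4})
        diff = contact_diff(wt, mut)
        assert diff.deltas["R78"] == pytest.approx(-1.0)
        assert diff.deltas["K189"] == pytest.approx(0.4)

    def test_highlight_threshold(self):
        wt = ContactTable({"A": 0.0, "B": 0.0})
        mut = ContactTable({"A": 0.6, "B": 0.4})
        assert contact_diff(wt, mut).highlighted == ["A"]

    def test_mismatched_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            contact_diff(ContactTable({}, cutoff=5.0), ContactTable({}, cutoff=4.0))


class TestHydration:
    def _water(self, serial, resid):
        return [
            atom(serial, "O", "HOH", "W", resid, "O"),
            atom(serial + 1, "H1", "HOH", "W", resid, "H"),
            atom(serial + 2, "H2", "HOH", "W", resid, "H"),
        ]

    def test_hand_placed_waters_counted(self):
        rows = [atom(1, "P1", "PIP", "A", 500, "P")]
        coords = [[0.0, 0.0, 0.0]]
        rng = np.random.default_rng(2)
        for w in range(12):
            rows += self._water(10 + 3 * w, 1000 + w)
            r = 3.0 if w < 7 else 9.0
            u = rng.standard_normal(3)
            u = r * u / np.linalg.norm(u)
            coords += [list(u), list(u + [0.96, 0, 0]), list(u + [0, 0.96, 0])]
        t = make_traj(rows, [coords] * 3)
        res = hydration_count(t, Selection(resname="PIP"), shell_radius=3.5)
        assert res.mean == 7.0
        assert np.all(res.per_frame == 7.0)

    def test_boundary_water_counted(self):
        rows = [atom(1, "P1", "PIP", "A", 500, "P")] + self._water(2, 1000)
        coords = [[0, 0, 0], [3.5, 0, 0], [4.3, 0, 0], [3.5, 0.96, 0]]
        t = make_traj(rows, [coords])
        assert hydration_count(t, Selection(resname="PIP"), 3.5).mean == 1.0

    def test_no_waters_returns_zero(self, caplog):
        rows = [atom(1, "P1", "PIP", "A", 500, "P")]
        t = make_traj(rows, [[[0, 0, 0]]])
        res = hydration_count(t, Selection(resname="PIP"), 3.5)
        assert res.mean == 0.0

    def test_permutation_invariance(self):
        rows = [atom(1, "P1", "PIP", "A", 500, "P")]
        coords = [[0.0, 0.0, 0.0]]
        for w in range(6):
            rows += self._water(10 + 3 * w, 1000 + w)
            base = [2.0 + w, 0.0, 0.0]
            coords += [base, [base[0], 0.96, 0], [base[0], 0, 0.96]]
        t = make_traj(rows, [coords])
        baseline = hydration_count(t, Selection(resname="PIP"), 3.5).mean
        perm = np.random.default_rng(1).permutation(len(rows))
        t2 = make_traj([rows[i] for i in perm], [[coords[i] for i in perm]])
        assert hydration_count(t2, Selection(resname="PIP"), 3.5).mean == baseline


class TestDesolvation:
    @pytest.mark.parametrize(
        "free,bound,expected", [(38, 21, 17), (45, 30, 15), (10, 10, 0)]
    )
    def test_arithmetic(self, free, bound, expected):
        assert desolvation_count(free, bound) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            desolvation_count(-1, 0)


class TestMinHeavyDistance:
    def test_three_four_five_triangle(self):
        rows = [atom(1, "CA", "ALA", "A", 1, "C"), atom(2, "CB", "GLY", "A", 2, "C")]
        t = make_traj(rows, [[[0, 0, 0], [3, 4, 0]]])
        assert min_heavy_distance(t, Selection(resid=1), Selection(resid=2)) == pytest.approx(5.0)

    def test_shared_atom_gives_zero(self):
        rows = [atom(1, "CA", "ALA", "A", 1, "C")]
        t = make_traj(rows, [[[1, 2, 3]]])
        assert min_heavy_distance(t, Selection(resid=1), Selection(resid=1)) == 0.0

    def test_nearer_hydrogen_ignored(self):
        rows = [
            atom(1, "NZ", "LYS", "A", 189, "N"),
            atom(2, "HZ", "LYS", "A", 189, "H"),
            atom(3, "P5", "PIP", "A", 500, "P"),
        ]
        t = make_traj(rows, [[[0, 0, 0], [3, 0, 0], [4, 0, 0]]])
        d = min_heavy_distance(t, Selection(resid=189), Selection(resname="PIP"))
        assert d == pytest.approx(4.0)

    def test_hydrogen_only_selection_rejected(self):
        rows = [atom(1, "HZ", "LYS", "A", 189, "H"), atom(2, "P5", "PIP", "A", 500, "P")]
        t = make_traj(rows, [[[0, 0, 0], [4, 0, 0]]])
        with pytest.raises(ValueError):
            min_heavy_distance(t, Selection(resid=189), Selection(resname="PIP"))


def ring_traj(radii_z, atoms_per_ring=24):
    rows, coords = [], []
    s = 0
    for j, (R, z) in enumerate(radii_z):
        for a in range(atoms_per_ring):
            s += 1
            phi = 2 * math.pi * a / atoms_per_ring
            rows.append(atom(s, f"C{a}", "RNG", "A", j + 1, "C"))
            coords.append([R * math.cos(phi), R * math.sin(phi), z])
    return make_traj(rows, [coords])


class TestPoreProfile:
    def test_single_ring_analytic(self):
        t = ring_traj([(10.0, 0.0)])
        prof = pore_profile(t, z_range=(0.0, 0.0), radii=np.full(t.n_atoms, 1.7))
        assert prof.radius[0] == pytest.approx(10.0 - 1.7, abs=0.02)

    def test_two_stacked_rings_match_dense_grid_oracle(self):
        t = ring_traj([(9.0, 0.0), (6.0, 10.0)])
        radii = np.full(t.n_atoms, 1.7)
        prof = pore_profile(t, z_range=(0.0, 10.0), z_step=5.0, radii=radii, grid_step=0.2)
        # dense-grid oracle: brute force over a fine xy grid
        for k, z in enumerate(prof.z):
            g = np.arange(-5.0, 5.0001, 0.05)
            gx, gy = np.meshgrid(g, g)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            d = np.sqrt(
                ((pts[:, None, :] - t.coords[0][None, :, :2]) ** 2).sum(-1)
                + (t.coords[0][:, 2] - z)[None, :] ** 2
            )
            oracle = np.clip((d - radii[None, :]).min(axis=1).max(), 0, 15.0)
            assert prof.radius[k] == pytest.approx(oracle, abs=0.05)

    def test_empty_slice_reports_cap(self):
        t = ring_traj([(10.0, 0.0)])
        prof = pore_profile(
            t, z_range=(100.0, 100.0), max_radius=15.0, radii=np.full(t.n_atoms, 1.7)
        )
        assert prof.radius[0] == 15.0

    def test_constriction_is_profile_minimum(self):
        t = ring_traj([(10.0, 0.0), (5.0, 12.0), (10.0, 24.0)])
        prof = pore_profile(t, z_step=2.0, radii=np.full(t.n_atoms, 1.7))
        assert prof.z[np.argmin(prof.radius)] == pytest.approx(12.0)


class TestRmsdRmsf:
    def _traj(self, frames):
        rows = [atom(i + 1, f"C{i}", "ALA", "A", i + 1, "C") for i in range(4)]
        return make_traj(rows, frames)

    def test_identical_frames_zero(self):
        base = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        t = self._traj([base] * 5)
        rmsd, rmsf = rmsd_rmsf(t)
        assert np.allclose(rmsd, 0.0, atol=1e-12)
        assert np.allclose(rmsf["rmsf"], 0.0, atol=1e-12)

    def test_rigid_motion_invisible_after_superposition(self):
        base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        rot = Rotation.from_euler("xyz", [0.3, -0.5, 1.0])
        moved = rot.apply(base) + np.array([5.0, -2.0, 3.0])
        t = self._traj([base, moved])
        rmsd, _ = rmsd_rmsf(t)
        assert rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_two_frame_displacement_hand_value(self):
        # displace one of 2 atoms by d: after superposition of a 2-atom system
        # the optimal fit shares the error equally; use 1 atom fixed reference
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], dtype=float)
        moved = base.copy()
        moved[3, 2] += 0.2
        t = self._traj([base, moved])
        rmsd, _ = rmsd_rmsf(t)
        # independent oracle: superposition handled by scipy on centered sets
        mob = moved - moved.mean(0)
        ref = base - base.mean(0)
        r, _ = Rotation.align_vectors(ref, mob)
        expected = math.sqrt(((r.apply(mob) - ref) ** 2).sum(1).mean())
        assert rmsd[1] == pytest.approx(expected, rel=1e-9)

    def test_single_frame_rmsf_zero(self):
        base = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        t = self._traj([base])
        _, rmsf = rmsd_rmsf(t)
        assert np.allclose(rmsf["rmsf"], 0.0)
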