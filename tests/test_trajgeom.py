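"""Pocket distances, ring breadths, steric fit and superposition."""

import numpy as np
import pytest

from conftest import make_atom, random_rigid_transform
from deamscan.errors import PairingError, SelectionError, UnderdeterminedError
from deamscan.structio import AtomSelector, Structure, Trajectory
from deamscan.synth import make_pocket_trajectory
from deamscan.trajgeom import (
    PocketDefinition,
    VdwRadiusTable,
    atom_distance,
    fit_assessment,
    load_base_geometry,
    pocket_distance_series,
    ring_breadth,
    segment_rmsd,
    superpose,
)


class TestAtomDistance:
    def test_same_position_distinct_atoms(self):
        a = make_atom(1, "CA", 1, coord=(0, 0, 0))
        b = make_atom(2, "CB", 1, coord=(0, 0, 0))
        assert atom_distance(None, a, b) == 0.0

    def test_three_four_five(self):
        a = make_atom(1, "CA", 1, coord=(0, 0, 0))
        b = make_atom(2, "CB", 1, coord=(3, 4, 0))
        assert atom_distance(None, a, b) == 5.0

    def test_identical_atom_rejected(self):
        a = make_atom(1, "CA", 1)
        with pytest.raises(ValueError):
            atom_distance(None, a, a)

    def test_matches_hand_coded_norm(self, rng):
        frame = rng.uniform(-50, 50, (10, 3))
        i, j = 2, 7
        hand = sum((frame[i][k] - frame[j][k]) ** 2 for k in range(3)) ** 0.5
        assert atom_distance(frame, i, j) == pytest.approx(hand, abs=1e-12)


class TestPocketSeries:
    def test_single_frame_mean_equals_min_max(self):
        traj = make_pocket_trajectory(2, seed=1)
        traj = Trajectory(traj.topology, [traj.frames[0]])
        series = pocket_distance_series(traj, PocketDefinition("wt"))
        for s in series.values():
            assert s.mean == s.min == s.max

    def test_planted_gate_range_recovered(self):
        """d2 planted at the published wt range 9.9-16.3 A is read back."""
        traj = make_pocket_trajectory(100, seed=7, variant="wt")
        series = pocket_distance_series(traj, PocketDefinition("wt"))
        assert series["d2"].min == pytest.approx(9.9, abs=0.05)
        assert series["d2"].max == pytest.approx(16.3, abs=0.05)
        assert series["d2"].mean == pytest.approx(13.1, abs=0.2)

    def test_statistics_equal_frame_loop_recomputation(self, rng):
        traj = make_pocket_trajectory(50, seed=3, variant="N51A")
        pocket = PocketDefinition("N51A")
        series = pocket_distance_series(traj, pocket)
        # brute force: explicit per-frame loop with resolved indices
        topo = traj.topology
        for label, (sa, sb) in pocket.pairs.items():
            ia = [i for i, a in enumerate(topo.atoms) if sa.matches(a)]
            ib = [i for i, a in enumerate(topo.atoms) if sb.matches(a)]
            assert len(ia) == len(ib) == 1
            dists = [float(np.linalg.norm(f[ia[0]] - f[ib[0]])) for f in traj.frames]
            assert np.allclose(series[label].values, dists)
            assert series[label].mean == pytest.approx(np.mean(dists))

    def test_concatenation_consistency(self):
        traj = make_pocket_trajectory(40, seed=5)
        pocket = PocketDefinition("wt")
        full = pocket_distance_series(traj, pocket)
        part1 = Trajectory(traj.topology, traj.frames[:15])
        part2 = Trajectory(traj.topology, traj.frames[15:])
        s1 = pocket_distance_series(part1, pocket)
        s2 = pocket_distance_series(part2, pocket)
        for label in full:
            joined = np.concatenate([s1[label].values, s2[label].values])
            assert np.allclose(full[label].values, joined)

    def test_unresolvable_selector_names_pair(self):
        traj = make_pocket_trajectory(5, seed=1, variant="wt")
        with pytest.raises(SelectionError, match="d1"):
            # N51A definition looks for CB at residue 51; the wt fixture has ND2
            pocket_distance_series(traj, PocketDefinition("N51A"))


class TestRingBreadth:
    def test_two_sphere_example(self):
        # two atoms 2.0 A apart, radii 1.0 each -> breadth 4.0
        radii = VdwRadiusTable(radii={"X": 1.0})
        from deamscan.trajgeom import _caliper_breadth

        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        val = _caliper_breadth(coords, ["X", "X"], np.array([True, True]), radii,
                               np.array([0.0, 0.0, 1.0]))
        assert val == pytest.approx(4.0)

    def test_published_breadths_c_and_5mc(self):
        """Idealized geometry + Bondi radii reproduce the printed 7.8 / 8.8 A."""
        assert ring_breadth(load_base_geometry("C")) == pytest.approx(7.8, abs=0.3)
        assert ring_breadth(load_base_geometry("5mC")) == pytest.approx(8.8, abs=0.3)

    def test_5mc_increment_matches_bond_radius_arithmetic(self):
        """5mC exceeds C by ~ (C5-CH3 bond + r_C) - (C5-H bond + r_H)."""
        c = ring_breadth(load_base_geometry("C"))
        mc = ring_breadth(load_base_geometry("5mC"))
        expected = (1.496 + 1.70) - (1.08 + 1.20)
        assert mc - c == pytest.approx(expected, abs=0.05)

    def test_breadth_against_brute_force_projection_oracle(self):
        """Caliper equals an all-pairs pure-python recomputation."""
        radii = VdwRadiusTable.bondi()
        for kind in ("C", "5mC"):
            geom = load_base_geometry(kind)
            pts = [tuple(c) for c, m in zip(geom.coords, geom.breadth_set) if m]
            els = [e for e, m in zip(geom.elements, geom.breadth_set) if m]
            best = 0.0
            for i in range(len(pts)):
                for j in range(len(pts)):
                    d = sum((pts[i][k] - pts[j][k]) ** 2 for k in range(2)) ** 0.5
                    best = max(best, d + radii[els[i]] + radii[els[j]])
            assert ring_breadth(geom, radii) == pytest.approx(best, abs=1e-9)

    def test_5hmc_rotamer_interval_and_ordering(self):
        c = ring_breadth(load_base_geometry("C"))
        mc = ring_breadth(load_base_geometry("5mC"))
        lo, hi = ring_breadth(load_base_geometry("5hmC"))
        assert lo <= hi
        assert hi >= mc >= c
        assert 8.5 <= lo and hi <= 10.1  # printed 8.8-9.8 band, convention slack

    def test_monotone_under_added_substituent(self):
        """Marking an extra atom into the breadth set never shrinks the caliper."""
        geom = load_base_geometry("5mC")
        base = ring_breadth(geom)
        bigger = geom.breadth_set.copy()
        bigger[[r == "substituent_hydrogen" for r in geom.roles]] = True
        import dataclasses

        geom2 = dataclasses.replace(geom, breadth_set=bigger)
        assert ring_breadth(geom2) >= base

    def test_axes_orthogonal(self):
        for kind in ("C", "5mC", "5hmC"):
            geom = load_base_geometry(kind)
            assert abs(np.dot(geom.depth_axis, geom.breadth_axis)) < 1e-9


class TestFitAssessment:
    def gate(self, lo, mean, hi):
        from deamscan.trajgeom import DistanceSeries

        vals = np.array([lo, mean, hi])
        return DistanceSeries(label="d2", values=vals)

    def test_published_5mc_fits_n51a_minimum(self):
        # breadth 8.8 vs N51A gate minimum 10.4 -> fits, clearance 1.6
        v = fit_assessment(8.8, self.gate(10.4, 12.75, 15.1))
        assert v.fits_at_min and v.clearance == pytest.approx(1.6)

    def test_boundary_counts_as_fit(self):
        v = fit_assessment(10.4, self.gate(10.4, 12.0, 15.0))
        assert v.fits_at_min and v.clearance == 0.0

    def test_hydrated_5hmc_excluded(self):
        """max 5hmC breadth 9.8 + one water (2.8 A) exceeds the wt gate minimum."""
        from deamscan.trajgeom import WATER_BULK_MIN

        v = fit_assessment(9.8 + WATER_BULK_MIN, self.gate(9.9, 13.1, 16.3))
        assert not v.fits_at_min
        assert v.clearance == pytest.approx(9.9 - 12.6)

    def test_interval_uses_max_breadth(self):
        v = fit_assessment((8.8, 9.8), self.gate(9.0, 12.0, 15.0))
        assert v.clearance == pytest.approx(9.0 - 9.8)


def _horn_quaternion_rmsd(mobile, target):
    """Independent closed-form (Horn quaternion) superposition RMSD."""
    mobile = mobile - mobile.mean(axis=0)
    target = target - target.mean(axis=0)
    M = mobile.T @ target
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (mobile**2).sum() + (target**2).sum() - 2.0 * lam
    return np.sqrt(max(sq, 0.0) / len(mobile))


class TestSuperpose:
    def _structure(self, coords, name="CA"):
        atoms = [make_atom(i + 1, name, i + 1, coord=c) for i, c in enumerate(coords)]
        return Structure(atoms=atoms)

    def test_identity(self, rng):
        s = self._structure(rng.uniform(-10, 10, (8, 3)))
        fit = superpose(s, s)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_rigid_invariance(self, rng):
        coords = rng.uniform(-10, 10, (12, 3))
        s = self._structure(coords)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
        moved = self._structure(coords @ R.T + np.array([5.0, -3.0, 11.0]))
        fit = superpose(moved, s)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_noisy_copy(self, rng):
        coords = rng.uniform(-10, 10, (10, 3))
        noisy = coords + rng.normal(0, 0.1, coords.shape)
        fit = superpose(self._structure(noisy), self._structure(coords))
        assert fit.rmsd == pytest.approx(_horn_quaternion_rmsd(noisy, coords), abs=1e-9)

    def test_rmsd_invariant_to_preapplied_rigid_transform(self, rng):
        coords = rng.uniform(-10, 10, (10, 3))
        noisy = coords + rng.normal(0, 0.2, coords.shape)
        base = superpose(self._structure(noisy), self._structure(coords)).rmsd
        R, t = random_rigid_transform(rng)
        moved = superpose(self._structure(noisy @ R.T + t), self._structure(coords)).rmsd
        assert moved == pytest.approx(base, abs=1e-9)
        assert moved >= 0.0

    def test_underdetermined_and_pairing_errors(self, rng):
        s2 = self._structure(rng.uniform(-5, 5, (2, 3)))
        with pytest.raises(UnderdeterminedError):
            superpose(s2, s2)
        a = self._structure(rng.uniform(-5, 5, (5, 3)))
        b = self._structure(rng.uniform(-5, 5, (4, 3)))
        with pytest.raises(PairingError, match="unmatched"):
            superpose(a, b)

    def test_residue_offset_map(self, rng):
        coords = rng.uniform(-10, 10, (6, 3))
        mobile = self._structure(coords)
        shifted_atoms = [make_atom(i + 1, "CA", i + 101, coord=c) for i, c in enumerate(coords)]
        target = Structure(atoms=shifted_atoms)
        fit = superpose(mobile, target, residue_offset=100)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)


class TestSegmentRmsd:
    def test_zero_on_identical(self, rng):
        coords = rng.uniform(-10, 10, (10, 3))
        atoms = [make_atom(i + 1, "CA", i + 1, coord=c) for i, c in enumerate(coords)]
        s = Structure(atoms=atoms)
        seg = AtomSelector(res_num=4, name="CA")
        assert segment_rmsd(s, s, None, AtomSelector(name="CA")) == pytest.approx(0.0, abs=1e-9)
        assert segment_rmsd(s, s, None, seg) == pytest.approx(0.0, abs=1e-9)

    def test_planted_loop_displacement(self, rng):
        """Only a 3-residue 'loop' moves by 0.5 A; global fit is anchored elsewhere."""
        n = 40
        coords = rng.uniform(-15, 15, (n, 3))
        atoms = [make_atom(i + 1, "CA", i + 1,
                           res_name="LOO" if 10 <= i < 13 else "COR", coord=c)
                 for i, c in enumerate(coords)]
        target = Structure(atoms=atoms)
        moved = coords.copy()
        moved[10:13] += np.array([0.0, 0.0, 0.5])
        mobile = target.with_coords(moved)
        core = AtomSelector(res_name="COR")
        loop = AtomSelector(res_name="LOO")
        val = segment_rmsd(mobile, target, core, loop)
        # the global fit on the untouched core is exact, leaving the planted shift
        assert val == pytest.approx(0.5, abs=1e-9)
        # definition check: equals explicit per-atom recomputation after the fit
        fit = superpose(mobile, target, core)
        dev = fit.transform(moved[10:13]) - coords[10:13]
        assert val == pytest.approx(np.sqrt((dev**2).sum(axis=1).mean()), abs=1e-12)

    def test_empty_segment_rejected(self, rng):
        coords = rng.uniform(-5, 5, (5, 3))
        atoms = [make_atom(i + 1, "CA", i + 1, coord=c) for i, c in enumerate(coords)]
        s = Structure(atoms=atoms)
        with pytest.raises(SelectionError):
            segment_rmsd(s, s, None, AtomSelector(res_num=99))
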