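"""vdW / H-bond / stacking detectors and interaction-network aggregation."""

import numpy as np
import pytest

from conftest import make_atom, random_rigid_transform
from deamscan.errors import GeometryError
from deamscan.interact import (
    InteractionConfig,
    RingSpec,
    aggregate_network,
    detect_hbonds,
    detect_stacking,
    detect_vdw_contacts,
    donors_in_group,
    network_diff,
    triple_stack_series,
)
from deamscan.structio import AtomSelector, Structure, Trajectory
from deamscan.synth import (
    PlantedContact,
    make_interaction_frame,
    make_interaction_trajectory,
    make_stack_pattern_trajectory,
)
from deamscan.trajgeom import VdwRadiusTable


def _pair_structure(d, name_a="CB", name_b="CG2"):
    atoms = [
        make_atom(1, name_a, 1, chain="A", res_name="ALA", coord=(0, 0, 0)),
        make_atom(2, name_b, 2, chain="B", res_name="THR", coord=(d, 0, 0)),
    ]
    return Structure(atoms=atoms)


class TestVdw:
    def test_boundary_inclusive(self):
        s = _pair_structure(3.4)
        hits = detect_vdw_contacts(s, s.coords, [0], [1], tolerance=0.0)
        assert len(hits) == 1 and hits[0][2] == pytest.approx(3.4)

    def test_beyond_cutoff(self):
        s = _pair_structure(4.2)
        assert detect_vdw_contacts(s, s.coords, [0], [1], tolerance=0.6) == []

    def test_empty_group_is_empty_result(self):
        s = _pair_structure(3.0)
        assert detect_vdw_contacts(s, s.coords, [], [1]) == []

    def test_equals_brute_force_oracle(self, rng):
        """Vectorized detector vs pure-python all-pairs oracle on random frames."""
        radii = VdwRadiusTable.bondi()
        names = ["CB", "OG", "ND2", "SG", "CA"]
        for trial in range(20):
            n_a, n_b = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            atoms, coords = [], []
            for i in range(n_a + n_b):
                chain = "A" if i < n_a else "B"
                atoms.append(
                    make_atom(i + 1, names[i % len(names)], i + 1, chain=chain,
                              coord=rng.uniform(0, 12, 3))
                )
            s = Structure(atoms=atoms)
            ga, gb = list(range(n_a)), list(range(n_a, n_a + n_b))
            got = {(i, j) for i, j, _ in detect_vdw_contacts(s, s.coords, ga, gb,
                                                             radii, 0.6)}
            want = set()
            for i in ga:
                for j in gb:
                    d = sum((s.coords[i][k] - s.coords[j][k]) ** 2 for k in range(3)) ** 0.5
                    if d <= radii[s.atoms[i].element] + radii[s.atoms[j].element] + 0.6:
                        want.add((i, j))
            assert got == want

    def test_counts_monotone_in_tolerance(self, rng):
        atoms = [make_atom(i + 1, "CB", i + 1, chain="A" if i < 10 else "B",
                           coord=rng.uniform(0, 10, 3)) for i in range(20)]
        s = Structure(atoms=atoms)
        ga, gb = list(range(10)), list(range(10, 20))
        n_prev = -1
        for tol in (0.0, 0.3, 0.6, 1.0):
            n = len(detect_vdw_contacts(s, s.coords, ga, gb, tolerance=tol))
            assert n >= n_prev
            n_prev = n


class TestHbond:
    def _dha(self, d_a=2.9, angle=165.0):
        """Donor at origin, H on x-axis, acceptor placed to realize the angle."""
        h = np.array([1.0, 0.0, 0.0])
        theta = np.radians(180.0 - angle)  # D-H...A angle at the hydrogen
        acc = h + (d_a - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
        atoms = [
            make_atom(1, "ND2", 51, chain="A", res_name="ASN", coord=(0, 0, 0)),
            make_atom(2, "HD21", 51, chain="A", res_name="ASN", coord=tuple(h)),
            make_atom(3, "O2", 3, chain="B", res_name="DC", coord=tuple(acc)),
        ]
        return Structure(atoms=atoms)

    def test_good_geometry_detected(self):
        s = self._dha(2.9, 165.0)
        donors = donors_in_group(s, s.coords, [0, 1])
        hits = detect_hbonds(s, s.coords, donors, [2])
        assert len(hits) == 1
        assert hits[0].angle == pytest.approx(165.0, abs=1e-6)

    def test_angle_gate_rejects(self):
        s = self._dha(2.9, 90.0)
        donors = donors_in_group(s, s.coords, [0, 1])
        assert detect_hbonds(s, s.coords, donors, [2]) == []

    def test_no_hydrogens_distance_only(self):
        s = self._dha(2.9, 90.0)
        hits = detect_hbonds(s, s.coords, [(0, [])], [2])
        assert len(hits) == 1 and hits[0].angle is None and hits[0].hydrogen is None

    def test_n51_to_cytosine_o2_fixture(self):
        """The N51 ND2 -> cytosine O2 bond of the wild-type complex."""
        frame = make_interaction_frame(
            [PlantedContact("hbond", ("ASN", 51, "ND2"), ("DC", 3, "O2"))]
        )
        idx = {a.key: i for i, a in enumerate(frame.atoms)}
        donors = donors_in_group(frame, frame.coords,
                                 [i for i, a in enumerate(frame.atoms) if a.chain == "A"])
        hits = detect_hbonds(frame, frame.coords, donors,
                             [idx[("B", 3, "O2")]])
        assert len(hits) == 1
        assert frame.atoms[hits[0].donor].name == "ND2"

    def test_donor_equal_acceptor_rejected(self):
        s = self._dha()
        with pytest.raises(ValueError):
            detect_hbonds(s, s.coords, [(2, [])], [2])


def _hexagon(center, normal_tilt_deg=0.0, z=0.0, res_num=1, chain="A", res_name="TYR"):
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    tilt = np.radians(normal_tilt_deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(tilt), -np.sin(tilt)], [0, np.sin(tilt), np.cos(tilt)]]
    )
    atoms = []
    for i, name in enumerate(names):
        ang = 2 * np.pi * i / 6
        p = rot @ np.array([1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0])
        atoms.append(
            make_atom(100 * res_num + i, name, res_num, chain=chain, res_name=res_name,
                      coord=tuple(np.asarray(center) + p + [0, 0, z]))
        )
    return atoms, RingSpec(f"{res_name}{res_num}", names, res_num=res_num, chain=chain)


class TestStacking:
    def test_ideal_parallel_stack(self):
        a1, r1 = _hexagon((0, 0, 0), res_num=1)
        a2, r2 = _hexagon((0, 0, 3.5), res_num=2)
        s = Structure(atoms=a1 + a2)
        hits = detect_stacking(s, s.coords, [r1, r2])
        assert len(hits) == 1
        assert hits[0].plane_angle == pytest.approx(0.0, abs=1e-6)
        assert hits[0].lateral_offset == pytest.approx(0.0, abs=1e-6)

    def test_tilted_rejected(self):
        a1, r1 = _hexagon((0, 0, 0), res_num=1)
        a2, r2 = _hexagon((0, 0, 3.5), normal_tilt_deg=60.0, res_num=2)
        s = Structure(atoms=a1 + a2)
        assert detect_stacking(s, s.coords, [r1, r2]) == []

    def test_offset_gate(self):
        a1, r1 = _hexagon((0, 0, 0), res_num=1)
        a2, r2 = _hexagon((3.0, 0, 0), z=3.0, res_num=2)
        s = Structure(atoms=a1 + a2)
        # centroid distance 4.24 <= 4.5, angle 0, but offset 3.0 > 2.0
        assert detect_stacking(s, s.coords, [r1, r2]) == []

    def test_collinear_ring_is_geometry_error(self):
        atoms = [make_atom(i + 1, n, 1, coord=(float(i), 0, 0))
                 for i, n in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))]
        s = Structure(atoms=atoms)
        ring = RingSpec("bad", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), res_num=1)
        with pytest.raises(GeometryError):
            detect_stacking(s, s.coords, [ring])

    def test_triple_coaxial_stack(self):
        a1, r1 = _hexagon((0, 0, 0), res_num=1)
        a2, r2 = _hexagon((0, 0, 3.5), res_num=2)
        a3, r3 = _hexagon((0, 0, 7.0), res_num=3)
        s = Structure(atoms=a1 + a2 + a3)
        hits = detect_stacking(s, s.coords, [r1, r2, r3])
        pairs = {frozenset((h.ring_i, h.ring_j)) for h in hits}
        assert frozenset(("TYR1", "TYR2")) in pairs
        assert frozenset(("TYR2", "TYR3")) in pairs


class TestTripleStack:
    def test_all_frames_stacked_is_stable(self):
        traj, rings = make_stack_pattern_trajectory(["WYG"] * 5)
        res = triple_stack_series(traj, rings)
        assert res.occupancy["W84:Y114:G"] == 1.0
        assert res.label == "stable"

    def test_planted_partial_occupancy(self):
        traj, rings = make_stack_pattern_trajectory(["WYG"] * 4 + ["none"] * 6)
        res = triple_stack_series(traj, rings)
        assert res.occupancy["W84:Y114:G"] == pytest.approx(0.4)
        assert res.label.startswith("unstable/alternative")

    def test_alternative_triple_dominates(self):
        """The methylated-substrate pattern: A:Y114:G replaces W84:Y114:G."""
        traj, rings = make_stack_pattern_trajectory(["AYG"] * 7 + ["WYG"] * 3)
        res = triple_stack_series(traj, rings)
        assert res.dominant == "A:Y114:G"
        assert "A:Y114:G" in res.label


WT_C_PLANT = [
    PlantedContact("vdw", ("THR", 27, "CG2"), ("DC", 3, "C4")),
    PlantedContact("vdw", ("THR", 27, "CG1"), ("DC", 3, "C5")),
    PlantedContact("vdw", ("THR", 27, "CB"), ("DC", 3, "C6")),
    PlantedContact("hbond", ("ASN", 51, "ND2"), ("DC", 3, "O2")),
]
# N51A twin: the N51-O2 H-bond is gone
N51A_C_PLANT = WT_C_PLANT[:3]
# 5mC twin: methyl bridges to W84 and T27 appear
WT_5MC_PLANT = WT_C_PLANT[:1] + [
    PlantedContact("hbond", ("ASN", 51, "ND2"), ("5CM", 3, "O2")),
    # methyl contacts realized by two distinct methyl-group atom names; both
    # collapse onto the single "5mC-methyl" partner key
    PlantedContact("vdw", ("TRP", 84, "CZ2"), ("5CM", 3, "C7")),
    PlantedContact("vdw", ("THR", 27, "CG1"), ("5CM", 3, "C5M")),
]


def _one_frame_traj(structure):
    return Trajectory(structure, [structure.coords])


class TestAggregateNetwork:
    def test_planted_counts(self):
        net = aggregate_network(
            _one_frame_traj(make_interaction_frame(WT_C_PLANT)),
            AtomSelector(chain="A"), AtomSelector(chain="B"), complex_label="wt:C",
        )
        assert net.counts == {"n_vdw": 3, "n_hbond": 1, "n_stack": 0, "n_total": 4}

    def test_no_plants_empty_network(self):
        net = aggregate_network(
            _one_frame_traj(make_interaction_frame([])),
            AtomSelector(chain="A"), AtomSelector(chain="B"),
        )
        assert net.counts["n_total"] == 0 and net.records == []

    def test_occupancy_boundary_half_counts(self):
        traj = make_interaction_trajectory(WT_C_PLANT[:1], np.array([[True, False]]))
        net = aggregate_network(traj, AtomSelector(chain="A"), AtomSelector(chain="B"))
        assert net.counts["n_vdw"] == 1  # occupancy 0.5 >= threshold 0.5
        rec = [r for r in net.records if r.kind == "vdw"][0]
        assert rec.occupancy == pytest.approx(0.5)

    def test_counts_monotone_in_occupancy_threshold(self):
        presence = np.array([[True, True, False, False],
                             [True, True, True, False],
                             [True, False, False, False],
                             [True, True, True, True]])
        traj = make_interaction_trajectory(WT_C_PLANT, presence)
        prev = None
        for thr in (0.2, 0.5, 0.8, 1.0):
            net = aggregate_network(
                traj, AtomSelector(chain="A"), AtomSelector(chain="B"),
                InteractionConfig(occupancy_threshold=thr),
            )
            if prev is not None:
                assert net.counts["n_total"] <= prev
            prev = net.counts["n_total"]

    def test_frame_order_invariance(self):
        presence = np.array([[True, False, True], [True, True, False],
                             [False, True, True], [True, True, True]])
        traj = make_interaction_trajectory(WT_C_PLANT, presence)
        rev = Trajectory(traj.topology, traj.frames[::-1])
        sel = (AtomSelector(chain="A"), AtomSelector(chain="B"))
        net_a, net_b = aggregate_network(traj, *sel), aggregate_network(rev, *sel)
        assert {r.key: r.occupancy for r in net_a.records} == {
            r.key: r.occupancy for r in net_b.records
        }

    def test_rigid_transform_invariance(self, rng):
        traj = _one_frame_traj(make_interaction_frame(WT_C_PLANT))
        R, t = random_rigid_transform(rng)
        moved = Trajectory(traj.topology, [traj.frames[0] @ R.T + t])
        sel = (AtomSelector(chain="A"), AtomSelector(chain="B"))
        assert aggregate_network(traj, *sel).counts == aggregate_network(moved, *sel).counts

    def test_hbond_vdw_exclusive(self):
        """The planted H-bond pair (N...O, 2.9 A) is never also a vdW record."""
        net = aggregate_network(
            _one_frame_traj(make_interaction_frame(WT_C_PLANT)),
            AtomSelector(chain="A"), AtomSelector(chain="B"),
        )
        hb = {(r.partner_a, r.partner_b) for r in net.records if r.kind == "hbond"}
        vdw = {(r.partner_a, r.partner_b) for r in net.records if r.kind == "vdw"}
        assert hb and not (hb & vdw)

    def test_mean_distance_over_present_frames(self):
        traj = make_interaction_trajectory(WT_C_PLANT[:1], np.array([[True, False, True]]))
        net = aggregate_network(traj, AtomSelector(chain="A"), AtomSelector(chain="B"))
        rec = net.records[0]
        d_planted = 1.7 + 1.7 + 0.6 - 0.2
        assert rec.mean_distance == pytest.approx(d_planted, abs=1e-9)


class TestNetworkDiff:
    def _net(self, plant, label):
        return aggregate_network(
            _one_frame_traj(make_interaction_frame(plant)),
            AtomSelector(chain="A"), AtomSelector(chain="B"), complex_label=label,
        )

    def test_self_diff_all_shared(self):
        net = self._net(WT_C_PLANT, "wt:C")
        d = network_diff(net, net)
        assert d.gained == [] and d.lost == [] and len(d.shared) == 4

    def test_n51a_loses_the_n51_o2_hbond(self):
        d = network_diff(self._net(WT_C_PLANT, "wt:C"), self._net(N51A_C_PLANT, "N51A:C"))
        assert d.gained == []
        assert d.lost == [("hbond", ("ASN", 51, "ND2"), ("DC", 3, "O2"))]

    def test_methylation_gains_collapse_to_methyl_partner(self):
        """5mC fixture gains W84/T27 methyl bridges under the '5mC-methyl' key."""
        wt_c = self._net(WT_C_PLANT, "wt:C")
        wt_5mc = self._net(WT_5MC_PLANT, "wt:5mC")
        d = network_diff(wt_c, wt_5mc)
        gained_kinds = {(k, a, b) for (k, a, b) in d.gained}
        assert ("vdw", ("TRP", 84, "CZ2"), ("5CM", 3, "5mC-methyl")) in gained_kinds
        assert ("vdw", ("THR", 27, "CG1"), ("5CM", 3, "5mC-methyl")) in gained_kinds
        # every gained vdW key on the substrate methyl uses the collapsed label
        for k, a, b in d.gained:
            if b[0] == "5CM" and k == "vdw":
                assert b[2] == "5mC-methyl"
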