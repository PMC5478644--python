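"""Per-frame interaction detection and per-complex interaction networks.

Three interaction kinds are detected between a protein group and a substrate
group:

* van der Waals contacts: heavy-atom pairs with center distance at most
  r_a + r_b + tolerance (Bondi radii by default);
* hydrogen bonds: donor (N/O/S) to acceptor (N/O) heavy-atom distance at most
  ``hbond_d_max`` and, when the donor carries explicit hydrogens, a D-H...A
  angle of at least ``hbond_angle_min`` for the best hydrogen.  H-bonds take
  precedence: a donor-acceptor atom pair classified as an H-bond in a frame is
  excluded from that frame's vdW contacts;
* pi-stacking: ring pairs with centroid distance, interplanar angle (folded to
  [0, 90] degrees) and lateral offset within their cutoffs.

Aggregation over a trajectory yields one record per unique partner pair and
kind, with per-frame presence, occupancy (fraction of frames present) and the
mean distance over present frames.  Counts include only records at or above
the configured occupancy threshold.  Contacts made by any atom of a 5mC
methyl group collapse onto a single "5mC-methyl" partner so that network
diffs read like the methyl-bridge narrative they support.

The geometric cutoffs are community-standard defaults and are configurable;
they are echoed into every network so results carry their provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import GeometryError, SelectionError
from .structio import AtomSelector, Structure, Trajectory, atom_indices
from .trajgeom import VdwRadiusTable, _best_fit_plane

__all__ = [
    "InteractionConfig",
    "RingSpec",
    "InteractionRecord",
    "InteractionNetwork",
    "detect_vdw_contacts",
    "detect_hbonds",
    "detect_stacking",
    "triple_stack_series",
    "aggregate_network",
    "network_diff",
    "NetworkDiff",
    "donors_in_group",
]

_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O"}
_H_BOND_LENGTH_MAX = 1.25  # covalent D-H attachment cutoff, Angstrom


@dataclass(frozen=True)
class InteractionConfig:
    """Geometric criteria and aggregation thresholds (all configurable)."""

    vdw_tolerance: float = 0.6  # Angstrom beyond r_a + r_b
    hbond_d_max: float = 3.5  # donor-acceptor heavy-atom distance, Angstrom
    hbond_angle_min: float = 120.0  # D-H...A angle, degrees
    stack_centroid_max: float = 4.5  # Angstrom
    stack_plane_angle_max: float = 30.0  # degrees
    stack_offset_max: float = 2.0  # Angstrom
    occupancy_threshold: float = 0.5  # record counted as "an interaction exists"
    stable_threshold: float = 0.7  # stacking called stable at this occupancy
    methyl_res_names: tuple = ("5CM", "5MC", "5mC")
    methyl_atom_names: tuple = ("C7", "C5M", "H71", "H72", "H73")

    def as_dict(self) -> dict:
        return {
            "vdw_tolerance": self.vdw_tolerance,
            "hbond_d_max": self.hbond_d_max,
            "hbond_angle_min": self.hbond_angle_min,
            "stack_centroid_max": self.stack_centroid_max,
            "stack_plane_angle_max": self.stack_plane_angle_max,
            "stack_offset_max": self.stack_offset_max,
            "occupancy_threshold": self.occupancy_threshold,
            "stable_threshold": self.stable_threshold,
        }


@dataclass(frozen=True)
class RingSpec:
    """An aromatic ring: a label, its member atom names and owner residue."""

    label: str
    member_names: tuple
    res_num: int
    chain: str | None = None
    res_name: str | None = None

    def __post_init__(self):
        if len(self.member_names) < 5:
            raise ValueError(f"ring {self.label!r} needs >= 5 member atoms")

    def resolve(self, structure: Structure) -> list[int]:
        idx = []
        for name in self.member_names:
            sel = AtomSelector(
                chain=self.chain, res_num=self.res_num, res_name=self.res_name, name=name
            )
            found = atom_indices(structure, sel)
            if len(found) != 1:
                raise SelectionError(
                    f"ring {self.label!r}: atom {name!r} resolved {len(found)} times"
                )
            idx.extend(found)
        return idx


#: default ring definitions for the triple-stacking analysis
def default_rings(chain_protein: str = "A", chain_dna: str = "B",
                  w84: int = 84, y114: int = 114, g_res: int = 2, a_res: int = 1) -> dict:
    """RingSpecs for W84 indole, Y114 phenol and the substrate G/A purines."""
    return {
        "W84": RingSpec("W84-indole",
                        ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
                        res_num=w84, chain=chain_protein),
        "Y114": RingSpec("Y114-phenol", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                         res_num=y114, chain=chain_protein),
        "G": RingSpec("G-purine", ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
                      res_num=g_res, chain=chain_dna),
        "A": RingSpec("A-purine", ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
                      res_num=a_res, chain=chain_dna),
    }


# --------------------------------------------------------------------------
# Per-frame detectors
# --------------------------------------------------------------------------


def detect_vdw_contacts(
    structure: Structure,
    frame: np.ndarray,
    group_a: list[int],
    group_b: list[int],
    radii: VdwRadiusTable | None = None,
    tolerance: float = 0.6,
    exclude_pairs: frozenset | set = frozenset(),
) -> list[tuple[int, int, float]]:
    """Heavy-atom pairs (i from a, j from b) with d <= r_i + r_j + tolerance.

    ``exclude_pairs`` holds (i, j) atom-index pairs already classified as
    H-bonds in this frame (classification precedence is exclusive).
    """
    radii = radii or VdwRadiusTable.bondi()
    frame = np.asarray(frame, dtype=float)
    ga = [i for i in group_a if structure.atoms[i].element != "H"]
    gb = [j for j in group_b if structure.atoms[j].element != "H"]
    if not ga or not gb:
        return []
    pa, pb = frame[ga], frame[gb]
    ra = np.array([radii[structure.atoms[i].element] for i in ga])
    rb = np.array([radii[structure.atoms[j].element] for j in gb])
    dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    cutoff = ra[:, None] + rb[None, :] + tolerance
    out = []
    for ii, jj in zip(*np.nonzero(dist <= cutoff)):
        i, j = ga[ii], gb[jj]
        if (i, j) in exclude_pairs or (j, i) in exclude_pairs:
            continue
        out.append((i, j, float(dist[ii, jj])))
    return out


def donors_in_group(
    structure: Structure, frame: np.ndarray, group: list[int]
) -> list[tuple[int, list[int]]]:
    """(donor heavy atom, attached hydrogens) for every N/O/S in the group.

    Hydrogens are attached when they belong to the same residue and sit within
    1.25 A of the heavy atom.  Donors without explicit hydrogens are returned
    with an empty list (distance-only criterion applies downstream).
    """
    frame = np.asarray(frame, dtype=float)
    by_residue: dict[tuple, list[int]] = {}
    for i in group:
        a = structure.atoms[i]
        if a.element == "H":
            by_residue.setdefault((a.chain, a.res_num), []).append(i)
    donors = []
    for i in group:
        a = structure.atoms[i]
        if a.element not in _DONOR_ELEMENTS:
            continue
        hs = [
            h
            for h in by_residue.get((a.chain, a.res_num), [])
            if np.linalg.norm(frame[h] - frame[i]) <= _H_BOND_LENGTH_MAX
        ]
        donors.append((i, hs))
    return donors


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float | None


def detect_hbonds(
    structure: Structure,
    frame: np.ndarray,
    donors: list[tuple[int, list[int]]],
    acceptors: list[int],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Hydrogen bonds from (donor, hydrogens) entries to acceptor atoms.

    A bond is reported when the donor-acceptor distance is at most ``d_max``
    and, if the donor carries hydrogens, the best D-H...A angle is at least
    ``angle_min``.  Without hydrogens the distance criterion alone applies and
    the angle is None.
    """
    frame = np.asarray(frame, dtype=float)
    acceptors = [j for j in acceptors if structure.atoms[j].element in _ACCEPTOR_ELEMENTS]
    out = []
    for d_idx, hydrogens in donors:
        for a_idx in acceptors:
            if d_idx == a_idx:
                raise ValueError("donor and acceptor are the same atom")
            dist = float(np.linalg.norm(frame[d_idx] - frame[a_idx]))
            if dist > d_max:
                continue
            if hydrogens:
                best_h, best_angle = None, -1.0
                for h in hydrogens:
                    v1 = frame[d_idx] - frame[h]
                    v2 = frame[a_idx] - frame[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if ang > best_angle:
                        best_h, best_angle = h, ang
                if best_angle < angle_min:
                    continue
                out.append(HBond(d_idx, best_h, a_idx, dist, best_angle))
            else:
                out.append(HBond(d_idx, None, a_idx, dist, None))
    return out


@dataclass(frozen=True)
class StackContact:
    ring_i: str
    ring_j: str
    centroid_distance: float
    plane_angle: float
    lateral_offset: float


def _ring_frame_geometry(frame: np.ndarray, idx: list[int]):
    pts = frame[idx]
    centroid = pts.mean(axis=0)
    normal, dev = _best_fit_plane(pts)
    if dev > 0.3:
        raise GeometryError(f"ring atoms deviate {dev:.2f} A from planarity (> 0.3 A)")
    return centroid, normal


def detect_stacking(
    structure: Structure,
    frame: np.ndarray,
    rings: list[RingSpec],
    centroid_max: float = 4.5,
    plane_angle_max: float = 30.0,
    offset_max: float = 2.0,
) -> list[StackContact]:
    """Stacked ring pairs by centroid distance, interplanar angle and offset."""
    frame = np.asarray(frame, dtype=float)
    geo = {}
    for ring in rings:
        idx = ring.resolve(structure)
        geo[ring.label] = _ring_frame_geometry(frame, idx)
    out = []
    for ra, rb in combinations(rings, 2):
        ca, na = geo[ra.label]
        cb, nb = geo[rb.label]
        delta = cb - ca
        dist = float(np.linalg.norm(delta))
        if dist > centroid_max:
            continue
        cosang = abs(float(np.dot(na, nb)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
        if angle > plane_angle_max:
            continue
        mean_normal = na + (nb if np.dot(na, nb) >= 0 else -nb)
        mean_normal /= np.linalg.norm(mean_normal)
        offset = float(np.linalg.norm(delta - np.dot(delta, mean_normal) * mean_normal))
        if offset > offset_max:
            continue
        out.append(StackContact(ra.label, rb.label, dist, angle, offset))
    return out


# --------------------------------------------------------------------------
# Triple stacking over a trajectory
# --------------------------------------------------------------------------


@dataclass
class TripleStackResult:
    occupancy: dict  # triple label -> fraction of frames
    presence: dict  # triple label -> per-frame boolean array
    label: str  # "stable" or "unstable/alternative (...)"
    dominant: str


def triple_stack_series(
    traj: Trajectory,
    rings: dict,
    config: InteractionConfig | None = None,
) -> TripleStackResult:
    """Occupancy of the W84:Y114:G and A:Y114:G triple stacks over frames.

    A triple is present in a frame when both of its adjacent ring pairs are
    stacked.  The W84:Y114:G triple is labeled "stable" at or above
    ``stable_threshold`` occupancy; otherwise the dominant triple is named.
    """
    config = config or InteractionConfig()
    needed = ["W84", "Y114", "G"]
    for key in needed:
        if key not in rings:
            raise SelectionError(f"triple_stack_series needs a ring spec for {key!r}")
    ring_list = [rings[k] for k in needed] + ([rings["A"]] if "A" in rings else [])
    triples = {"W84:Y114:G": ("W84", "Y114", "G")}
    if "A" in rings:
        triples["A:Y114:G"] = ("A", "Y114", "G")
    label_of = {k: rings[k].label for k in rings}
    presence = {t: np.zeros(traj.n_frames, dtype=bool) for t in triples}
    for f, frame in enumerate(traj.frames):
        contacts = detect_stacking(
            traj.topology,
            frame,
            ring_list,
            config.stack_centroid_max,
            config.stack_plane_angle_max,
            config.stack_offset_max,
        )
        stacked = {frozenset((c.ring_i, c.ring_j)) for c in contacts}
        for t, (x, y, z) in triples.items():
            pair1 = frozenset((label_of[x], label_of[y]))
            pair2 = frozenset((label_of[y], label_of[z]))
            presence[t][f] = pair1 in stacked and pair2 in stacked
    occupancy = {t: float(p.mean()) for t, p in presence.items()}
    dominant = max(occupancy, key=lambda t: (occupancy[t], t == "W84:Y114:G"))
    if occupancy["W84:Y114:G"] >= config.stable_threshold:
        label = "stable"
    else:
        label = f"unstable/alternative ({dominant})"
    return TripleStackResult(occupancy=occupancy, presence=presence, label=label, dominant=dominant)


# --------------------------------------------------------------------------
# Network aggregation
# --------------------------------------------------------------------------


@dataclass
class InteractionRecord:
    kind: str  # vdw | hbond | stack
    partner_a: tuple  # (res_name, res_num, atom name or ring label), protein side
    partner_b: tuple  # substrate side
    presence: np.ndarray
    occupancy: float = field(init=False)
    mean_distance: float = field(init=False)
    _distances: np.ndarray = None

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        self.occupancy = float(self.presence.mean())
        if self._distances is not None and self.presence.any():
            self.mean_distance = float(np.asarray(self._distances)[self.presence].mean())
        else:
            self.mean_distance = float("nan")

    @property
    def key(self) -> tuple:
        return (self.kind, self.partner_a, self.partner_b)


@dataclass
class InteractionNetwork:
    complex_label: str
    records: list
    counts: dict
    config: dict = field(default_factory=dict)

    def present_keys(self, threshold: float) -> set:
        return {r.key for r in self.records if r.occupancy >= threshold}


def _partner_label(structure: Structure, idx: int, config: InteractionConfig) -> tuple:
    a = structure.atoms[idx]
    if a.res_name in config.methyl_res_names and a.name in config.methyl_atom_names:
        return (a.res_name, a.res_num, "5mC-methyl")
    return (a.res_name, a.res_num, a.name)


def aggregate_network(
    traj: Trajectory,
    group_protein: AtomSelector,
    group_substrate: AtomSelector,
    config: InteractionConfig | None = None,
    radii: VdwRadiusTable | None = None,
    rings: dict | None = None,
    complex_label: str = "",
) -> InteractionNetwork:
    """Aggregate per-frame detections into an interaction network.

    One record per unique (kind, partner_a, partner_b); occupancy over frames;
    mean distance over present frames.  Counts are taken at the configured
    occupancy threshold.  H-bonds and vdW contacts are mutually exclusive
    within a frame (H-bond precedence).
    """
    config = config or InteractionConfig()
    radii = radii or VdwRadiusTable.bondi()
    topo = traj.topology
    prot = atom_indices(topo, group_protein)
    subs = atom_indices(topo, group_substrate)
    if set(prot) & set(subs):
        raise SelectionError("protein and substrate groups overlap")
    n = traj.n_frames
    seen: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def record(kind, key_a, key_b, f, dist):
        key = (kind, key_a, key_b)
        if key not in seen:
            seen[key] = (np.zeros(n, dtype=bool), np.full(n, np.nan))
        seen[key][0][f] = True
        seen[key][1][f] = dist

    ring_pairs = list(rings.values()) if rings else []
    prot_chains = {topo.atoms[i].chain for i in prot}

    for f, frame in enumerate(traj.frames):
        donors_p = donors_in_group(topo, frame, prot)
        donors_s = donors_in_group(topo, frame, subs)
        acc_p = [i for i in prot if topo.atoms[i].element in _ACCEPTOR_ELEMENTS]
        acc_s = [i for i in subs if topo.atoms[i].element in _ACCEPTOR_ELEMENTS]
        hbonds = detect_hbonds(topo, frame, donors_p, acc_s,
                               config.hbond_d_max, config.hbond_angle_min)
        hbonds += detect_hbonds(topo, frame, donors_s, acc_p,
                                config.hbond_d_max, config.hbond_angle_min)
        hb_pairs = set()
        for hb in hbonds:
            if hb.donor in prot:
                ia, ib = hb.donor, hb.acceptor
            else:
                ia, ib = hb.acceptor, hb.donor
            hb_pairs.add((ia, ib))
            record("hbond", _partner_label(topo, ia, config),
                   _partner_label(topo, ib, config), f, hb.distance)
        for i, j, dist in detect_vdw_contacts(
            topo, frame, prot, subs, radii, config.vdw_tolerance, hb_pairs
        ):
            record("vdw", _partner_label(topo, i, config),
                   _partner_label(topo, j, config), f, dist)
        if ring_pairs:
            prot_labels = {r.label for r in ring_pairs if r.chain in prot_chains}
            for c in detect_stacking(topo, frame, ring_pairs, config.stack_centroid_max,
                                     config.stack_plane_angle_max, config.stack_offset_max):
                # orient the key protein-side first where identifiable
                a_lab, b_lab = c.ring_i, c.ring_j
                if b_lab in prot_labels and a_lab not in prot_labels:
                    a_lab, b_lab = b_lab, a_lab
                record("stack", (a_lab,), (b_lab,), f, c.centroid_distance)

    records = []
    for (kind, ka, kb), (presence, dists) in sorted(seen.items(), key=lambda kv: repr(kv[0])):
        records.append(InteractionRecord(kind=kind, partner_a=ka, partner_b=kb,
                                         presence=presence, _distances=dists))
    thr = config.occupancy_threshold
    counted = [r for r in records if r.occupancy >= thr]
    counts = {
        "n_vdw": sum(1 for r in counted if r.kind == "vdw"),
        "n_hbond": sum(1 for r in counted if r.kind == "hbond"),
        "n_stack": sum(1 for r in counted if r.kind == "stack"),
    }
    counts["n_total"] = counts["n_vdw"] + counts["n_hbond"] + counts["n_stack"]
    return InteractionNetwork(
        complex_label=complex_label, records=records, counts=counts, config=config.as_dict()
    )


@dataclass
class NetworkDiff:
    gained: list  # keys in b, not in a
    lost: list  # keys in a, not in b
    shared: list


def network_diff(
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
    threshold: float | None = None,
) -> NetworkDiff:
    """Set differences on record keys between two networks.

    Only records at or above the occupancy threshold participate (the
    threshold defaults to the one echoed in net_a's config).  Keys are sorted
    deterministically.
    """
    if threshold is None:
        threshold = net_a.config.get("occupancy_threshold", 0.5)
    keys_a = net_a.present_keys(threshold)
    keys_b = net_b.present_keys(threshold)
    return NetworkDiff(
        gained=sorted(keys_b - keys_a, key=repr),
        lost=sorted(keys_a - keys_b, key=repr),
        shared=sorted(keys_a & keys_b, key=repr),
    )
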