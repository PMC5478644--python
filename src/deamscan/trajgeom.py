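"""Pocket geometry, substrate ring breadths and rigid superposition.

The catalytic-pocket size is tracked as four labeled atom-pair distances over
a trajectory:

* ``d1``: residue 51 (ND2 in the wild type, CB in the N51A variant) - Y114 CE2
* ``d2``: residue 51 - P86 CB  (the gate: the breadth of a heterocyclic ring
  that can enter the pocket)
* ``d3``: residue 51 - C87 SG
* ``d4``: Y114 CE2 - H56 CE1  (pocket height)

Substrate ring breadths are computed from idealized base geometries shipped
with the package, including van der Waals radii (Bondi set by default).  The
breadth convention is a vdW caliper measured in the ring plane: the maximum
over breadth-set atom pairs of (in-plane center distance + both radii), where
the breadth set contains the base's heavy atoms plus the C5 substituent (H5
for cytosine; heavy atoms for the rotating methyl / hydroxymethyl groups) and
excludes the glycosidic C1'.  With standard geometry this yields 7.8 A for C
and 8.7 A for 5mC; the hydroxymethyl dihedral of 5hmC is scanned on a grid
and the breadth reported as a [min, max] interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    GeometryError,
    PairingError,
    SelectionError,
    UnderdeterminedError,
)
from .structio import Atom, AtomSelector, Structure, Trajectory, atom_indices, select

__all__ = [
    "VdwRadiusTable",
    "WATER_BULK_MIN",
    "WATER_BULK_MAX",
    "PocketDefinition",
    "DistanceSeries",
    "atom_distance",
    "pocket_distance_series",
    "SubstrateRingGeometry",
    "load_base_geometry",
    "ring_breadth",
    "FitVerdict",
    "fit_assessment",
    "SuperpositionResult",
    "superpose",
    "segment_rmsd",
    "kabsch_rmsd",
]

# Steric bulk added by a single hydration water, Angstrom (documented constants
# used by the 5hmC fit argument).
WATER_BULK_MIN = 2.8
WATER_BULK_MAX = 3.2

_BONDI = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "Zn": 1.39,
}


@dataclass(frozen=True)
class VdwRadiusTable:
    """Element -> van der Waals radius in Angstrom (Bondi set by default)."""

    radii: dict = field(default_factory=lambda: dict(_BONDI))

    def __post_init__(self):
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"vdW radius for {el} out of range (0.5, 3.0): {r}")

    @classmethod
    def bondi(cls) -> "VdwRadiusTable":
        return cls()

    @classmethod
    def from_json(cls, path) -> "VdwRadiusTable":
        with open(path) as fh:
            override = json.load(fh)
        radii = dict(_BONDI)
        radii.update({k: float(v) for k, v in override.items()})
        return cls(radii=radii)

    def __getitem__(self, element: str) -> float:
        key = element.capitalize() if len(element) > 1 else element.upper()
        try:
            return self.radii[key]
        except KeyError:
            raise KeyError(f"no vdW radius for element {element!r}") from None


# --------------------------------------------------------------------------
# Pocket distances
# --------------------------------------------------------------------------

#: default residue numbers of the pocket-defining residues
POCKET_RESIDUES = {"res51": 51, "Y114": 114, "P86": 86, "C87": 87, "H56": 56}


@dataclass(frozen=True)
class PocketDefinition:
    """Four labeled atom pairs that define the catalytic-pocket size."""

    variant_flag: str = "wt"  # "wt" | "N51A"
    chain: str | None = None
    residues: dict = field(default_factory=lambda: dict(POCKET_RESIDUES))

    def __post_init__(self):
        if self.variant_flag not in ("wt", "N51A"):
            raise ValueError(f"variant_flag must be 'wt' or 'N51A', got {self.variant_flag!r}")

    @property
    def res51_atom(self) -> str:
        return "ND2" if self.variant_flag == "wt" else "CB"

    @property
    def pairs(self) -> dict:
        """label -> (AtomSelector, AtomSelector)"""
        r = self.residues
        s51 = AtomSelector(chain=self.chain, res_num=r["res51"], name=self.res51_atom)
        y114 = AtomSelector(chain=self.chain, res_num=r["Y114"], name="CE2")
        return {
            "d1": (s51, y114),
            "d2": (s51, AtomSelector(chain=self.chain, res_num=r["P86"], name="CB")),
            "d3": (s51, AtomSelector(chain=self.chain, res_num=r["C87"], name="SG")),
            "d4": (y114, AtomSelector(chain=self.chain, res_num=r["H56"], name="CE1")),
        }


@dataclass
class DistanceSeries:
    """Per-frame distances for one labeled pair, with summary statistics."""

    label: str
    values: np.ndarray
    mean: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")
        self.mean = float(self.values.mean())
        self.min = float(self.values.min())
        self.max = float(self.values.max())


def atom_distance(frame: np.ndarray, a: int | Atom, b: int | Atom) -> float:
    """Euclidean distance (Angstrom) between two resolved atoms in a frame.

    ``a``/``b`` are atom indices into the frame (or Atom objects carrying their
    own coordinates, in which case ``frame`` may be None).
    """
    if isinstance(a, Atom) and isinstance(b, Atom):
        if a is b or a.key == b.key:
            raise ValueError("atom_distance requires two distinct atoms")
        pa, pb = a.xyz, b.xyz
    else:
        if a == b:
            raise ValueError("atom_distance requires two distinct atoms")
        frame = np.asarray(frame, dtype=float)
        pa, pb = frame[a], frame[b]
    return float(np.linalg.norm(pa - pb))


def _resolve_unique(structure: Structure, sel: AtomSelector, label: str) -> int:
    idx = atom_indices(structure, sel)
    if len(idx) != 1:
        raise SelectionError(
            f"pocket pair {label!r}: selector {sel} resolved {len(idx)} atoms, expected 1"
        )
    return idx[0]


def pocket_distance_series(traj: Trajectory, pocket: PocketDefinition) -> dict:
    """Per-frame pocket distances d1..d4 -> {label: DistanceSeries}."""
    coords = np.stack(traj.frames)  # (n_frames, n_atoms, 3)
    out = {}
    for label, (sa, sb) in pocket.pairs.items():
        ia = _resolve_unique(traj.topology, sa, label)
        ib = _resolve_unique(traj.topology, sb, label)
        d = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=1)
        out[label] = DistanceSeries(label=label, values=d)
    return out


# --------------------------------------------------------------------------
# Substrate ring breadths
# --------------------------------------------------------------------------


@dataclass
class SubstrateRingGeometry:
    """Idealized geometry of a C / 5mC / 5hmC base.

    Atoms carry a role and a flag marking membership in the breadth set.  The
    depth axis is the C1'->C4 direction; the breadth axis is the in-plane
    direction perpendicular to it.
    """

    base_kind: str
    names: list[str]
    elements: list[str]
    coords: np.ndarray
    roles: list[str]
    breadth_set: np.ndarray  # boolean mask
    rotatable: dict | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        ring = self.coords[[r == "ring" for r in self.roles]]
        if self.base_kind in ("C", "5mC"):
            # ring coplanarity within 0.1 A
            _, res = _best_fit_plane(ring)
            if res > 0.1:
                raise GeometryError(f"{self.base_kind} ring not coplanar: max dev {res:.3f} A")
        if abs(np.dot(self.depth_axis, self.breadth_axis)) > 1e-9:
            raise GeometryError("depth and breadth axes are not orthogonal")

    def _pos(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.names.index(name)]
        except ValueError:
            raise GeometryError(f"{self.base_kind}: required atom {name!r} missing") from None

    @property
    def plane_normal(self) -> np.ndarray:
        ring = self.coords[[r == "ring" for r in self.roles]]
        n, _ = _best_fit_plane(ring)
        return n

    @property
    def depth_axis(self) -> np.ndarray:
        v = self._pos("C4") - self._pos("C1'")
        n = self.plane_normal
        v = v - np.dot(v, n) * n
        return v / np.linalg.norm(v)

    @property
    def breadth_axis(self) -> np.ndarray:
        v = np.cross(self.plane_normal, self.depth_axis)
        return v / np.linalg.norm(v)

    def rotamers(self):
        """Yield coordinate sets over the rotatable-group dihedral grid.

        For rigid bases yields the single geometry.
        """
        if self.rotatable is None:
            yield self.coords
            return
        a0 = self._pos(self.rotatable["axis"][0])
        a1 = self._pos(self.rotatable["axis"][1])
        axis = (a1 - a0) / np.linalg.norm(a1 - a0)
        moving = [self.names.index(n) for n in self.rotatable["moving"]]
        step = self.rotatable.get("grid_step_deg", 10)
        for deg in range(0, 360, step):
            rot = Rotation.from_rotvec(np.radians(deg) * axis)
            coords = self.coords.copy()
            coords[moving] = a1 + rot.apply(coords[moving] - a1)
            yield coords


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit normal of the least-squares plane and max |deviation| from it."""
    points = np.asarray(points, dtype=float)
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:  # rank < 2: collinear
        raise GeometryError("degenerate (collinear) atom set: no plane defined")
    normal = vt[2]
    dev = float(np.abs(centered @ normal).max())
    return normal, dev


def load_base_geometry(base_kind: str) -> SubstrateRingGeometry:
    """Load the idealized geometry for base_kind in {'C', '5mC', '5hmC'}."""
    text = resources.files("deamscan.data").joinpath("base_geometry.json").read_text()
    data = json.loads(text)
    try:
        entry = data["bases"][base_kind]
    except KeyError:
        raise GeometryError(f"no idealized geometry for base kind {base_kind!r}") from None
    atoms = entry["atoms"]
    return SubstrateRingGeometry(
        base_kind=base_kind,
        names=[a["name"] for a in atoms],
        elements=[a["element"] for a in atoms],
        coords=np.array([a["coord"] for a in atoms], dtype=float),
        roles=[a["role"] for a in atoms],
        breadth_set=np.array([a["breadth"] for a in atoms], dtype=bool),
        rotatable=entry.get("rotatable"),
    )


def _caliper_breadth(coords, elements, mask, radii, normal) -> float:
    """Max over breadth-set pairs of in-plane distance + both vdW radii."""
    pts = coords[mask]
    els = [e for e, m in zip(elements, mask) if m]
    # project onto the ring plane: remove the normal component
    flat = pts - np.outer(pts @ normal, normal)
    rr = np.array([radii[e] for e in els])
    diff = flat[:, None, :] - flat[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    width = dist + rr[:, None] + rr[None, :]
    np.fill_diagonal(width, 2 * rr)  # a single sphere's own diameter
    return float(width.max())


def _projection_breadth(coords, elements, mask, radii, axis) -> float:
    pts = coords[mask]
    els = [e for e, m in zip(elements, mask) if m]
    proj = pts @ axis
    rr = np.array([radii[e] for e in els])
    return float((proj + rr).max() - (proj - rr).min())


def ring_breadth(
    geom: SubstrateRingGeometry,
    radii: VdwRadiusTable | None = None,
    include_all_hydrogens: bool = False,
    convention: str = "caliper",
):
    """Ring breadth in Angstrom, including vdW radii.

    Returns a float for rigid bases and a ``(min, max)`` tuple for bases with
    a rotatable substituent (the hydroxymethyl dihedral is scanned on the
    configured grid; the ring of 5hmC is treated as not flat).

    ``convention="caliper"`` (default) measures the widest vdW-to-vdW span in
    the ring plane.  ``convention="projection"`` measures the vdW extent along
    the in-plane axis perpendicular to C1'->C4.  ``include_all_hydrogens``
    adds ring/amine/substituent hydrogens to the breadth set (alternative
    value; the headline uses the heavy-atom substituent envelope).
    """
    radii = radii or VdwRadiusTable.bondi()
    mask = geom.breadth_set.copy()
    if include_all_hydrogens:
        mask |= np.array([r in ("hydrogen", "substituent_hydrogen") for r in geom.roles])
    if not mask.any():
        raise GeometryError("empty breadth atom set")
    if convention not in ("caliper", "projection"):
        raise ValueError(f"unknown breadth convention {convention!r}")
    normal = geom.plane_normal
    axis = geom.breadth_axis

    def one(coords):
        if convention == "caliper":
            return _caliper_breadth(coords, geom.elements, mask, radii, normal)
        return _projection_breadth(coords, geom.elements, mask, radii, axis)

    values = [one(c) for c in geom.rotamers()]
    if geom.rotatable is None:
        return values[0]
    return (min(values), max(values))


# --------------------------------------------------------------------------
# Steric fit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitVerdict:
    fits_at_min: bool
    fits_at_mean: bool
    clearance: float  # gate minimum minus (max) breadth; may be negative


def fit_assessment(breadth, gate_series: DistanceSeries) -> FitVerdict:
    """Does a ring of the given breadth fit through the pocket gate (d2)?

    For a breadth interval the maximal breadth is used.  ``clearance`` is the
    gate's minimal opening minus the breadth.
    """
    b = max(breadth) if isinstance(breadth, (tuple, list)) else float(breadth)
    return FitVerdict(
        fits_at_min=b <= gate_series.min,
        fits_at_mean=b <= gate_series.mean,
        clearance=gate_series.min - b,
    )


# --------------------------------------------------------------------------
# Superposition and RMSD
# --------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    dev = (mobile - mc) @ R.T - (target - tc)
    rmsd = float(np.sqrt((dev**2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=tc - R @ mc, rmsd=rmsd)


def kabsch_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Optimal-superposition RMSD between two matched coordinate arrays."""
    if len(mobile) != len(target):
        raise PairingError(f"coordinate count mismatch: {len(mobile)} vs {len(target)}")
    if len(mobile) < 3:
        raise UnderdeterminedError("need at least 3 atoms for a rigid superposition")
    return _kabsch(mobile, target).rmsd


def _match_atoms(
    mobile: Structure,
    target: Structure,
    sel: AtomSelector | None,
    residue_offset=None,
) -> tuple[list[int], list[int]]:
    """Pair atoms by (res_num, name) after applying a residue-offset map."""
    if sel is None:
        sel = AtomSelector(name="CA")

    def mapped(res_num: int) -> int:
        if residue_offset is None:
            return res_num
        if isinstance(residue_offset, dict):
            return residue_offset.get(res_num, res_num)
        return res_num + int(residue_offset)

    mob_idx = atom_indices(mobile, sel)
    tgt_idx = atom_indices(target, sel)
    tgt_by_key = {(target.atoms[i].res_num, target.atoms[i].name): i for i in tgt_idx}
    pairs_m, pairs_t = [], []
    unmatched = []
    used = set()
    for i in mob_idx:
        a = mobile.atoms[i]
        key = (mapped(a.res_num), a.name)
        j = tgt_by_key.get(key)
        if j is None:
            unmatched.append(f"mobile {a.res_name}{a.res_num}:{a.name}")
        else:
            pairs_m.append(i)
            pairs_t.append(j)
            used.add(j)
    unmatched += [
        f"target {target.atoms[j].res_name}{target.atoms[j].res_num}:{target.atoms[j].name}"
        for j in tgt_idx
        if j not in used
    ]
    if unmatched:
        raise PairingError("unmatched atoms in superposition pairing: " + ", ".join(unmatched))
    return pairs_m, pairs_t


def superpose(
    mobile: Structure,
    target: Structure,
    sel: AtomSelector | None = None,
    residue_offset=None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto target.

    Atoms are matched by (res_num, name) within the selection (default: CA
    atoms); ``residue_offset`` (int or {mobile_res: target_res} dict) maps
    renumbered constructs.  The returned rotation is proper (det +1).
    """
    im, it = _match_atoms(mobile, target, sel, residue_offset)
    if len(im) < 3:
        raise UnderdeterminedError(
            f"only {len(im)} matched atoms; a rigid superposition needs >= 3"
        )
    return _kabsch(mobile.coords[im], target.coords[it])


def segment_rmsd(
    mobile: Structure,
    target: Structure,
    superpose_sel: AtomSelector | None = None,
    segment_sel: AtomSelector | None = None,
    residue_offset=None,
) -> float:
    """RMSD over a segment after a global superposition.

    The rigid transform is fitted on ``superpose_sel`` and the deviation is
    measured on ``segment_sel`` (e.g. a loop's residues).
    """
    fit = superpose(mobile, target, superpose_sel, residue_offset)
    if segment_sel is None:
        raise SelectionError("segment_rmsd requires a segment selector")
    im, it = _match_atoms(mobile, target, segment_sel, residue_offset)
    if not im:
        raise SelectionError("segment selection resolved no atoms")
    moved = fit.transform(mobile.coords[im])
    dev = moved - target.coords[it]
    return float(np.sqrt((dev**2).sum(axis=1).mean()))
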