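"""Synthetic inputs with planted ground truth.

Every generator is deterministic under a fixed seed (one pseudo-random stream
per call, no global state) and produces data in the same formats the analyzers
read, so generator + analyzer round trips recover the planted parameters:

* pocket trajectories whose labeled atom-pair distances realize prescribed
  min / mean / max values exactly (endpoint frames planted);
* single frames / trajectories in which exactly a planted list of vdW, H-bond
  and stacking interactions satisfy the default detection criteria (each
  contact lives in its own cell of a 25-Angstrom lattice, so every non-planted
  pair is far beyond threshold);
* trajectories with k planted conformational clusters at a chosen
  center-spread-to-noise ratio;
* clone sets with per-motif C->T Bernoulli deamination plus a uniform
  sequencing-error rate;
* gel lanes from the assay simulator with multiplicative log-normal intensity
  noise, in replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import (
    GLYCOSYLASES,
    PROTOCOL_GLYCOSYLASE,
    EnzymeProfile,
    GelLane,
    make_central_substrate,
    simulate_assay,
)
from .errors import ConstructionError
from .nncn import NncnDesign
from .structio import Atom, Structure, Trajectory, _infer_element
from .trajgeom import VdwRadiusTable

__all__ = [
    "DEFAULT_POCKET_TARGETS",
    "make_pocket_trajectory",
    "PlantedContact",
    "make_interaction_frame",
    "make_interaction_trajectory",
    "make_stack_pattern_trajectory",
    "make_clustered_trajectory",
    "make_clone_set",
    "make_gel_lanes",
]


# --------------------------------------------------------------------------
# Pocket trajectories
# --------------------------------------------------------------------------

#: planted pocket-distance conditions (Angstrom).  The d2 (gate) ranges are the
#: published wt (9.9-16.3) and N51A (10.4-15.1) values; the other pairs use
#: plausible mid-size pocket values (their exact levels are not analysed
#: quantitatively downstream).
DEFAULT_POCKET_TARGETS = {
    "wt": {
        "d1": {"min": 8.0, "mean": 10.0, "max": 12.0},
        "d2": {"min": 9.9, "mean": 13.1, "max": 16.3},
        "d3": {"min": 7.0, "mean": 9.0, "max": 11.0},
        "d4": {"min": 9.0, "mean": 10.5, "max": 12.0},
    },
    "N51A": {
        "d1": {"min": 8.5, "mean": 10.2, "max": 12.0},
        "d2": {"min": 10.4, "mean": 12.8, "max": 15.1},
        "d3": {"min": 7.2, "mean": 9.1, "max": 11.0},
        "d4": {"min": 9.2, "mean": 10.6, "max": 12.1},
    },
}

_POCKET_ATOMS = {
    # pair-partner atoms: (res_name, res_num, atom_name)
    "Y114": ("TYR", 114, "CE2"),
    "P86": ("PRO", 86, "CB"),
    "C87": ("CYS", 87, "SG"),
    "H56": ("HIS", 56, "CE1"),
}


def _planted_series(rng, n, lo, mean, hi, sigma):
    if not lo <= mean <= hi:
        raise ValueError(f"infeasible targets: need min <= mean <= max, got {lo}, {mean}, {hi}")
    if lo == hi:
        return np.full(n, float(mean))
    if n < 2:
        raise ValueError("need >= 2 frames to realize distinct min and max")
    vals = np.clip(rng.normal(mean, sigma, size=n), lo, hi)
    i_min, i_max = 0, n - 1  # endpoint frames carry the planted extremes
    vals[i_min], vals[i_max] = lo, hi
    if n > 2:
        # shift interior values so the realized mean hits the target, re-clipped
        interior = np.arange(1, n - 1)
        deficit = mean * n - vals.sum()
        vals[interior] = np.clip(vals[interior] + deficit / len(interior), lo, hi)
    return vals


def make_pocket_trajectory(
    n_frames: int,
    targets: dict | None = None,
    jitter_sigma: float = 0.8,
    seed: int = 0,
    variant: str = "wt",
    n_filler_residues: int = 40,
) -> Trajectory:
    """Trajectory whose pocket distances realize the target min/mean/max.

    Residue 51 (ND2 for wt, CB for N51A) sits at the origin; Y114, P86 and C87
    move along fixed orthogonal axes at the planted d1/d2/d3 distances, and
    H56 rides at the planted d4 offset from Y114, so every pair's realized
    series has its min and max exactly at the targets (endpoint frames) and
    its mean on target up to clipping.  Filler CA atoms are jittered i.i.d.
    Gaussian (sigma = ``jitter_sigma``).
    """
    if targets is None:
        targets = DEFAULT_POCKET_TARGETS[variant]
    rng = np.random.default_rng(seed)
    series = {
        label: _planted_series(
            rng, n_frames, t["min"], t["mean"], t["max"], jitter_sigma
        )
        for label, t in targets.items()
    }
    res51 = ("ASN", 51, "ND2") if variant == "wt" else ("ALA", 51, "CB")
    u1, u2, u3 = np.eye(3)
    u4 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)

    atoms, base = [], []

    def add(res_name, res_num, name, pos):
        atoms.append(
            Atom(
                serial=len(atoms) + 1,
                name=name,
                element=_infer_element(name),
                res_name=res_name,
                res_num=res_num,
                chain="A",
                coord=tuple(pos),
            )
        )
        base.append(np.asarray(pos, dtype=float))

    add(*res51, np.zeros(3))
    add(*_POCKET_ATOMS["Y114"], series["d1"][0] * u1)
    add(*_POCKET_ATOMS["P86"], series["d2"][0] * u2)
    add(*_POCKET_ATOMS["C87"], series["d3"][0] * u3)
    add(*_POCKET_ATOMS["H56"], series["d1"][0] * u1 + series["d4"][0] * u4)
    pocket_count = len(atoms)
    filler_res = [r for r in range(150, 150 + n_filler_residues)]
    for r in filler_res:
        add("GLY", r, "CA", np.array([3.8 * (r - 150), 30.0, 30.0]))

    frames = []
    for f in range(n_frames):
        coords = np.array(base)
        coords[1] = series["d1"][f] * u1
        coords[2] = series["d2"][f] * u2
        coords[3] = series["d3"][f] * u3
        coords[4] = series["d1"][f] * u1 + series["d4"][f] * u4
        coords[pocket_count:] += rng.normal(0.0, jitter_sigma, size=(len(atoms) - pocket_count, 3))
        frames.append(coords)
    title = f"synthetic pocket trajectory ({variant}, seed={seed})"
    return Trajectory(topology=Structure(atoms=atoms, title=title).with_coords(frames[0]),
                      frames=frames)


# --------------------------------------------------------------------------
# Planted interaction frames
# --------------------------------------------------------------------------

_RING_NAMES = {
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "DG": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "DA": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
}


@dataclass(frozen=True)
class PlantedContact:
    """One interaction to realize in a synthetic frame.

    ``protein`` / ``substrate`` are (res_name, res_num, atom_name) triples;
    for ``kind="stack"`` the atom name is ignored and a planar ring with the
    residue's standard ring atom names is planted instead.
    """

    kind: str  # vdw | hbond | stack
    protein: tuple
    substrate: tuple
    distance: float | None = None  # pair distance (vdw/hbond) or ring separation


def _ring_coords(names, center, z):
    coords = []
    for i in range(len(names)):
        ang = 2 * np.pi * i / len(names)
        coords.append(center + np.array([1.35 * np.cos(ang), 1.35 * np.sin(ang), z]))
    return coords


def _build_planted(planted, tolerance=0.6):
    radii = VdwRadiusTable.bondi()
    atoms: dict[tuple, np.ndarray] = {}  # (chain, res_num, name, res_name) -> coord
    contact_atoms: list[list[tuple]] = []

    def place(chain, res_name, res_num, name, pos):
        key = (chain, res_num, name)
        if key in atoms and not np.allclose(atoms[key][0], pos):
            raise ConstructionError(
                f"atom {key} required at two different positions — inconsistent plants"
            )
        atoms[key] = (np.asarray(pos, dtype=float), res_name)
        return key

    for i, pc in enumerate(planted):
        origin = np.array([25.0 * i, 0.0, 0.0])
        moved = []
        p_res, p_num, p_atom = pc.protein
        s_res, s_num, s_atom = pc.substrate
        if pc.kind == "vdw":
            ra = radii[_infer_element(p_atom)]
            rb = radii[_infer_element(s_atom)]
            d = pc.distance if pc.distance is not None else ra + rb + tolerance - 0.2
            if d > ra + rb + tolerance:
                raise ConstructionError(
                    f"planted vdw distance {d:.2f} exceeds threshold {ra + rb + tolerance:.2f}"
                )
            place("A", p_res, p_num, p_atom, origin)
            moved.append(place("B", s_res, s_num, s_atom, origin + [d, 0.0, 0.0]))
        elif pc.kind == "hbond":
            d = pc.distance if pc.distance is not None else 2.9
            if d > 3.5:
                raise ConstructionError(f"planted hbond distance {d:.2f} exceeds 3.5")
            h_name = "H" + (p_atom[1:] if len(p_atom) > 1 else "") + "1"
            place("A", p_res, p_num, p_atom, origin)
            place("A", p_res, p_num, h_name, origin + [1.0, 0.0, 0.0])
            moved.append(place("B", s_res, s_num, s_atom, origin + [d, 0.0, 0.0]))
        elif pc.kind == "stack":
            sep = pc.distance if pc.distance is not None else 3.5
            if sep > 4.5:
                raise ConstructionError(f"planted stack separation {sep:.2f} exceeds 4.5")
            names_p = _RING_NAMES[p_res]
            names_s = _RING_NAMES[s_res]
            for name, pos in zip(names_p, _ring_coords(names_p, origin, 0.0)):
                place("A", p_res, p_num, name, pos)
            for name, pos in zip(names_s, _ring_coords(names_s, origin, sep)):
                moved.append(place("B", s_res, s_num, name, pos))
        else:
            raise ConstructionError(f"unknown planted kind {pc.kind!r}")
        contact_atoms.append(moved)

    # decoy anchors keep both groups non-empty and far from everything
    place("A", "GLY", 201, "CA", np.array([-40.0, -40.0, 0.0]))
    place("B", "DT", 90, "C1'", np.array([-40.0, 40.0, 0.0]))

    atom_list = []
    for serial, ((chain, res_num, name), (pos, res_name)) in enumerate(
        sorted(atoms.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])), start=1
    ):
        atom_list.append(
            Atom(serial=serial, name=name, element=_infer_element(name),
                 res_name=res_name, res_num=res_num, chain=chain, coord=tuple(pos))
        )
    structure = Structure(atoms=atom_list, title="synthetic planted-interaction frame")
    index_of = {a.key: i for i, a in enumerate(structure.atoms)}
    contact_idx = [[index_of[k] for k in moved] for moved in contact_atoms]
    return structure, contact_idx


def make_interaction_frame(planted: list, tolerance: float = 0.6) -> Structure:
    """A structure in which exactly the planted interactions hold.

    Each contact occupies its own 25-Angstrom lattice cell, so all non-planted
    pairs are far beyond the default criteria.
    """
    structure, _ = _build_planted(planted, tolerance)
    return structure


def make_interaction_trajectory(
    planted: list, presence: np.ndarray, tolerance: float = 0.6
) -> Trajectory:
    """Trajectory toggling planted contacts per frame.

    ``presence[i, f]`` says whether contact i holds in frame f; in absent
    frames the substrate-side atoms of that contact are displaced 12 Angstrom
    away, breaking the interaction without touching any other cell.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.shape[0] != len(planted):
        raise ConstructionError("presence needs one row per planted contact")
    structure, contact_idx = _build_planted(planted, tolerance)
    base = structure.coords
    frames = []
    for f in range(presence.shape[1]):
        coords = base.copy()
        for i, idx in enumerate(contact_idx):
            if not presence[i, f]:
                coords[idx] += np.array([0.0, 12.0, 0.0])
        frames.append(coords)
    return Trajectory(topology=structure, frames=frames)


def make_stack_pattern_trajectory(patterns: list):
    """Trajectory realizing a triple-stack pattern per frame.

    ``patterns`` holds one of "WYG" (W84:Y114:G stacked), "AYG" (A:Y114:G
    stacked) or "none" per frame.  The Y114:G core stays stacked throughout;
    the third ring (W84 indole or A purine) is either coaxial above Y114 or
    parked 15 Angstrom away.  Returns (Trajectory, ring spec dict) matching
    :func:`deamscan.interact.default_rings`.
    """
    from .interact import default_rings

    rings = default_rings(chain_protein="A", chain_dna="B", w84=84, y114=114, g_res=2, a_res=1)
    layout = {
        "G": ("DG", 2, "B", np.array([0.0, 0.0, 0.0])),
        "Y114": ("TYR", 114, "A", np.array([0.0, 0.0, 3.5])),
        "W84": ("TRP", 84, "A", np.array([0.0, 0.0, 7.0])),
        "A": ("DA", 1, "B", np.array([15.0, 0.0, 7.0])),
    }
    atoms, slices = [], {}
    for key, (res_name, res_num, chain, center) in layout.items():
        names = _RING_NAMES[res_name]
        start = len(atoms)
        for name, pos in zip(names, _ring_coords(names, center, 0.0)):
            atoms.append(
                Atom(serial=len(atoms) + 1, name=name, element=_infer_element(name),
                     res_name=res_name, res_num=res_num, chain=chain, coord=tuple(pos))
            )
        slices[key] = slice(start, len(atoms))
    topo = Structure(atoms=atoms, title="synthetic triple-stack trajectory")
    base = topo.coords
    away = np.array([15.0, 0.0, 0.0])
    frames = []
    for pat in patterns:
        coords = base.copy()
        # W84 starts stacked, A starts away (base layout)
        if pat == "AYG":
            coords[slices["W84"], 0] += 15.0
            coords[slices["W84"], 2] += 5.0
            coords[slices["A"]] -= away
        elif pat == "none":
            coords[slices["W84"], 0] += 15.0
        elif pat != "WYG":
            raise ValueError(f"unknown stack pattern {pat!r}")
        frames.append(coords)
    return Trajectory(topology=topo, frames=frames), rings


# --------------------------------------------------------------------------
# Clustered trajectories
# --------------------------------------------------------------------------


def make_clustered_trajectory(
    k: int,
    frames_per_cluster=8,
    spread: float = 5.0,
    noise: float = 0.5,
    seed: int = 0,
    n_atoms: int = 20,
):
    """Trajectory with k planted conformations -> (Trajectory, true labels).

    Cluster centers differ by independent per-atom displacement fields with
    pairwise RMSD approximately ``spread``; members add Gaussian noise with
    per-atom RMS ``noise``.  Frames are shuffled (seeded) so cluster recovery
    cannot rely on frame order.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 planted clusters, got {k}")
    rng = np.random.default_rng(seed)
    sizes = (
        [int(frames_per_cluster)] * k
        if np.isscalar(frames_per_cluster)
        else list(frames_per_cluster)
    )
    if len(sizes) != k or any(s < 1 for s in sizes):
        raise ValueError("frames_per_cluster must give >= 1 frame for each cluster")
    base = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    centers = [
        base + rng.normal(0.0, spread / np.sqrt(6.0), size=(n_atoms, 3)) for _ in range(k)
    ]
    frames, labels = [], []
    for cid, (center, size) in enumerate(zip(centers, sizes), start=1):
        for _ in range(size):
            frames.append(center + rng.normal(0.0, noise / np.sqrt(3.0), size=(n_atoms, 3)))
            labels.append(cid)
    order = rng.permutation(len(frames))
    frames = [frames[i] for i in order]
    labels = np.array(labels)[order]
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", res_name="GLY", res_num=i + 1,
             chain="A", coord=tuple(base[i]))
        for i in range(n_atoms)
    ]
    topo = Structure(atoms=atoms, title=f"synthetic {k}-cluster trajectory (seed={seed})")
    return Trajectory(topology=topo, frames=frames), labels


# --------------------------------------------------------------------------
# Clone sets
# --------------------------------------------------------------------------


def make_clone_set(
    design: NncnDesign,
    per_motif_p,
    n_clones: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict:
    """Synthetic Sanger clones per oligo -> {oligo id: [clone sequences]}.

    Per clone, every non-flank C flips to T with its motif's probability
    (``per_motif_p``: scalar or {motif: p}); then every position is
    independently substituted uniformly (to one of the other three bases) with
    rate ``error_rate``.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    p_of = (lambda m: float(per_motif_p)) if np.isscalar(per_motif_p) else (
        lambda m: float(per_motif_p.get(m, 0.0))
    )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    clones = {}
    for oid, ref in design.oligos.items():
        sites = design.c_sites[oid]
        out = []
        for _ in range(n_clones):
            seq = np.array(list(ref))
            for pos, context in sites:
                if rng.random() < p_of(context):
                    seq[pos - 1] = "T"
            if error_rate > 0:
                hit = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                for i in hit:
                    choices = bases[bases != seq[i]]
                    seq[i] = choices[rng.integers(len(choices))]
            out.append("".join(seq))
        clones[oid] = out
    return clones


# --------------------------------------------------------------------------
# Gel lanes
# --------------------------------------------------------------------------


def make_gel_lanes(
    efficiencies: dict,
    n_molecules: int = 100_000,
    noise_sigma: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    substrate_length: int = 80,
) -> dict:
    """Replicate gel lanes -> {(variant, substrate): [GelLane, ...]}.

    ``efficiencies`` maps (variant, substrate) to the planted per-reaction
    deamination probability.  Each replicate runs the protocol-matched assay
    (UDG for C, TDG for 5mC, hSMUG1 for 5hmC) and applies multiplicative
    log-normal noise (sigma ``noise_sigma``) to both band intensities.
    """
    rng = np.random.default_rng(seed)
    lanes = {}
    for (variant, substrate), eff in sorted(efficiencies.items()):
        oligo = make_central_substrate(substrate, length=substrate_length, seed=0)
        glyco = GLYCOSYLASES[PROTOCOL_GLYCOSYLASE[substrate]]
        enzyme = EnzymeProfile(variant=variant, efficiency={substrate: float(eff)})
        reps = []
        for r in range(n_replicates):
            res = simulate_assay(
                oligo, enzyme, glyco, n_molecules, seed=int(rng.integers(2**31 - 1))
            )
            bands = []
            for length, count in sorted(res.fragments.items()):
                intensity = count * float(rng.lognormal(0.0, noise_sigma)) if noise_sigma > 0 else float(count)
                bands.append((length, intensity))
            reps.append(GelLane(bands=bands, label=f"{variant}:{substrate} rep{r + 1}"))
        lanes[(variant, substrate)] = reps
    return lanes
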