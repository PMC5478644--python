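"""NNCN hot-spot oligo design, clone alignment and per-motif deamination calls.

The deaminase's sequence-context preference is profiled on four 104-nt ssDNA
oligos that together tile all 64 NNCN 4-mers (N in {A, C, G, T}, target C
third): each oligo is a 20-nt C-free 5' primer flank, 16 contiguous 4-mer
motifs (64 nt) and a 20-nt C-free 3' flank.  Treated oligos are PCR-amplified,
cloned and Sanger-sequenced; every clone is globally aligned to its reference
and C->T transitions are called per reference C position outside the flanks.
Because a motif's N slots may themselves be C, every C position is indexed and
counted in its actual 4-mer context (intended and incidental sites alike).

Positions within one alignment column of an insertion/deletion are classified
``indel_adjacent`` and excluded from frequency numerators and denominators
(indels are attributed to the polymerase, not the deaminase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import DesignError, InputError

__all__ = [
    "ALL_NNCN_MOTIFS",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
    "NncnDesign",
    "design_nncn_oligos",
    "CloneAlignment",
    "align_clone",
    "TransitionEvent",
    "call_transitions",
    "MotifFrequencyTable",
    "motif_frequency_table",
]

#: all 64 NNCN 4-mers, lexicographic
ALL_NNCN_MOTIFS = tuple(f"{a}{b}C{d}" for a, b, d in product("ACGT", repeat=3))

FLANK_LEN = 20
MOTIFS_PER_OLIGO = 16
OLIGO_LEN = 2 * FLANK_LEN + 4 * MOTIFS_PER_OLIGO  # 104

#: default C-free primer-site flanks (fixed arbitrary sequences)
DEFAULT_FLANK5 = "GTGGATAGTTAGGTTGAGTA"
DEFAULT_FLANK3 = "ATGAGTTGGATGTTAGGTGG"


def _check_flank(flank: str, which: str) -> str:
    flank = flank.upper()
    if len(flank) != FLANK_LEN:
        raise DesignError(f"{which} flank must be {FLANK_LEN} nt, got {len(flank)}")
    if set(flank) - set("AGT"):
        bad = sorted(set(flank) - set("AGT"))
        raise DesignError(
            f"{which} flank contains {bad} — flanks must be C-free (and ACGT only) "
            "so primer sites never contribute deamination calls"
        )
    return flank


@dataclass(frozen=True)
class NncnDesign:
    """Four 104-nt oligos that jointly cover all 64 NNCN motifs."""

    oligos: dict  # oligo id -> sequence
    flank5: str
    flank3: str
    motif_assignment: dict  # oligo id -> tuple of 16 motifs
    c_sites: dict = field(default_factory=dict)  # oligo id -> ((pos, context), ...)

    def __post_init__(self):
        motifs = [m for ms in self.motif_assignment.values() for m in ms]
        if sorted(motifs) != sorted(ALL_NNCN_MOTIFS):
            raise DesignError("motif lists must be disjoint and cover all 64 NNCN 4-mers")
        for oid, seq in self.oligos.items():
            expected = self.flank5 + "".join(self.motif_assignment[oid]) + self.flank3
            if seq != expected or len(seq) != OLIGO_LEN:
                raise DesignError(f"oligo {oid} is not flank5 + 16 motifs + flank3")

    def reference(self, oligo_id: str) -> str:
        return self.oligos[oligo_id]


def _index_c_sites(seq: str) -> tuple:
    """All C positions (1-based) outside the flanks, with their 4-mer context.

    The context is the reference 4-mer with that C third (two bases upstream,
    one downstream) — the position's actual NNCN context, intended or
    incidental.
    """
    sites = []
    for pos in range(FLANK_LEN + 1, len(seq) - FLANK_LEN + 1):
        if seq[pos - 1] == "C":
            context = seq[pos - 3 : pos + 1]
            sites.append((pos, context))
    return tuple(sites)


def design_nncn_oligos(
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    seed: int = 0,
) -> NncnDesign:
    """Partition the 64 NNCN motifs into four 16-motif oligos (seeded).

    Motifs are tiled contiguously between the two 20-nt C-free flanks: 104 nt
    = 20 + 16 x 4 + 20.  Deterministic for a fixed seed.
    """
    flank5 = _check_flank(flank5, "5'")
    flank3 = _check_flank(flank3, "3'")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ALL_NNCN_MOTIFS))
    oligos, assignment, c_sites = {}, {}, {}
    for i in range(4):
        oid = f"NNCN_{i + 1}"
        motifs = tuple(ALL_NNCN_MOTIFS[j] for j in order[i * 16 : (i + 1) * 16])
        seq = flank5 + "".join(motifs) + flank3
        oligos[oid] = seq
        assignment[oid] = motifs
        c_sites[oid] = _index_c_sites(seq)
    return NncnDesign(
        oligos=oligos, flank5=flank5, flank3=flank3,
        motif_assignment=assignment, c_sites=c_sites,
    )


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass
class CloneAlignment:
    """A global reference/clone alignment with per-column classification."""

    ref_row: str
    clone_row: str
    score: int
    columns: list = field(init=False)  # "identical" | "substitution" | "indel"

    def __post_init__(self):
        if len(self.ref_row) != len(self.clone_row):
            raise ValueError("alignment rows must have equal length")
        cols = []
        for r, c in zip(self.ref_row, self.clone_row):
            if r == "-" or c == "-":
                cols.append("indel")
            elif r == c:
                cols.append("identical")
            else:
                cols.append("substitution")
        self.columns = cols

    @property
    def reference(self) -> str:
        return self.ref_row.replace("-", "")

    def ref_position_columns(self) -> dict:
        """1-based ungapped reference position -> alignment column index."""
        out, pos = {}, 0
        for col, r in enumerate(self.ref_row):
            if r != "-":
                pos += 1
                out[pos] = col
        return out


def align_clone(reference: str, clone: str) -> CloneAlignment:
    """Global Needleman-Wunsch alignment (match +1, mismatch -1, gap -2).

    The traceback tie-break is deterministic: diagonal over up (gap in the
    clone) over left (gap in the reference).
    """
    ref, cl = reference.upper(), clone.upper()
    if not ref or not cl:
        raise ValueError("both sequences must be non-empty")
    n, m = len(ref), len(cl)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = GAP * np.arange(m + 1)
    H[:, 0] = GAP * np.arange(n + 1)
    for i in range(1, n + 1):
        ri = ref[i - 1]
        prev, cur = H[i - 1], H[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (MATCH if ri == cl[j - 1] else MISMATCH)
            up = prev[j] + GAP
            left = cur[j - 1] + GAP
            cur[j] = max(diag, up, left)
    # traceback, tie-break diagonal > up > left
    i, j = n, m
    out_r, out_c = [], []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            MATCH if ref[i - 1] == cl[j - 1] else MISMATCH
        ):
            out_r.append(ref[i - 1])
            out_c.append(cl[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + GAP:
            out_r.append(ref[i - 1])
            out_c.append("-")
            i -= 1
        else:
            out_r.append("-")
            out_c.append(cl[j - 1])
            j -= 1
    return CloneAlignment(
        ref_row="".join(reversed(out_r)),
        clone_row="".join(reversed(out_c)),
        score=int(H[n, m]),
    )


# --------------------------------------------------------------------------
# Transition calling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionEvent:
    ref_pos: int  # 1-based reference coordinate
    context: str  # reference 4-mer, C third
    event: str  # unmutated | C→T | other_substitution | indel_adjacent


def call_transitions(
    aln: CloneAlignment, design: NncnDesign, oligo_id: str
) -> list[TransitionEvent]:
    """One event per reference C position outside the 20-nt flanks.

    Positions within one alignment column of an indel column are classified
    ``indel_adjacent`` (and excluded from frequencies downstream).  Flank
    positions are never reported.
    """
    reference = design.reference(oligo_id)
    if aln.reference != reference:
        raise InputError(f"alignment reference does not match design oligo {oligo_id!r}")
    pos_to_col = aln.ref_position_columns()
    indel_cols = {c for c, kind in enumerate(aln.columns) if kind == "indel"}
    events = []
    for pos, context in design.c_sites[oligo_id]:
        col = pos_to_col[pos]
        if indel_cols & {col - 1, col, col + 1}:
            event = "indel_adjacent"
        else:
            clone_base = aln.clone_row[col]
            if clone_base == "C":
                event = "unmutated"
            elif clone_base == "T":
                event = "C→T"
            else:
                event = "other_substitution"
        events.append(TransitionEvent(ref_pos=pos, context=context, event=event))
    return events


# --------------------------------------------------------------------------
# Per-motif frequency table
# --------------------------------------------------------------------------


@dataclass
class MotifFrequencyTable:
    """Per-NNCN deamination frequencies aggregated over clones and oligos."""

    table: pd.DataFrame  # indexed by motif
    n_clones: int
    no_detectable_activity: bool


def motif_frequency_table(
    events_by_clone: list,
    design: NncnDesign,
    min_clones_for_flag: int = 20,
) -> MotifFrequencyTable:
    """Aggregate per-clone transition events into per-motif frequencies.

    ``events_by_clone`` is a list of per-clone event lists (any oligo mix).
    frequency = n_transitions / n_eligible, where eligible events exclude the
    indel-adjacent ones.  Motifs with no eligible site anywhere are flagged
    absent rather than given frequency 0.  The ``no_detectable_activity``
    summary flag is set when no C->T transition was called across at least
    ``min_clones_for_flag`` clones.
    """
    if not events_by_clone:
        raise ValueError("need events for at least one clone")
    site_counts: dict[str, int] = {}
    for sites in design.c_sites.values():
        for _pos, context in sites:
            site_counts[context] = site_counts.get(context, 0) + 1
    rows = {
        m: {"n_c_sites": site_counts.get(m, 0), "n_eligible": 0, "n_transitions": 0}
        for m in ALL_NNCN_MOTIFS
    }
    for events in events_by_clone:
        for ev in events:
            row = rows.setdefault(
                ev.context, {"n_c_sites": 0, "n_eligible": 0, "n_transitions": 0}
            )
            if ev.event == "indel_adjacent":
                continue
            row["n_eligible"] += 1
            if ev.event == "C→T":
                row["n_transitions"] += 1
    n_clones = len(events_by_clone)
    records = []
    for motif in sorted(rows):
        r = rows[motif]
        present = r["n_c_sites"] > 0 or r["n_eligible"] > 0
        freq = (r["n_transitions"] / r["n_eligible"]) if r["n_eligible"] else np.nan
        records.append(
            {
                "motif": motif,
                "n_c_sites": r["n_c_sites"],
                "n_clones": n_clones,
                "n_eligible": r["n_eligible"],
                "n_transitions": r["n_transitions"],
                "frequency": freq,
                "present": present,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("motif")
    total_transitions = int(table["n_transitions"].sum())
    flag = total_transitions == 0 and n_clones >= min_clones_for_flag
    return MotifFrequencyTable(table=table, n_clones=n_clones, no_detectable_activity=flag)
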