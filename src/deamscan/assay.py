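"""In-silico glycosylase-coupled deamination assays and gel quantification.

The wet assay has three stages: (1) the deaminase converts the single special
base of a 5'-radiolabeled ssDNA oligo (C->U, 5mC->T, 5hmC->5hmU); (2) a
glycosylase excises the deamination product, leaving an abasic site (UDG
excises U; hSMUG1 excises U and 5hmU; TDG excises the T of the G:T mismatch
formed by annealing a complementary strand — duplex required); (3) hot alkali
cleaves the strand at the abasic site.  Only 5'-labeled fragments are visible
on the gel, so deamination of the central base of an 80-mer (position 41)
yields a 40-nt product band.

Deamination is modeled as a single per-molecule Bernoulli event with the
enzyme's per-reaction efficiency for that base; glycosylase excision and
alkaline cleavage are deterministic and complete (the wet protocol's controls
treat them as saturating steps).  Control oligos carrying U, T or 5hmU at the
special position bypass deamination and are cleaved directly.

Band quantification and the relative-activity statistic mirror the gel
densitometry: product fraction = I_product / (I_product + I_substrate),
activity of a variant = 100 x mean(variant fractions) / mean(wt fractions),
with the standard deviation propagated from the replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedCorrelationError, UndefinedLaneError

__all__ = [
    "SubstrateOligo",
    "EnzymeProfile",
    "GlycosylaseSpec",
    "GelLane",
    "AssayResult",
    "DEAMINATION_PRODUCT",
    "GLYCOSYLASES",
    "ENZYME_PRESETS",
    "DETECTION_LIMIT",
    "simulate_assay",
    "quantify_lane",
    "relative_activity",
    "RelativeActivity",
    "activity_correlation",
    "make_central_substrate",
]

#: chemistry of deamination at the special position
DEAMINATION_PRODUCT = {"C": "U", "5mC": "T", "5hmC": "5hmU"}

#: control base kinds that bypass deamination (deamination products themselves)
CONTROL_KINDS = {"U", "T", "5hmU"}

#: limit-of-detection product fraction used only for labeling outputs
DETECTION_LIMIT = 0.01


@dataclass(frozen=True)
class SubstrateOligo:
    """A 5'->3' ssDNA oligo with one annotated special position (1-based)."""

    sequence: str
    special_pos: int
    base_kind: str  # C | 5mC | 5hmC | U | T | 5hmU
    labeled_5prime: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGT"):
            raise ValueError("sequence must be over {A, C, G, T}")
        if not 1 <= self.special_pos <= len(seq):
            raise ValueError("special position outside the sequence")
        if self.base_kind not in set(DEAMINATION_PRODUCT) | CONTROL_KINDS:
            raise ValueError(f"unknown base kind {self.base_kind!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fragment_lengths(self) -> tuple[int, int]:
        """5' and 3' fragment lengths after cleavage at the special position.

        The 3' fragment keeps the abasic sugar position, so lengths sum to the
        substrate length.
        """
        return self.special_pos - 1, self.length - self.special_pos + 1


def make_central_substrate(
    base_kind: str, length: int = 80, motif: str = "AGCT", seed: int = 0
) -> SubstrateOligo:
    """Assay substrate: ``length``-nt oligo, single C analog at the center.

    The special base sits at position length/2 + 1 inside the given 4-mer
    motif (AGCT by default); every other position is drawn from {A, G, T} so
    the oligo contains exactly one C-type residue.
    """
    if length % 2 != 0 or length < 8:
        raise ValueError("length must be even and >= 8")
    pos = length // 2 + 1  # 1-based; the printed 40-nt product fixes this
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("AGT"), size=length))
    seq[pos - 3 : pos + 1] = list(motif)
    return SubstrateOligo(sequence="".join(seq), special_pos=pos, base_kind=base_kind)


@dataclass(frozen=True)
class EnzymeProfile:
    """A deaminase variant and its per-reaction deamination probabilities."""

    variant: str
    efficiency: dict  # base_kind -> probability in [0, 1]

    def __post_init__(self):
        for kind, p in self.efficiency.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"efficiency for {kind} outside [0, 1]: {p}")


def _preset(variant: str, c: float, mc: float) -> EnzymeProfile:
    return EnzymeProfile(variant=variant, efficiency={"C": c, "5mC": mc, "5hmC": 0.0})


#: Fixture efficiency presets (NOT measurements): wt C efficiency is an
#: arbitrary 0.50 baseline (5mC baseline 0.20) and variants are scaled by the
#: published relative-activity ratios; 5hmC efficiency is 0 for every preset
#: (no variant shows detectable activity on 5hmC).
ENZYME_PRESETS = {
    "wt": _preset("wt", 0.50, 0.20),
    "R50A": _preset("R50A", 0.10, 0.12),
    "N51A": _preset("N51A", 0.00, 0.156),
    "R190X": _preset("R190X", 0.70, 0.11),
}
for _p in ENZYME_PRESETS.values():
    assert _p.efficiency["5hmC"] == 0.0


@dataclass(frozen=True)
class GlycosylaseSpec:
    """A glycosylase: which base kinds it excises, and whether it needs dsDNA."""

    name: str
    excises: frozenset
    requires_duplex: bool = False

    def __post_init__(self):
        if not self.excises:
            raise ValueError("a glycosylase must excise at least one base kind")
        if self.requires_duplex != (self.name == "TDG"):
            raise ValueError("requires_duplex is a TDG-only property")


GLYCOSYLASES = {
    "UDG": GlycosylaseSpec("UDG", frozenset({"U"})),
    "SMUG1": GlycosylaseSpec("SMUG1", frozenset({"U", "5hmU"})),
    "TDG": GlycosylaseSpec("TDG", frozenset({"T"}), requires_duplex=True),
}

#: glycosylase used for each substrate in the published protocols
PROTOCOL_GLYCOSYLASE = {"C": "UDG", "5mC": "TDG", "5hmC": "SMUG1",
                        "U": "UDG", "T": "TDG", "5hmU": "SMUG1"}


@dataclass
class GelLane:
    """Bands of one denaturing-PAGE lane: (fragment length nt, intensity)."""

    bands: list  # [(length, intensity), ...]
    label: str = ""

    def __post_init__(self):
        for length, intensity in self.bands:
            if length < 1:
                raise ValueError("band fragment lengths must be >= 1")
            if intensity < 0:
                raise ValueError("band intensities must be >= 0")

    def intensity_at(self, length: int) -> float:
        return float(sum(i for l, i in self.bands if l == length))


@dataclass
class AssayResult:
    product_fraction: float
    fragments: dict  # labeled fragment length -> molecule count
    n_molecules: int
    detectable: bool = field(init=False)

    def __post_init__(self):
        self.detectable = self.product_fraction >= DETECTION_LIMIT


def simulate_assay(
    oligo: SubstrateOligo,
    enzyme: EnzymeProfile,
    glyco: GlycosylaseSpec,
    n_molecules: int,
    seed: int = 0,
    anneal: bool = True,
) -> AssayResult:
    """Simulate the three-stage assay on a population of molecules.

    Per molecule: Bernoulli(efficiency) deamination converts the special base
    (C->U, 5mC->T, 5hmC->5hmU); the glycosylase excises eligible bases
    (TDG only after annealing), creating an abasic site; alkaline cleavage
    splits the strand there.  The fragment histogram covers 5'-labeled
    fragments only.  Control oligos (U/T/5hmU) bypass deamination.
    """
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    rng = np.random.default_rng(seed)
    kind = oligo.base_kind
    if kind in CONTROL_KINDS:
        n_converted = n_molecules  # already the deamination product
        converted_base = kind
    else:
        p = float(enzyme.efficiency.get(kind, 0.0))
        n_converted = int(rng.binomial(n_molecules, p))
        converted_base = DEAMINATION_PRODUCT[kind]
    excisable = converted_base in glyco.excises and (not glyco.requires_duplex or anneal)
    n_cleaved = n_converted if excisable else 0
    product_len, _ = oligo.fragment_lengths()
    fragments = {}
    if n_cleaved:
        fragments[product_len] = n_cleaved
    if n_molecules - n_cleaved:
        fragments[oligo.length] = n_molecules - n_cleaved
    return AssayResult(
        product_fraction=n_cleaved / n_molecules,
        fragments=fragments,
        n_molecules=n_molecules,
    )


def quantify_lane(lane: GelLane, product_length: int, substrate_length: int) -> float:
    """Product fraction I_product / (I_product + I_substrate) from a lane."""
    ip = lane.intensity_at(product_length)
    is_ = lane.intensity_at(substrate_length)
    if ip == 0 and is_ == 0:
        raise UndefinedLaneError(
            f"lane {lane.label!r}: no intensity at {product_length} nt or {substrate_length} nt"
        )
    return ip / (ip + is_)


@dataclass(frozen=True)
class RelativeActivity:
    percent_of_wt: float
    sd: float


def relative_activity(variant_fractions, wt_fractions) -> RelativeActivity:
    """Variant activity as a percent of wild type (wt = 100%).

    percent = 100 x mean(variant) / mean(wt); the standard deviation is
    propagated (first order) from the replicate means of both series.
    """
    v = np.asarray(variant_fractions, dtype=float)
    w = np.asarray(wt_fractions, dtype=float)
    if v.size < 1 or w.size < 1:
        raise ValueError("need at least one replicate per series")
    wmean = w.mean()
    if wmean == 0:
        raise ZeroDivisionError("wt mean activity is zero; relative activity undefined")
    vmean = v.mean()
    percent = 100.0 * vmean / wmean
    sem_v2 = v.var(ddof=1) / v.size if v.size > 1 else 0.0
    sem_w2 = w.var(ddof=1) / w.size if w.size > 1 else 0.0
    sd = 100.0 * np.sqrt(sem_v2 / wmean**2 + (vmean**2 / wmean**4) * sem_w2)
    return RelativeActivity(percent_of_wt=float(percent), sd=float(sd))


def activity_correlation(values_c, values_5mc) -> float:
    """Pearson product-moment correlation between two activity profiles."""
    x = np.asarray(values_c, dtype=float)
    y = np.asarray(values_5mc, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with >= 3 points")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float((xd * yd).sum() / (sx * sy))
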