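# Methods

This note documents the models, conventions and numerical choices behind
deamscan, and what its synthetic-data tests do and do not establish.

## Structures and trajectories

Coordinates are in Å; residue numbering is 1-based; nucleotide atom names use
the PDB prime convention. Trajectories are exchanged as multi-model PDB text
files (MODEL 1 is the topology; every model must repeat the same atoms in the
same order, enforced with an error naming the offending model). The reader
keeps the highest-occupancy altloc (first on ties), keeps hydrogens (needed
for H-bond angles), and rejects insertion codes. No frame striding is imposed
at read time; analyses that want a stride subsample the frame list.

## Pocket geometry and ring breadths

The pocket is characterized by four atom-pair distances (d1–d4, see README);
d2 (residue 51 ↔ P86 CB) is the gate that limits the breadth of a
heterocyclic ring entering the pocket. Distances are reported per frame with
mean/min/max; all statistics are plain Euclidean distances, so they are
invariant to rigid motion and additive over trajectory concatenation.

Substrate breadths use idealized base geometries shipped as a JSON data file:
ring and exocyclic heavy atoms follow the standard reference-frame pyrimidine
coordinates (internally consistent with standard bond lengths, e.g. N1–C2
1.397 Å, C2–O2 1.240 Å); hydrogens sit at 1.08/1.01 Å along external
bisectors; the C5 substituent carbon sits 1.496 Å from C5; the hydroxymethyl
oxygen at 1.43 Å with a 110.5° bond angle, its dihedral scanned every 10°.

**Breadth convention.** The breadth is the widest van-der-Waals-inclusive
span across the ring, measured in the ring plane: atoms are projected onto
the best-fit ring plane and the maximum of (center distance + both Bondi
radii) is taken over the breadth atom set. That set contains the heavy atoms
of the base plus its C5 substituent — H5 itself for cytosine, the heavy atoms
of the methyl/hydroxymethyl groups (whose own hydrogens rotate and are
represented by the carbon/oxygen envelope) — and excludes the glycosidic C1′,
which defines the depth axis rather than the breadth. An alternative
projection convention (extent along the in-plane axis perpendicular to
C1′→C4) and an all-hydrogens variant are available as options; the caliper
with the substituent rule is the headline because it is the only convention
consistent with the printed 7.8/8.8 Å pair (the projection variant gives
7.1/8.0 Å). For 5hmC the breadth is a [min, max] interval over the dihedral
grid (9.04–9.20 Å): the ring is treated as not flat.

Hydration of the 5hmC hydroxyl is encoded only as two documented constants —
a single bound water adds 2.8–3.2 Å of steric bulk — used by the fit
assessment (`fits_at_min ⇔ breadth ≤ min(d2)`); no solvation energetics are
computed.

## Interaction detection

Geometric criteria (all configurable, echoed into outputs): vdW contact at
d ≤ r_i + r_j + 0.6 Å between heavy atoms; H-bond at donor–acceptor ≤ 3.5 Å
with D–H⋯A ≥ 120° when explicit hydrogens are attached (≤ 1.25 Å, same
residue), distance-only otherwise; stacking at centroid distance ≤ 4.5 Å,
interplanar angle ≤ 30° (best-fit plane normals, folded to [0°, 90°]) and
lateral offset ≤ 2.0 Å. These are community-standard MD-analysis defaults —
no cutoff set is canonical for this kind of contact fingerprinting — so all
planted-fixture tests are built to satisfy the defaults with ≥ 1.5 Å margin
rather than to sit near a cutoff. H-bonds take precedence over vdW for the same atom
pair within a frame, keeping the two counts disjoint. An interaction "exists"
at trajectory level at occupancy ≥ 0.5; a triple stack is "stable" at ≥ 0.7
(both thresholds configurable). Methyl-group contacts collapse onto a single
`5mC-methyl` partner key so network diffs read at the chemical-group level.

## Conformational clustering

Average-linkage hierarchical clustering on pairwise superposed RMSDs (CA
atoms by default). The Kelley penalty selects the cluster count: the average
within-cluster spread (mean pairwise RMSD over clusters with ≥ 2 members) is
min–max rescaled onto [1, n−1] across all hierarchy levels — including the
single-cluster level, whose full-data spread anchors the top of the scale —
and the cluster count is added; the minimizing k (ties toward smaller k) over
k = 2..n−1 wins. When the spread range across levels is below 1 mÅ the data
carry no cluster structure, the curve is treated as flat, and k = 2 is
returned deterministically. Cluster averages are coordinate-wise means after
superposing every member onto the cluster's first frame; no geometry
idealization follows. Comparison to a reference structure uses least-squares
superposition (scipy Kabsch) with atoms matched by (residue number, atom
name) through an optional residue-offset map, and segment RMSDs are measured
after the global fit. Loop-segment boundaries are configuration, not
constants, since loop definitions vary between numbering schemes.

## Assay model

Deamination is a single per-molecule Bernoulli event with the enzyme's
per-reaction efficiency for the substrate's special base; there is no
kinetics or time course because the assay is quantified at the end point.
Glycosylase excision and alkaline cleavage are deterministic and complete
(the wet protocol treats them as saturating control steps, confirmed by its
U/T/5hmU controls, which here bypass deamination and cleave directly). The
TDG branch requires the annealing step; on an unannealed population it yields
zero product. Cleavage at special position p of an L-mer yields a labeled
5′ fragment of p−1 nt and an unlabeled 3′ fragment of L−p+1 nt (the abasic
sugar stays with the 3′ piece, so lengths conserve L); the "central position"
of an 80-mer is position 41, forced by the 40-nt product length. Synthetic
lanes apply multiplicative log-normal noise (σ = 0.05 by default) to band
intensities, in 3 replicates per condition.

Enzyme presets are fixture values, not measurements: wt efficiency is set to
an arbitrary 0.50 baseline on C (0.20 on 5mC, reflecting the reported
several-fold lower turnover on methylated substrate) and variants are scaled
by the published activity ratios (R190X 1.4× on C, 0.55× on 5mC; R50A 0.2×
and 0.6×; N51A 0 and 0.78×); every preset has zero efficiency on 5hmC. A
limit-of-detection product fraction of 0.01 labels outputs as
detectable/undetectable and plays no other role.

## NNCN profiling

The four 104-nt oligos are regenerated from their arithmetic constraints
(20 + 16×4 + 20) with a seeded partition of the 64 motifs; tiling motifs
contiguously is the only arrangement consistent with the length. Flanks must
be C-free so primer-binding sites can never contribute deamination calls;
the shipped defaults are fixed arbitrary A/G/T 20-mers. Because an N slot may
itself be C, every non-flank C is indexed in its actual 4-mer context —
intended and incidental sites alike — and the frequency table reports
per-site counts so multiply-occurring motifs stay auditable. Alignment is
global Needleman–Wunsch with match +1, mismatch −1, linear gap −2 and a
deterministic traceback (diagonal over reference-gap over clone-gap).
Positions within one alignment column of an indel are excluded from both
numerator and denominator (indels are attributed to the amplifying
polymerase). The `no_detectable_activity` flag is strict — zero C→T calls
across ≥ 20 clones — so with a nonzero sequencing-error rate the expected
ε/3 background should be compared against the per-motif frequencies instead;
the analysis driver prints that comparison. G→A calls on the opposite strand
are out of scope: the assay sequences the treated strand.

## Synthetic data: what it does and does not show

Generators are seeded (`numpy.random.default_rng`, one stream per call) and
bit-reproducible. The pocket generator moves the labeled pocket atoms along
fixed orthogonal axes so each pair's distance series realizes its planted
min/max exactly (endpoint frames) and its mean up to clipping; the planted
gate ranges are the published 9.9–16.3 Å (wt) and 10.4–15.1 Å (N51A), while
d1/d3/d4 use plausible defaults since their printed values are
figure-embedded. Planted-interaction frames put each contact in its own
25 Å lattice cell, guaranteeing every non-planted pair is far beyond
threshold. Clustered trajectories draw per-cluster displacement fields with
pairwise RMSD ≈ the requested spread. Clone sets apply per-motif Bernoulli
deamination then uniform substitution errors. None of this emulates real
molecular dynamics, real electrophoresis or real Sanger chemistry: passing
tests establish that the *analysis* code recovers planted truth under the
stated noise models, not that the published MD observables (interaction
counts 24/17/19/20, model-vs-crystal RMSDs) are reproduced — those require
the original trajectories and models, which are outside this package's
inputs.

## Problem sizes

Default analysis sizes are chosen to be statistically meaningful yet quick:
100 000 molecules and 3 replicates per lane with 50 seeded generations for
activity recovery; 100–200 trajectory frames for pocket series; 20 clones per
oligo (the wet protocol's count) for the NNCN drivers and 100 clones per
oligo for frequency-recovery checks; clustering fixtures of 15–30 atoms and
up to ~60 frames.
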