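# deamscan

In-silico analyses of how human activation-induced cytidine deaminase (AID)
and its point mutants discriminate between deoxycytidine (C),
5-methyl-deoxycytidine (5mC) and 5-hydroxymethyl-deoxycytidine (5hmC) in
single-stranded DNA. The package is aimed at structural bioinformaticians and
enzymologists who want the computational half of a deaminase
structure–function study as reusable, tested code: catalytic-pocket geometry
over MD-style trajectories, substrate ring breadths with van der Waals radii,
protein–ssDNA interaction fingerprints, conformational clustering, an
in-silico twin of the glycosylase-coupled deamination assays, and NNCN
sequence-context mutation profiling. Every analysis is exercisable on
synthetic data with planted ground truth — no structure downloads or wet-lab
inputs are required.

## What it computes

**Pocket geometry** (`deamscan.trajgeom`). The catalytic-pocket size is
tracked as four atom-pair distances per frame — d1: res51(ND2/CB)–Y114(CE2),
d2: res51–P86(CB) (the *gate* a heterocyclic ring must pass), d3:
res51–C87(SG), d4: Y114–H56(CE1) (pocket height) — each summarized as
mean/min/max over the trajectory. Substrate breadths come from idealized base
geometry: the breadth *b* of a base is the widest in-plane van der Waals span,

    b = max over atom pairs (i, j) of  ||p_i − p_j||_plane + r_i + r_j ,

over the base's heavy atoms plus its C5 substituent (Bondi radii). With
standard pyrimidine geometry this gives b(C) = 7.80 Å, b(5mC) = 8.72 Å, and a
hydroxymethyl-rotamer range of 9.04–9.20 Å for 5hmC. A base *fits* the pocket
when b ≤ min(d2); hydration of the 5hmC hydroxyl adds a documented 2.8–3.2 Å
of steric bulk per bound water, which is what excludes it.

**Interaction networks** (`deamscan.interact`). Per frame: vdW contacts
(d ≤ r_i + r_j + 0.6 Å, heavy atoms), hydrogen bonds (donor–acceptor ≤ 3.5 Å
and D–H⋯A ≥ 120° when hydrogens are present; H-bonds take precedence over vdW
for the same pair), and π-stacking (ring-centroid distance ≤ 4.5 Å,
interplanar angle ≤ 30°, lateral offset ≤ 2.0 Å). Aggregation yields one
record per partner pair with occupancy (fraction of frames) and mean distance;
networks are diffed by record key, with all contacts of a 5mC methyl group
collapsed onto one `5mC-methyl` partner. A triple stack (e.g. W84:Y114:G) is
present when both adjacent ring pairs stack; it is *stable* at ≥ 0.7 occupancy.

**Conformational clustering** (`deamscan.clusterconf`). Average-linkage
hierarchical clustering on the matrix of pairwise superposed RMSDs, with the
cluster count selected by the Kelley penalty
P(k) = norm_spread(k) + k, where the average within-cluster spread is min–max
rescaled onto [1, n−1] across hierarchy levels. Cluster-average structures
(members superposed onto the cluster's first frame, coordinate-wise mean)
feed global and per-segment RMSD comparison against a reference structure.

**Assay simulation** (`deamscan.assay`). The three-stage, 5′-radiolabeled
assay: Bernoulli(efficiency) deamination of the single special base of an
80-mer (C→U, 5mC→T, 5hmC→5hmU), glycosylase excision (UDG: U; hSMUG1: U and
5hmU; TDG: the T of a G:T mismatch, duplex required), and alkaline cleavage
at the abasic site. Deamination of the central base (position 41) yields a
40-nt labeled product; lanes are quantified as
I_product / (I_product + I_substrate), and a variant's activity is
100 × mean(variant)/mean(wt) with first-order error propagation. Pearson's r
compares activity profiles across substrates.

**NNCN profiling** (`deamscan.nncn`). Four 104-nt oligos
(20-nt C-free flank + 16 tiled NNCN 4-mers + 20-nt C-free flank) jointly tile
all 64 contexts with the target C third. Clones are globally aligned
(Needleman–Wunsch, +1/−1/−2, deterministic tie-break), C→T transitions called
per non-flank reference C in its actual 4-mer context, and per-motif
frequencies tabulated (positions adjacent to indels are excluded).

**Synthetic data** (`deamscan.synth`). Deterministic, seeded generators for
all of the above: pocket trajectories realizing prescribed distance
min/mean/max exactly, planted-interaction frames on a non-interacting
lattice, k-cluster trajectories, clone sets with per-motif deamination plus
uniform sequencing error, and replicate gel lanes with log-normal intensity
noise.

## Worked example

```sh
$ deamscan simulate pocket --frames 100 --variant wt --seed 7 --out traj.pdb
wrote 100 frames to traj.pdb
$ deamscan pocket --traj traj.pdb --variant wt --out pocket/
wrote pocket/pocket_distances.tsv and pocket_report.json
```

`pocket_report.json` then contains (abridged):

```json
"d2": {"mean": 13.1, "min": 9.9, "max": 16.3},
"fit": {"C":   {"breadth": 7.80, "fits_at_min": true,  "clearance":  2.10},
        "5mC": {"breadth": 8.72, "fits_at_min": true,  "clearance":  1.18}}
```

The gate distance d2 (residue 51 to P86) spans 9.9–16.3 Å over the
trajectory, so both C (7.80 Å) and 5mC (8.72 Å) pass even at the pocket's
minimal opening — steric exclusion cannot explain differential activity on
these substrates. Running the assay twin:

```sh
$ deamscan assay --substrate 5mC --variant N51A --n 100000 --seed 7 --out assay.json
N51A on 5mC (TDG): product fraction 0.1561
```

against a wild-type fraction of ~0.20 this is ~78% of wt — the mutant that is
dead on C retains most of its activity on 5mC.

The full study-shaped pipeline lives in `analysis/` (numbered drivers:
`01_simulate_assays.py` … `05_conformational_clustering.py`); each prints its
findings and writes tables under `results/`.

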