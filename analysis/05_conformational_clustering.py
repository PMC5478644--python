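#!/usr/bin/env python
"""Conformational clustering of a trajectory and comparison to a reference.

Generates a trajectory with seven planted conformational states, clusters it
with average linkage + Kelley-penalty selection of the cluster count, computes
the seven cluster-average structures (ranked by membership), and superposes
each average onto a crystal-like reference structure (a perturbed copy of the
largest cluster's center, standing in for an independently solved structure)
to report global and segment RMSDs.

Writes results/clustering.json and results/cluster_vs_reference.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from deamscan.clusterconf import (
    cluster_average_structures,
    kelley_cluster,
    pairwise_rmsd_matrix,
)
from deamscan.structio import AtomSelector
from deamscan.synth import make_clustered_trajectory
from deamscan.trajgeom import segment_rmsd, superpose

SEED = 20170620
K_PLANTED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"

#: synthetic "loop" segment: residues 12-18 of the 30-atom CA chain
LOOP_RESIDUES = range(12, 19)


def main():
    RESULTS.mkdir(exist_ok=True)
    traj, truth = make_clustered_trajectory(
        K_PLANTED, frames_per_cluster=[12, 10, 9, 8, 7, 6, 5],
        spread=8.0, noise=0.6, seed=SEED, n_atoms=30,
    )
    matrix = pairwise_rmsd_matrix(traj)
    clustering = kelley_cluster(matrix)
    averages = cluster_average_structures(traj, clustering, min(7, clustering.k))

    # crystal-like reference: the largest cluster's average, mildly perturbed
    rng = np.random.default_rng(SEED)
    reference = averages[0].with_coords(
        averages[0].coords + rng.normal(0, 0.15, averages[0].coords.shape),
        title="synthetic crystal-like reference",
    )

    rows = []
    for rank, avg in enumerate(averages, start=1):
        fit = superpose(avg, reference, AtomSelector(name="CA"))
        seg = np.mean([
            segment_rmsd(avg, reference, AtomSelector(name="CA"),
                         AtomSelector(res_num=r, name="CA"))
            for r in LOOP_RESIDUES
        ])
        rows.append({"rank": rank, "members": int(avg.title.split("(")[1].split()[0]),
                     "global_rmsd_A": round(fit.rmsd, 3),
                     "loop_rmsd_A": round(float(seg), 3)})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cluster_vs_reference.tsv", sep="\t", index=False)

    payload = {
        "seed": SEED,
        "planted_k": K_PLANTED,
        "recovered_k": clustering.k,
        "ranked_sizes": clustering.ranked_sizes,
        "penalty_curve": {str(k): round(v, 3) for k, v in
                          sorted(clustering.penalty_curve.items())[:12]},
        "partition_matches_plant": bool(_partition_match(clustering.labels, truth)),
    }
    (RESULTS / "clustering.json").write_text(json.dumps(payload, indent=1))

    print(f"planted k={K_PLANTED}, recovered k={clustering.k}; "
          f"ranked sizes {clustering.ranked_sizes}")
    print(f"partition matches the plant: {payload['partition_matches_plant']}")
    print(table.to_string(index=False))
    print("\nThe largest cluster's average sits closest to the reference "
          "(it was used, perturbed, as the stand-in crystal); RMSDs grow for "
          "the other conformational states, as expected for distinct states.")


def _partition_match(labels, truth):
    mapping = {}
    for got, want in zip(labels, truth):
        if mapping.setdefault(got, want) != want:
            return False
    return len(set(mapping.values())) == len(mapping)


if __name__ == "__main__":
    main()
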