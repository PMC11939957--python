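"""Extract metastable brain states from the cohort with LEiDA.

Band-pass filters every subject's series (0.01-0.08 Hz), computes
per-volume phase-coherence leading eigenvectors, clusters them with
city-block k-means (K = 3, 100 restarts), and writes centroids, per-volume
state assignments, per-subject occupancy distributions (PMS) and
state-network correlations (Fisher-z CIs, BH-corrected) under
results/leida/.
"""

import argparse
import time
from pathlib import Path

import numpy as np
import pandas as pd

from braindyn.cohort import NETWORKS, read_cohort
from braindyn.leida import (
    cluster_states,
    eigenvector_series,
    network_correlation,
    occurrence_probabilities,
)
from braindyn.stats import fdr_bh

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/leida"))
parser.add_argument("--k", type=int, default=3)
parser.add_argument("--replicates", type=int, default=100)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

t0 = time.time()
cohort, meta, region_table, sc = read_cohort(args.cohort)
es = eigenvector_series(cohort)
print(f"{es.n_rows} leading eigenvectors from {len(cohort)} subjects "
      f"[{time.time()-t0:.0f}s]")

states = cluster_states(es, k=args.k, n_replicates=args.replicates, seed=args.seed)
print(f"k-means (K={args.k}, {args.replicates} restarts): inertia={states.inertia:.1f}")

args.out.mkdir(parents=True, exist_ok=True)
np.savetxt(args.out / "centroids.tsv", states.centroids, delimiter="\t", fmt="%.6g")
pd.DataFrame({
    "subject": es.subject_index, "volume": es.time_index, "state": states.assignment,
}).to_csv(args.out / "assignments.tsv", sep="\t", index=False)

pms_rows = []
for s in range(len(cohort)):
    pms = occurrence_probabilities(states.assignment[es.subject_index == s], args.k)
    pms_rows.append(pms.probabilities)
pms_matrix = np.array(pms_rows)
pms_df = pd.DataFrame(pms_matrix, columns=[f"state_{j+1}" for j in range(args.k)])
pms_df.insert(0, "subject_id", cohort.subject_ids)
pms_df.insert(1, "group", meta["group"])
pms_df.to_csv(args.out / "pms.tsv", sep="\t", index=False)

for label in ("A", "B"):
    sel = (meta["group"] == label).to_numpy()
    print(f"group {label} mean PMS:", np.round(pms_matrix[sel].mean(axis=0), 3))

# which functional systems does each state's positive community overlap?
rows = []
for j in range(args.k):
    for net in NETWORKS:
        try:
            r, lo, hi, p = network_correlation(states.centroids[j], region_table, net)
        except ValueError:
            continue
        rows.append((j + 1, net, r, lo, hi, p))
net_df = pd.DataFrame(rows, columns=["state", "network", "r", "ci_low", "ci_high", "p"])
net_df["p_adj"] = np.concatenate([
    fdr_bh(net_df.loc[net_df["state"] == j + 1, "p"]) for j in range(args.k)
])
net_df.to_csv(args.out / "network_correlations.tsv", sep="\t", index=False)
sig = net_df[net_df["p_adj"] < 0.05]
print(f"significant state-network correlations (BH across networks per state):")
for _, row in sig.iterrows():
    print(f"  state {row['state']:.0f} ~ {row['network']}: r={row['r']:.2f} "
          f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], p_adj={row['p_adj']:.4f}")
print(f"done [{time.time()-t0:.0f}s]")
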