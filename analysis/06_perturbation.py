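"""Drive state transitions between the two regimes by in-silico perturbation.

Takes the model fitted to one group (base), shifts single regions'
bifurcation parameters over a strength grid, and scores each (region,
strength) cell by the symmetrized-KL distance between the perturbed
occupancy distribution and the other group's empirical one.  Positive
strengths push the region into the oscillatory (synchronization) regime,
negative ones into the noise regime.  Selects the top 0.5% of cells,
compares them against the strength-0 benchmark with paired t-tests, and
reports the homolog (left/right) perturbation asymmetry.  Writes under
results/perturbation/.
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from braindyn.cohort import read_cohort
from braindyn.hopf import (
    HopfModelSpec,
    SimulationConfig,
    estimate_natural_frequencies,
    normalize_coupling,
)
from braindyn.leida import StatePMS, occurrence_probabilities
from braindyn.perturb import (
    PerturbationProtocol,
    benchmark_compare,
    homolog_asymmetry,
    scan_perturbations,
    select_top_fraction,
)

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--leida", type=Path, default=Path("results/leida"))
parser.add_argument("--fit", type=Path, default=Path("results/fit"))
parser.add_argument("--ec", type=Path, default=Path("results/ec"))
parser.add_argument("--out", type=Path, default=Path("results/perturbation"))
parser.add_argument("--direction", choices=["toward_B", "toward_A"],
                    default="toward_B")
parser.add_argument("--step", type=float, default=0.025,
                    help="strength grid step (full protocol grids use 0.01)")
parser.add_argument("--reps", type=int, default=3)
parser.add_argument("--duration", type=float, default=1500.0)
parser.add_argument("--fraction", type=float, default=0.005)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

t0 = time.time()
cohort, meta, region_table, sc = read_cohort(args.cohort)
assign = pd.read_csv(args.leida / "assignments.tsv", sep="\t")
centroids = np.loadtxt(args.leida / "centroids.tsv", delimiter="\t", ndmin=2)
k = centroids.shape[0]
fit = json.loads((args.fit / "fit_summary.json").read_text())

base_group = "A" if args.direction == "toward_B" else "B"
target_group = "B" if args.direction == "toward_B" else "A"
lo, hi = (-0.15, 0.2) if args.direction == "toward_B" else (-0.3, 0.05)
strengths = np.round(np.arange(lo, hi + 1e-9, args.step), 10)

subjects = np.flatnonzero((meta["group"] == target_group).to_numpy())
labels = assign.loc[assign["subject"].isin(subjects), "state"].to_numpy()
target = occurrence_probabilities(labels, k, level="group")
print(f"target ({target_group}) PMS: {np.round(target.probabilities, 3)}")

ec_file = args.ec / f"ec_{base_group}_fs_plus_fsdiff.tsv"
coupling = (np.loadtxt(ec_file, delimiter="\t", ndmin=2) if ec_file.exists()
            else normalize_coupling(sc))
base_subjects = np.flatnonzero((meta["group"] == base_group).to_numpy())
omega = estimate_natural_frequencies(cohort.subset(base_subjects))
base_spec = HopfModelSpec(a=np.full(cohort.n_regions, -0.02), omega=omega,
                          coupling=coupling, g=fit[base_group]["best_g"],
                          sigma=0.02)

protocol = PerturbationProtocol(base_spec=base_spec, target_pms=target,
                                direction=args.direction, strengths=strengths,
                                n_reps=args.reps)
sim_cfg = SimulationConfig(duration=args.duration, tr=cohort.tr, dt=0.1,
                           burn_in=200.0, seed=args.seed)
grid = scan_perturbations(protocol, centroids, sim_cfg, master_seed=args.seed)
print(f"scanned {grid.valid.sum()} valid cells "
      f"({len(grid.regions)} regions x {len(strengths)} strengths, "
      f"{args.reps} reps) [{time.time()-t0:.0f}s]")

args.out.mkdir(parents=True, exist_ok=True)
tag = args.direction
np.savetxt(args.out / f"js_grid_{tag}.tsv", grid.js, delimiter="\t", fmt="%.6g")
sel = select_top_fraction(grid, args.fraction)
sel[["region", "strength", "js"]].to_csv(
    args.out / f"selection_{tag}.tsv", sep="\t", index=False)
report = benchmark_compare(grid, sel)
report.to_csv(args.out / f"benchmark_{tag}.tsv", sep="\t", index=False)
asym = homolog_asymmetry(grid, region_table)

improved = (report["mean_diff"] < 0).sum()
print(f"top {args.fraction:.1%}: {len(sel)} configurations; "
      f"{improved}/{len(report)} beat their strength-0 benchmark")
print(sel[["region", "strength", "js"]].head(5).to_string(index=False))
print(f"homolog perturbation asymmetry: {asym:.4f}")
(args.out / f"summary_{tag}.json").write_text(json.dumps({
    "direction": tag, "n_selected": int(len(sel)),
    "n_improved_vs_benchmark": int(improved),
    "homolog_asymmetry": asym,
    "best": sel.iloc[0][["region", "strength", "js"]].to_dict(),
}, indent=1))
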