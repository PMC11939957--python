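"""Covariate-adjusted group comparison of state occupancies, plus
severity-occupancy associations in group B.

MANCOVA (Wilks' lambda, exact F) over the K-1 free state probabilities,
per-state ANCOVA post hocs with BH correction, and Spearman partial
correlations (1000-replicate bootstrap CIs) between group-B state
probabilities and the severity indices, controlling age, sex, education
and mean FD.  Writes a tidy results table under results/stats/.
"""

import argparse
import time
from pathlib import Path

import numpy as np
import pandas as pd

from braindyn.cohort import SEVERITY_INDICES, read_cohort
from braindyn.stats import (
    ancova_univariate,
    fdr_bh,
    mancova_wilks,
    spearman_partial_bootstrap,
    state_probability_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--leida", type=Path, default=Path("results/leida"))
parser.add_argument("--out", type=Path, default=Path("results/stats"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

t0 = time.time()
cohort, meta, region_table, sc = read_cohort(args.cohort)
pms_df = pd.read_csv(args.leida / "pms.tsv", sep="\t")
k = sum(c.startswith("state_") for c in pms_df.columns)
pms = pms_df[[f"state_{j+1}" for j in range(k)]].to_numpy()

design = state_probability_table(meta, pms)
f, df1, df2, p = mancova_wilks(design)
print(f"MANCOVA group effect: F({df1},{df2}) = {f:.2f}, p = {p:.4f}")

rows = [("mancova", "group", f, df1, df2, p, np.nan)]
p_states = []
for j in range(k):
    fj, d1, d2, pj = ancova_univariate(design, state=j)
    p_states.append(pj)
    rows.append((f"ancova_state_{j+1}", "group", fj, d1, d2, pj, np.nan))
p_adj = fdr_bh(p_states)
for j in range(k):
    rows[j + 1] = rows[j + 1][:6] + (p_adj[j],)
    print(f"  state {j+1}: F({rows[j+1][3]},{rows[j+1][4]}) = {rows[j+1][2]:.2f}, "
          f"p = {p_states[j]:.4f}, p_adj = {p_adj[j]:.4f}")

# severity associations within group B
sel = (meta["group"] == "B").to_numpy()
cov_b = meta.loc[sel, ["age", "sex", "education", "mean_fd"]].to_numpy(float)
cov_b = cov_b[:, cov_b.std(axis=0) > 0]
for j in range(k):
    for idx_name in SEVERITY_INDICES:
        rho, p_rho, (lo, hi) = spearman_partial_bootstrap(
            pms[sel, j], meta.loc[sel, idx_name].to_numpy(float), cov_b,
            n_boot=1000, seed=args.seed,
        )
        rows.append((f"spearman_state_{j+1}", idx_name, rho, np.nan, np.nan,
                     p_rho, np.nan))
        flag = "*" if p_rho < 0.05 else " "
        print(f" {flag}state {j+1} ~ {idx_name}: rho = {rho:.2f} "
              f"[{lo:.2f}, {hi:.2f}], p = {p_rho:.4f}")

args.out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows, columns=["test", "term", "statistic", "df1", "df2", "p",
                            "p_adj"]).to_csv(args.out / "group_stats.tsv",
                                             sep="\t", index=False)
print(f"done [{time.time()-t0:.0f}s]")
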