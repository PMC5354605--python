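"""Statistical tests on the quantified phenotypes, plus the published-style
summary reconstruction.

* Unpaired t test between the round and elongated conditions' per-dataset
  elongation means (the experiment is the replication unit).
* One-way ANOVA + Tukey HSD across three vacuole-size-style groups
  simulated at the summary statistics of a rescue experiment
  (0.39/0.65/0.40 um, SEM x sqrt(n) spread, n = 4).
* Reconstruction of a two-group viability comparison from printed
  summaries (98.7 +/- 0.27 vs 81.5 +/- 2.2%, n = 3): expected p ~ 0.0015.

Writes results/stats/tests.tsv and a plain-text report.
"""

import os

import numpy as np
import pandas as pd

from sgaphen.stats_report import GroupSummary, anova_tukey, unpaired_t, write_report

OUT = "results/stats"
os.makedirs(OUT, exist_ok=True)
SEED = 200

results = []

# elongation: per-dataset means from 05_quantify_phenotypes.py
per_cell = pd.read_csv("results/phenotypes/per_cell_elongation.tsv", sep="\t")
ds_means = per_cell.groupby(["condition", "dataset"])["elongation"].mean()
res = unpaired_t(ds_means["round"].to_numpy(), ds_means["elongated"].to_numpy())
res.groups[0].label, res.groups[1].label = "round", "elongated"
results.append(res)
print(f"elongation round vs elongated: t = {res.statistic:.2f}, "
      f"p = {res.p_value:.2g} {res.stars}")

# vacuole rescue-style three-group comparison (simulated at summary stats)
rng = np.random.default_rng(SEED)
wt = rng.normal(0.39, 0.01 * 2, 4)
mutant = rng.normal(0.65, 0.03 * 2, 4)
rescue = rng.normal(0.40, 0.03 * 2, 4)
res = anova_tukey([wt, mutant, rescue], ["wild-type", "mutant", "rescued"])
results.append(res)
print(f"vacuole ANOVA: F = {res.statistic:.1f}, p = {res.p_value:.2g}")
for _, row in res.pairwise.iterrows():
    print(f"  {row.group_a} vs {row.group_b}: p_adj = {row.p_adj:.2g} {row.stars}")

# viability reconstruction from printed summaries
res = unpaired_t(GroupSummary("minimal medium", 3, 98.7, 0.27),
                 GroupSummary("nitrogen-starved", 3, 81.5, 2.2))
results.append(res)
print(f"viability summaries: t = {res.statistic:.2f} (df = {res.df[0]:.0f}), "
      f"p = {res.p_value:.2g} {res.stars}")

write_report(results, f"{OUT}/tests.tsv", f"{OUT}/tests.txt")
print(f"wrote {OUT}/tests.tsv and {OUT}/tests.txt")
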