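"""Quantify elongation, viability and vacuole size from the simulated fields.

Reads the TIFF fields written by 04_simulate_cell_fields.py, measures:

* per-cell elongation (1 - 4*pi*A/P^2) in the round and elongated
  conditions, summarized as mean +/- SEM over 30 cells x 5 datasets;
* viability from the 500-cell field (propidium-iodide-style dead stain
  against the calcofluor-style total population);
* vacuole diameters from the ring channel of the four vacuole datasets.

Writes results/phenotypes/summary.tsv and per-cell tables.
"""

import os

import numpy as np
import pandas as pd
import tifffile

from sgaphen.phenotype_quant import (
    elongation_score,
    measure_vacuoles,
    score_viability,
    segment_cells,
    summarize_elongation,
)

IN = "results/cell_fields"
OUT = "results/phenotypes"
os.makedirs(OUT, exist_ok=True)

summary_rows = []
per_cell = []

# --- elongation: 5 datasets per condition, 30 cells per dataset -----------
for cond in ("round", "elongated"):
    datasets = []
    for d in range(1, 6):
        wall = tifffile.imread(f"{IN}/shape_{cond}_d{d}_wall.tiff")
        masks = segment_cells(wall)
        scores = [elongation_score(m) for m in masks]
        datasets.append(scores)
        per_cell += [{"condition": cond, "dataset": d, "elongation": s}
                     for s in scores]
    summ = summarize_elongation(datasets, n_per_dataset=30)
    summary_rows.append({"assay": "elongation", "condition": cond,
                         "mean": round(summ["mean"], 4),
                         "sem": round(summ["sem"], 4),
                         "n_datasets": summ["n_datasets"]})
    print(f"elongation [{cond}]: {summ['mean']:.3f} +/- {summ['sem']:.3f} "
          f"(SEM over {summ['n_datasets']} datasets of 30 cells)")

pd.DataFrame(per_cell).to_csv(f"{OUT}/per_cell_elongation.tsv", sep="\t",
                              index=False)

# --- viability -------------------------------------------------------------
wall = tifffile.imread(f"{IN}/viability_24h_wall.tiff")
dead = tifffile.imread(f"{IN}/viability_24h_dead_stain.tiff")
rec = score_viability(wall, dead, n_scored=500, timepoint_h=24.0)
summary_rows.append({"assay": "viability", "condition": "24h_starved",
                     "mean": round(rec.viability_percent, 1), "sem": np.nan,
                     "n_datasets": 1})
print(f"viability at 24 h: {rec.viability_percent:.1f}% "
      f"({rec.n_dead} dead of {rec.n_total} scored)")

# --- vacuole diameters -----------------------------------------------------
dataset_means = []
for d in range(1, 5):
    img = tifffile.imread(f"{IN}/vacuole_d{d}_vacuole.tiff")
    vacs = measure_vacuoles(img, pixel_size=0.05)
    dataset_means.append(float(np.mean([v.diameter_um for v in vacs])))
from sgaphen.stats_report import sem as sem_fn  # noqa: E402

summary_rows.append({"assay": "vacuole_diameter_um", "condition": "rings_0.65um",
                     "mean": round(float(np.mean(dataset_means)), 3),
                     "sem": round(sem_fn(dataset_means), 3),
                     "n_datasets": len(dataset_means)})
print(f"vacuole diameter: {np.mean(dataset_means):.3f} +/- "
      f"{sem_fn(dataset_means):.3f} um (SEM over {len(dataset_means)} datasets)")

pd.DataFrame(summary_rows).to_csv(f"{OUT}/summary.tsv", sep="\t", index=False)
print(f"wrote {OUT}/summary.tsv")
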