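"""Simulate the fluorescence cell fields for the three validation assays.

Three kinds of field, each with a wall (segmentation) channel, a dead-cell
stain channel, a vacuole-membrane channel and a ground-truth table:

* shape fields: five round-cell and five elongated-cell datasets (30+ cells
  each) for the elongation assay;
* a viability field: 500 small cells with an 18.5% dead fraction;
* vacuole fields: four datasets of cells carrying 0.65 um membrane rings at
  0.05 um/px.

Images are written as 16-bit TIFF under results/cell_fields/.
"""

import os

import tifffile

from sgaphen.synthetic_data import CellFieldConfig, generate_cell_field

SEED = 100
OUT = "results/cell_fields"
os.makedirs(OUT, exist_ok=True)


def write_field(name, cfg):
    fld = generate_cell_field(cfg)
    for chan in ("wall", "dead_stain", "vacuole"):
        tifffile.imwrite(os.path.join(OUT, f"{name}_{chan}.tiff"),
                         getattr(fld, chan))
    fld.truth.to_csv(os.path.join(OUT, f"{name}_truth.tsv"), sep="\t",
                     index=False)
    return fld


n = 0
for d in range(5):  # five independent shape datasets per condition
    for cond, ratio in (("round", 1.0), ("elongated", 2.5)):
        cfg = CellFieldConfig(
            n_cells=34, axis_ratio_mean=ratio, minor_diameter_um=3.0,
            pixel_size=0.1, image_shape=(1100, 1100), seed=SEED + 10 * d + (ratio > 1),
        )
        write_field(f"shape_{cond}_d{d + 1}", cfg)
        n += 1

viab = CellFieldConfig(
    n_cells=500, axis_ratio_mean=1.5, minor_diameter_um=3.0, pixel_size=0.2,
    image_shape=(1600, 1600), dead_fraction=0.185, vacuole_diameter_mean=0.0,
    seed=SEED + 50,
)
write_field("viability_24h", viab)
n += 1

for d in range(4):  # four vacuole datasets
    cfg = CellFieldConfig(
        n_cells=40, axis_ratio_mean=1.6, minor_diameter_um=2.6,
        pixel_size=0.05, image_shape=(1280, 1280),
        vacuole_diameter_mean=0.65, seed=SEED + 60 + d,
    )
    write_field(f"vacuole_d{d + 1}", cfg)
    n += 1

print(f"wrote {n} fields (3 channels + truth each) under {OUT}/")
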