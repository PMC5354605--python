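"""Simulate the colony-array screen used throughout this analysis.

A 3,000-gene deletion-library screen: query and control arrays in 1536
format, four query isolates, two biological replicates, 10% multiplicative
colony noise, a 10% growth boost on the outermost two rows/columns, and
planted interaction effects (ratio 0.5 for 2% of genes, 1.5 for another
2%).  Writes the colony-size and ground-truth tables under
results/screen/.
"""

from sgaphen.synthetic_data import ScreenConfig, generate_screen

SEED = 1

config = ScreenConfig(
    n_genes=3000, n_isolates=4, n_replicates=2, noise_cv=0.10,
    edge_effect=1.1, interaction_fractions=(0.02, 0.02),
    effect_magnitudes=(0.5, 1.5), seed=SEED,
)
screen = generate_screen(config)
paths = screen.write("results/screen")

n_neg = (screen.truth["category"] == "negative").sum()
n_pos = (screen.truth["category"] == "positive").sum()
print(f"simulated {config.n_genes} genes on {len(screen.plates)} plates "
      f"({config.n_pages} pages x {config.n_isolates} isolates x "
      f"{config.n_replicates} replicates x 2 roles)")
print(f"planted {n_neg} negative and {n_pos} positive interactions")
for name, path in paths.items():
    print(f"  {name}: {path}")
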