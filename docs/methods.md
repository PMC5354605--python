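# Methods

`sgaphen` re-implements the computational layer of a fission-yeast
synthetic-genetic-array (SGA) screen and its microscopy validation assays:
colony-array quantification, interaction scoring by colony-size ratios,
cell-elongation / viability / vacuole-size measurement, and the small
statistical toolkit used to compare conditions.  Every stage can be
exercised against synthetic data with known ground truth; this note
records the models, the defaults and why, and what the synthetic tests do
and do not demonstrate.

## The screen model

A query deletion strain is crossed into a genome-wide deletion library and
the double mutants are pinned in 1536 format (32 x 48 colonies per plate),
alongside a control array built from a neutral marker-only query.  The
simulator draws colony sizes from a multiplicative model,

    s(g, p) = base_g * f_p * pos(r, c) * eps_g * eta,

where `base_g` is the gene's baseline colony size (lognormal around 400
px^2-equivalents, CV 0.15 between genes), `f_p` a per-plate scale factor
(lognormal, relative SD 0.10), `pos(r, c)` a positional growth field,
`eps_g` the planted genetic-interaction effect on the query array only
(1 = none; defaults plant 0.5 in 2% of genes and 1.5 in another 2%), and
`eta` lognormal multiplicative noise with CV 0.10.  Lognormal noise keeps
sizes positive and matches the roughly constant coefficient of variation
of colony growth.  The positional field boosts the outermost two
rows/columns by 10% — the canonical nutrient-competition edge artifact.
Gene-to-position layout is row-major and fixed across plates, as with a
real arrayed library; screens larger than one plate span consecutive plate
pages, each page an independent physical plate with its own scale factor.
Failed pinnings (size 0, flagged `empty`) are supported with default
probability 0, since their true prevalence in real screens is unreported.

## Interaction scoring

1. **Normalization.** Each plate is divided by the median of its retained
   (unflagged, non-zero) colony sizes.  Flagged positions are excluded from
   the median because dead pins would drag it; with an even retained count
   (1536 is even) the median is the midpoint of the two central order
   statistics.
2. **Ratios.** Per position, normalized query / normalized control.  A
   ratio is undefined — with a recorded reason — when either side is
   missing or the normalized control is below 0.05 (a dead control pin
   cannot witness a fitness ratio, and tiny denominators explode).
3. **Isolate averaging.** The arithmetic mean of the defined ratios across
   the independent query isolates (4 by default); genes with fewer than 2
   defined ratios are dropped with reason `no_ratio`.
4. **Calls.** mean ratio < 0.8 -> negative interaction, > 1.2 -> positive,
   anything else (including exactly at a threshold) -> none.  The
   inequalities are strict.
5. **Replicate intersection.** Only genes called with the same sign in
   every biological replicate (2 by default) are robust; opposite-sign
   genes are flagged `discordant`.

Two readings of the protocol were genuinely open and are resolved here as
follows: plates are normalized separately (query and control each to their
own median), and replicate intersection requires matching sign, not mere
presence.  Both choices are the stricter reading.

**Known limitation.** Median normalization absorbs whole-plate scale but
*not* within-plate positional structure: the edge boost cancels only
because query and control share the same field.  A query-specific spatial
artifact would propagate into ratios; no LOESS-style spatial correction is
attempted (out of scope, as is any multiplicative-model fit of interaction
scores with significance testing).

The hub-membership computation (`hub_fraction`) reports the count of
robust negative interactors inside a supplied hub gene list and the
percentage of all negatives, truncated (not rounded) to one decimal, the
convention that makes 39/131 print as 29.7%.  The packaged gene lists are
synthetic stand-ins with the same set sizes (131 negatives, 39 in the
hub); the real lists live in the source screen's supplementary material.

## Colony quantification from images

`render_plate_image` draws each colony as a filled disc of area
proportional to its size on a flat background, then blurs (sigma 0.8 px)
and optionally adds Gaussian noise — enough realism to exercise the
quantifier, deliberately ignoring agar smears, lid glare and robot
dynamics.

`fit_grid` reduces the image to row/column mean-intensity profiles,
detects peaks, and least-squares-fits a regular lattice
(offset + i * pitch) to the detected peaks, which tolerates weak or
spurious peaks; fewer than half the expected peaks on an axis raises
"grid not found".

`quantify_colonies` measures each grid window independently.  Background
statistics (median, MAD) come from the window's border ring, which
colonies cannot reach given the pitch constraint; the threshold is

    background_median + max(3 * MAD, 0.5 * robust_amplitude),

where the robust amplitude is the window's 99.5th percentile minus the
background median.  The half-amplitude floor makes the zero-noise case
well defined and preserves the area of blur-softened edges (a symmetric
edge profile crosses half-maximum at the original boundary); both terms
scale linearly with intensity, so quantification is invariant to global
intensity rescaling.  The size is the pixel count of the largest connected
blob (ties broken by distance to the window centre, resolving debris);
integrated background-subtracted intensity is available as an option since
grid quantifiers differ on this point.  A window is flagged `empty` when
its amplitude is indistinguishable from border noise (<= 6 MAD) or the
best blob is under 4 px.

Accuracy is resolution-limited: with 0.8 px blur, discs under ~4 px radius
quantify with errors up to ~8%, so round-trip demonstrations render at a
26 px pitch (photograph-like; smallest colonies ~4.5 px radius), where
noise-free recovery is r > 0.998 against rasterized truth.

## Cell-field simulation and phenotype quantification

`generate_cell_field` renders non-overlapping elliptical cells (bounded
rejection sampling; bounding-circle overlap test) into three channels:
a wall channel with bright 2 px elliptical outlines (what a cell-wall
stain shows and the segmentation input), a dead-stain channel filling the
interiors of a Bernoulli-sampled dead subset, and a vacuole channel with
one membrane ring per live cell.  All channels get blur (sigma 1 px),
a background level and Gaussian noise.  The generator emulates the
measurement geometry, not biology: no touching cells, no septation, no
uneven illumination, no photobleaching — so passing round-trips validate
the measurement code, not robustness to crowded real fields.

**Segmentation** is Otsu thresholding of the wall channel, hole-filling
(outlines become solid cells), connected-component labelling, area
filtering, and exclusion of border-touching cells whose geometry is
truncated.  On synthetic fields this recovers every cell with IoU >= 0.9
against truth masks; it has no watershed splitting, so touching cells in
real images would merge.

**Elongation** is `1 - 4*pi*area/perimeter^2`: 0 for a circle (the
isoperimetric identity), approaching 1 for elongated shapes, and scale-free
so pixel-vs-micrometre calibration is irrelevant.  The perimeter uses the
Crofton (line-intercept, 4-direction) estimator: naive pixel-edge counting
overestimates smooth boundaries by ~4%, which would push a perfect disc's
score to ~0.08 and destroy the statistic's anchor at zero; with Crofton a
rasterized disc of radius >= 30 px scores <= 0.02 (slight negative raw
values clamp to 0).  Condition summaries average 30 cells per dataset and
report mean +/- SEM across dataset means — the independent experiment, not
the cell, is the replication unit.

**Viability** is 100 * (1 - n_dead / n_total) over the first 500 segmented
cells in raster order (deterministic; a seeded random sample is the
obvious variant).  A cell is dead-positive when at least 20% of its mask
exceeds a half-amplitude threshold of the dead channel; counts, not
intensities, carry the result, so it is intensity-scale invariant.

**Vacuole diameter.** Membrane rings are thresholded, filled and labelled;
the diameter is read at the ring-band *midline*: the mean of the
equivalent-circle diameters (`sqrt(4A/pi)`) of the filled region and of
its interior hole, times the pixel size.  The midline is insensitive to
how much blur thickens the band (blur widens it symmetrically), which a
pure outer-edge reading is not; the simulator draws rings with the midline
at the stated diameter, and round-trips recover 0.65 um rings at
0.05 um/px to within ~0.005 um.  Equivalent-circle diameter was chosen
because how diameters are read in practice (line tool vs region measure)
is tool-dependent; for near-circular rings the two agree.

## Statistics

Two-group comparisons use the two-sided unpaired Student t test with
pooled variance (the common "unpaired t test" default; Welch is a flag).
Summary-form inputs (mean, SEM, n) reconstruct
`t = dmean / sqrt(SEM_1^2 + SEM_2^2)` with df = n1 + n2 - 2, which is what
checking a printed comparison requires.  Three or more groups get ordinary
one-way ANOVA with Tukey's HSD post-test (studentized-range adjusted
p-values); the pairwise table also carries the unadjusted comparison on
the same pooled error term (Fisher LSD), the quantity Tukey provably never
undercuts — a two-sample t using only the pair's own variance can be
larger *or* smaller, since other groups inform the pooled error.  All-
constant inputs define F = 0, p = 1.  SEM is sample SD (n-1)/sqrt(n);
stars are * p<0.05, ** p<0.01, *** p<0.001.  Under a null simulation
(Normal, n = 3 per group, 10^4 reps) the t test's rejection rate at
alpha = 0.05 is calibrated within +/- 0.01.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded from one root
seed per run; identical config + seed reproduces tables and images
byte-for-byte (the pipeline manifest records SHA-256 checksums to make
this checkable).  Demonstration problem sizes — a 3,000-gene screen
(2 pages x 4 isolates x 2 replicates x 2 roles = 32 plates), 16x24
rendered plates, 500-cell viability fields, 40-cell vacuole fields —
run the full suite and the acceptance script in well under a minute each
while leaving every statistic comfortably estimable.
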