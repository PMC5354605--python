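"""Ground-truth simulators for every stage of the screen pipeline.

Two generators live here:

* :func:`generate_screen` emulates a colony-array genetic screen: a query
  mutant crossed into a deletion library and pinned in 1536 format (32 x 48)
  alongside a neutral-marker control array.  Colony sizes follow a
  multiplicative model

      size = base_gene x plate_factor x positional_factor x effect x noise

  where ``effect`` is the planted per-gene interaction (query arrays only;
  1 = no interaction, <1 negative, >1 positive) and noise is lognormal so
  sizes stay positive.  The planted effects are returned as a truth table
  so scoring recall/precision can be measured exactly.

* :func:`generate_cell_field` emulates three-channel fluorescence imaging
  of fission-yeast cells: a cell-wall stain (elliptical outlines, the
  segmentation channel), a dead-cell stain carried by a known fraction of
  cells, and a vacuole-membrane stain drawn as rings of known diameter.
  True masks and per-cell parameters are returned alongside the images.

* :func:`render_plate_image` turns a simulated plate into a photograph-like
  grayscale image (discs on a background, blur, noise) so the colony
  quantifier can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .colony_quant import FLAG_EMPTY, GridGeometry, PlateGrid

__all__ = [
    "ScreenConfig",
    "ScreenData",
    "CellFieldConfig",
    "CellField",
    "generate_screen",
    "render_plate_image",
    "generate_cell_field",
]


def _lognormal_sigma(cv: float) -> float:
    """Sigma of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


# --------------------------------------------------------------------------
# colony-array screen
# --------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """Parameters of a simulated colony-array screen.

    Defaults mirror the screen design being emulated: 1536-format plates
    (32 x 48), four independent query isolates, two biological replicates,
    interaction thresholds applied to query/control size ratios.

    ``interaction_fractions`` is (fraction negative, fraction positive);
    ``effect_magnitudes`` the corresponding planted ratios.  ``base_sizes``
    may pin per-gene baseline sizes explicitly (useful for hand-checkable
    toy screens); otherwise baselines are lognormal around ``base_size``.
    """

    n_genes: int = 1536
    rows: int = 32
    cols: int = 48
    n_isolates: int = 4
    n_replicates: int = 2
    plate_scale_sd: float = 0.10  # relative SD of per-plate factor
    edge_effect: float = 1.1  # multiplier on outermost two rows/cols
    noise_cv: float = 0.10  # per-colony lognormal CV
    interaction_fractions: tuple[float, float] = (0.02, 0.02)
    effect_magnitudes: tuple[float, float] = (0.5, 1.5)
    base_size: float = 400.0  # px^2-equivalent baseline colony size
    gene_size_cv: float = 0.15  # gene-to-gene baseline variation
    missing_prob: float = 0.0  # per-position failed-pinning probability
    base_sizes: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if min(self.plate_scale_sd, self.noise_cv, self.gene_size_cv) < 0:
            raise ValueError("SDs and CVs must be non-negative")
        fneg, fpos = self.interaction_fractions
        if not (0 <= fneg <= 1 and 0 <= fpos <= 1 and fneg + fpos <= 1):
            raise ValueError("interaction fractions must lie in [0,1] and sum to <= 1")
        if any(m <= 0 for m in self.effect_magnitudes):
            raise ValueError("effect magnitudes must be positive")
        if not (0 <= self.missing_prob <= 1):
            raise ValueError("missing_prob must lie in [0,1]")
        if self.base_sizes is not None and len(self.base_sizes) != self.n_genes:
            raise ValueError("base_sizes length must equal n_genes")

    @property
    def positions_per_plate(self) -> int:
        return self.rows * self.cols

    @property
    def n_pages(self) -> int:
        """Plates needed per (replicate, isolate, role) to hold all genes."""
        return -(-self.n_genes // self.positions_per_plate)


@dataclass
class ScreenData:
    """All plates of a simulated screen plus its ground truth.

    ``truth`` has one row per gene: ``gene``, ``epsilon`` (planted
    multiplicative effect, 1 = none) and ``category`` in
    {negative, none, positive}.
    """

    plates: list[PlateGrid]
    truth: pd.DataFrame
    config: ScreenConfig

    def select(self, replicate: int | None = None, isolate: int | None = None,
               array_role: str | None = None) -> list[PlateGrid]:
        out = []
        for p in self.plates:
            if replicate is not None and p.replicate != replicate:
                continue
            if isolate is not None and p.isolate != isolate:
                continue
            if array_role is not None and p.array_role != array_role:
                continue
            out.append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.plates], ignore_index=True)

    def write(self, outdir) -> dict[str, str]:
        """Write colony table and truth table as TSV; returns paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        colony_path = os.path.join(outdir, "colony_sizes.tsv")
        truth_path = os.path.join(outdir, "truth_table.tsv")
        self.to_frame().to_csv(colony_path, sep="\t", index=False)
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {"colony_sizes": colony_path, "truth_table": truth_path}


def _positional_matrix(rows: int, cols: int, edge_effect: float) -> np.ndarray:
    """Multiplicative positional growth field: a boost on the outermost two
    rows/columns, where colonies face less nutrient competition."""
    pos = np.ones((rows, cols))
    edge = np.zeros((rows, cols), dtype=bool)
    edge[:2, :] = edge[-2:, :] = True
    edge[:, :2] = edge[:, -2:] = True
    pos[edge] = edge_effect
    return pos


def generate_screen(config: ScreenConfig) -> ScreenData:
    """Simulate query and control plate sets for every replicate x isolate.

    Genes are laid out row-major, in the same fixed positions on every
    plate (as with a real arrayed library).  Screens larger than one plate
    span consecutive plate pages, each page an independent physical plate
    with its own scale factor.  Control arrays carry no interaction effect.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"gene{i + 1:04d}" for i in range(n)], dtype=object)

    if config.base_sizes is not None:
        base = np.asarray(config.base_sizes, dtype=float)
    elif config.gene_size_cv > 0:
        sig = _lognormal_sigma(config.gene_size_cv)
        base = config.base_size * rng.lognormal(-0.5 * sig * sig, sig, size=n)
    else:
        base = np.full(n, config.base_size)

    # plant interaction effects
    eps = np.ones(n)
    category = np.full(n, "none", dtype=object)
    fneg, fpos = config.interaction_fractions
    n_neg = int(round(fneg * n))
    n_pos = int(round(fpos * n))
    chosen = rng.choice(n, size=n_neg + n_pos, replace=False)
    neg_idx, pos_idx = chosen[:n_neg], chosen[n_neg:]
    eps[neg_idx] = config.effect_magnitudes[0]
    eps[pos_idx] = config.effect_magnitudes[1]
    category[neg_idx] = "negative"
    category[pos_idx] = "positive"
    truth = pd.DataFrame({"gene": genes, "epsilon": eps, "category": category})

    pos_field = _positional_matrix(config.rows, config.cols, config.edge_effect)
    per_plate = config.positions_per_plate
    plate_sig = _lognormal_sigma(config.plate_scale_sd)
    noise_sig = _lognormal_sigma(config.noise_cv)

    plates: list[PlateGrid] = []
    for rep in range(1, config.n_replicates + 1):
        for iso in range(1, config.n_isolates + 1):
            for role in ("query", "control"):
                for page in range(config.n_pages):
                    lo, hi = page * per_plate, min((page + 1) * per_plate, n)
                    n_here = hi - lo
                    sizes = np.zeros(per_plate)
                    gene_layout = np.full(per_plate, "", dtype=object)
                    gene_layout[:n_here] = genes[lo:hi]
                    effect = eps[lo:hi] if role == "query" else 1.0
                    plate_factor = (
                        rng.lognormal(0.0, plate_sig) if plate_sig > 0 else 1.0
                    )
                    if noise_sig > 0:
                        noise = rng.lognormal(
                            -0.5 * noise_sig**2, noise_sig, size=n_here
                        )
                    else:
                        noise = 1.0
                    vals = base[lo:hi] * plate_factor * effect * noise
                    sizes[:n_here] = vals
                    sizes = sizes.reshape(config.rows, config.cols) * pos_field
                    empty = np.zeros(per_plate, dtype=bool)
                    empty[n_here:] = True
                    if config.missing_prob > 0:
                        failed = rng.random(n_here) < config.missing_prob
                        empty[:n_here] |= failed
                    empty = empty.reshape(config.rows, config.cols)
                    sizes[empty] = 0.0
                    plates.append(
                        PlateGrid(
                            sizes=sizes,
                            plate_id=f"rep{rep}_iso{iso}_{role}_p{page + 1}",
                            replicate=rep,
                            isolate=iso,
                            array_role=role,
                            flags={FLAG_EMPTY: empty},
                            genes=gene_layout.reshape(config.rows, config.cols),
                        )
                    )
    return ScreenData(plates=plates, truth=truth, config=config)


def render_plate_image(
    plate: PlateGrid,
    pitch: int = 20,
    margin: int = 12,
    background: float = 1500.0,
    amplitude: float = 20000.0,
    area_scale: float = 1.0,
    blur_sigma: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GridGeometry, np.ndarray]:
    """Render a plate as a photograph-like 16-bit grayscale image.

    Each colony becomes a filled disc of area ``area_scale * size`` centred
    on its grid node, so disc radius is sqrt(area_scale * size / pi).  A
    flat background, Gaussian blur and optional additive Gaussian noise
    follow.  Returns (image, true grid geometry, rasterized truth areas) —
    the truth areas are the exact pre-blur foreground pixel counts, the
    oracle for quantifier round-trip tests.

    Raises ``ValueError`` when the largest disc would not fit its grid cell
    (discs must never overlap or touch window borders).
    """
    rows, cols = plate.shape
    max_radius = math.sqrt(area_scale * plate.sizes.max() / math.pi)
    if max_radius > pitch / 2.0 - 2.0 - 2.0 * blur_sigma:
        raise ValueError(
            f"max colony radius {max_radius:.1f}px does not fit pitch {pitch}px; "
            "increase pitch or decrease area_scale"
        )
    shape = (2 * margin + rows * pitch, 2 * margin + cols * pitch)
    img = np.zeros(shape)
    row_centers = margin + pitch * (np.arange(rows) + 0.5)
    col_centers = margin + pitch * (np.arange(cols) + 0.5)
    truth_areas = np.zeros((rows, cols))
    yy, xx = np.mgrid[0:pitch, 0:pitch]  # local window coordinates
    for i in range(rows):
        for j in range(cols):
            s = plate.sizes[i, j]
            if s <= 0:
                continue
            r = math.sqrt(area_scale * s / math.pi)
            yc, xc = row_centers[i], col_centers[j]
            y0 = int(yc) - pitch // 2
            x0 = int(xc) - pitch // 2
            disc = (yy + y0 - yc) ** 2 + (xx + x0 - xc) ** 2 <= r * r
            img[y0 : y0 + pitch, x0 : x0 + pitch][disc] = amplitude
            truth_areas[i, j] = disc.sum()
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    img += background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    geometry = GridGeometry(
        row_centers=row_centers,
        col_centers=col_centers,
        row_pitch=float(pitch),
        col_pitch=float(pitch),
        half_width=pitch // 2,
    )
    return img, geometry, truth_areas


# --------------------------------------------------------------------------
# fluorescence cell fields
# --------------------------------------------------------------------------


@dataclass
class CellFieldConfig:
    """Parameters of a simulated three-channel fluorescence field.

    Cells are non-overlapping ellipses; ``axis_ratio_mean``/``sd`` set the
    major:minor axis ratio distribution (truncated at 1, so 1/0 gives
    circles), ``minor_diameter_um`` the cell width.  A ``dead_fraction``
    subset carries dead-stain signal; each live cell contains one
    vacuole-membrane ring whose outer diameter is drawn from
    ``vacuole_diameter_mean``/``sd`` (micrometres).
    """

    n_cells: int = 40
    axis_ratio_mean: float = 1.8
    axis_ratio_sd: float = 0.0
    minor_diameter_um: float = 3.5
    minor_diameter_sd_um: float = 0.0
    dead_fraction: float = 0.0
    vacuole_diameter_mean: float = 0.65
    vacuole_diameter_sd: float = 0.0
    pixel_size: float = 0.1  # um per pixel
    image_shape: tuple[int, int] = (1024, 1024)
    background: float = 400.0
    amplitude: float = 12000.0
    blur_sigma: float = 1.0
    noise_sd: float = 30.0
    wall_thickness_px: float = 2.0
    vacuole_thickness_px: float = 1.5
    max_tries_per_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dead_fraction <= 1):
            raise ValueError("dead_fraction must lie in [0,1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.axis_ratio_mean < 1:
            raise ValueError("axis ratio must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


@dataclass
class CellField:
    """Rendered channels plus ground truth for one field of cells."""

    wall: np.ndarray  # cell-wall stain (segmentation channel), uint16
    dead_stain: np.ndarray  # dead-cell stain channel, uint16
    vacuole: np.ndarray  # vacuole-membrane stain channel, uint16
    labels: np.ndarray  # truth label mask, 0 = background
    truth: pd.DataFrame  # per cell: id, centroid, axes, ratio, dead, vacuole diameter
    config: CellFieldConfig


def _place_cells(rng: np.random.Generator, cfg: CellFieldConfig) -> pd.DataFrame:
    """Sample non-overlapping ellipse parameters by bounded rejection."""
    H, W = cfg.image_shape
    placed: list[dict] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    tries_left = cfg.n_cells * cfg.max_tries_per_cell
    while len(placed) < cfg.n_cells:
        if tries_left <= 0:
            raise ValueError(
                f"could not place {cfg.n_cells} non-overlapping cells in "
                f"{cfg.image_shape} after bounded retries; enlarge the image "
                "or reduce n_cells"
            )
        tries_left -= 1
        minor_um = cfg.minor_diameter_um
        if cfg.minor_diameter_sd_um > 0:
            minor_um = max(
                0.5 * cfg.minor_diameter_um,
                rng.normal(cfg.minor_diameter_um, cfg.minor_diameter_sd_um),
            )
        ratio = cfg.axis_ratio_mean
        if cfg.axis_ratio_sd > 0:
            ratio = max(1.0, rng.normal(cfg.axis_ratio_mean, cfg.axis_ratio_sd))
        b = 0.5 * minor_um / cfg.pixel_size  # semi-minor, px
        a = ratio * b  # semi-major, px
        pad = a + 4.0
        if 2 * pad >= min(H, W):
            raise ValueError("cells are too large for the image")
        cy = rng.uniform(pad, H - pad)
        cx = rng.uniform(pad, W - pad)
        if len(placed):
            d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            if np.any(d < radii + a + 3.0):
                continue
        angle = rng.uniform(0.0, np.pi)
        placed.append(
            {"cell_id": len(placed) + 1, "cy": cy, "cx": cx, "semi_major_px": a,
             "semi_minor_px": b, "axis_ratio": ratio, "angle_rad": angle}
        )
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, a)
    return pd.DataFrame(placed)


def _ellipse_mask(shape, cy, cx, a, b, angle) -> np.ndarray:
    y0, y1 = int(max(0, cy - a - 2)), int(min(shape[0], cy + a + 3))
    x0, x1 = int(max(0, cx - a - 2)), int(min(shape[1], cx + a + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    X = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    Y = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    local = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def generate_cell_field(config: CellFieldConfig) -> CellField:
    """Render one synthetic three-channel field with known ground truth.

    Wall channel: bright elliptical outlines (the cell wall) on a dark
    background.  Dead-stain channel: filled interiors of the dead subset.
    Vacuole channel: one membrane ring per live cell; the ring's *outer*
    edge sits at the stated vacuole diameter, so the equivalent-circle
    diameter of the filled ring recovers the truth value.

    Deterministic given ``config.seed``.  Raises ``ValueError`` when cells
    cannot be placed without overlap within the retry budget.
    """
    rng = np.random.default_rng(config.seed)
    cells = _place_cells(rng, config)
    H, W = config.image_shape
    wall = np.zeros((H, W))
    dead_img = np.zeros((H, W))
    vac = np.zeros((H, W))
    labels = np.zeros((H, W), dtype=np.int32)

    dead = rng.random(len(cells)) < config.dead_fraction
    vac_d_um = np.full(len(cells), float(config.vacuole_diameter_mean))
    if config.vacuole_diameter_sd > 0:
        vac_d_um = rng.normal(
            config.vacuole_diameter_mean, config.vacuole_diameter_sd, len(cells)
        )
        vac_d_um = np.clip(vac_d_um, 0.1, None)

    rendered_d = np.zeros(len(cells))
    for k, cell in cells.iterrows():
        cy, cx = cell.cy, cell.cx
        a, b = cell.semi_major_px, cell.semi_minor_px
        outer = _ellipse_mask((H, W), cy, cx, a, b, cell.angle_rad)
        t = config.wall_thickness_px
        inner = _ellipse_mask((H, W), cy, cx, max(a - t, 1.0), max(b - t, 1.0),
                              cell.angle_rad)
        wall[outer & ~inner] = config.amplitude
        labels[outer] = int(cell.cell_id)
        if dead[k]:
            dead_img[inner] = config.amplitude
        elif config.vacuole_diameter_mean > 0:
            # vacuole membrane ring: an annulus whose midline radius is the
            # stated diameter / 2 (the dye marks the membrane itself), kept
            # inside the cell interior
            R = 0.5 * vac_d_um[k] / config.pixel_size
            R = min(R, max(b - t - 2.0, 1.0))
            rendered_d[k] = 2.0 * R * config.pixel_size
            half_t = 0.5 * config.vacuole_thickness_px
            y0, y1 = int(cy - R - 4), int(cy + R + 5)
            x0, x1 = int(cx - R - 4), int(cx + R + 5)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            rr = np.hypot(yy - cy, xx - cx)
            ring = np.abs(rr - R) <= half_t
            vac[y0:y1, x0:x1][ring] = config.amplitude

    def _finish(channel: np.ndarray, sub_seed: int) -> np.ndarray:
        out = channel.copy()
        if config.blur_sigma > 0:
            out = ndimage.gaussian_filter(out, config.blur_sigma)
        out += config.background
        if config.noise_sd > 0:
            sub = np.random.default_rng((config.seed, sub_seed))
            out += sub.normal(0.0, config.noise_sd, size=out.shape)
        return np.clip(out, 0, 65535).astype(np.uint16)

    truth = cells.copy()
    truth["dead"] = dead
    truth["vacuole_diameter_um"] = np.where(dead, np.nan, rendered_d)
    return CellField(
        wall=_finish(wall, 1),
        dead_stain=_finish(dead_img, 2),
        vacuole=_finish(vac, 3),
        labels=labels,
        truth=truth,
        config=config,
    )
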