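"""Phenotype quantification: segmentation against truth masks, the
elongation statistic and its geometric anchors, viability counting and
vacuole diameters."""

import numpy as np
import pytest
from scipy.integrate import quad
from skimage.draw import disk as draw_disk

from sgaphen.phenotype_quant import (
    elongation_from_geometry,
    elongation_score,
    measure_vacuoles,
    score_viability,
    segment_cells,
    summarize_elongation,
)
from sgaphen.synthetic_data import CellFieldConfig, generate_cell_field


def _disc_mask(radius, pad=4):
    n = 2 * (radius + pad) + 1
    img = np.zeros((n, n), dtype=bool)
    rr, cc = draw_disk((n // 2, n // 2), radius)
    img[rr, cc] = True
    return img


def _ellipse_mask(a, b, angle_deg=0.0, pad=4):
    n = 2 * (a + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n] - n // 2
    th = np.deg2rad(angle_deg)
    X = xx * np.cos(th) + yy * np.sin(th)
    Y = -xx * np.sin(th) + yy * np.cos(th)
    return (X / a) ** 2 + (Y / b) ** 2 <= 1.0


class TestSegmentation:
    def test_forty_ellipses_found_with_high_iou(self, ellipse_field):
        masks = segment_cells(ellipse_field.wall)
        assert len(masks) == 40
        labels = ellipse_field.labels
        for m in masks:
            full = np.zeros(labels.shape, bool)
            r0, c0, r1, c1 = m.bbox
            full[r0:r1, c0:c1] = m.image
            truth_label = np.bincount(labels[full]).argmax()
            truth = labels == truth_label
            iou = (full & truth).sum() / (full | truth).sum()
            assert iou >= 0.9

    def test_blank_image_gives_empty_list(self):
        with pytest.warns(UserWarning, match="no cells"):
            assert segment_cells(np.full((200, 200), 400.0)) == []

    def test_border_touching_cell_excluded(self):
        img = np.full((200, 200), 400.0)
        # one interior cell outline, one crossing the border
        for cy, cx in [(100, 100), (5, 100)]:
            yy, xx = np.mgrid[0:200, 0:200]
            rr = np.hypot(yy - cy, xx - cx)
            img[(rr <= 30) & (rr >= 27)] = 12000.0
        masks = segment_cells(img, min_area=100)
        assert len(masks) == 1
        assert abs(masks[0].centroid[0] - 100) < 2


class TestElongation:
    def test_disc_scores_near_zero(self):
        assert elongation_score(_disc_mask(50)) <= 0.02
        assert elongation_score(_disc_mask(30)) <= 0.02

    def test_rectangle_closed_form(self):
        # continuous 4w x w rectangle (w = 1): area 4, perimeter 10
        assert elongation_from_geometry(4.0, 10.0) == pytest.approx(
            1 - 16 * np.pi / 100, abs=1e-12
        )

    def test_ellipse_matches_arc_length_quadrature(self):
        """Rasterized 2:1 ellipse vs the continuum value computed by
        numerical quadrature of the ellipse arc length."""
        a, b = 100.0, 50.0
        arc = 4 * quad(
            lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0, np.pi / 2
        )[0]
        expected = 1 - 4 * np.pi * (np.pi * a * b) / arc**2
        got = elongation_score(_ellipse_mask(100, 50))
        assert got == pytest.approx(expected, abs=0.01)

    def test_rotation_invariance_90_degrees(self):
        m = _ellipse_mask(80, 40)
        assert elongation_score(m) == pytest.approx(
            elongation_score(m.T), abs=0.02
        )

    def test_scale_stability_at_double_resolution(self):
        s1 = elongation_score(_ellipse_mask(60, 30))
        s2 = elongation_score(_ellipse_mask(120, 60))
        assert abs(s1 - s2) < 0.01

    def test_monotone_in_axis_ratio(self):
        scores = [elongation_score(_ellipse_mask(int(40 * q), 40))
                  for q in (1.0, 1.5, 2.0, 3.0)]
        assert all(x < y for x, y in zip(scores, scores[1:]))

    def test_degenerate_perimeter_rejected(self):
        with pytest.raises(ValueError):
            elongation_from_geometry(10.0, 0.0)
        with pytest.raises(ValueError):
            elongation_score(np.zeros((5, 5), dtype=bool))


class TestSummaries:
    def test_constant_scores_zero_sem(self):
        out = summarize_elongation([np.full(30, 0.25)] * 5)
        assert out["mean"] == pytest.approx(0.25)
        assert out["sem"] == 0.0
        assert out["n_datasets"] == 5

    def test_two_dataset_sem(self):
        out = summarize_elongation([np.full(30, 0.2), np.full(30, 0.3)])
        assert out["mean"] == pytest.approx(0.25)
        assert out["sem"] == pytest.approx(0.05)

    def test_short_dataset_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="rejected"):
            out = summarize_elongation([np.full(30, 0.2), np.full(10, 0.9)])
        assert out["n_datasets"] == 1

    def test_flat_input_chunked_consecutively(self):
        scores = np.concatenate([np.full(30, 0.1), np.full(30, 0.3)])
        out = summarize_elongation(scores, n_per_dataset=30)
        np.testing.assert_allclose(out["dataset_means"], [0.1, 0.3])

    def test_populations_separate_by_two_sem(self, ellipse_field, circle_field):
        se = [elongation_score(m) for m in segment_cells(ellipse_field.wall)]
        sc = [elongation_score(m) for m in segment_cells(circle_field.wall)]
        oe = summarize_elongation(se, n_per_dataset=10)
        oc = summarize_elongation(sc, n_per_dataset=6)
        assert oc["mean"] + 2 * oc["sem"] < oe["mean"] - 2 * oe["sem"]


class TestViability:
    def test_count_arithmetic(self):
        rec = score_viability(500, 10)
        assert rec.viability_percent == pytest.approx(98.0)
        assert score_viability(500, 0).viability_percent == 100.0

    def test_dead_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            score_viability(10, 11)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning, match="no cells"):
            score_viability(np.full((100, 100), 400.0), np.full((100, 100), 400.0))

    def test_image_counts_match_truth(self):
        cfg = CellFieldConfig(n_cells=60, axis_ratio_mean=1.5,
                              minor_diameter_um=3.0, pixel_size=0.2,
                              image_shape=(600, 600), dead_fraction=0.3,
                              vacuole_diameter_mean=0.0, seed=13)
        fld = generate_cell_field(cfg)
        rec = score_viability(fld.wall, fld.dead_stain, n_scored=60)
        assert rec.n_total == 60
        assert rec.n_dead == int(fld.truth["dead"].sum())

    def test_intensity_scaling_leaves_counts(self):
        cfg = CellFieldConfig(n_cells=30, minor_diameter_um=3.0, pixel_size=0.2,
                              image_shape=(500, 500), dead_fraction=0.4,
                              vacuole_diameter_mean=0.0, seed=14)
        fld = generate_cell_field(cfg)
        r1 = score_viability(fld.wall, fld.dead_stain)
        r2 = score_viability(fld.wall.astype(float) * 2.5,
                             fld.dead_stain.astype(float) * 2.5)
        assert (r1.n_total, r1.n_dead) == (r2.n_total, r2.n_dead)


class TestVacuoles:
    def test_single_ring_arithmetic(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        rr = np.hypot(yy - 32, xx - 32)
        img[np.abs(rr - 10) <= 0.75] = 1000.0
        vacs = measure_vacuoles(img, pixel_size=0.05)
        assert len(vacs) == 1
        assert vacs[0].diameter_um == pytest.approx(1.0, abs=0.05)

    def test_generator_round_trip(self):
        cfg = CellFieldConfig(n_cells=40, axis_ratio_mean=1.6,
                              minor_diameter_um=2.6, pixel_size=0.05,
                              image_shape=(1280, 1280),
                              vacuole_diameter_mean=0.65, seed=8)
        fld = generate_cell_field(cfg)
        vacs = measure_vacuoles(fld.vacuole, 0.05)
        mean_d = np.mean([v.diameter_um for v in vacs])
        assert mean_d == pytest.approx(0.65, abs=2 * 0.05)

    def test_blank_channel_raises(self):
        with pytest.raises(ValueError, match="no vacuoles"):
            measure_vacuoles(np.full((200, 200), 400.0), 0.05)
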