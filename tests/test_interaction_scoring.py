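"""Interaction scoring: normalization, ratios, isolate averaging, threshold
calls, replicate intersection — including a brute-force recomputation of
the whole pipeline on a toy screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sgaphen.colony_quant import PlateGrid
from sgaphen.interaction_scoring import (
    classify_interactions,
    compute_ratios,
    hub_fraction,
    intersect_replicates,
    mean_over_isolates,
    normalize_plate,
    recovery_metrics,
    score_screen,
)


def _plate(sizes, **kw):
    return PlateGrid(sizes=np.asarray(sizes, dtype=float), **kw)


class TestNormalize:
    def test_toy_midpoint_median(self):
        norm = normalize_plate(_plate([[100.0, 200.0], [300.0, 400.0]]))
        assert norm.median_size == 250.0
        np.testing.assert_allclose(norm.values, [[0.4, 0.8], [1.2, 1.6]])

    def test_scale_invariance(self):
        p = _plate([[100.0, 200.0], [300.0, 400.0]])
        q = _plate(p.sizes * 17.3)
        np.testing.assert_allclose(normalize_plate(p).values,
                                   normalize_plate(q).values, rtol=1e-12)

    def test_flagged_position_excluded_from_median(self):
        flags = {"empty": np.array([[True, False], [False, False]])}
        norm = normalize_plate(_plate([[100.0, 200.0], [300.0, 400.0]], flags=flags))
        assert norm.median_size == 300.0  # median of 200,300,400
        assert np.isnan(norm.values[0, 0])
        np.testing.assert_allclose(norm.values[0, 1], 200 / 300)

    def test_zero_size_treated_as_missing(self):
        norm = normalize_plate(_plate([[0.0, 200.0], [300.0, 400.0]]))
        assert np.isnan(norm.values[0, 0])
        assert norm.median_size == 300.0

    def test_all_flagged_raises(self):
        with pytest.raises(ValueError, match="no retained"):
            normalize_plate(_plate([[0.0, 0.0], [0.0, 0.0]]))

    def test_retained_median_is_one(self):
        rng = np.random.default_rng(0)
        p = _plate(rng.lognormal(5, 0.4, (8, 12)))
        norm = normalize_plate(p)
        assert np.nanmedian(norm.values) == pytest.approx(1.0, abs=1e-12)


class TestRatios:
    def _pair(self, q, c, layout=None):
        gq = _plate(q, genes=layout)
        gc = _plate(c, genes=layout)
        return normalize_plate(gq), normalize_plate(gc)

    def test_simple_ratio(self):
        layout = np.array([["g1", "g2"], ["g3", "g4"]], dtype=object)
        nq, nc = self._pair([[60.0, 100.0], [100.0, 140.0]],
                            [[100.0, 100.0], [100.0, 100.0]], layout)
        r = compute_ratios(nq, nc).set_index("gene")["ratio"]
        assert r["g1"] == pytest.approx(0.6)

    def test_missing_control_recorded(self):
        layout = np.array([["g1", "g2"], ["g3", "g4"]], dtype=object)
        nq, nc = self._pair([[60.0, 100.0], [100.0, 140.0]],
                            [[0.0, 100.0], [100.0, 100.0]], layout)
        out = compute_ratios(nq, nc).set_index("gene")
        assert np.isnan(out.loc["g1", "ratio"])
        assert out.loc["g1", "reason"] == "control_missing"

    def test_control_floor(self):
        layout = np.array([["g1", "g2", "g3", "g4", "g5"]], dtype=object)
        nq = normalize_plate(_plate([[100.0] * 5], genes=layout))
        nc = normalize_plate(_plate([[0.1, 100.0, 100.0, 100.0, 100.0]],
                                    genes=layout))
        out = compute_ratios(nq, nc).set_index("gene")
        # normalized control for g1 is 0.001 < floor 0.05
        assert out.loc["g1", "reason"] == "control_below_floor"
        assert np.isnan(out.loc["g1", "ratio"])

    def test_layout_mismatch_raises(self):
        nq, _ = self._pair([[1.0, 2.0]], [[1.0, 2.0]],
                           np.array([["a", "b"]], dtype=object))
        _, nc = self._pair([[1.0], [2.0]], [[1.0], [2.0]],
                           np.array([["a"], ["b"]], dtype=object))
        with pytest.raises(ValueError, match="shape"):
            compute_ratios(nq, nc)


class TestMeanOverIsolates:
    def _tables(self, ratio_lists):
        return [pd.DataFrame({"gene": [f"g{i+1}" for i in range(len(r))],
                              "ratio": r, "reason": ""})
                for r in ratio_lists]

    def test_arithmetic_mean(self):
        tabs = self._tables([[0.70], [0.75], [0.80], [0.75]])
        out = mean_over_isolates(tabs)
        assert out.loc[0, "mean_ratio"] == pytest.approx(0.75)
        assert out.loc[0, "n_isolates_used"] == 4

    def test_missing_isolates_tolerated_at_min_two(self):
        tabs = self._tables([[0.70], [np.nan], [0.80], [np.nan]])
        out = mean_over_isolates(tabs, min_isolates=2)
        assert out.loc[0, "mean_ratio"] == pytest.approx(0.75)
        assert out.loc[0, "n_isolates_used"] == 2

    def test_all_missing_dropped_with_reason(self):
        tabs = self._tables([[np.nan], [np.nan]])
        out = mean_over_isolates(tabs)
        assert bool(out.loc[0, "dropped"])
        assert out.loc[0, "reason"] == "no_ratio"
        assert np.isnan(out.loc[0, "mean_ratio"])


class TestClassify:
    @pytest.mark.parametrize(
        "ratio,call",
        [(0.79, "negative"), (0.80, "none"), (1.00, "none"),
         (1.20, "none"), (1.21, "positive")],
    )
    def test_threshold_semantics(self, ratio, call):
        """Strict inequalities: <0.8 negative, >1.2 positive, else none."""
        df = pd.DataFrame({"gene": ["g"], "mean_ratio": [ratio]})
        assert classify_interactions(df).loc[0, "call"] == call

    def test_invalid_thresholds(self):
        df = pd.DataFrame({"gene": ["g"], "mean_ratio": [1.0]})
        with pytest.raises(ValueError):
            classify_interactions(df, low=1.2, high=0.8)

    @given(st.floats(min_value=1e-6, max_value=100.0))
    def test_calls_partition_positive_ratios(self, ratio):
        df = pd.DataFrame({"gene": ["g"], "mean_ratio": [ratio]})
        call = classify_interactions(df).loc[0, "call"]
        expected = "negative" if ratio < 0.8 else ("positive" if ratio > 1.2 else "none")
        assert call == expected


class TestIntersect:
    def _calls(self, *calls):
        return [pd.DataFrame({"gene": ["g"], "call": [c]}) for c in calls]

    def test_concordant_negative_retained(self):
        out = intersect_replicates(self._calls("negative", "negative"))
        assert out.loc[0, "call"] == "negative" and bool(out.loc[0, "robust"])

    def test_single_replicate_call_excluded(self):
        out = intersect_replicates(self._calls("negative", "none"))
        assert out.loc[0, "call"] == "none" and not out.loc[0, "robust"]

    def test_discordant_flagged(self):
        out = intersect_replicates(self._calls("negative", "positive"))
        assert not out.loc[0, "robust"]
        assert bool(out.loc[0, "discordant"])

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            intersect_replicates(self._calls("negative"))

    def test_idempotent_and_order_invariant(self):
        reps = [
            pd.DataFrame({"gene": ["a", "b", "c"],
                          "call": ["negative", "positive", "none"]}),
            pd.DataFrame({"gene": ["a", "b", "c"],
                          "call": ["negative", "none", "positive"]}),
        ]
        out1 = intersect_replicates(reps)
        out2 = intersect_replicates(reps[::-1])
        assert (out1["robust"] == out2["robust"]).all()
        assert (out1["call"] == out2["call"]).all()
        # feeding the consensus back in with itself changes nothing
        cons = out1[["gene", "call"]]
        again = intersect_replicates([cons, cons])
        assert (again["call"] == out1["call"]).all()


class TestHubFraction:
    def test_hub_membership_worked_example(self):
        negatives = [f"n{i}" for i in range(131)]
        hub = set(negatives[:39]) | {"extra1", "extra2"}
        assert hub_fraction(negatives, hub) == (39, 29.7)

    def test_zero_and_full_overlap(self):
        negs = [f"n{i}" for i in range(131)]
        assert hub_fraction(negs, set()) == (0, 0.0)
        assert hub_fraction(negs, set(negs)) == (131, 100.0)

    def test_empty_negative_set_raises(self):
        with pytest.raises(ValueError):
            hub_fraction([], {"a"})

    @given(st.integers(1, 200), st.integers(0, 200))
    def test_percent_truncated_one_decimal(self, n_neg, n_hub):
        negs = [f"n{i}" for i in range(n_neg)]
        hub = set(negs[: min(n_hub, n_neg)])
        n_in, pct = hub_fraction(negs, hub)
        assert n_in == min(n_hub, n_neg)
        exact = 100.0 * n_in / n_neg
        assert 0 <= exact - pct < 0.1 + 1e-9
        assert pct == np.floor(exact * 10) / 10


def test_brute_force_pipeline_oracle(toy_screen):
    """Full pipeline on a 16-gene screen vs direct recomputation of every
    formula with plain numpy (independent of the package's code path)."""
    robust, rep_tables = score_screen(toy_screen.plates)

    # --- brute-force recomputation ---------------------------------------
    gene_order = toy_screen.truth["gene"].tolist()
    expected_calls = {}
    for rep in (1, 2):
        mean_ratios = {}
        for g_i, gene in enumerate(gene_order):
            per_isolate = []
            for iso in (1, 2):
                q = toy_screen.select(rep, iso, "query")[0]
                c = toy_screen.select(rep, iso, "control")[0]
                qv = q.sizes.ravel()[g_i] / np.median(q.sizes[q.sizes > 0])
                cv = c.sizes.ravel()[g_i] / np.median(c.sizes[c.sizes > 0])
                per_isolate.append(qv / cv)
            mean_ratios[gene] = float(np.mean(per_isolate))
        for gene, m in mean_ratios.items():
            call = "negative" if m < 0.8 else ("positive" if m > 1.2 else "none")
            expected_calls.setdefault(gene, []).append(call)
    expected = {
        g: (calls[0] if len(set(calls)) == 1 and calls[0] != "none" else "none")
        for g, calls in expected_calls.items()
    }

    got = robust.set_index("gene")["call"].to_dict()
    assert got == expected
    # and the planted truth is recovered exactly (zero-noise screen)
    rec = recovery_metrics(robust, toy_screen.truth)
    assert (rec["recall"] == 1.0).all() and (rec["precision"] == 1.0).all()


def test_single_plate_scale_change_changes_no_call(toy_screen):
    robust1, _ = score_screen(toy_screen.plates)
    import copy

    plates = copy.deepcopy(toy_screen.plates)
    plates[3].sizes *= 5.0
    robust2, _ = score_screen(plates)
    assert (robust1["call"] == robust2["call"]).all()
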