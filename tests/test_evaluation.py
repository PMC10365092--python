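"""Metric oracles: confusion-based overlap metrics, surface distances,
VVC, Spearman correlation, residual maps."""

import numpy as np
import pytest

import tractuq as tq
from tractuq.errors import ShapeError
from tractuq.evaluation import ConfusionCounts
from tractuq.inference import ProbabilityStack


class TestConfusion:
    def test_perfect_agreement(self):
        m = np.zeros(10, dtype=bool)
        m[:4] = True
        c = tq.confusion(m, m)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 6, 0, 0)

    def test_empty_prediction(self):
        t = np.zeros(10, dtype=bool)
        t[:3] = True
        c = tq.confusion(np.zeros(10, dtype=bool), t)
        assert c.fn == 3 and c.tp == 0

    def test_counts_conserve_grid_size(self, rng):
        p = rng.random((5, 5, 5)) > 0.5
        t = rng.random((5, 5, 5)) > 0.5
        assert tq.confusion(p, t).total == 125

    def test_eval_mask_restricts(self, rng):
        p = rng.random((4, 4, 4)) > 0.5
        t = rng.random((4, 4, 4)) > 0.5
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0] = True
        assert tq.confusion(p, t, m).total == 16


def _brute_force_metrics(pred, truth):
    """Independent elementwise oracle for all overlap metrics."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    d = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return d, sens, spec


class TestOverlapMetrics:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        a[0] = True
        b = np.zeros((3, 3, 3), dtype=bool)
        b[2] = True
        same = tq.confusion(a, a)
        assert tq.dice(same) == 1.0 and tq.sensitivity(same) == 1.0
        assert tq.dice(tq.confusion(a, b)) == 0.0

    def test_conventions_differ_as_designed(self):
        # truth=[1,1,1,0], pred=[1,0,0,0]
        truth = np.array([1, 1, 1, 0], dtype=bool)
        pred = np.array([1, 0, 0, 0], dtype=bool)
        c = tq.confusion(pred, truth)
        assert tq.sensitivity(c, "standard") == pytest.approx(1 / 3)
        assert tq.sensitivity(c, "as_printed") == pytest.approx(1.0)

    def test_both_empty_flagged_as_perfect(self):
        z = np.zeros((2, 2, 2), dtype=bool)
        assert tq.dice(tq.confusion(z, z)) == 1.0

    def test_agrees_with_bruteforce_on_random_3cube_pairs(self, rng):
        for _ in range(200):
            pred = rng.random((3, 3, 3)) > rng.uniform(0.2, 0.8)
            truth = rng.random((3, 3, 3)) > rng.uniform(0.2, 0.8)
            c = tq.confusion(pred, truth)
            d, sens, spec = _brute_force_metrics(pred, truth)
            assert tq.dice(c) == pytest.approx(d)
            if not np.isnan(sens):
                assert tq.sensitivity(c) == pytest.approx(sens)
            if not np.isnan(spec):
                assert tq.specificity(c) == pytest.approx(spec)


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        sd = tq.surface_distances(m, m)
        assert np.all(sd.union == 0)
        assert tq.hausdorff(sd) == 0 and tq.assd(sd) == 0

    def test_single_voxel_pair_distance(self):
        a = np.zeros((7, 3, 3), dtype=bool)
        b = np.zeros((7, 3, 3), dtype=bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        sd = tq.surface_distances(a, b)
        assert np.allclose(sd.pred_to_truth, 3.0)
        assert np.allclose(sd.truth_to_pred, 3.0)

    def test_anisotropic_spacing_scales_distance(self):
        a = np.zeros((3, 3, 5), dtype=bool)
        b = np.zeros((3, 3, 5), dtype=bool)
        a[1, 1, 1] = True
        b[1, 1, 2] = True
        sd = tq.surface_distances(a, b, spacing=(1, 1, 2))
        assert tq.hausdorff(sd) == pytest.approx(2.0)

    def test_hand_mean_and_max_of_union(self):
        sd = tq.evaluation.SurfaceDistanceSet(
            pred_to_truth=np.array([1.0, 3.0]), truth_to_pred=np.array([2.0])
        )
        assert tq.hausdorff(sd) == 3.0
        assert tq.assd(sd) == pytest.approx(2.0)

    def test_hausdorff_at_least_assd_and_symmetric(self, rng):
        a = rng.random((6, 6, 6)) > 0.7
        b = rng.random((6, 6, 6)) > 0.7
        a[3, 3, 3] = b[2, 2, 2] = True  # ensure non-empty
        sd_ab = tq.surface_distances(a, b)
        sd_ba = tq.surface_distances(b, a)
        assert tq.hausdorff(sd_ab) >= tq.assd(sd_ab)
        assert tq.hausdorff(sd_ab) == pytest.approx(tq.hausdorff(sd_ba))

    def test_empty_mask_rejected(self):
        m = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            tq.surface_distances(np.zeros_like(m), m)


def _stack_from_volumes(volumes, side=6):
    """Stack whose pass t has exactly volumes[t] foreground voxels."""
    t = len(volumes)
    probs = np.zeros((t, side, side, side, 1))
    for i, v in enumerate(volumes):
        flat = probs[i, ..., 0].reshape(-1)
        flat[:v] = 1.0
    return ProbabilityStack(probs=probs, mode="ttd")


class TestVVC:
    def test_identical_passes_zero(self):
        series, v = tq.vvc(_stack_from_volumes([5, 5, 5]))
        assert v == 0.0

    def test_hand_example_population_sd(self):
        series, v = tq.vvc(_stack_from_volumes([2, 4]))
        assert series.mean == 3.0 and series.sd == 1.0
        assert v == pytest.approx(1 / 3)

    def test_scale_invariance(self):
        _, a = tq.vvc(_stack_from_volumes([2, 4, 6]))
        _, b = tq.vvc(_stack_from_volumes([20, 40, 60]))
        assert a == pytest.approx(b)

    def test_zero_mean_volume_is_nan(self):
        _, v = tq.vvc(_stack_from_volumes([0, 0]))
        assert np.isnan(v)


class TestMeanPassDice:
    def test_all_passes_perfect(self):
        truth = np.zeros((6, 6, 6), dtype=bool)
        truth.reshape(-1)[:5] = True
        stack = _stack_from_volumes([5, 5, 5])
        assert tq.mean_pass_dice(stack, truth) == 1.0

    def test_alternating_passes(self):
        truth = np.zeros((6, 6, 6), dtype=bool)
        truth.reshape(-1)[:4] = True
        probs = np.zeros((2, 6, 6, 6, 1))
        probs[0, ..., 0] = truth  # perfect
        probs[1].reshape(-1)[-4:] = 1.0  # disjoint
        stack = ProbabilityStack(probs=probs, mode="ttd")
        assert tq.mean_pass_dice(stack, truth) == pytest.approx(0.5)


class TestSpearman:
    def test_perfect_monotone_limits(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert tq.spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert tq.spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_average_ranks_hand_value(self):
        assert tq.spearman([1, 2, 3], [2, 2, 3]) == pytest.approx(
            0.866025, abs=1e-6
        )

    def test_zero_variance_is_nan(self):
        assert np.isnan(tq.spearman([1, 2, 3], [5, 5, 5]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tq.spearman([1, 2], [3, 4])


class TestSubjectReport:
    def test_one_row_per_tract_with_expected_columns(self, rng):
        from tractuq.core import TractMaskSet
        from tractuq.evaluation import aggregate_report, evaluate_subject

        probs = rng.random((4, 8, 8, 8, 2)) * 0.4
        probs[:, 2:6, 2:6, 2:6, 0] += 0.5  # tract 0 confidently present
        stack = ProbabilityStack(probs=probs, mode="hybrid")
        truth = np.zeros((8, 8, 8, 2), dtype=bool)
        truth[2:6, 2:6, 2:6, 0] = True
        truth[1:3, 1:3, 1:3, 1] = True
        report = evaluate_subject(stack, TractMaskSet(truth), subject_id="s0")
        assert len(report) == 2
        for col in ("dice", "sensitivity", "specificity", "hausdorff_mm",
                    "assd_mm", "vvc", "mean_pass_dice"):
            assert col in report.columns
        assert report.loc[0, "dice"] > report.loc[1, "dice"]
        agg = aggregate_report(report)
        assert {"mean", "sd"} == set(agg.columns)


class TestResidualMap:
    def test_perfect_probabilities_zero(self):
        truth = np.zeros((3, 3, 3, 1))
        assert np.all(tq.residual_map(truth, truth) == 0)

    def test_signed_values(self):
        truth = np.ones((1, 1, 1, 1))
        r = tq.residual_map(truth, np.full((1, 1, 1, 1), 0.3))
        assert r[0, 0, 0, 0] == pytest.approx(0.7)

    def test_complement_symmetry(self, rng):
        truth = (rng.random((3, 3, 3, 2)) > 0.5).astype(float)
        prob = rng.random((3, 3, 3, 2))
        r = tq.residual_map(truth, prob)
        r_comp = tq.residual_map(1 - truth, 1 - prob)
        assert np.allclose(r_comp, -r)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            tq.residual_map(np.zeros((2, 2, 2, 1)), np.zeros((2, 2, 2, 2)))
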