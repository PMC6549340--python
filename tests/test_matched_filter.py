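"""Matched-filter response, the two counting algorithms, and threshold tuning."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from combiscreen.fixtures import make_background, plant_objects, random_positions, ring_template
from combiscreen.matched_filter import (
    MatchedFilterModel,
    NotTunedError,
    OverfitError,
    Prototype,
    build_filter,
    filter_response,
    frame_count,
    position_count,
    taboo_count,
    tune_threshold,
    well_counts,
)


def brute_force_response(frame, w):
    """Independent double-loop oracle for the sliding dot product."""
    nr, nc = w.shape
    H, W = frame.shape
    out = np.empty((H - nr + 1, W - nc + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            out[r, c] = float(np.sum(w * frame[r : r + nr, c : c + nc]))
    return out


def make_model(template, level=100.0):
    return build_filter(Prototype(template + level), level)


class TestBuildFilter:
    def test_coefficients_are_signal_minus_background(self):
        s = np.full((5, 5), 10.0)
        s[2, 2] = 10.5
        with np.errstate(all="ignore"):
            model = build_filter(Prototype(s), 10.0)
        expected = np.zeros((5, 5))
        expected[2, 2] = 0.5
        assert np.array_equal(model.w, expected)

    def test_degenerate_prototype_warns(self):
        with pytest.warns(UserWarning):
            build_filter(Prototype(np.full((4, 4), 3.0)), 3.0)

    def test_case_study_like_shape(self):
        patch = np.random.default_rng(0).normal(100, 10, (33, 32))
        model = build_filter(Prototype(patch), 100.0)
        assert model.w.shape == (33, 32)

    def test_tiny_patch_rejected(self):
        with pytest.raises(ValueError):
            Prototype(np.ones((2, 5)))


class TestFilterResponse:
    def test_pure_background_closed_form(self, small_template):
        model = make_model(small_template)
        frame = np.full((30, 30), 100.0)
        resp = filter_response(frame, model)
        assert np.allclose(resp, model.w.sum() * 100.0)

    def test_oracle_equivalence_seeded_sweep(self, small_template):
        model = make_model(small_template)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = make_background((64, 64), 100, 5, rng)
            resp = filter_response(frame, model)
            assert resp.shape == (64 - 11 + 1, 64 - 10 + 1)
            assert np.allclose(resp, brute_force_response(frame, model.w), atol=1e-9)

    def test_peak_at_planted_position(self, small_template):
        frame = np.full((100, 100), 100.0)
        frame, _ = plant_objects(frame, small_template, [(50, 40)])
        model = make_model(small_template)
        resp = filter_response(frame, model)
        r, c = np.unravel_index(np.argmax(resp), resp.shape)
        # response coordinates are patch corners; the center convention
        # rounds even dimensions toward the top-left
        assert (r + 5, c + 4) == (50, 40)

    def test_contrast_linearity(self, small_template):
        model = make_model(small_template)
        rng = np.random.default_rng(11)
        frame = make_background((40, 40), 100, 3, rng)
        base = filter_response(np.full((40, 40), 100.0), model)
        resp1 = filter_response(frame, model) - base
        doubled = 100.0 + 2.0 * (frame - 100.0)
        resp2 = filter_response(doubled, model) - base
        assert np.allclose(resp2, 2.0 * resp1, atol=1e-8)

    def test_small_frame_rejected(self, small_template):
        with pytest.raises(ValueError):
            filter_response(np.ones((5, 5)), make_model(small_template))


def planted_fixture(small_template, n_objects, seed, shape=(64, 64)):
    rng = np.random.default_rng(seed)
    frame = make_background(shape, 100, 2, rng)
    positions = random_positions(n_objects, shape, small_template.shape, rng)
    frame, truth = plant_objects(frame, small_template, positions)
    return frame, truth


def detection_threshold(template, level=100.0, prominence=0.6):
    """A threshold between the background response and the planted peaks."""
    peak = float((template**2).sum())
    background = float(template.sum() * level)
    return background + prominence * peak


class TestCounting:
    def test_all_below_threshold(self, small_template):
        resp = np.zeros((20, 20))
        count, centers = taboo_count(resp, 1.0, small_template.shape)
        assert (count, centers) == (0, [])
        assert position_count(resp, 1.0) == 0

    def test_single_object(self, small_template):
        frame, truth = planted_fixture(small_template, 1, seed=0)
        model = make_model(small_template)
        tau = detection_threshold(small_template)
        result = frame_count(frame, model, tau)
        assert result.taboo_count == result.position_count == 1
        (det_r, det_c), (true_r, true_c) = result.centers[0], truth["centers"][0]
        assert abs(det_r - true_r) <= 1 and abs(det_c - true_c) <= 1

    @pytest.mark.parametrize("seed", range(50))
    def test_separated_objects_recovered_exactly(self, small_template, seed):
        """Both counters find every planted object when separations exceed
        the patch diagonal."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 6))
        frame, truth = planted_fixture(small_template, n, seed=seed + 1000)
        model = make_model(small_template)
        tau = detection_threshold(small_template)
        result = frame_count(frame, model, tau)
        assert result.taboo_count == truth["count"]
        assert result.position_count == truth["count"]

    def test_position_count_vertical_pass(self):
        """Two blobs sharing columns but not rows are split by the row pass."""
        resp = np.zeros((30, 30))
        resp[2:5, 10:14] = 1.0
        resp[20:23, 11:15] = 1.0
        assert position_count(resp, 0.5) == 2

    def test_position_count_matches_connected_components(self):
        """On blob patterns whose projections do not merge, the two-pass count
        equals the connected-component count."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            resp = np.zeros((40, 40))
            n_blobs = int(rng.integers(1, 5))
            placed = 0
            for _ in range(50):
                if placed == n_blobs:
                    break
                r, c = rng.integers(2, 34, 2)
                if not resp[max(0, r - 5) : r + 9, max(0, c - 5) : c + 9].any():
                    resp[r : r + 3, c : c + 3] = 1.0
                    placed += 1
            n_cc = cc_label(resp > 0.5)[1]
            assert n_cc == placed
            # well-separated square blobs: interval projection equals the
            # connected-component oracle unless projections merge blobs
            assert position_count(resp, 0.5) <= n_cc
            assert position_count(resp, 0.5) >= 1 if placed else position_count(resp, 0.5) == 0

    def test_taboo_centers_separated(self, small_template):
        frame, _ = planted_fixture(small_template, 4, seed=3)
        model = make_model(small_template)
        resp = filter_response(frame, model)
        _, centers = taboo_count(resp, detection_threshold(small_template), (11, 10))
        for i, (r1, c1) in enumerate(centers):
            for r2, c2 in centers[i + 1 :]:
                assert abs(r1 - r2) > 5 or abs(c1 - c2) > 4

    def test_agreement_property(self, small_template):
        """The two algorithms agree within one count on separated fixtures."""
        model = make_model(small_template)
        tau = detection_threshold(small_template)
        for seed in range(20):
            frame, _ = planted_fixture(small_template, 3, seed=200 + seed)
            res = frame_count(frame, model, tau)
            assert abs(res.taboo_count - res.position_count) <= 1


class TestWellCounts:
    def test_requires_threshold(self, small_template):
        model = make_model(small_template)
        with pytest.raises(NotTunedError):
            frame_count(np.full((30, 30), 100.0), model)

    def test_blank_frame_counts_zero(self, small_template):
        model = make_model(small_template)
        model.threshold = detection_threshold(small_template)
        res = frame_count(np.full((30, 30), 100.0), model)
        assert (res.taboo_count, res.position_count, res.mean_count) == (0, 0, 0.0)

    def test_monotone_planted_schedule_recovered(self, small_template):
        model = make_model(small_template)
        model.threshold = detection_threshold(small_template)
        frames = []
        schedule = list(range(6))
        for i, n in enumerate(schedule):
            frame, _ = planted_fixture(small_template, n, seed=500 + i, shape=(96, 96))
            frames.append(frame)
        counts = well_counts(frames, model)
        assert len(counts) == len(schedule)
        assert np.all(np.abs(counts - np.array(schedule, float)) <= 1.0)

    def test_order_invariance(self, small_template):
        model = make_model(small_template)
        model.threshold = detection_threshold(small_template)
        frames = [planted_fixture(small_template, k, seed=600 + k)[0] for k in range(4)]
        forward = well_counts(frames, model)
        backward = well_counts(frames[::-1], model)
        assert np.array_equal(forward, backward[::-1])

    def test_inconsistent_sizes_rejected(self, small_template):
        model = make_model(small_template)
        model.threshold = 0.0
        with pytest.raises(ValueError):
            well_counts([np.ones((30, 30)), np.ones((20, 20))], model)


class TestPrototypeRobustness:
    def test_similar_prototypes_agree_within_ten_percent(self, small_template):
        """Counts from slightly different prototype crops stay within 10%."""
        rng = np.random.default_rng(13)
        frames = [planted_fixture(small_template, 4, seed=700 + i, shape=(96, 96))[0] for i in range(3)]
        counts_by_proto = []
        for jitter_seed in range(4):
            jrng = np.random.default_rng(jitter_seed)
            jittered = small_template * jrng.uniform(0.95, 1.05) + jrng.normal(0, 1.0, small_template.shape)
            model = make_model(jittered)
            tau = detection_threshold(jittered)
            counts_by_proto.append([frame_count(f, model, tau).mean_count for f in frames])
        counts_by_proto = np.array(counts_by_proto)
        mean = counts_by_proto.mean(axis=0)
        assert np.all(np.abs(counts_by_proto - mean) <= 0.10 * np.maximum(mean, 1.0))


class TestThresholdTuning:
    def build_training(self, small_template, n_images=8, seed=0):
        training = []
        for i in range(n_images):
            n = (i % 4) + 1
            frame, truth = planted_fixture(small_template, n, seed=seed + i, shape=(96, 96))
            training.append((frame, float(truth["count"])))
        return training

    def test_zero_loss_interval_recovered(self, small_template):
        training = self.build_training(small_template)
        model = make_model(small_template)
        tune_threshold(training, model, folds=4, repeats=2, seed=0)
        assert model.tuning.median_test_loss == 0.0
        # the tuned threshold achieves zero loss on every training image
        for frame, n in training:
            assert frame_count(frame, model).mean_count == n

    def test_fold_median(self, small_template):
        training = self.build_training(small_template, seed=50)
        model = make_model(small_template)
        tune_threshold(training, model, folds=4, repeats=2, seed=1)
        assert model.threshold == pytest.approx(
            float(np.median(model.tuning.fold_optima))
        )

    def test_overfit_abort_on_inconsistent_annotations(self, small_template):
        """Blank images annotated with large counts cannot be fit: abort."""
        rng = np.random.default_rng(14)
        training = [
            (make_background((64, 64), 100, 2, rng), 50.0) for _ in range(8)
        ]
        model = make_model(small_template)
        with pytest.raises(OverfitError) as err:
            tune_threshold(training, model, seed=2)
        assert err.value.median_test_loss > 5

    def test_too_few_images_rejected(self, small_template):
        model = make_model(small_template)
        with pytest.raises(ValueError):
            tune_threshold([(np.full((30, 30), 100.0), 0.0)] * 3, model, folds=4)
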