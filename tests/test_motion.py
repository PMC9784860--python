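import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from endoskill import (MotionConfig, binarize, coverage, difference_image,
                       fine_movement, frame_score)
from endoskill.errors import ComputationError

from conftest import make_stream


def brute_force_coverage(curr, prev, threshold):
    """Nested-loop recomputation of the difference -> mask -> coverage chain."""
    h, w = curr.shape
    ones = 0
    for i in range(h):
        for j in range(w):
            d = abs(int(curr[i, j]) - int(prev[i, j]))
            if d > threshold:
                ones += 1
    return 100.0 * ones / (h * w)


class TestDifferenceImage:
    def test_identical_frames_give_zero(self):
        f = np.full((8, 8), 123, dtype=np.uint8)
        assert difference_image(f, f).max() == 0

    def test_single_pixel_arithmetic(self):
        a = np.full((2, 2), 120, dtype=np.uint8)
        b = np.full((2, 2), 70, dtype=np.uint8)
        assert difference_image(a, b)[0, 0] == 50

    def test_matches_loop_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
            b = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
            diff = difference_image(a, b)
            for i in range(8):
                for j in range(8):
                    assert diff[i, j] == abs(int(a[i, j]) - int(b[i, j]))

    @given(hnp.arrays(np.uint8, (6, 6)), hnp.arrays(np.uint8, (6, 6)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_in_operands(self, a, b):
        np.testing.assert_array_equal(difference_image(a, b),
                                      difference_image(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_image(np.zeros((4, 4), np.uint8),
                             np.zeros((4, 5), np.uint8))


class TestBinarize:
    def test_threshold_is_strict(self):
        diff = np.array([[49, 50, 51]], dtype=np.uint8)
        np.testing.assert_array_equal(binarize(diff, 50), [[0, 0, 1]])

    def test_all_zero_diff_gives_empty_mask(self):
        assert binarize(np.zeros((5, 5), np.uint8), 50).sum() == 0

    def test_matches_elementwise_oracle(self, rng):
        diff = rng.integers(0, 256, size=(10, 10), dtype=np.uint8)
        mask = binarize(diff, 50)
        for i in range(10):
            for j in range(10):
                assert mask[i, j] == (1 if diff[i, j] > 50 else 0)


class TestCoverage:
    @pytest.mark.parametrize("mask,expected", [
        (np.zeros((10, 10)), 0.0),
        (np.ones((10, 10)), 100.0),
    ])
    def test_extremes(self, mask, expected):
        assert coverage(mask) == expected

    def test_counting_oracle(self, rng):
        mask = np.zeros((10, 10), dtype=np.uint8)
        idx = rng.choice(100, size=37, replace=False)
        mask.ravel()[idx] = 1
        assert coverage(mask) == pytest.approx(37.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            coverage(np.zeros((0, 0)))


class TestFrameScore:
    cfg = MotionConfig(eps_low=0.5, eps_high=20.0)

    @pytest.mark.parametrize("cov,expected", [
        (10.0, 100.0),    # inside the band: appropriate speed
        (0.5, 100.0),     # boundaries inclusive as defined
        (20.0, 100.0),
        (0.49, 0.0),      # too slow
        (20.01, 0.0),     # too fast
        (0.0, 0.0),
        (100.0, 0.0),
    ])
    def test_band_scoring(self, cov, expected):
        assert frame_score(cov, self.cfg) == expected


class TestFineMovement:
    def test_all_pairs_in_band_scores_100(self, rng):
        # consecutive sampled frames differ in exactly 10% of pixels by 70
        frames = [np.full((20, 20), 100, dtype=np.uint8)]
        for _ in range(6):
            nxt = frames[-1].copy()
            idx = rng.choice(400, size=40, replace=False)
            nxt.ravel()[idx] = np.where(nxt.ravel()[idx] < 128,
                                        nxt.ravel()[idx] + 70,
                                        nxt.ravel()[idx] - 70)
            frames.append(nxt)
        stream = make_stream([f for f in frames for _ in range(3)][:19], fps=10.0)
        trace = fine_movement(stream, MotionConfig())
        assert trace.session_score == 100.0
        assert all(s.coverage == pytest.approx(10.0) for s in trace.samples)

    def test_half_in_band_scores_50(self):
        from endoskill import FramePair, FrameSample

        base = np.full((10, 10), 100, dtype=np.uint8)
        moved = base.copy()
        moved.ravel()[:10] += 100  # 10% change: in band

        def pair(k, curr, prev):
            return FramePair(
                current=FrameSample(index=3 * k, timestamp=0.3 * k, pixels=curr),
                previous=FrameSample(index=3 * (k - 1), timestamp=0.3 * (k - 1),
                                     pixels=prev))

        pairs = [pair(1, base, base), pair(2, moved, base),
                 pair(3, moved, moved), pair(4, base, moved)]
        trace = fine_movement(pairs, MotionConfig())
        assert [s.score for s in trace.samples] == [0.0, 100.0, 0.0, 100.0]
        assert trace.session_score == 50.0

    def test_static_stream_scores_zero(self, static_stream):
        trace = fine_movement(static_stream, MotionConfig())
        assert trace.session_score == 0.0
        assert all(s.coverage == 0.0 for s in trace.samples)

    def test_no_pairs_is_an_error(self):
        stream = make_stream([np.zeros((4, 4), np.uint8)] * 2, fps=10.0)
        with pytest.raises(ComputationError):
            fine_movement(stream, MotionConfig())

    def test_pipeline_equals_brute_force_on_random_stream(self, rng):
        """Full vectorized chain == nested-loop recomputation, bit-exact."""
        frames = [rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
                  for _ in range(13)]
        stream = make_stream(frames, fps=10.0)
        cfg = MotionConfig()
        trace = fine_movement(stream, cfg)
        assert len(trace.samples) == 4
        expected_scores = []
        for k, sample in enumerate(trace.samples, start=1):
            cov = brute_force_coverage(frames[3 * k], frames[3 * (k - 1)],
                                       cfg.diff_threshold)
            assert sample.coverage == cov
            expected_scores.append(100.0 if cfg.eps_low <= cov <= cfg.eps_high
                                   else 0.0)
        assert trace.session_score == np.mean(expected_scores)

    def test_coverage_monotone_in_changed_pixels(self, rng):
        base = np.full((12, 12), 100, dtype=np.uint8)
        prev_cov = -1.0
        order = rng.permutation(144)
        for n_changed in (0, 5, 20, 60, 144):
            nxt = base.copy()
            nxt.ravel()[order[:n_changed]] += 100
            cov = coverage(binarize(difference_image(nxt, base), 50))
            assert cov >= prev_cov
            prev_cov = cov

    def test_session_score_invariant_to_resolution(self, rng):
        """Same changed-pixel fraction, two resolutions -> same score."""
        scores = []
        for size in ((10, 10), (40, 40)):
            n = size[0] * size[1]
            base = np.full(size, 100, dtype=np.uint8)
            moved = base.copy()
            idx = rng.choice(n, size=n // 10, replace=False)
            moved.ravel()[idx] += 100
            stream = make_stream([base, base, base, moved], fps=10.0)
            trace = fine_movement(stream, MotionConfig())
            assert trace.samples[0].coverage == pytest.approx(10.0)
            scores.append(trace.session_score)
        assert scores[0] == scores[1]
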