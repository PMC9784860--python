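import math

import numpy as np
import pytest

from endoskill import (ExposureConfig, denoise_and_blobs, frame_exposure,
                       overexposure_mask, visualization)
from endoskill.errors import ComputationError
from endoskill.exposure import frame_center, half_diagonal, weight_for_distance

from conftest import make_stream


def place_rect(frame, top, left, h, w, value=255):
    frame[top:top + h, left:left + w] = value
    return frame


# ---------------------------------------------------------------------------
# independent oracle: loop-based opening + flood fill + enumeration
# ---------------------------------------------------------------------------

def oracle_opening(mask, k=3):
    h, w = mask.shape
    pad = k // 2
    eroded = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            window = mask[max(0, i - pad):i + pad + 1,
                          max(0, j - pad):j + pad + 1]
            full = (i - pad >= 0 and i + pad < h and j - pad >= 0
                    and j + pad < w)
            eroded[i, j] = 1 if (full and window.all()) else 0
    dilated = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            window = eroded[max(0, i - pad):i + pad + 1,
                            max(0, j - pad):j + pad + 1]
            dilated[i, j] = 1 if window.any() else 0
    return dilated


def oracle_blobs(mask, cfg):
    """Flood-fill enumeration of 8-connected components after opening."""
    opened = oracle_opening(mask, cfg.opening_size)
    h, w = mask.shape
    seen = np.zeros_like(opened, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if opened[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                pix = []
                while stack:
                    r, c = stack.pop()
                    pix.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and opened[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(pix)
    results = []
    center = frame_center(h, w)
    r_half = half_diagonal(h, w)
    for pix in comps:
        if len(pix) < cfg.min_blob_area / 100.0 * h * w:
            continue
        cy = sum(p[0] for p in pix) / len(pix)
        cx = sum(p[1] for p in pix) / len(pix)
        d = min(math.hypot(cy - center[0], cx - center[1]), r_half)
        area = 100.0 * len(pix) / (h * w)
        results.append((area, d))
    return results, r_half


class TestOverexposureMask:
    def test_threshold_is_strict_at_245(self):
        frame = np.array([[244, 245, 246]], dtype=np.uint8)
        np.testing.assert_array_equal(overexposure_mask(frame), [[0, 0, 1]])

    def test_unsaturated_frame_gives_empty_mask(self, rng):
        frame = rng.integers(0, 246, size=(16, 16), dtype=np.uint8)
        assert overexposure_mask(frame).sum() == 0

    def test_matches_elementwise_oracle(self, rng):
        frame = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        mask = overexposure_mask(frame)
        for i in range(12):
            for j in range(12):
                assert mask[i, j] == (1 if frame[i, j] > 245 else 0)


class TestWeightForDistance:
    r = 70.0

    @pytest.mark.parametrize("d_frac,expected", [
        (0.0, 1.0),            # dead centre
        (1.0 / 3.0, 1.0),      # inner boundary inclusive
        (0.5, 2.0 / 3.0),      # middle annulus
        (2.0 / 3.0, 1.0 / 3.0),  # outer boundary belongs to the outer band
        (0.9, 1.0 / 3.0),
        (1.0, 1.0 / 3.0),
    ])
    def test_band_values(self, d_frac, expected):
        assert weight_for_distance(d_frac * self.r, self.r) == expected

    def test_distance_beyond_half_diagonal_rejected(self):
        with pytest.raises(ValueError):
            weight_for_distance(self.r * 1.01, self.r)
        with pytest.raises(ValueError):
            weight_for_distance(-1.0, self.r)


class TestDenoiseAndBlobs:
    def test_single_square_area_and_centroid(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        place_rect(mask, 10, 20, 5, 5, 1)
        blobs = denoise_and_blobs(mask)
        assert len(blobs) == 1
        assert blobs[0].area_percent == pytest.approx(0.25)
        assert blobs[0].centroid == pytest.approx((12.0, 22.0))

    def test_two_isolated_squares_are_two_blobs(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        place_rect(mask, 5, 5, 6, 6, 1)
        place_rect(mask, 60, 70, 8, 8, 1)
        assert len(denoise_and_blobs(mask)) == 2

    def test_scattered_single_pixels_removed(self, rng):
        mask = np.zeros((50, 50), dtype=np.uint8)
        # isolated salt pixels: no 3x3 neighbourhood survives opening
        for i, j in [(3, 3), (10, 40), (25, 7), (44, 44), (30, 30)]:
            mask[i, j] = 1
        assert denoise_and_blobs(mask) == []

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        cfg = ExposureConfig()
        for _ in range(10):
            mask = (rng.random((20, 20)) < 0.35).astype(np.uint8)
            blobs = denoise_and_blobs(mask, cfg)
            expected, _ = oracle_blobs(mask, cfg)
            got = sorted((round(b.area_percent, 9), round(b.distance, 6))
                         for b in blobs)
            want = sorted((round(a, 9), round(d, 6)) for a, d in expected)
            assert got == want


class TestFrameExposure:
    def test_no_blobs_gives_zero(self):
        frame = np.full((50, 50), 100, dtype=np.uint8)
        assert frame_exposure(frame) == 0.0

    def test_central_blob_weighted_fully(self):
        # 30x30 saturated square centred in 100x100: 9% area at d=0
        frame = np.full((100, 100), 100, dtype=np.uint8)
        place_rect(frame, 35, 35, 30, 30)
        assert frame_exposure(frame) == pytest.approx(9.0)

    def test_maximum_weighted_blob_chosen(self):
        # central 2% (w=1 -> 2) vs corner 9% (w=1/3 -> 3): corner wins
        frame = np.full((200, 200), 100, dtype=np.uint8)
        place_rect(frame, 80, 90, 40, 20)   # central 800 px
        place_rect(frame, 0, 0, 60, 60)     # corner 3600 px
        r = half_diagonal(200, 200)
        d_corner = math.hypot(99.5 - 29.5, 99.5 - 29.5)
        assert d_corner >= 2 * r / 3  # corner square sits in the outer band
        assert frame_exposure(frame) == pytest.approx(3.0)

    def test_matches_enumeration_oracle(self, rng):
        cfg = ExposureConfig()
        for _ in range(5):
            frame = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
            expected, r_half = oracle_blobs(overexposure_mask(frame, cfg), cfg)
            want = max((weight_for_distance(d, r_half, cfg) * a
                        for a, d in expected), default=0.0)
            assert frame_exposure(frame, cfg) == pytest.approx(min(100.0, want))


class TestVisualization:
    def test_clean_video_scores_100(self, static_stream):
        assert visualization(static_stream).session_score == 100.0

    def test_constant_weighted_area_closed_form(self):
        # every frame: central saturated 10% blob -> score = 100 - 10
        frame = np.full((100, 100), 100, dtype=np.uint8)
        place_rect(frame, 30, 37, 40, 25)  # 1000 px, centred
        stream = make_stream([frame] * 13, fps=10.0)
        trace = visualization(stream)
        assert all(s.weighted_area == pytest.approx(10.0) for s in trace.samples)
        assert trace.session_score == pytest.approx(90.0)

    def test_empty_stream_is_an_error(self):
        with pytest.raises(ComputationError):
            visualization([])

    def test_monotone_under_added_saturation(self, rng):
        base = rng.integers(0, 200, size=(60, 60), dtype=np.uint8)
        score_clean = visualization(make_stream([base] * 7)).session_score
        worse = base.copy()
        place_rect(worse, 20, 20, 10, 10)
        score_blob = visualization(make_stream([worse] * 7)).session_score
        worst = worse.copy()
        place_rect(worst, 40, 5, 14, 14)
        score_two = visualization(make_stream([worst] * 7)).session_score
        assert score_clean >= score_blob >= score_two
        # salt pixels are denoised away: score unchanged
        salted = base.copy()
        for i, j in [(2, 2), (50, 11), (33, 58)]:
            salted[i, j] = 255
        assert visualization(make_stream([salted] * 7)).session_score == score_clean

    def test_blob_move_within_annulus_keeps_wa_moving_inward_raises_it(self):
        h = w = 120
        r = half_diagonal(h, w)
        area_px = 100  # 10x10 square

        def frame_with_square_at(d_frac):
            frame = np.full((h, w), 100, dtype=np.uint8)
            cy = (h - 1) / 2 + d_frac * r * (h - 1) / math.hypot(h - 1, w - 1)
            cx = (w - 1) / 2 + d_frac * r * (w - 1) / math.hypot(h - 1, w - 1)
            place_rect(frame, int(cy) - 5, int(cx) - 5, 10, 10)
            return frame

        wa = {f: frame_exposure(frame_with_square_at(f))
              for f in (0.0, 0.2, 0.5, 0.55, 0.8)}
        assert wa[0.0] == wa[0.2]      # both inside the inner band
        assert wa[0.5] == wa[0.55]     # both in the middle annulus
        assert wa[0.8] <= wa[0.5] <= wa[0.2]  # inward never decreases

    def test_score_bounded_on_random_input(self, rng):
        frames = [rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
                  for _ in range(7)]
        score = visualization(make_stream(frames)).session_score
        assert 0.0 <= score <= 100.0
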