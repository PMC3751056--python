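"""Polar/Cartesian morphological reconstruction and gap machinery."""

import numpy as np
import pytest

from ivoct_lumen import (
    BinaryMask, ParameterError, SegmentationError,
    cartesian_to_polar, cartesian_reconstruct, correct_gaps, detect_gaps,
    extract_contour, height_signal, polar_reconstruct, rebuild_from_height,
)
from ivoct_lumen.preprocess import GrayImage

from conftest import dice, disk_image, disk_mask, step_polar_mask

N_R, N_THETA = 200, 630
R_MAX = 30


class TestPolarReconstruct:
    def test_clean_step_is_fixed_point(self):
        mask = step_polar_mask(N_R, N_THETA, 120)
        out = polar_reconstruct(mask, R_MAX)
        assert np.array_equal(out.pixels, mask.pixels)

    def test_lumen_speckles_removed(self, rng):
        mask = step_polar_mask(N_R, N_THETA, 120)
        noisy = mask.pixels.copy()
        rows = rng.integers(5, 110, 10)
        cols = rng.integers(0, N_THETA, 10)
        noisy[rows, cols] = True  # isolated 1-px speckles in the lumen
        out = polar_reconstruct(BinaryMask(noisy, "polar"), R_MAX)
        assert np.array_equal(out.pixels, mask.pixels)

    def test_shallow_notch_closed_by_adaptive_closing(self):
        mask = step_polar_mask(N_R, N_THETA, 120).pixels.copy()
        mask[120:122, 300:305] = False  # 2-px-deep notch, much narrower than D
        out = polar_reconstruct(BinaryMask(mask, "polar"), R_MAX)
        h = height_signal(out)
        assert np.abs(h - 120).max() <= 1

    def test_all_background_is_an_error(self):
        with pytest.raises(SegmentationError, match="no tissue"):
            polar_reconstruct(BinaryMask(np.zeros((N_R, N_THETA), bool), "polar"),
                              R_MAX)

    def test_idempotent_on_own_output(self, rng):
        mask = step_polar_mask(N_R, N_THETA, 120).pixels.copy()
        mask[:100, :] |= rng.random((100, N_THETA)) < 0.02
        once = polar_reconstruct(BinaryMask(mask, "polar"), R_MAX)
        twice = polar_reconstruct(once, R_MAX)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_single_bottom_attached_component(self, rng):
        from scipy import ndimage as ndi
        mask = step_polar_mask(N_R, N_THETA, 120).pixels.copy()
        mask[:100, :] |= rng.random((100, N_THETA)) < 0.05
        out = polar_reconstruct(BinaryMask(mask, "polar"), R_MAX)
        _, n = ndi.label(out.pixels, structure=np.ones((3, 3)))
        assert n == 1
        assert out.pixels[-1, :].all()          # attached to the max-r edge
        assert not (~out.pixels)[-1, :].any()
        assert (~out.pixels)[0, :].all()        # negation attached to the top


class TestHeightSignal:
    def test_all_foreground_is_zero(self):
        m = BinaryMask(np.ones((N_R, 16), bool), "polar")
        assert np.array_equal(height_signal(m), np.zeros(16, int))

    def test_step_and_empty_columns(self):
        m = step_polar_mask(N_R, N_THETA, 120).pixels.copy()
        m[:, 100:140] = False
        h = height_signal(BinaryMask(m, "polar"))
        assert (h[100:140] == N_R).all()
        keep = np.ones(N_THETA, bool)
        keep[100:140] = False
        assert (h[keep] == 120).all()


class TestDetectGaps:
    def test_constant_signal_has_no_gaps(self):
        assert detect_gaps(np.full(N_THETA, 120)) == []

    @pytest.mark.parametrize("lo, hi", [(300, 360), (0, 40), (600, 629)])
    def test_single_raised_run_recovered_within_two_columns(self, lo, hi):
        h = np.full(N_THETA, 120)
        h[lo:hi + 1] = N_R
        gaps = detect_gaps(h)
        assert len(gaps) == 1
        g = gaps[0]
        assert abs(g.start - lo) <= 2
        assert abs(g.end - hi) <= 2

    def test_lowered_run_recovered(self):
        # the orientation real branch shadows take: h pulled toward the catheter
        h = np.full(N_THETA, 120)
        h[200:240] = 25
        gaps = detect_gaps(h)
        assert len(gaps) == 1
        assert abs(gaps[0].start - 200) <= 2 and abs(gaps[0].end - 239) <= 2

    def test_two_disjoint_runs_found_separately(self):
        h = np.full(N_THETA, 120)
        h[100:140] = N_R
        h[400:440] = N_R
        gaps = sorted(detect_gaps(h), key=lambda g: g.start)
        assert len(gaps) == 2
        for g, (lo, hi) in zip(gaps, [(100, 139), (400, 439)]):
            run = set(range(lo, hi + 1))
            assert run & set(g.columns(N_THETA).tolist())
            assert abs(g.start - lo) <= 2 and abs(g.end - hi) <= 2

    def test_wrapping_run(self):
        h = np.full(N_THETA, 120)
        h[610:] = N_R
        h[:15] = N_R
        gaps = detect_gaps(h)
        assert len(gaps) == 1
        cols = set(gaps[0].columns(N_THETA).tolist())
        assert set(range(610, N_THETA)) <= cols and set(range(15)) <= cols

    def test_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            detect_gaps(np.arange(4))


class TestCorrectGaps:
    def test_no_gaps_is_identity(self):
        h = np.arange(N_THETA) % 50 + 100
        assert np.array_equal(correct_gaps(h, []), h)

    def test_constant_signal_restored_exactly(self):
        h = np.full(N_THETA, 120)
        h[300:361] = N_R
        gaps = detect_gaps(h)
        fixed = correct_gaps(h, gaps, n_r=N_R)
        assert (fixed == 120).all()

    def test_sinusoid_restored_within_three_rows(self):
        j = np.arange(N_THETA)
        truth = np.rint(120 + 10 * np.sin(2 * np.pi * j / N_THETA)).astype(int)
        h = truth.copy()
        h[250:290] = N_R
        gaps = detect_gaps(h)
        assert len(gaps) == 1
        fixed = correct_gaps(h, gaps, n_r=N_R)
        assert np.abs(fixed[250:290] - truth[250:290]).max() <= 3

    def test_wrapping_gap_interpolates_circularly(self):
        j = np.arange(N_THETA)
        truth = np.rint(120 + 8 * np.cos(2 * np.pi * j / N_THETA)).astype(int)
        h = truth.copy()
        h[615:] = N_R
        h[:15] = N_R
        fixed = correct_gaps(h, detect_gaps(h), n_r=N_R)
        bad = np.r_[615:N_THETA, 0:15]
        assert np.abs(fixed[bad] - truth[bad]).max() <= 3

    def test_too_few_support_columns_rejected(self):
        h = np.full(N_THETA, 120)
        h[5:] = N_R
        with pytest.raises(SegmentationError):
            correct_gaps(h, [__import__("ivoct_lumen").GapInterval(5, N_THETA - 1)],
                         n_r=N_R)


class TestRebuildFromHeight:
    def test_extremes(self):
        assert rebuild_from_height(np.zeros(16, int), (N_R, 16)).pixels.all()
        assert not rebuild_from_height(np.full(16, N_R), (N_R, 16)).pixels.any()

    def test_round_trip_with_height_signal(self, rng):
        for _ in range(20):
            h = rng.integers(0, N_R + 1, N_THETA)
            mask = rebuild_from_height(h, (N_R, N_THETA))
            assert np.array_equal(height_signal(mask), h)

    def test_gap_free_signals_pass_through_detect_correct_rebuild(self, rng):
        # full identity: smooth boundary signals are left untouched
        j = np.arange(N_THETA)
        for amp, freq in [(0, 1), (8, 1), (15, 2), (10, 3)]:
            h = np.rint(120 + amp * np.sin(2 * np.pi * freq * j / N_THETA)).astype(int)
            fixed = correct_gaps(h, detect_gaps(h), n_r=N_R)
            rebuilt = rebuild_from_height(fixed, (N_R, N_THETA))
            assert np.array_equal(rebuilt.pixels,
                                  rebuild_from_height(h, (N_R, N_THETA)).pixels)


class TestCartesianReconstruct:
    def _geometry(self, side=400):
        return cartesian_to_polar(disk_image(side, 10.0), N_R, N_THETA)

    def test_row_step_object_becomes_centered_disk(self):
        pol = self._geometry()
        star = step_polar_mask(N_R, N_THETA, 100)
        lumen = cartesian_reconstruct(star, pol)
        assert lumen.domain == "cartesian"
        radius = 100 * pol.r_scale_px
        assert dice(lumen.pixels, disk_mask(400, radius)) >= 0.97

    def test_single_column_spike_removed_by_adaptive_opening(self):
        pol = self._geometry()
        m = step_polar_mask(N_R, N_THETA, 100).pixels.copy()
        m[60:100, 315] = True  # 1-column spike of tissue into the lumen
        lumen_spiked = cartesian_reconstruct(BinaryMask(m, "polar"), pol)
        # no deep intrusion survives: the lumen interior stays covered
        assert lumen_spiked.pixels[disk_mask(400, 90.0)].all()
        # and the overall disagreement stays a small smoothing margin,
        # not a 40-row wedge
        lumen_clean = cartesian_reconstruct(step_polar_mask(N_R, N_THETA, 100), pol)
        diff = np.count_nonzero(lumen_clean.pixels != lumen_spiked.pixels)
        assert diff < 0.01 * lumen_clean.pixels.sum()

    def test_full_foreground_has_no_lumen(self):
        pol = self._geometry()
        with pytest.raises(SegmentationError, match="lumen"):
            cartesian_reconstruct(
                BinaryMask(np.ones((N_R, N_THETA), bool), "polar"), pol)


class TestExtractContour:
    def test_square_perimeter(self):
        m = np.zeros((32, 32), bool)
        m[10:20, 10:20] = True
        contour = extract_contour(BinaryMask(m, "cartesian"))
        assert len(contour) >= 8
        assert np.array_equal(contour[0], contour[-1])  # closed
        per = np.hypot(*np.diff(contour, axis=0).T).sum()
        assert 32 <= per <= 44

    def test_disk_circumference_within_five_percent(self):
        m = disk_mask(128, 50.0)
        contour = extract_contour(BinaryMask(m, "cartesian"))
        per = np.hypot(*np.diff(contour, axis=0).T).sum()
        assert abs(per - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            extract_contour(BinaryMask(np.zeros((16, 16), bool), "cartesian"))
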