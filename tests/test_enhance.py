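import numpy as np
import pytest
from skimage.exposure import equalize_adapthist

from raclahe.enhance import (DegenerateHistogramError, PatchHistogram, agccpf,
                             agcwd, clahe, equalize_patch, global_he,
                             otsu_threshold, rlbhe)
from raclahe.volio import Frame


def brute_force_equalize(patch, levels):
    """Direct per-level counting: P, CDF, LUT, applied pixel by pixel.

    Exact rational arithmetic so half-up ties are decided by the true
    value of (L-1)*CDF, not by floating-point association.
    """
    import math
    from fractions import Fraction

    flat = patch.ravel()
    cum = 0
    lut = []
    for i in range(levels):
        cum += int((flat == i).sum())
        lut.append(math.floor(Fraction((levels - 1) * cum, flat.size) + Fraction(1, 2)))
    return np.asarray(lut)[patch]


class TestEqualizePatch:
    def test_four_level_worked_example(self):
        out = equalize_patch(np.array([[0, 1], [2, 3]]), levels=4)
        assert np.array_equal(out, [[1, 2], [2, 3]])

    def test_constant_patch_maps_to_top_level(self):
        out = equalize_patch(np.full((3, 3), 17), levels=256)
        assert (out == 255).all()

    def test_preserve_constant_flag(self):
        out = equalize_patch(np.full((3, 3), 17), levels=256, preserve_constant=True)
        assert (out == 17).all()

    def test_half_level_rounds_up(self):
        out = equalize_patch(np.array([0, 0, 1, 1]), levels=2)
        assert (out == 1).all()

    def test_value_above_levels_rejected(self):
        with pytest.raises(ValueError):
            equalize_patch(np.array([[4]]), levels=4)

    def test_matches_brute_force_on_1000_random_patches(self, rng):
        for _ in range(1000):
            h, w = rng.integers(1, 17, size=2)
            levels = int(rng.choice([4, 16, 256]))
            patch = rng.integers(0, levels, size=(h, w))
            assert np.array_equal(equalize_patch(patch, levels),
                                  brute_force_equalize(patch, levels))


class TestGlobalHE:
    def test_uniform_ramp_is_near_identity(self):
        px = np.arange(256).repeat(4).reshape(32, 32)
        out = global_he(Frame(px, 256))
        assert np.abs(out.pixels - px).max() <= 1

    def test_constant_frame_maps_to_255(self):
        out = global_he(Frame(np.full((8, 8), 3), 256))
        assert (out.pixels == 255).all()

    def test_output_cdf_is_nearly_linear(self, rng):
        """Classical HE: the equalized CDF deviates from linear by at most
        the largest single-level probability mass of the input."""
        px = rng.integers(0, 256, size=(64, 64)) // 3 * 3
        frame = Frame(px, 256)
        out = global_he(frame)
        out_cdf = np.cumsum(np.bincount(out.pixels.ravel(), minlength=256)) / out.pixels.size
        linear = np.arange(1, 257) / 256
        max_mass = np.bincount(px.ravel(), minlength=256).max() / px.size
        assert np.abs(out_cdf - linear).max() <= max_mass + 1 / 256


class TestClahe:
    def test_single_patch_equals_global_he(self, rng):
        frame = Frame(rng.integers(0, 256, size=(16, 16)), 256)
        out = clahe(frame, patch_size=16, mode="literal")
        assert np.array_equal(out.pixels, global_he(frame).pixels)

    def test_literal_quadrants_are_independent_equalizations(self, rng):
        frame = Frame(rng.integers(0, 256, size=(16, 16)), 256)
        out = clahe(frame, patch_size=8, mode="literal")
        for r in (0, 8):
            for c in (0, 8):
                block = frame.pixels[r:r + 8, c:c + 8]
                assert np.array_equal(out.pixels[r:r + 8, c:c + 8],
                                      equalize_patch(block, 256))

    def test_partial_edge_patches_use_own_histograms(self, rng):
        frame = Frame(rng.integers(0, 256, size=(20, 20)), 256)
        out = clahe(frame, patch_size=8, mode="literal")
        assert np.array_equal(out.pixels[16:, 16:],
                              equalize_patch(frame.pixels[16:, 16:], 256))

    def test_oversized_patch_degrades_to_global_he(self, rng):
        frame = Frame(rng.integers(0, 256, size=(8, 8)), 256)
        out = clahe(frame, patch_size=64, mode="literal")
        assert np.array_equal(out.pixels, global_he(frame).pixels)

    def test_standard_mode_tracks_reference_implementation(self, rng):
        """skimage's CLAHE differs structurally (shifted tile grid, ~253
        effective bins, iterative redistribution, output stretch), so the
        comparison is correlation + bounded mean deviation rather than
        per-pixel equality."""
        px = rng.integers(0, 256, size=(64, 64))
        mine = clahe(Frame(px, 256), patch_size=8, clip_limit=0.05,
                     mode="standard").pixels
        ref = np.round(equalize_adapthist(px.astype(np.uint8), kernel_size=8,
                                          clip_limit=0.05, nbins=256) * 255)
        assert np.corrcoef(mine.ravel(), ref.ravel())[0, 1] >= 0.98
        assert np.abs(mine - ref).mean() <= 4.0

    def test_standard_mode_stays_within_levels(self, rng):
        frame = Frame(rng.integers(0, 256, size=(40, 56)), 256)
        out = clahe(frame, patch_size=16, clip_limit=0.02, mode="standard")
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
        assert out.shape == frame.shape

    def test_invalid_clip_limit_rejected(self):
        with pytest.raises(ValueError):
            clahe(Frame(np.zeros((8, 8), int), 256), clip_limit=0.0, mode="standard")


class TestAGCWD:
    def test_endpoints_are_fixed_points(self, rng):
        px = rng.integers(0, 256, size=(16, 16))
        px[0, 0], px[0, 1] = 0, 255
        out = agcwd(Frame(px, 256))
        assert out.pixels[0, 0] == 0 and out.pixels[0, 1] == 255

    def test_brightens_every_level_at_alpha_one(self, rng):
        """gamma(l) = 1 - cdf_w(l) <= 1, so T(l) >= l for all 256 levels."""
        px = rng.integers(0, 256, size=(64, 64))
        frame = Frame(px, 256)
        out = agcwd(frame, alpha=1.0)
        lut = np.full(256, -1)
        lut[frame.pixels.ravel()] = out.pixels.ravel()
        present = lut >= 0
        assert (lut[present] >= np.arange(256)[present]).all()

    def test_constant_frame_unchanged(self):
        frame = Frame(np.full((8, 8), 100), 256)
        assert np.array_equal(agcwd(frame).pixels, frame.pixels)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            agcwd(Frame(np.zeros((4, 4), int), 256), alpha=0.0)


class TestAGCCPF:
    def test_blend_zero_equals_agcwd(self, rng):
        frame = Frame(rng.integers(0, 256, size=(32, 32)), 256)
        assert np.array_equal(agccpf(frame, blend=0.0).pixels,
                              agcwd(frame, alpha=1.0).pixels)

    def test_endpoint_preservation_for_any_blend(self, rng):
        px = rng.integers(0, 256, size=(16, 16))
        px[0, 0], px[0, 1] = 0, 255
        for blend in (0.0, 0.3, 1.0):
            out = agccpf(Frame(px, 256), blend=blend)
            assert out.pixels[0, 0] == 0 and out.pixels[0, 1] == 255

    def test_partial_blend_annulled_by_weighting_transform(self, rng):
        """At alpha = 1 the weighting distribution subtracts pdf_min and
        renormalizes, which cancels any uniform-histogram blend < 1:
        pdf' - pdf'_min = (1 - blend)(pdf - pdf_min)."""
        frame = Frame(rng.integers(0, 256, size=(32, 32)), 256)
        assert np.array_equal(agccpf(frame, blend=0.7).pixels,
                              agcwd(frame, alpha=1.0).pixels)

    def test_blend_one_matches_closed_form_uniform_cdf(self, rng):
        """With a uniform modified histogram, cdf_w is linear in l and the
        gamma LUT is computable in closed form."""
        frame = Frame(rng.integers(0, 256, size=(16, 16)), 256)
        out = agccpf(frame, blend=1.0)
        levels = np.arange(256)
        cdf = (levels + 1) / 256  # uniform pdf; weighting transform is degenerate
        gamma = 1 - cdf
        expected_lut = np.floor(255 * (levels / 255) ** gamma + 0.5).astype(int)
        expected_lut[0] = 0
        assert np.array_equal(out.pixels, expected_lut[frame.pixels])


class TestMonotonicity:
    @pytest.mark.parametrize("enhancer", [
        global_he,
        lambda f: agcwd(f, 1.0),
        lambda f: agccpf(f, 0.5),
        rlbhe,
    ], ids=["he", "agcwd", "agccpf", "rlbhe"])
    def test_per_level_mapping_monotone_over_all_levels(self, enhancer, rng):
        px = rng.integers(0, 256, size=(64, 64))
        px[0, :2] = [0, 255]
        frame = Frame(px, 256)
        out = enhancer(frame)
        order = np.argsort(frame.pixels.ravel(), kind="stable")
        assert (np.diff(out.pixels.ravel()[order]) >= 0).all()

    @pytest.mark.parametrize("enhancer", [
        global_he, lambda f: clahe(f, 8), lambda f: agcwd(f),
        lambda f: agccpf(f), rlbhe,
    ], ids=["he", "clahe", "agcwd", "agccpf", "rlbhe"])
    def test_shape_levels_and_range_preserved(self, enhancer, rng):
        frame = Frame(rng.integers(0, 256, size=(24, 40)), 256)
        out = enhancer(frame)
        assert out.shape == frame.shape and out.levels == frame.levels
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255


def exhaustive_otsu(counts):
    """O(L^2) scan of all splits; maximize w0*w1*(mu0-mu1)^2."""
    levels = np.arange(len(counts))
    best_t, best_v = None, -1.0
    total = counts.sum()
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * counts[: t + 1]).sum() / counts[: t + 1].sum()
        mu1 = (levels[t + 1:] * counts[t + 1:]).sum() / counts[t + 1:].sum()
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


class TestOtsu:
    def test_equal_spikes_split_between_them(self):
        counts = np.zeros(256, dtype=int)
        counts[50] = counts[200] = 10
        hist = PatchHistogram(counts, 20, 256)
        t = otsu_threshold(hist)
        assert 50 <= t <= 199
        assert t == exhaustive_otsu(counts)

    def test_single_occupied_level_raises(self):
        counts = np.zeros(256, dtype=int)
        counts[7] = 5
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(PatchHistogram(counts, 5, 256))

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 20, size=256)
            if np.count_nonzero(counts) < 2:
                continue
            hist = PatchHistogram(counts, int(counts.sum()), 256)
            assert otsu_threshold(hist) == exhaustive_otsu(counts)


class TestRLBHE:
    def test_constant_frame_unchanged(self):
        frame = Frame(np.full((8, 8), 42), 256)
        assert np.array_equal(rlbhe(frame).pixels, frame.pixels)

    def test_brightness_preserved_on_bimodal_frames(self, rng):
        """Mean output brightness within 2 gray levels of the input on
        seeded two-blob frames."""
        for _ in range(20):
            px = np.clip(np.where(
                rng.random((48, 48)) < 0.4,
                rng.normal(70, 12, (48, 48)),
                rng.normal(170, 15, (48, 48)),
            ).round(), 0, 255).astype(int)
            frame = Frame(px, 256)
            out = rlbhe(frame)
            assert abs(out.pixels.mean() - frame.pixels.mean()) <= 2.0

    def test_classes_map_to_disjoint_ranges(self, rng):
        px = rng.integers(0, 256, size=(32, 32))
        frame = Frame(px, 256)
        hist = PatchHistogram.from_patch(px, 256)
        t = otsu_threshold(hist)
        out = rlbhe(frame)
        lower = frame.pixels <= t
        assert out.pixels[lower].max() <= t
        assert out.pixels[~lower].min() > t
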