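import numpy as np
import pytest

import resectseq as rs
from resectseq.errors import DegenerateProfileError, ValidationError
from resectseq.profiles import hann_kernel, hann_smooth_array


def make_profile(values, offsets=None, **flags):
    values = np.asarray(values, dtype=float)
    if offsets is None:
        W = (len(values) - 1) // 2
        offsets = np.arange(-W, W + 1)
    defaults = dict(units="RPM", co_oriented=True)
    defaults.update(flags)
    return rs.AverageProfile(offsets, values, **defaults)


def one_hotspot_track(genome, position, value, strand="top", total=1e6):
    return rs.StrandedTrack(
        genome, {("chr1", strand): (np.array([position]), np.array([float(value)]))}, total)


def single_hotspot(genome, center=50_000):
    return rs.HotspotSet(np.array(["chr1"], dtype=object), np.array([center]),
                         np.array([1.0]), np.array([False]))


class TestStackWindows:
    def test_count_lands_at_its_offset(self, genome):
        hs = single_hotspot(genome)
        track = one_hotspot_track(genome, 50_010, 5)
        mat = rs.stack_windows(track, hs, 3000)
        assert mat.top[0, 3000 + 10] == 5
        assert mat.top.sum() == 5 and mat.bottom.sum() == 0

    def test_count_just_outside_window_excluded(self, genome):
        hs = single_hotspot(genome)
        track = one_hotspot_track(genome, 50_000 + 3001, 5)
        mat = rs.stack_windows(track, hs, 3000)
        assert mat.top.sum() == 0

    def test_boundary_position_included(self, genome):
        hs = single_hotspot(genome)
        track = one_hotspot_track(genome, 50_000 + 3000, 5)
        mat = rs.stack_windows(track, hs, 3000)
        assert mat.top[0, -1] == 5

    def test_window_overflowing_chromosome_dropped(self, genome):
        hs = rs.HotspotSet(np.array(["chr1", "chr1"], dtype=object),
                           np.array([1000, 50_000]), np.array([1.0, 1.0]),
                           np.array([False, False]))
        mat = rs.stack_windows(one_hotspot_track(genome, 123, 1), hs, 3000)
        assert mat.n_hotspots == 1 and mat.n_dropped == 1
        assert mat.hotspot_index.tolist() == [1]

    def test_total_mass_matches_brute_force(self, genome, rng):
        centers = np.array([10_000, 30_000, 50_000, 70_000])
        hs = rs.HotspotSet(np.array(["chr1"] * 4, dtype=object), centers,
                           np.ones(4), np.zeros(4, bool))
        pos = np.sort(rng.choice(100_000, size=500, replace=False))
        val = rng.integers(1, 5, size=500).astype(float)
        track = rs.StrandedTrack(genome, {("chr1", "top"): (pos, val)}, 1e6)
        mat = rs.stack_windows(track, hs, 3000)
        brute = sum(val[(pos >= c - 3000) & (pos <= c + 3000)].sum() for c in centers)
        assert mat.top.sum() == pytest.approx(brute)

    def test_empty_hotspots_rejected(self, genome):
        hs = rs.HotspotSet(np.array([], dtype=object), np.array([], dtype=int),
                           np.array([]), np.array([], dtype=bool))
        with pytest.raises(ValidationError):
            rs.stack_windows(one_hotspot_track(genome, 1, 1), hs, 3000)


class TestCoorient:
    def test_bottom_offset_mirrored(self, genome):
        hs = single_hotspot(genome)
        track = one_hotspot_track(genome, 50_000 - 7, 2, strand="bottom")
        mat = rs.coorient(rs.stack_windows(track, hs, 3000))
        assert mat.bottom[0, 3000 + 7] == 2

    def test_involution(self, genome, wt_small):
        track, hs, _ = wt_small
        mat = rs.stack_windows(track, hs, 1000)
        flipped = rs.coorient(mat)
        # flipping the already-flipped bottom restores the original
        twice = flipped.bottom[:, ::-1]
        np.testing.assert_array_equal(twice, mat.bottom)
        with pytest.raises(ValidationError):
            rs.coorient(flipped)

    def test_symmetric_resection_strands_agree_after_flip(self, wt_small):
        # left/right resection is symmetric, so the flipped bottom strand must
        # match the top strand within sampling error at every offset
        track, hs, _ = wt_small
        mat = rs.coorient(rs.stack_windows(track, hs, 3000))
        n = mat.n_hotspots
        diff = mat.top.mean(axis=0) - mat.bottom.mean(axis=0)
        se = np.sqrt(mat.top.var(axis=0, ddof=1) / n + mat.bottom.var(axis=0, ddof=1) / n)
        frac_out = np.mean(np.abs(diff) > 3 * se + 1e-12)
        assert frac_out < 0.02


class TestGenomeAverage:
    def test_identical_rows_return_that_row(self):
        row = np.arange(7, dtype=float)
        mat = rs.HotspotMatrix(top=np.vstack([row, row]), bottom=np.vstack([row, row]),
                               half_width=3, units="RPM",
                               hotspot_index=np.arange(2), co_oriented=True)
        prof = rs.genome_average(mat)
        np.testing.assert_allclose(prof.values, row)

    def test_two_complementary_rows_average(self):
        mat = rs.HotspotMatrix(top=np.array([[0.0, 2.0, 0.0]]),
                               bottom=np.array([[2.0, 0.0, 2.0]]),
                               half_width=1, units="RPM",
                               hotspot_index=np.arange(1), co_oriented=True)
        prof = rs.genome_average(mat)
        np.testing.assert_allclose(prof.values, [1.0, 1.0, 1.0])

    def test_matches_brute_force_mean(self, rng):
        top = rng.random((9, 11))
        bottom = rng.random((9, 11))
        mat = rs.HotspotMatrix(top=top, bottom=bottom, half_width=5, units="RPM",
                               hotspot_index=np.arange(9), co_oriented=True)
        prof = rs.genome_average(mat)
        np.testing.assert_allclose(prof.values, (top.sum(0) + bottom.sum(0)) / 18, rtol=1e-12)

    def test_commutes_with_row_scaling(self, rng):
        top = rng.random((5, 9))
        bottom = rng.random((5, 9))
        mat = rs.HotspotMatrix(top=top, bottom=bottom, half_width=4, units="RPM",
                               hotspot_index=np.arange(5), co_oriented=True)
        scaled = rs.HotspotMatrix(top=3.5 * top, bottom=3.5 * bottom, half_width=4,
                                  units="RPM", hotspot_index=np.arange(5), co_oriented=True)
        np.testing.assert_allclose(rs.genome_average(scaled).values,
                                   3.5 * rs.genome_average(mat).values, rtol=1e-12)

    def test_mask_restricts_rows(self, rng):
        top = rng.random((4, 5))
        mat = rs.HotspotMatrix(top=top, bottom=np.zeros_like(top), half_width=2,
                               units="RPM", hotspot_index=np.arange(4), co_oriented=True)
        mask = np.array([True, False, True, False])
        prof = rs.genome_average(mat, mask=mask)
        np.testing.assert_allclose(prof.values, top[mask].sum(0) / 4, rtol=1e-12)


class TestHannSmooth:
    def test_constant_profile_unchanged(self):
        prof = make_profile(np.full(501, 3.25))
        out = rs.hann_smooth(prof, 151)
        np.testing.assert_allclose(out.values, 3.25, rtol=1e-12)
        assert out.smoothing_window == 151

    def test_window_one_is_identity(self, rng):
        prof = make_profile(rng.random(101))
        np.testing.assert_array_equal(rs.hann_smooth(prof, 1).values, prof.values)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            rs.hann_smooth(make_profile(np.ones(11)), 10)

    def test_matches_naive_convolution(self, rng):
        values = rng.random(301)
        window = 51
        kernel = hann_kernel(window)
        half = window // 2
        expected = np.empty_like(values)
        for i in range(len(values)):  # direct truncated-renormalized convolution
            lo, hi = max(0, i - half), min(len(values), i + half + 1)
            klo = half - (i - lo)
            seg = kernel[klo:klo + (hi - lo)]
            expected[i] = (values[lo:hi] * seg).sum() / seg.sum()
        np.testing.assert_allclose(hann_smooth_array(values, window), expected, atol=1e-10)

    def test_interior_sum_preserved(self, rng):
        values = np.zeros(1001)
        values[300:700] = rng.random(400)  # support >= window away from edges
        out = hann_smooth_array(values, 151)
        assert out.sum() == pytest.approx(values.sum(), rel=5e-3)


class TestBackgroundSubtraction:
    def test_constant_profile_becomes_zero(self, analysis_config):
        prof = make_profile(np.full(6001, 0.7))
        out = rs.subtract_background(prof, analysis_config)
        assert out.background_subtracted
        np.testing.assert_allclose(out.values, 0.0)

    def test_zero_background_leaves_profile(self, analysis_config):
        values = np.zeros(6001)
        values[3000] = 5.0  # far from the +2500 background window
        prof = make_profile(values)
        out = rs.subtract_background(prof, analysis_config)
        np.testing.assert_allclose(out.values, values)

    def test_output_never_negative(self, analysis_config, rng):
        for _ in range(20):
            prof = make_profile(rng.random(6001))
            out = rs.subtract_background(prof, analysis_config)
            assert out.values.min() >= 0

    def test_short_profile_rejected(self, analysis_config):
        with pytest.raises(ValidationError):
            rs.subtract_background(make_profile(np.ones(501)), analysis_config)


class TestNormalization:
    def _subtracted(self, values, cfg):
        return rs.subtract_background(make_profile(values), cfg)

    def test_peak_becomes_one(self, analysis_config, rng):
        values = np.zeros(6001)
        values[3900] = 0.004  # offset +900
        out = rs.normalize_to_peak(self._subtracted(values, analysis_config), analysis_config)
        assert out.values[3900] == 1.0
        assert out.normalization == "peak"

    def test_peak_is_exactly_one_for_random_input(self, analysis_config, rng):
        for _ in range(10):
            values = rng.random(6001)
            out = rs.normalize_to_peak(self._subtracted(values, analysis_config),
                                       analysis_config)
            sel = (out.offsets >= 100) & (out.offsets <= 2500)
            assert out.values[sel].max() == pytest.approx(1.0, abs=1e-12)

    def test_zero_resection_window_rejected(self, analysis_config):
        values = np.zeros(6001)
        values[0] = 1.0  # offset -3000 only
        with pytest.raises(DegenerateProfileError):
            rs.normalize_to_peak(self._subtracted(values, analysis_config), analysis_config)

    def test_area_sums_to_one(self, analysis_config, rng):
        values = rng.random(6001)
        out = rs.normalize_area(self._subtracted(values, analysis_config), analysis_config)
        assert out.window_sum(-1000, 2500) == pytest.approx(1.0, abs=1e-9)

    def test_area_normalization_scale_invariant(self, analysis_config, rng):
        values = rng.random(6001) + 0.1
        a = rs.normalize_area(self._subtracted(values, analysis_config), analysis_config)
        b = rs.normalize_area(self._subtracted(5.5 * values, analysis_config), analysis_config)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_subtract_then_peak_idempotent(self, analysis_config):
        # signal bump on a flat background: one pass zeroes the background and
        # sets the peak to 1, so a second pass changes nothing
        offsets = np.arange(-3000, 3001)
        values = 0.2 + 0.004 * np.exp(-0.5 * ((offsets - 800) / 200.0) ** 2)
        once = rs.normalize_to_peak(self._subtracted(values, analysis_config), analysis_config)
        again = rs.normalize_to_peak(
            rs.subtract_background(make_profile(once.values), analysis_config),
            analysis_config)
        np.testing.assert_allclose(again.values, once.values, atol=1e-12)


def test_pipeline_determinism(wt_small, analysis_config):
    track, hs, _ = wt_small
    a_raw, a_sm = rs.resection_stats.analysis_profiles(track, hs, analysis_config)
    b_raw, b_sm = rs.resection_stats.analysis_profiles(track, hs, analysis_config)
    assert np.array_equal(a_raw.values, b_raw.values)
    assert np.array_equal(a_sm.values, b_sm.values)
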