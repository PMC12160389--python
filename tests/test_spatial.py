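"""Band-pass filter, correlation maps, surrogates, and wavelength tests."""

import numpy as np
import pytest

from spontdyn.movie import disk_roi
from spontdyn.events import max_active_frame
from spontdyn.spatial import (
    FilterSpec,
    FrameTransformer,
    bandpass,
    correlation_map,
    dog_transfer,
    long_range_significance,
    surrogate_ensemble,
    wavelength,
)


class TestBandpass:
    def test_constant_frame_maps_to_zero(self):
        roi = np.ones((30, 30), bool)
        out = bandpass(np.full((30, 30), 7.0), roi)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_impulse_center_surround(self):
        roi = np.ones((41, 41), bool)
        frame = np.zeros((41, 41))
        frame[20, 20] = 1.0
        out = bandpass(frame, roi)
        assert out[20, 20] > 0
        assert out.min() < 0
        assert abs(out.sum()) < 1e-6 * abs(out[20, 20])

    def test_sinusoid_amplitude_matches_analytic_transfer(self):
        """Oracle: the DoG transfer exp(-2 pi^2 s^2 f^2) difference."""
        pitch = 46.9
        lam_mm = 0.69
        h = w = 96
        x_mm = np.arange(w) * pitch / 1000.0
        frame = np.cos(2 * np.pi * x_mm / lam_mm)[None, :] * np.ones((h, 1))
        roi = np.ones((h, w), bool)
        out = bandpass(frame, roi, pixel_pitch_um=pitch)
        # measure amplitude away from edges
        gain = out[h // 2, 20:-20].std() / frame[h // 2, 20:-20].std()
        expected = dog_transfer(1.0 / lam_mm)
        assert gain == pytest.approx(float(expected), rel=0.05)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(200.0, 100.0)
        with pytest.raises(ValueError, match="one pixel"):
            bandpass(np.ones((5, 5)), np.ones((5, 5), bool), FilterSpec(5.0, 20.0), 46.9)


class TestCorrelationMap:
    def test_seed_autocorrelation_is_one(self, rng):
        roi = np.ones((10, 10), bool)
        frames = rng.standard_normal((30, 10, 10))
        cm = correlation_map(frames, (4, 4), roi)
        assert cm[4, 4] == pytest.approx(1.0)

    def test_sign_flipping_pattern_gives_unit_magnitude(self, rng):
        roi = np.ones((12, 12), bool)
        pat = rng.standard_normal((12, 12))
        frames = np.stack([pat if i % 2 == 0 else -pat for i in range(20)])
        cm = correlation_map(frames, (6, 6), roi)
        np.testing.assert_allclose(np.abs(cm), 1.0, atol=1e-10)

    def test_matches_brute_force_pearson(self, rng):
        """Oracle: per-pixel np.corrcoef."""
        roi = np.ones((8, 9), bool)
        frames = rng.standard_normal((25, 8, 9))
        seed = (3, 4)
        cm = correlation_map(frames, seed, roi)
        for r in range(8):
            for c in range(9):
                expect = np.corrcoef(frames[:, r, c], frames[:, seed[0], seed[1]])[0, 1]
                assert cm[r, c] == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_seed_raises(self):
        roi = np.ones((5, 5), bool)
        frames = np.zeros((20, 5, 5))
        with pytest.raises(ValueError, match="seed"):
            correlation_map(frames, (2, 2), roi)


class _IdentityRng:
    """Stub generator: always rotation 0, never reflect."""

    def choice(self, options, size):
        return np.zeros(size, dtype=int)

    def random(self, n):
        return np.ones(n)


class TestSurrogates:
    def test_identity_transform_preserves_frame(self, rng):
        roi = disk_roi((21, 21), 0.9, 46.9)
        tf = FrameTransformer(roi)
        frame = rng.standard_normal((21, 21))
        out = tf.transform(frame, 0, False, False)
        np.testing.assert_array_equal(out[roi], frame[roi])

    def test_identity_surrogate_equals_real_map(self, rng):
        roi = disk_roi((21, 21), 0.9, 46.9)
        frames = np.stack([np.where(roi, rng.standard_normal((21, 21)), np.nan) for _ in range(15)])
        seed = (10, 10)
        real = correlation_map(frames, seed, roi)
        surr = surrogate_ensemble(frames, seed, roi, n_surrogates=2, rng=_IdentityRng())
        for sm in surr:
            np.testing.assert_allclose(sm[roi], real[roi], atol=1e-10)

    def test_rotation_masks_pixels_outside_roi(self, rng):
        roi = np.zeros((21, 21), bool)
        roi[8:13, 2:19] = True  # elongated ROI: rotation by 90 deg exits it
        tf = FrameTransformer(roi)
        out = tf.transform(rng.standard_normal((21, 21)), 90, False, False)
        assert np.isnan(out[roi]).any()


class TestLongRangeSignificance:
    def _map_with_peak(self, roi, seed, value, pitch=100.0):
        """Smooth map: global max at the seed plus one bump 1.5 mm away."""
        h, w = roi.shape
        rr, cc = np.mgrid[0:h, 0:w]
        sr, sc = seed
        d_seed = np.hypot(rr - sr, cc - sc)
        d_bump = np.hypot(rr - (sr + 15), cc - sc)  # 15 px * 0.1 mm = 1.5 mm
        cmap = np.exp(-d_seed / 4.0) + value * np.exp(-(d_bump**2) / (2 * 2.0**2))
        return np.where(roi, cmap, np.nan)

    def test_p_zero_and_one(self):
        pitch = 100.0
        roi = disk_roi((41, 41), 4.0, pitch)
        seed = (20, 20)
        real = self._map_with_peak(roi, seed, 0.9, pitch)
        low = [self._map_with_peak(roi, seed, 0.1, pitch) for _ in range(10)]
        high = [self._map_with_peak(roi, seed, 0.95, pitch) for _ in range(10)]
        res = long_range_significance(real, low, seed, roi, pixel_pitch_um=pitch)
        assert res.p_value == 0.0
        res = long_range_significance(real, high, seed, roi, pixel_pitch_um=pitch)
        assert res.p_value == 1.0

    def test_no_peak_in_band_is_flagged_not_zero(self):
        pitch = 100.0
        roi = disk_roi((41, 41), 4.0, pitch)
        seed = (20, 20)
        h, w = roi.shape
        rr, cc = np.mgrid[0:h, 0:w]
        cone = np.where(roi, np.exp(-np.hypot(rr - 20, cc - 20) / 6.0), np.nan)
        res = long_range_significance(cone, [cone] * 5, seed, roi, pixel_pitch_um=pitch)
        assert res.p_value is None and res.long_range_median is None

    def test_null_calibration(self):
        """On isotropic noise frames the surrogate p-value is roughly
        uniform: the 5% tail is hit about 5% of the time."""
        pitch = 80.0
        grid = (50, 50)
        roi = disk_roi(grid, 3.8, pitch)
        seed = (25, 25)
        ps = []
        for rep in range(40):
            r2 = np.random.default_rng(500 + rep)
            frames = np.stack(
                [bandpass(r2.standard_normal(grid), roi, pixel_pitch_um=pitch) for _ in range(25)]
            )
            cm = correlation_map(frames, seed, roi)
            surr = surrogate_ensemble(frames, seed, roi, n_surrogates=40, rng=r2)
            res = long_range_significance(cm, surr, seed, roi, pixel_pitch_um=pitch)
            if res.p_value is not None:
                ps.append(res.p_value)
        ps = np.asarray(ps)
        assert len(ps) >= 30
        assert (ps < 0.05).mean() <= 0.2
        assert 0.25 < ps.mean() < 0.75

    def test_planted_long_range_structure_detected(self, rng):
        """A module network activating with varying strength across events
        produces long-range correlations that beat the rotation null."""
        from spontdyn.synthetic import make_modular_pattern

        pitch = 46.9
        grid = (80, 80)
        roi = disk_roi(grid, 3.7, pitch)
        pat = make_modular_pattern(grid, 0.69, pitch, rng=3)
        amps = rng.standard_normal(60)
        frames = np.stack(
            [a * pat + 0.5 * rng.standard_normal(grid) for a in amps]
        )
        frames = np.stack([bandpass(f, roi, pixel_pitch_um=pitch) for f in frames])
        sr, sc = np.unravel_index(np.argmax(np.where(roi, pat, -np.inf)), grid)
        cm = correlation_map(frames, (sr, sc), roi)
        surr = surrogate_ensemble(frames, (sr, sc), roi, n_surrogates=40, rng=rng)
        res = long_range_significance(cm, surr, (sr, sc), roi, pixel_pitch_um=pitch)
        assert res.p_value is not None and res.p_value <= 0.05


class TestWavelength:
    def test_scale_invariance(self):
        from spontdyn.synthetic import make_modular_pattern

        roi = np.ones((64, 64), bool)
        pat = make_modular_pattern((64, 64), 0.69, 46.9, rng=5)
        a = wavelength(pat, roi, 46.9, prefiltered=True)
        b = wavelength(123.0 * pat, roi, 46.9, prefiltered=True)
        assert a == pytest.approx(b)

    def test_matches_brute_force_first_minimum(self):
        """Oracle: direct spatial-domain radial autocorrelation, including
        on a plane wave (whose radial average is Bessel-like, putting the
        first minimum well beyond half the sinusoid period)."""
        from test_synthetic import brute_force_radial_autocorr
        from spontdyn.synthetic import make_modular_pattern

        roi = np.ones((64, 64), bool)
        x_mm = np.arange(64) * 46.9 / 1000.0
        plane = np.cos(2 * np.pi * x_mm / 0.69)[None, :] * np.ones((64, 1))
        for pat in (plane, make_modular_pattern((64, 64), 0.69, 46.9, rng=2)):
            est = wavelength(pat, roi, 46.9, prefiltered=True)
            prof = brute_force_radial_autocorr(pat, 24)
            mins = [
                b
                for b in range(1, len(prof) - 1)
                if prof[b] < prof[b - 1] and prof[b] < prof[b + 1]
            ]
            expect = 2 * mins[0] * 46.9 / 1000.0
            assert est == pytest.approx(expect, abs=2 * 46.9 / 1000.0)

    def test_modular_frames_recover_generator_wavelength(self):
        from spontdyn.synthetic import make_modular_pattern

        rng = np.random.default_rng(8)
        roi = np.ones((64, 64), bool)
        lams = [
            wavelength(make_modular_pattern((64, 64), 0.69, 46.9, rng), roi, 46.9)
            for _ in range(20)
        ]
        lams = [x for x in lams if x is not None]
        assert np.median(lams) == pytest.approx(0.69, abs=0.0469)

    def test_undefined_when_no_minimum(self):
        """A monotonically decaying autocorrelation has no first minimum
        within the ROI radius: flagged undefined rather than guessed."""
        roi = np.ones((32, 32), bool)
        rr = np.hypot(*np.mgrid[-16:16, -16:16])
        smooth = np.exp(-(rr**2) / (2 * 30.0**2))
        assert wavelength(smooth, roi, 46.9, prefiltered=True) is None


def test_single_frame_and_summed_maps_similar(motif_segmented):
    """Maximally-active-frame and summed-event correlation maps share
    spatial structure on repeated-motif sessions."""
    _, _, y, events, _, _ = motif_segmented
    maxf, sumf = [], []
    for ev in events:
        t = max_active_frame(ev)
        maxf.append(bandpass(ev.activity[..., t], y.roi, pixel_pitch_um=y.pixel_pitch_um))
        sumf.append(bandpass(ev.activity.sum(axis=-1), y.roi, pixel_pitch_um=y.pixel_pitch_um))
    maxf, sumf = np.stack(maxf), np.stack(sumf)
    var = np.var(maxf, axis=0)
    sr, sc = np.unravel_index(np.argmax(np.where(y.roi, var, -1)), y.roi.shape)
    cm_max = correlation_map(maxf, (sr, sc), y.roi)
    cm_sum = correlation_map(sumf, (sr, sc), y.roi)
    ok = np.isfinite(cm_max) & np.isfinite(cm_sum)
    r = np.corrcoef(cm_max[ok], cm_sum[ok])[0, 1]
    assert r > 0.8
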