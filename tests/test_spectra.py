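import numpy as np
import pytest

import minispec as ms
from minispec.spectra import (
    FLAG_NONPOSITIVE,
    FLAG_OK,
    FLAG_SATURATED,
    UnusableBaselineError,
    WavelengthCalibration,
)
from minispec.simulate import acquire_frames, expected_counts


class TestRawSpectrum:
    def test_counts_validated_against_adc_range(self, frame_factory):
        with pytest.raises(ValueError, match="pixel 1"):
            frame_factory([0, 2000, 5], bits=10)

    def test_negative_counts_rejected(self, frame_factory):
        with pytest.raises(ValueError):
            frame_factory([-1, 0, 0])

    def test_bad_role_rejected(self, frame_factory):
        with pytest.raises(ValueError, match="role"):
            frame_factory([1, 2], role="blank")

    def test_full_scale_default_10_bits(self, frame_factory):
        assert frame_factory([0]).full_scale == 1023

    def test_saturated_mask(self, frame_factory):
        f = frame_factory([1023, 100, 1023])
        assert f.saturated.tolist() == [True, False, True]


class TestWavelengthCalibration:
    def test_default_map_strictly_increasing(self, cal):
        lam = cal.wavelengths()
        assert np.all(np.diff(lam) > 0)

    def test_default_map_spans_chip_limits(self, cal):
        lam = cal.wavelengths()
        assert lam[0] == pytest.approx(340.0)
        assert lam[-1] == pytest.approx(850.0, abs=0.5)

    def test_working_range_step_bounds(self, cal):
        # adjacent-pixel steps over 450-750 nm stay within [1.5, 3.0] nm
        lam = cal.wavelengths(cal.working_pixels())
        steps = np.diff(lam)
        assert steps.min() >= 1.5 and steps.max() <= 3.0

    def test_mean_step_over_working_range(self, cal):
        # oracle: finite differences of the default polynomial
        lam = cal.wavelengths(cal.working_pixels())
        assert 2.0 <= np.diff(lam).mean() <= 2.4

    def test_constant_term_is_pixel_zero(self):
        c = WavelengthCalibration(
            coefficients=(340.0, 1.77, 0.0), working_range=(450.0, 750.0)
        )
        assert ms.pixel_to_wavelength(c, 0) == pytest.approx(340.0)

    def test_linear_map_pixel_100(self):
        c = WavelengthCalibration(
            coefficients=(340.0, 1.77, 0.0), working_range=(450.0, 750.0)
        )
        assert ms.pixel_to_wavelength(c, 100) == pytest.approx(517.0)

    def test_out_of_range_pixel_rejected(self, cal):
        with pytest.raises(ValueError):
            ms.pixel_to_wavelength(cal, 288)

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WavelengthCalibration(coefficients=(500.0, -1.0), working_range=(450.0, 460.0))

    def test_working_range_must_be_covered(self):
        with pytest.raises(ValueError, match="working_range"):
            WavelengthCalibration(coefficients=(500.0, 0.1), working_range=(450.0, 750.0))


class TestDarkCorrect:
    def test_identity_gives_zero(self, frame_factory):
        f = frame_factory([7, 8, 9])
        assert ms.dark_correct(f, f).tolist() == [0.0, 0.0, 0.0]

    def test_hand_arithmetic(self, frame_factory):
        frame = frame_factory([100, 200])
        dark = frame_factory([10, 10], role="dark")
        assert ms.dark_correct(frame, dark).tolist() == [90.0, 190.0]

    def test_negative_residuals_preserved(self, frame_factory):
        frame = frame_factory([5, 20])
        dark = frame_factory([10, 10], role="dark")
        assert ms.dark_correct(frame, dark).tolist() == [-5.0, 10.0]

    def test_length_mismatch_rejected(self, frame_factory):
        with pytest.raises(ValueError, match="pixel count"):
            ms.dark_correct(frame_factory([1, 2]), frame_factory([1, 2, 3]))

    def test_exposure_mismatch_rejected(self, frame_factory):
        with pytest.raises(ValueError, match="exposure"):
            ms.dark_correct(frame_factory([1], exposure=200), frame_factory([1], exposure=100))

    def test_residual_mean_near_zero_on_simulated_dark(self, instrument, rng):
        # oracle: averaging 50 simulated dark frames with known offset
        det = instrument.detector
        frames = acquire_frames(instrument, 50, role="dark", rng=rng)
        mean_frame = ms.accumulate(frames)
        offset = ms.RawSpectrum(
            counts=np.full(det.n_pixels, round(det.dark_mean), dtype=np.int64),
            exposure_us=det.exposure_ref_us, role="dark", bits=det.bits,
        )
        residual = ms.dark_correct(mean_frame, offset)
        assert abs(residual.mean()) < 3 * det.dark_rms / np.sqrt(50)


class TestAccumulate:
    def test_single_frame_identity(self, frame_factory):
        f = frame_factory([1, 2, 3])
        acc = ms.accumulate([f])
        assert acc.counts.tolist() == [1.0, 2.0, 3.0]
        assert acc.n_frames == 1

    def test_two_frame_mean(self, frame_factory):
        acc = ms.accumulate([frame_factory([0, 2]), frame_factory([2, 0])])
        assert acc.counts.tolist() == [1.0, 1.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ms.accumulate([])

    def test_mixed_roles_rejected(self, frame_factory):
        with pytest.raises(ValueError, match="roles"):
            ms.accumulate([frame_factory([1]), frame_factory([1], role="dark")])

    def test_std_of_mean_shrinks_like_sqrt_n(self, instrument, rng):
        # oracle: sample statistics of 40 independent 50-frame accumulations
        det = instrument.detector
        means = np.stack(
            [ms.accumulate(acquire_frames(instrument, 50, role="dark", rng=rng)).counts
             for _ in range(40)]
        )
        pooled_sd = means.std(axis=0, ddof=1).mean()
        expected = det.dark_rms / np.sqrt(50)
        assert pooled_sd == pytest.approx(expected, rel=0.25)

    def test_saturation_propagates(self, frame_factory):
        acc = ms.accumulate([frame_factory([1023, 5]), frame_factory([100, 5])])
        assert acc.saturated.tolist() == [True, False]


class TestComputeAbsorbance:
    def test_sample_equals_baseline_gives_zero(self, instrument, cal, rng):
        frame = acquire_frames(instrument, 1, role="baseline", rng=rng)[0]
        spec = ms.compute_absorbance(frame, frame, cal=cal)
        ok = [i for i, f in enumerate(spec.flags) if f == FLAG_OK]
        assert len(ok) > 50
        assert np.allclose(spec.absorbance[ok], 0.0)

    def test_decade_attenuation_gives_unit_absorbance(self, frame_factory):
        n = 288
        baseline = frame_factory([1000] * n, role="baseline")
        sample = frame_factory([100] * n, role="sample")
        spec = ms.compute_absorbance(sample, baseline)
        assert np.allclose(spec.absorbance, 1.0)

    def test_dark_subtraction_applied(self, frame_factory):
        n = 288
        baseline = frame_factory([1010] * n, role="baseline")
        sample = frame_factory([110] * n, role="sample")
        dark = frame_factory([10] * n, role="dark")
        spec = ms.compute_absorbance(sample, baseline, dark)
        assert np.allclose(spec.absorbance, 1.0)

    def test_nonpositive_signal_flagged_nan(self, frame_factory):
        n = 288
        baseline = frame_factory([100] * n, role="baseline")
        counts = [50] * n
        sample = frame_factory(counts, role="sample")
        dark = frame_factory([60] * n, role="dark")  # sample - dark < 0
        spec = ms.compute_absorbance(sample, baseline, dark)
        assert all(f == FLAG_NONPOSITIVE for f in spec.flags)
        assert np.all(np.isnan(spec.absorbance))

    def test_unusable_baseline_raises(self, frame_factory):
        n = 288
        baseline = frame_factory([5] * n, role="baseline")
        sample = frame_factory([50] * n, role="sample")
        dark = frame_factory([10] * n, role="dark")
        with pytest.raises(UnusableBaselineError):
            ms.compute_absorbance(sample, baseline, dark)

    def test_saturated_pixels_flagged(self, frame_factory):
        n = 288
        base = [500] * n
        base[100] = 1023
        baseline = frame_factory(base, role="baseline")
        sample = frame_factory([250] * n, role="sample")
        spec = ms.compute_absorbance(sample, baseline)
        cal = ms.default_calibration()
        idx = 100 - cal.working_pixels()[0]
        assert spec.flags[idx] == FLAG_SATURATED

    def test_wavelengths_restricted_to_working_range(self, frame_factory, cal):
        n = 288
        spec = ms.compute_absorbance(
            frame_factory([100] * n), frame_factory([200] * n, role="baseline"), cal=cal
        )
        lo, hi = cal.working_range
        assert spec.wavelengths[0] >= lo and spec.wavelengths[-1] <= hi

    def test_recovers_programmed_absorbance(self, instrument, flat_sample, cal, rng):
        # oracle: noiseless forward model sets epsilon*c*l = 0.5 on a flat band
        base = ms.accumulate(acquire_frames(instrument, 50, role="baseline", rng=rng))
        samp = ms.accumulate(acquire_frames(instrument, 50, flat_sample, "sample", rng=rng))
        dark = ms.accumulate(acquire_frames(instrument, 50, role="dark", rng=rng))
        spec = ms.compute_absorbance(samp, base, dark, cal)
        core = (spec.wavelengths > 510) & (spec.wavelengths < 590)
        assert np.nanmean(spec.absorbance[core]) == pytest.approx(0.5, abs=0.02)

    def test_absorbance_additivity_noiseless(self, instrument, flat_analyte, cal):
        # two sequential attenuations equal their sum in the noiseless limit
        from minispec.simulate import SampleModel

        det = instrument.detector
        def noiseless_absorbance(conc):
            sample = SampleModel(constituents=((flat_analyte, conc),))
            b = expected_counts(instrument, None, "baseline", det.exposure_ref_us)
            s = expected_counts(instrument, sample, "sample", det.exposure_ref_us)
            pix = cal.working_pixels()
            return np.log10((b - det.dark_mean)[pix] / (s - det.dark_mean)[pix])

        a1, a2, a12 = noiseless_absorbance(0.2), noiseless_absorbance(0.3), noiseless_absorbance(0.5)
        lam = cal.wavelengths(cal.working_pixels())
        core = (lam > 510) & (lam < 590)
        assert np.allclose(a12[core], (a1 + a2)[core], atol=1e-9)


class TestAbsorbanceAt:
    def _spec(self, grid, values, flags=None):
        flags = flags or tuple(FLAG_OK for _ in grid)
        return ms.AbsorbanceSpectrum(np.asarray(grid, float), np.asarray(values, float), flags)

    def test_grid_hit_returns_stored_value(self):
        spec = self._spec([500.0, 502.0], [0.1, 0.3])
        value, flag = ms.absorbance_at(spec, 502.0)
        assert value == 0.3 and flag == FLAG_OK

    def test_midpoint_interpolation(self):
        spec = self._spec([500.0, 502.0], [0.1, 0.3])
        value, _ = ms.absorbance_at(spec, 501.0)
        assert value == pytest.approx(0.2)

    def test_out_of_range_query_rejected(self):
        spec = self._spec([500.0, 502.0], [0.1, 0.3])
        with pytest.raises(ValueError, match="outside"):
            ms.absorbance_at(spec, 499.0)

    def test_undefined_bracket_returns_nan_flag(self):
        spec = self._spec(
            [500.0, 502.0], [0.1, np.nan], (FLAG_OK, FLAG_NONPOSITIVE)
        )
        value, flag = ms.absorbance_at(spec, 501.0)
        assert np.isnan(value) and flag == FLAG_NONPOSITIVE

    @pytest.mark.parametrize("query_nm", [550.0, 600.0, 700.0])
    def test_interpolation_matches_dense_oracle(self, instrument, cal, query_nm):
        # oracle: noiseless forward model evaluated on the pixel grid, with
        # the interpolation error bound from the max second difference
        from minispec.simulate import AnalyteSpectrum, SampleModel

        analyte = AnalyteSpectrum("band", bands=(ms.GaussianBand(query_nm, 60.0, 1.0),))
        sample = SampleModel(constituents=((analyte, 0.8),))
        det = instrument.detector
        b = expected_counts(instrument, None, "baseline", det.exposure_ref_us) - det.dark_mean
        s = expected_counts(instrument, sample, "sample", det.exposure_ref_us) - det.dark_mean
        pix = cal.working_pixels()
        lam = cal.wavelengths(pix)
        a = np.log10(b[pix] / s[pix])
        spec = ms.AbsorbanceSpectrum(lam, a, tuple(FLAG_OK for _ in lam))
        value, _ = ms.absorbance_at(spec, query_nm)

        # dense oracle: blurred forward model evaluated at the query itself
        truth_b = instrument.expected_signal_at(None, det.exposure_ref_us, query_nm)
        truth_s = instrument.expected_signal_at(sample, det.exposure_ref_us, query_nm)
        truth = np.log10(truth_b / truth_s)
        bound = 0.5 * np.max(np.abs(np.diff(a, 2)))
        assert abs(value - truth) <= max(bound, 1e-9)
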