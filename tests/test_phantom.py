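"""Generators must honour their own ground truth: prescribed transit
delays, wrap arithmetic, disk diameters and the cohort's linear model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortapwv import (
    CinePhantomSpec,
    CohortSpec,
    PhantomSpec,
    make_cine_phantom,
    make_flow_phantom,
    simulate_cohort,
)
from aortapwv.phantom import TABLE3_CELL_SIZES, systolic_waveform, wrap_to_venc

from conftest import small_flow_spec


class TestFlowPhantom:
    def test_transit_delay_matches_arc_length_over_pwv(self, small_phantom):
        """Through-lumen velocity at arc length s lags the inlet by s/PWV."""
        field, cl, mask = small_phantom
        spec = small_flow_spec()
        t = field.times
        for s in (0.0, 75.0, 150.0):
            p = cl.point_at(s)
            vox = tuple(np.round(p / np.asarray(field.spacing)).astype(int))
            # the voxel center sits slightly off the requested arc length;
            # use its own nearest point on the centerline
            world = np.asarray(vox) * np.asarray(field.spacing)
            nearest = np.argmin(np.linalg.norm(cl.points - world, axis=1))
            s_vox = cl.arc_length[nearest]
            speed = np.sqrt(sum(field.velocity[c][vox] ** 2 for c in range(3)))
            expected = systolic_waveform(
                t - s_vox / (spec.true_pwv * 1000.0),
                spec.onset_s, spec.upstroke_s, spec.downstroke_s,
                spec.peak_velocity,
            )
            assert np.allclose(speed, np.abs(expected), atol=1e-9)

    def test_wrap_arithmetic(self):
        """A 1.7 m/s component at venc 1.5 stores as 1.7 - 2*1.5 = -1.3."""
        assert wrap_to_venc(np.array([1.7]), 1.5)[0] == pytest.approx(-1.3)
        assert wrap_to_venc(np.array([-1.6]), 1.5)[0] == pytest.approx(1.4)

    def test_wrapped_field_lies_within_venc(self):
        spec = small_flow_spec(peak_velocity=1.7, wrap_enabled=True, noise_sd=0.05)
        field, _, _ = make_flow_phantom(spec)
        assert field.velocity.min() >= -spec.venc
        assert field.velocity.max() < spec.venc

    def test_deterministic_under_seed(self):
        spec = small_flow_spec(noise_sd=0.05, seed=7)
        f1, _, _ = make_flow_phantom(spec)
        f2, _, _ = make_flow_phantom(small_flow_spec(noise_sd=0.05, seed=7))
        assert np.array_equal(f1.velocity, f2.velocity)

    def test_zero_away_from_lumen_without_artifacts(self, small_phantom):
        """Velocity vanishes beyond the one-voxel partial-volume rim."""
        from scipy import ndimage

        field, _, mask = small_phantom
        far = ~ndimage.binary_dilation(mask.mask, iterations=2)
        assert np.all(field.velocity[:, far, :] == 0.0)
        # and the rim voxels carry attenuated, not full, velocity
        rim = ndimage.binary_dilation(mask.mask) & ~mask.mask
        rim_peak = np.abs(field.velocity[:, rim, :]).max()
        assert 0.0 < rim_peak < 0.6 * small_flow_spec().peak_velocity

    def test_unresolvable_lumen_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            small_flow_spec(lumen_radius_mm=4.0)

    def test_short_acquisition_warns(self):
        with pytest.warns(UserWarning, match="never fully arrives"):
            make_flow_phantom(small_flow_spec(n_phases=10))

    @given(v=st.floats(-4.0, 4.0), venc=st.floats(0.5, 2.0))
    @settings(deadline=None, derandomize=True)
    def test_wrap_stays_in_encoding_range(self, v, venc):
        w = wrap_to_venc(np.array([v]), venc)[0]
        assert -venc <= w < venc
        # difference from the true value is an even multiple of venc
        k = (v - w) / (2 * venc)
        assert abs(k - round(k)) < 1e-9


class TestCinePhantom:
    def test_true_curve_matches_spec(self, cine_phantom):
        spec, _, truth = cine_phantom
        assert truth.dd_mm == pytest.approx(24.0)
        assert truth.delta_d_mm == pytest.approx(2.0)
        assert truth.diameters_mm.max() == pytest.approx(26.0)

    def test_thresholded_area_matches_rasterization_oracle(self):
        """Noise/blur-free disk: pixel-count area within 2% of pi r^2."""
        spec = CinePhantomSpec(blur_sd_px=0.0, noise_sd=0.0)
        series, truth = make_cine_phantom(spec)
        frame = series.frames[0]
        level = 0.5 * (spec.background_intensity + spec.vessel_intensity)
        area_px = np.sum(frame > level)
        # oracle: count pixel centers inside the analytic circle
        h, w = spec.image_size
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        r_px = truth.dd_mm / 2 / spec.pixel_spacing_mm
        oracle = np.sum(
            (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2 <= r_px**2
        )
        analytic = np.pi * r_px**2
        assert abs(area_px - analytic) / analytic < 0.02
        assert abs(oracle - analytic) / analytic < 0.02

    def test_deterministic_under_seed(self):
        s1, _ = make_cine_phantom(CinePhantomSpec(noise_sd=0.05, seed=3))
        s2, _ = make_cine_phantom(CinePhantomSpec(noise_sd=0.05, seed=3))
        assert np.array_equal(s1.frames, s2.frames)

    def test_disk_exceeding_image_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            make_cine_phantom(CinePhantomSpec(dd_mm=24.0, image_size=(16, 16)))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CinePhantomSpec(delta_d_mm=-1.0)
        with pytest.raises(ValueError):
            CinePhantomSpec(dd_mm=2.0, delta_d_mm=3.0)


class TestCohortSimulator:
    def test_noise_free_pwv_is_exactly_linear_in_age_and_sex(self):
        """sigma = 0 subjects lie exactly on the generating plane."""
        spec = CohortSpec(sigma=0.0, method_scatter=0.0, covariates=False, seed=3)
        df = simulate_cohort(spec)
        expected = spec.beta0 + spec.beta_age * df["age"] + spec.beta_male * df["male"]
        assert np.allclose(df["pwv_xcor"], expected, atol=1e-12)

    def test_reference_predictions_match_worked_examples(self):
        """Model fitted on sigma=0 data predicts 6.04 m/s for a 50-year-old
        man and 3.11 m/s for a 20-year-old woman."""
        from aortapwv import fit_reference_model

        df = simulate_cohort(
            CohortSpec(sigma=0.0, method_scatter=0.0, covariates=False, seed=3)
        )
        res = fit_reference_model(df)
        assert res.predict(50, 1) == pytest.approx(6.04, abs=1e-6)
        assert res.predict(20, 0) == pytest.approx(3.11, abs=1e-6)

    def test_reference_cell_sizes_total_126(self):
        df = simulate_cohort(CohortSpec(covariates=False, seed=0))
        assert len(df) == 126
        assert sum(TABLE3_CELL_SIZES.values()) == 126
        assert (df["sex"] == "female").sum() == 64

    def test_ages_stay_inside_their_decades(self):
        df = simulate_cohort(CohortSpec(seed=5, covariates=False))
        assert df["age"].between(20, 80).all()

    def test_ols_recovers_generating_coefficients_when_noise_free(self):
        from aortapwv import fit_reference_model

        df = simulate_cohort(
            CohortSpec(sigma=0.0, method_scatter=0.0, covariates=False, seed=9)
        )
        res = fit_reference_model(df)
        assert res.beta0 == pytest.approx(1.51, abs=1e-9)
        assert res.beta_age == pytest.approx(0.080, abs=1e-12)
        assert res.beta_male == pytest.approx(0.53, abs=1e-9)
        assert res.sigma == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        d1 = simulate_cohort(CohortSpec(seed=11))
        d2 = simulate_cohort(CohortSpec(seed=11))
        assert d1.equals(d2)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(sigma=-0.1)
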