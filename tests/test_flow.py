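"""Flow integration, the three wave-arrival detectors, and the
transit-time PWV fit."""

import numpy as np
import pytest

from aortapwv import (
    ArrivalTimes,
    Centerline,
    FlowWaveform,
    PulseWaveModel,
    arrival_shift_xcor,
    arrival_time_half_peak,
    arrival_time_ttf,
    extract_flow_waveform,
    fit_pwv,
    make_flow_phantom,
    place_planes,
)
from aortapwv.phantom import systolic_waveform

from conftest import small_flow_spec


def _wave(flow, dt=0.02, s_mm=0.0):
    return FlowWaveform(0, s_mm, np.arange(len(flow)) * dt, np.asarray(flow, float))


def _pulse(times, onset=0.1, peak=100.0):
    return systolic_waveform(times, onset, 0.1, 0.18, peak)


@pytest.fixture(scope="module")
def phantom_planes():
    """Noiseless phantom with planes placed on the *true* centerline."""
    spec = small_flow_spec()
    field, cl, mask = make_flow_phantom(spec)
    planes = place_planes(cl, mask, spacing_mm=5.0, s_start=10.0,
                          s_end=cl.length - 10.0)
    return spec, field, planes


class TestFlowIntegration:
    def test_plug_flow_equals_area_times_velocity(self, phantom_planes):
        """Q = A * v for plug flow, within discretization error."""
        spec, field, planes = phantom_planes
        # at the phase of peak inflow the proximal plane carries peak velocity
        w = extract_flow_waveform(field, planes[0])
        expected = np.pi * spec.lumen_radius_mm**2 * spec.peak_velocity
        assert w.flow.max() == pytest.approx(expected, rel=0.03)

    def test_conservation_across_planes_and_phases(self, phantom_planes):
        """Plug profile: plane-integrated flow equals lumen area times the
        centerline speed at every plane and phase. Trilinear sampling mixes
        adjacent slices (sub-ms timing smear on the upstroke), so the bound
        is 2% of the peak flow."""
        spec, field, planes = phantom_planes
        scale = np.pi * spec.lumen_radius_mm**2 * spec.peak_velocity
        for p in planes[:: max(1, len(planes) // 6)]:
            w = extract_flow_waveform(field, p)
            delay = p.s_mm / (spec.true_pwv * 1000.0)
            v_center = _pulse(
                w.times - delay, onset=spec.onset_s, peak=spec.peak_velocity
            )
            expected = np.pi * spec.lumen_radius_mm**2 * v_center
            assert np.abs(w.flow - expected).max() / scale < 0.02

    def test_zero_field_gives_zero_flow(self, phantom_planes):
        _, field, planes = phantom_planes
        zero = field.copy()
        zero.velocity[:] = 0.0
        w = extract_flow_waveform(zero, planes[3])
        assert np.allclose(w.flow, 0.0)

    def test_parabolic_profile_mean_is_half_peak(self):
        spec = small_flow_spec(profile="parabolic")
        field, cl, mask = make_flow_phantom(spec)
        planes = place_planes(cl, mask, spacing_mm=5.0, s_start=20.0, s_end=30.0)
        w = extract_flow_waveform(field, planes[0])
        expected = np.pi * spec.lumen_radius_mm**2 * spec.peak_velocity / 2.0
        assert w.flow.max() == pytest.approx(expected, rel=0.03)

    def test_plane_outside_field_rejected(self, phantom_planes):
        _, field, planes = phantom_planes
        import dataclasses

        p = planes[0]
        far = dataclasses.replace(p, center=p.center + 500.0)
        with pytest.raises(ValueError, match="outside"):
            extract_flow_waveform(field, far)

    def test_empty_lumen_rejected(self, phantom_planes):
        import dataclasses

        _, field, planes = phantom_planes
        p = dataclasses.replace(planes[0], lumen=np.zeros_like(planes[0].lumen))
        with pytest.raises(ValueError, match="empty"):
            extract_flow_waveform(field, p)


class TestArrivalDetectors:
    def test_ttf_on_noiseless_ramp(self):
        t = np.arange(40) * 0.02
        q = np.where(t < 0.1, 0.0, (t - 0.1) * 1000.0)
        q[t > 0.3] = 200.0
        assert arrival_time_ttf(_wave(q)) == pytest.approx(0.100, abs=1e-9)

    def test_half_peak_on_triangle(self):
        t = np.arange(40) * 0.02
        q = np.interp(t, [0, 0.1, 0.2, 0.3, 0.78], [0, 0, 100, 0, 0])
        assert arrival_time_half_peak(_wave(q)) == pytest.approx(0.150, abs=1e-9)

    @pytest.mark.parametrize("detector", [arrival_time_ttf, arrival_time_half_peak])
    def test_shift_equivariance(self, detector):
        """Shifting the waveform by k samples shifts tau by k*dt."""
        t = np.arange(50) * 0.02
        q = _pulse(t)
        base = detector(_wave(q))
        for k in (1, 3, 7):
            shifted = detector(_wave(np.roll(q, k)))
            assert shifted - base == pytest.approx(k * 0.02, abs=1e-6)

    @pytest.mark.parametrize(
        "detector", [arrival_time_ttf, arrival_time_half_peak]
    )
    def test_flat_waveform_rejected(self, detector):
        with pytest.raises(ValueError):
            detector(_wave(np.ones(30)))

    def test_xcor_identity(self):
        t = np.arange(40) * 0.02
        w = _wave(_pulse(t))
        assert arrival_shift_xcor(w, w) == pytest.approx(0.0, abs=1e-12)

    def test_xcor_recovers_known_subsample_shift(self):
        """A 12 ms shift on a 20 ms grid is recovered within 2 ms."""
        t = np.arange(40) * 0.02
        ref = _wave(_pulse(t))
        shifted = _wave(_pulse(t - 0.012))
        assert arrival_shift_xcor(shifted, ref) == pytest.approx(0.012, abs=0.002)

    def test_xcor_antisymmetric(self):
        t = np.arange(40) * 0.02
        a = _wave(_pulse(t))
        b = _wave(_pulse(t - 0.012))
        assert arrival_shift_xcor(a, b) == pytest.approx(
            -arrival_shift_xcor(b, a), abs=1e-3
        )

    def test_xcor_constant_waveform_rejected(self):
        t = np.arange(40) * 0.02
        with pytest.raises(ValueError):
            arrival_shift_xcor(_wave(np.ones(40)), _wave(_pulse(t)))

    @pytest.mark.parametrize("scale", [0.5, 3.0, 250.0])
    def test_amplitude_scaling_leaves_arrivals_unchanged(self, scale):
        t = np.arange(50) * 0.02
        q = _pulse(t)
        ref = _wave(_pulse(t - 0.01))
        w, ws = _wave(q), _wave(q * scale)
        assert arrival_time_ttf(ws) == pytest.approx(arrival_time_ttf(w))
        assert arrival_time_half_peak(ws) == pytest.approx(
            arrival_time_half_peak(w)
        )
        assert arrival_shift_xcor(ws, ref) == pytest.approx(
            arrival_shift_xcor(w, ref)
        )


class TestPWVFit:
    def test_exact_line_gives_exact_pwv(self):
        s = np.arange(0.0, 300.0, 5.0)
        arr = ArrivalTimes("ttf", s, s / 5000.0)
        est = fit_pwv(arr)
        assert est.pwv == pytest.approx(5.000, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0)
        assert est.valid

    def test_constant_tau_flags_invalid(self):
        arr = ArrivalTimes("xcor", np.arange(0.0, 100.0, 5.0), np.zeros(20))
        est = fit_pwv(arr)
        assert not est.valid
        assert np.isnan(est.pwv)

    def test_fewer_than_two_planes_rejected(self):
        with pytest.raises(ValueError):
            fit_pwv(ArrivalTimes("ttf", np.array([10.0]), np.array([0.01])))

    def test_robust_mode_ignores_single_outlier(self):
        s = np.arange(0.0, 200.0, 5.0)
        tau = s / 5000.0
        tau[8] += 0.05  # gross outlier
        est = fit_pwv(ArrivalTimes("ttf", s, tau), robust=True)
        assert est.pwv == pytest.approx(5.0, rel=0.01)

    def test_model_recovers_phantom_pwv_on_true_geometry(self, phantom_planes):
        spec, field, planes = phantom_planes
        results = PulseWaveModel.from_field(field, planes).fit_all()
        for method in ("ttf", "half_peak", "xcor"):
            est = results.estimate(method)
            assert est.pwv == pytest.approx(spec.true_pwv, rel=0.02), method
            assert est.r_squared > 0.99

    def test_summary_lists_all_methods(self, phantom_planes):
        _, field, planes = phantom_planes
        res = PulseWaveModel.from_field(field, planes).fit_all()
        text = res.summary()
        for m in ("ttf", "half_peak", "xcor"):
            assert m in text
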