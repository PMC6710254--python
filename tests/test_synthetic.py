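"""Generators: temperature protocols, contraction traces, rendered videos,
fibril/foam images and CD spectra against their closed-form ground truths."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gelswitch import SyntheticTruth, synthetic
from gelswitch.errors import InvalidParameterError


class TestTemperatureProfile:
    def test_cyclic_protocol_spans_and_dwells(self):
        p = synthetic.make_temperature_profile("cyclic", 28, 42, 0.04, n_cycles=20,
                                               dwell=300, sampling_dt=1)
        assert p.temps.min() == pytest.approx(28.0)
        assert p.temps.max() == pytest.approx(42.0, abs=1 * 0.04)
        assert p.temps[0] == 28.0 and p.temps[-1] == 28.0
        # 20 cycles: 2 ramps of 350 s plus 2 dwells of 300 s each
        assert p.times[-1] == pytest.approx(20 * (2 * 350 + 2 * 300))

    def test_ramp_reaches_peak_and_returns(self):
        p = synthetic.make_temperature_profile("ramp", 30, 45, 0.04, sampling_dt=1)
        assert p.temps.max() == pytest.approx(45.0, abs=1 * 0.04)
        assert p.temps[0] == 30.0 and p.temps[-1] == 30.0
        i_peak = np.argmax(p.temps)
        assert np.all(np.diff(p.temps[:i_peak + 1]) >= 0)
        assert np.all(np.diff(p.temps[i_peak:]) <= 0)

    def test_zero_span_ramp_is_constant(self):
        p = synthetic.make_temperature_profile("ramp", 30, 30, 0.04, sampling_dt=1)
        assert np.all(p.temps == 30.0) and len(p.times) >= 2

    @pytest.mark.parametrize("kwargs", [
        {"sampling_dt": 0.0}, {"sampling_dt": -1.0}, {"rate": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            synthetic.make_temperature_profile("ramp", 30, 45, kwargs.get("rate", 0.04),
                                               sampling_dt=kwargs.get("sampling_dt", 1.0))

    @settings(derandomize=True, max_examples=25)
    @given(t_low=st.floats(10, 40), span=st.floats(1, 30), n=st.integers(1, 5))
    def test_cyclic_conservation_property(self, t_low, span, n):
        p = synthetic.make_temperature_profile("cyclic", t_low, t_low + span, 0.05,
                                               n_cycles=n, dwell=30, sampling_dt=2)
        assert np.all(np.diff(p.times) > 0)
        assert p.temps[0] == pytest.approx(t_low)
        assert p.temps[-1] == pytest.approx(t_low)
        assert p.temps.max() == pytest.approx(t_low + span, abs=2 * 0.05 + 1e-9)


class TestContractionTrace:
    def test_noiseless_ramp_minimum_matches_closed_form(self):
        p = synthetic.make_temperature_profile("ramp", 30, 45, 0.04, sampling_dt=1)
        truth = SyntheticTruth(T_t=40.0, stroke_area=0.8, width_w=0.7, A0=1.0)
        trace, _ = synthetic.make_contraction_trace(p, truth, noise_sd=0)
        expected_min = 1.0 * (1 - 0.8 * expit((45.0 - 40.0) / 0.7))
        assert trace.area_raw.min() == pytest.approx(expected_min, rel=1e-12)
        assert trace.area_raw.min() == pytest.approx(0.2, abs=2e-3)

    def test_cyclic_loss_compounds_at_cool_end(self):
        p = synthetic.make_temperature_profile("cyclic", 28, 42, 0.04, n_cycles=20,
                                               dwell=300, sampling_dt=2)
        truth = SyntheticTruth(T_t=40.0, stroke_area=0.8, width_w=0.7,
                               loss_per_cycle=0.0034, A0=1.0)
        trace, _ = synthetic.make_contraction_trace(p, truth, noise_sd=0)
        s_low = expit((28.0 - 40.0) / 0.7)
        # final sample sits in the 20th cool dwell
        assert trace.area_raw[-1] == pytest.approx(
            (1 - 0.0034) ** 20 * (1 - 0.8 * s_low), rel=1e-9)

    def test_profile_below_transition_gives_flat_trace(self):
        p = synthetic.make_temperature_profile("ramp", 30, 33, 0.04, sampling_dt=2)
        truth = SyntheticTruth(T_t=40.0, stroke_area=0.8, width_w=0.7, A0=1.0)
        trace, _ = synthetic.make_contraction_trace(p, truth, noise_sd=0)
        assert np.ptp(trace.area_raw) / trace.area_raw.max() < 1e-3

    def test_too_short_profile_rejected(self):
        from gelswitch.datatypes import TemperatureProfile
        p = TemperatureProfile(times=[0.0], temps=[30.0])
        with pytest.raises(InvalidParameterError):
            synthetic.make_contraction_trace(p, SyntheticTruth(40, 0.8, 0.7))

    @settings(derandomize=True, max_examples=20)
    @given(a0=st.floats(0.5, 5.0))
    def test_area_scales_linearly_with_initial_area(self, a0):
        p = synthetic.make_temperature_profile("ramp", 30, 45, 0.04, sampling_dt=10)
        t1, _ = synthetic.make_contraction_trace(
            p, SyntheticTruth(40, 0.8, 0.7, A0=a0), noise_sd=0)
        t2, _ = synthetic.make_contraction_trace(
            p, SyntheticTruth(40, 0.8, 0.7, A0=2 * a0), noise_sd=0)
        np.testing.assert_allclose(t2.area_raw, 2 * t1.area_raw, rtol=1e-12)


class TestRenderFrames:
    def test_constant_trace_renders_identical_calibrated_frames(self):
        from gelswitch.datatypes import AreaTrace
        trace = AreaTrace(times=np.arange(5.0), area_raw=np.full(5, np.pi * 1.0 ** 2))
        fs = synthetic.render_contraction_frames(trace, image_shape=(256, 256),
                                                 pixel_size=0.02, seed=0)
        assert all(np.array_equal(fs.frames[0], f) for f in fs.frames[1:])
        # calibrated pixel-count area within 2% of the analytic area (r = 50 px)
        count = (fs.frames[0] > 125).sum()
        assert count * 0.02 ** 2 == pytest.approx(np.pi, rel=0.02)

    def test_stroke_in_rendered_pixel_counts(self):
        from gelswitch.datatypes import AreaTrace
        trace = AreaTrace(times=np.arange(2.0), area_raw=np.array([2.0, 0.4]))
        fs = synthetic.render_contraction_frames(trace, pixel_size=0.02, seed=0)
        c0 = (fs.frames[0] > 125).sum()
        c1 = (fs.frames[1] > 125).sum()
        assert c1 / c0 == pytest.approx(0.2, rel=0.03)

    def test_reference_object_pixel_extent(self):
        from gelswitch.datatypes import AreaTrace
        trace = AreaTrace(times=[0.0], area_raw=[0.1])
        fs = synthetic.render_contraction_frames(
            trace, image_shape=(256, 256), pixel_size=0.01,
            include_reference_object=True, reference_extent=1.0, seed=0)
        assert (fs.frames[0] == 0).sum() == 100 * 100

    def test_oversized_disk_rejected(self):
        from gelswitch.datatypes import AreaTrace
        trace = AreaTrace(times=[0.0], area_raw=[50.0])
        with pytest.raises(InvalidParameterError):
            synthetic.render_contraction_frames(trace, image_shape=(64, 64), pixel_size=0.02)


class TestFibrilAndFoamImages:
    def test_deterministic_per_seed(self):
        a = synthetic.make_fibril_image((128, 128), n_fibers=10, fiber_width=3, seed=42)
        b = synthetic.make_fibril_image((128, 128), n_fibers=10, fiber_width=3, seed=42)
        assert np.array_equal(a, b)
        c = synthetic.make_fibril_image((128, 128), n_fibers=10, fiber_width=3, seed=43)
        assert not np.array_equal(a, c)

    def test_no_fibers_gives_uniform_dark_image(self):
        img = synthetic.make_fibril_image((64, 64), n_fibers=0, fiber_width=3, seed=0)
        assert np.ptp(img) == 0

    def test_subpixel_fiber_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.make_fibril_image((64, 64), pixel_size=2.0, fiber_width=1.0)

    def test_foam_recovers_placed_radii(self):
        img, truth_r = synthetic.make_foam_image((256, 256), pixel_size=1.5, n_pores=15,
                                                 seed=3, return_truth=True)
        from gelswitch import pores
        found = pores.find_pores(pores.segment_fibrils(img), pixel_size=1.5)
        got = np.sort([p.radius for p in found])[::-1][:len(truth_r)]
        np.testing.assert_allclose(np.sort(got), np.sort(truth_r), atol=1.6)


class TestCDGenerator:
    def test_empty_mixture_is_zero(self):
        s = synthetic.make_cd_spectrum({}, 25, noise_sd=0)
        assert np.all(s.ellipticity == 0)

    def test_single_component_equals_basis(self):
        s = synthetic.make_cd_spectrum({"collagen": 1.0}, 25, noise_sd=0)
        from gelswitch.synthetic import _component_spectrum
        np.testing.assert_array_equal(
            s.ellipticity, _component_spectrum("collagen", s.wavelengths, 25.0))

    def test_mixture_linearity(self):
        c = synthetic.make_cd_spectrum({"collagen": 1.0}, 25)
        e = synthetic.make_cd_spectrum({"elastin": 1.0}, 25)
        mix = synthetic.make_cd_spectrum({"collagen": 2 / 3, "elastin": 1 / 3}, 25)
        np.testing.assert_allclose(
            mix.ellipticity, 2 / 3 * c.ellipticity + 1 / 3 * e.ellipticity, atol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic.make_cd_spectrum({"collagen": -0.1}, 25)

    def test_ht_channel_monotone_toward_uv(self):
        s = synthetic.make_cd_spectrum({"elastin": 1.0}, 25)
        # wavelengths descend 250 -> 190, so HT must be non-decreasing along the array
        assert np.all(np.diff(s.ht) >= 0)
        assert s.ht[s.wavelengths >= 195].max() < 600
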