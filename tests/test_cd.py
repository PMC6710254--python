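"""CD spectra: file dialect, preprocessing contracts, HT rule, band features
and two-component superposition fits."""
import numpy as np
import pytest

from gelswitch import cd, synthetic
from gelswitch.datatypes import CDSpectrum
from gelswitch.errors import (
    AlignmentError,
    FeatureExtractionError,
    FitError,
    FormatError,
)


def _gauss_band(center, amp=-8.0, width=5.0):
    wl = synthetic.cd_wavelength_grid()
    return CDSpectrum(wavelengths=wl, ellipticity=amp * np.exp(-0.5 * ((wl - center) / width) ** 2))


class TestFileDialect:
    def test_write_read_round_trip_bit_exact(self, tmp_path):
        spec = synthetic.make_cd_spectrum({"collagen": 0.7, "elastin": 0.3},
                                          temperature=35.0, dose=60.0, noise_sd=0.2, seed=4)
        path = str(tmp_path / "s.csv")
        cd.write_cd(path, spec)
        back = cd.read_cd(path)[0]
        np.testing.assert_array_equal(back.wavelengths, spec.wavelengths)
        np.testing.assert_allclose(back.ellipticity, spec.ellipticity, rtol=1e-9)
        assert back.temperature == 35.0 and back.dose == 60.0

    def test_truncated_grid_rejected(self, tmp_path):
        spec = synthetic.make_cd_spectrum({"collagen": 1.0})
        short = spec.copy(wavelengths=spec.wavelengths[:-1],
                          ellipticity=spec.ellipticity[:-1],
                          ht=spec.ht[:-1])
        path = str(tmp_path / "short.csv")
        cd.write_cd(path, short)
        with pytest.raises(FormatError, match="301"):
            cd.read_cd(path)
        assert len(cd.read_cd(path, strict_grid=False)) == 1

    def test_non_monotone_wavelengths_name_the_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# temperature_C=25\n"
                        "wavelength_nm,ellipticity_mdeg\n"
                        "250.0,1.0\n249.8,1.0\n249.9,1.0\n249.4,1.0\n")
        with pytest.raises(FormatError, match="line 5"):
            cd.read_cd(str(path), strict_grid=False)


class TestPreprocess:
    def test_identity_when_nothing_requested(self):
        spec = synthetic.make_cd_spectrum({"elastin": 1.0}, noise_sd=0.1, seed=1)
        reps = [spec, spec.copy(), spec.copy()]
        zero_ref = spec.copy(ellipticity=np.zeros_like(spec.ellipticity))
        out = cd.preprocess(replicates=reps, reference=zero_ref, normalize=False, sigma=0)
        np.testing.assert_allclose(out.ellipticity, spec.ellipticity, atol=1e-12)

    def test_normalization_yields_unit_norm(self):
        spec = synthetic.make_cd_spectrum({"collagen": 3.0})
        out = cd.preprocess(spec, normalize=True, sigma=0)
        assert np.linalg.norm(out.ellipticity[out.valid]) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_after_first_application(self):
        spec = synthetic.make_cd_spectrum({"collagen": 1.0, "elastin": 0.5})
        once = cd.preprocess(spec, normalize=True, sigma=0)
        twice = cd.preprocess(once, normalize=True, sigma=0)
        np.testing.assert_allclose(twice.ellipticity, once.ellipticity, atol=1e-12)

    def test_triplicate_averaging_reduces_noise_by_sqrt3(self):
        truth = synthetic.make_cd_spectrum({"elastin": 1.0}).ellipticity
        singles, triples = [], []
        for s in range(50):
            reps = [synthetic.make_cd_spectrum({"elastin": 1.0}, noise_sd=0.5,
                                               seed=900 + 3 * s + k) for k in range(3)]
            singles.append(np.sqrt(np.mean((reps[0].ellipticity - truth) ** 2)))
            avg = cd.preprocess(replicates=reps, sigma=0)
            triples.append(np.sqrt(np.mean((avg.ellipticity - truth) ** 2)))
        ratio = np.mean(triples) / np.mean(singles)
        assert ratio == pytest.approx(1 / np.sqrt(3), abs=0.05)

    def test_grid_mismatch_rejected(self):
        a = synthetic.make_cd_spectrum({"collagen": 1.0})
        b = a.copy(wavelengths=a.wavelengths + 1.0)
        with pytest.raises(AlignmentError):
            cd.preprocess(a, reference=b)

    def test_reference_subtraction(self):
        a = synthetic.make_cd_spectrum({"collagen": 1.0})
        ref = a.copy(ellipticity=np.full_like(a.ellipticity, 2.0))
        out = cd.preprocess(a, reference=ref, sigma=0)
        np.testing.assert_allclose(out.ellipticity, a.ellipticity - 2.0)


class TestHTRule:
    def _spec_with_ht(self, cross_nm):
        wl = synthetic.cd_wavelength_grid()
        ht = np.where(wl <= cross_nm, 650.0, 400.0)
        return CDSpectrum(wavelengths=wl, ellipticity=np.ones_like(wl), ht=ht)

    def test_low_ht_passes_unmasked(self):
        wl = synthetic.cd_wavelength_grid()
        spec = CDSpectrum(wavelengths=wl, ellipticity=np.ones_like(wl),
                          ht=np.full_like(wl, 400.0))
        out = cd.ht_mask(spec)
        assert out.valid.all() and out.qc_pass

    def test_crossing_below_floor_masks_but_passes(self):
        out = cd.ht_mask(self._spec_with_ht(193.0))
        assert out.qc_pass
        assert not out.valid[out.wavelengths <= 193.0].any()
        assert out.valid[out.wavelengths > 193.0].all()

    def test_crossing_above_floor_fails_qc(self):
        out = cd.ht_mask(self._spec_with_ht(199.0))
        assert not out.qc_pass


class TestBandFeatures:
    def test_single_negative_band_minimum_located(self):
        f = cd.band_features(_gauss_band(203.0))
        assert len(f.minima) == 1
        assert f.minima[0][0] == pytest.approx(203.0, abs=0.2)

    def test_flat_spectrum_has_no_extrema(self):
        wl = synthetic.cd_wavelength_grid()
        f = cd.band_features(CDSpectrum(wavelengths=wl, ellipticity=np.zeros_like(wl)))
        assert f.minima == [] and f.maxima == []

    def test_fully_masked_spectrum_rejected(self):
        spec = _gauss_band(203.0)
        spec = spec.copy(valid=np.zeros_like(spec.valid))
        with pytest.raises(FeatureExtractionError):
            cd.band_features(spec)

    def test_band_shift_track_follows_generator(self):
        """A 203 -> 207 nm shifting band is tracked within 0.4 nm."""
        centers = np.linspace(203.0, 207.0, 5)
        tracked = []
        for c in centers:
            proc = cd.preprocess(_gauss_band(c), sigma=10)
            tracked.append(cd.band_features(proc).minima[0][0])
        shifts = np.array(tracked) - tracked[0]
        np.testing.assert_allclose(shifts, centers - centers[0], atol=0.4)

    def test_smoothing_preserves_band_center(self):
        """sigma=10 smoothing shifts a synthetic band center by < 0.2 nm."""
        raw = cd.band_features(_gauss_band(203.0)).minima[0][0]
        smoothed = cd.band_features(cd.preprocess(_gauss_band(203.0), sigma=10)).minima[0][0]
        assert abs(smoothed - raw) < 0.2

    def test_normalization_leaves_extrema_positions(self):
        spec = synthetic.make_cd_spectrum({"collagen": 1.0, "elastin": 0.4})
        f_raw = cd.band_features(cd.preprocess(spec, sigma=0))
        f_norm = cd.band_features(cd.preprocess(spec, sigma=0, normalize=True))
        assert [m[0] for m in f_raw.minima] == [m[0] for m in f_norm.minima]
        assert [m[0] for m in f_raw.maxima] == [m[0] for m in f_norm.maxima]

    def test_canonical_values_read_off_grid(self):
        spec = _gauss_band(222.0, amp=5.0)
        f = cd.band_features(spec)
        assert f.value_at[222.0] == pytest.approx(5.0, rel=1e-6)
        assert set(f.value_at) == {197.0, 203.0, 207.0, 220.0, 222.0}


class TestSuperposition:
    def test_exact_mixture_recovered_to_machine_precision(self):
        c1 = synthetic.make_cd_spectrum({"collagen": 1.0})
        c2 = synthetic.make_cd_spectrum({"elastin": 1.0})
        target = c1.copy(ellipticity=0.6 * c1.ellipticity + 0.4 * c2.ellipticity)
        fit = cd.fit_superposition(target, [c1, c2])
        np.testing.assert_allclose(fit.weights, [0.6, 0.4], atol=1e-9)
        assert fit.residual_rms < 1e-9

    def test_noisy_mixture_recovery(self):
        c1 = synthetic.make_cd_spectrum({"collagen": 1.0})
        c2 = synthetic.make_cd_spectrum({"elastin": 1.0})
        errs = []
        for s in range(50):
            noisy = synthetic.make_cd_spectrum({"collagen": 0.6, "elastin": 0.4},
                                               noise_sd=0.5, seed=500 + s)
            w = cd.fit_superposition(noisy, [c1, c2]).weights
            errs.append(np.abs(w - [0.6, 0.4]).max())
        assert np.mean(errs) < 0.02

    def test_identical_components_rejected(self):
        c1 = synthetic.make_cd_spectrum({"collagen": 1.0})
        with pytest.raises(FitError):
            cd.fit_superposition(c1, [c1, c1.copy()])

    def test_residual_orthogonal_to_component_span(self):
        c1 = synthetic.make_cd_spectrum({"collagen": 1.0})
        c2 = synthetic.make_cd_spectrum({"elastin": 1.0})
        target = synthetic.make_cd_spectrum({"coil": 1.0})
        fit = cd.fit_superposition(target, [c1, c2])
        resid = target.ellipticity - fit.weights[0] * c1.ellipticity - fit.weights[1] * c2.ellipticity
        scale = np.linalg.norm(target.ellipticity)
        assert abs(resid @ c1.ellipticity) / (scale * np.linalg.norm(c1.ellipticity)) < 1e-8
        assert abs(resid @ c2.ellipticity) / (scale * np.linalg.norm(c2.ellipticity)) < 1e-8

    def test_fixed_weights_evaluated_without_fitting(self):
        c1 = synthetic.make_cd_spectrum({"collagen": 1.0})
        c2 = synthetic.make_cd_spectrum({"elastin": 1.0})
        target = c1.copy(ellipticity=(2 * c1.ellipticity + c2.ellipticity) / 3)
        fit = cd.fit_superposition(target, [c1, c2], weights=[2 / 3, 1 / 3])
        np.testing.assert_allclose(fit.weights, [2 / 3, 1 / 3])
        assert fit.residual_rms < 1e-12
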