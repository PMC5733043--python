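"""Band averaging, system assembly and spectral decomposition."""

import numpy as np
import pytest

import oisi
from oisi.mbll import MBLLDecomposer, band_average_extinction


class TestBandAveraging:
    def test_constant_extinction_returns_constant(self):
        emission = oisi.SpectrumCurve(np.linspace(500, 550, 20), np.random.default_rng(0).random(20) + 0.1)
        extinction = oisi.SpectrumCurve(np.linspace(400, 700, 31), np.full(31, 2.5))
        assert band_average_extinction(emission, extinction) == pytest.approx(2.5, rel=1e-12)

    def test_single_point_emission_is_point_evaluation(self):
        emission = oisi.SpectrumCurve(np.array([612.0]), np.array([1.0]))
        wl = np.linspace(600, 620, 21)
        extinction = oisi.SpectrumCurve(wl, wl**2)
        assert band_average_extinction(emission, extinction) == pytest.approx(612.0**2, rel=1e-12)

    def test_triangular_emission_linear_extinction_dense_quadrature(self):
        """Triangular LED on [600, 620] nm with eps(lam)=lam -> weighted mean 610."""
        wl = np.array([600.0, 610.0, 620.0])
        emission = oisi.SpectrumCurve(wl, np.array([0.0, 1.0, 0.0]))
        ext_grid = np.linspace(590, 630, 41)
        extinction = oisi.SpectrumCurve(ext_grid, ext_grid)
        got = band_average_extinction(emission, extinction)
        # dense-grid quadrature oracle at 0.01 nm
        f = np.arange(600.0, 620.0 + 1e-9, 0.01)
        L = np.interp(f, wl, emission.value)
        oracle = np.trapezoid(L * f, f) / np.trapezoid(L, f)
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got == pytest.approx(610.0, rel=1e-9)

    def test_disjoint_grids_rejected(self):
        emission = oisi.SpectrumCurve(np.array([500.0, 510.0]), np.array([1.0, 1.0]))
        extinction = oisi.SpectrumCurve(np.array([600.0, 700.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            band_average_extinction(emission, extinction)


class TestAssembleSystem:
    def test_pathlength_is_doubled_depth(self, bands):
        model = oisi.assemble_system(bands, d_iv=0.35)
        assert model.pathlength == 0.7
        raw = np.array([[b.eps_hbo, b.eps_hbr, b.mu_s_prime] for b in bands])
        np.testing.assert_allclose(model.matrix, 0.7 * raw, rtol=1e-12)

    def test_chromophore_selective_bands_give_diagonal(self):
        selective = [
            oisi.SpectralBand("HBO", 2.0, 0.0, 0.0),
            oisi.SpectralBand("HBR", 0.0, 3.0, 0.0),
            oisi.SpectralBand("S", 0.0, 0.0, 4.0),
        ]
        model = oisi.assemble_system(selective, d_iv=0.5)
        np.testing.assert_allclose(model.matrix, np.diag([2.0, 3.0, 4.0]), rtol=1e-12)

    def test_band_permutation_permutes_rows(self, bands):
        m1 = oisi.assemble_system(bands, 0.35).matrix
        m2 = oisi.assemble_system(bands[::-1], 0.35).matrix
        np.testing.assert_array_equal(m2, m1[::-1])

    def test_too_few_bands_rejected(self, bands):
        with pytest.raises(ValueError, match="3"):
            oisi.assemble_system(bands[:2], 0.35)


def _traces_from(tr, model, mode="reflectance", polarity="raw"):
    sign = -1.0 if (mode == "reflectance" and polarity == "raw") else 1.0
    t = np.arange(tr[model.band_names[0]].size) * 0.2
    return {
        name: oisi.TimeCourse(t=t, y=sign * tr[name], stim_onset_s=5.0, mode=mode,
                              polarity=polarity, band=name)
        for name in model.band_names
    }


class TestDecomposition:
    def test_zero_traces_zero_chromophores(self, bands):
        model = oisi.assemble_system(bands, 0.35)
        t = np.arange(10) * 0.2
        traces = {b.name: oisi.TimeCourse(t=t, y=np.zeros(10), stim_onset_s=1.0, polarity="raw")
                  for b in bands}
        c = oisi.decompose(traces, model)
        assert not c.d_hbo.any() and not c.d_hbr.any() and not c.d_s.any()

    def test_three_band_round_trip_machine_precision(self, bands):
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        forward = oisi.forward_project(truth, bands, 0.35)
        model = oisi.assemble_system(bands, 0.35)
        rec = oisi.decompose(_traces_from(forward, model), model)
        scale = np.max(np.abs(truth.as_array()))
        err = np.max(np.abs(rec.as_array() - truth.as_array())) / scale
        assert err < 1e-10

    def test_scalar_scattering_only_inversion(self):
        """Single band, eps=0, mu_s'=1/mm, d_IV=0.35: OIS 0.007 -> dS 0.01."""
        band = oisi.SpectralBand("S-ONLY", 0.0, 0.0, 1.0)
        model = oisi.assemble_system([band], 0.35, chromophores=("s",))
        t = np.array([0.0, 0.2])
        tc = oisi.TimeCourse(t=t, y=np.array([0.0, -0.007]), stim_onset_s=0.0,
                             mode="reflectance", polarity="raw", band="S-ONLY")
        c = oisi.decompose({"S-ONLY": tc}, model)
        assert c.d_s[1] == pytest.approx(0.01, rel=1e-12)
        assert not c.d_hbo.any() and not c.d_hbr.any()

    def test_reflectance_and_transmission_decompose_identically(self, bands):
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        forward = oisi.forward_project(truth, bands, 0.35)
        model = oisi.assemble_system(bands, 0.35)
        c_refl = oisi.decompose(_traces_from(forward, model, "reflectance", "raw"), model)
        c_trans = oisi.decompose(_traces_from(forward, model, "transmission", "raw"), model)
        np.testing.assert_allclose(c_refl.as_array(), c_trans.as_array(), atol=1e-15)

    def test_ill_conditioned_system_refused(self):
        nearly_dependent = [
            oisi.SpectralBand("A", 1.0, 1.0, 1.0),
            oisi.SpectralBand("B", 1.0, 1.0, 1.0 + 1e-12),
            oisi.SpectralBand("C", 1.0, 1.0 + 1e-12, 1.0),
        ]
        model = oisi.assemble_system(nearly_dependent, 0.35)
        t = np.arange(5) * 0.2
        traces = {n: oisi.TimeCourse(t=t, y=np.ones(5), stim_onset_s=0.0, polarity="raw")
                  for n in "ABC"}
        with pytest.raises(ValueError, match="condition number"):
            oisi.decompose(traces, model)

    def test_time_grid_mismatch_rejected(self, bands):
        model = oisi.assemble_system(bands, 0.35)
        traces = {}
        for k, b in enumerate(bands):
            t = np.arange(10) * (0.2 if k < 2 else 0.25)
            traces[b.name] = oisi.TimeCourse(t=t, y=np.zeros(10), stim_onset_s=0.0, polarity="raw")
        with pytest.raises(ValueError, match="time grid"):
            oisi.decompose(traces, model)

    def test_hbt_is_sum_by_construction(self, bands):
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        forward = oisi.forward_project(truth, bands, 0.35)
        model = oisi.assemble_system(bands, 0.35)
        rec = oisi.decompose(_traces_from(forward, model), model)
        np.testing.assert_array_equal(rec.hbt, rec.d_hbo + rec.d_hbr)

    def test_neonatal_temporal_separation_survives_decomposition(self, bands):
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        forward = oisi.forward_project(truth, bands, 0.35)
        model = oisi.assemble_system(bands, 0.35)
        rec = oisi.decompose(_traces_from(forward, model), model)
        onset = rec.stim_onset_s
        assert rec.t[np.argmax(rec.d_s)] - onset <= 10.0
        assert rec.t[np.argmax(rec.hbt)] - onset > 10.0

    def test_noise_error_scales_with_pseudoinverse_norm(self, bands):
        """Chromophore noise grows linearly with trace noise, slope ~ ||row(M^-1)||."""
        model = oisi.assemble_system(bands, 0.35)
        Minv = np.linalg.inv(model.matrix)
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        forward = oisi.forward_project(truth, bands, 0.35)
        rng = np.random.default_rng(3)
        sigmas = np.array([1e-5, 2e-5, 4e-5])
        errs = np.zeros((sigmas.size, 3))
        for i, s in enumerate(sigmas):
            noisy = {n: tr + rng.normal(0, s, tr.shape) for n, tr in forward.items()}
            rec = oisi.decompose(_traces_from(noisy, model), model)
            errs[i] = (rec.as_array() - truth.as_array()).std(axis=0)
        for j in range(3):
            slope = np.polyfit(sigmas, errs[:, j], 1)[0]
            predicted = np.linalg.norm(Minv[j])
            assert slope == pytest.approx(predicted, rel=0.2)


class TestEstimatorInterface:
    def test_get_params_round_trip_and_clone(self, bands):
        from sklearn.base import clone

        est = MBLLDecomposer(bands=bands, d_iv=0.75)
        cloned = clone(est)
        assert cloned.get_params()["d_iv"] == 0.75
        cloned.fit()
        assert cloned.matrix_.shape == (3, 3)
        assert cloned.condition_number_ > 1.0

    def test_transform_inverse_transform_consistency(self, bands):
        est = MBLLDecomposer(bands=bands, d_iv=0.35).fit()
        rng = np.random.default_rng(5)
        C = rng.normal(size=(50, 3)) * [1.0, 0.5, 1e-3]
        np.testing.assert_allclose(est.transform(est.inverse_transform(C)), C, atol=1e-12)

    def test_unfitted_transform_raises(self, bands):
        with pytest.raises(AttributeError):
            MBLLDecomposer(bands=bands).transform(np.zeros((3, 3)))

    def test_overdetermined_least_squares_with_residuals(self, bands):
        extra = oisi.SpectralBand("YELLOW", 2.0e-3, 2.2e-3, 1.9)
        four = list(bands) + [extra]
        est = MBLLDecomposer(bands=four, d_iv=0.35).fit()
        truth = oisi.simulate_chromophores(oisi.NEONATAL)
        X = est.inverse_transform(truth.as_array())
        C = est.transform(X)
        np.testing.assert_allclose(C, truth.as_array(), atol=1e-10)
        assert np.all(est.residuals(X, C) < 1e-12)


def test_spectrum_csv_round_trip(tmp_path):
    curve = oisi.SpectrumCurve(np.linspace(500, 600, 11), np.linspace(0, 1, 11),
                               units="1/(mm*uM)", name="hbo")
    path = tmp_path / "hbo.csv"
    curve.to_csv(path)
    back = oisi.SpectrumCurve.from_csv(path)
    np.testing.assert_allclose(back.wavelength_nm, curve.wavelength_nm)
    np.testing.assert_allclose(back.value, curve.value, atol=1e-9)
    assert back.units == "1/(mm*uM)"
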