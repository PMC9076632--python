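"""Spectral features: chromophore basis, hemoglobin unmixing, PWFR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skindrs import (
    ChromophoreBasis,
    OpticalPropertySpectrum,
    compute_pwfr,
    extract_site_features,
    fit_hemoglobin,
    load_chromophore_basis,
)
from skindrs.chromophores import write_fixture_files


def optics_from_mu_a(wavelengths, mu_a):
    return OpticalPropertySpectrum(
        wavelengths=np.asarray(wavelengths, dtype=float),
        mu_a=np.asarray(mu_a, dtype=float),
        mu_s_prime=np.ones(len(wavelengths)),
    )


def toy_basis(wavelengths, water):
    wl = np.asarray(wavelengths, dtype=float)
    return ChromophoreBasis(
        wavelengths=wl,
        eps_o2hb=np.zeros(len(wl)),
        eps_hhb=np.zeros(len(wl)),
        mu_a_water=np.asarray(water, dtype=float),
    )


class TestBasisLoading:
    def test_hemoglobin_window_shape(self):
        b = load_chromophore_basis(wavelengths=np.arange(500.0, 601.0, 2.0))
        assert len(b.wavelengths) == 51
        assert np.all(b.eps_o2hb > 0) and np.all(b.eps_hhb > 0)

    def test_water_window_shape(self):
        b = load_chromophore_basis(wavelengths=np.arange(1230.0, 1381.0, 2.0))
        assert len(b.wavelengths) == 76
        assert np.all(b.mu_a_water > 0)

    def test_coverage_error(self):
        with pytest.raises(ValueError, match="coverage"):
            load_chromophore_basis(wavelengths=np.arange(400.0, 451.0, 2.0))

    def test_fixture_files_match_generator(self, tmp_path):
        # bundled CSVs are exactly what the analytic generator writes
        write_fixture_files(tmp_path)
        regenerated = load_chromophore_basis(source=str(tmp_path))
        bundled = load_chromophore_basis()
        np.testing.assert_allclose(regenerated.eps_o2hb, bundled.eps_o2hb)
        np.testing.assert_allclose(regenerated.mu_a_water, bundled.mu_a_water)

    def test_hemoglobin_zero_in_water_band(self):
        b = load_chromophore_basis(wavelengths=np.arange(1230.0, 1381.0, 2.0))
        assert np.all(b.eps_o2hb == 0) and np.all(b.eps_hhb == 0)


class TestHemoglobinUnmixing:
    def test_zero_absorption(self, basis):
        wl = basis.wavelengths
        res = fit_hemoglobin(optics_from_mu_a(wl, np.zeros(len(wl))), basis)
        assert res.c_o2hb == 0 and res.c_hhb == 0 and res.fit_rss == 0

    def test_single_basis_identity(self, basis):
        mu_a = 10.0 * basis.eps_o2hb
        res = fit_hemoglobin(optics_from_mu_a(basis.wavelengths, mu_a), basis)
        assert res.c_o2hb == pytest.approx(10.0, rel=1e-10)
        assert res.c_hhb == pytest.approx(0.0, abs=1e-8)
        assert res.fit_rss < 1e-12

    @pytest.mark.parametrize("c_o2,c_h", [(20.0, 5.0), (3.0, 40.0), (12.5, 12.5)])
    def test_noiseless_mixture_recovery(self, basis, c_o2, c_h):
        mu_a = c_o2 * basis.eps_o2hb + c_h * basis.eps_hhb
        res = fit_hemoglobin(optics_from_mu_a(basis.wavelengths, mu_a), basis)
        assert res.c_o2hb == pytest.approx(c_o2, rel=1e-8)
        assert res.c_hhb == pytest.approx(c_h, rel=1e-8)
        assert res.c_thb == res.c_o2hb + res.c_hhb

    def test_noisy_recovery_within_standard_errors(self, basis, rng):
        # oracle: explicit normal-equations least squares with its SEs
        mask = basis.window_mask((500.0, 600.0))
        X = np.column_stack([basis.eps_o2hb[mask], basis.eps_hhb[mask]])
        truth = np.array([20.0, 5.0])
        clean = X @ truth
        sigma = 0.01 * clean.mean()
        mu_a = np.zeros(len(basis.wavelengths))
        mu_a[mask] = clean + sigma * rng.standard_normal(mask.sum())
        res = fit_hemoglobin(
            optics_from_mu_a(basis.wavelengths, np.maximum(mu_a, 0)), basis
        )
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ mu_a[mask]
        resid = mu_a[mask] - X @ beta
        s2 = resid @ resid / (len(resid) - 2)
        se = np.sqrt(np.diag(XtX_inv) * s2)
        assert abs(res.c_o2hb - truth[0]) < 3 * se[0]
        assert abs(res.c_hhb - truth[1]) < 3 * se[1]

    def test_too_few_points_error(self, basis):
        wl = np.array([550.0, 560.0])
        sub = basis.resample(wl)
        with pytest.raises(ValueError, match=">= 3"):
            fit_hemoglobin(optics_from_mu_a(wl, np.ones(2)), sub)


class TestPwfr:
    def test_proportional_water_is_exact_fit(self, basis):
        mu_a = 0.7 * basis.mu_a_water
        res = compute_pwfr(optics_from_mu_a(basis.wavelengths, mu_a), basis)
        assert res.scale == pytest.approx(0.7, rel=1e-12)
        assert res.pwfr == pytest.approx(0.0, abs=1e-20)

    def test_three_point_closed_form(self):
        # hand-computed: A = 17/14, residuals (-3, -6, 5)/14,
        # pwfr = 100 * (70/196) / 3
        wl = np.array([1300.0, 1320.0, 1340.0])
        b = toy_basis(wl, [1.0, 2.0, 3.0])
        res = compute_pwfr(optics_from_mu_a(wl, [1.0, 2.0, 4.0]), b)
        assert res.scale == pytest.approx(17.0 / 14.0, rel=1e-12)
        assert res.pwfr == pytest.approx(100.0 * (70.0 / 196.0) / 3.0, abs=1e-9)

    def test_single_point_exact_fit(self):
        wl = np.array([1300.0])
        res = compute_pwfr(optics_from_mu_a(wl, [2.4]), toy_basis(wl, [1.2]))
        assert res.scale == pytest.approx(2.0)
        assert res.pwfr == 0.0

    @given(
        amp=st.floats(min_value=0.0, max_value=50.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_scaled_water_always_scores_zero(self, amp, seed):
        r = np.random.default_rng(seed)
        wl = np.sort(1230 + 150 * r.random(12))
        water = 0.05 + r.random(12)
        b = toy_basis(wl, water)
        res = compute_pwfr(optics_from_mu_a(wl, amp * water), b)
        assert res.pwfr == pytest.approx(0.0, abs=1e-18)
        assert res.scale == pytest.approx(amp, rel=1e-9, abs=1e-12)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_closed_form_on_random_vectors(self, seed):
        r = np.random.default_rng(seed)
        n = int(3 + 10 * r.random())
        wl = np.sort(1230 + 150 * r.random(n))
        water = 0.05 + r.random(n)
        measured = np.abs(water + 0.5 * r.standard_normal(n))
        A = max(float(water @ measured / (water @ water)), 0.0)
        expected = 100.0 * float(np.sum((measured - A * water) ** 2)) / n
        res = compute_pwfr(optics_from_mu_a(wl, measured), toy_basis(wl, water))
        assert res.pwfr == pytest.approx(expected, rel=1e-10)

    def test_quadratic_in_orthogonal_distortion(self):
        rng = np.random.default_rng(0)
        wl = np.linspace(1230, 1380, 20)
        water = 1.0 + rng.random(20)
        d = rng.standard_normal(20)
        d -= (d @ water) / (water @ water) * water  # orthogonalise
        d /= np.abs(d).max()  # |d| <= 1 keeps spectra positive
        b = toy_basis(wl, water)
        p1 = compute_pwfr(optics_from_mu_a(wl, water + 0.2 * d), b).pwfr
        p2 = compute_pwfr(optics_from_mu_a(wl, water + 0.4 * d), b).pwfr
        assert p2 == pytest.approx(4 * p1, rel=1e-9)


class TestSiteFeatures:
    def test_pwfr_reported_on_cm_scale(self, basis):
        # extract_site_features evaluates PWFR on absorption in cm^-1:
        # the score is 100x the mm^-1 value
        rng = np.random.default_rng(2)
        mask = basis.window_mask((1230.0, 1380.0))
        mu_a = 0.6 * basis.mu_a_water
        mu_a = mu_a + np.where(mask, 0.01 * rng.standard_normal(len(mu_a)), 0.0)
        mu_a = np.maximum(mu_a, 1e-5)
        optics = optics_from_mu_a(basis.wavelengths, mu_a)
        feats = extract_site_features(optics, basis)
        raw = compute_pwfr(optics, basis)
        assert feats.pwfr == pytest.approx(100.0 * raw.pwfr, rel=1e-9)
        assert feats.water_scale == pytest.approx(raw.scale, rel=1e-9)
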