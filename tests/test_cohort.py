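"""Synthetic cohort generator: physiology, optics composition, instruments."""

import numpy as np
import pytest

from skindrs import (
    CohortConfig,
    SitePhysiology,
    compute_pwfr,
    generate_cohort,
    physiology_to_medium,
    sample_physiology,
    simulate_corneometer,
    simulate_drs_measurement,
    simulate_mexameter,
    simulate_pasi_scores,
)
from skindrs.cohort import (
    LESION,
    UNINVOLVED,
    physiology_to_absorption,
    water_band_distortion,
)
from skindrs.features import ABSORPTION_UNIT_SCALE
from skindrs.spectra import OpticalPropertySpectrum, ReflectanceSpectrum


def make_phys(**overrides):
    defaults = dict(
        site_type=LESION,
        c_o2hb=35.0,
        c_hhb=25.0,
        bound_water_deviation=0.02,
        epidermal_hydration=0.1,
        scatter_amplitude=2.5,
        scatter_power=1.3,
    )
    defaults.update(overrides)
    return SitePhysiology(**defaults)


class TestPhysiologySampling:
    def test_deterministic_under_seed(self):
        cfg = CohortConfig(seed=5)
        a = sample_physiology(cfg, LESION, np.random.default_rng(5))
        b = sample_physiology(cfg, LESION, np.random.default_rng(5))
        assert a == b

    def test_lesion_hemoglobin_exceeds_uninvolved_on_average(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(0)
        lesion = [sample_physiology(cfg, LESION, rng).c_thb for _ in range(500)]
        rng = np.random.default_rng(0)
        normal = [sample_physiology(cfg, UNINVOLVED, rng).c_thb for _ in range(500)]
        assert np.mean(lesion) > np.mean(normal)

    def test_draws_respect_physical_bounds(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = sample_physiology(cfg, LESION, rng)
            assert 0 <= p.epidermal_hydration <= 1
            assert p.c_o2hb >= 0 and p.c_hhb >= 0
            assert p.bound_water_deviation >= 0


class TestOpticsComposition:
    def test_distortion_orthogonal_to_water(self, basis):
        mask = basis.window_mask((1230.0, 1380.0))
        d = water_band_distortion(basis.wavelengths)[mask]
        w = basis.mu_a_water[mask]
        assert abs(d @ w) / (np.linalg.norm(d) * np.linalg.norm(w)) < 1e-12
        assert np.sqrt(np.mean(d**2)) == pytest.approx(1.0, rel=1e-12)

    def test_zero_deviation_gives_zero_pwfr(self, basis):
        phys = make_phys(bound_water_deviation=0.0)
        mu_a = physiology_to_absorption(phys, basis)
        optics = OpticalPropertySpectrum(
            basis.wavelengths, mu_a, np.ones(len(mu_a))
        )
        assert compute_pwfr(optics, basis).pwfr == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_pwfr_quadratic_in_deviation(self, basis):
        # 10^4 b^2 on the cm^-1 reporting scale (orthogonalised distortion)
        for b_amp in (0.005, 0.01, 0.02):
            phys = make_phys(bound_water_deviation=b_amp)
            mu_a = physiology_to_absorption(phys, basis)
            optics = OpticalPropertySpectrum(
                basis.wavelengths, mu_a, np.ones(len(mu_a))
            )
            pw = compute_pwfr(optics, basis).pwfr * ABSORPTION_UNIT_SCALE**2
            assert pw == pytest.approx(1e4 * b_amp**2, rel=1e-9)

    def test_composition_matches_hand_sum(self, basis):
        phys = make_phys(c_o2hb=10.0, c_hhb=0.0, bound_water_deviation=0.0)
        medium = physiology_to_medium(phys, basis, 560.0)
        sub = basis.resample(np.array([560.0]))
        expected = (
            10.0 * sub.eps_o2hb[0] + phys.water_fraction * sub.mu_a_water[0]
        )
        assert medium.mu_a == pytest.approx(expected, rel=1e-12)
        assert medium.mu_s_prime == pytest.approx(
            2.5 * (560.0 / 500.0) ** -1.3, rel=1e-12
        )

    def test_wavelength_outside_basis(self, basis):
        with pytest.raises(ValueError):
            physiology_to_medium(make_phys(), basis, 2000.0)


class TestDrsSimulation:
    def test_noiseless_spectrum_deterministic(self, basis):
        cfg = CohortConfig(noise_sd_fraction=0.0)
        phys = make_phys()
        s1 = simulate_drs_measurement(phys, basis, cfg, np.random.default_rng(0))
        s2 = simulate_drs_measurement(phys, basis, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(s1.r_sds1, s2.r_sds1)

    def test_noise_perturbs_spectra_mildly(self, basis):
        phys = make_phys()
        clean = simulate_drs_measurement(
            phys, basis, CohortConfig(noise_sd_fraction=0.0), np.random.default_rng(0)
        )
        noisy = simulate_drs_measurement(
            phys, basis, CohortConfig(noise_sd_fraction=0.01), np.random.default_rng(0)
        )
        rel = np.abs(noisy.r_sds1 / clean.r_sds1 - 1)
        assert rel.max() > 0
        assert rel.max() < 0.06  # a few noise SDs

    def test_round_trip_recovers_thb(self, basis, lookup_model):
        from skindrs import extract_site_features, invert_spectrum

        cfg = CohortConfig(noise_sd_fraction=0.0)
        phys = make_phys()
        spectrum = simulate_drs_measurement(phys, basis, cfg, np.random.default_rng(0))
        optics = invert_spectrum(lookup_model, spectrum)
        feats = extract_site_features(optics, basis)
        assert feats.c_thb == pytest.approx(phys.c_thb, rel=0.10)

    def test_empty_grid(self):
        from skindrs.chromophores import ChromophoreBasis

        empty = ChromophoreBasis(
            np.array([]), np.array([]), np.array([]), np.array([])
        )
        out = simulate_drs_measurement(
            make_phys(), empty, CohortConfig(), np.random.default_rng(0)
        )
        assert len(out) == 0


class TestInstruments:
    def test_mexameter_baseline_and_value(self):
        assert simulate_mexameter(0.3, 0.3) == 0.0
        assert simulate_mexameter(0.2, 0.4) == pytest.approx(
            500.0 * np.log10(2.0), rel=1e-12
        )

    def test_mexameter_monotone_until_clamp(self):
        r660 = 0.4
        vals = [simulate_mexameter(r568, r660) for r568 in (0.4, 0.2, 0.1, 0.05)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert simulate_mexameter(1e-9, 0.4) == 999.0

    def test_mexameter_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            simulate_mexameter(0.0, 0.1)

    def test_mexameter_accepts_spectrum(self, basis):
        spec = simulate_drs_measurement(
            make_phys(), basis, CohortConfig(noise_sd_fraction=0.0),
            np.random.default_rng(0),
        )
        assert simulate_mexameter(spec) > 0

    def test_corneometer_values(self):
        rng = np.random.default_rng(0)
        dry = simulate_corneometer(
            make_phys(epidermal_hydration=0.0), rng, noise_sd=0.0
        )
        assert dry == 0.0
        half = simulate_corneometer(
            make_phys(epidermal_hydration=0.5), rng, noise_sd=0.0
        )
        assert half == pytest.approx(60.0, rel=1e-12)

    def test_corneometer_monotone(self):
        rng = np.random.default_rng(0)
        vals = [
            simulate_corneometer(make_phys(epidermal_hydration=h), rng, noise_sd=0.0)
            for h in (0.1, 0.3, 0.6, 0.9)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestPasi:
    def test_null_physiology_scores_zero(self):
        phys = make_phys(
            c_o2hb=0.0, c_hhb=0.0, bound_water_deviation=0.0,
            epidermal_hydration=1.0, scatter_amplitude=1.5,
        )
        scores = simulate_pasi_scores(phys, 4, np.random.default_rng(0), 0.0)
        assert scores == (0.0, 0.0, 0.0)

    def test_single_rater_noise_free_deterministic(self):
        phys = make_phys()
        a = simulate_pasi_scores(phys, 1, np.random.default_rng(0), 0.0)
        b = simulate_pasi_scores(phys, 1, np.random.default_rng(9), 0.0)
        assert a == b

    def test_scores_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = simulate_pasi_scores(make_phys(), 4, rng)
            assert all(0 <= s <= 4 for s in scores)


class TestGenerateCohort:
    def test_empty_cohort(self):
        cohort = generate_cohort(CohortConfig(n_subjects=0))
        assert len(cohort) == 0

    def test_seed_determinism(self, basis):
        a = generate_cohort(CohortConfig(n_subjects=4, seed=8), basis)
        b = generate_cohort(CohortConfig(n_subjects=4, seed=8), basis)
        assert a.table.equals(b.table)
        for key in a.spectra:
            np.testing.assert_array_equal(
                a.spectra[key].r_sds1, b.spectra[key].r_sds1
            )

    def test_paired_structure(self, basis):
        cohort = generate_cohort(CohortConfig(n_subjects=6, seed=1), basis)
        counts = cohort.table.groupby("subject")["site_type"].nunique()
        assert (counts == 2).all()
        assert np.isfinite(
            cohort.table.select_dtypes("number").to_numpy()
        ).all()

    def test_round_trip_serialisation(self, basis, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=3, seed=2), basis)
        cohort.to_dir(tmp_path)
        loaded = type(cohort).from_dir(tmp_path)
        assert len(loaded) == len(cohort)
        key = (0, LESION)
        np.testing.assert_allclose(
            loaded.spectra[key].r_sds1, cohort.spectra[key].r_sds1
        )

    def test_noiseless_pipeline_rank_orders_sites_with_truth(
        self, basis, lookup_model
    ):
        from skindrs import SeverityStudy
        from dataclasses import replace

        cfg = CohortConfig(n_subjects=12, seed=4, noise_sd_fraction=0.0)
        cohort = generate_cohort(cfg, basis)
        res = SeverityStudy(cohort, inverse_model=lookup_model, basis=basis).fit()
        merged = res.site_features.merge(
            cohort.table, on=["subject", "site_type"]
        )
        thb_rank = np.corrcoef(
            merged["c_thb"].rank(), merged["true_c_thb"].rank()
        )[0, 1]
        pwfr_rank = np.corrcoef(
            merged["pwfr"].rank(),
            (merged["true_bound_water_deviation"] ** 2).rank(),
        )[0, 1]
        assert thb_rank > 0.99
        assert pwfr_rank > 0.99
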