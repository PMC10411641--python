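import math

import numpy as np
import pytest

from skinbis.dielectric import InvalidInputError
from skinbis.drt import (
    DRTResult,
    RelaxationFeatures,
    TauGrid,
    build_rbf_matrices,
    find_relaxation_features,
    fit_drt,
    mu_from_grid,
    rbf_mass,
    reconstruct_impedance,
    select_frequency_pairs,
    synthesize_rc_spectrum,
)
from skinbis.forward_cem import ImpedanceSpectrum

CANDIDATES = [2e3, 1e4, 3.5e4, 1e5, 2.25e5]


class TestRBFMatrices:
    def test_low_frequency_limit_recovers_full_mass(self):
        grid = TauGrid(np.array([1e-4]), 10, 0)
        mu = 5.0
        A_re, A_im = build_rbf_matrices([1e-9, 1e-8], grid, mu)
        assert A_re[0, 0] == pytest.approx(rbf_mass(mu), rel=1e-6)
        assert abs(A_im[0, 0]) < 1e-6 * rbf_mass(mu)

    def test_high_frequency_limit_vanishes(self):
        grid = TauGrid(np.array([1e-4]), 10, 0)
        A_re, A_im = build_rbf_matrices([1e10, 1e11], grid, 5.0)
        assert abs(A_re[0, 0]) < 1e-6
        assert abs(A_im[0, 0]) < 1e-3  # decays ~1/(2 pi f tau)

    def test_against_dense_trapezoid_quadrature(self):
        grid = TauGrid(np.array([1e-4, 3e-3]), 10, 0)
        mu = 4.0
        f = np.array([1e2, 1591.5, 1e5])
        A_re, A_im = build_rbf_matrices(f, grid, mu)
        for m, tau_m in enumerate(grid.tau):
            x = np.linspace(math.log(tau_m) - 6 / mu, math.log(tau_m) + 6 / mu, 20001)
            g = np.exp(-((mu * (x - math.log(tau_m))) ** 2))
            for l, fl in enumerate(f):
                wt = 2 * np.pi * fl * np.exp(x)
                assert A_re[l, m] == pytest.approx(
                    np.trapezoid(g / (1 + wt**2), x), rel=1e-6)
                assert A_im[l, m] == pytest.approx(
                    np.trapezoid(g * wt / (1 + wt**2), x), rel=1e-6, abs=1e-12)

    def test_doubled_quadrature_order_agrees(self):
        grid = TauGrid.from_frequencies(np.logspace(1, 5, 10))
        mu = mu_from_grid(grid)
        A1 = build_rbf_matrices(np.logspace(1, 5, 10), grid, mu, order=32)
        A2 = build_rbf_matrices(np.logspace(1, 5, 10), grid, mu, order=64)
        for a, b in zip(A1, A2):
            assert np.allclose(a, b, rtol=1e-8, atol=1e-14)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            TauGrid(np.array([]), 10, 0)


class TestFitDRT:
    def test_single_debye_recovery(self, debye_spectrum):
        res = fit_drt(debye_spectrum, extension_decades=2.0)
        feats = find_relaxation_features(res)
        assert len(feats.peak_tau) == 1
        assert abs(math.log(feats.peak_tau[0] / 1e-4)) <= res.tau_grid.spacing
        assert res.polarization_resistance == pytest.approx(5.0, rel=0.05)
        assert res.r_inf == pytest.approx(10.0, rel=0.02)

    def test_flat_spectrum_has_no_polarization(self):
        f = np.logspace(2, 5, 20)
        spec = ImpedanceSpectrum(f, np.full(20, 50.0 + 0j))
        res = fit_drt(spec, lam=1e-6)
        assert res.polarization_resistance < 1e-3 * res.r_inf
        assert res.r_inf == pytest.approx(50.0, rel=1e-6)

    def test_two_debye_masses(self, two_debye_spectrum):
        res = fit_drt(two_debye_spectrum)
        feats = find_relaxation_features(res)
        assert len(feats.peak_tau) == 2
        assert len(feats.valley_tau) == 1
        lt, g = res.dense_ln_tau, res.gamma
        split = math.log(feats.valley_tau[0])
        m_fast = np.trapezoid(g[lt < split], lt[lt < split])
        m_slow = np.trapezoid(g[lt >= split], lt[lt >= split])
        assert m_fast == pytest.approx(5.0, rel=0.10)
        assert m_slow == pytest.approx(8.0, rel=0.10)

    def test_theta_nonnegative_and_gamma_nonnegative(self, two_debye_spectrum):
        res = fit_drt(two_debye_spectrum)
        assert np.all(res.theta >= 0)
        assert np.all(res.gamma >= -1e-15)

    def test_residual_nondecreasing_in_lambda(self, debye_spectrum):
        residuals = [fit_drt(debye_spectrum, lam=lam).residual
                     for lam in (1e-6, 1e-4, 1e-2, 1.0)]
        assert np.all(np.diff(residuals) >= -1e-12)

    def test_deterministic(self, debye_spectrum):
        r1 = fit_drt(debye_spectrum)
        r2 = fit_drt(debye_spectrum)
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.r_inf == r2.r_inf

    def test_peak_stable_under_one_percent_noise(self):
        f = np.logspace(1, 5, 40)
        clean = synthesize_rc_spectrum([(5.0, 1e-4)], 10.0, f)
        noisy = synthesize_rc_spectrum([(5.0, 1e-4)], 10.0, f, noise=0.01, seed=7)
        p0 = find_relaxation_features(fit_drt(clean)).peak_tau[0]
        p1 = find_relaxation_features(fit_drt(noisy)).peak_tau[0]
        res = fit_drt(clean)
        assert abs(math.log(p1 / p0)) < 2 * res.tau_grid.spacing

    def test_short_spectrum_rejected(self):
        spec = ImpedanceSpectrum(np.array([1.0, 2.0]), np.array([1 + 0j, 1 + 0j]))
        with pytest.raises(InvalidInputError):
            fit_drt(spec)

    def test_json_output(self, debye_spectrum, tmp_path):
        import json
        res = fit_drt(debye_spectrum)
        res.to_json(tmp_path / "drt.json")
        doc = json.loads((tmp_path / "drt.json").read_text())
        assert doc["r_inf_ohm"] == res.r_inf
        assert len(doc["theta_ohm"]) == len(res.tau_grid.tau)


class TestReconstruction:
    def test_zero_theta_returns_r_inf(self):
        grid = TauGrid.from_frequencies([1e2, 1e5])
        res = DRTResult(grid, np.zeros(len(grid.tau)), 12.5, mu_from_grid(grid),
                        1e-3, 0.0, np.array([1e2, 1e5]))
        z = reconstruct_impedance(res, [1e2, 1e4, 1e6])
        assert np.allclose(z, 12.5)

    def test_refit_residual_matches_fit(self, debye_spectrum):
        res = fit_drt(debye_spectrum)
        z = reconstruct_impedance(res, debye_spectrum.frequencies)
        refit = float(np.sqrt(np.sum((z.real - debye_spectrum.Z.real) ** 2)
                              + np.sum((z.imag - debye_spectrum.Z.imag) ** 2)))
        assert refit == pytest.approx(res.residual, rel=1e-12)

    def test_debye_refit_within_one_percent(self, debye_spectrum):
        res = fit_drt(debye_spectrum, extension_decades=2.0)
        z = reconstruct_impedance(res, debye_spectrum.frequencies)
        rel = np.abs(z - debye_spectrum.Z) / np.abs(debye_spectrum.Z)
        assert rel.max() < 0.01

    def test_high_frequency_limit_is_r_inf(self, debye_spectrum):
        res = fit_drt(debye_spectrum)
        z = reconstruct_impedance(res, [1e12])
        assert z[0] == pytest.approx(res.r_inf, rel=1e-4)


class TestPeakDetection:
    def test_monotone_gamma_has_no_interior_peak(self):
        grid = TauGrid(np.logspace(-5, -2, 31), 10, 0)
        lt = np.linspace(grid.ln_tau[0], grid.ln_tau[-1], 310)
        gamma = np.linspace(0.0, 1.0, 310)  # monotone ramp
        res = DRTResult(grid, np.zeros(31), 1.0, mu_from_grid(grid), 1e-3, 0.0,
                        np.array([1.0, 10.0]), dense_ln_tau=lt, gamma=gamma)
        feats = find_relaxation_features(res)
        assert len(feats.peak_tau) == 0
        assert len(feats.valley_tau) == 0

    def test_too_few_points_rejected(self):
        grid = TauGrid(np.array([1e-4]), 10, 0)
        res = DRTResult(grid, np.array([1.0]), 1.0, 5.0, 1e-3, 0.0,
                        np.array([1.0, 10.0]),
                        dense_ln_tau=np.array([0.0, 1.0]),
                        gamma=np.array([0.0, 1.0]))
        with pytest.raises(InvalidInputError):
            find_relaxation_features(res)


class TestPairSelection:
    def test_enumerates_all_ten_pairs(self):
        feats = RelaxationFeatures(np.array([]), np.array([]),
                                   np.array([]), np.array([]))
        pairs = select_frequency_pairs(feats, CANDIDATES)
        assert len(pairs) == 10
        assert all(p.f_low < p.f_high for p in pairs)
        assert [p.rank for p in pairs] == list(range(1, 11))

    def test_valley_straddling_pairs_rank_first(self):
        tau_v = 1.0 / (2 * np.pi * 5e4)  # valley at 50 kHz
        feats = RelaxationFeatures(np.array([1e-6, 1e-3]), np.array([1.0, 1.0]),
                                   np.array([tau_v]), np.array([0.1]))
        ranks = {(p.f_low, p.f_high): p.rank
                 for p in select_frequency_pairs(feats, CANDIDATES)}
        assert ranks[(1e4, 1e5)] < ranks[(1e5, 2.25e5)]
        assert ranks[(1e4, 1e5)] < ranks[(2e3, 3.5e4)]

    def test_no_valley_falls_back_to_log_span(self):
        feats = RelaxationFeatures(np.array([]), np.array([]),
                                   np.array([]), np.array([]))
        pairs = select_frequency_pairs(feats, CANDIDATES)
        assert (pairs[0].f_low, pairs[0].f_high) == (2e3, 2.25e5)
        spans = [p.log_span for p in pairs]
        assert spans == sorted(spans, reverse=True)

    def test_single_candidate_rejected(self):
        feats = RelaxationFeatures(np.array([]), np.array([]),
                                   np.array([]), np.array([]))
        with pytest.raises(InvalidInputError):
            select_frequency_pairs(feats, [1e3])


class TestSynthesizer:
    def test_no_elements_gives_flat_spectrum(self):
        spec = synthesize_rc_spectrum([], 7.0, np.logspace(1, 4, 5))
        assert np.allclose(spec.Z, 7.0)

    def test_debye_semicircle_geometry(self):
        r_inf, rp, tau = 10.0, 5.0, 1e-4
        spec = synthesize_rc_spectrum([(rp, tau)], r_inf, np.logspace(1, 6, 50))
        center = r_inf + rp / 2
        radius = np.abs(spec.Z - center)
        assert np.allclose(radius, rp / 2, rtol=1e-12)

    def test_seeded_noise_reproducible(self):
        f = np.logspace(1, 5, 30)
        a = synthesize_rc_spectrum([(5.0, 1e-4)], 10.0, f, noise=0.02, seed=3)
        b = synthesize_rc_spectrum([(5.0, 1e-4)], 10.0, f, noise=0.02, seed=3)
        assert np.array_equal(a.Z, b.Z)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidInputError):
            synthesize_rc_spectrum([(1.0, 1e-4)], 1.0, [1e3], noise=-0.1)

    def test_nonpositive_element_rejected(self):
        with pytest.raises(InvalidInputError):
            synthesize_rc_spectrum([(-1.0, 1e-4)], 1.0, [1e3])
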