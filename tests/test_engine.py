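"""Demixing engine: magnitude step, phase step, weight/delay step, fitting."""

import itertools
import warnings

import numpy as np
import pytest

from fada.engine import (AnechoicFit, ConstraintSpec, FitOptions,
                         apply_constraints, estimate_magnitudes,
                         estimate_phases, estimate_weights_delays,
                         fit_anechoic, _batched_nnls_normal)
from fada.fourier import FourierSeries, analyze, apply_delay, reconstruct
from fada.models import AnechoicParams, embed_temporal, signals_from_dataset
from fada.simulate import SimulationSpec, generate_benchmark

from conftest import band_limited


class TestEstimateMagnitudes:
    def test_rank_one_factorization_is_exact(self, rng):
        a = rng.uniform(0.5, 2.0, size=12)
        h = rng.uniform(0.1, 1.0, size=7)
        X = np.outer(a**2, h**2)
        Asq, Nsq = estimate_magnitudes(X, U=1)
        assert np.max(np.abs(np.outer(Asq[:, 0], Nsq[0]) - X)) < 1e-6 * X.max()

    def test_all_zero_input_gives_zero_factors(self):
        Asq, Nsq = estimate_magnitudes(np.zeros((5, 4)), U=2)
        assert np.all(Asq == 0) and np.all(Nsq == 0)

    def test_disjoint_supports_recovered(self, rng):
        # source 1 lives on k in {1,2}; source 2 on k in {4,5}
        Nsq = np.zeros((2, 7))
        Nsq[0, [1, 2]] = [1.0, 0.6]
        Nsq[1, [4, 5]] = [0.8, 0.5]
        Asq = rng.uniform(0.2, 1.5, size=(20, 2))
        X = Asq @ Nsq
        est_A, est_N = estimate_magnitudes(X, U=2, seed=3)
        # oracle: exhaustive assignment of the two supports
        best = None
        for perm in itertools.permutations(range(2)):
            supports_ok = all(
                est_N[perm[i], [1, 2] if i == 0 else [4, 5]].sum()
                > 10 * est_N[perm[i], [4, 5] if i == 0 else [1, 2]].sum()
                for i in range(2))
            if supports_ok:
                best = perm
        assert best is not None, "supports not separated"

    def test_nn_ica_solver_reconstructs(self, rng):
        Nsq = np.zeros((2, 7))
        Nsq[0, [1, 2]] = [1.0, 0.6]
        Nsq[1, [4, 5]] = [0.8, 0.5]
        Asq = rng.uniform(0.2, 1.5, size=(20, 2))
        X = Asq @ Nsq
        est_A, est_N = estimate_magnitudes(X, U=2, solver="nn_ica", seed=3)
        rel = np.linalg.norm(X - est_A @ est_N) / np.linalg.norm(X)
        assert rel < 0.05

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            estimate_magnitudes(-np.ones((3, 3)), U=1)

    def test_underdetermined_warns(self):
        with pytest.warns(UserWarning, match="under-determined"):
            estimate_magnitudes(np.ones((2, 2)), U=3)


class TestEstimatePhases:
    def test_single_source_closed_form(self, rng):
        K = 5
        c = rng.normal(size=K + 1) + 1j * rng.normal(size=K + 1)
        c[0] = abs(c[0])
        C = c[None, :]
        phi = estimate_phases(C, np.ones((1, 1)), np.zeros((1, 1)),
                              np.abs(c)[None, :])
        expect = np.angle(c)
        assert np.max(np.abs(np.angle(np.exp(1j * (phi[0] - expect))))) < 1e-10

    def test_duplicate_rows_equal_single_row_solution(self, rng):
        K = 4
        c = rng.normal(size=K + 1) + 1j * rng.normal(size=K + 1)
        c[0] = abs(c[0])
        mags = np.abs(c)[None, :]
        phi1 = estimate_phases(c[None, :], np.ones((1, 1)), np.zeros((1, 1)), mags)
        phi2 = estimate_phases(np.vstack([c, c]), np.ones((2, 1)),
                               np.zeros((2, 1)), mags)
        assert np.max(np.abs(np.angle(np.exp(1j * (phi1 - phi2))))) < 1e-10

    def test_recovers_known_phases_against_grid_oracle(self, rng):
        # single source mixed into several rows with zero delays
        K = 4
        mags = rng.uniform(0.5, 1.5, size=K + 1)
        true_phi = rng.uniform(-np.pi, np.pi, size=K + 1)
        true_phi[0] = 0.0
        nu = mags * np.exp(1j * true_phi)
        A = rng.normal(size=(6, 1))
        C = A @ nu[None, :]
        phi = estimate_phases(C, A, np.zeros((6, 1)), mags[None, :])
        for k in range(1, K + 1):
            # dense grid oracle for this frequency
            grid = np.linspace(-np.pi, np.pi, 20001)
            costs = np.abs(C[:, k:k + 1] - A * mags[k]
                           * np.exp(1j * grid)[None, :]).sum(axis=0)
            oracle = grid[np.argmin(costs)]
            err = np.angle(np.exp(1j * (phi[0, k] - oracle)))
            assert abs(err) < 1e-3

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            estimate_phases(np.array([[np.nan + 0j]]), np.ones((1, 1)),
                            np.zeros((1, 1)), np.ones((1, 1)))


class TestEstimateWeightsDelays:
    def test_scaled_copy_recovered(self, rng):
        x, coeffs = band_limited(rng, T=100, K=6)
        f = FourierSeries(coeffs, 1.0)
        a, tau = estimate_weights_delays(2.0 * x, [f])
        assert a[0] == pytest.approx(2.0, abs=1e-6)
        assert abs(tau[0]) < 1e-9

    def test_shifted_copy_found_to_grid_resolution(self, rng):
        T = 100
        x, coeffs = band_limited(rng, T=T, K=6)
        f = FourierSeries(coeffs, 1.0)
        y = reconstruct(apply_delay(f, 5 / T), T)
        a, tau = estimate_weights_delays(y, [f])
        assert a[0] == pytest.approx(1.0, abs=1e-6)
        assert tau[0] == pytest.approx(5 / T, abs=1.0 / T)

    def test_zero_signal_gives_zero_weight_and_delay(self, rng):
        _, coeffs = band_limited(rng, T=50, K=4)
        a, tau = estimate_weights_delays(np.zeros(50), [FourierSeries(coeffs, 1.0)])
        assert np.all(a == 0) and np.all(tau == 0)

    def test_zero_energy_source_tie_break(self, rng):
        x, coeffs = band_limited(rng, T=50, K=4)
        dead = FourierSeries(np.zeros(5, dtype=complex), 1.0)
        a, tau = estimate_weights_delays(x, [FourierSeries(coeffs, 1.0), dead])
        assert a[1] == 0 and tau[1] == 0
        assert a[0] == pytest.approx(1.0, abs=1e-6)


class TestApplyConstraints:
    def _fit(self, rng, R=4, U=2, K=3, T=40):
        nu = rng.normal(size=(U, K + 1)) + 1j * rng.normal(size=(U, K + 1))
        nu[:, 0] = np.abs(nu[:, 0].real)
        from fada.engine import _rows_to_time
        F = _rows_to_time(nu, T)
        A = rng.normal(size=(R, U))
        Tau = rng.uniform(-0.3, 0.3, size=(R, U))
        params = AnechoicParams(F, A, Tau, 1.0)
        return AnechoicFit(params, nu, 0.9, np.zeros(1), True, 0, K)

    def test_empty_spec_is_identity(self, rng):
        fit = self._fit(rng)
        out = apply_constraints(fit, ConstraintSpec())
        assert np.allclose(out.params.A, fit.params.A)
        assert np.allclose(out.nu, fit.nu)

    def test_zero_delays_enforced_exactly(self, rng):
        out = apply_constraints(self._fit(rng), ConstraintSpec(zero_delays=True))
        assert np.all(out.params.Tau == 0)

    def test_tie_group_becomes_energy_weighted_mean(self, rng):
        fit = self._fit(rng)
        # two cells on the SAME source -> equal energies -> plain mean
        fit.params.A[0, 0] = 1.0
        fit.params.A[1, 0] = 3.0
        spec = ConstraintSpec(weight_ties=[[(0, 0), (1, 0)]])
        out = apply_constraints(fit, spec)
        assert out.params.A[0, 0] == pytest.approx(2.0)
        assert out.params.A[1, 0] == pytest.approx(2.0)

    def test_nonneg_weights_clipped(self, rng):
        out = apply_constraints(self._fit(rng), ConstraintSpec(nonneg_weights=True))
        assert np.all(out.params.A >= 0)

    def test_conflicting_ties_rejected(self, rng):
        spec = ConstraintSpec(weight_ties=[[(0, 0), (1, 0)], [(1, 0), (2, 0)]])
        with pytest.raises(ValueError, match="conflicting"):
            apply_constraints(self._fit(rng), spec)


class TestSquaredMagnitudeIdentity:
    def test_disjoint_spectrum_mixture_obeys_identity(self, rng):
        # orthogonal-spectrum sources make the cross terms vanish exactly
        K, T = 6, 100
        nu = np.zeros((2, K + 1), dtype=complex)
        nu[0, [1, 2]] = rng.normal(size=2) + 1j * rng.normal(size=2)
        nu[1, [4, 5]] = rng.normal(size=2) + 1j * rng.normal(size=2)
        A = rng.normal(size=(8, 2))
        Tau = rng.uniform(-0.4, 0.4, size=(8, 2))
        from fada.engine import _rows_to_time
        F = _rows_to_time(nu, T)
        y = np.zeros((8, T))
        from fada.fourier import circular_shift
        for r in range(8):
            for u in range(2):
                y[r] += A[r, u] * circular_shift(F[u], Tau[r, u], 1.0)
        C = np.fft.rfft(y, axis=1)[:, :K + 1] / T
        lhs = np.abs(C) ** 2
        rhs = (A**2) @ (np.abs(nu) ** 2)
        scale = np.max(lhs)
        assert np.max(np.abs(lhs - rhs)) < 1e-8 * scale


class TestFitAnechoic:
    def test_single_source_noiseless_fit_is_tight(self, rng):
        T = 80
        x, coeffs = band_limited(rng, T=T, K=5)
        A = rng.normal(size=(6, 1))
        Tau = rng.uniform(-0.3, 0.3, size=(6, 1))
        y = synth = None
        from fada.models import synthesize_anechoic
        y = synthesize_anechoic(AnechoicParams(x[None, :], A, Tau, 1.0))
        fit = fit_anechoic(y, U=1, opts=FitOptions(seed=0, n_restarts=2))
        assert fit.r2 >= 0.999

    def test_zero_data_defines_perfect_degenerate_fit(self):
        fit = fit_anechoic(np.zeros((4, 50)), U=2, opts=FitOptions(seed=0))
        assert fit.r2 == 1.0 and fit.converged

    def test_trace_is_monotone_within_slack(self, small_bundle):
        y = signals_from_dataset(small_bundle.dataset)
        fit = fit_anechoic(y, U=2, opts=FitOptions(seed=1, n_restarts=1,
                                                   max_outer_iters=40))
        tr = fit.trace
        assert np.all(np.diff(tr) <= 1e-6 * np.maximum(tr[:-1], 1e-30) + 1e-12)

    def test_seed_determinism_is_bitwise(self, small_bundle):
        y = signals_from_dataset(small_bundle.dataset)
        opts = FitOptions(seed=3, n_restarts=2, max_outer_iters=30)
        f1 = fit_anechoic(y, U=2, opts=opts)
        f2 = fit_anechoic(y, U=2, opts=opts)
        assert np.array_equal(f1.params.A, f2.params.A)
        assert np.array_equal(f1.params.Tau, f2.params.Tau)
        assert np.array_equal(f1.nu, f2.nu)

    def test_r2_never_exceeds_one(self, small_bundle):
        y = signals_from_dataset(small_bundle.dataset)
        fit = fit_anechoic(y, U=2, opts=FitOptions(seed=0, n_restarts=1,
                                                   max_outer_iters=20))
        assert fit.r2 <= 1.0


class TestBatchedNnls:
    def test_matches_scipy_reference(self, rng):
        import scipy.optimize
        for _ in range(20):
            D = rng.normal(size=(12, 4))
            b_vec = rng.normal(size=12)
            H = (D.T @ D)[None]
            g = (D.T @ b_vec)[None]
            ours = _batched_nnls_normal(H, g)[0]
            ref, _ = scipy.optimize.nnls(D, b_vec)
            assert np.max(np.abs(ours - ref)) < 1e-8
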