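"""Synthetic benchmark generator: sources, parameters, noise, bundles."""

import numpy as np
import pytest
from scipy import stats

from fada.models import signals_from_dataset, synthesize_anechoic
from fada.simulate import (NOISE_LEVELS, SimulationSpec, add_noise,
                           generate_benchmark, make_parameters, make_sources,
                           synthesize_truth)


class TestMakeSources:
    def test_single_source_is_unit_rms(self, rng):
        s = make_sources(1, 100, 8, False, rng)
        assert np.sqrt(np.mean(s**2)) == pytest.approx(1.0, rel=1e-9)

    def test_nonneg_sources_are_nonnegative(self, rng):
        s = make_sources(4, 100, 8, True, rng)
        assert np.min(s) >= 0

    @pytest.mark.parametrize("nonneg", [False, True])
    def test_spectral_support_within_band(self, rng, nonneg):
        K_gen, T = 8, 100
        s = make_sources(3, T, K_gen, nonneg, rng)
        spectrum = np.abs(np.fft.rfft(s, axis=1)) / T
        out_of_band = spectrum[:, K_gen + 1:]
        assert np.max(out_of_band) < 1e-10 * max(np.max(spectrum), 1e-30)

    def test_correlation_rejection_bound_holds(self, rng):
        s = make_sources(5, 100, 8, False, rng, max_corr=0.5)
        sc = s - s.mean(axis=1, keepdims=True)
        for i in range(5):
            for j in range(i):
                rho = sc[i] @ sc[j] / (np.linalg.norm(sc[i]) * np.linalg.norm(sc[j]))
                assert abs(rho) <= 0.5 + 1e-12

    def test_lag_invariant_rejection_bounds_all_lags(self, rng):
        T = 100
        s = make_sources(3, T, 8, False, rng, max_corr=0.6, lag_invariant=True)
        sc = s - s.mean(axis=1, keepdims=True)
        for i in range(3):
            for j in range(i):
                cc = np.fft.irfft(np.fft.rfft(sc[i]) * np.conj(np.fft.rfft(sc[j])), n=T)
                denom = np.linalg.norm(sc[i]) * np.linalg.norm(sc[j])
                assert np.max(np.abs(cc)) / denom <= 0.6 + 1e-12

    def test_impossible_rejection_raises(self, rng):
        with pytest.raises(RuntimeError, match="uncorrelated"):
            make_sources(8, 30, 1, False, rng, max_corr=0.01, max_attempts=3)


class TestMakeParameters:
    def test_zero_delay_models_have_zero_delays(self, rng):
        for kind in ("temporal", "spatial"):
            spec = SimulationSpec(model_kind=kind, M=4, L=3, T=60, P=2, K_gen=5)
            params = make_parameters(spec, rng)
            if hasattr(params, "Tau"):
                assert np.all(params.Tau == 0)

    def test_nonneg_spec_gives_nonneg_weights(self, rng):
        spec = SimulationSpec(model_kind="temporal_delays", nonneg=True,
                              M=4, L=3, T=60, P=2, K_gen=5)
        params = make_parameters(spec, rng)
        assert np.all(params.C >= 0) and np.all(params.S >= 0)

    def test_delays_are_uniform_within_range(self):
        # pool delays from many draws and compare to U(-0.15, 0.15)
        delays = []
        for i in range(8):
            spec = SimulationSpec(model_kind="temporal_delays", M=10, L=20,
                                  T=60, P=3, K_gen=5, seed=i)
            params = make_parameters(spec, np.random.default_rng([55, i]))
            delays.append(params.Tau.ravel())
        pooled = np.concatenate(delays)
        assert pooled.size >= 1e4 / 3
        u = (pooled + 0.15) / 0.30
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_space_by_time_is_fully_nonneg(self, rng):
        spec = SimulationSpec(model_kind="space_by_time", M=4, L=3, T=60,
                              P_tp=2, P_sp=2, K_gen=5)
        p = make_parameters(spec, rng)
        assert np.all(p.W >= 0) and np.all(p.S >= 0) and np.all(p.C >= 0)


class TestAddNoise:
    def test_level_zero_is_identity(self, rng):
        spec = SimulationSpec(model_kind="temporal", M=3, L=2, T=50, P=2, K_gen=5)
        ds = synthesize_truth(make_parameters(spec, rng), spec)
        assert add_noise(ds, 0.0, rng) is ds

    def test_nonneg_dataset_stays_nonneg(self, rng):
        spec = SimulationSpec(model_kind="temporal", nonneg=True, M=3, L=2,
                              T=50, P=2, K_gen=5)
        ds = synthesize_truth(make_parameters(spec, rng), spec)
        noisy = add_noise(ds, 0.35, rng)
        assert np.all(noisy.data >= 0)

    def test_empirical_noise_level_matches_request(self, rng):
        spec = SimulationSpec(model_kind="temporal", M=10, L=20, T=100, P=3)
        ds = synthesize_truth(make_parameters(spec, rng), spec)
        level = 0.25
        noisy = add_noise(ds, level, rng)
        ratio = np.sqrt(np.mean((noisy.data - ds.data) ** 2)) \
            / np.sqrt(np.mean(ds.data**2))
        assert ratio == pytest.approx(level, rel=0.10)


class TestGenerateBenchmark:
    def test_default_realization_count_is_twenty(self):
        spec = SimulationSpec(model_kind="temporal", M=3, L=2, T=40, P=2, K_gen=5)
        assert len(generate_benchmark(spec)) == 20

    def test_same_seed_is_bitwise_identical(self):
        spec = SimulationSpec(model_kind="temporal_delays", M=3, L=2, T=40,
                              P=2, K_gen=5, n_realizations=2, seed=9,
                              noise_level=0.15)
        b1 = generate_benchmark(spec)
        b2 = generate_benchmark(spec)
        for x, y in zip(b1, b2):
            assert np.array_equal(x.dataset.data, y.dataset.data)

    def test_distinct_seeds_differ(self):
        s1 = SimulationSpec(model_kind="temporal", M=3, L=2, T=40, P=2,
                            K_gen=5, n_realizations=1, seed=1)
        s2 = SimulationSpec(model_kind="temporal", M=3, L=2, T=40, P=2,
                            K_gen=5, n_realizations=1, seed=2)
        assert not np.array_equal(generate_benchmark(s1)[0].dataset.data,
                                  generate_benchmark(s2)[0].dataset.data)

    def test_truth_plus_noise_reproduces_dataset_exactly(self):
        spec = SimulationSpec(model_kind="temporal_delays", M=4, L=3, T=50,
                              P=2, K_gen=5, n_realizations=2, seed=3,
                              noise_level=0.25)
        for bundle in generate_benchmark(spec):
            clean = synthesize_truth(bundle.truth, spec)
            assert np.array_equal(clean.data + bundle.noise, bundle.dataset.data)

    @pytest.mark.parametrize("kind", ["spatial", "temporal", "temporal_delays",
                                      "spatiotemporal", "space_by_time"])
    def test_bundles_pass_dual_forward_equivalence(self, kind):
        from fada.models import (embed_space_by_time, embed_spatial,
                                 embed_spatiotemporal, embed_temporal)
        spec = SimulationSpec(model_kind=kind, M=4, L=3, T=50, P=2,
                              P_tp=2, P_sp=2, K_gen=5, n_realizations=1, seed=4)
        bundle = generate_benchmark(spec)[0]
        clean = synthesize_truth(bundle.truth, spec)
        embed = {"spatial": embed_spatial, "temporal": embed_temporal,
                 "temporal_delays": embed_temporal,
                 "spatiotemporal": embed_spatiotemporal,
                 "space_by_time": embed_space_by_time}[kind]
        an, _ = embed(bundle.truth)
        y = synthesize_anechoic(an)
        # nonneg datasets are clipped of float dust after synthesis
        y_cmp = np.clip(y, 0, None) if clean.nonneg_domain else y
        assert np.max(np.abs(y_cmp - signals_from_dataset(clean))) < 1e-10
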