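"""Recovery metrics: R^2, matching, normalized similarity, delay scoring."""

import itertools

import numpy as np
import pytest

from fada.evaluation import (baseline_similarity, delay_similarity, evaluate,
                             explained_variance, match_components,
                             normalized_similarity, spatial_similarity,
                             temporal_similarity)
from fada.api import ModelFit
from fada.engine import FitOptions
from fada.gauge import canonicalize
from fada.models import TemporalParams
from fada.simulate import (GroundTruthBundle, SimulationSpec,
                           generate_benchmark, make_parameters)


class TestExplainedVariance:
    def test_perfect_reconstruction_scores_one(self, rng):
        x = rng.normal(size=(3, 4))
        assert explained_variance(x, x) == 1.0

    def test_grand_mean_reconstruction_scores_zero(self, rng):
        x = rng.normal(size=(5, 5))
        assert explained_variance(x, np.full_like(x, x.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        recon = np.array([[1.0, 2.0], [3.0, 5.0]])
        # SS_res = 1, SS_tot (about grand mean 2.5) = 5
        assert explained_variance(data, recon) == pytest.approx(0.8)

    def test_zero_variance_conventions(self):
        z = np.zeros((2, 2))
        assert explained_variance(z, z) == 1.0
        assert explained_variance(z, np.ones((2, 2))) == -np.inf

    def test_matches_independent_formula(self, rng):
        x = rng.normal(size=(4, 6))
        y = rng.normal(size=(4, 6))
        expected = 1 - np.sum((x - y) ** 2) / np.sum((x - x.mean()) ** 2)
        assert explained_variance(x, y) == pytest.approx(expected, rel=1e-12)


class TestMatching:
    def test_self_match_is_identity_with_unit_scores(self, rng):
        comps = [rng.normal(size=30) for _ in range(3)]
        perm, scores = match_components(comps, comps, temporal_similarity)
        assert np.array_equal(perm, [0, 1, 2])
        assert np.allclose(scores, 1.0)

    def test_reversed_order_gives_reversing_permutation(self, rng):
        comps = [rng.normal(size=8) for _ in range(3)]
        perm, _ = match_components(comps[::-1], comps, spatial_similarity)
        assert np.array_equal(perm, [2, 1, 0])

    def test_matches_exhaustive_assignment_oracle(self, rng):
        est = [rng.normal(size=10) for _ in range(4)]
        tru = [rng.normal(size=10) for _ in range(4)]
        perm, scores = match_components(est, tru, spatial_similarity)
        best = max(
            (sum(spatial_similarity(est[p[i]], tru[i]) for i in range(4)), p)
            for p in itertools.permutations(range(4)))
        assert sum(scores) == pytest.approx(best[0])

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="counts"):
            match_components([rng.normal(size=4)], [], spatial_similarity)


class TestNormalizedSimilarity:
    @pytest.mark.parametrize("raw,base,expected",
                             [(1.0, 0.4, 1.0), (0.4, 0.4, 0.0), (0.7, 0.4, 0.5)])
    def test_affine_rescaling(self, raw, base, expected):
        assert normalized_similarity(raw, base) == pytest.approx(expected)

    def test_below_chance_clamps_to_zero_but_preclamp_is_negative(self):
        assert normalized_similarity(0.2, 0.4) == 0.0
        assert normalized_similarity(0.2, 0.4, clamp=False) < 0

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalized_similarity(0.5, 1.0)


class TestDelaySimilarity:
    def test_exact_delays_score_one(self, rng):
        tau = rng.uniform(-0.1, 0.1, size=(5, 3))
        score, rms = delay_similarity(tau, tau, 1.0)
        assert score == 1.0 and rms == pytest.approx(0.0, abs=1e-12)

    def test_rms_of_quarter_period_scores_zero(self):
        # balanced +-T_s/4 errors: zero offset, RMS exactly the score scale
        true = np.zeros((400, 1))
        est = np.tile([[0.25], [-0.25]], (200, 1))
        score, rms = delay_similarity(est, true, 1.0)
        assert rms == pytest.approx(0.25, rel=1e-9)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_table(self):
        true = np.array([[0.0], [0.1], [-0.1], [0.05], [-0.05]])
        est = np.array([[0.02], [0.08], [-0.12], [0.05], [-0.03]])
        diffs = (est - true).ravel()
        offset = np.angle(np.mean(np.exp(2j * np.pi * diffs))) / (2 * np.pi)
        resid = np.angle(np.exp(2j * np.pi * (diffs - offset))) / (2 * np.pi)
        expected_rms = np.sqrt(np.mean(resid**2))
        _, rms = delay_similarity(est, true, 1.0)
        assert rms == pytest.approx(expected_rms, rel=1e-9)

    def test_global_offset_gauge_is_removed(self, rng):
        tau = rng.uniform(-0.1, 0.1, size=(6, 2))
        shifted = tau + np.array([[0.2, -0.3]])
        score, rms = delay_similarity(shifted, tau, 1.0)
        assert rms == pytest.approx(0.0, abs=1e-9) and score == 1.0

    def test_weighting_ignores_silent_components(self, rng):
        true = np.zeros((10, 1))
        est = np.zeros((10, 1))
        est[0, 0] = 0.4  # wildly wrong, but weight ~ 0
        w = np.ones((10, 1))
        w[0, 0] = 0.0
        _, rms_weighted = delay_similarity(est, true, 1.0, weights=w)
        _, rms_plain = delay_similarity(est, true, 1.0)
        assert rms_weighted < 1e-9 < rms_plain


class TestEvaluate:
    def _bundle(self, seed=0):
        spec = SimulationSpec(model_kind="temporal_delays", M=4, L=5, T=60,
                              P=2, K_gen=5, seed=seed, n_realizations=1)
        return generate_benchmark(spec)[0]

    def _as_fit(self, params, spec):
        return ModelFit(spec.model_kind, params, 1.0, spec.P, FitOptions())

    def test_truth_scores_perfectly(self):
        b = self._bundle()
        rep = evaluate(self._as_fit(b.truth, b.spec), b, n_baseline_pairs=15)
        assert rep.sn_primitives == pytest.approx(1.0, abs=1e-9)
        assert rep.sn_weights == pytest.approx(1.0, abs=1e-9)
        assert rep.sn_delays == pytest.approx(1.0, abs=1e-6)

    def test_gauge_invariance_under_permutation_and_sign(self):
        b = self._bundle(1)
        t = b.truth
        perm = [1, 0]
        flipped = TemporalParams(-t.S[perm], -t.C[:, :, perm],
                                 t.Tau[:, :, perm], t.nonneg)
        rep = evaluate(self._as_fit(canonicalize(flipped), b.spec), b,
                       n_baseline_pairs=15)
        assert rep.sn_primitives == pytest.approx(1.0, abs=1e-9)
        assert rep.sn_weights == pytest.approx(1.0, abs=1e-9)

    def test_random_estimates_score_near_zero_preclamp(self):
        b = self._bundle(2)
        vals = []
        baselines = {}
        for i in range(12):
            fake = make_parameters(b.spec, np.random.default_rng([777, i]))
            rep = evaluate(self._as_fit(fake, b.spec), b, n_baseline_pairs=60,
                           clamp=False, baselines=baselines)
            vals.append(rep.sn_primitives)
        assert abs(np.mean(vals)) < 0.12

    def test_baseline_similarity_is_seed_stable(self):
        spec = SimulationSpec(model_kind="temporal", M=4, L=4, T=60, P=2,
                              K_gen=5)
        a = baseline_similarity(spec, "primitives", n_pairs=40, seed=0)
        b = baseline_similarity(spec, "primitives", n_pairs=40, seed=1)
        assert abs(a - b) < 0.05
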