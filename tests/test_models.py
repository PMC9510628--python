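"""Forward models, Table-1 embeddings, and their exact equivalence."""

import numpy as np
import pytest

from fada.models import (AnechoicParams, SpaceByTimeParams, SpatialParams,
                         SpatiotemporalParams, TemporalParams, TrialDataset,
                         TrialMeta, embed_space_by_time, embed_spatial,
                         embed_spatiotemporal, embed_temporal,
                         signals_from_dataset, synthesize_anechoic,
                         synthesize_space_by_time, synthesize_spatial,
                         synthesize_spatiotemporal, synthesize_temporal)

from conftest import band_limited


# --- independent brute-force synthesis oracles (nested loops, np.roll) ----

def loop_spatial(W, C):
    M, P = W.shape
    L, _, T = C.shape
    out = np.zeros((L, M, T))
    for l in range(L):
        for m in range(M):
            for t in range(T):
                for p in range(P):
                    out[l, m, t] += W[m, p] * C[l, p, t]
    return out


def loop_temporal_integer_delays(S, C, shifts):
    """shifts in integer samples; circular."""
    P, T = S.shape
    L, M, _ = C.shape
    out = np.zeros((L, M, T))
    for l in range(L):
        for m in range(M):
            for p in range(P):
                out[l, m, :] += C[l, m, p] * np.roll(S[p], shifts[l, m, p])
    return out


def loop_anechoic_integer_delays(F, A, shifts):
    R, U = A.shape
    out = np.zeros((R, F.shape[1]))
    for r in range(R):
        for u in range(U):
            out[r] += A[r, u] * np.roll(F[u], shifts[r, u])
    return out


def random_sources(rng, n, T, K=6):
    return np.stack([band_limited(rng, T=T, K=K)[0] for _ in range(n)])


# --- synthesis ------------------------------------------------------------

class TestSynthesis:
    def test_constant_spatial_source_repeats_pattern(self):
        W = np.array([[1.0], [2.0]])
        C = np.ones((1, 1, 5))
        ds = synthesize_spatial(SpatialParams(W, C))
        assert np.allclose(ds.data[0], np.array([[1.0] * 5, [2.0] * 5]))

    def test_zero_weights_give_zero_data(self):
        ds = synthesize_spatial(SpatialParams(np.ones((3, 2)), np.zeros((2, 2, 7))))
        assert np.all(ds.data == 0)

    def test_spatial_matches_loop_oracle(self, rng):
        W = rng.normal(size=(4, 2))
        C = rng.normal(size=(3, 2, 50))
        ds = synthesize_spatial(SpatialParams(W, C))
        assert np.max(np.abs(ds.data - loop_spatial(W, C))) < 1e-12

    def test_temporal_zero_delay_unit_weight_repeats_source(self, rng):
        S = random_sources(rng, 1, 40)
        C = np.ones((2, 3, 1))
        ds = synthesize_temporal(TemporalParams(S, C, np.zeros((2, 3, 1))))
        assert np.allclose(ds.data, np.broadcast_to(S[0], (2, 3, 40)))

    def test_temporal_integer_delay_is_circular_roll(self, rng):
        T = 50
        S = random_sources(rng, 1, T)
        C = np.ones((1, 1, 1))
        Tau = np.full((1, 1, 1), 6 / T)
        ds = synthesize_temporal(TemporalParams(S, C, Tau), TrialMeta(1.0))
        assert np.max(np.abs(ds.data[0, 0] - np.roll(S[0], 6))) < 1e-10

    def test_temporal_matches_loop_oracle(self, rng):
        T = 60
        S = random_sources(rng, 2, T)
        C = rng.normal(size=(3, 4, 2))
        shifts = rng.integers(-10, 10, size=(3, 4, 2))
        ds = synthesize_temporal(TemporalParams(S, C, shifts / T))
        assert np.max(np.abs(ds.data - loop_temporal_integer_delays(S, C, shifts))) < 1e-10

    def test_anechoic_single_source_identity(self, rng):
        F = random_sources(rng, 1, 30)
        y = synthesize_anechoic(AnechoicParams(F, np.ones((1, 1)), np.zeros((1, 1))))
        assert np.max(np.abs(y - F)) < 1e-12

    def test_anechoic_half_period_flips_fundamental(self):
        T = 64
        F = np.cos(2 * np.pi * np.arange(T) / T)[None, :]
        y = synthesize_anechoic(
            AnechoicParams(F, np.ones((1, 1)), np.full((1, 1), 0.5), 1.0))
        assert np.max(np.abs(y[0] + F[0])) < 1e-10

    def test_anechoic_matches_loop_oracle(self, rng):
        T = 50
        F = random_sources(rng, 3, T)
        A = rng.normal(size=(5, 3))
        shifts = rng.integers(-15, 15, size=(5, 3))
        y = synthesize_anechoic(AnechoicParams(F, A, shifts / T, 1.0))
        assert np.max(np.abs(y - loop_anechoic_integer_delays(F, A, shifts))) < 1e-10

    def test_delay_exceeding_duration_rejected(self, rng):
        S = random_sources(rng, 1, 20)
        with pytest.raises(ValueError, match="duration"):
            synthesize_temporal(TemporalParams(S, np.ones((1, 1, 1)),
                                               np.full((1, 1, 1), 1.5)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SpatialParams(np.ones((3, 2)), np.ones((2, 3, 7)))

    def test_nonneg_closure_with_zero_delays(self, rng):
        W = rng.uniform(0, 1, size=(4, 2))
        C = rng.uniform(0, 1, size=(3, 2, 30))
        ds = synthesize_spatial(SpatialParams(W, C, nonneg=True))
        assert ds.nonneg_domain and np.all(ds.data >= 0)

    def test_zero_delay_temporal_equals_synchronous_path(self, rng):
        S = random_sources(rng, 2, 40)
        C = rng.normal(size=(2, 3, 2))
        a = synthesize_temporal(TemporalParams(S, C, np.zeros((2, 3, 2))))
        manual = np.einsum("lmp,pt->lmt", C, S)
        assert np.array_equal(a.data, manual)


# --- embeddings -----------------------------------------------------------

def _dual(specific: TrialDataset, anechoic, T=None):
    y = synthesize_anechoic(anechoic, T)
    return np.max(np.abs(y - signals_from_dataset(specific)))


class TestEmbeddings:
    def test_spatial_single_component_shapes(self, rng):
        p = SpatialParams(np.array([[1.0], [2.0]]), rng.normal(size=(1, 1, 20)))
        an, imap = embed_spatial(p)
        assert an.U == 1 and an.R == 2
        assert np.allclose(an.A, p.W)
        assert np.all(an.Tau == 0)

    def test_spatial_dual_forward_equality(self, rng):
        p = SpatialParams(rng.normal(size=(4, 2)), rng.normal(size=(3, 2, 50)))
        an, imap = embed_spatial(p)
        assert _dual(synthesize_spatial(p), an) < 1e-12

    def test_spatial_embedding_has_zero_delays(self, rng):
        p = SpatialParams(rng.normal(size=(3, 2)), rng.normal(size=(2, 2, 30)))
        an, _ = embed_spatial(p)
        assert np.all(an.Tau == 0)

    def test_temporal_dual_forward_equality(self, rng):
        S = random_sources(rng, 2, 60)
        p = TemporalParams(S, rng.normal(size=(3, 4, 2)),
                           rng.uniform(-0.3, 0.3, size=(3, 4, 2)))
        an, imap = embed_temporal(p)
        assert an.U == p.P
        assert _dual(synthesize_temporal(p), an) < 1e-10

    def test_temporal_embedding_ties_weights_to_model(self, rng):
        S = random_sources(rng, 2, 40)
        C = rng.normal(size=(2, 3, 2))
        Tau = rng.uniform(-0.2, 0.2, size=(2, 3, 2))
        an, imap = embed_temporal(TemporalParams(S, C, Tau))
        for l in range(2):
            for m in range(3):
                r = imap.r_of(m, l)
                assert np.allclose(an.A[r], C[l, m])
                assert np.allclose(an.Tau[r], Tau[l, m])

    def test_spatiotemporal_dual_forward_equality(self, rng):
        Wt = np.stack([random_sources(rng, 4, 50) for _ in range(2)])
        p = SpatiotemporalParams(Wt, rng.uniform(0, 1, size=(3, 2)),
                                 rng.uniform(-0.2, 0.2, size=(3, 2)),
                                 nonneg=False)
        an, imap = embed_spatiotemporal(p)
        assert an.U == p.P * p.M
        assert _dual(synthesize_spatiotemporal(p), an) < 1e-10

    def test_spatiotemporal_ties_delays_across_dofs(self, rng):
        Wt = np.stack([random_sources(rng, 3, 30) for _ in range(2)])
        p = SpatiotemporalParams(Wt, rng.uniform(0, 1, (2, 2)),
                                 rng.uniform(-0.1, 0.1, (2, 2)), nonneg=False)
        an, imap = embed_spatiotemporal(p)
        for l in range(2):
            for pp in range(2):
                delays = [an.Tau[imap.r_of(m, l), imap.u_of(pp, m)]
                          for m in range(3)]
                assert np.allclose(delays, p.Tau[l, pp])

    def test_space_by_time_dual_forward_equality(self, rng):
        S = np.abs(random_sources(rng, 2, 40))
        p = SpaceByTimeParams(rng.uniform(0, 1, (4, 2)), S,
                              rng.uniform(0, 1, (3, 2, 2)),
                              rng.uniform(-0.2, 0.2, (3, 2, 2)))
        an, imap = embed_space_by_time(p)
        assert _dual(synthesize_space_by_time(p), an) < 1e-10

    def test_space_by_time_bilinear_weight_structure(self, rng):
        S = np.abs(random_sources(rng, 2, 30))
        p = SpaceByTimeParams(rng.uniform(0, 1, (3, 2)), S,
                              rng.uniform(0, 1, (2, 2, 2)),
                              np.zeros((2, 2, 2)))
        an, imap = embed_space_by_time(p)
        for l in range(2):
            for m in range(3):
                for pp in range(2):
                    for q in range(2):
                        cell = an.A[imap.r_of(m, l), imap.u_of(pp, q)]
                        assert cell == pytest.approx(p.C[l, pp, q] * p.W[m, q])

    def test_index_map_round_trips(self, rng):
        p = SpatialParams(rng.normal(size=(4, 3)), rng.normal(size=(5, 3, 20)))
        _, imap = embed_spatial(p)
        for m in range(4):
            for l in range(5):
                r = imap.r_of(m, l)
                assert imap.m_of(r) == m and imap.l_of(r) == l
        for u in range(imap.U):
            assert imap.u_of(imap.p_of(u), imap.second_of(u)) == u
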