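"""Per-model fitting front end.

:func:`fit` specializes the anechoic demixing engine to one of the five
decomposition models by building the appropriate constraint set (Table-1
ties, structural zeros, zero delays, non-negativity, bilinear weights),
running :func:`fada.engine.fit_anechoic` on the flattened trial data, and
unpacking the result back into model-specific parameters through the index
bijections of :mod:`fada.models`.

:func:`r2_curve` and :func:`elbow_select` implement model-order selection:
the number of primitives is the smallest order from which the R-squared
versus order curve is well fit by a straight line (suffix mean squared
error below a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dataclasses import replace as _replace

from . import engine as _engine
from .engine import (AnechoicFit, BilinearSpec, ConstraintSpec, FitOptions,
                     fit_anechoic)
from .evaluation import explained_variance
from .fourier import choose_num_harmonics
from .gauge import canonicalize
from .models import (IndexMap, SpaceByTimeParams, SpatialParams,
                     SpatiotemporalParams, TemporalParams, TrialDataset,
                     TrialMeta, embed_spatial, embed_temporal,
                     signals_from_dataset)
from .rotation import unmixing_matrix
from .simulate import MODEL_KINDS, synthesize_truth
from .simulate import SimulationSpec as _SimSpec

__all__ = ["ModelFit", "fit", "r2_curve", "elbow_select", "build_constraints"]


@dataclass
class ModelFit:
    """A fitted decomposition model."""

    model_kind: str
    params: object
    r2: float
    n_primitives: int
    options: FitOptions
    provenance: dict = field(default_factory=dict)
    anechoic: AnechoicFit | None = None


def build_constraints(model_kind: str, M: int, L: int, P: int | None = None,
                      P_tp: int | None = None, P_sp: int | None = None,
                      nonneg: bool = False) -> tuple[ConstraintSpec, int]:
    """Constraint set and source count embedding a model into the engine."""
    R = M * L
    if model_kind == "spatial":
        U = P * L
        zeros = np.ones((R, U), dtype=bool)
        for l in range(L):
            zeros[np.ix_(l * M + np.arange(M), np.arange(P) * L + l)] = False
        ties = [[(l * M + m, p * L + l) for l in range(L)]
                for m in range(M) for p in range(P)]
        spec = ConstraintSpec(zero_delays=True, nonneg_weights=nonneg,
                              nonneg_sources=nonneg, weight_ties=ties,
                              weight_zeros=zeros)
        return spec, U
    if model_kind in ("temporal", "temporal_delays"):
        spec = ConstraintSpec(zero_delays=(model_kind == "temporal"),
                              nonneg_weights=nonneg, nonneg_sources=nonneg)
        return spec, P
    if model_kind == "spatiotemporal":
        U = P * M
        zeros = np.ones((R, U), dtype=bool)
        for m in range(M):
            rows = np.arange(L) * M + m
            cols = np.arange(P) * M + m
            zeros[np.ix_(rows, cols)] = False
        ties = [[(l * M + m, p * M + m) for m in range(M)]
                for l in range(L) for p in range(P)]
        spec = ConstraintSpec(zero_delays=False, nonneg_weights=nonneg,
                              nonneg_sources=nonneg, weight_ties=ties,
                              delay_ties=[list(g) for g in ties],
                              weight_zeros=zeros)
        return spec, U
    if model_kind == "space_by_time":
        spec = ConstraintSpec(zero_delays=False, nonneg_weights=True,
                              nonneg_sources=True,
                              bilinear=BilinearSpec(P_tp, P_sp, M, L))
        return spec, P_tp * P_sp
    raise ValueError(f"unknown model_kind {model_kind!r}")


def fit(dataset: TrialDataset, model_kind: str, P: int | None = None,
        P_tp: int | None = None, P_sp: int | None = None,
        nonneg: bool | None = None, opts: FitOptions | None = None) -> ModelFit:
    """Fit one decomposition model to a dataset.

    Parameters
    ----------
    dataset : TrialDataset
    model_kind : {"spatial", "temporal", "temporal_delays", "spatiotemporal",
                  "space_by_time"}
    P : int
        Number of primitives (ignored for space_by_time).
    P_tp, P_sp : int
        Temporal/spatial primitive counts for space_by_time.
    nonneg : bool, optional
        Non-negativity of primitives and weights.  Defaults to the dataset's
        ``nonneg_domain``; space_by_time is always non-negative.
    opts : FitOptions, optional
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    M, L, T = dataset.M, dataset.L, dataset.T
    R = M * L
    if model_kind == "space_by_time":
        P_tp = P_tp if P_tp is not None else P
        P_sp = P_sp if P_sp is not None else P_tp
        if P_tp is None or P_tp < 1 or P_sp < 1:
            raise ValueError("space_by_time needs P_tp >= 1 and P_sp >= 1")
        if max(P_tp, P_sp) > R:
            raise ValueError("number of primitives exceeds the number of signals")
        nonneg = True
        n_prim = P_tp
    else:
        if P is None or P < 1:
            raise ValueError("P must be >= 1")
        if P > R:
            raise ValueError("number of primitives exceeds the number of signals")
        if nonneg is None:
            nonneg = dataset.nonneg_domain
        n_prim = P
    opts = opts or FitOptions()
    if opts.K is None:
        opts = _replace(opts, K=choose_num_harmonics(signals_from_dataset(dataset)))
    spec, U = build_constraints(model_kind, M, L, P, P_tp, P_sp, nonneg)
    if model_kind in ("spatial", "temporal") and nonneg:
        # two-stage: an unconstrained fit, rotated to the maximally
        # uncorrelated basis and projected onto the non-negative orthant,
        # seeds the constrained fit
        opts = _replace(opts, initial_state=_nonneg_seed(
            dataset, model_kind, P, opts))
    afit = fit_anechoic(dataset, U, spec, opts)
    params = _unpack(afit, model_kind, M, L, T, P, P_tp, P_sp, nonneg)
    if model_kind in ("spatial", "temporal") and not nonneg:
        # the synchronous least-squares factorization leaves a rotation
        # freedom; fix it by lagged-covariance joint diagonalization
        params = _fix_rotation(params)
    params = canonicalize(params)
    sim_spec = _SimSpec(model_kind=model_kind, nonneg=bool(nonneg), M=M, L=L, T=T,
                        duration_s=dataset.duration_s,
                        P=n_prim, P_tp=P_tp or n_prim, P_sp=P_sp or n_prim)
    recon = synthesize_truth(params, sim_spec)
    r2 = explained_variance(dataset.data, recon.data)
    return ModelFit(model_kind, params, r2, n_prim, opts,
                    provenance={"seed": opts.seed, "K": afit.K,
                                "converged": bool(afit.converged),
                                "engine_r2": afit.r2},
                    anechoic=afit)


def _fix_rotation(params):
    """Rotate synchronous components to the maximally uncorrelated basis."""
    if isinstance(params, TemporalParams):
        if params.P < 2:
            return params
        G = unmixing_matrix(params.S, T=params.S.shape[1])
        S_new = G @ params.S
        C_new = np.einsum("lmp,pq->lmq", params.C, np.linalg.inv(G))
        return TemporalParams(S_new, C_new, params.Tau, params.nonneg)
    if isinstance(params, SpatialParams):
        if params.P < 2:
            return params
        T = params.C.shape[2]
        Cs = params.C.transpose(1, 0, 2).reshape(params.P, -1)
        G = unmixing_matrix(Cs, T=T)
        C_new = np.einsum("qp,lpt->lqt", G, params.C)
        W_new = params.W @ np.linalg.inv(G)
        return SpatialParams(W_new, C_new, params.nonneg)
    return params


def _nonneg_seed(dataset: TrialDataset, model_kind: str, P: int,
                 opts: FitOptions) -> dict:
    """Initial engine state for a non-negative synchronous fit.

    Runs a reduced unconstrained fit, rotates it to the uncorrelated basis,
    flips component signs toward the positive orthant and clips, then embeds
    the result back into anechoic form.
    """
    free_opts = _replace(opts, n_restarts=2, max_outer_iters=60,
                         initial_state=None)
    free = fit(dataset, model_kind, P=P, nonneg=False, opts=free_opts)
    params = free.params
    if isinstance(params, TemporalParams):
        S, C = params.S.copy(), params.C.copy()
        for p in range(P):
            if S[p].sum() < 0:
                S[p] *= -1
                C[:, :, p] *= -1
        seeded = TemporalParams(np.clip(S, 0, None), np.clip(C, 0, None),
                                params.Tau, True)
        an, _ = embed_temporal(seeded, dataset.duration_s)
    else:
        W, C = params.W.copy(), params.C.copy()
        for p in range(P):
            if W[:, p].sum() < 0:
                W[:, p] *= -1
                C[:, p, :] *= -1
        seeded = SpatialParams(np.clip(W, 0, None), np.clip(C, 0, None), True)
        an, _ = embed_spatial(seeded, dataset.duration_s)
    nu = _engine._analyze_rows(an.F, opts.K)
    return {"nu": nu, "A": an.A, "Tau": an.Tau}


def _unpack(afit: AnechoicFit, model_kind: str, M: int, L: int, T: int,
            P: int | None, P_tp: int | None, P_sp: int | None, nonneg: bool):
    A, Tau, nu = afit.params.A, afit.params.Tau, afit.nu
    duration_s = afit.params.duration_s
    F = _engine._rows_to_time(nu, T)

    def clip(x):
        return np.clip(x, 0.0, None) if nonneg else x

    if model_kind == "spatial":
        W = np.zeros((M, P))
        C = np.zeros((L, P, T))
        for p in range(P):
            for l in range(L):
                C[l, p] = F[p * L + l]
            W[:, p] = np.mean(
                [[A[l * M + m, p * L + l] for l in range(L)] for m in range(M)],
                axis=1)
        return SpatialParams(clip(W), clip(C), nonneg)
    if model_kind in ("temporal", "temporal_delays"):
        S = F[:P]
        C = A.reshape(L, M, P)
        TauP = np.zeros((L, M, P)) if model_kind == "temporal" \
            else Tau.reshape(L, M, P).copy()
        return TemporalParams(clip(S), clip(C), TauP, nonneg)
    if model_kind == "spatiotemporal":
        Wt = F.reshape(P, M, T)
        C = np.zeros((L, P))
        TauP = np.zeros((L, P))
        for l in range(L):
            for p in range(P):
                cells_a = [A[l * M + m, p * M + m] for m in range(M)]
                cells_t = [Tau[l * M + m, p * M + m] for m in range(M)]
                C[l, p] = np.mean(cells_a)
                TauP[l, p] = cells_t[int(np.argmax(np.abs(cells_a)))]
        return SpatiotemporalParams(clip(Wt), clip(C), TauP, nonneg)
    if model_kind == "space_by_time":
        fac = afit.factors
        S = _engine._rows_to_time(fac["nu_S"], T)
        return SpaceByTimeParams(np.clip(fac["W"], 0, None),
                                 np.clip(S, 0, None),
                                 np.clip(fac["C"], 0, None), fac["Tau"])
    raise ValueError(model_kind)


def r2_curve(dataset: TrialDataset, model_kind: str, P_range,
             nonneg: bool | None = None,
             opts: FitOptions | None = None) -> list[tuple[int, float]]:
    """Explained variance as a function of the number of primitives.

    Each order is fit independently (no warm start), so the curve carries no
    order-dependent bias.  For space_by_time, ``P`` sets both primitive
    counts.
    """
    P_range = list(P_range)
    if any(b <= a for a, b in zip(P_range, P_range[1:])):
        raise ValueError("P_range must be ascending")
    curve = []
    for P in P_range:
        mf = fit(dataset, model_kind, P=P, P_tp=P, P_sp=P, nonneg=nonneg, opts=opts)
        curve.append((P, mf.r2))
    return curve


def elbow_select(curve, mse_threshold: float = 1e-4) -> int:
    """Smallest order from which a line fits the R^2 curve well.

    Scans candidate orders in ascending sequence; for each, an ordinary
    least-squares line is fit to the curve points from that order to the
    end, and the first candidate whose fit has mean squared error below
    ``mse_threshold`` is returned.  If none qualifies the largest order is
    returned (documented fallback).
    """
    pts = [(int(p), float(r)) for p, r in curve]
    if len(pts) < 3:
        raise ValueError("elbow selection needs at least 3 curve points")
    for i in range(len(pts)):
        tail = pts[i:]
        if len(tail) < 2:
            break
        x = np.array([p for p, _ in tail], dtype=float)
        y = np.array([r for _, r in tail], dtype=float)
        X = np.stack([x, np.ones_like(x)], axis=1)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        mse = float(np.mean((y - X @ coef) ** 2))
        if mse < mse_threshold:
            return pts[i][0]
    return pts[-1][0]
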