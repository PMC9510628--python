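"""Generative models of motor primitives and their anechoic embeddings.

Five classical decompositions of multi-trial movement data are implemented as
forward (synthesis) operators:

* **spatial** — fixed spatial patterns (columns of ``W``) mixed by
  time-varying, trial-specific coefficients ``C[l, p, t]``;
* **temporal** — fixed temporal source functions ``S[p, t]`` mixed by
  trial-and-DOF-specific scalars ``C[l, m, p]`` (synchronous, zero delays);
* **temporal with delays** — as temporal, but each (trial, DOF, primitive)
  carries its own activation delay ``Tau[l, m, p]``;
* **spatiotemporal** — vector-valued (time-varying) primitives ``Wt[p, m, t]``
  recruited with one scalar weight and one delay per trial;
* **space-by-time** — independent spatial (``W``) and temporal (``S``)
  primitives combined through a trial-specific weight ``C[l, p, q]`` and delay
  ``Tau[l, p, q]`` per (temporal, spatial) pair.

Every one of these is a constrained special case of the anechoic mixture

    y_r(t) = sum_u  A[r, u] * f_u(t - Tau[r, u]),

where the row index ``r`` enumerates (DOF, trial) pairs.  The ``embed_*``
operations perform that rewriting explicitly, returning the anechoic
parameters together with the index bijections that relate the two views.

Delays are circular with period ``duration_s`` (see :mod:`fada.fourier`) and
are stored in seconds in ``[-T_s/2, T_s/2)``.  Arrays are 0-based with
trial-major layout: ``r = l * M + m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fourier import circular_shift, wrap_delay

__all__ = [
    "TrialDataset",
    "TrialMeta",
    "SpatialParams",
    "TemporalParams",
    "SpatiotemporalParams",
    "SpaceByTimeParams",
    "AnechoicParams",
    "IndexMap",
    "synthesize_spatial",
    "synthesize_temporal",
    "synthesize_spatiotemporal",
    "synthesize_space_by_time",
    "synthesize_anechoic",
    "embed_spatial",
    "embed_temporal",
    "embed_spatiotemporal",
    "embed_space_by_time",
    "signals_from_dataset",
    "dataset_from_signals",
]


# ---------------------------------------------------------------------------
# types


@dataclass
class TrialDataset:
    """Observed movement data: ``L`` trials of ``M`` DOFs over ``T`` samples.

    ``data[l, m, t]`` is the value of DOF ``m`` at sample ``t`` in trial
    ``l``.  All trials share the duration ``duration_s`` and sampling grid.
    ``nonneg_domain`` marks EMG-like (rectified, non-negative) data.
    """

    data: np.ndarray
    duration_s: float
    dof_labels: list[str] | None = None
    nonneg_domain: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (L, M, T)")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if self.dof_labels is None:
            self.dof_labels = [f"dof_{m}" for m in range(self.M)]
        if len(self.dof_labels) != self.M:
            raise ValueError("dof_labels must have M entries")
        if self.nonneg_domain and np.any(self.data < 0):
            raise ValueError("nonneg_domain dataset contains negative entries")

    @property
    def L(self) -> int:
        return self.data.shape[0]

    @property
    def M(self) -> int:
        return self.data.shape[1]

    @property
    def T(self) -> int:
        return self.data.shape[2]

    @property
    def dt(self) -> float:
        return self.duration_s / self.T


@dataclass(frozen=True)
class TrialMeta:
    """Shape/sampling metadata used when synthesizing a dataset."""

    duration_s: float = 1.0
    T: int | None = None
    dof_labels: Sequence[str] | None = None


def _check_nonneg(nonneg: bool, **arrays: np.ndarray) -> None:
    if not nonneg:
        return
    for name, arr in arrays.items():
        if np.any(np.asarray(arr) < 0):
            raise ValueError(f"nonneg parameters require {name} >= 0")


@dataclass
class SpatialParams:
    """Spatial model: ``x[l, :, t] = W @ C[l, :, t]``."""

    W: np.ndarray  # (M, P) spatial primitives
    C: np.ndarray  # (L, P, T) time-varying mixing weights
    nonneg: bool = False

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.W.ndim != 2 or self.C.ndim != 3 or self.W.shape[1] != self.C.shape[1]:
            raise ValueError("W must be (M, P) and C (L, P, T) with matching P")
        _check_nonneg(self.nonneg, W=self.W, C=self.C)

    @property
    def M(self) -> int:
        return self.W.shape[0]

    @property
    def P(self) -> int:
        return self.W.shape[1]

    @property
    def L(self) -> int:
        return self.C.shape[0]

    @property
    def T(self) -> int:
        return self.C.shape[2]


@dataclass
class TemporalParams:
    """Temporal model, with (model 3) or without (model 2) delays.

    ``Tau`` identically zero encodes the synchronous model; the delayed model
    otherwise.  Delays are in seconds and unconstrained in sign.
    """

    S: np.ndarray    # (P, T) temporal primitives
    C: np.ndarray    # (L, M, P) scalar weights
    Tau: np.ndarray  # (L, M, P) delays in seconds
    nonneg: bool = False

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.Tau = np.asarray(self.Tau, dtype=float)
        if self.S.ndim != 2 or self.C.ndim != 3 or self.C.shape[2] != self.S.shape[0]:
            raise ValueError("S must be (P, T) and C (L, M, P) with matching P")
        if self.Tau.shape != self.C.shape:
            raise ValueError("Tau must match C's shape (L, M, P)")
        _check_nonneg(self.nonneg, S=self.S, C=self.C)

    @property
    def P(self) -> int:
        return self.S.shape[0]

    @property
    def L(self) -> int:
        return self.C.shape[0]

    @property
    def M(self) -> int:
        return self.C.shape[1]

    @property
    def has_delays(self) -> bool:
        return bool(np.any(self.Tau != 0))


@dataclass
class SpatiotemporalParams:
    """Time-varying primitives shared across trials, one weight/delay each."""

    Wt: np.ndarray   # (P, M, T') vector-valued primitives
    C: np.ndarray    # (L, P) scalar weights
    Tau: np.ndarray  # (L, P) delays in seconds (shared across DOFs)
    nonneg: bool = True

    def __post_init__(self) -> None:
        self.Wt = np.asarray(self.Wt, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.Tau = np.asarray(self.Tau, dtype=float)
        if self.Wt.ndim != 3 or self.C.ndim != 2 or self.Wt.shape[0] != self.C.shape[1]:
            raise ValueError("Wt must be (P, M, T') and C (L, P) with matching P")
        if self.Tau.shape != self.C.shape:
            raise ValueError("Tau must match C's shape (L, P)")
        _check_nonneg(self.nonneg, Wt=self.Wt, C=self.C)

    @property
    def P(self) -> int:
        return self.Wt.shape[0]

    @property
    def M(self) -> int:
        return self.Wt.shape[1]

    @property
    def L(self) -> int:
        return self.C.shape[0]


@dataclass
class SpaceByTimeParams:
    """Independent spatial and temporal primitives, bilinear trial weights.

    All parameters are non-negative except the delays.
    """

    W: np.ndarray    # (M, P_sp) spatial primitives
    S: np.ndarray    # (P_tp, T) temporal primitives
    C: np.ndarray    # (L, P_tp, P_sp) weights
    Tau: np.ndarray  # (L, P_tp, P_sp) delays in seconds

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.Tau = np.asarray(self.Tau, dtype=float)
        if self.W.ndim != 2 or self.S.ndim != 2 or self.C.ndim != 3:
            raise ValueError("W must be (M, P_sp), S (P_tp, T), C (L, P_tp, P_sp)")
        if self.C.shape[1] != self.S.shape[0] or self.C.shape[2] != self.W.shape[1]:
            raise ValueError("C must be (L, P_tp, P_sp) consistent with S and W")
        if self.Tau.shape != self.C.shape:
            raise ValueError("Tau must match C's shape")
        _check_nonneg(True, W=self.W, S=self.S, C=self.C)

    @property
    def M(self) -> int:
        return self.W.shape[0]

    @property
    def P_sp(self) -> int:
        return self.W.shape[1]

    @property
    def P_tp(self) -> int:
        return self.S.shape[0]

    @property
    def L(self) -> int:
        return self.C.shape[0]


@dataclass
class AnechoicParams:
    """General anechoic mixture: per-(row, source) weight and delay."""

    F: np.ndarray    # (U, T) source functions, sampled
    A: np.ndarray    # (R, U) mixing weights
    Tau: np.ndarray  # (R, U) delays in seconds
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.Tau = np.asarray(self.Tau, dtype=float)
        if self.F.ndim != 2 or self.A.ndim != 2 or self.A.shape[1] != self.F.shape[0]:
            raise ValueError("F must be (U, T) and A (R, U) with matching U")
        if self.Tau.shape != self.A.shape:
            raise ValueError("Tau must match A's shape (R, U)")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")

    @property
    def U(self) -> int:
        return self.F.shape[0]

    @property
    def R(self) -> int:
        return self.A.shape[0]

    @property
    def T(self) -> int:
        return self.F.shape[1]


@dataclass(frozen=True)
class IndexMap:
    """Bijections between model-specific indices and the anechoic (r, u).

    Rows: ``r = l * M + m`` for DOF ``m`` in trial ``l`` (trial-major).
    Sources: ``u`` enumerates a model-specific pair; ``u_first[u]`` is always
    the primitive index ``p`` and ``u_second[u]`` the companion index (trial
    ``l`` for the spatial model, DOF ``m`` for the spatiotemporal model,
    spatial primitive ``q`` for space-by-time, absent for temporal models).
    """

    M: int
    L: int
    u_first: np.ndarray
    u_second: np.ndarray | None
    second_name: str | None  # "l" | "m" | "q" | None
    second_size: int = 0

    @property
    def R(self) -> int:
        return self.M * self.L

    @property
    def U(self) -> int:
        return self.u_first.size

    def r_of(self, m: int, l: int) -> int:
        if not (0 <= m < self.M and 0 <= l < self.L):
            raise IndexError("(m, l) out of range")
        return l * self.M + m

    def m_of(self, r: int) -> int:
        return int(r % self.M)

    def l_of(self, r: int) -> int:
        return int(r // self.M)

    def u_of(self, p: int, second: int | None = None) -> int:
        if self.u_second is None:
            if second not in (None, 0):
                raise IndexError("this mapping has no second source index")
            return int(p)
        u = int(p) * self.second_size + int(second)
        if not (0 <= u < self.U) or self.u_first[u] != p or self.u_second[u] != second:
            raise IndexError("(p, second) out of range")
        return u

    def p_of(self, u: int) -> int:
        return int(self.u_first[u])

    def second_of(self, u: int) -> int | None:
        return None if self.u_second is None else int(self.u_second[u])


def _make_index_map(M: int, L: int, P: int, second_name: str | None, second_size: int) -> IndexMap:
    if second_name is None:
        return IndexMap(M, L, np.arange(P), None, None, 0)
    pp, ss = np.meshgrid(np.arange(P), np.arange(second_size), indexing="ij")
    return IndexMap(M, L, pp.ravel(), ss.ravel(), second_name, second_size)


# ---------------------------------------------------------------------------
# synthesis (forward) operators


def _resolve_T(meta: TrialMeta | None, default_T: int) -> tuple[float, int, Sequence[str] | None]:
    meta = meta or TrialMeta()
    T = meta.T if meta.T is not None else default_T
    return meta.duration_s, T, meta.dof_labels


def _check_delays(Tau: np.ndarray, duration_s: float) -> None:
    if np.any(np.abs(Tau) > duration_s):
        raise ValueError("delays exceeding the trial duration are rejected")


def synthesize_spatial(params: SpatialParams, meta: TrialMeta | None = None) -> TrialDataset:
    """Noise-free synthesis ``data[l, :, t] = sum_p W[:, p] * C[l, p, t]``."""
    duration_s, T, labels = _resolve_T(meta, params.T)
    if T != params.T:
        raise ValueError("meta.T inconsistent with C's time axis")
    data = np.einsum("mp,lpt->lmt", params.W, params.C)
    return TrialDataset(data, duration_s, list(labels) if labels else None,
                        nonneg_domain=params.nonneg)


def _delayed_sum(sources: np.ndarray, weights: np.ndarray, delays: np.ndarray,
                 duration_s: float, T: int) -> np.ndarray:
    """``out[..., t] = sum_j weights[..., j] * shift(sources[j], delays[..., j])``.

    ``sources`` is (J, T'), zero-padded to T; ``weights``/``delays`` share the
    leading shape and a trailing source axis J.  Vectorized via one rfft of
    the sources and a phase ramp per (..., j).
    """
    J, Tp = sources.shape
    if Tp < T:
        sources = np.concatenate([sources, np.zeros((J, T - Tp))], axis=1)
    elif Tp > T:
        raise ValueError("source duration exceeds the trial length")
    spec = np.fft.rfft(sources, axis=-1)  # (J, F)
    k = np.arange(spec.shape[-1])
    phase = np.exp(-2j * np.pi * np.multiply.outer(delays, k) / duration_s)  # (..., J, F)
    mixed = np.einsum("...j,jf,...jf->...f", weights, spec, phase)
    return np.fft.irfft(mixed, n=T, axis=-1)


def synthesize_temporal(params: TemporalParams, meta: TrialMeta | None = None) -> TrialDataset:
    """``data[l, m, t] = sum_p C[l, m, p] * S[p, t - Tau[l, m, p]]`` (circular)."""
    duration_s, T, labels = _resolve_T(meta, params.S.shape[1])
    if T != params.S.shape[1]:
        raise ValueError("meta.T inconsistent with S's time axis")
    _check_delays(params.Tau, duration_s)
    if not params.has_delays:
        data = np.einsum("lmp,pt->lmt", params.C, params.S)
    else:
        data = _delayed_sum(params.S, params.C, params.Tau, duration_s, T)
    return TrialDataset(data, duration_s, list(labels) if labels else None,
                        nonneg_domain=params.nonneg and not params.has_delays)


def synthesize_spatiotemporal(params: SpatiotemporalParams,
                              meta: TrialMeta | None = None) -> TrialDataset:
    """``data[l, m, t] = sum_p C[l, p] * Wt[p, m, t - Tau[l, p]]``.

    One delay per (trial, primitive), shared across all DOFs.  Primitives
    shorter than the trial are zero-padded before the circular shift.
    """
    duration_s, T, labels = _resolve_T(meta, params.Wt.shape[2])
    _check_delays(params.Tau, duration_s)
    P, M, _ = params.Wt.shape
    L = params.L
    data = np.empty((L, M, T))
    for m in range(M):
        data[:, m, :] = _delayed_sum(params.Wt[:, m, :], params.C, params.Tau, duration_s, T)
    return TrialDataset(data, duration_s, list(labels) if labels else None,
                        nonneg_domain=params.nonneg and not np.any(params.Tau != 0))


def synthesize_space_by_time(params: SpaceByTimeParams,
                             meta: TrialMeta | None = None) -> TrialDataset:
    """``data[l, m, t] = sum_{p,q} S[p, t - Tau[l, p, q]] * C[l, p, q] * W[m, q]``."""
    duration_s, T, labels = _resolve_T(meta, params.S.shape[1])
    if T != params.S.shape[1]:
        raise ValueError("meta.T inconsistent with S's time axis")
    _check_delays(params.Tau, duration_s)
    L, P_tp, P_sp = params.C.shape
    spec = np.fft.rfft(params.S, axis=-1)  # (P_tp, F)
    k = np.arange(spec.shape[-1])
    phase = np.exp(-2j * np.pi * np.multiply.outer(params.Tau, k) / duration_s)  # (L,P_tp,P_sp,F)
    mixed = np.einsum("lpq,mq,pf,lpqf->lmf", params.C, params.W, spec, phase)
    data = np.fft.irfft(mixed, n=T, axis=-1)
    return TrialDataset(data, duration_s, list(labels) if labels else None,
                        nonneg_domain=not np.any(params.Tau != 0))


def synthesize_anechoic(params: AnechoicParams, T: int | None = None) -> np.ndarray:
    """``y[r, t] = sum_u A[r, u] * F[u, t - Tau[r, u]]`` (circular shifts)."""
    T = T if T is not None else params.T
    _check_delays(params.Tau, params.duration_s)
    return _delayed_sum(params.F, params.A, params.Tau, params.duration_s, T)


def signals_from_dataset(dataset: TrialDataset) -> np.ndarray:
    """Flatten ``(L, M, T)`` trial data into anechoic rows ``r = l*M + m``."""
    return dataset.data.reshape(dataset.L * dataset.M, dataset.T)


def dataset_from_signals(y: np.ndarray, M: int, duration_s: float,
                         dof_labels: list[str] | None = None,
                         nonneg_domain: bool = False) -> TrialDataset:
    """Inverse of :func:`signals_from_dataset`."""
    R, T = y.shape
    if R % M:
        raise ValueError("row count is not a multiple of M")
    return TrialDataset(y.reshape(R // M, M, T), duration_s, dof_labels, nonneg_domain)


# ---------------------------------------------------------------------------
# Table-1 embeddings


def embed_spatial(params: SpatialParams,
                  duration_s: float = 1.0) -> tuple[AnechoicParams, IndexMap]:
    """Spatial model as an anechoic mixture with zero delays.

    Sources are the per-trial mixing time courses (``U = P * L``); weights tie
    ``A[r(m,l), u(p,l)] = W[m, p]`` within the trial and vanish across trials.
    """
    M, P, L, T = params.M, params.P, params.L, params.T
    imap = _make_index_map(M, L, P, "l", L)
    F = params.C.transpose(1, 0, 2).reshape(P * L, T)  # u = p * L + l
    A = np.zeros((M * L, P * L))
    for l in range(L):
        rows = l * M + np.arange(M)
        cols = np.arange(P) * L + l
        A[np.ix_(rows, cols)] = params.W
    Tau = np.zeros_like(A)
    return AnechoicParams(F, A, Tau, duration_s), imap


def embed_temporal(params: TemporalParams,
                   duration_s: float = 1.0) -> tuple[AnechoicParams, IndexMap]:
    """Temporal models: sources are the primitives themselves (``U = P``)."""
    M, P, L = params.M, params.P, params.L
    imap = _make_index_map(M, L, P, None, 0)
    A = params.C.reshape(L * M, P)
    Tau = params.Tau.reshape(L * M, P)
    return AnechoicParams(params.S, A, Tau, duration_s), imap


def embed_spatiotemporal(params: SpatiotemporalParams, duration_s: float = 1.0,
                         T: int | None = None) -> tuple[AnechoicParams, IndexMap]:
    """Spatiotemporal model: one source per (primitive, DOF) component.

    Weights and delays are tied across the DOFs of a primitive:
    ``A[r(m,l), u(p,m')] = C[l, p] * delta_{m,m'}`` and
    ``Tau[r(m,l), u(p,m)] = Tau[l, p]``.
    """
    P, M, Tp = params.Wt.shape
    L = params.L
    T = T if T is not None else Tp
    imap = _make_index_map(M, L, P, "m", M)
    F = params.Wt.reshape(P * M, Tp)  # u = p * M + m
    if Tp < T:
        F = np.concatenate([F, np.zeros((P * M, T - Tp))], axis=1)
    A = np.zeros((M * L, P * M))
    Tau = np.zeros_like(A)
    for l in range(L):
        for m in range(M):
            r = l * M + m
            cols = np.arange(P) * M + m
            A[r, cols] = params.C[l]
            Tau[r, cols] = params.Tau[l]
    return AnechoicParams(F, A, Tau, duration_s), imap


def embed_space_by_time(params: SpaceByTimeParams,
                        duration_s: float = 1.0) -> tuple[AnechoicParams, IndexMap]:
    """Space-by-time model: sources tied by temporal primitive, bilinear weights.

    ``F[u(p,q)] = S[p]``; ``A[r(m,l), u(p,q)] = C[l, p, q] * W[m, q]``;
    ``Tau[r(m,l), u(p,q)] = Tau[l, p, q]``.
    """
    M, P_sp, P_tp, L = params.M, params.P_sp, params.P_tp, params.L
    imap = _make_index_map(M, L, P_tp, "q", P_sp)
    F = np.repeat(params.S, P_sp, axis=0)  # u = p * P_sp + q
    A = np.einsum("lpq,mq->lmpq", params.C, params.W).reshape(L * M, P_tp * P_sp)
    Tau = np.broadcast_to(params.Tau[:, None, :, :], (L, M, P_tp, P_sp)).reshape(
        L * M, P_tp * P_sp).copy()
    return AnechoicParams(F, A, Tau, duration_s), imap
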