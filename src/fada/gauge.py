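"""Canonical gauge fixing for decomposition parameters.

Blind source separation leaves permutation, scale, and (for unconstrained
models) sign of each component undetermined.  These helpers map any
parameter set to a canonical representative so that ground truth and
estimates can be compared directly:

* primitives are normalized (unit L2 norm for spatial vectors, unit RMS for
  temporal/spatiotemporal waveforms), with the scale absorbed into the
  mixing weights;
* for unconstrained models the sign is fixed so the largest-magnitude
  primitive entry is positive;
* components are ordered by the total energy of their weighted contribution.
"""

from __future__ import annotations

import numpy as np

from .models import (SpaceByTimeParams, SpatialParams, SpatiotemporalParams,
                     TemporalParams)

__all__ = ["canonicalize"]


def _rms(x: np.ndarray, axis=None) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def canonicalize(params):
    """Return a gauge-fixed copy of any ``*Params`` object."""
    if isinstance(params, SpatialParams):
        return _canon_spatial(params)
    if isinstance(params, TemporalParams):
        return _canon_temporal(params)
    if isinstance(params, SpatiotemporalParams):
        return _canon_spatiotemporal(params)
    if isinstance(params, SpaceByTimeParams):
        return _canon_space_by_time(params)
    raise TypeError(f"cannot canonicalize {type(params).__name__}")


def _canon_spatial(p: SpatialParams) -> SpatialParams:
    W = p.W.copy()
    C = p.C.copy()
    norms = np.linalg.norm(W, axis=0)
    for j in range(p.P):
        if norms[j] > 1e-12:
            W[:, j] /= norms[j]
            C[:, j, :] *= norms[j]
        if not p.nonneg and W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] *= -1
            C[:, j, :] *= -1
    order = np.argsort(-np.sum(C**2, axis=(0, 2)), kind="stable")
    return SpatialParams(W[:, order], C[:, order, :], p.nonneg)


def _canon_temporal(p: TemporalParams) -> TemporalParams:
    S = p.S.copy()
    C = p.C.copy()
    Tau = p.Tau.copy()
    for j in range(p.P):
        r = _rms(S[j])
        if r > 1e-12:
            S[j] /= r
            C[:, :, j] *= r
        if not p.nonneg and S[j, np.argmax(np.abs(S[j]))] < 0:
            S[j] *= -1
            C[:, :, j] *= -1
    order = np.argsort(-np.sum(C**2, axis=(0, 1)), kind="stable")
    return TemporalParams(S[order], C[:, :, order], Tau[:, :, order], p.nonneg)


def _canon_spatiotemporal(p: SpatiotemporalParams) -> SpatiotemporalParams:
    Wt = p.Wt.copy()
    C = p.C.copy()
    Tau = p.Tau.copy()
    for j in range(p.P):
        r = _rms(Wt[j])
        if r > 1e-12:
            Wt[j] /= r
            C[:, j] *= r
        if not p.nonneg:
            flat = Wt[j].ravel()
            if flat[np.argmax(np.abs(flat))] < 0:
                Wt[j] *= -1
                C[:, j] *= -1
    order = np.argsort(-np.sum(C**2, axis=0), kind="stable")
    return SpatiotemporalParams(Wt[order], C[:, order], Tau[:, order], p.nonneg)


def _canon_space_by_time(p: SpaceByTimeParams) -> SpaceByTimeParams:
    W = p.W.copy()
    S = p.S.copy()
    C = p.C.copy()
    Tau = p.Tau.copy()
    for j in range(p.P_tp):
        r = _rms(S[j])
        if r > 1e-12:
            S[j] /= r
            C[:, j, :] *= r
    for q in range(p.P_sp):
        n = np.linalg.norm(W[:, q])
        if n > 1e-12:
            W[:, q] /= n
            C[:, :, q] *= n
    order_tp = np.argsort(-np.sum(C**2, axis=(0, 2)), kind="stable")
    order_sp = np.argsort(-np.sum(C**2, axis=(0, 1)), kind="stable")
    return SpaceByTimeParams(W[:, order_sp], S[order_tp],
                             C[np.ix_(range(p.L), order_tp, order_sp)],
                             Tau[np.ix_(range(p.L), order_tp, order_sp)])
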