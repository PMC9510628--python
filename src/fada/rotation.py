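"""Rotation fixing for synchronous (zero-delay) decompositions.

A least-squares factorization ``X = W C`` of a synchronous mixture is only
determined up to an invertible mixing of the components.  The demixing
model, however, assumes the latent sources are mutually uncorrelated at
*every* pair of time points, not just simultaneously.  For wide-sense
stationary-like sources with distinct autocorrelation structure this pins
the mixing: in the true basis every time-lagged covariance matrix of the
sources is diagonal.

:func:`unmixing_matrix` therefore whitens the estimated source waveforms
and jointly diagonalizes a family of circular lagged covariance matrices
(Jacobi angle sweeps, as in classical second-order blind identification).
Applying the returned matrix to the estimated sources — and its inverse to
the weights — leaves the reconstruction untouched while rotating the
components toward the maximally uncorrelated solution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["joint_diagonalize", "unmixing_matrix"]


def joint_diagonalize(mats: np.ndarray, tol: float = 1e-12,
                      max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal ``V`` approximately diagonalizing all symmetric ``mats``.

    ``mats`` has shape (n_mats, P, P).  Jacobi rotations over index pairs
    maximize the sum of squared diagonals (Cardoso–Souloumiac angle
    formula).  Returns ``V`` such that ``V.T @ M @ V`` is nearly diagonal
    for every ``M``.
    """
    M = np.array(mats, dtype=float)
    n_m, P, _ = M.shape
    V = np.eye(P)
    for _ in range(max_sweeps):
        changed = False
        for p in range(P - 1):
            for q in range(p + 1, P):
                h1 = M[:, p, p] - M[:, q, q]
                h2 = M[:, p, q] + M[:, q, p]
                G11 = np.sum(h1 * h1)
                G12 = np.sum(h1 * h2)
                G22 = np.sum(h2 * h2)
                # principal eigenvector of [[G11, G12], [G12, G22]]
                diff = G11 - G22
                r = np.hypot(diff, 2 * G12)
                if r <= 0:
                    continue
                x = diff + r  # proportional to (eigvec_x) with eig >= 0
                y = 2 * G12
                nrm = np.hypot(x, y)
                if nrm < 1e-300:
                    continue
                cos2t = x / nrm
                c = np.sqrt((1 + cos2t) / 2)
                s = y / nrm / (2 * c) if c > 0 else 0.0
                if abs(s) < tol:
                    continue
                changed = True
                # apply Givens rotation to all matrices and to V
                Mp = M[:, :, p].copy()
                Mq = M[:, :, q].copy()
                M[:, :, p] = c * Mp + s * Mq
                M[:, :, q] = -s * Mp + c * Mq
                Mp = M[:, p, :].copy()
                Mq = M[:, q, :].copy()
                M[:, p, :] = c * Mp + s * Mq
                M[:, q, :] = -s * Mp + c * Mq
                Vp = V[:, p].copy()
                Vq = V[:, q].copy()
                V[:, p] = c * Vp + s * Vq
                V[:, q] = -s * Vp + c * Vq
        if not changed:
            break
    return V


def _cumulant_matrices(Z: np.ndarray) -> np.ndarray:
    """Fourth-order cumulant matrices of whitened data (JADE parametrization).

    ``Z`` is (P, n) with identity covariance.  Returns the P(P+1)/2 matrices
    ``Q_ij = E[z_i z_j z z'] - delta_ij I - e_i e_j' - e_j e_i'``, whose
    joint diagonalizer separates independent non-Gaussian components.
    """
    P, n = Z.shape
    C4 = np.einsum("it,jt,at,bt->ijab", Z, Z, Z, Z, optimize=True) / n
    eye = np.eye(P)
    mats = []
    for i in range(P):
        for j in range(i, P):
            Q = C4[i, j] - (eye if i == j else 0) \
                - np.outer(eye[i], eye[j]) - np.outer(eye[j], eye[i])
            mats.append((Q + Q.T) / 2)
    return np.stack(mats)


def unmixing_matrix(sources: np.ndarray, T: int | None = None,
                    use_cumulants: bool = True) -> np.ndarray:
    """Matrix ``G`` rotating estimated sources to the maximally independent basis.

    Two families of statistics are jointly diagonalized after whitening:

    * per-frequency spectral covariances averaged over trial segments — the
      sample analogue of the model's ``E{nu_ik conj(nu_jk)} = 0`` for
      ``i != j``.  By Parseval this covers the cross-covariance at *all*
      circular lags (only the real parts matter under real rotations);
    * fourth-order cumulant matrices (classical cumulant-based separation) —
      smooth oscillatory waveforms have strongly sub-Gaussian marginals, so
      these carry substantial rotation information even when the spectra
      overlap.

    Parameters
    ----------
    sources : array (P, n) of waveform samples.  When the waveforms are a
        concatenation of equal-length trial segments, pass the segment
        length ``T`` (each segment contributes its own spectral matrices).

    Returns
    -------
    G : (P, P) such that ``G @ sources`` is maximally uncorrelated/
        independent under the combined criterion, with unit power per
        component.
    """
    S = np.asarray(sources, dtype=float)
    P, n = S.shape
    T = T if T is not None else n
    if n % T:
        raise ValueError("source length must be a multiple of the segment length")
    Sc = S - S.mean(axis=1, keepdims=True)
    segs = Sc.reshape(P, -1, T)
    nu = np.fft.rfft(segs, axis=-1) / T  # (P, n_seg, K_full+1)
    weights = np.full(nu.shape[-1], 2.0)
    weights[0] = 1.0
    if T % 2 == 0:
        weights[-1] = 1.0
    mats = np.einsum("isk,jsk,k->kij", nu, np.conj(nu), weights).real \
        / nu.shape[1]
    power = np.trace(mats, axis1=1, axis2=2)
    keep = power > 1e-12 * max(power.max(), 1e-300)
    mats = mats[keep]
    R0 = mats.sum(axis=0)
    evals, evecs = np.linalg.eigh(R0)
    evals = np.clip(evals, 1e-12 * max(evals.max(), 1e-300), None)
    white = (evecs / np.sqrt(evals)) @ evecs.T  # R0^{-1/2}
    mats_w = np.einsum("ab,kbc,cd->kad", white, mats, white)
    mats_w = mats_w / np.linalg.norm(mats_w, axis=(1, 2)).sum()
    if use_cumulants:
        Z = white @ Sc
        Z = Z / np.sqrt(np.mean(Z**2, axis=1, keepdims=True))
        cums = _cumulant_matrices(Z)
        cums = cums / max(np.linalg.norm(cums, axis=(1, 2)).sum(), 1e-30)
        mats_w = np.concatenate([mats_w, cums])
    V = joint_diagonalize(mats_w)
    return V.T @ white
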