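"""Iterative Fourier-domain estimator for the anechoic mixture model.

The estimator works entirely on the truncated Fourier coefficients
``c_rk`` of the observed rows (``k = 0..K``, see :mod:`fada.fourier`):

1.  **Magnitude demixing** — the delay-blind identity
    ``|c_rk|^2 = sum_u |a_ru|^2 |nu_uk|^2`` is factorized by non-negative
    matrix factorization (or non-negative ICA) to initialize the source
    magnitude spectra and weight magnitudes.
2.  **Phase estimation** — with magnitudes anchored, the source phases are
    found by per-frequency coordinate descent on the Frobenius objective
    ``||C - Z||_F^2`` with ``Z_rk = sum_u a_ru e^{-2 pi i k tau_ru / T_s}
    |nu_uk| e^{i phi_uk}``.
3.  **Weight/delay refitting** — per signal (or per tied group), delays are
    found by maximizing the circular cross-correlation between the partial
    residual and each source, and weights are refit by (non-negative) least
    squares.

After the anchored warm-up, the outer loop generalizes step 2 to a full
per-frequency complex least-squares refresh of the source coefficients
(the exact minimizer of the same objective over magnitudes and phases
jointly), alternated with step 3, until the relative objective change falls
below ``tol``.

Constraints (zero delays, non-negativity, weight/delay equality ties,
structural zeros, and the bilinear space-by-time weight structure) are
enforced natively inside the update steps; :func:`apply_constraints`
additionally provides the standalone projection of an unconstrained fit
onto a constraint set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.optimize
from sklearn.decomposition import NMF

from .fourier import (FourierSeries, analyze, choose_num_harmonics,
                      delay_phase_factors, reconstruct, wrap_delay)
from .models import AnechoicParams, IndexMap, TrialDataset, signals_from_dataset

__all__ = [
    "ConstraintSpec",
    "BilinearSpec",
    "FitOptions",
    "AnechoicFit",
    "estimate_magnitudes",
    "estimate_phases",
    "estimate_weights_delays",
    "apply_constraints",
    "fit_anechoic",
]


# ---------------------------------------------------------------------------
# specification types


@dataclass(frozen=True)
class BilinearSpec:
    """Bilinear weight structure ``A[r(m,l), u(p,q)] = C[l,p,q] * W[m,q]``.

    Implies that the anechoic sources are tied by temporal primitive:
    ``F[u(p,q)] = S[p]``.
    """

    P_tp: int
    P_sp: int
    M: int
    L: int


@dataclass
class ConstraintSpec:
    """Equality/sign constraints that specialize the anechoic model.

    ``weight_ties`` / ``delay_ties`` are lists of groups; each group is a
    sequence of ``(r, u)`` cells forced to share one value.  ``weight_zeros``
    is a set of cells forced to zero (or a boolean (R, U) mask).  Tie groups
    must be disjoint within each family.
    """

    zero_delays: bool = False
    nonneg_weights: bool = False
    nonneg_sources: bool = False
    weight_ties: list = field(default_factory=list)
    delay_ties: list = field(default_factory=list)
    weight_zeros: object = None  # set of (r, u) or boolean mask
    bilinear: BilinearSpec | None = None

    def zero_mask(self, R: int, U: int) -> np.ndarray:
        mask = np.zeros((R, U), dtype=bool)
        if self.weight_zeros is None:
            return mask
        wz = self.weight_zeros
        if isinstance(wz, np.ndarray):
            if wz.shape != (R, U):
                raise ValueError("weight_zeros mask has wrong shape")
            return wz.astype(bool)
        for (r, u) in wz:
            mask[r, u] = True
        return mask

    def validate(self, R: int, U: int) -> None:
        for family in (self.weight_ties, self.delay_ties):
            seen: set[tuple[int, int]] = set()
            for group in family:
                for cell in group:
                    cell = (int(cell[0]), int(cell[1]))
                    if cell in seen:
                        raise ValueError(f"conflicting tie groups share cell {cell}")
                    if not (0 <= cell[0] < R and 0 <= cell[1] < U):
                        raise ValueError(f"tie cell {cell} out of range")
                    seen.add(cell)


@dataclass
class FitOptions:
    """Loop control and solver choices for :func:`fit_anechoic`."""

    K: int | None = None
    max_outer_iters: int = 200
    inner_iters: int = 2          # delay/weight alternation sweeps per outer iteration
    tol: float = 1e-5             # relative objective change for convergence
    n_restarts: int = 5
    seed: int = 0
    magnitude_solver: str = "nmf"  # "nmf" (multiplicative updates) or "nn_ica"
    delay_grid_resolution_samples: float = 1.0
    refine_delays: bool = True    # parabolic sub-sample refinement of the peak
    warmup_iters: int = 3         # anchored (fixed-magnitude) iterations
    restart_r2_stop: float = 0.999  # stop restarting once this r2 is reached
    initial_state: dict | None = None  # optional {nu, A, Tau} used by restart 0

    def __post_init__(self) -> None:
        if not (self.tol > 0):
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.magnitude_solver not in ("nmf", "nn_ica"):
            raise ValueError("magnitude_solver must be 'nmf' or 'nn_ica'")


@dataclass
class AnechoicFit:
    """Result of :func:`fit_anechoic`."""

    params: AnechoicParams
    nu: np.ndarray          # complex (U, K+1) source Fourier coefficients
    r2: float
    trace: np.ndarray       # per-outer-iteration objective (non-increasing)
    converged: bool
    seed_used: int
    K: int
    options: FitOptions | None = None
    factors: dict | None = None  # bilinear (space-by-time) factors, when used

    @property
    def source_series(self) -> list[FourierSeries]:
        return [FourierSeries(self.nu[u], self.params.duration_s)
                for u in range(self.nu.shape[0])]


# ---------------------------------------------------------------------------
# small shared helpers


def _analyze_rows(Y: np.ndarray, K: int) -> np.ndarray:
    """First K+1 Fourier coefficients of each row (``c = rfft / T``)."""
    T = Y.shape[-1]
    return np.fft.rfft(Y, axis=-1)[:, : K + 1] / T


def _rows_to_time(Z: np.ndarray, T: int) -> np.ndarray:
    """Band-limited reconstruction of coefficient rows (inverse of analyze)."""
    spec = np.zeros(Z.shape[:-1] + (T // 2 + 1,), dtype=complex)
    spec[..., : Z.shape[-1]] = Z * T
    return np.fft.irfft(spec, n=T, axis=-1)


def _k_weights(K: int) -> np.ndarray:
    w = np.full(K + 1, 2.0)
    w[0] = 1.0
    return w


def _source_rms(nu: np.ndarray) -> np.ndarray:
    """Time-domain RMS of each source from its coefficients (Parseval)."""
    w = _k_weights(nu.shape[1] - 1)
    return np.sqrt(np.sum(w * np.abs(nu) ** 2, axis=1))


def _objective(C: np.ndarray, Z: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * np.abs(C - Z) ** 2))


def _mix(nu: np.ndarray, A: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """``Z_rk = sum_u A[r,u] nu[u,k] phases[r,u,k]``."""
    return np.einsum("ru,uk,ruk->rk", A, nu, phases)


def _explained_variance(data: np.ndarray, recon: np.ndarray) -> float:
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    ss_res = float(np.sum((data - recon) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _nnls_from_normal(H: np.ndarray, b: np.ndarray) -> np.ndarray:
    """NNLS solution from normal equations via a Cholesky square root."""
    n = H.shape[0]
    Hr = H + 1e-12 * np.trace(H) / max(n, 1) * np.eye(n)
    try:
        Lc = np.linalg.cholesky(Hr)
    except np.linalg.LinAlgError:
        w_eig, V = np.linalg.eigh(Hr)
        w_eig = np.clip(w_eig, 0, None)
        Lc = V * np.sqrt(w_eig)
        sol, _ = scipy.optimize.nnls(Lc.T, np.linalg.pinv(Lc) @ b)
        return sol
    rhs = scipy.linalg.solve_triangular(Lc, b, lower=True)
    sol, _ = scipy.optimize.nnls(Lc.T, rhs)
    return sol


# ---------------------------------------------------------------------------
# spec operations


def _batched_nnls_normal(H: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact batched NNLS from normal equations for small U.

    ``H`` is (n, U, U) positive definite, ``b`` is (n, U).  For U <= 6 all
    2^U - 1 support sets are enumerated and solved in batch; the feasible
    support with the lowest quadratic cost wins (this is exact for strictly
    convex problems).  Larger U falls back to a per-row solver.
    """
    n, U = b.shape
    if U > 6:
        return np.stack([_nnls_from_normal(H[i], b[i]) for i in range(n)])
    best_x = np.zeros((n, U))
    best_cost = np.zeros(n)  # cost of the empty support
    for mask in range(1, 2**U):
        sup = [u for u in range(U) if mask >> u & 1]
        Hs = H[:, sup][:, :, sup]
        bs = b[:, sup]
        try:
            xs = np.linalg.solve(Hs, bs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            continue
        feasible = np.all(xs >= -1e-12, axis=1)
        cost = -0.5 * np.einsum("ni,ni->n", xs, bs)  # 0.5 x'Hx - b'x at optimum
        upd = feasible & (cost < best_cost - 1e-15 * np.abs(best_cost))
        if np.any(upd):
            x_full = np.zeros((n, U))
            x_full[:, sup] = np.clip(xs, 0.0, None)
            best_x[upd] = x_full[upd]
            best_cost[upd] = cost[upd]
    return best_x


def estimate_magnitudes(sq_mags: np.ndarray, U: int, solver: str = "nmf",
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Factor squared magnitudes ``|c_rk|^2 ~= |A|^2 @ |nu|^2``.

    Returns ``(Asq, Nsq)`` with ``Asq`` of shape (R, U) and ``Nsq`` of shape
    (U, K+1), both non-negative, scale-normalized so that each row of ``Nsq``
    sums to 1 (scale absorbed into ``Asq``).

    ``solver='nmf'`` uses Lee–Seung multiplicative updates; ``solver='nn_ica'``
    uses a Plumbley-style non-negative ICA (whitening plus an orthogonal
    rotation found by alternating projection).
    """
    X = np.asarray(sq_mags, dtype=float)
    if X.ndim != 2:
        raise ValueError("sq_mags must be 2-D (R, K+1)")
    if np.any(X < 0):
        raise ValueError("squared magnitudes must be non-negative")
    if U < 1:
        raise ValueError("U must be >= 1")
    R, Kp1 = X.shape
    if U > min(R, Kp1):
        warnings.warn("U exceeds min(R, K+1): the magnitude system is under-determined")
    if not np.any(X > 0):
        return np.zeros((R, U)), np.zeros((U, Kp1))

    if U == 1:
        # rank-1 non-negative factorization is exact: Perron vectors of X
        Us, s, Vt = np.linalg.svd(X, full_matrices=False)
        a = np.abs(Us[:, 0]) * s[0]
        h = np.abs(Vt[0])
        Asq, Nsq = a[:, None], h[None, :]
    elif solver == "nmf":
        candidates = []
        for init in ("nndsvda", "random"):
            try:
                with warnings.catch_warnings():
                    from sklearn.exceptions import ConvergenceWarning
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model = NMF(n_components=U, init=init, solver="mu",
                                max_iter=800, tol=1e-8,
                                random_state=seed % (2**31))
                    W = model.fit_transform(X)
                    H = model.components_
                candidates.append((W, H))
            except ValueError:
                continue
        spa = _spa_factorization(X, U)
        if spa is not None:
            candidates.append(spa)
        best = None
        for W, H in candidates:
            err = np.linalg.norm(X - W @ H)
            if best is None or err < best[0]:
                best = (err, W, H)
        _, Asq, Nsq = best
    elif solver == "nn_ica":
        Asq, Nsq = _nonneg_ica(X, U, seed)
    else:
        raise ValueError(f"unknown magnitude solver {solver!r}")

    scale = Nsq.sum(axis=1)
    live = scale > 0
    Nsq = np.where(live[:, None], Nsq / np.where(live, scale, 1.0)[:, None], 0.0)
    Asq = Asq * np.where(live, scale, 0.0)[None, :]
    return Asq, Nsq


def _spa_factorization(X: np.ndarray, U: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Separable-NMF candidate via successive projection on the columns.

    When each source owns at least one frequency bin (near-disjoint spectral
    supports) the corresponding column of X is a pure rescaled copy of that
    source's weight column; successive projection finds those anchors
    exactly, where multiplicative updates may settle in a mixed optimum.
    """
    R, n = X.shape
    live = np.nonzero(X.sum(axis=0) > 0)[0]
    if live.size < U:
        return None
    V = X[:, live].astype(float)
    resid = V.copy()
    anchors = []
    for _ in range(U):
        norms = np.linalg.norm(resid, axis=0)
        j = int(np.argmax(norms))
        if norms[j] <= 1e-12:
            return None
        anchors.append(live[j])
        a = resid[:, j] / norms[j]
        resid = resid - np.outer(a, a @ resid)
    W = X[:, anchors]
    G = W.T @ W + 1e-12 * np.eye(U)
    H = np.stack([_nnls_from_normal(G, W.T @ X[:, j]) for j in range(n)]).T
    # one alternating refinement of the anchors' scales
    G2 = H @ H.T + 1e-12 * np.eye(U)
    W = np.clip(np.linalg.solve(G2, H @ X.T).T, 0.0, None)
    return W, H


def _nonneg_ica(X: np.ndarray, U: int, seed: int, n_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Whiten rows of X and rotate so the recovered factors are non-negative."""
    Us, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = min(U, int(np.sum(s > 1e-12 * s[0])))
    Y = Us[:, :U] * s[:U]  # (R, U) scores; columns may be rank-deficient
    rng = np.random.default_rng(seed % (2**31))
    Q = np.linalg.qr(rng.standard_normal((U, U)))[0]
    for _ in range(n_iter):
        W = np.clip(Y @ Q.T, 0, None)
        P, _, Rt = np.linalg.svd(W.T @ Y, full_matrices=False)
        Q_new = P @ Rt
        if np.linalg.norm(Q_new - Q) < 1e-12:
            Q = Q_new
            break
        Q = Q_new
    Wfac = np.clip(Y @ Q.T, 0, None)
    # non-negative loadings by least squares given the recovered factors,
    # then a short alternating refinement to a proper constrained optimum
    H = np.zeros((U, X.shape[1]))
    for _ in range(40):
        G = Wfac.T @ Wfac + 1e-12 * np.eye(U)
        for j in range(X.shape[1]):
            H[:, j] = _nnls_from_normal(G, Wfac.T @ X[:, j])
        G2 = H @ H.T + 1e-12 * np.eye(U)
        for i in range(X.shape[0]):
            Wfac[i] = _nnls_from_normal(G2, H @ X[i])
    _ = rank
    return Wfac, H


def estimate_phases(C: np.ndarray, A: np.ndarray, TauRU: np.ndarray,
                    nu_mags: np.ndarray, inner_opts: dict | None = None,
                    duration_s: float = 1.0,
                    phi0: np.ndarray | None = None) -> np.ndarray:
    """Source phases minimizing ``||C - Z(Phi)||_F^2`` with magnitudes fixed.

    The objective decouples over frequencies for fixed weights and delays;
    each ``phi[:, k]`` is optimized by coordinate descent with the closed-form
    single-source update, warm-started from ``phi0`` (zeros by default).  The
    DC phase is restricted to {0, pi} so the sources stay real.
    """
    C = np.asarray(C, dtype=complex)
    A = np.asarray(A, dtype=float)
    TauRU = np.asarray(TauRU, dtype=float)
    nu_mags = np.asarray(nu_mags, dtype=float)
    for arr in (C, A, TauRU, nu_mags):
        if not np.all(np.isfinite(arr.view(float))):
            raise ValueError("non-finite inputs rejected")
    opts = {"n_sweeps": 30, "tol": 1e-12}
    opts.update(inner_opts or {})
    R, Kp1 = C.shape
    U = A.shape[1]
    phi = np.zeros((U, Kp1)) if phi0 is None else np.array(phi0, dtype=float)
    phases = delay_phase_factors(Kp1 - 1, TauRU, duration_s)  # (R, U, K+1)
    M = A[:, :, None] * phases * nu_mags[None, :, :]  # (R, U, K+1)
    # the objective decouples over k; the closed-form coordinate update for
    # each source is applied to all frequencies at once
    e = np.exp(1j * phi)  # (U, K+1)
    Z = np.einsum("ruk,uk->rk", M, e)
    prev = np.inf
    for _ in range(opts["n_sweeps"]):
        for u in range(U):
            resid_u = C - Z + M[:, u, :] * e[u][None, :]
            g = np.sum(np.conj(M[:, u, :]) * resid_u, axis=0)  # (K+1,)
            mag = np.abs(g)
            new = np.where(mag > 0, g / np.where(mag > 0, mag, 1.0), 1.0 + 0j)
            new[0] = 1.0 if g[0].real >= 0 else -1.0
            Z = Z + M[:, u, :] * (new - e[u])[None, :]
            e[u] = new
        obj = float(np.sum(np.abs(C - Z) ** 2))
        if prev - obj < opts["tol"] * max(prev, 1e-30):
            break
        prev = obj
    return np.angle(e)


def estimate_weights_delays(y_r: np.ndarray, sources: list[FourierSeries],
                            constraints: ConstraintSpec | None = None,
                            grid_resolution: float = 1.0,
                            n_sweeps: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Weights and delays of a single signal given fixed sources.

    Coordinate descent over sources: for each source the delay maximizing the
    circular cross-correlation with the partial residual is selected on a
    grid (``grid_resolution`` in samples), then all weights are refit jointly
    by (non-negative) least squares.  Zero-energy sources get weight 0 and
    delay 0 by tie-break.
    """
    constraints = constraints or ConstraintSpec()
    y = np.asarray(y_r, dtype=float)
    T = y.size
    U = len(sources)
    duration_s = sources[0].duration_s
    K = max(s.K for s in sources)
    nu = np.zeros((U, K + 1), dtype=complex)
    for u, s in enumerate(sources):
        nu[u, : s.K + 1] = s.coeffs
    c = _analyze_rows(y[None, :], K)[0]
    w = _k_weights(K)
    energies = np.sum(w * np.abs(nu) ** 2, axis=1)
    live = energies > 1e-15 * max(energies.max(), 1e-30)
    a = np.zeros(U)
    tau = np.zeros(U)
    if not np.any(live) or not np.any(np.abs(y) > 0):
        return a, tau
    n_grid = max(2, int(round(T / grid_resolution)))
    kvec = np.arange(K + 1)
    prev_cost = np.inf
    for _ in range(n_sweeps):
        phases = delay_phase_factors(K, tau, duration_s)  # (U, K+1)
        z = np.einsum("u,uk,uk->k", a, nu, phases)
        if not constraints.zero_delays:
            for u in np.nonzero(live)[0]:
                resid = c - z + a[u] * nu[u] * phases[u]
                g = resid * np.conj(nu[u])
                score = np.fft.irfft(g, n=n_grid) * n_grid
                idx = int(np.argmax(score if constraints.nonneg_weights else np.abs(score)))
                tau[u] = wrap_delay(idx * duration_s / n_grid, duration_s)
                phases[u] = np.exp(-2j * np.pi * kvec * tau[u] / duration_s)
                z = c - resid + a[u] * nu[u] * phases[u]
        # joint weight refit
        D = (nu * phases).T  # (K+1, U)
        H = np.einsum("ku,kv,k->uv", np.conj(D), D, w).real
        b = np.einsum("ku,k,k->u", np.conj(D), c, w).real
        H = H[np.ix_(live, live)]
        bl = b[live]
        if constraints.nonneg_weights:
            sol = _nnls_from_normal(H, bl)
        else:
            sol = np.linalg.lstsq(H, bl, rcond=None)[0]
        a[:] = 0.0
        a[live] = sol
        cost = _objective(c[None, :], np.einsum(
            "u,uk,uk->k", a, nu, delay_phase_factors(K, tau, duration_s))[None, :], w)
        if prev_cost - cost < 1e-12 * max(prev_cost, 1e-30):
            break
        prev_cost = cost
    tau[~live] = 0.0
    tau[a == 0] = 0.0
    return a, tau


def apply_constraints(fit: AnechoicFit, spec: ConstraintSpec) -> AnechoicFit:
    """Project a fit onto a constraint set.

    Zero delays are set exactly; tie groups are replaced by their
    least-squares-optimal common value (weights: source-energy-weighted mean;
    delays: circular mean); structural zeros and sign constraints are
    enforced by clipping; non-negative sources are clipped in the time domain
    and re-analyzed to K harmonics; the bilinear structure is restored by an
    alternating non-negative refactorization of the weight matrix.
    """
    params = fit.params
    A = params.A.copy()
    Tau = params.Tau.copy()
    nu = fit.nu.copy()
    R, U = A.shape
    spec.validate(R, U)
    duration_s = params.duration_s
    T = params.T
    w = _k_weights(fit.K)
    energies = np.sum(w * np.abs(nu) ** 2, axis=1)

    if spec.zero_delays:
        Tau[:] = 0.0
    for group in spec.delay_ties:
        cells = np.asarray(group, dtype=int)
        angles = 2 * np.pi * Tau[cells[:, 0], cells[:, 1]] / duration_s
        mean = np.angle(np.mean(np.exp(1j * angles)))
        Tau[cells[:, 0], cells[:, 1]] = wrap_delay(mean * duration_s / (2 * np.pi), duration_s)
    for group in spec.weight_ties:
        cells = np.asarray(group, dtype=int)
        e = energies[cells[:, 1]]
        vals = A[cells[:, 0], cells[:, 1]]
        rep = float(np.sum(e * vals) / np.sum(e)) if np.sum(e) > 0 else float(np.mean(vals))
        A[cells[:, 0], cells[:, 1]] = rep
    mask = spec.zero_mask(R, U)
    A[mask] = 0.0
    if spec.nonneg_weights:
        A = np.clip(A, 0, None)
    if spec.nonneg_sources:
        F = _rows_to_time(nu, T)
        nu = _analyze_rows(np.clip(F, 0, None), fit.K)
    factors = fit.factors
    if spec.bilinear is not None:
        C_fac, W_fac = _bilinear_refactor(A, spec.bilinear)
        A = np.einsum("lpq,mq->lmpq", C_fac, W_fac).reshape(A.shape)
        factors = dict(factors or {})
        factors.update({"C": C_fac, "W": W_fac})
    F = _rows_to_time(nu, T)
    new_params = AnechoicParams(F, A, wrap_delay(Tau, duration_s), duration_s)
    return replace(fit, params=new_params, nu=nu, factors=factors)


def _bilinear_refactor(A: np.ndarray, bl: BilinearSpec, n_iter: int = 50
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Alternating NNLS factorization ``A[r(m,l), u(p,q)] ~= C[l,p,q] W[m,q]``."""
    M, L, P_tp, P_sp = bl.M, bl.L, bl.P_tp, bl.P_sp
    A4 = np.clip(A.reshape(L, M, P_tp, P_sp), 0, None)
    W = np.sqrt(np.clip(A4.mean(axis=(0, 2)), 0, None)) + 1e-6  # (M, P_sp)
    C = np.ones((L, P_tp, P_sp))
    for _ in range(n_iter):
        denom = np.sum(W**2, axis=0)  # (P_sp,)
        C = np.clip(np.einsum("lmpq,mq->lpq", A4, W) / np.maximum(denom, 1e-30), 0, None)
        denom_w = np.sum(C**2, axis=(0, 1))  # (P_sp,)
        W = np.clip(np.einsum("lmpq,lpq->mq", A4, C) / np.maximum(denom_w, 1e-30), 0, None)
    return C, W


# ---------------------------------------------------------------------------
# compiled constraint structure


class _Structure:
    """Constraint bookkeeping for the update steps."""

    def __init__(self, R: int, U: int, spec: ConstraintSpec):
        self.R, self.U = R, U
        self.spec = spec
        spec.validate(R, U)
        self.active = ~spec.zero_mask(R, U)
        # --- weight groups: ties first, singletons for the rest
        tied = np.zeros((R, U), dtype=bool)
        self.tie_groups: list[np.ndarray] = []
        for group in spec.weight_ties:
            cells = np.asarray(group, dtype=int)
            if np.any(~self.active[cells[:, 0], cells[:, 1]]):
                raise ValueError("tie group includes a structurally zero cell")
            tied[cells[:, 0], cells[:, 1]] = True
            self.tie_groups.append(cells)
        self.untied = self.active & ~tied
        # --- row components: rows linked by multi-row tie groups
        parent = np.arange(R)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for cells in self.tie_groups:
            rows = np.unique(cells[:, 0])
            for r in rows[1:]:
                ra, rb = find(rows[0]), find(r)
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(r) for r in range(R)])
        self.row_simple = np.ones(R, dtype=bool)
        comp_rows: dict[int, list[int]] = {}
        for r in range(R):
            comp_rows.setdefault(roots[r], []).append(r)
        self.complex_components: list[dict] = []
        for root, rows in comp_rows.items():
            rows_arr = np.asarray(rows)
            has_tie = any(np.isin(cells[:, 0], rows_arr).any() for cells in self.tie_groups)
            all_active = bool(np.all(self.active[rows_arr]))
            if len(rows) == 1 and not has_tie and all_active:
                continue  # simple row, handled in the batched path
            self.row_simple[rows_arr] = False
            groups = [cells for cells in self.tie_groups
                      if np.isin(cells[:, 0], rows_arr).any()]
            single_cells = np.argwhere(self.untied[rows_arr][:, :])
            singles = [np.array([[rows_arr[i], u]]) for i, u in single_cells]
            self.complex_components.append({
                "rows": rows_arr, "groups": list(groups) + singles})
        # --- delay groups
        self.delay_tie_groups = [np.asarray(g, dtype=int) for g in spec.delay_ties]
        in_delay_tie = np.zeros((R, U), dtype=bool)
        for cells in self.delay_tie_groups:
            in_delay_tie[cells[:, 0], cells[:, 1]] = True
        self.delay_free = self.active & ~in_delay_tie
        # --- source blocks: sources sharing rows (via the active mask)
        sparent = np.arange(U)

        def sfind(i):
            while sparent[i] != i:
                sparent[i] = sparent[sparent[i]]
                i = sparent[i]
            return i

        for r in range(R):
            us = np.nonzero(self.active[r])[0]
            for u in us[1:]:
                ua, ub = sfind(us[0]), sfind(u)
                if ua != ub:
                    sparent[ub] = ua
        sroots = np.array([sfind(u) for u in range(U)])
        self.source_blocks: list[tuple[np.ndarray, np.ndarray]] = []
        for root in np.unique(sroots):
            cols = np.nonzero(sroots == root)[0]
            rows = np.nonzero(self.active[:, cols].any(axis=1))[0]
            self.source_blocks.append((rows, cols))
        # --- scale groups: sources coupled through cross-row weight ties
        gparent = np.arange(U)

        def gfind(i):
            while gparent[i] != i:
                gparent[i] = gparent[gparent[i]]
                i = gparent[i]
            return i

        for cells in self.tie_groups:
            us = np.unique(cells[:, 1])
            for u in us[1:]:
                ua, ub = gfind(us[0]), gfind(u)
                if ua != ub:
                    gparent[ub] = ua
        groots = np.array([gfind(u) for u in range(U)])
        self.scale_groups = [np.nonzero(groots == root)[0] for root in np.unique(groots)]
        self.has_structure = bool(self.tie_groups) or bool(np.any(~self.active))


# ---------------------------------------------------------------------------
# update steps (array-level, used by the main loop)


def _update_sources(C: np.ndarray, A: np.ndarray, phases: np.ndarray,
                    nu: np.ndarray, structure: _Structure) -> None:
    """Per-frequency complex least squares for the source coefficients."""
    Kp1 = C.shape[1]
    for rows, cols in structure.source_blocks:
        G = (A[np.ix_(rows, cols)][None, :, :]
             * phases[np.ix_(rows, cols)].transpose(2, 0, 1))  # (K+1, nr, nc)
        Gh = np.conj(G.transpose(0, 2, 1))
        H = Gh @ G.transpose(0, 1, 2)
        ridge = 1e-12 * np.trace(H, axis1=1, axis2=2).real
        H = H + (ridge[:, None, None] + 1e-30) * np.eye(len(cols))
        rhs = np.einsum("kur,rk->ku", Gh, C[rows])
        try:
            sol = np.linalg.solve(H, rhs[..., None])[..., 0]  # (K+1, nc)
        except np.linalg.LinAlgError:
            sol = np.stack([np.linalg.lstsq(G[k], C[rows][:, k], rcond=None)[0]
                            for k in range(Kp1)])
        nu[cols, :] = sol.T
    nu[:, 0] = nu[:, 0].real  # DC of a real signal


def _project_sources_nonneg(nu: np.ndarray, T: int) -> np.ndarray:
    F = _rows_to_time(nu, T)
    return _analyze_rows(np.clip(F, 0, None), nu.shape[1] - 1)


def _update_weights(C: np.ndarray, A: np.ndarray, phases: np.ndarray,
                    nu: np.ndarray, structure: _Structure, w: np.ndarray,
                    nonneg: bool) -> None:
    """(Non-negative) least-squares weight refit, ties enforced exactly."""
    D = nu[None, :, :] * phases  # (R, U, K+1)
    simple = structure.row_simple
    if np.any(simple):
        Ds = D[simple]
        H = np.einsum("ruk,rvk,k->ruv", np.conj(Ds), Ds, w).real
        b = np.einsum("ruk,rk,k->ru", np.conj(Ds), C[simple], w).real
        n = H.shape[1]
        H = H + 1e-12 * np.einsum("ruu->r", H)[:, None, None] / n * np.eye(n) + 1e-30 * np.eye(n)
        if nonneg:
            sol = _batched_nnls_normal(H, b)
        else:
            sol = np.linalg.solve(H, b[..., None])[..., 0]
        A[simple] = sol
    for comp in structure.complex_components:
        rows, groups = comp["rows"], comp["groups"]
        pos = {r: i for i, r in enumerate(rows)}
        nJ = len(groups)
        Kp1 = C.shape[1]
        Dm = np.zeros((len(rows), Kp1, nJ), dtype=complex)
        for j, cells in enumerate(groups):
            for (r, u) in cells:
                Dm[pos[r], :, j] += D[r, u]
        sw = np.sqrt(w)
        design = np.concatenate([(Dm * sw[None, :, None]).real,
                                 (Dm * sw[None, :, None]).imag], axis=1
                                ).reshape(-1, nJ)
        target = np.concatenate([(C[rows] * sw).real, (C[rows] * sw).imag],
                                axis=1).reshape(-1)
        if nonneg:
            theta, _ = scipy.optimize.nnls(design, target)
        else:
            theta = np.linalg.lstsq(design, target, rcond=None)[0]
        for j, cells in enumerate(groups):
            A[cells[:, 0], cells[:, 1]] = theta[j]


def _delay_scores(g: np.ndarray, n_grid: int) -> np.ndarray:
    """Circular cross-correlation scores on the delay grid from ``g_k``.

    ``g_k = resid_k * conj(nu_k)``; score(t) is proportional to the decrease
    in squared error when the source is delayed by ``t`` grid steps (up to
    the weight refit).  Works on the last axis.
    """
    return np.fft.irfft(g, n=n_grid, axis=-1) * n_grid


def _update_delays(C: np.ndarray, A: np.ndarray, Tau: np.ndarray,
                   phases: np.ndarray, nu: np.ndarray, structure: _Structure,
                   duration_s: float, T: int, opts: FitOptions) -> None:
    """Coordinate-descent delay update (cross-correlation peak per group)."""
    if structure.spec.zero_delays:
        return
    Kp1 = C.shape[1]
    kvec = np.arange(Kp1)
    n_grid = max(2, int(round(T / opts.delay_grid_resolution_samples)))
    nonneg = structure.spec.nonneg_weights
    for _ in range(opts.inner_iters):
        Z = _mix(nu, A, phases)
        # batched singleton cells, source by source
        for u in range(structure.U):
            rows = np.nonzero(structure.delay_free[:, u])[0]
            if rows.size == 0:
                continue
            contrib = (A[rows, u, None] * nu[u][None, :] * phases[rows, u, :])
            resid = C[rows] - Z[rows] + contrib
            g = resid * np.conj(nu[u])[None, :]
            scores = _delay_scores(g, n_grid)  # (nr, n_grid)
            use = scores if nonneg else np.abs(scores)
            idx = np.argmax(use, axis=1)
            tau_new = idx * duration_s / n_grid
            if opts.refine_delays:
                s0 = np.take_along_axis(use, idx[:, None], 1)[:, 0]
                sm = np.take_along_axis(use, ((idx - 1) % n_grid)[:, None], 1)[:, 0]
                sp = np.take_along_axis(use, ((idx + 1) % n_grid)[:, None], 1)[:, 0]
                denom = sm - 2 * s0 + sp
                shift = np.where(np.abs(denom) > 1e-30, 0.5 * (sm - sp) / denom, 0.0)
                tau_new = tau_new + np.clip(shift, -0.5, 0.5) * duration_s / n_grid
            tau_new = wrap_delay(tau_new, duration_s)
            # accept only where the (weight-optimal) score does not decrease
            k_old = np.exp(2j * np.pi * np.outer(Tau[rows, u], kvec) / duration_s)
            old_scores = np.sum((g * k_old).real * _k_weights(Kp1 - 1), axis=1)
            k_new = np.exp(2j * np.pi * np.outer(tau_new, kvec) / duration_s)
            new_scores = np.sum((g * k_new).real * _k_weights(Kp1 - 1), axis=1)
            if not nonneg:
                old_scores, new_scores = np.abs(old_scores), np.abs(new_scores)
            better = new_scores >= old_scores
            Tau[rows[better], u] = tau_new[better]
            phases[rows, u, :] = np.exp(-2j * np.pi * np.outer(Tau[rows, u], kvec)
                                        / duration_s)
            Z[rows] = C[rows] - resid + (A[rows, u, None] * nu[u][None, :]
                                         * phases[rows, u, :])
        # tied delay groups, one shared value per group
        for cells in structure.delay_tie_groups:
            rs, us = cells[:, 0], cells[:, 1]
            contrib = A[rs, us, None] * nu[us] * phases[rs, us, :]
            resid = C[rs] - Z[rs] + contrib
            g_cells = resid * np.conj(nu[us])
            weights_c = A[rs, us]
            if np.all(weights_c == 0):
                weights_c = np.ones_like(weights_c)
            g = np.sum(weights_c[:, None] * g_cells, axis=0)
            scores = _delay_scores(g[None, :], n_grid)[0]
            idx = int(np.argmax(scores))
            tau_new = idx * duration_s / n_grid
            if opts.refine_delays:
                s0, sm, sp = scores[idx], scores[(idx - 1) % n_grid], scores[(idx + 1) % n_grid]
                denom = sm - 2 * s0 + sp
                if abs(denom) > 1e-30:
                    tau_new += np.clip(0.5 * (sm - sp) / denom, -0.5, 0.5) * duration_s / n_grid
            tau_new = wrap_delay(float(tau_new), duration_s)
            wk = _k_weights(Kp1 - 1)
            old = float(np.sum((g * np.exp(2j * np.pi * kvec * Tau[rs[0], us[0]]
                                           / duration_s)).real * wk))
            new = float(np.sum((g * np.exp(2j * np.pi * kvec * tau_new / duration_s)).real * wk))
            if new >= old:
                Tau[rs, us] = tau_new
            phases[rs, us, :] = np.exp(-2j * np.pi * np.outer(Tau[rs, us], kvec) / duration_s)
            Z[rs] = C[rs] - resid + A[rs, us, None] * nu[us] * phases[rs, us, :]


def _newton_refine_delays(g: np.ndarray, tau: np.ndarray, w: np.ndarray,
                          duration_s: float, n_iter: int = 3) -> np.ndarray:
    """Refine cross-correlation peaks to sub-sample precision (batched).

    ``g`` is ``(n, K+1)`` with ``g_k = resid_k * conj(nu_k)``; the score
    ``s(tau) = sum_k w_k Re(g_k e^{2 pi i k tau / T_s})`` is a trigonometric
    polynomial whose local extremum near ``tau`` is found by Newton steps on
    ``|s|`` (sign taken from the current value).
    """
    kvec = np.arange(g.shape[-1])
    omega = 2j * np.pi * kvec / duration_s
    T_step = duration_s / max(g.shape[-1] * 2, 4)
    tau = tau.copy()
    for _ in range(n_iter):
        e = np.exp(np.multiply.outer(tau, kvec) * (2j * np.pi / duration_s))
        s0 = np.sum(w * (g * e).real, axis=-1)
        s1 = np.sum(w * (g * e * omega).real, axis=-1)
        s2 = np.sum(w * (g * e * omega**2).real, axis=-1)
        sgn = np.where(s0 >= 0, 1.0, -1.0)
        concave = sgn * s2 < 0
        step = np.where(concave, -(sgn * s1) / np.where(concave, sgn * s2, -1.0), 0.0)
        step = np.clip(step, -T_step, T_step)
        tau = tau + step
    return tau


def _row_costs(C: np.ndarray, nu: np.ndarray, A: np.ndarray,
               phases: np.ndarray, w: np.ndarray) -> np.ndarray:
    Z = _mix(nu, A, phases)
    return np.sum(w * np.abs(C - Z) ** 2, axis=1)


def _multistart_rows(C: np.ndarray, nu: np.ndarray, A: np.ndarray,
                     Tau: np.ndarray, phases: np.ndarray, rows: np.ndarray,
                     w: np.ndarray, duration_s: float, T: int,
                     nonneg: bool, rng: np.random.Generator,
                     n_starts: int = 4, n_sweeps: int = 4) -> None:
    """Re-fit weights and delays of selected rows by multistart coordinate
    descent against the current sources (batched across rows).

    Each start draws random delays, fits weights first (so starts are
    genuinely diverse), then alternates per-source delay updates (global
    cross-correlation peak + Newton refinement, with the source's weight
    re-optimized immediately) with joint weight refits.  The best state per
    row replaces the current one only if it lowers that row's cost.
    """
    if rows.size == 0:
        return
    U = nu.shape[0]
    Kp1 = C.shape[1]
    kvec = np.arange(Kp1)
    Cr = C[rows]
    n = rows.size
    nu_energy = np.sum(w * np.abs(nu) ** 2, axis=1)

    def weight_refit(tau_s):
        ph = np.exp(np.multiply.outer(tau_s, kvec) * (-2j * np.pi / duration_s))
        D = nu[None, :, :] * ph
        H = np.einsum("ruk,rvk,k->ruv", np.conj(D), D, w).real
        b = np.einsum("ruk,rk,k->ru", np.conj(D), Cr, w).real
        H = H + 1e-10 * np.einsum("ruu->r", H)[:, None, None] / U * np.eye(U) \
            + 1e-30 * np.eye(U)
        if nonneg:
            a = _batched_nnls_normal(H, b)
        else:
            a = np.linalg.solve(H, b[..., None])[..., 0]
        return a, ph

    best_tau = Tau[rows].copy()
    best_a = A[rows].copy()
    best_cost = np.sum(w * np.abs(Cr - np.einsum(
        "ru,uk,ruk->rk", best_a, nu, phases[rows])) ** 2, axis=1)
    for s in range(n_starts):
        if s == 0:
            tau_s = Tau[rows].copy()
        else:
            tau_s = rng.uniform(-duration_s / 2, duration_s / 2, size=(n, U))
        a, ph = weight_refit(tau_s)
        for _ in range(n_sweeps):
            Z = np.einsum("ru,uk,ruk->rk", a, nu, ph)
            for u in range(U):
                if nu_energy[u] <= 0:
                    continue
                contrib = a[:, u, None] * nu[u] * ph[:, u]
                resid = Cr - Z + contrib
                g = resid * np.conj(nu[u])
                sc = np.fft.irfft(g, n=T, axis=-1)
                val = sc if nonneg else np.abs(sc)
                idx = np.argmax(val, axis=1)
                cand = _newton_refine_delays(g, idx * duration_s / T, w, duration_s)
                tau_s[:, u] = wrap_delay(cand, duration_s)
                ph[:, u] = np.exp(-2j * np.pi * np.outer(tau_s[:, u], kvec)
                                  / duration_s)
                a_u = np.sum(w * (resid * np.conj(nu[u] * ph[:, u])).real, axis=1) \
                    / nu_energy[u]
                a[:, u] = np.clip(a_u, 0, None) if nonneg else a_u
                Z = Cr - resid + a[:, u, None] * nu[u] * ph[:, u]
            a, ph = weight_refit(tau_s)
        cost = np.sum(w * np.abs(Cr - np.einsum(
            "ru,uk,ruk->rk", a, nu, ph)) ** 2, axis=1)
        upd = cost < best_cost
        best_tau[upd] = tau_s[upd]
        best_a[upd] = a[upd]
        best_cost[upd] = cost[upd]
    A[rows] = best_a
    Tau[rows] = wrap_delay(best_tau, duration_s)
    phases[rows] = np.exp(np.multiply.outer(Tau[rows], kvec)
                          * (-2j * np.pi / duration_s))


def _rescale(nu: np.ndarray, A: np.ndarray, structure: _Structure) -> None:
    """Unit-RMS source gauge, applied per tie-consistent scale group."""
    rms = _source_rms(nu)
    for group in structure.scale_groups:
        s = np.sqrt(np.mean(rms[group] ** 2))
        if s > 1e-12:
            nu[group] /= s
            A[:, group] *= s
        else:
            A[:, group] = 0.0


# ---------------------------------------------------------------------------
# the main estimator


def fit_anechoic(data, U: int, spec: ConstraintSpec | None = None,
                 opts: FitOptions | None = None,
                 index_map: IndexMap | None = None) -> AnechoicFit:
    """Fit the anechoic mixture model to a set of signals.

    Parameters
    ----------
    data : array (R, T) or TrialDataset
        Observed signals.  A :class:`TrialDataset` is flattened row-major
        (``r = l * M + m``); pass ``index_map`` for bookkeeping only.
    U : int
        Number of sources.
    spec : ConstraintSpec, optional
        Constraints specializing the model (see Table-1 builders in
        :mod:`fada.api`).  Default: unconstrained.
    opts : FitOptions, optional

    Returns
    -------
    AnechoicFit
        Best fit over random restarts; ``converged=False`` flags a run that
        hit ``max_outer_iters`` (not an exception).  Deterministic given the
        seed.
    """
    spec = spec or ConstraintSpec()
    opts = opts or FitOptions()
    if isinstance(data, TrialDataset):
        duration_s = data.duration_s
        Y = signals_from_dataset(data)
    else:
        Y = np.asarray(data, dtype=float)
        duration_s = 1.0
    if Y.ndim != 2:
        raise ValueError("data must be (R, T)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("data must be finite")
    if U < 1:
        raise ValueError("U must be >= 1")
    R, T = Y.shape
    K = opts.K if opts.K is not None else choose_num_harmonics(Y)
    C = _analyze_rows(Y, K)
    w = _k_weights(K)

    if not np.any(np.abs(Y) > 0):
        # degenerate zero dataset: by convention a perfect fit with silent sources
        params = AnechoicParams(np.zeros((U, T)), np.zeros((R, U)),
                                np.zeros((R, U)), duration_s)
        return AnechoicFit(params, np.zeros((U, K + 1), complex), 1.0,
                           np.zeros(1), True, opts.seed, K, opts)

    if spec.bilinear is not None:
        return _fit_bilinear(Y, C, spec, opts, duration_s)

    structure = _Structure(R, U, spec)
    best: AnechoicFit | None = None
    for restart in range(opts.n_restarts):
        fit = _fit_once(Y, C, structure, opts, duration_s, restart)
        if best is None or fit.r2 > best.r2:
            best = fit
        if best.r2 >= opts.restart_r2_stop:
            break
    return best


def _init_magnitudes(C: np.ndarray, structure: _Structure, opts: FitOptions,
                     seed: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Eq-11 magnitude initialization, structure-aware when ties/zeros exist."""
    sq = np.abs(C) ** 2
    R, Kp1 = sq.shape
    U = structure.U
    if not structure.has_structure:
        Asq, Nsq = estimate_magnitudes(sq, U, opts.magnitude_solver, seed)
        return np.sqrt(Asq), np.sqrt(Nsq)
    # alternating NNLS on |c|^2 respecting ties and zeros
    Nsq = rng.uniform(0.2, 1.0, size=(U, Kp1)) * sq.mean()
    Asq = np.where(structure.active, 1.0, 0.0)
    w1 = np.ones(Kp1)
    for _ in range(8):
        # theta step (grouped, non-negative)
        _update_weights(sq.astype(complex), Asq, np.ones((R, U, Kp1)), Nsq.astype(complex),
                        structure, w1, nonneg=True)
        # source step per block; the Gram matrix is frequency-independent,
        # so all frequencies are solved in one batched NNLS
        for rows, cols in structure.source_blocks:
            Ablk = Asq[np.ix_(rows, cols)]
            G = Ablk.T @ Ablk + 1e-12 * np.eye(len(cols))
            B = Ablk.T @ sq[rows]  # (nc, K+1)
            sol = _batched_nnls_normal(np.repeat(G[None], Kp1, axis=0), B.T)
            Nsq[cols, :] = sol.T
    return np.sqrt(np.clip(Asq, 0, None)), np.sqrt(np.clip(Nsq, 0, None))


def _fit_once(Y: np.ndarray, C: np.ndarray, structure: _Structure,
              opts: FitOptions, duration_s: float, restart: int) -> AnechoicFit:
    spec = structure.spec
    R, T = Y.shape
    U = structure.U
    Kp1 = C.shape[1]
    K = Kp1 - 1
    w = _k_weights(K)
    kvec = np.arange(Kp1)
    seed = int((opts.seed * 1000003 + restart * 7919) % (2**31))
    rng = np.random.default_rng([opts.seed % (2**31), restart])

    external_init = restart == 0 and opts.initial_state is not None
    if external_init:
        state = opts.initial_state
        nu0 = np.asarray(state["nu"], dtype=complex)
        if nu0.shape != (U, Kp1):
            raise ValueError("initial_state nu has wrong shape")
        Nmag = np.abs(nu0)
        phi = np.angle(nu0)
        A = np.asarray(state["A"], dtype=float).copy()
        Tau = np.asarray(state["Tau"], dtype=float).copy()
        A[~structure.active] = 0.0
    else:
        Amag, Nmag = _init_magnitudes(C, structure, opts, seed, rng)
        phi = rng.uniform(-np.pi, np.pi, size=(U, Kp1))
        phi[:, 0] = 0.0 if spec.nonneg_sources else rng.choice([0.0, np.pi], size=U)
        A = Amag.copy()
        if not spec.nonneg_weights and restart > 0:
            A *= rng.choice([-1.0, 1.0], size=A.shape)
        A[~structure.active] = 0.0
        Tau = np.zeros((R, U))
        if restart > 0 and not spec.zero_delays:
            Tau = rng.uniform(-duration_s / 2, duration_s / 2, size=(R, U))
            Tau[~structure.active] = 0.0
            for cells in structure.delay_tie_groups:  # ties share one random value
                Tau[cells[:, 0], cells[:, 1]] = Tau[cells[0, 0], cells[0, 1]]
    phases = np.exp(np.multiply.outer(Tau, kvec) * (-2j * np.pi / duration_s))
    # when every row has untied weights and free delays (delayed temporal /
    # free anechoic), the weights/delays step is the batched multistart
    # coordinate solver, which is far more robust to delay local minima
    pure_rows = (not spec.zero_delays
                 and bool(np.all(structure.row_simple))
                 and bool(np.all(structure.delay_free == structure.active))
                 and bool(np.all(structure.active)))

    # anchored warm-up: source magnitudes fixed at the Eq-11 estimate while
    # phases and weights (and delays, if free) are iterated
    n_anchor = 0 if external_init else opts.warmup_iters
    prev_anchor = np.inf
    for _ in range(n_anchor):
        phi = estimate_phases(C, A, Tau, Nmag, {"n_sweeps": 8}, duration_s, phi)
        nu = Nmag * np.exp(1j * phi)
        nu[:, 0] = nu[:, 0].real
        _update_delays(C, A, Tau, phases, nu, structure, duration_s, T, opts)
        _update_weights(C, A, phases, nu, structure, w, spec.nonneg_weights)
        obj = _objective(C, _mix(nu, A, phases), w)
        if prev_anchor - obj < 10 * opts.tol * max(prev_anchor, 1e-30):
            break
        prev_anchor = obj

    nu = Nmag * np.exp(1j * phi)
    nu[:, 0] = nu[:, 0].real
    trace = []
    prev = np.inf
    converged = False
    for outer in range(opts.max_outer_iters):
        _update_sources(C, A, phases, nu, structure)
        if spec.nonneg_sources:
            nu = _project_sources_nonneg(nu, T)
        if pure_rows:
            n_starts = 4 if outer < 10 else 2
            _multistart_rows(C, nu, A, Tau, phases, np.arange(R), w,
                             duration_s, T, spec.nonneg_weights, rng,
                             n_starts=n_starts, n_sweeps=opts.inner_iters)
        else:
            _update_delays(C, A, Tau, phases, nu, structure, duration_s, T, opts)
            _update_weights(C, A, phases, nu, structure, w, spec.nonneg_weights)
        _rescale(nu, A, structure)
        obj = _objective(C, _mix(nu, A, phases), w)
        trace.append(obj)
        if prev - obj < opts.tol * max(prev, 1e-30) and len(trace) > 1:
            converged = True
            break
        prev = obj

    if pure_rows:
        # final intensive polish: aggressive per-row multistart to clean the
        # few rows left in delay local minima, then a last source refresh
        for _ in range(3):
            _multistart_rows(C, nu, A, Tau, phases, np.arange(R), w,
                             duration_s, T, spec.nonneg_weights, rng,
                             n_starts=8, n_sweeps=3)
            _update_sources(C, A, phases, nu, structure)
            if spec.nonneg_sources:
                nu = _project_sources_nonneg(nu, T)
        # very intensive passes on rows still off, but only when this restart
        # is a serious candidate (near-perfect overall reconstruction);
        # repeated while they keep improving the objective
        energy = np.sum(w * np.abs(C) ** 2, axis=1)
        prev_cost = None
        for _ in range(3):
            costs = _row_costs(C, nu, A, phases, w)
            if costs.sum() >= 5e-3 * max(energy.sum(), 1e-30):
                break
            if prev_cost is not None and costs.sum() > 0.7 * prev_cost:
                break
            prev_cost = costs.sum()
            stubborn = np.nonzero(costs > 1e-7 * np.maximum(energy, 1e-30))[0]
            if not stubborn.size:
                break
            _multistart_rows(C, nu, A, Tau, phases, stubborn, w, duration_s,
                             T, spec.nonneg_weights, rng,
                             n_starts=32, n_sweeps=6)
            _update_sources(C, A, phases, nu, structure)
            if spec.nonneg_sources:
                nu = _project_sources_nonneg(nu, T)
        # escalate on rows that still resist (cost well above the bulk):
        # their delay landscapes are spiky but solvable with enough starts
        if prev_cost is not None:
            for _ in range(2):
                costs = _row_costs(C, nu, A, phases, w)
                floor = max(5.0 * float(np.median(costs)), 1e-30)
                hard = np.nonzero((costs > floor)
                                  & (costs > 1e-7 * np.maximum(energy, 1e-30)))[0]
                if not hard.size:
                    break
                _multistart_rows(C, nu, A, Tau, phases, hard, w, duration_s,
                                 T, spec.nonneg_weights, rng,
                                 n_starts=200, n_sweeps=8)
                _update_sources(C, A, phases, nu, structure)
                if spec.nonneg_sources:
                    nu = _project_sources_nonneg(nu, T)
        _rescale(nu, A, structure)

    Tau = wrap_delay(Tau, duration_s)
    Tau[A == 0] = 0.0
    if not structure.has_structure:
        _canonical_gauge(nu, A, Tau, spec)
    F = _rows_to_time(nu, T)
    recon = _rows_to_time(_mix(nu, A, phases), T)
    r2 = _explained_variance(Y, recon)
    params = AnechoicParams(F, A, Tau, duration_s)
    return AnechoicFit(params, nu, r2, np.asarray(trace), converged, seed, K, opts)


def _canonical_gauge(nu: np.ndarray, A: np.ndarray, Tau: np.ndarray,
                     spec: ConstraintSpec) -> None:
    """Order sources by explained energy; fix signs (largest sample positive)."""
    T_probe = 4 * nu.shape[1]
    F = _rows_to_time(nu, T_probe)
    if not spec.nonneg_sources:
        for u in range(nu.shape[0]):
            peak = F[u, np.argmax(np.abs(F[u]))] if np.any(F[u]) else 1.0
            if peak < 0:
                nu[u] *= -1
                A[:, u] *= -1
    energy = np.sum(A**2, axis=0) * _source_rms(nu) ** 2
    order = np.argsort(-energy, kind="stable")
    nu[:] = nu[order]
    A[:] = A[:, order]
    Tau[:] = Tau[:, order]
# ---------------------------------------------------------------------------
# bilinear (space-by-time) path


def _sbt_phase(Tau: np.ndarray, kvec: np.ndarray, duration_s: float) -> np.ndarray:
    return np.exp(np.multiply.outer(Tau, kvec) * (-2j * np.pi / duration_s))


def _sbt_mix(nu: np.ndarray, Wf: np.ndarray, Cf: np.ndarray,
             phase: np.ndarray) -> np.ndarray:
    """Model coefficients per trial: ``Z[l, m, k]``."""
    return np.einsum("lpq,mq,pk,lpqk->lmk", Cf, Wf, nu, phase)


def _sbt_trial_weights(C3: np.ndarray, nu: np.ndarray, Wf: np.ndarray,
                       Tau: np.ndarray, w: np.ndarray,
                       duration_s: float) -> np.ndarray:
    """Joint NNLS refit of every trial's weight matrix ``C[l, p, q]``."""
    L, M, Kp1 = C3.shape
    P_tp, P_sp = Tau.shape[1], Tau.shape[2]
    kvec = np.arange(Kp1)
    phase = _sbt_phase(Tau, kvec, duration_s)
    D = np.einsum("mq,pk,lpqk->lmkpq", Wf, nu, phase).reshape(L, M * Kp1, P_tp * P_sp)
    sw = np.sqrt(np.tile(w, M))
    design = np.concatenate([(D * sw[None, :, None]).real,
                             (D * sw[None, :, None]).imag], axis=1)
    target = np.concatenate([(C3.reshape(L, -1) * sw).real,
                             (C3.reshape(L, -1) * sw).imag], axis=1)
    Cf = np.empty((L, P_tp * P_sp))
    for l in range(L):
        Cf[l], _ = scipy.optimize.nnls(design[l], target[l])
    return Cf.reshape(L, P_tp, P_sp)


def _sbt_fit_trials(C3: np.ndarray, nu: np.ndarray, Wf: np.ndarray,
                    Cf: np.ndarray, Tau: np.ndarray, w: np.ndarray,
                    duration_s: float, T: int, rng: np.random.Generator,
                    n_starts: int = 3, n_sweeps: int = 2
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Multistart delay/weight fitting of every trial (batched over trials).

    Per start, delays are drawn at random (start 0 continues from the
    current state), weights are refit first, then coordinate descent over
    the (temporal, spatial) primitive pairs updates each shared delay by the
    channel-weighted cross-correlation peak with Newton refinement.  The
    best state per trial is kept.
    """
    L, M, Kp1 = C3.shape
    P_tp, P_sp = Cf.shape[1], Cf.shape[2]
    kvec = np.arange(Kp1)
    nu_energy = np.sum(w * np.abs(nu) ** 2, axis=1)
    wq_energy = np.sum(Wf**2, axis=0)

    def cost(Cf_s, Tau_s):
        Z = _sbt_mix(nu, Wf, Cf_s, _sbt_phase(Tau_s, kvec, duration_s))
        return np.sum(w * np.abs(C3 - Z) ** 2, axis=(1, 2))

    best_Cf, best_Tau = Cf.copy(), Tau.copy()
    best_cost = cost(best_Cf, best_Tau)
    for s in range(n_starts):
        if s == 0:
            Tau_s = Tau.copy()
        else:
            Tau_s = rng.uniform(-duration_s / 2, duration_s / 2,
                                size=(L, P_tp, P_sp))
        Cf_s = _sbt_trial_weights(C3, nu, Wf, Tau_s, w, duration_s)
        for _ in range(n_sweeps):
            phase = _sbt_phase(Tau_s, kvec, duration_s)
            Z = _sbt_mix(nu, Wf, Cf_s, phase)
            for p in range(P_tp):
                for q in range(P_sp):
                    contrib = np.einsum("l,m,k,lk->lmk", Cf_s[:, p, q],
                                        Wf[:, q], nu[p], phase[:, p, q])
                    resid = C3 - Z + contrib
                    g = np.einsum("m,lmk->lk", Wf[:, q], resid * np.conj(nu[p]))
                    scores = np.fft.irfft(g, n=T, axis=-1)
                    idx = np.argmax(scores, axis=1)
                    cand = _newton_refine_delays(g, idx * duration_s / T, w,
                                                 duration_s)
                    Tau_s[:, p, q] = wrap_delay(cand, duration_s)
                    phase[:, p, q] = np.exp(-2j * np.pi * np.outer(
                        Tau_s[:, p, q], kvec) / duration_s)
                    denom = nu_energy[p] * wq_energy[q]
                    if denom > 0:
                        a = np.sum(w * (g * np.exp(2j * np.pi * np.outer(
                            Tau_s[:, p, q], kvec) / duration_s)).real, axis=1) / denom
                        Cf_s[:, p, q] = np.clip(a, 0.0, None)
                    Z = C3 - resid + np.einsum("l,m,k,lk->lmk", Cf_s[:, p, q],
                                               Wf[:, q], nu[p], phase[:, p, q])
            Cf_s = _sbt_trial_weights(C3, nu, Wf, Tau_s, w, duration_s)
        c = cost(Cf_s, Tau_s)
        upd = c < best_cost
        best_Cf[upd] = Cf_s[upd]
        best_Tau[upd] = Tau_s[upd]
        best_cost[upd] = c[upd]
    return best_Cf, wrap_delay(best_Tau, duration_s)


def _sbt_primitive_updates(C: np.ndarray, C3: np.ndarray, nu: np.ndarray,
                           Wf: np.ndarray, Cf: np.ndarray, Tau: np.ndarray,
                           w: np.ndarray, duration_s: float, T: int
                           ) -> np.ndarray:
    """Spatial-primitive NNLS update (in place) and temporal-source complex
    least squares; returns the new source coefficients."""
    L, M, Kp1 = C3.shape
    P_tp, P_sp = Cf.shape[1], Cf.shape[2]
    kvec = np.arange(Kp1)
    phase = _sbt_phase(Tau, kvec, duration_s)
    Gq = np.einsum("lpq,pk,lpqk->lqk", Cf, nu, phase)
    sw = np.sqrt(np.tile(w, L))
    Dg = Gq.transpose(0, 2, 1).reshape(L * Kp1, P_sp)
    design = np.concatenate([(Dg * sw[:, None]).real, (Dg * sw[:, None]).imag])
    for m in range(M):
        tvec = C3[:, m, :].reshape(-1) * sw
        Wf[m], _ = scipy.optimize.nnls(
            design, np.concatenate([tvec.real, tvec.imag]))
    D = np.einsum("mq,lpq,lpqk->lmpk", Wf, Cf, phase).reshape(L * M, P_tp, Kp1)
    H = np.einsum("rpk,rqk->kpq", np.conj(D), D) + 1e-10 * np.eye(P_tp)
    rhs = np.einsum("rpk,rk->kp", np.conj(D), C)
    nu_new = np.linalg.solve(H, rhs[..., None])[..., 0].T
    nu_new[:, 0] = nu_new[:, 0].real
    return _project_sources_nonneg(nu_new, T)


def _sbt_gauge(nu: np.ndarray, Wf: np.ndarray, Cf: np.ndarray) -> None:
    """Unit-RMS temporal and unit-norm spatial primitives (scale into C)."""
    rms = _source_rms(nu)
    for p in range(nu.shape[0]):
        if rms[p] > 1e-12:
            nu[p] /= rms[p]
            Cf[:, p, :] *= rms[p]
    norms = np.linalg.norm(Wf, axis=0)
    for q in range(Wf.shape[1]):
        if norms[q] > 1e-12:
            Wf[:, q] /= norms[q]
            Cf[:, :, q] *= norms[q]


def _sbt_explore(C, C3, w, kvec, duration_s, T, rng, seed, opts, bl,
                 explore_iters, random_delays=True):
    """One short exploration run of the space-by-time estimator."""
    L, M, P_tp, P_sp = bl.L, bl.M, bl.P_tp, bl.P_sp
    R = L * M
    Kp1 = C.shape[1]
    Bsq, Nsq = estimate_magnitudes(np.abs(C) ** 2, P_tp,
                                   opts.magnitude_solver, seed)
    Nmag = np.sqrt(Nsq) * np.sqrt(np.mean(np.abs(C) ** 2)) / max(
        np.sqrt(np.mean(Nsq)), 1e-30)
    phi = rng.uniform(-np.pi, np.pi, size=(P_tp, Kp1))
    phi[:, 0] = 0.0
    nu = Nmag * np.exp(1j * phi)
    nu[:, 0] = np.abs(nu[:, 0].real)
    # Bsq[(m,l), p] ~ sum_q (C[l,p,q] W[m,q])^2; its sum over p admits a
    # rank-P_sp non-negative factorization that seeds W, then C
    Bq = Bsq.reshape(L, M, P_tp)
    Wsq, _ = estimate_magnitudes(Bq.sum(axis=2).T, P_sp, "nmf", seed + 1)
    Wf = np.sqrt(np.clip(Wsq, 0, None)) + 1e-3
    Cf = np.empty((L, P_tp, P_sp))
    Wsq_design = Wf**2
    Hw = Wsq_design.T @ Wsq_design + 1e-10 * np.eye(P_sp)
    for l in range(L):
        for p in range(P_tp):
            csq = _nnls_from_normal(Hw, Wsq_design.T @ Bq[l, :, p])
            Cf[l, p] = np.sqrt(np.clip(csq, 0, None))
    Cf += 0.05 * rng.uniform(0.0, 1.0, size=Cf.shape)
    Tau = np.zeros((L, P_tp, P_sp))
    if random_delays:
        Tau = rng.uniform(-duration_s / 2, duration_s / 2, size=Tau.shape)
    trace = []
    prev = np.inf
    converged = False
    for outer in range(explore_iters):
        Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s, T,
                                  rng, n_starts=3 if outer < 8 else 2,
                                  n_sweeps=opts.inner_iters)
        nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w, duration_s, T)
        _sbt_gauge(nu, Wf, Cf)
        Z = _sbt_mix(nu, Wf, Cf, _sbt_phase(Tau, kvec, duration_s)
                     ).reshape(R, Kp1)
        obj = _objective(C, Z, w)
        trace.append(obj)
        if prev - obj < opts.tol * max(prev, 1e-30) and len(trace) > 1:
            converged = True
            break
        prev = obj
    return {"nu": nu, "Wf": Wf, "Cf": Cf, "Tau": Tau, "trace": trace,
            "converged": converged, "seed": seed, "rng": rng,
            "obj": trace[-1] if trace else np.inf}


def _fit_bilinear(Y: np.ndarray, C: np.ndarray, spec: ConstraintSpec,
                  opts: FitOptions, duration_s: float) -> AnechoicFit:
    """Space-by-time estimator: shared spatial/temporal primitives, per-trial
    bilinear weights and per-(trial, pair) delays.

    Random restarts explore the basin structure; the best restart (by
    reconstruction objective) then receives an intensive polish in which
    the per-trial multistart, the spatial-primitive NNLS and the temporal
    per-frequency least squares are alternated until progress stalls.
    """
    bl = spec.bilinear
    M, L, P_tp, P_sp = bl.M, bl.L, bl.P_tp, bl.P_sp
    R, T = Y.shape
    if R != M * L:
        raise ValueError("bilinear spec inconsistent with the number of rows")
    Kp1 = C.shape[1]
    K = Kp1 - 1
    w = _k_weights(K)
    kvec = np.arange(Kp1)
    C3 = C.reshape(L, M, Kp1)
    n_restarts = max(opts.n_restarts, 14)
    explore_iters = 25  # short exploration runs; top candidates continue
    candidates = []
    for restart in range(n_restarts):
        seed = int((opts.seed * 1000003 + restart * 7919) % (2**31))
        rng = np.random.default_rng([opts.seed % (2**31), restart, 1])
        state = _sbt_explore(C, C3, w, kvec, duration_s, T, rng, seed, opts,
                             bl, explore_iters, random_delays=restart > 0)
        candidates.append(state)
        energy = np.sum(w * np.abs(C) ** 2)
        if state["obj"] < (1 - opts.restart_r2_stop) * energy:
            break
    # continue the most promising restarts to convergence, keep the best
    candidates.sort(key=lambda s: s["obj"])
    best = None
    for state in candidates[:4]:
        nu, Wf, Cf, Tau = state["nu"], state["Wf"], state["Cf"], state["Tau"]
        rng = state["rng"]
        trace = list(state["trace"])
        prev = trace[-1] if trace else np.inf
        converged = state["converged"]
        for outer in range(opts.max_outer_iters):
            Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s, T,
                                      rng, n_starts=2, n_sweeps=opts.inner_iters)
            nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w,
                                        duration_s, T)
            _sbt_gauge(nu, Wf, Cf)
            obj = _objective(C, _sbt_mix(nu, Wf, Cf, _sbt_phase(
                Tau, kvec, duration_s)).reshape(R, Kp1), w)
            trace.append(obj)
            if prev - obj < opts.tol * max(prev, 1e-30):
                converged = True
                break
            prev = obj
        state.update({"nu": nu, "Wf": Wf, "Cf": Cf, "Tau": Tau,
                      "trace": trace, "converged": converged,
                      "obj": trace[-1]})
        if best is None or state["obj"] < best["obj"]:
            best = state
    # adaptive second wave when no candidate converged well
    energy = np.sum(w * np.abs(C) ** 2)
    if best["obj"] > 3e-3 * energy:
        wave2 = []
        for restart in range(n_restarts, n_restarts + 10):
            seed = int((opts.seed * 1000003 + restart * 7919) % (2**31))
            rng = np.random.default_rng([opts.seed % (2**31), restart, 1])
            state = _sbt_explore(C, C3, w, kvec, duration_s, T, rng, seed,
                                 opts, bl, explore_iters)
            wave2.append(state)
        wave2.sort(key=lambda s: s["obj"])
        for state in wave2[:2]:
            nu, Wf, Cf, Tau = (state["nu"], state["Wf"], state["Cf"],
                               state["Tau"])
            rng = state["rng"]
            trace = list(state["trace"])
            prev = trace[-1] if trace else np.inf
            for outer in range(opts.max_outer_iters):
                Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s,
                                          T, rng, n_starts=2,
                                          n_sweeps=opts.inner_iters)
                nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w,
                                            duration_s, T)
                _sbt_gauge(nu, Wf, Cf)
                obj = _objective(C, _sbt_mix(nu, Wf, Cf, _sbt_phase(
                    Tau, kvec, duration_s)).reshape(R, Kp1), w)
                trace.append(obj)
                if prev - obj < opts.tol * max(prev, 1e-30):
                    break
                prev = obj
            state.update({"nu": nu, "Wf": Wf, "Cf": Cf, "Tau": Tau,
                          "trace": trace, "obj": trace[-1]})
            if state["obj"] < best["obj"]:
                best = state
    nu, Wf, Cf, Tau = best["nu"], best["Wf"], best["Cf"], best["Tau"]
    rng = best["rng"]
    trace = list(best["trace"])
    prev_pol = trace[-1]
    for _ in range(30):
        Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s, T,
                                  rng, n_starts=8, n_sweeps=3)
        nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w, duration_s, T)
        obj = _objective(C, _sbt_mix(nu, Wf, Cf, _sbt_phase(
            Tau, kvec, duration_s)).reshape(R, Kp1), w)
        trace.append(obj)
        if prev_pol - obj < 3e-5 * max(prev_pol, 1e-30):
            break
        prev_pol = obj
    for _ in range(4):  # very intensive last rounds to clean stubborn delays
        Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s, T,
                                  rng, n_starts=24, n_sweeps=5)
        nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w, duration_s, T)
        trace.append(_objective(C, _sbt_mix(nu, Wf, Cf, _sbt_phase(
            Tau, kvec, duration_s)).reshape(R, Kp1), w))
    # escalate on trials whose residual stays well above the bulk
    for _ in range(2):
        tc = np.sum(w * np.abs(C3 - _sbt_mix(nu, Wf, Cf, _sbt_phase(
            Tau, kvec, duration_s))) ** 2, axis=(1, 2))
        floor = max(5.0 * float(np.median(tc)), 1e-30)
        if not np.any(tc > floor):
            break
        Cf, Tau = _sbt_fit_trials(C3, nu, Wf, Cf, Tau, w, duration_s, T,
                                  rng, n_starts=120, n_sweeps=6)
        nu = _sbt_primitive_updates(C, C3, nu, Wf, Cf, Tau, w, duration_s, T)
        trace.append(_objective(C, _sbt_mix(nu, Wf, Cf, _sbt_phase(
            Tau, kvec, duration_s)).reshape(R, Kp1), w))
    _sbt_gauge(nu, Wf, Cf)
    Z = _sbt_mix(nu, Wf, Cf, _sbt_phase(Tau, kvec, duration_s)).reshape(R, Kp1)
    Tau = wrap_delay(Tau, duration_s)
    A = np.einsum("lpq,mq->lmpq", Cf, Wf).reshape(R, P_tp * P_sp)
    TauRU = np.broadcast_to(Tau[:, None, :, :], (L, M, P_tp, P_sp)
                            ).reshape(R, P_tp * P_sp).copy()
    F = _rows_to_time(np.repeat(nu, P_sp, axis=0), T)
    recon = _rows_to_time(Z, T)
    r2 = _explained_variance(Y, recon)
    params = AnechoicParams(F, A, TauRU, duration_s)
    return AnechoicFit(params, np.repeat(nu, P_sp, axis=0), r2,
                       np.asarray(trace), best["converged"], best["seed"],
                       K, opts,
                       factors={"W": Wf.copy(), "C": Cf.copy(),
                                "Tau": Tau.copy(), "nu_S": nu.copy()})
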