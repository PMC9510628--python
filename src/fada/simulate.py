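"""Seeded generator of EMG-like and kinematic-like benchmark datasets.

Ground-truth datasets are drawn from the eight model variants (spatial,
temporal, and delayed-temporal models each in unconstrained/kinematic-like
and non-negative/EMG-like form, plus the non-negative spatiotemporal and
space-by-time models) and corrupted with signal-dependent noise, emulating
the variability of motor output: the noise standard deviation grows with
the instantaneous signal magnitude.

Sources are smooth band-limited waveforms (random Fourier coefficients up
to ``K_gen`` harmonics with a 1/k amplitude decay).  Non-negative sources
are built as squares of signals band-limited to ``K_gen // 2``, which are
therefore *exactly* band-limited to ``K_gen`` and non-negative — the shape
of a smooth EMG burst.  Pairwise time-domain correlations above
``max_source_corr`` are rejected, reflecting the uncorrelatedness the
demixing derivation assumes.

Default problem sizes (M=10 DOFs, L=20 trials, T=100 samples over 1 s,
P=3 primitives, delays within +-15% of the trial) are desk-scale choices
representative of multi-muscle EMG recordings; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fourier import analyze, reconstruct
from .gauge import canonicalize
from .models import (SpaceByTimeParams, SpatialParams, SpatiotemporalParams,
                     TemporalParams, TrialDataset, TrialMeta,
                     synthesize_space_by_time, synthesize_spatial,
                     synthesize_spatiotemporal, synthesize_temporal)

__all__ = [
    "SimulationSpec",
    "GroundTruthBundle",
    "make_sources",
    "make_parameters",
    "add_noise",
    "synthesize_truth",
    "generate_benchmark",
    "MODEL_KINDS",
    "NOISE_LEVELS",
]

MODEL_KINDS = ("spatial", "temporal", "temporal_delays", "spatiotemporal",
               "space_by_time")
#: noise levels of the benchmark protocol (fractions of signal magnitude)
NOISE_LEVELS = (0.0, 0.05, 0.15, 0.25, 0.35)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one benchmark simulation."""

    model_kind: str = "temporal_delays"
    nonneg: bool = False
    M: int = 10
    L: int = 20
    T: int = 100
    duration_s: float = 1.0
    P: int = 3
    P_tp: int = 3
    P_sp: int = 3
    K_gen: int = 8
    noise_level: float = 0.0
    n_realizations: int = 20
    seed: int = 0
    delay_frac: float = 0.15       # delays drawn uniform over +-delay_frac * T_s
    max_source_corr: float = 0.6

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if not self.K_gen < self.T / 2:
            raise ValueError("K_gen must be below the Nyquist limit T/2")
        if self.model_kind == "space_by_time" and not self.nonneg:
            object.__setattr__(self, "nonneg", True)

    @property
    def n_primitives(self) -> int:
        return self.P_tp if self.model_kind == "space_by_time" else self.P


@dataclass
class GroundTruthBundle:
    """One simulated dataset together with its generating parameters."""

    dataset: TrialDataset
    truth: object
    spec: SimulationSpec
    realization: int
    noise: np.ndarray  # stored so truth + noise reproduces dataset exactly


def make_sources(n: int, T: int, K_gen: int, nonneg: bool,
                 rng: np.random.Generator, duration_s: float = 1.0,
                 max_corr: float = 0.6, max_attempts: int = 400,
                 lag_invariant: bool = False) -> np.ndarray:
    """Draw ``n`` unit-RMS band-limited source waveforms of length ``T``.

    Unconstrained sources have zero mean and random coefficients with a 1/k
    amplitude decay up to ``K_gen``.  Non-negative sources are squares of
    half-band signals (exactly band-limited, >= 0).  Any candidate whose
    absolute time-domain correlation with an accepted source exceeds
    ``max_corr`` is redrawn.  With ``lag_invariant=True`` the correlation is
    maximized over all circular lags first — the appropriate notion of
    dissimilarity when the sources enter the mixture with free delays.
    """
    if not K_gen < T / 2:
        raise ValueError("K_gen must be below the Nyquist limit")
    out = np.empty((n, T))
    kept = 0
    attempts = 0
    while kept < n:
        if attempts > max_attempts * n:
            raise RuntimeError(
                "could not draw sufficiently uncorrelated sources; "
                "try a larger K_gen or a looser max_corr")
        attempts += 1
        x = _one_source(T, K_gen, nonneg, rng, duration_s)
        ok = True
        for j in range(kept):
            if _abs_corr(out[j], x, lag_invariant) > max_corr:
                ok = False
                break
        if ok:
            out[kept] = x
            kept += 1
    return out


def _abs_corr(a: np.ndarray, b: np.ndarray, lag_invariant: bool) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        return 0.0
    if not lag_invariant:
        return float(abs(ac @ bc) / denom)
    cc = np.fft.irfft(np.fft.rfft(ac) * np.conj(np.fft.rfft(bc)), n=a.size)
    return float(np.max(np.abs(cc)) / denom)


def _one_source(T: int, K_gen: int, nonneg: bool, rng: np.random.Generator,
                duration_s: float) -> np.ndarray:
    if nonneg:
        K_half = max(1, K_gen // 2)
        coeffs = np.zeros(K_half + 1, dtype=complex)
        coeffs[0] = rng.normal(0, 0.5)
        k = np.arange(1, K_half + 1)
        coeffs[1:] = (rng.normal(size=K_half) + 1j * rng.normal(size=K_half)) / k
        g = reconstruct(_series(coeffs, duration_s), T)
        x = g * g  # exactly band-limited to 2 * K_half <= K_gen, and >= 0
    else:
        coeffs = np.zeros(K_gen + 1, dtype=complex)
        k = np.arange(1, K_gen + 1)
        coeffs[1:] = (rng.normal(size=K_gen) + 1j * rng.normal(size=K_gen)) / k
        x = reconstruct(_series(coeffs, duration_s), T)
    r = np.sqrt(np.mean(x * x))
    if r < 1e-12:
        return _one_source(T, K_gen, nonneg, rng, duration_s)
    return x / r


def _series(coeffs: np.ndarray, duration_s: float):
    from .fourier import FourierSeries
    return FourierSeries(coeffs, duration_s)


def make_parameters(spec: SimulationSpec, rng: np.random.Generator):
    """Draw gauge-normalized ground-truth parameters for ``spec``."""
    M, L, T, P = spec.M, spec.L, spec.T, spec.P
    lo = 0.0 if spec.nonneg else -1.0
    tau_half = spec.delay_frac * spec.duration_s

    if spec.model_kind == "spatial":
        W = rng.uniform(lo, 1.0, size=(M, P))
        C = np.empty((L, P, T))
        for l in range(L):
            C[l] = make_sources(P, T, spec.K_gen, spec.nonneg, rng,
                                spec.duration_s, spec.max_source_corr)
        params = SpatialParams(W, C, spec.nonneg)
    elif spec.model_kind in ("temporal", "temporal_delays"):
        S = make_sources(P, T, spec.K_gen, spec.nonneg, rng,
                         spec.duration_s, spec.max_source_corr,
                         lag_invariant=(spec.model_kind == "temporal_delays"))
        C = rng.uniform(lo, 1.0, size=(L, M, P))
        if spec.model_kind == "temporal_delays":
            Tau = rng.uniform(-tau_half, tau_half, size=(L, M, P))
        else:
            Tau = np.zeros((L, M, P))
        params = TemporalParams(S, C, Tau, spec.nonneg)
    elif spec.model_kind == "spatiotemporal":
        comps = make_sources(P * M, T, spec.K_gen, spec.nonneg, rng,
                             spec.duration_s, spec.max_source_corr)
        Wt = comps.reshape(P, M, T)
        C = rng.uniform(0.2 if spec.nonneg else lo, 1.0, size=(L, P))
        Tau = rng.uniform(-tau_half, tau_half, size=(L, P))
        params = SpatiotemporalParams(Wt, C, Tau, spec.nonneg)
    elif spec.model_kind == "space_by_time":
        W = rng.uniform(0.0, 1.0, size=(M, spec.P_sp))
        S = make_sources(spec.P_tp, T, spec.K_gen, True, rng,
                         spec.duration_s, spec.max_source_corr,
                         lag_invariant=True)
        C = rng.uniform(0.0, 1.0, size=(L, spec.P_tp, spec.P_sp))
        Tau = rng.uniform(-tau_half, tau_half, size=(L, spec.P_tp, spec.P_sp))
        params = SpaceByTimeParams(W, S, C, Tau)
    else:  # pragma: no cover - guarded by SimulationSpec
        raise ValueError(spec.model_kind)
    return canonicalize(params)


def synthesize_truth(params, spec: SimulationSpec) -> TrialDataset:
    """Noise-free forward synthesis of a truth parameter set."""
    meta = TrialMeta(duration_s=spec.duration_s, T=spec.T)
    if isinstance(params, SpatialParams):
        ds = synthesize_spatial(params, meta)
    elif isinstance(params, TemporalParams):
        ds = synthesize_temporal(params, meta)
    elif isinstance(params, SpatiotemporalParams):
        ds = synthesize_spatiotemporal(params, meta)
    elif isinstance(params, SpaceByTimeParams):
        ds = synthesize_space_by_time(params, meta)
    else:
        raise TypeError(type(params).__name__)
    if spec.nonneg:
        # delayed non-negative models are non-negative up to float dust
        data = np.clip(ds.data, 0.0, None)
        ds = TrialDataset(data, ds.duration_s, ds.dof_labels, nonneg_domain=True)
    return ds


def _noise_for(data: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    if level == 0:
        return np.zeros_like(data)
    rms = np.sqrt(np.mean(data**2))
    std = level * (np.abs(data) + 0.05 * rms)
    return rng.normal(0.0, 1.0, size=data.shape) * std


def add_noise(dataset: TrialDataset, level: float,
              rng: np.random.Generator) -> TrialDataset:
    """Corrupt a dataset with signal-dependent Gaussian noise.

    Per sample, ``std = level * (|x| + 0.05 * RMS(x))`` — noise grows with
    activation, with a small floor so silent samples are not noise-free.
    Non-negative datasets are clipped at zero after corruption.  ``level=0``
    returns the dataset unchanged.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return dataset
    noisy = dataset.data + _noise_for(dataset.data, level, rng)
    if dataset.nonneg_domain:
        noisy = np.clip(noisy, 0.0, None)
    return TrialDataset(noisy, dataset.duration_s, list(dataset.dof_labels),
                        dataset.nonneg_domain)


def generate_benchmark(spec: SimulationSpec) -> list[GroundTruthBundle]:
    """Generate ``spec.n_realizations`` independent ground-truth bundles.

    Fully reproducible: realization ``i`` uses the PCG64 stream seeded with
    ``[spec.seed, i]``.
    """
    bundles = []
    for i in range(spec.n_realizations):
        rng = np.random.default_rng([spec.seed, i])
        truth = make_parameters(spec, rng)
        clean = synthesize_truth(truth, spec)
        noise = _noise_for(clean.data, spec.noise_level, rng)
        data = clean.data + noise
        if clean.nonneg_domain:
            data = np.clip(data, 0.0, None)
        dataset = TrialDataset(data, clean.duration_s, list(clean.dof_labels),
                               clean.nonneg_domain)
        # store the *effective* noise (after clipping) so that
        # synthesize_truth(truth) + noise == dataset exactly
        bundles.append(GroundTruthBundle(dataset, truth, spec, i,
                                         data - clean.data))
    return bundles
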