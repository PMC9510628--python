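"""Truncated Fourier representation of band-limited periodic signals.

Smooth motor signals (EMG envelopes, joint-angle trajectories) sampled over a
trial of duration ``T_s`` are represented by the first ``K + 1`` complex
Fourier coefficients of the periodic basis ``exp(2*pi*i*k*t/T_s)``.  Because
the signals are real, the negative-frequency coefficients are implied by
conjugate symmetry and only ``k >= 0`` is stored.  Time delays act as phase
ramps ``exp(-2*pi*i*k*tau/T_s)``, which makes delayed mixtures linear in the
coefficients and is the calculus the demixing engine is built on.

Conventions
-----------
* The observation window is one period: a trial of ``T`` samples covers
  ``t_n = n * T_s / T`` for ``n = 0..T-1``.
* Delays are circular with period ``T_s``; ``tau = T_s`` is the identity.
* The shift factor is ``exp(-2*pi*i*k*tau/T_s)`` (so that a delay by one full
  period is the identity for every harmonic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FourierSeries",
    "analyze",
    "reconstruct",
    "apply_delay",
    "magnitude_spectrum",
    "phase_spectrum",
    "circular_shift",
    "delay_phase_factors",
    "choose_num_harmonics",
    "wrap_delay",
]


@dataclass(frozen=True)
class FourierSeries:
    """Coefficients ``c_k`` for ``k = 0..K`` of a real band-limited signal.

    Parameters
    ----------
    coeffs : complex array, shape (K + 1,)
        ``coeffs[0]`` is the (real) mean; ``coeffs[k]`` for ``k >= 1`` is the
        complex amplitude of ``exp(2*pi*i*k*t/T_s)``.  The implied
        negative-frequency coefficient is ``conj(coeffs[k])``.
    duration_s : float
        Period / trial duration ``T_s`` in seconds.
    """

    coeffs: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=complex)
        if coeffs.ndim != 1 or coeffs.size < 1:
            raise ValueError("coeffs must be a 1-D array with at least one entry")
        if not np.all(np.isfinite(coeffs.view(float))):
            raise ValueError("coeffs must be finite")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def K(self) -> int:
        return self.coeffs.size - 1


def analyze(signal: np.ndarray, K: int, duration_s: float) -> FourierSeries:
    """Project a sampled signal onto the first ``K + 1`` Fourier harmonics.

    The window is assumed to span exactly one period, so the least-squares
    projection coincides with the rescaled DFT: ``c_k = DFT(x)[k] / T``.

    Raises
    ------
    ValueError
        If ``K >= T/2`` (harmonics at or above the Nyquist limit alias).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    T = x.size
    if not 1 <= K:
        raise ValueError("K must be >= 1")
    if K >= T / 2:
        raise ValueError(f"K={K} reaches the Nyquist limit for T={T} samples (aliasing)")
    coeffs = np.fft.rfft(x)[: K + 1] / T
    return FourierSeries(coeffs, duration_s)


def reconstruct(series: FourierSeries, T: int) -> np.ndarray:
    """Evaluate the truncated expansion at ``T`` evenly spaced sample times."""
    K = series.K
    if T <= 2 * K:
        raise ValueError(f"need T > 2K to reconstruct (T={T}, K={K})")
    spectrum = np.zeros(T // 2 + 1, dtype=complex)
    spectrum[: K + 1] = series.coeffs * T
    return np.fft.irfft(spectrum, n=T)


def apply_delay(series: FourierSeries, tau_s: float) -> FourierSeries:
    """Delay the represented signal by ``tau_s`` seconds (circularly).

    ``coeffs[k] -> coeffs[k] * exp(-2*pi*i*k*tau_s/T_s)``, the exact circular
    shift of the band-limited reconstruction.  Non-integer-sample delays are
    permitted (pure phase ramp).
    """
    if not np.isfinite(tau_s):
        raise ValueError("tau_s must be finite")
    k = np.arange(series.K + 1)
    phase = np.exp(-2j * np.pi * k * tau_s / series.duration_s)
    return FourierSeries(series.coeffs * phase, series.duration_s)


def magnitude_spectrum(series: FourierSeries) -> np.ndarray:
    """Elementwise magnitudes ``|c_k|`` of the stored coefficients."""
    return np.abs(series.coeffs)


def phase_spectrum(series: FourierSeries) -> np.ndarray:
    """Elementwise phases ``angle(c_k)`` in radians."""
    return np.angle(series.coeffs)


def delay_phase_factors(K: int, tau_s: np.ndarray, duration_s: float) -> np.ndarray:
    """Phase ramp ``exp(-2*pi*i*k*tau/T_s)`` for ``k = 0..K``.

    ``tau_s`` may be any array; one trailing axis of length ``K + 1`` is added.
    """
    tau = np.asarray(tau_s, dtype=float)
    k = np.arange(K + 1)
    return np.exp(-2j * np.pi * np.multiply.outer(tau, k) / duration_s)


def circular_shift(x: np.ndarray, tau_s: float, duration_s: float) -> np.ndarray:
    """Circularly delay a sampled signal by ``tau_s`` seconds.

    Implemented as a phase ramp on the full DFT, so integer-sample delays
    reduce exactly to ``np.roll`` and fractional delays are band-limited
    interpolation.  Operates on the last axis.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    spectrum = np.fft.rfft(x, axis=-1)
    k = np.arange(spectrum.shape[-1])
    spectrum = spectrum * np.exp(-2j * np.pi * k * tau_s / duration_s)
    return np.fft.irfft(spectrum, n=T, axis=-1)


def wrap_delay(tau_s: np.ndarray | float, duration_s: float):
    """Canonicalize delays modulo ``T_s`` into ``[-T_s/2, T_s/2)``."""
    return np.mod(np.asarray(tau_s, dtype=float) + duration_s / 2, duration_s) - duration_s / 2


def choose_num_harmonics(
    signals: np.ndarray,
    energy_fraction: float = 0.9999,
    cap_fraction: float = 0.25,
) -> int:
    """Pick the smallest K whose truncation keeps ``energy_fraction`` of energy.

    ``signals`` is ``(n_signals, T)``.  The retained fraction is averaged over
    signals; the result is capped at ``floor(T * cap_fraction)`` and floored
    at 1.  Zero-energy input returns 1.
    """
    Y = np.atleast_2d(np.asarray(signals, dtype=float))
    T = Y.shape[-1]
    spectrum = np.fft.rfft(Y, axis=-1) / T
    power = np.abs(spectrum) ** 2
    weights = np.full(power.shape[-1], 2.0)
    weights[0] = 1.0
    if T % 2 == 0:
        weights[-1] = 1.0
    power = power * weights
    total = power.sum(axis=-1)
    live = total > 0
    if not np.any(live):
        return 1
    frac = np.cumsum(power[live], axis=-1) / total[live, None]
    mean_frac = frac.mean(axis=0)
    cap = max(1, int(np.floor(T * cap_fraction)))
    qualifying = np.nonzero(mean_frac >= energy_fraction)[0]
    K = int(qualifying[0]) if qualifying.size else mean_frac.size - 1
    return int(np.clip(K, 1, cap))
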