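"""Fit quality and ground-truth recovery metrics.

Two families of measures are provided:

* the fraction of explained variance ``R^2 = 1 - SS_res / SS_tot`` (sum of
  squares about the grand mean of the data, the centered convention);
* the normalized similarity ``S_N`` between estimated and ground-truth
  quantities.  Raw similarities (delay-invariant normalized
  cross-correlation for waveforms, cosine for spatial vectors) are computed
  after optimal component matching (Hungarian assignment) and rescaled by
  the chance level: ``S_N = (S - S_base) / (1 - S_base)``, where ``S_base``
  is the Monte-Carlo mean matched similarity between independent random
  parameter draws of the same model.  ``S_N`` is 1 for perfect recovery and
  0 (after clamping) for chance-level estimates.

Delay recovery is scored after removing one global per-source delay offset
(the shift gauge of anechoic mixtures) as ``1 - RMS_circular / (T_s / 4)``,
clamped to [0, 1]; the raw circular RMS error is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import (SpaceByTimeParams, SpatialParams, SpatiotemporalParams,
                     TemporalParams)
from .simulate import GroundTruthBundle, SimulationSpec, make_parameters

__all__ = [
    "EvaluationReport",
    "explained_variance",
    "temporal_similarity",
    "spatial_similarity",
    "match_components",
    "baseline_similarity",
    "normalized_similarity",
    "delay_similarity",
    "evaluate",
]


@dataclass
class EvaluationReport:
    """Recovery scores for one fitted model against its ground truth."""

    r2: float
    sn_primitives: float | None = None
    sn_weights: float | None = None
    sn_delays: float | None = None
    sn_primitives_temporal: float | None = None  # space-by-time only
    sn_primitives_spatial: float | None = None   # space-by-time only
    delay_rms_samples: float | None = None
    matching: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "sn_primitives": self.sn_primitives,
            "sn_weights": self.sn_weights,
            "sn_delays": self.sn_delays,
            "sn_primitives_temporal": self.sn_primitives_temporal,
            "sn_primitives_spatial": self.sn_primitives_spatial,
            "delay_rms_samples": self.delay_rms_samples,
            "matching": {k: np.asarray(v).tolist() for k, v in self.matching.items()},
            "baseline": self.baseline,
            "raw": self.raw,
        }


# ---------------------------------------------------------------------------
# elementary measures


def explained_variance(data: np.ndarray, reconstruction: np.ndarray,
                       centered: bool = True) -> float:
    """Fraction of explained variance, ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the grand mean of the data (the stricter,
    standard convention); pass ``centered=False`` for the uncentered variant
    used in parts of the EMG literature.  A zero-variance dataset scores 1
    when reconstructed exactly and ``-inf`` otherwise.
    """
    data = np.asarray(data, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if data.shape != reconstruction.shape:
        raise ValueError("data and reconstruction must have the same shape")
    mean = data.mean() if centered else 0.0
    ss_tot = float(np.sum((data - mean) ** 2))
    ss_res = float(np.sum((data - reconstruction) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def temporal_similarity(a: np.ndarray, b: np.ndarray, signed: bool = False) -> float:
    """Max-over-circular-lag normalized cross-correlation of two waveforms.

    Accepts 1-D waveforms or (channels, T) arrays (a common lag is applied
    to all channels).  Mean-centered, so the measure is invariant to offsets
    as well as to circular time shifts; with ``signed=False`` the absolute
    correlation is used (sign-gauge invariance for unconstrained models).
    """
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("waveforms must share a shape")
    A = A - A.mean()
    B = B - B.mean()
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        return 0.0
    T = A.shape[-1]
    corr = np.fft.irfft(np.sum(np.fft.rfft(A, axis=-1)
                               * np.conj(np.fft.rfft(B, axis=-1)), axis=0), n=T)
    corr = corr / (na * nb)
    return float(np.max(corr if signed else np.abs(corr)))


def spatial_similarity(a: np.ndarray, b: np.ndarray, signed: bool = False) -> float:
    """Cosine similarity of two spatial vectors (abs unless ``signed``)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    c = float(a @ b / (na * nb))
    return c if signed else abs(c)


def match_components(est: list, truth: list, similarity_fn) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment of estimated to ground-truth components.

    Returns ``(perm, scores)`` where ``est[perm[i]]`` is matched to
    ``truth[i]`` and ``scores[i]`` is the corresponding raw similarity; the
    permutation maximizes the total similarity (Hungarian algorithm).
    """
    if len(est) != len(truth):
        raise ValueError("component counts differ")
    n = len(truth)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = similarity_fn(est[j], truth[i])
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty(n, dtype=int)
    perm[rows] = cols
    scores = S[np.arange(n), perm]
    return perm, scores


def normalized_similarity(raw_S: float, S_base: float, clamp: bool = True) -> float:
    """Rescale a raw similarity so chance maps to 0 and perfection to 1."""
    if S_base >= 1.0:
        raise ValueError("degenerate baseline: S_base >= 1")
    s = (raw_S - S_base) / (1.0 - S_base)
    return float(np.clip(s, 0.0, 1.0)) if clamp else float(s)


def delay_similarity(est_delays: np.ndarray, true_delays: np.ndarray,
                     duration_s: float, source_axis: int = -1,
                     scale_fraction: float = 0.25,
                     weights: np.ndarray | None = None) -> tuple[float, float]:
    """Delay-recovery score and circular RMS error (in seconds).

    The circular error is computed modulo ``T_s``; one global offset per
    source (along ``source_axis``) is removed first — shifting a source and
    all of its delays together is a gauge freedom.  The score is
    ``1 - RMS / (scale_fraction * T_s)``, clamped to [0, 1].

    ``weights`` (same shape, e.g. the magnitudes of the true mixing weights)
    turn both the offset and the RMS into weighted statistics: the delay of
    a component that is mixed with weight ~0 is unidentifiable and should
    not dominate the error.
    """
    est = np.asarray(est_delays, dtype=float)
    true = np.asarray(true_delays, dtype=float)
    if est.shape != true.shape:
        raise ValueError("delay arrays must share a shape")
    if weights is None:
        wts = np.ones_like(est)
    else:
        wts = np.abs(np.asarray(weights, dtype=float))
        if wts.shape != est.shape:
            raise ValueError("weights must match the delay arrays")
        if wts.sum() == 0:
            wts = np.ones_like(est)
    diff = est - true
    ang = 2 * np.pi * diff / duration_s
    z = np.moveaxis(np.exp(1j * ang), source_axis, -1)
    wm = np.moveaxis(wts, source_axis, -1)
    axes = tuple(range(z.ndim - 1))
    offset = np.angle(np.sum(wm * z, axis=axes))  # per-source circular mean
    resid = np.angle(z * np.exp(-1j * offset))
    rms_ang = np.sqrt(np.sum(wm * resid**2) / np.sum(wm))
    rms = float(rms_ang) * duration_s / (2 * np.pi)
    score = float(np.clip(1.0 - rms / (scale_fraction * duration_s), 0.0, 1.0))
    return score, rms


# ---------------------------------------------------------------------------
# quantity extraction per model kind


def _components(params) -> dict:
    """Primitive/weight/delay component lists of a parameter object."""
    if isinstance(params, SpatialParams):
        return {
            "primitives": [params.W[:, p] for p in range(params.P)],
            "primitive_kind": "spatial",
            "weights": [params.C[:, p, :] for p in range(params.P)],
            "weight_kind": "temporal",
            "signed": not params.nonneg,
        }
    if isinstance(params, TemporalParams):
        out = {
            "primitives": [params.S[p] for p in range(params.P)],
            "primitive_kind": "temporal",
            "weights": [params.C[:, :, p] for p in range(params.P)],
            "weight_kind": "spatial",
            "signed": not params.nonneg,
        }
        if params.has_delays:
            out["delays"] = params.Tau
            out["delay_axis"] = -1
        return out
    if isinstance(params, SpatiotemporalParams):
        return {
            "primitives": [params.Wt[p] for p in range(params.P)],
            "primitive_kind": "temporal",
            "weights": [params.C[:, p] for p in range(params.P)],
            "weight_kind": "spatial",
            "delays": params.Tau,
            "delay_axis": -1,
            "signed": not params.nonneg,
        }
    if isinstance(params, SpaceByTimeParams):
        return {
            "primitives_temporal": [params.S[p] for p in range(params.P_tp)],
            "primitives_spatial": [params.W[:, q] for q in range(params.P_sp)],
            "weights": params.C,
            "delays": params.Tau,
            "signed": False,
        }
    raise TypeError(type(params).__name__)


def _matched_mean(est_list, truth_list, kind: str) -> tuple[np.ndarray, float, np.ndarray]:
    fn = temporal_similarity if kind == "temporal" else spatial_similarity
    perm, scores = match_components(est_list, truth_list, fn)
    return perm, float(np.mean(scores)), scores


def baseline_similarity(spec: SimulationSpec, quantity: str = "primitives",
                        n_pairs: int = 100, seed: int = 0) -> float:
    """Monte-Carlo chance level of the matched similarity for ``spec``.

    Draws ``n_pairs`` independent pairs of parameter sets from the model and
    averages the matched raw similarity of the requested quantity
    (``primitives``, ``weights``, ``primitives_temporal``,
    ``primitives_spatial``).
    """
    vals = []
    for i in range(n_pairs):
        pa = make_parameters(spec, np.random.default_rng([seed, 2 * i]))
        pb = make_parameters(spec, np.random.default_rng([seed, 2 * i + 1]))
        ca, cb = _components(pa), _components(pb)
        if quantity in ("primitives", "weights"):
            kind = ca["primitive_kind" if quantity == "primitives" else "weight_kind"]
            _, mean, _ = _matched_mean(ca[quantity], cb[quantity], kind)
        elif quantity == "primitives_temporal":
            _, mean, _ = _matched_mean(ca[quantity], cb[quantity], "temporal")
        elif quantity == "primitives_spatial":
            _, mean, _ = _matched_mean(ca[quantity], cb[quantity], "spatial")
        elif quantity == "weights_sbt":
            perm_t, _, _ = _matched_mean(ca["primitives_temporal"],
                                         cb["primitives_temporal"], "temporal")
            perm_s, _, _ = _matched_mean(ca["primitives_spatial"],
                                         cb["primitives_spatial"], "spatial")
            Wa = ca["weights"][:, perm_t][:, :, perm_s]
            mean = spatial_similarity(Wa, cb["weights"])
        else:
            raise ValueError(quantity)
        vals.append(mean)
    return float(np.mean(vals))


def evaluate(fit, truth: GroundTruthBundle, n_baseline_pairs: int = 100,
             seed: int = 0, clamp: bool = True,
             baselines: dict | None = None) -> EvaluationReport:
    """Score a :class:`fada.api.ModelFit` against its generating bundle.

    Components are matched by similarity before scoring, so the report is
    invariant to the permutation/sign/scale gauge of the fit.  Pass a
    ``baselines`` dict (quantity name -> chance level) to reuse Monte-Carlo
    baselines across evaluations of the same simulation conditions.
    """
    spec = truth.spec
    baselines = baselines if baselines is not None else {}

    def _base(quantity):
        if quantity not in baselines:
            baselines[quantity] = baseline_similarity(
                spec, quantity, n_baseline_pairs, seed)
        return baselines[quantity]
    est = _components(fit.params)
    tru = _components(truth.truth)
    report = EvaluationReport(r2=fit.r2)
    T_s = spec.duration_s
    dt = T_s / spec.T

    if spec.model_kind == "space_by_time":
        perm_t, raw_t, sc_t = _matched_mean(est["primitives_temporal"],
                                            tru["primitives_temporal"], "temporal")
        perm_s, raw_s, sc_s = _matched_mean(est["primitives_spatial"],
                                            tru["primitives_spatial"], "spatial")
        base_t = _base("primitives_temporal")
        base_s = _base("primitives_spatial")
        sn_t = normalized_similarity(raw_t, base_t, clamp)
        sn_s = normalized_similarity(raw_s, base_s, clamp)
        report.sn_primitives_temporal = sn_t
        report.sn_primitives_spatial = sn_s
        report.sn_primitives = 0.5 * (sn_t + sn_s)
        W_est = est["weights"][:, perm_t][:, :, perm_s]
        raw_w = spatial_similarity(W_est, tru["weights"])
        base_w = _base("weights_sbt")
        report.sn_weights = normalized_similarity(raw_w, base_w, clamp)
        tau_est = est["delays"][:, perm_t][:, :, perm_s]
        score, rms = delay_similarity(tau_est, tru["delays"], T_s, source_axis=1,
                                      weights=np.abs(tru["weights"]))
        report.sn_delays = score
        report.delay_rms_samples = rms / dt
        report.matching = {"temporal": perm_t, "spatial": perm_s}
        report.baseline = {"primitives_temporal": base_t,
                           "primitives_spatial": base_s, "weights": base_w}
        report.raw = {"primitives_temporal": raw_t, "primitives_spatial": raw_s,
                      "weights": raw_w}
        return report

    kind_p = tru["primitive_kind"]
    kind_w = tru["weight_kind"]
    perm, raw_p, scores = _matched_mean(est["primitives"], tru["primitives"], kind_p)
    base_p = _base("primitives")
    report.sn_primitives = normalized_similarity(raw_p, base_p, clamp)
    est_w = [est["weights"][p] for p in perm]
    raw_w = float(np.mean([
        (temporal_similarity if kind_w == "temporal" else spatial_similarity)(w_e, w_t)
        for w_e, w_t in zip(est_w, tru["weights"])]))
    base_w = _base("weights")
    report.sn_weights = normalized_similarity(raw_w, base_w, clamp)
    if "delays" in tru:
        tau_est = np.take(est.get("delays"), perm, axis=-1)
        wts = np.stack([np.abs(w) for w in tru["weights"]], axis=-1)
        score, rms = delay_similarity(tau_est, tru["delays"], T_s, source_axis=-1,
                                      weights=wts)
        report.sn_delays = score
        report.delay_rms_samples = rms / dt
    report.matching = {"primitives": perm}
    report.baseline = {"primitives": base_p, "weights": base_w}
    report.raw = {"primitives": raw_p, "weights": raw_w}
    return report
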