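"""Thin adapters to library factorization baselines.

These wrap scikit-learn's FastICA and NMF so that the benchmark runner can
compare the unified demixing engine against the field's standard
model-specific extraction methods on the synchronous (zero-delay) models —
the only models those methods apply to.  They are labeled adapters, not
re-implementations, and are kept strictly outside the engine.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import NMF, FastICA

from .gauge import canonicalize
from .models import SpatialParams, TemporalParams, TrialDataset

__all__ = ["fastica_fit", "nmf_fit", "BASELINE_ALGORITHMS"]


def _spatial_stack(dataset: TrialDataset) -> np.ndarray:
    """(M, L*T) matrix whose columns are time samples across trials."""
    return np.concatenate(list(dataset.data), axis=1)


def fastica_fit(dataset: TrialDataset, model_kind: str, P: int,
                seed: int = 0) -> object:
    """FastICA baseline for the unconstrained synchronous models."""
    L, M, T = dataset.L, dataset.M, dataset.T
    if model_kind == "spatial":
        X = _spatial_stack(dataset)  # = W @ C_stack
        ica = FastICA(n_components=P, random_state=seed, max_iter=1000,
                      tol=1e-6)
        C_stack = ica.fit_transform(X.T).T  # (P, L*T)
        W = ica.mixing_                     # (M, P)
        C = C_stack.reshape(P, L, T).transpose(1, 0, 2)
        return canonicalize(SpatialParams(W, C, nonneg=False))
    if model_kind == "temporal":
        X = dataset.data.reshape(L * M, T)  # = C_flat @ S
        ica = FastICA(n_components=P, random_state=seed, max_iter=1000,
                      tol=1e-6)
        S = ica.fit_transform(X.T).T        # (P, T)
        C = ica.mixing_.reshape(L, M, P)
        return canonicalize(TemporalParams(S, C, np.zeros((L, M, P)),
                                           nonneg=False))
    raise ValueError("fastICA adapter applies to synchronous models only")


def nmf_fit(dataset: TrialDataset, model_kind: str, P: int,
            seed: int = 0) -> object:
    """Multiplicative-update NMF baseline for non-negative synchronous models."""
    L, M, T = dataset.L, dataset.M, dataset.T
    if model_kind == "spatial":
        X = np.clip(_spatial_stack(dataset), 0, None)
        model = NMF(n_components=P, init="nndsvda", solver="mu",
                    max_iter=600, random_state=seed)
        W = model.fit_transform(X)           # (M, P)
        C = model.components_.reshape(P, L, T).transpose(1, 0, 2)
        return canonicalize(SpatialParams(W, C, nonneg=True))
    if model_kind == "temporal":
        X = np.clip(dataset.data.reshape(L * M, T), 0, None)
        model = NMF(n_components=P, init="nndsvda", solver="mu",
                    max_iter=600, random_state=seed)
        C = model.fit_transform(X).reshape(L, M, P)
        S = model.components_                # (P, T)
        return canonicalize(TemporalParams(S, C, np.zeros((L, M, P)),
                                           nonneg=True))
    raise ValueError("NMF adapter applies to synchronous models only")


#: adapter registry: algorithm name -> (callable, applicable nonneg flag)
BASELINE_ALGORITHMS = {
    "fastica": (fastica_fit, False),
    "nmf": (nmf_fit, True),
}
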