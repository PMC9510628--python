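"""File formats and run configuration.

Datasets travel as long-form CSV (``trial,time_s,<dof_1>,...,<dof_M>``) with
a JSON metadata sidecar (``<stem>.meta.json``: duration, non-negativity
flag, labels).  Parameter sets, fits and evaluation reports use a JSON
envelope with named row-major arrays and a ``model_kind`` tag.  Run
configurations are validated with pydantic models whose JSON schemas are
shipped under ``fada/schemas``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .engine import FitOptions
from .models import (AnechoicParams, SpaceByTimeParams, SpatialParams,
                     SpatiotemporalParams, TemporalParams, TrialDataset)

__all__ = [
    "read_dataset",
    "write_dataset",
    "params_to_dict",
    "params_from_dict",
    "write_fit",
    "read_fit",
    "write_report",
    "SimulateConfig",
    "FitConfig",
    "BenchConfig",
    "export_schemas",
]


# ---------------------------------------------------------------------------
# datasets


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write long-form CSV plus the metadata sidecar."""
    path = Path(path)
    L, M, T = dataset.L, dataset.M, dataset.T
    t = np.arange(T) * dataset.duration_s / T
    frames = []
    for l in range(L):
        df = pd.DataFrame(dataset.data[l].T, columns=list(dataset.dof_labels))
        df.insert(0, "time_s", t)
        df.insert(0, "trial", l)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {"duration_s": dataset.duration_s,
            "nonneg_domain": bool(dataset.nonneg_domain),
            "dof_labels": list(dataset.dof_labels)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_dataset(path) -> TrialDataset:
    """Parse the long-form CSV + sidecar back into a :class:`TrialDataset`.

    Errors on ragged trials, non-monotone time within a trial, or NaNs.  A
    missing sidecar falls back to defaults (duration inferred from the time
    column) with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("dataset contains NaNs")
    if "trial" not in df.columns or "time_s" not in df.columns:
        raise ValueError("expected columns 'trial' and 'time_s'")
    dof_cols = [c for c in df.columns if c not in ("trial", "time_s")]
    trials = sorted(df["trial"].unique())
    blocks = []
    T = None
    for l in trials:
        sub = df[df["trial"] == l]
        tvals = sub["time_s"].to_numpy()
        if np.any(np.diff(tvals) <= 0):
            raise ValueError(f"non-monotone time in trial {l}")
        if T is None:
            T = len(sub)
        elif len(sub) != T:
            raise ValueError("ragged trials: lengths differ")
        blocks.append(sub[dof_cols].to_numpy().T)
    data = np.stack(blocks)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        duration = float(meta["duration_s"])
        nonneg = bool(meta.get("nonneg_domain", False))
        labels = meta.get("dof_labels", dof_cols)
    else:
        warnings.warn(f"missing sidecar {side.name}; using defaults")
        tvals = df[df["trial"] == trials[0]]["time_s"].to_numpy()
        dt = float(np.median(np.diff(tvals))) if T > 1 else 1.0
        duration = dt * T
        nonneg = bool(np.all(data >= 0))
        labels = dof_cols
    return TrialDataset(data, duration, list(labels), nonneg)


# ---------------------------------------------------------------------------
# parameter envelopes


_KIND_OF_TYPE = {
    SpatialParams: "spatial",
    TemporalParams: "temporal",
    SpatiotemporalParams: "spatiotemporal",
    SpaceByTimeParams: "space_by_time",
    AnechoicParams: "anechoic",
}


def params_to_dict(params) -> dict:
    """JSON-ready envelope with a ``model_kind`` tag and named arrays."""
    kind = _KIND_OF_TYPE.get(type(params))
    if kind is None:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    if kind == "temporal" and params.has_delays:
        kind = "temporal_delays"
    out = {"model_kind": kind, "arrays": {}}
    for name, value in vars(params).items():
        if isinstance(value, np.ndarray):
            out["arrays"][name] = {"shape": list(value.shape),
                                   "data": value.ravel().tolist()}
        else:
            out[name] = value
    return out


def params_from_dict(doc: dict):
    """Inverse of :func:`params_to_dict`."""
    kind = doc["model_kind"]
    arrays = {name: np.asarray(spec["data"], dtype=float).reshape(spec["shape"])
              for name, spec in doc["arrays"].items()}
    extra = {k: v for k, v in doc.items() if k not in ("model_kind", "arrays")}
    if kind == "spatial":
        return SpatialParams(arrays["W"], arrays["C"], bool(extra.get("nonneg", False)))
    if kind in ("temporal", "temporal_delays"):
        return TemporalParams(arrays["S"], arrays["C"], arrays["Tau"],
                              bool(extra.get("nonneg", False)))
    if kind == "spatiotemporal":
        return SpatiotemporalParams(arrays["Wt"], arrays["C"], arrays["Tau"],
                                    bool(extra.get("nonneg", True)))
    if kind == "space_by_time":
        return SpaceByTimeParams(arrays["W"], arrays["S"], arrays["C"], arrays["Tau"])
    if kind == "anechoic":
        return AnechoicParams(arrays["F"], arrays["A"], arrays["Tau"],
                              float(extra.get("duration_s", 1.0)))
    raise ValueError(f"unknown model_kind {kind!r}")


def write_fit(model_fit, path) -> None:
    """Serialize a :class:`fada.api.ModelFit` (params + fit block)."""
    doc = params_to_dict(model_fit.params)
    doc["fit"] = {
        "r2": model_fit.r2,
        "n_primitives": model_fit.n_primitives,
        "provenance": model_fit.provenance,
        "options": {k: v for k, v in asdict(model_fit.options).items()
                    if k != "initial_state"},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit(path) -> tuple[object, dict]:
    """Read a fit JSON; returns ``(params, fit_block)``."""
    doc = json.loads(Path(path).read_text())
    return params_from_dict(doc), doc.get("fit", {})


def write_report(report, path) -> None:
    """Serialize an :class:`fada.evaluation.EvaluationReport`."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# run configurations (pydantic-validated; schemas shipped in fada/schemas)


class SimulateConfig(BaseModel):
    """``fada simulate`` parameters."""

    model_kind: str = "temporal_delays"
    nonneg: bool = False
    M: int = Field(10, ge=1)
    L: int = Field(20, ge=1)
    T: int = Field(100, ge=4)
    duration_s: float = Field(1.0, gt=0)
    P: int = Field(3, ge=1)
    P_tp: int = Field(3, ge=1)
    P_sp: int = Field(3, ge=1)
    K_gen: int = Field(8, ge=1)
    noise_level: float = Field(0.0, ge=0)
    n_realizations: int = Field(20, ge=1)
    seed: int = 0


class FitConfig(BaseModel):
    """``fada fit`` / ``fada select`` parameters."""

    model_kind: str
    P: int | None = Field(None, ge=1)
    P_tp: int | None = Field(None, ge=1)
    P_sp: int | None = Field(None, ge=1)
    nonneg: bool | None = None
    K: int | None = Field(None, ge=1)
    seed: int = 0
    n_restarts: int = Field(5, ge=1)
    max_p: int = Field(8, ge=3)


class BenchConfig(BaseModel):
    """``fada bench`` parameters: the simulation benchmark grid."""

    models: list[str] = ["spatial", "temporal", "temporal_delays",
                         "spatiotemporal", "space_by_time"]
    nonneg_variants: bool = True
    noise_levels: list[float] = [0.0, 0.05, 0.15, 0.25, 0.35]
    n_realizations: int = Field(20, ge=1)
    seed: int = 0
    M: int = Field(10, ge=1)
    L: int = Field(20, ge=1)
    T: int = Field(100, ge=4)
    P: int = Field(3, ge=1)
    n_baseline_pairs: int = Field(100, ge=1)


def export_schemas(directory) -> list[Path]:
    """Write the JSON schema of every config model to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for model in (SimulateConfig, FitConfig, BenchConfig):
        path = directory / f"{model.__name__}.schema.json"
        path.write_text(json.dumps(model.model_json_schema(), indent=1,
                                   sort_keys=True))
        written.append(path)
    return written
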