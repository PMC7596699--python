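"""Run configuration: flat parameter files with embedded defaults.

A run config is a YAML (or JSON) mapping with the biophysical and synaptic
constants at top level under their conventional symbol names (``C``,
``gL``, ``gNaP``, ``EL``, ``ENa``, ``Eex``, ``Einh``, ``VmNaP``, ``kmNaP``,
``VhNaP``, ``khNaP``, ``tauNaP``, ``VtauNaP``, ``ktauNaP``, ``Vmin``,
``Vmax``, the weights ``b12 b21 b31 b42 b13 b24 b41 b32`` and ``DE0``),
plus optional ``drives`` and ``solver`` sections.  Omitted keys fall back
to the reference defaults, so an empty file resolves to the default model.
Validation is exhaustive: every violation is reported, not only the first.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import (
    FLEXOR_L,
    FLEXOR_R,
    EXTENSOR_L,
    EXTENSOR_R,
    DriveConfig,
    NetworkConfig,
    UnitParams,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "resolve_config", "MODEL_DEFAULTS"]

MODEL_DEFAULTS: dict[str, float] = {
    # unit biophysics
    "C": 20.0,
    "gL": 2.8,
    "gNaP": 5.0,
    "EL": -65.0,
    "ENa": 50.0,
    "Eex": -10.0,
    "Einh": -90.0,
    "VmNaP": -40.0,
    "kmNaP": -6.0,
    "VhNaP": -50.0,
    "khNaP": 10.0,
    "tauNaP": 1500.0,
    "VtauNaP": -100.0,
    "ktauNaP": 40.0,
    "Vmin": -50.0,
    "Vmax": 0.0,
    # synaptic weights (nS); commissural defaults are the reference point
    "b12": 0.4,
    "b21": 0.4,
    "b41": 0.2,
    "b32": 0.2,
    "b31": 0.5,
    "b42": 0.5,
    "b13": 1.0,
    "b24": 1.0,
    # gross extensor drive of the coupling rule
    "DE0": 1.4,
}

DRIVE_DEFAULTS: dict = {
    "dF_left": 0.5,
    "dF_right": 0.5,
    "coupled": True,
    "dE_left": None,
    "dE_right": None,
}

SOLVER_DEFAULTS: dict = {
    "method": "rk4",
    "dt_ms": 0.05,
    "sample_dt_ms": 1.0,
    "duration_ms": 40_000.0,
    "transient_ms": 10_000.0,
}


class ConfigError(ValueError):
    """Configuration invalid; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """Fully resolved configuration for one simulation run."""

    network: NetworkConfig
    drives: DriveConfig
    solver: dict
    transient: float
    resolved: dict = field(default_factory=dict)

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved, sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_dict(self) -> dict:
        return dict(self.resolved)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_model(m: dict, errors: list[str]) -> None:
    if m["C"] <= 0:
        errors.append(f"C must be positive, got {m['C']}")
    for key in ("gL", "gNaP"):
        if m[key] < 0:
            errors.append(f"{key} must be non-negative, got {m[key]}")
    if m["Vmax"] <= m["Vmin"]:
        errors.append(f"Vmax ({m['Vmax']}) must exceed Vmin ({m['Vmin']})")
    if m["kmNaP"] >= 0:
        errors.append(f"kmNaP must be negative, got {m['kmNaP']}")
    if m["khNaP"] <= 0:
        errors.append(f"khNaP must be positive, got {m['khNaP']}")
    if m["tauNaP"] == 0:
        errors.append("tauNaP must be nonzero")
    for key in ("b12", "b21", "b31", "b42", "b13", "b24", "b41", "b32"):
        if m[key] < 0:
            errors.append(f"{key} must be non-negative, got {m[key]}")
    if m["DE0"] < 0:
        errors.append(f"DE0 must be non-negative, got {m['DE0']}")


def resolve_config(raw: dict | None) -> RunConfig:
    """Validate a raw mapping and resolve it against the defaults."""
    raw = dict(raw or {})
    errors: list[str] = []

    drives_raw = raw.pop("drives", {}) or {}
    solver_raw = raw.pop("solver", {}) or {}

    unknown = set(raw) - set(MODEL_DEFAULTS)
    for key in sorted(unknown):
        errors.append(f"unknown key: {key}")
    unknown_d = set(drives_raw) - set(DRIVE_DEFAULTS)
    for key in sorted(unknown_d):
        errors.append(f"unknown key: drives.{key}")
    unknown_s = set(solver_raw) - set(SOLVER_DEFAULTS)
    for key in sorted(unknown_s):
        errors.append(f"unknown key: solver.{key}")

    model = {**MODEL_DEFAULTS, **{k: raw[k] for k in raw if k in MODEL_DEFAULTS}}
    drives = {**DRIVE_DEFAULTS, **{k: drives_raw[k] for k in drives_raw if k in DRIVE_DEFAULTS}}
    solver = {**SOLVER_DEFAULTS, **{k: solver_raw[k] for k in solver_raw if k in SOLVER_DEFAULTS}}

    if model["tauNaP"] < 0:
        warnings.warn(
            f"tauNaP given as {model['tauNaP']} ms; a relaxation time must be "
            "positive, using its magnitude",
            stacklevel=2,
        )
        model["tauNaP"] = abs(model["tauNaP"])

    _check_model(model, errors)

    for key in ("dF_left", "dF_right"):
        if drives[key] < 0:
            errors.append(f"drives.{key} must be non-negative, got {drives[key]}")
    if not drives["coupled"]:
        for key in ("dE_left", "dE_right"):
            if drives[key] is None:
                errors.append(f"drives.{key} required when drives.coupled is false")
            elif drives[key] < 0:
                errors.append(f"drives.{key} must be non-negative")

    if solver["method"] not in ("rk4", "lsoda"):
        errors.append(f"solver.method must be rk4 or lsoda, got {solver['method']!r}")
    for key in ("dt_ms", "sample_dt_ms", "duration_ms"):
        if not solver[key] > 0:
            errors.append(f"solver.{key} must be positive, got {solver[key]}")
    if solver["transient_ms"] < 0:
        errors.append(f"solver.transient_ms must be non-negative")
    if solver["transient_ms"] >= solver["duration_ms"]:
        errors.append("solver.transient_ms must be smaller than solver.duration_ms")

    if errors:
        raise ConfigError(errors)

    unit = UnitParams(
        C=model["C"],
        g_L=model["gL"],
        E_L=model["EL"],
        g_NaP=model["gNaP"],
        E_Na=model["ENa"],
        V_mNaP=model["VmNaP"],
        k_mNaP=model["kmNaP"],
        V_hNaP=model["VhNaP"],
        k_hNaP=model["khNaP"],
        tau_NaP_max=model["tauNaP"],
        V_tauNaP=model["VtauNaP"],
        k_tauNaP=model["ktauNaP"],
        V_min=model["Vmin"],
        V_max=model["Vmax"],
    )
    b = np.zeros((4, 4))
    b[FLEXOR_L, FLEXOR_R] = model["b12"]
    b[FLEXOR_R, FLEXOR_L] = model["b21"]
    b[EXTENSOR_L, FLEXOR_L] = model["b31"]
    b[EXTENSOR_R, FLEXOR_R] = model["b42"]
    b[FLEXOR_L, EXTENSOR_L] = model["b13"]
    b[FLEXOR_R, EXTENSOR_R] = model["b24"]
    b[EXTENSOR_R, FLEXOR_L] = model["b41"]
    b[EXTENSOR_L, FLEXOR_R] = model["b32"]
    network = NetworkConfig(
        b=b, E_ex=model["Eex"], E_inh=model["Einh"], units=(unit,) * 4
    )
    drive_cfg = DriveConfig(
        d_F_left=drives["dF_left"],
        d_F_right=drives["dF_right"],
        D_E0=model["DE0"],
        coupled=bool(drives["coupled"]),
        d_E_left_override=drives["dE_left"],
        d_E_right_override=drives["dE_right"],
    )
    resolved = {**model, "drives": drives, "solver": solver}
    return RunConfig(
        network=network,
        drives=drive_cfg,
        solver=solver,
        transient=solver["transient_ms"],
        resolved=resolved,
    )


def load_config(path) -> RunConfig:
    """Load and resolve a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    return resolve_config(raw)
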