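"""Experiment configuration: one plain YAML/JSON document drives a run.

The packaged defaults reproduce the standard protocols out of the box
(nominal subject, 30% parameter ranges, single-meal recovery scenario,
3-day meal protocol, 200-subject cohort).  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import (
    NOMINAL_PATIENT,
    ParamRanges,
    PatientParams,
    StateBox,
    UncertaintyBounds,
    default_bounds,
)
from .design import SynthesisOptions

__all__ = ["ExperimentConfig", "ConfigError", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "patient": {"c1": 0.0, "c2": 0.015, "c3": 2e-6, "c4": 0.2, "c5": 0.05,
                "Gb": 80.0, "Ib": 7.0},
    "ranges": {"c1": [0.0, 0.0], "c2": [0.0105, 0.0195],
               "c3": [1.4e-6, 2.6e-6], "c4": [0.14, 0.26], "c5": [0.045, 0.055]},
    "state_box": {"x1d": [-80.0, 320.0], "x2d": [0.0, 0.05],
                  "x3d": [-7.0, 93.0], "d": [0.0, 10.0]},
    "synthesis": {
        "alpha_grid": [0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0],
        "eps_grid": "logspace(-4, 2, 13)",
        "margin": 1e-9,
        "scale_to_box": True,
        "bilinear_as_uncertainty": True,   # state-feedback design
        "bilinear_as_disturbance": True,   # observer design
    },
    "gains": "reference",  # "reference" | "synthesize" | {"K": [...], "L": [...]}
    "scenario1": {"t_end": 800.0, "x0": [200.0, 0.001, 7.0], "d0": 8.0},
    "scenario2": {"days": 3, "seed": 0, "modulate": True},
    "cohort": {"n": 200, "seed": 0, "days": 3, "modulate": True},
    "integrator": {"rtol": 1e-8, "atol": 1e-10, "dt_out": 1.0, "method": "LSODA"},
    "metrics": {"window_start": 120.0, "basal_band": 2.0},
}


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in '{where}'")


@dataclass
class ExperimentConfig:
    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        _check_keys(self.raw, DEFAULT_CONFIG, "<root>")
        merged = copy.deepcopy(DEFAULT_CONFIG)
        for key, val in self.raw.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                _check_keys(val, merged[key], key)
                merged[key].update(val)
            else:
                merged[key] = val
        self.raw = merged

    # -- constructors -------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        return cls(raw=data)

    # -- views --------------------------------------------------------
    def patient(self) -> PatientParams:
        return PatientParams(**self.raw["patient"])

    def ranges(self) -> ParamRanges:
        return ParamRanges(**{k: tuple(v) for k, v in self.raw["ranges"].items()})

    def state_box(self) -> StateBox:
        return StateBox(**{k: tuple(v) for k, v in self.raw["state_box"].items()})

    def bounds(self) -> UncertaintyBounds:
        return default_bounds(self.patient(), self.ranges(), self.state_box())

    def synthesis_options(self) -> SynthesisOptions:
        s = dict(self.raw["synthesis"])
        eps = s["eps_grid"]
        if isinstance(eps, str):
            if not eps.startswith("logspace(") or not eps.endswith(")"):
                raise ConfigError(f"cannot parse eps_grid spec {eps!r}")
            a, b, n = (float(x) for x in eps[len("logspace("):-1].split(","))
            s["eps_grid"] = tuple(float(x) for x in np.logspace(a, b, int(n)))
        else:
            s["eps_grid"] = tuple(float(x) for x in eps)
        s["alpha_grid"] = tuple(float(x) for x in s["alpha_grid"])
        return SynthesisOptions(
            alpha_grid=s["alpha_grid"],
            eps_grid=s["eps_grid"],
            margin=float(s["margin"]),
            scale_to_box=bool(s["scale_to_box"]),
            bilinear_as_uncertainty=bool(s["bilinear_as_uncertainty"]),
            bilinear_as_disturbance=bool(s["bilinear_as_disturbance"]),
        )

    def gains(self) -> tuple[np.ndarray, np.ndarray] | str:
        g = self.raw["gains"]
        if isinstance(g, str):
            if g not in ("reference", "synthesize"):
                raise ConfigError("gains must be 'reference', 'synthesize' or {K, L}")
            return g
        _check_keys(g, ("K", "L"), "gains")
        return np.asarray(g["K"], dtype=float), np.asarray(g["L"], dtype=float)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=float).encode()
        ).hexdigest()[:12]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)
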