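"""Configuration files, trace/report I/O and reproducibility plumbing.

Config files are YAML; a run configuration resolves to a fully specified
circuit (preset plus overrides) and a stimulation protocol.  Traces are
exchanged as CSV with the header
``t_ms,v_mem_V,v_s_V,v_gk_V,i_naca_uA,i_k_uA,i_in_uA`` at full float
precision; externally recorded waveforms may instead be two-column
(time in ms, voltage in V).  JSON reports carry a provenance block with
the config hash, preset version and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .circuit import OECMParams, SolverOptions, Trace
from .oect import ElectrolyteCondition
from .presets import PRESET_VERSION, get_preset
from .stimulus import Pulse, StimulusProtocol

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trace",
    "read_trace",
    "provenance",
    "write_report",
]

TRACE_COLUMNS = ["t_ms", "v_mem_V", "v_s_V", "v_gk_V", "i_naca_uA", "i_k_uA", "i_in_uA"]

_CIRCUIT_FIELDS = {"e_nc", "e_s", "e_k", "c_mem", "c_dk", "r_dk", "c_s",
                   "gamma", "kappa", "pka", "hill", "delta"}
_ELECTROLYTE_FIELDS = {"nacl_mM", "kcl_mM", "ph"}
_PROTOCOL_KEYS = {"mode", "pulses", "dc_amplitude", "external_file"}
_SOLVER_KEYS = {"rtol", "atol", "max_step_stim", "max_step_free", "method",
                "rest_duration", "rest_tol"}
_TOP_KEYS = {"preset", "overrides", "electrolytes", "protocol", "solver",
             "seed", "log_level"}


@dataclass
class RunConfig:
    """A fully resolved run: circuit parameters, protocol, solver, seed."""

    preset: str = "paper2026"
    overrides: dict = field(default_factory=dict)
    electrolytes: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=lambda: {
        "mode": "pulses", "pulses": [[0.05, 10e-6, 0.02]]
    })
    solver: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def params(self) -> OECMParams:
        p = get_preset(self.preset)
        if self.overrides:
            p = replace(p, **self.overrides)
        if self.electrolytes:
            elec = dict(p.electrolytes)
            for role, fields in self.electrolytes.items():
                old = elec[role]
                merged = {f: getattr(old, f) for f in _ELECTROLYTE_FIELDS}
                merged.update(fields)
                elec[role] = ElectrolyteCondition(**merged)
            p = replace(p, electrolytes=elec)
        return p

    def stimulus(self) -> StimulusProtocol:
        mode = self.protocol.get("mode", "pulses")
        if mode == "pulses":
            pulses = tuple(Pulse(*map(float, row)) for row in self.protocol.get("pulses", []))
            return StimulusProtocol(mode="pulses", pulses=pulses)
        if mode == "dc":
            return StimulusProtocol(mode="dc", dc_amplitude=float(self.protocol["dc_amplitude"]))
        if mode == "external_gate":
            tr = read_trace(self.protocol["external_file"])
            return StimulusProtocol(mode="external_gate",
                                    external=(tr.t, tr.v_mem))
        raise ValueError(f"unknown protocol mode {mode!r}")

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections fall back to the preset defaults (the standard testing
    condition); unknown keys are rejected with their location.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    if "overrides" in raw:
        _reject_unknown(raw["overrides"], _CIRCUIT_FIELDS, "overrides")
    if "electrolytes" in raw:
        for role, fields in raw["electrolytes"].items():
            if role not in ("S_inverter", "NaCa_channel", "K_channel"):
                raise ValueError(f"unknown electrolyte role {role!r}")
            _reject_unknown(fields, _ELECTROLYTE_FIELDS, f"electrolytes.{role}")
    if "protocol" in raw:
        _reject_unknown(raw["protocol"], _PROTOCOL_KEYS, "protocol")
    if "solver" in raw:
        _reject_unknown(raw["solver"], _SOLVER_KEYS, "solver")
    cfg = RunConfig(**raw)
    cfg.params()      # validates preset + overrides
    cfg.stimulus()    # validates protocol
    return cfg


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))


def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Lossless CSV export (times ms, voltages V, currents uA)."""
    df = pd.DataFrame({
        "t_ms": trace.t * 1e3,
        "v_mem_V": trace.v_mem,
        "v_s_V": trace.v_s,
        "v_gk_V": trace.v_gk,
        "i_naca_uA": trace.i_naca * 1e6,
        "i_k_uA": trace.i_k * 1e6,
        "i_in_uA": trace.i_in * 1e6,
    })
    df.to_csv(path, index=False)  # pandas writes shortest round-trip floats


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace CSV; accepts the full 7-column format or an external
    two-column (t_ms, v_V) time series, whose current channels are NaN."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if df.shape[1] == 1:  # not comma-separated: sniff the delimiter
            df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as e:
        raise ValueError(f"{path}: cannot parse delimited file: {e}") from None
    if list(df.columns) == TRACE_COLUMNS:
        return Trace(
            t=df["t_ms"].to_numpy() * 1e-3,
            v_mem=df["v_mem_V"].to_numpy(),
            v_s=df["v_s_V"].to_numpy(),
            v_gk=df["v_gk_V"].to_numpy(),
            i_naca=df["i_naca_uA"].to_numpy() * 1e-6,
            i_k=df["i_k_uA"].to_numpy() * 1e-6,
            i_in=df["i_in_uA"].to_numpy() * 1e-6,
            meta={"source": str(path)},
        )
    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float) * 1e-3
        v = df.iloc[:, 1].to_numpy(dtype=float)
        nan = np.full_like(v, np.nan)
        z = np.zeros_like(v)
        return Trace(t=t, v_mem=v, v_s=z, v_gk=z.copy(), i_naca=nan,
                     i_k=nan.copy(), i_in=nan.copy(),
                     meta={"source": str(path), "external": True})
    raise ValueError(
        f"{path}: expected columns {TRACE_COLUMNS} or a 2-column series, "
        f"got {list(df.columns)}"
    )


def provenance(cfg: RunConfig) -> dict:
    return {
        "config_sha256_16": cfg.digest(),
        "preset_version": PRESET_VERSION,
        "seed": cfg.seed,
    }


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if math.isnan(v) else v
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, pd.DataFrame):
        return _jsonable(x.to_dict(orient="records"))
    return x


def write_report(payload: dict, cfg: Optional[RunConfig], path: Union[str, Path]) -> None:
    """JSON report with a provenance block (config hash, version, seed)."""
    body = dict(payload)
    if cfg is not None:
        body["provenance"] = provenance(cfg)
    Path(path).write_text(json.dumps(_jsonable(body), indent=2, sort_keys=True))
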