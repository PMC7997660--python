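"""TSV trace/table formats and run configuration.

Traces are plain tab-separated files with ``# key=value`` comment headers
(force_pN, sampling_rate_Hz, units, condition metadata) and two columns,
time_s and position.  Positions may be stored in bp unwound or in nm of
extension; nm files are converted to bp on load through the worm-like-chain
relation given the force in the header.  All derived tables (steps, events,
bursts, fit parameters) are TSV with the configuration hash echoed in a
header comment so a pipeline run is auditable end to end.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .simulate import Trace
from .wlc import bp_unwound


class ParseError(ValueError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k1_per_nM: float = 0.015          # s^-1 per nM, plus basal below
    k1_basal: float = 0.02            # s^-1
    k_minus1: float = 0.18            # s^-1
    k2: float = 0.17                  # s^-1
    k_off: float = 0.037              # s^-1
    k_off_prime: float = 0.0          # s^-1
    k_on: float = 1.2e8               # M^-1 s^-1, melting on-rate
    melt_amplitude_bp: float = 5.0
    melt_lifetime_s: float = 0.020
    noise_sd_bp: float = 0.3
    sampling_rate_hz: float = 89.0
    force_pN: float = 12.0
    duration_s: float = 120.0
    bursts_per_molecule_mean: float = 5.0
    bursts_per_molecule_sd: float = 1.0


class RunConfig(BaseModel):
    """Schema-validated defaults for the whole pipeline.

    Unknown keys are rejected so silent typos cannot change an analysis.
    """

    model_config = ConfigDict(extra="forbid")

    # polymer mechanics
    kbt_pN_nm: float = 4.11
    # burst analysis
    burst_min_excursion_bp: float = 5.0
    high_threshold_bp: float = 25.0
    smooth_window_points: int = 51
    velocity_window_points: int = 50
    velocity_bin_bp: float = 2.0
    stall_exit_bp: float = 10.0
    tau_low_s: float = 7.0
    # melt detection
    melt_min_amplitude_bp: float = 2.0
    melt_bare_min_amplitude_bp: float = 4.0
    melt_max_separation_points: int = 5
    melt_max_lifetime_s: float = 0.2
    step_quality_threshold: float = 1.2
    # fitting
    bootstrap_resamples: int = 200
    # simulation
    seed: int = 0
    simulator: SimulatorConfig = SimulatorConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def sha256(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV with a ``# key=value`` metadata header."""
    meta = {"force_pN": trace.force,
            "sampling_rate_Hz": trace.sampling_rate,
            "units": trace.metadata.get("units", "bp")}
    for k, v in trace.metadata.items():
        if k != "units":
            meta[k] = v
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("time_s\tposition\n")
        for t, x in zip(trace.time, trace.position):
            fh.write(f"{t:.6f}\t{x:.6f}\n")


def read_trace(path) -> Trace:
    """Read a TSV trace; nm-unit files are converted to bp unwound using
    the force declared in the header."""
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" not in body:
                raise ParseError(path, line_no,
                                 f"header line without key=value: {body!r}")
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    if list(df.columns[:2]) != ["time_s", "position"]:
        raise ParseError(path, header_lines + 1,
                         f"expected columns time_s, position; "
                         f"got {list(df.columns)}")
    time = df["time_s"].to_numpy(float)
    pos = df["position"].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise ParseError(path, header_lines + 2,
                         "time column must be strictly increasing")
    units = meta.pop("units", "bp")
    force = meta.pop("force_pN", None)
    rate = meta.pop("sampling_rate_Hz", None)
    if rate is None:
        rate = 1.0 / np.median(np.diff(time))
    if units == "nm":
        if force is None:
            raise ParseError(path, 1,
                             "nm-unit trace requires force_pN in the header")
        pos = bp_unwound(pos, float(force))
    elif units != "bp":
        raise ParseError(path, 1, f"unknown units {units!r}")
    if force is None:
        raise ParseError(path, 1, "missing force_pN header")
    extra = {}
    for k, v in meta.items():
        try:
            extra[k] = float(v)
        except ValueError:
            extra[k] = v
    extra["units"] = "bp"
    return Trace(time=time, position=pos, force=float(force),
                 sampling_rate=float(rate), metadata=extra)


def write_table(df: pd.DataFrame, path, config: Optional[RunConfig] = None,
                float_format: str = "%.6f") -> None:
    """Write a derived table as TSV, stamping the config hash."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_sha256={config.sha256()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
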