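"""Readers/writers for transients, drug specs and result artifacts.

CSV is the single tabular interchange format (`time_ms,value` for
transients, tidy tables for effects and sensitivities); JSON carries
structured results and provenance (protocol, scaling, seeds).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .models import SimulationResult, StimulusProtocol
from .transients import Transient

__all__ = [
    "read_transient_csv",
    "write_transient_csv",
    "write_simulation_result",
    "RunConfig",
]


def write_transient_csv(tr: Transient, path) -> None:
    """Two-column CSV, header ``time_ms,value``, one row per output sample."""
    pd.DataFrame({"time_ms": tr.time, "value": tr.value}).to_csv(path, index=False)


def read_transient_csv(
    path,
    kind: str,
    pacing_frequency: float,
    stimulus_times=None,
) -> Transient:
    """Read a ``time_ms,value`` CSV into a Transient.

    The grid must be uniform and strictly increasing; stimulus times
    default to one stimulus per pacing period starting at the first sample.
    Extra columns are ignored.
    """
    tab = pd.read_csv(path)
    if "time_ms" not in tab.columns or "value" not in tab.columns:
        raise ValueError(f"{path}: expected header with time_ms,value")
    time = tab["time_ms"].to_numpy(dtype=float)
    dt = np.diff(time)
    if np.any(dt <= 0):
        i = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise ValueError(f"{path}: non-monotone time at row {i + 1}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        i = int(np.nonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))[0][0]) + 1
        raise ValueError(f"{path}: non-uniform grid at row {i + 1}")
    if stimulus_times is None:
        period = 1000.0 / pacing_frequency
        stimulus_times = np.arange(time[0], time[-1] + 1e-9, period)
    return Transient(
        time, tab["value"].to_numpy(dtype=float), kind,
        np.asarray(stimulus_times, dtype=float), pacing_frequency,
    )


def write_simulation_result(result: SimulationResult, outdir, stem: str = "run") -> dict:
    """SL and Ca CSVs plus a JSON metadata companion; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sl": outdir / f"{stem}_sl.csv",
        "cai": outdir / f"{stem}_cai.csv",
        "meta": outdir / f"{stem}_meta.json",
    }
    write_transient_csv(result.sl_transient, paths["sl"])
    write_transient_csv(result.cai_transient, paths["cai"])
    meta = {
        "species": result.params_used.species,
        "scaling": dict(result.scaling_used),
        "stimulus_times_ms": list(map(float, result.stimulus_times)),
        "pacing_frequency_hz": float(result.sl_transient.pacing_frequency),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_calibration_targets(path):
    """Calibration-targets CSV -> CalibrationTargets.

    Columns ``biomarker,kind,stat,value`` with stat in {median, mean, sd}:
    SL biomarkers enter as medians, Ca biomarkers as mean +/- SD ranges.
    """
    from .calibration import CalibrationTargets

    tab = pd.read_csv(path)
    required = {"biomarker", "kind", "stat", "value"}
    if not required.issubset(tab.columns):
        raise ValueError(f"targets CSV must have columns {sorted(required)}")
    sl = {}
    ca_mean: dict[str, float] = {}
    ca_sd: dict[str, float] = {}
    for _, row in tab.iterrows():
        kind, stat = row["kind"], row["stat"]
        name, value = row["biomarker"], float(row["value"])
        if kind == "SL" and stat == "median":
            sl[name] = value
        elif kind == "Ca" and stat == "mean":
            ca_mean[name] = value
        elif kind == "Ca" and stat == "sd":
            ca_sd[name] = value
    missing_sd = set(ca_mean) ^ set(ca_sd)
    if missing_sd:
        raise ValueError(f"Ca targets need both mean and sd: {sorted(missing_sd)}")
    ca = {k: (ca_mean[k] - ca_sd[k], ca_mean[k] + ca_sd[k]) for k in ca_mean}
    return CalibrationTargets(sl_targets=sl, ca_targets=ca)


def write_calibration_targets(targets, path) -> None:
    """Inverse of :func:`read_calibration_targets`."""
    rows = [
        {"biomarker": k, "kind": "SL", "stat": "median", "value": v}
        for k, v in targets.sl_targets.items()
    ]
    for k, (lo, hi) in targets.ca_targets.items():
        rows.append({"biomarker": k, "kind": "Ca", "stat": "mean",
                     "value": 0.5 * (lo + hi)})
        rows.append({"biomarker": k, "kind": "Ca", "stat": "sd",
                     "value": 0.5 * (hi - lo)})
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Seeds, thresholds and protocol defaults of one pipeline run.

    Every stochastic component has an explicit seed and every screening
    threshold is config-visible.
    """

    species: str = "rat"
    frequency_hz: float = 1.0
    n_beats: int = 100
    dt_solver_ms: float = 0.01
    dt_output_ms: float = 1.0
    drug_seed: int = 0
    restart_seed: int = 0
    alternans_ratio: float = 1.1
    fluctuation_rate: float = 1.0e-3
    insensitivity_threshold: float = 0.1
    inclusion_range_pct: tuple[float, float] = (-100.0, 500.0)
    classification_scheme: str = "rat_sim"
    output_dir: str = "results"

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            frequency=self.frequency_hz,
            n_beats=self.n_beats,
            dt_solver=self.dt_solver_ms,
            dt_output=self.dt_output_ms,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)
        if "inclusion_range_pct" in obj:
            obj["inclusion_range_pct"] = tuple(obj["inclusion_range_pct"])
        return cls(**obj)
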