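"""Packaged reference data, file I/O, and synthetic-data generation.

The package ships two reference tables from the IMR90 X-ray experiment the
model was built around: per-(time, dose) phase percentages with standard
errors, and the derived irradiated-vs-sham relative differences. Both load
as long-format pandas frames.

The synthetic generator emulates that measurement process: it runs the
kinetic model (optionally under a perturbation schedule), samples phase
percentages at the experimental time points, and adds independent
truncated-at-zero Gaussian noise per phase on the percent scale, then
renormalises each sample to 100%. One integer seed fixes the whole stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import math

import numpy as np
import pandas as pd
import yaml

from .kinetic_core import (FRACTION_COLUMNS, PHASES, RateParameters,
                           SimConfig, build_transition_matrix, dominant_mode)
from .perturbation import (PerturbationSchedule, RateMultipliers,
                           ScheduleSegment, simulate_perturbed)

__all__ = [
    "FIXTURES",
    "DEFAULT_PHASE_SEMS",
    "SyntheticSpec",
    "load_fixture",
    "read_experiment_table",
    "write_experiment_table",
    "read_timecourse",
    "write_timecourse",
    "read_growth_curve",
    "write_growth_curve",
    "load_config",
    "save_config",
    "rates_from_config",
    "simconfig_from_config",
    "load_schedule",
    "save_schedule",
    "generate_synthetic_timecourse",
    "generate_synthetic_growth",
]

FIXTURES = ("table1", "table2")

#: Phase-percentage measurement noise (percent scale), matching the RMS
#: standard errors of the sham reference data over the 0-24 h window.
DEFAULT_PHASE_SEMS = (1.59, 1.52, 1.01, 0.28)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table ('table1' or 'table2').

    table1: columns time_h, dose_Gy, phase, percent, sem.
    table2: columns time_h, dose_Gy, phase, delta, err.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    with resources.files("cyclekin.data").joinpath(f"{name}.csv").open() as fh:
        frame = pd.read_csv(fh)
    frame.attrs["provenance"] = "fixture"
    return frame


# ---------------------------------------------------------------- CSV I/O

def write_experiment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_experiment_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"time_h", "dose_Gy", "phase", "percent", "sem"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"experiment table missing columns {sorted(missing)}")
    frame.attrs["provenance"] = "user"
    return frame


def write_timecourse(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_timecourse(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"time_h", *FRACTION_COLUMNS}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"time course missing columns {sorted(missing)}")
    return frame


def write_growth_curve(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_growth_curve(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"time_h", "count"} - set(frame.columns)
    if missing:
        raise ValueError(f"growth curve missing columns {sorted(missing)}")
    return frame


# ------------------------------------------------------------- config I/O

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def rates_from_config(cfg: dict) -> RateParameters:
    return RateParameters(
        k1=float(cfg["k1"]), g=float(cfg["g"]),
        k2=float(cfg["k2"]), b=float(cfg["b"]),
        mu_g1=float(cfg.get("mu_g1", 0.0)), mu_s=float(cfg.get("mu_s", 0.0)),
        mu_g2=float(cfg.get("mu_g2", 0.0)), mu_m=float(cfg.get("mu_m", 0.0)))


def simconfig_from_config(cfg: dict) -> SimConfig:
    kw = {}
    for key in ("dt", "sdd_tol", "sdd_lag", "fraction_scale", "max_horizon"):
        if key in cfg:
            kw[key] = cfg[key]
    return SimConfig(**kw)


def save_schedule(schedule: PerturbationSchedule, path) -> None:
    payload = {
        "dose_label": schedule.dose_label,
        "segments": [
            {"t_start": seg.t_start,
             "t_end": "inf" if math.isinf(seg.t_end) else seg.t_end,
             "k1_factor": seg.multipliers.k1, "g_factor": seg.multipliers.g,
             "k2_factor": seg.multipliers.k2, "b_factor": seg.multipliers.b}
            for seg in schedule.segments],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_schedule(path) -> PerturbationSchedule:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    segs = []
    for raw in payload["segments"]:
        t_end = raw["t_end"]
        t_end = math.inf if t_end in ("inf", ".inf", None) else float(t_end)
        segs.append(ScheduleSegment(
            t_start=float(raw["t_start"]), t_end=t_end,
            multipliers=RateMultipliers(
                k1=float(raw.get("k1_factor", 1.0)),
                g=float(raw.get("g_factor", 1.0)),
                k2=float(raw.get("k2_factor", 1.0)),
                b=float(raw.get("b_factor", 1.0)))))
    return PerturbationSchedule(segments=tuple(segs),
                                dose_label=str(payload.get("dose_label", "")))


# ------------------------------------------------------- synthetic data

@dataclass
class SyntheticSpec:
    """Recipe for a synthetic phase-percentage experiment table.

    ``noise_sd`` is the per-phase additive Gaussian noise on the percent
    scale; its default matches the measurement errors of the reference
    sham data. The recorded ``sem`` column carries the same values (or the
    default measurement scale when generating noiseless tables, so that
    chi-square weights remain defined). ``dose`` only labels the output.
    """

    rates: RateParameters
    schedule: PerturbationSchedule | None = None
    sample_times: tuple[float, ...] = (0.0, 6.0, 16.0, 24.0)
    noise_sd: tuple[float, float, float, float] = DEFAULT_PHASE_SEMS
    seed: int = 0
    n_replicates: int = 1
    dose: float = 0.0
    config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _model_percentages(spec: SyntheticSpec) -> np.ndarray:
    """Noiseless model percentages at the sample times, one row per time."""
    if spec.schedule is None or spec.schedule.is_identity():
        mode = dominant_mode(build_transition_matrix(spec.rates,
                                                     spec.config.dt))
        return np.tile(mode.sdd_fractions * 100.0,
                       (len(spec.sample_times), 1))
    horizon = max(spec.sample_times)
    tc = simulate_perturbed(spec.rates, spec.schedule, horizon, spec.config)
    rows = []
    for t in spec.sample_times:
        idx = (tc["time_h"] - t).abs().idxmin()
        rows.append(tc.loc[idx, list(FRACTION_COLUMNS)].to_numpy(float) * 100.0)
    return np.array(rows)


def generate_synthetic_timecourse(spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate, sample, add truncated Gaussian noise, renormalise to 100%."""
    model = _model_percentages(spec)
    rng = np.random.default_rng(spec.seed)
    sd = np.asarray(spec.noise_sd, dtype=float)
    sem_out = np.where(sd > 0, sd, DEFAULT_PHASE_SEMS)
    records = []
    for rep in range(1, spec.n_replicates + 1):
        noisy = model + rng.normal(0.0, 1.0, size=model.shape) * sd
        noisy = np.clip(noisy, 0.0, None)
        noisy = noisy / noisy.sum(axis=1, keepdims=True) * 100.0
        for i, t in enumerate(spec.sample_times):
            for j, phase in enumerate(PHASES):
                records.append({"time_h": t, "dose_Gy": spec.dose,
                                "phase": phase, "percent": noisy[i, j],
                                "sem": sem_out[j], "replicate": rep})
    frame = pd.DataFrame(records)
    frame.attrs["provenance"] = "synthetic"
    return frame


def generate_synthetic_growth(n0: float, gamma: float,
                              times=(6.0, 16.0, 24.0, 48.0, 72.0),
                              cv: float = 0.1, seed: int = 0,
                              n_replicates: int = 1) -> pd.DataFrame:
    """Exponential cell counts with multiplicative Gaussian noise.

    Counts are ``n0 * exp(gamma t) * (1 + eps)`` with eps ~ N(0, cv),
    floored at zero. Columns: time_h, count, replicate.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    records = []
    for rep in range(1, n_replicates + 1):
        eps = rng.normal(0.0, cv, size=t.size) if cv > 0 else np.zeros(t.size)
        counts = np.clip(n0 * np.exp(gamma * t) * (1.0 + eps), 0.0, None)
        for tt, cc in zip(t, counts):
            records.append({"time_h": tt, "count": cc, "replicate": rep})
    frame = pd.DataFrame(records)
    frame.attrs["provenance"] = "synthetic"
    return frame
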