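"""Radiation-induced perturbations as piecewise-constant rate schedules.

DNA damage transiently halts cell-cycle progression at the G1/S and G2/M
checkpoints. On the population level this shows up as a G2 block shortly
after exposure followed by G1 accumulation, and it is captured here by
multiplying the baseline transition rates k1 (G1 -> S) and k2 (G2 -> M) by
piecewise-constant factors of time since irradiation. Presets encode the
schedules that reproduce IMR90 X-ray data at 2 and 5 Gy; arbitrary
schedules can be built or loaded from file.

Simulated perturbations start from the steady DNA distribution of the
baseline (the state of an unperturbed exponentially growing culture) with
the exposure at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .kinetic_core import (AgeStructuredState, RateParameters, SimConfig,
                           evolve_to_sdd, simulate_timecourse)

__all__ = [
    "RateMultipliers",
    "ScheduleSegment",
    "PerturbationSchedule",
    "identity_schedule",
    "preset_schedule",
    "rates_at",
    "simulate_perturbed",
]


@dataclass(frozen=True)
class RateMultipliers:
    """Factors applied to the four baseline kinetic rates."""

    k1: float = 1.0
    g: float = 1.0
    k2: float = 1.0
    b: float = 1.0

    def __post_init__(self):
        for name in ("k1", "g", "k2", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"multiplier {name} must be > 0")

    def is_identity(self) -> bool:
        return self.k1 == self.g == self.k2 == self.b == 1.0


@dataclass(frozen=True)
class ScheduleSegment:
    """One constant-multiplier interval [t_start, t_end) post-irradiation."""

    t_start: float
    t_end: float
    multipliers: RateMultipliers = field(default_factory=RateMultipliers)

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError(f"segment needs t_start < t_end, got "
                             f"[{self.t_start}, {self.t_end})")


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered segments tiling [0, inf); evaluation is right-continuous."""

    segments: tuple[ScheduleSegment, ...]
    dose_label: str = ""

    def __post_init__(self):
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0].t_start != 0:
            raise ValueError("schedule must start at t = 0")
        for a, b in zip(segs, segs[1:]):
            if not math.isclose(a.t_end, b.t_start, abs_tol=1e-9):
                raise ValueError(
                    f"segments must tile [0, inf) without gaps or overlaps: "
                    f"[..., {a.t_end}) then [{b.t_start}, ...)")
        if segs[-1].t_end != math.inf:
            raise ValueError("last segment must extend to +inf")

    def segment_at(self, t: float) -> ScheduleSegment:
        if t < 0:
            raise ValueError("t must be >= 0")
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        raise AssertionError("unreachable: segments tile [0, inf)")

    def multipliers_at(self, t: float) -> RateMultipliers:
        return self.segment_at(t).multipliers

    def breakpoints(self) -> list[float]:
        return [s.t_start for s in self.segments]

    def is_identity(self) -> bool:
        return all(s.multipliers.is_identity() for s in self.segments)


def identity_schedule(dose_label: str = "0 Gy") -> PerturbationSchedule:
    return PerturbationSchedule(
        segments=(ScheduleSegment(0.0, math.inf),), dose_label=dose_label)


def preset_schedule(dose: float) -> PerturbationSchedule:
    """Schedules reproducing IMR90 cell-cycle data after X-ray exposure.

    2 Gy: k2 is cut to 1/12 for the first 6 h (the G2 block), then partially
    restored to 1/2 of baseline; k1 drops to 1/10 at 6 h (G1 accumulation)
    and doubles to 1/5 at 48 h. 5 Gy: the k2 block at 1/12 lasts until 24 h
    with recovery only to 1/4; k1 drops to 1/10 at 16 h. 0 Gy is the
    identity. All factors are relative to the unperturbed baseline.
    """
    inf = math.inf
    if dose == 0:
        return identity_schedule()
    if dose == 2:
        return PerturbationSchedule(segments=(
            ScheduleSegment(0.0, 6.0, RateMultipliers(k2=1 / 12)),
            ScheduleSegment(6.0, 48.0, RateMultipliers(k1=1 / 10, k2=1 / 2)),
            ScheduleSegment(48.0, inf, RateMultipliers(k1=1 / 5, k2=1 / 2)),
        ), dose_label="2 Gy")
    if dose == 5:
        return PerturbationSchedule(segments=(
            ScheduleSegment(0.0, 16.0, RateMultipliers(k2=1 / 12)),
            ScheduleSegment(16.0, 24.0, RateMultipliers(k1=1 / 10, k2=1 / 12)),
            ScheduleSegment(24.0, inf, RateMultipliers(k1=1 / 10, k2=1 / 4)),
        ), dose_label="5 Gy")
    raise ValueError(f"no preset for dose {dose!r} Gy (supported: 0, 2, 5)")


def rates_at(schedule: PerturbationSchedule, baseline: RateParameters,
             t: float) -> RateParameters:
    """Baseline rates scaled by the segment containing t (right-continuous)."""
    m = schedule.multipliers_at(t)
    return baseline.scaled(k1=m.k1, g=m.g, k2=m.k2, b=m.b)


def simulate_perturbed(baseline: RateParameters,
                       schedule: PerturbationSchedule,
                       horizon: float,
                       config: SimConfig = SimConfig(),
                       initial: AgeStructuredState | None = None,
                       ) -> pd.DataFrame:
    """Phase-fraction time course after irradiation at t = 0.

    The baseline is first run to its steady DNA distribution (unless a
    converged ``initial`` state is supplied); the schedule's multipliers
    then apply from t = 0. Output times are hours post-exposure; the t = 0
    row holds the steady (pre-exposure) fractions. Schedules that touch the
    DNA synthesis rate g are rejected: the S-phase delay-line length is
    fixed by the baseline.
    """
    for seg in schedule.segments:
        if seg.multipliers.g != 1.0:
            raise ValueError(
                f"segment [{seg.t_start}, {seg.t_end}) scales g by "
                f"{seg.multipliers.g}: resizing the S-phase delay line "
                "mid-run is not supported")
    if initial is None:
        sdd = evolve_to_sdd(baseline, config)
        state = sdd.state
    else:
        state = initial
    state = AgeStructuredState(n1=state.n1, ns=state.ns.copy(),
                               n2=state.n2, nm=state.nm, t=0.0)
    segments = [(seg.t_start, rates_at(schedule, baseline, seg.t_start))
                for seg in schedule.segments if seg.t_start < horizon]
    if not segments:
        segments = [(0.0, rates_at(schedule, baseline, 0.0))]
    return simulate_timecourse(segments, horizon, config, state)
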