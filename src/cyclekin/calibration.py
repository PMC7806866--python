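"""Parameter estimation from growth curves and phase-percentage data.

Two routes feed the kinetic model with numbers:

* Steel's formulas turn steady phase fractions plus the population doubling
  time ``T_D`` into mean phase durations, whose reciprocals (minus any death
  rate) are the transition rates. This gives a closed-form initial guess.
* A chi-square fit then refines the four rates against measured sham
  (0 Gy) phase percentages: the model prediction for an exponentially
  growing culture is its steady-DNA-distribution fraction vector, constant
  in time, computed from the dominant eigenmode of the transition matrix.
  The objective is minimised by bounded coordinate descent, cycled over
  (k1, g, k2, b) until stagnation, with candidate minima rejected when the
  implied cell-cycle length strays too far from the measured doubling time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize, minimize_scalar
from scipy.stats import t as student_t

from .kinetic_core import (PHASES, RateParameters, build_transition_matrix,
                           dominant_mode)

__all__ = [
    "PhaseFractions",
    "PhaseTimes",
    "GrowthFit",
    "FitResult",
    "RelativeDifference",
    "InadmissibleFitError",
    "PAPER_BOUNDS",
    "steel_phase_times",
    "rates_from_phase_times",
    "steel_rates",
    "average_fractions",
    "fit_growth_curve",
    "chi_square_objective",
    "fit_unperturbed",
    "relative_difference",
    "relative_difference_table",
]

log = logging.getLogger(__name__)

#: Bounds kept during the sham fit, per rate (1/h).
PAPER_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (0.03, 0.06),
    "g": (0.05, 0.5),
    "k2": (0.05, 0.5),
    "b": (2.0, 5.0),
}


class InadmissibleFitError(RuntimeError):
    """No minimum with an acceptable implied cell-cycle length was found.

    Carries the best inadmissible candidate in ``result``.
    """

    def __init__(self, msg: str, result: "FitResult"):
        super().__init__(msg)
        self.result = result


@dataclass(frozen=True)
class PhaseFractions:
    """Fractions of vital cells per phase, unit scale, optional SEMs."""

    f_g1: float
    f_s: float
    f_g2: float
    f_m: float
    sem_g1: float | None = None
    sem_s: float | None = None
    sem_g2: float | None = None
    sem_m: float | None = None

    def __post_init__(self):
        arr = self.as_array()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"fractions must lie in [0, 1], got {arr}")
        if not 0.999 <= arr.sum() <= 1.001:
            raise ValueError(f"fractions must sum to 1 +/- 1e-3, got {arr.sum():.4f}")

    @classmethod
    def from_percent(cls, percents, sems=None) -> "PhaseFractions":
        p = np.asarray(percents, dtype=float) / 100.0
        s = [None] * 4 if sems is None else list(np.asarray(sems, float) / 100.0)
        return cls(*p, *s)

    def as_array(self) -> np.ndarray:
        return np.array([self.f_g1, self.f_s, self.f_g2, self.f_m])

    def sem_array(self) -> np.ndarray:
        sems = [self.sem_g1, self.sem_s, self.sem_g2, self.sem_m]
        if any(s is None for s in sems):
            raise ValueError("standard errors are not set")
        return np.array(sems, dtype=float)


@dataclass(frozen=True)
class PhaseTimes:
    """Mean phase durations (hours); they sum to the doubling time."""

    t_g1: float
    t_s: float
    t_g2: float
    t_m: float
    t_d: float

    def __post_init__(self):
        total = self.t_g1 + self.t_s + self.t_g2 + self.t_m
        if abs(total - self.t_d) > 1e-9 * max(1.0, self.t_d):
            raise ValueError(
                f"phase durations sum to {total:.6f} h but T_D = {self.t_d:.6f} h")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_g1, self.t_s, self.t_g2, self.t_m])


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth-curve fit N(t) = N0 exp(gamma t)."""

    n0: float
    gamma: float
    t_d: float
    ci95: tuple[float, float]


@dataclass
class FitResult:
    """Outcome of the sham chi-square fit."""

    rates: RateParameters
    objective: float
    n_eval: int
    implied_cycle_length: float
    phi_per_cycle: list[float]


@dataclass(frozen=True)
class RelativeDifference:
    """Fractional change of an irradiated percentage relative to sham."""

    delta: float
    err: float | None = None


def steel_phase_times(fractions: PhaseFractions, t_d: float) -> PhaseTimes:
    """Mean phase durations from steady fractions and the doubling time.

    For an exponentially growing, asynchronous population the time spent in
    the terminal part of the cycle relates to the fraction of cells beyond
    that point through a log2 law; mitosis is estimated directly as
    ``T_M = T_D * f_M`` and G1 takes up the remainder.
    """
    if t_d <= 0:
        raise ValueError("t_d must be > 0")
    f = fractions
    t_m = t_d * f.f_m
    t_g2 = t_d * math.log2(f.f_g2 + f.f_m + 1.0) - t_m
    t_s = t_d * math.log2(f.f_s + f.f_g2 + f.f_m + 1.0) - t_g2 - t_m
    t_g1 = t_d - t_g2 - t_m - t_s
    for name, val in (("T_S", t_s), ("T_G1", t_g1), ("T_G2", t_g2), ("T_M", t_m)):
        if val < 0:
            raise ValueError(
                f"degenerate fractions: {name} = {val:.4f} h is negative")
    return PhaseTimes(t_g1=t_g1, t_s=t_s, t_g2=t_g2, t_m=t_m, t_d=t_d)


def rates_from_phase_times(times: PhaseTimes,
                           deaths: tuple[float, float, float, float] = (0, 0, 0, 0),
                           ) -> RateParameters:
    """Invert mean durations to rates: each duration is 1/(rate + death)."""
    durations = times.as_array()
    if (durations <= 0).any():
        raise ValueError("all phase durations must be > 0 to form rates")
    vals = 1.0 / durations - np.asarray(deaths, dtype=float)
    names = ("k1", "g", "k2", "b")
    for name, v in zip(names, vals):
        if v < 0:
            raise ValueError(
                f"death rate exceeds 1/duration: {name} would be {v:.4g}/h")
    return RateParameters(k1=vals[0], g=vals[1], k2=vals[2], b=vals[3],
                          mu_g1=deaths[0], mu_s=deaths[1],
                          mu_g2=deaths[2], mu_m=deaths[3])


def steel_rates(fractions: PhaseFractions, t_d: float) -> RateParameters:
    """Convenience composition: Steel durations -> transition rates."""
    return rates_from_phase_times(steel_phase_times(fractions, t_d))


def average_fractions(table: pd.DataFrame, dose: float = 0.0,
                      times=(0, 6, 16, 24)) -> PhaseFractions:
    """Average phase percentages of one dose over selected time points.

    ``table`` is a long experiment table (columns ``time_h, dose_Gy, phase,
    percent, sem``). The combined SEM per phase is the root mean square of
    the per-time SEMs.
    """
    sub = table[(table["dose_Gy"] == dose) & (table["time_h"].isin(times))]
    if sub.empty:
        raise ValueError(f"no rows for dose {dose} at times {times}")
    means, sems = [], []
    for phase in PHASES:
        rows = sub[sub["phase"] == phase]
        if len(rows) != len(times):
            raise ValueError(f"phase {phase}: expected {len(times)} rows, "
                             f"got {len(rows)}")
        means.append(rows["percent"].mean())
        sems.append(float(np.sqrt(np.mean(rows["sem"].to_numpy() ** 2))))
    return PhaseFractions.from_percent(means, sems)


def fit_growth_curve(times, counts) -> GrowthFit:
    """Nonlinear least-squares fit of exponential growth.

    The 95% CI on the doubling time is the gamma confidence interval
    (t-quantile on the fitted standard error) mapped through the monotone
    transform ``T_D = ln 2 / gamma``, which makes it asymmetric, wider on
    the slow-growth side. A non-positive fitted gamma yields
    ``T_D = inf`` with a warning.
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if (n <= 0).any():
        raise ValueError("counts must be positive")
    slope, intercept = np.polyfit(t, np.log(n), 1)
    p0 = (math.exp(intercept), slope)
    popt, pcov = curve_fit(lambda tt, n0, gam: n0 * np.exp(gam * tt),
                           t, n, p0=p0, maxfev=10000)
    n0, gamma = popt
    if gamma <= 0:
        log.warning("fitted growth rate gamma = %.4g <= 0; population is "
                    "not growing, T_D reported as +inf", gamma)
        return GrowthFit(n0=n0, gamma=gamma, t_d=math.inf,
                         ci95=(math.inf, math.inf))
    t_d = math.log(2.0) / gamma
    se_gamma = math.sqrt(pcov[1, 1])
    q = student_t.ppf(0.975, max(t.size - 2, 1))
    g_lo, g_hi = gamma - q * se_gamma, gamma + q * se_gamma
    hi = math.log(2.0) / g_lo if g_lo > 0 else math.inf
    return GrowthFit(n0=n0, gamma=gamma, t_d=t_d,
                     ci95=(math.log(2.0) / g_hi, hi))


def chi_square_objective(model_percent, data_percent, sems) -> float:
    """Sum of squared standardised residuals on the percent scale.

    ``model_percent`` may be a single 4-vector (a steady-state prediction
    broadcast over all times) or one row per time point.
    """
    data = np.atleast_2d(np.asarray(data_percent, dtype=float))
    sig = np.atleast_2d(np.asarray(sems, dtype=float))
    model = np.asarray(model_percent, dtype=float)
    if model.ndim == 1:
        model = np.broadcast_to(model, data.shape)
    if (sig <= 0).any():
        raise ValueError("all standard errors must be > 0")
    return float((((model - data) / sig) ** 2).sum())


def _sdd_percent(rates: RateParameters, dt: float) -> np.ndarray:
    matrix = build_transition_matrix(rates, dt)
    return dominant_mode(matrix).sdd_fractions * 100.0


def fit_unperturbed(table: pd.DataFrame,
                    init: RateParameters | None = None,
                    bounds: dict[str, tuple[float, float]] | None = None,
                    t_d: float = 38.4,
                    times=(0, 6, 16, 24),
                    dt: float = 0.05,
                    fix_b_first: bool = True,
                    b_hold: float = 3.0,
                    t_d_sigma: float | None = None,
                    max_cycles: int = 50,
                    ftol: float = 1e-6,
                    max_cycle_dev: float = 0.25) -> FitResult:
    """Chi-square fit of steady-state fractions to sham percentages.

    ``table`` is a long experiment table; only ``dose_Gy == 0`` rows at
    ``times`` enter the objective (later times are excluded because a
    culture nearing confluence is no longer in balanced exponential
    growth). The fit starts from the Steel's-formula guess (computed from
    the same data when ``init`` is None) and descends one coordinate at a
    time inside ``bounds``, first holding the division rate ``b`` at
    ``b_hold`` (its leverage on the objective is weak because M-phase
    percentages are small), then cycling over all four rates until the
    objective improves by less than ``ftol``, and finishes with a joint
    bounded Powell polish of all four rates.

    Steady-state fractions alone leave one direction of parameter space
    unconstrained (four rates, three independent fractions), so the
    measured doubling time enters the objective as one more chi-square
    term, ``((C - t_d)/t_d_sigma)**2`` with ``C`` the implied cycle length
    — the doubling time is a measurement with its own uncertainty, and it
    is exactly the quantity that resolves the flat direction.
    ``t_d_sigma`` defaults to 12% of ``t_d``, the relative uncertainty of
    the reference growth-curve fit. A result whose implied cycle length
    still deviates from ``t_d`` by more than ``max_cycle_dev`` (fractional)
    raises :class:`InadmissibleFitError` carrying the best candidate. The
    reported ``objective`` is the data-only chi-square.
    """
    bounds = dict(PAPER_BOUNDS if bounds is None else bounds)
    sub = table[(table["dose_Gy"] == 0) & (table["time_h"].isin(times))]
    data = np.array([[float(sub[(sub["time_h"] == t) & (sub["phase"] == ph)]
                           ["percent"].iloc[0]) for ph in PHASES]
                     for t in times])
    sems = np.array([[float(sub[(sub["time_h"] == t) & (sub["phase"] == ph)]
                           ["sem"].iloc[0]) for ph in PHASES]
                     for t in times])
    if init is None:
        init = steel_rates(average_fractions(table, dose=0.0, times=times), t_d)
    if t_d_sigma is None:
        t_d_sigma = 0.12 * t_d

    n_eval = 0

    def phi_data(params: dict[str, float]) -> float:
        nonlocal n_eval
        n_eval += 1
        rates = RateParameters(**params)
        return chi_square_objective(_sdd_percent(rates, dt), data, sems)

    def phi(params: dict[str, float]) -> float:
        cycle = sum(1.0 / params[n] for n in ("k1", "g", "k2", "b"))
        return phi_data(params) + ((cycle - t_d) / t_d_sigma) ** 2

    names = ("k1", "g", "k2", "b")
    current = {"k1": init.k1, "g": init.g, "k2": init.k2, "b": init.b}
    for name in names:  # clip the initial guess into the box
        lo, hi = bounds[name]
        current[name] = min(max(current[name], lo), hi)
    cur_phi = phi(current)
    phi_per_cycle = [cur_phi]

    def descend(name: str):
        nonlocal cur_phi
        def f(x):
            trial = dict(current)
            trial[name] = x
            return phi(trial)
        res = minimize_scalar(f, bounds=bounds[name], method="bounded",
                              options={"xatol": 1e-6})
        if res.fun < cur_phi:  # never accept a worse coordinate value
            current[name] = float(res.x)
            cur_phi = float(res.fun)

    if fix_b_first:
        lo, hi = bounds["b"]
        current["b"] = min(max(b_hold, lo), hi)
        cur_phi = phi(current)
        for name in ("k1", "g", "k2"):
            descend(name)
        phi_per_cycle.append(cur_phi)

    for _ in range(max_cycles):
        before = cur_phi
        for name in names:
            descend(name)
        phi_per_cycle.append(cur_phi)
        if before - cur_phi < ftol:
            break

    # Joint bounded polish: one-coordinate-at-a-time descent stalls in the
    # diagonal valley the doubling-time term creates, so finish with a
    # direction-set (Powell) minimisation over all four rates at once.
    joint = minimize(lambda x: phi(dict(zip(names, x))),
                     [current[n] for n in names], method="Powell",
                     bounds=[bounds[n] for n in names],
                     options={"xtol": 1e-12, "ftol": 1e-14,
                              "maxiter": 10000, "maxfev": 100000})
    if joint.fun < cur_phi:
        current = dict(zip(names, (float(v) for v in joint.x)))
        cur_phi = float(joint.fun)
        phi_per_cycle.append(cur_phi)

    rates = RateParameters(**current)
    cycle_len = rates.implied_cycle_length()
    result = FitResult(rates=rates, objective=phi_data(current), n_eval=n_eval,
                       implied_cycle_length=cycle_len,
                       phi_per_cycle=phi_per_cycle)
    if abs(cycle_len - t_d) / t_d > max_cycle_dev:
        raise InadmissibleFitError(
            f"implied cycle length {cycle_len:.2f} h deviates from the "
            f"measured doubling time {t_d:.2f} h by more than "
            f"{max_cycle_dev:.0%}", result)
    return result


def relative_difference(f_dose: float, f_sham: float,
                        sems: tuple[float, float] | None = None,
                        ) -> RelativeDifference:
    """Fractional change (f_dose - f_sham) / f_sham with propagated error.

    The uncertainty assumes independent errors on the two percentages
    (first-order propagation).
    """
    if f_sham == 0:
        raise ValueError("sham percentage must be non-zero")
    delta = (f_dose - f_sham) / f_sham
    err = None
    if sems is not None:
        s_dose, s_sham = sems
        err = math.sqrt((s_dose / f_sham) ** 2
                        + (f_dose * s_sham / f_sham ** 2) ** 2)
    return RelativeDifference(delta=delta, err=err)


def relative_difference_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(time, dose, phase) relative differences of irradiated vs sham.

    Mirrors the layout of the packaged relative-difference fixture:
    columns ``time_h, dose_Gy, phase, delta, err``.
    """
    out = []
    doses = sorted(d for d in table["dose_Gy"].unique() if d != 0)
    for t in sorted(table["time_h"].unique()):
        sham = table[(table["time_h"] == t) & (table["dose_Gy"] == 0)]
        if sham.empty:
            continue
        for dose in doses:
            irr = table[(table["time_h"] == t) & (table["dose_Gy"] == dose)]
            if irr.empty:
                continue
            for phase in PHASES:
                srow = sham[sham["phase"] == phase].iloc[0]
                irow = irr[irr["phase"] == phase].iloc[0]
                rd = relative_difference(irow["percent"], srow["percent"],
                                         sems=(irow["sem"], srow["sem"]))
                out.append({"time_h": t, "dose_Gy": dose, "phase": phase,
                            "delta": rd.delta, "err": rd.err})
    return pd.DataFrame(out)
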