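"""Age-structured matrix model of cell-cycle progression.

Four compartments (G1, S, G2, M) track a population of cycling cells. The
S-phase is age-structured: cells entering S are pushed through a delay line
of bins spaced ``dt`` hours apart, so every cell spends exactly
``T_S = 1/g`` hours replicating DNA before moving to G2 (``g`` is the DNA
synthesis rate). All other transitions are first-order with rates ``k1``
(G1 -> S), ``k2`` (G2 -> M) and ``b`` (division, M -> 2 G1). Optional death
rates ``mu_*`` remove cells from each phase; they default to zero, which
describes the vital-cells-only bookkeeping of flow-cytometry phase
percentages.

The update over one time step is linear, ``u(t+dt) = A u(t)``, where ``u``
stacks ``[n_G1, n_S(age 0), ..., n_S(age T_S), n_G2, n_M]``. The dominant
eigenpair of ``A`` gives the asymptotic exponential-growth state: the
eigenvalue sets the population growth factor per step (hence the doubling
time) and the eigenvector, collapsed to four phase totals, gives the steady
phase fractions. The same steady state is reached by forward simulation
from any non-degenerate start; the time to get there from a fully
G1-synchronised population is the convergence time to the steady DNA
distribution (SDD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "StabilityError",
    "ConvergenceError",
    "RateParameters",
    "SimConfig",
    "AgeStructuredState",
    "TransitionMatrix",
    "SDDResult",
    "DominantMode",
    "build_transition_matrix",
    "step_population",
    "evolve_to_sdd",
    "dominant_mode",
    "simulate_timecourse",
    "PHASES",
    "FRACTION_COLUMNS",
]

PHASES = ("G1", "S", "G2", "M")
FRACTION_COLUMNS = ("f_G1", "f_S", "f_G2", "f_M")


class StabilityError(ValueError):
    """A rate is too large for the requested time step (negative diagonal)."""


class ConvergenceError(RuntimeError):
    """Forward simulation failed to reach the steady DNA distribution."""

    def __init__(self, msg: str, last_residual: float | None = None):
        super().__init__(msg)
        self.last_residual = last_residual


@dataclass(frozen=True)
class RateParameters:
    """Kinetic parameters, all per hour.

    k1: G1 -> S transition rate; g: DNA synthesis rate (1/T_S);
    k2: G2 -> M transition rate; b: division rate (M -> 2 G1);
    mu_*: per-phase death rates, zero for vital-cells-only analyses.
    """

    k1: float
    g: float
    k2: float
    b: float
    mu_g1: float = 0.0
    mu_s: float = 0.0
    mu_g2: float = 0.0
    mu_m: float = 0.0

    def __post_init__(self):
        for name in ("k1", "g", "k2", "b", "mu_g1", "mu_s", "mu_g2", "mu_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={v!r} must be finite and >= 0")
        if self.g <= 0:
            raise ValueError("g must be > 0 (finite S duration sizes the delay line)")

    @property
    def t_s(self) -> float:
        """Mean S-phase duration in hours."""
        return 1.0 / self.g

    def implied_cycle_length(self) -> float:
        """Sum of mean phase durations 1/k1 + 1/g + 1/k2 + 1/b (hours)."""
        return 1.0 / self.k1 + 1.0 / self.g + 1.0 / self.k2 + 1.0 / self.b

    def scaled(self, k1: float = 1.0, g: float = 1.0, k2: float = 1.0,
               b: float = 1.0) -> "RateParameters":
        """Return a copy with the four kinetic rates multiplied by factors."""
        return replace(self, k1=self.k1 * k1, g=self.g * g,
                       k2=self.k2 * k2, b=self.b * b)


@dataclass(frozen=True)
class SimConfig:
    """Discretisation and convergence settings.

    dt: forward-difference step (hours). sdd_tol: threshold on the lagged
    sum of squared phase-fraction differences that declares the steady DNA
    distribution reached. sdd_lag: comparison lag in hours (must be a
    multiple of dt). fraction_scale: whether the convergence criterion sees
    fractions on the unit scale [0, 1] or the percent scale [0, 100].
    max_horizon: give up after this many simulated hours.
    """

    dt: float = 0.05
    sdd_tol: float = 1e-4
    sdd_lag: float = 5.0
    fraction_scale: str = "unit"
    max_horizon: float = 500.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sdd_tol <= 0:
            raise ValueError("sdd_tol must be > 0")
        if self.fraction_scale not in ("unit", "percent"):
            raise ValueError("fraction_scale must be 'unit' or 'percent'")
        n = self.sdd_lag / self.dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("sdd_lag must be a positive integer multiple of dt")

    @property
    def lag_steps(self) -> int:
        return int(round(self.sdd_lag / self.dt))

    @property
    def scale_factor(self) -> float:
        return 100.0 if self.fraction_scale == "percent" else 1.0


def n_age_bins(g: float, dt: float) -> int:
    """Delay-line length: ages 0, dt, ..., T_S with T_S = 1/g."""
    return int(round((1.0 / g) / dt)) + 1


@dataclass
class AgeStructuredState:
    """Cell counts per compartment, S-phase resolved by age since entry.

    ``ns[j]`` holds cells that entered S-phase ``j*dt`` hours ago; the last
    bin (age T_S) empties wholly into G2 at the next step.
    """

    n1: float
    ns: np.ndarray
    n2: float
    nm: float
    t: float = 0.0

    def __post_init__(self):
        self.ns = np.asarray(self.ns, dtype=float)
        if self.ns.ndim != 1 or self.ns.size < 1:
            raise ValueError("ns must be a 1-d array with at least one age bin")
        if self.n1 < 0 or self.n2 < 0 or self.nm < 0 or (self.ns < 0).any():
            raise ValueError("cell counts must be non-negative")
        if not np.isfinite(self.total()):
            raise ValueError("total cell count must be finite")

    @classmethod
    def all_in_g1(cls, rates: RateParameters, dt: float,
                  n1: float = 1.0) -> "AgeStructuredState":
        """Fully G1-synchronised population (the canonical initial state)."""
        return cls(n1=n1, ns=np.zeros(n_age_bins(rates.g, dt)), n2=0.0, nm=0.0)

    @classmethod
    def from_vector(cls, u: np.ndarray, t: float = 0.0) -> "AgeStructuredState":
        u = np.asarray(u, dtype=float)
        return cls(n1=u[0], ns=u[1:-2].copy(), n2=u[-2], nm=u[-1], t=t)

    @property
    def n_age_bins(self) -> int:
        return int(self.ns.size)

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.n1], self.ns, [self.n2, self.nm]))

    def total(self) -> float:
        return float(self.n1 + self.ns.sum() + self.n2 + self.nm)

    def fractions(self) -> np.ndarray:
        """Phase fractions (G1, S, G2, M) on the unit scale."""
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot compute fractions of an empty population")
        return np.array([self.n1, self.ns.sum(), self.n2, self.nm]) / tot


@dataclass
class TransitionMatrix:
    """One-step update operator for the stacked state vector."""

    entries: np.ndarray
    dt: float
    n_age_bins: int
    _csr: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def dim(self) -> int:
        return self.entries.shape[0]

    @property
    def csr(self) -> sp.csr_matrix:
        if self._csr is None:
            self._csr = sp.csr_matrix(self.entries)
        return self._csr

    def collapse_to_phases(self, u: np.ndarray) -> np.ndarray:
        nb = self.n_age_bins
        return np.array([u[0], u[1:nb + 1].sum(), u[nb + 1], u[nb + 2]])


@dataclass
class SDDResult:
    """Outcome of forward simulation to the steady DNA distribution."""

    t_sdd: float
    fractions: np.ndarray
    state: AgeStructuredState
    trajectory: pd.DataFrame


@dataclass
class DominantMode:
    """Dominant eigenpair of the transition matrix, per-step growth factor
    lambda, steady phase fractions, and the implied doubling time."""

    growth_factor: float
    sdd_fractions: np.ndarray
    doubling_time: float


def build_transition_matrix(rates: RateParameters, dt: float) -> TransitionMatrix:
    """Assemble the one-step forward-difference update matrix.

    Columns are conservative (sum to 1) except the M column, which sums to
    ``1 + b*dt`` because each division removes one M cell and deposits two
    daughters in G1. Raises :class:`StabilityError` if any retention
    coefficient ``1 - (rate + death)*dt`` would be negative.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for name, rate, mu in (("k1", rates.k1, rates.mu_g1),
                           ("k2", rates.k2, rates.mu_g2),
                           ("b", rates.b, rates.mu_m)):
        if (rate + mu) * dt > 1.0 + 1e-12:
            raise StabilityError(
                f"({name} + death)*dt = {(rate + mu) * dt:.4g} > 1: "
                f"rate {name}={rate:.4g}/h is unstable at dt={dt:.4g} h")
    if rates.mu_s * dt > 1.0 + 1e-12:
        raise StabilityError(
            f"mu_s*dt = {rates.mu_s * dt:.4g} > 1: death rate mu_s is "
            f"unstable at dt={dt:.4g} h")

    nb = n_age_bins(rates.g, dt)
    n = nb + 3
    i_g2, i_m = nb + 1, nb + 2
    a = np.zeros((n, n))
    a[0, 0] = 1.0 - (rates.k1 + rates.mu_g1) * dt
    a[0, i_m] = 2.0 * rates.b * dt
    a[1, 0] = rates.k1 * dt
    s_survival = 1.0 - rates.mu_s * dt  # age bins advance, minus S-phase deaths
    rows = np.arange(2, nb + 1)
    a[rows, rows - 1] = s_survival
    a[i_g2, nb] = s_survival
    a[i_g2, i_g2] = 1.0 - (rates.k2 + rates.mu_g2) * dt
    a[i_m, i_g2] = rates.k2 * dt
    a[i_m, i_m] = 1.0 - (rates.b + rates.mu_m) * dt
    return TransitionMatrix(entries=a, dt=dt, n_age_bins=nb)


def step_population(state: AgeStructuredState,
                    matrix: TransitionMatrix) -> AgeStructuredState:
    """Advance the population by one step of ``matrix.dt`` hours."""
    u = state.as_vector()
    if u.size != matrix.dim:
        raise ValueError(
            f"state dimension {u.size} does not match matrix dimension "
            f"{matrix.dim} (n_age_bins {state.n_age_bins} vs {matrix.n_age_bins})")
    return AgeStructuredState.from_vector(matrix.entries @ u,
                                          t=state.t + matrix.dt)


def _fractions_of(u: np.ndarray, nb: int) -> np.ndarray:
    tot = u.sum()
    return np.array([u[0], u[1:nb + 1].sum(), u[nb + 1], u[nb + 2]]) / tot


def evolve_to_sdd(rates: RateParameters,
                  config: SimConfig = SimConfig(),
                  initial: AgeStructuredState | None = None) -> SDDResult:
    """Step forward until phase fractions stop drifting.

    Starting (by default) from a fully G1-synchronised population, the state
    advances in steps of ``config.dt``. From ``t >= sdd_lag`` onward, every
    step compares the current phase fractions with those ``sdd_lag`` hours
    earlier; the first time the sum over the four phases of squared
    differences (on ``config.fraction_scale``) drops below ``sdd_tol``, the
    elapsed time is reported as the SDD convergence time.
    """
    matrix = build_transition_matrix(rates, config.dt)
    if initial is None:
        initial = AgeStructuredState.all_in_g1(rates, config.dt)
    u = initial.as_vector()
    if u.size != matrix.dim:
        raise ValueError("initial state dimension does not match the rates/dt")
    nb = matrix.n_age_bins
    lag = config.lag_steps
    scale = config.scale_factor

    history = [_fractions_of(u, nb)]
    n_steps = int(round(config.max_horizon / config.dt))
    residual = None
    a = matrix.entries
    for i in range(1, n_steps + 1):
        u = a @ u
        if u.sum() > 1e250:  # keep exponential growth inside float range
            u = u / u.sum()
        frac = _fractions_of(u, nb)
        history.append(frac)
        if i >= lag:
            diff = (frac - history[i - lag]) * scale
            residual = float(diff @ diff)
            if residual < config.sdd_tol:
                t_sdd = i * config.dt
                traj = _trajectory_frame(history, config.dt)
                state = AgeStructuredState.from_vector(u, t=t_sdd)
                return SDDResult(t_sdd=t_sdd, fractions=frac, state=state,
                                 trajectory=traj)
    raise ConvergenceError(
        f"no steady DNA distribution within {config.max_horizon} h "
        f"(last residual {residual!r})", last_residual=residual)


def _trajectory_frame(history: list[np.ndarray], dt: float) -> pd.DataFrame:
    arr = np.asarray(history)
    return pd.DataFrame(
        {"time_h": np.arange(arr.shape[0]) * dt,
         **{col: arr[:, j] for j, col in enumerate(FRACTION_COLUMNS)}})


def _dominant_mode_closed_form(matrix: TransitionMatrix):
    """Perron eigenpair via the scalar characteristic equation.

    Because the S delay line only shifts mass, an eigenvector's S bins are
    geometric with ratio (survival/lambda), and eliminating them reduces
    the eigenproblem to one scalar equation in lambda:

        (lambda - c1)(lambda - c2)(lambda - cM) = d e1 e2 (s/lambda)^nb

    with c* the diagonal retention coefficients, e1 the G1->S flux, e2 the
    G2->M flux, d the division feedback M->G1 and s the per-step S-phase
    survival. For positive fluxes the update matrix is primitive, so the
    Perron root is the unique root with all three factors positive; it is
    bracketed by max(c*) and the largest column sum. Returns None when the
    structure is degenerate (a zero flux breaks the cycle).
    """
    from scipy.optimize import brentq

    a = matrix.entries
    nb = matrix.n_age_bins
    i2, im = nb + 1, nb + 2
    c1, c2, cm = a[0, 0], a[i2, i2], a[im, im]
    e1, e2, d = a[1, 0], a[im, i2], a[0, im]
    s = a[i2, nb]  # per-step survival along the delay line
    if e1 <= 0 or e2 <= 0 or d <= 0:
        return None

    def f(lam: float) -> float:
        return ((lam - c1) * (lam - c2) * (lam - cm)
                - d * e1 * e2 * (s / lam) ** nb)

    lo = max(c1, c2, cm, 1e-12) + 1e-15
    hi = max(1.0, float(a.sum(axis=0).max())) + 1e-9
    while f(hi) < 0:  # defensive: widen until the root is bracketed
        hi *= 2
        if hi > 1e6:
            return None
    lam = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)

    q = s / lam
    s0 = e1 / lam  # n1 normalised to 1
    if abs(1.0 - q) < 1e-12:
        s_total = s0 * nb
    else:
        s_total = s0 * (1.0 - q ** nb) / (1.0 - q)
    n2 = s0 * lam * q ** nb / (lam - c2)
    nm = e2 * n2 / (lam - cm)
    fractions = np.array([1.0, s_total, n2, nm])
    return lam, fractions / fractions.sum()


def dominant_mode(matrix: TransitionMatrix,
                  imag_tol: float = 1e-8) -> DominantMode:
    """Largest-magnitude eigenpair, collapsed to phase fractions.

    Solved in closed form through the scalar characteristic equation of
    the delay-line structure whenever the phase cycle is complete; ARPACK
    (or a dense solve for tiny matrices) covers degenerate structures. The
    doubling time is ``dt * ln 2 / ln lambda`` (infinite when lambda == 1).
    """
    closed = _dominant_mode_closed_form(matrix)
    if closed is not None:
        lam, fractions = closed
        if abs(lam - 1.0) < 1e-12:
            doubling = math.inf
        else:
            doubling = matrix.dt * math.log(2.0) / math.log(lam)
        return DominantMode(growth_factor=lam, sdd_fractions=fractions,
                            doubling_time=doubling)
    n = matrix.dim
    if n >= 8:
        vals, vecs = spla.eigs(matrix.csr, k=1, which="LM",
                               v0=np.ones(n), tol=0)
        lam, vec = vals[0], vecs[:, 0]
    else:
        vals, vecs = np.linalg.eig(matrix.entries)
        k = int(np.argmax(np.abs(vals)))
        lam, vec = vals[k], vecs[:, k]
    if abs(lam.imag) > imag_tol * max(1.0, abs(lam.real)):
        raise ValueError(
            f"dominant eigenvalue {lam!r} is complex beyond tolerance; "
            "the transition matrix is malformed")
    lam = float(lam.real)
    vec = np.real(vec)
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    fractions = matrix.collapse_to_phases(vec)
    fractions = fractions / fractions.sum()
    if lam <= 0:
        raise ValueError(f"non-positive dominant eigenvalue {lam}")
    if abs(lam - 1.0) < 1e-12:
        doubling = math.inf
    else:
        doubling = matrix.dt * math.log(2.0) / math.log(lam)
    return DominantMode(growth_factor=lam, sdd_fractions=fractions,
                        doubling_time=doubling)


RateSchedule = RateParameters | list[tuple[float, RateParameters]]


def simulate_timecourse(rates: RateSchedule,
                        horizon: float,
                        config: SimConfig,
                        initial: AgeStructuredState) -> pd.DataFrame:
    """Simulate phase fractions over ``[0, horizon]`` hours.

    ``rates`` is either a single :class:`RateParameters` (constant) or an
    ordered list of ``(t_start, RateParameters)`` segments, applied
    right-continuously (a segment's rates hold on ``[t_start, t_next)``).
    The transition matrix is rebuilt only at segment breakpoints. All
    segments must share ``g``, since the S-phase delay-line length is fixed
    by the state's age structure. Returns a frame with one row per step:
    columns ``time_h, f_G1, f_S, f_G2, f_M`` (unit scale).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if isinstance(rates, RateParameters):
        segments = [(0.0, rates)]
    else:
        segments = sorted(rates, key=lambda p: p[0])
        if not segments or segments[0][0] > 0:
            raise ValueError("rate segments must cover t = 0")
    g0 = segments[0][1].g
    for t0, r in segments:
        if abs(r.g - g0) > 1e-12 * max(1.0, g0):
            raise ValueError(
                "all segments must share the DNA synthesis rate g "
                "(the S-phase delay line cannot be resized mid-run)")

    dt = config.dt
    n_steps = int(round(horizon / dt))
    u = initial.as_vector()
    nb = initial.n_age_bins
    records = [_fractions_of(u, nb)]
    seg_idx = 0
    matrix = None
    for i in range(n_steps):
        t = i * dt
        while seg_idx + 1 < len(segments) and segments[seg_idx + 1][0] <= t + 1e-9:
            seg_idx += 1
            matrix = None
        if matrix is None:
            try:
                matrix = build_transition_matrix(segments[seg_idx][1], dt)
            except StabilityError as err:
                raise StabilityError(
                    f"segment starting at t={segments[seg_idx][0]} h: {err}"
                ) from err
            if matrix.dim != u.size:
                raise ValueError("segment rates imply a different delay-line "
                                 "length than the state carries")
        u = matrix.entries @ u
        if u.sum() > 1e250:
            u = u / u.sum()
        records.append(_fractions_of(u, nb))
    frame = _trajectory_frame(records, dt)
    frame["time_h"] += initial.t
    return frame
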