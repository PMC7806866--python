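# Methods

## Model

Four compartments track vital cells by cell-cycle phase. G1, G2 and M are
well-mixed pools drained by first-order kinetics: k1 (G1 → S), k2 (G2 → M)
and the division rate b (M → 2 G1, the factor 2 making the M column of the
update matrix sum to 1 + b·Δt). S-phase is age-structured: DNA synthesis
proceeds at constant rate g, so every cell resides in S for exactly
T_S = 1/g hours; the implementation is a delay line of
`round(T_S/Δt) + 1` age bins that shift by one bin per step, the last bin
emptying wholly into G2. Optional per-phase death rates μ enter as extra
diagonal losses; they default to 0 because flow-cytometry phase
percentages are computed over living cells only, and all shipped analyses
keep them at 0.

Assumptions inherited by everything downstream: transitions are complete
and irreversible; G1, G2 and M durations are exponentially distributed
while S duration is fixed; the population is well mixed (no spatial
structure, no quiescent pool, no explicit death). Under these assumptions
an unperturbed population converges to balanced exponential growth with
constant phase fractions — the steady DNA distribution (SDD).

## Dominant eigenmode

The per-step update matrix A is non-negative and, when k1, k2, b and g are
all positive, primitive, so its Perron eigenvalue λ fixes the asymptotic
growth factor and its eigenvector the SDD fractions. Because the delay
line only shifts mass, an eigenvector's S bins form a geometric sequence
with ratio (survival/λ); eliminating them collapses the eigenproblem to a
scalar characteristic equation

    (λ − c1)(λ − c2)(λ − cM) = d·e1·e2·(s/λ)^nb,

(c\* the diagonal retention coefficients, e1/e2 the G1→S and G2→M fluxes,
d the division feedback, s the per-step S survival, nb the bin count),
solved with `brentq` between max(c\*) and the largest column sum to
machine precision. This agrees with a dense `numpy.linalg.eig` solve to
~1e-13 (tested) and is ~10³× faster, which is what makes the calibration
and the simulation studies cheap. Degenerate structures (a broken cycle,
e.g. b = 0) fall back to ARPACK or a dense solve. Doubling time is
Δt·ln2/lnλ, infinite at λ = 1.

## SDD convergence criterion

Started from 100% of cells in G1, the model is stepped with Δt = 0.05 h;
from t ≥ 5 h onward each step compares the current phase-fraction vector
with the one 5 h earlier, and convergence is declared the first time the
sum over the four phases of squared differences drops below the
tolerance. Fractions enter the criterion on the unit scale by default
(configurable to percent). The default tolerance is 1e-4, i.e. a combined
phase-fraction drift below about 1 percentage point over 5 h — far below
the measurement errors of the reference data (SEMs of 0.3–2 points). With
the reference initial rates this yields T_SDD = 40.45 h (809 steps).
Convergence is checked at every step; the run errors out (carrying the
last residual) if the horizon (default 500 h) is exhausted.

## Calibration

**Steel initialisation.** For an asynchronous exponentially growing
population, the measured steady fractions and doubling time give mean
phase durations: T_M = T_D·f_M, T_G2 = T_D·log2(f_G2 + f_M + 1) − T_M,
T_S = T_D·log2(f_S + f_G2 + f_M + 1) − T_G2 − T_M, and T_G1 as the
remainder, so durations sum to T_D identically. Rates are reciprocals of
durations (minus any death rate). These formulas assume fixed phase
durations, whereas the model's gap phases are exponential, so the model
run at Steel-initialised rates lands near, not on, the measured fractions
(within 3 SEM for the reference data — a tested property); they are an
initial guess, not the answer.

**χ² fit.** The model prediction for the fitted (sham, 0–24 h) window is
its SDD percentage vector, constant in time — later time points are
excluded because the culture approaches confluence and leaves balanced
growth. The objective is the standard chi-square over 4 phases × 4 time
points, plus one term ((C − T_D)/σ_TD)² with C the implied cycle length
1/k1 + 1/g + 1/k2 + 1/b and σ_TD = 12% of T_D, the relative width of the
growth-curve confidence interval. This term is required for
identifiability: the steady fractions carry 3 degrees of freedom against
4 parameters, so the data term alone has an exactly flat one-dimensional
minimum ridge, and the doubling time is precisely the measurement that
selects a point on it. Optimisation is deliberately local: bounded scalar
minimisation of each rate in the order (k1, g, k2, b) — first with b held
at 3, since the tiny M-phase percentages give it little leverage — cycled
to stagnation, then a joint bounded Powell polish. Staying near the Steel
initialisation is part of the procedure's definition (distant minima are
not trusted); results whose implied cycle length deviates from T_D by
more than 25% are rejected with the best candidate attached to the error.
Known wrinkle: the objective is piecewise in g because the delay-line bin
count is an integer, and the polish can park at a piece edge; in
round-trip experiments recovery of k1 and k2 is then limited to several
percent instead of being exact.

**Growth curve.** N(t) = N0·exp(γt) by nonlinear least squares;
T_D = ln2/γ. The 95% CI is the t-quantile interval on γ mapped through
ln2/γ (asymmetric, wider on the slow side). Its finite-sample coverage
under the synthetic generator's conditions measures ~89%, a few points
under nominal, as expected of a Wald interval at this sample size.

**Relative differences.** δ = (f_dose − f_sham)/f_sham per time, dose and
phase, with first-order error propagation assuming independent errors.

## Radiation perturbation

Exposure is modelled as piecewise-constant multipliers on the baseline
rates versus time since irradiation (t = 0 at exposure, the baseline
having first reached its SDD). Only k1 and k2 are perturbed: the
checkpoints sit in the gap phases, and S and M keep their average
durations. Presets, relative to baseline:

* **2 Gy** — k2 ×1/12 on [0, 6) h (G2 block), ×1/2 from 6 h on;
  k1 ×1/10 on [6, 48) h, ×1/5 from 48 h on.
* **5 Gy** — k2 ×1/12 on [0, 24) h, ×1/4 from 24 h on;
  k1 ×1/10 from 16 h on.

Segments are right-continuous and must tile [0, ∞). Two readings the
source data leave open are fixed as: the 2 Gy k2 recovery between 6 and
16 h is a single step to 1/2 (step functions, not ramps), and the 5 Gy k2
stays at 1/12 through the unspecified 16–24 h window. Multipliers on g
are representable in schedule files but rejected at simulation time,
because resizing the S delay line mid-run would require resampling the
age structure. The update matrix is rebuilt only at segment breakpoints.

## DNA-content profiles

Compartment counts are dressed with Gaussians over relative DNA content
x: G1 at mean 1, G2 and M at mean 2, and each S age bin at mean
1 + (2−1)·τ/T_S with variance interpolating linearly from θ₁² = 0.05 to
θ₂² = 0.1 (defaults). The grid runs to x_max = 4 in steps of 0.01, sized
so truncated Gaussian mass is < 1e-6; per-phase trapezoidal mass matches
compartment counts to 1e-4 (warned otherwise), and histogram binning
integrates the density so total mass is conserved. At the default
(broad) variances the reconstructed steady profile shows the G1 peak with
an S/G2 shoulder; the classic two-peaks-with-plateau cytometry shape
appears at narrower spread (e.g. θ₁² = 0.01).

## Synthetic data

The generator emulates the measurement process behind the packaged
tables: run the model (identity schedule → exact eigen-mode SDD
percentages; otherwise the perturbed simulation sampled at the requested
times), add independent per-phase Gaussian noise on the percent scale,
truncate at zero and renormalise each sample to 100%. Default noise SDs
(1.59, 1.52, 1.01, 0.28 points for G1/S/G2/M) equal the RMS standard
errors of the reference sham window, and the recorded `sem` column keeps
that scale even for noiseless tables so chi-square weights stay defined.
Growth curves are n0·exp(γt)·(1 + ε), ε ~ N(0, cv). One integer seed
drives the whole stream; equal seeds give bit-identical tables. What the
generator does **not** emulate: correlated errors between phases (beyond
the renormalisation), replicate-level biological variance components,
confluence effects at late times, and cell death — so passing recovery
tests demonstrate correctness of the machinery under the stated error
model, not robustness to every feature of real cultures.

## Problem sizes and tolerances

Default runs use a 274-dimensional state (271 S age bins at g = 0.074,
Δt = 0.05 h); an SDD run is ~800 steps, a 72 h perturbed simulation 1440
steps. The calibration evaluates the closed-form eigenmode a few hundred
times and completes in well under a second; the 20-dataset recovery study
in the test suite takes a few seconds. Conservation and non-negativity
hold to 1e-12 over 10⁴ steps (tested); eigen-mode and long-run simulated
fractions agree to 1e-3.

## Limitations

The model is phenomenological: perturbed rates are descriptive step
functions, not mechanistic checkpoint kinetics, and are calibrated per
dose rather than interpolated across doses. Cell death and quiescence are
carried as parameters but not exercised. M-phase percentages below ~0.1%
are at the edge of what the step-function perturbation can reproduce —
simulated M fractions after irradiation stay several measurement SEMs
above the smallest observed values. The fit is local by design; a global
treatment would need either a richer data window (time-resolved
relaxation, not just the steady state) or a hard cycle-length constraint,
each changing the reported optimum.
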