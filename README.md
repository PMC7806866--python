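# cyclekin

Deterministic compartmental modelling of cell-cycle progression and its
perturbation by ionizing radiation, for radiobiology and flow-cytometry
labs that measure phase percentages (G1 / S / G2 / M) over time and want a
kinetic model behind them.

## The model

A population of cycling cells is split into four compartments. G1, G2 and
M empty by first-order kinetics with transition rates k1 (G1 → S), k2
(G2 → M) and division rate b (each division returns two G1 daughters);
S-phase is age-structured: every cell spends exactly T_S = 1/g hours
synthesising DNA, implemented as a delay line of age bins spaced by the
time step Δt. One forward-difference step is the linear update

    u(t + Δt) = A · u(t),

where u stacks `[n_G1, n_S(age 0), …, n_S(age T_S), n_G2, n_M]`. The
dominant eigenvalue of A gives the asymptotic growth factor per step
(hence the population doubling time T_D = Δt·ln2/lnλ) and its eigenvector
the steady phase fractions — the *steady DNA distribution* (SDD) of an
asynchronous exponentially growing culture.

Calibration runs in two steps:

1. **Steel's formulas** convert measured steady fractions f_phase and the
   doubling time into mean phase durations (T_M = T_D·f_M,
   T_G2 = T_D·log2(f_G2+f_M+1) − T_M, …); their reciprocals are the
   initial rate estimates.
2. **χ² fit**: Φ = Σ_k Σ_j (M_j − f_j(t_k))²/σ²_j(t_k) compares the
   model's SDD percentages with the measured sham (0 Gy) percentages,
   plus one term ((C − T_D)/σ_TD)² tying the implied cycle length
   C = 1/k1 + 1/g + 1/k2 + 1/b to the measured doubling time. Bounded
   sequential minimisation over (k1, g, k2, b) with a joint Powell polish.

Radiation response is modelled as piecewise-constant multipliers on k1 and
k2 versus time after exposure (checkpoint arrest at G1/S and G2/M);
presets reproduce IMR90 fibroblast data at 2 and 5 Gy. DNA-content
histograms are reconstructed by superimposing Gaussians (G1 at relative
content x = 1, G2/M at x = 2, S interpolating between them).

## Worked example

```python
import cyclekin as ck

table = ck.load_fixture("table1")          # measured phase percentages
fr = ck.average_fractions(table)           # sham average over 0-24 h
rates = ck.steel_rates(fr, t_d=38.4)       # Steel initial estimates
print(f"k1={rates.k1:.4f} g={rates.g:.4f} k2={rates.k2:.4f} b={rates.b:.4f}")

sdd = ck.evolve_to_sdd(rates)              # from 100% G1 to steady state
print(f"T_SDD = {sdd.t_sdd:.2f} h, fractions = {sdd.fractions.round(4)}")

fit = ck.fit_unperturbed(table)            # chi-square refinement
r = fit.rates
print(f"fit: k1={r.k1:.4f} g={r.g:.4f} k2={r.k2:.4f} b={r.b:.4f} "
      f"(cycle {fit.implied_cycle_length:.1f} h)")
```

prints

```
k1=0.0496 g=0.0740 k2=0.2272 b=3.2583
T_SDD = 40.45 h, fractions = [0.5647 0.3427 0.0867 0.006 ]
fit: k1=0.0445 g=0.0745 k2=0.2304 b=2.6430 (cycle 40.6 h)
```

The Steel estimates say a 38.4-h cell cycle with those phase percentages
implies ~20 h in G1 and ~13.5 h in S; started fully G1-synchronised, the
model settles into balanced growth after ~40 h; the fit then nudges the
rates so the steady percentages match the data within measurement error.
A 2 Gy exposure is then one line:

```python
tc = ck.simulate_perturbed(r, ck.preset_schedule(2), horizon=72.0)
```

whose G2 fraction peaks at 6 h post-exposure (the radiation-induced G2
block) before cells pile up in G1. The same pipeline is scriptable from
the shell via the `cyclekin` command (`steel`, `simulate`, `fit-sham`,
`perturb`, `profile`, `synth`).

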