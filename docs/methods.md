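# Methods

## Model overview

A tumorlet is one well-mixed, PET-voxel-sized tumor subvolume: 64 mm³ at
10⁶ cells/mm³ (N₀ = 6.4×10⁷ cells), of which 1% are clonogens. Its
blood supply — hence the amount of oxygen and glucose available — is
assumed constant over the course of treatment. That single conservation
assumption fixes the architecture: cells with oxygen and glucose
proliferate (P), cells with glucose only are metabolically active but
arrested and hypoxic (I), cells with neither starve and die (H). The P-
and I-compartments have fixed carrying capacities; H is unbounded.

All quantities are expected values over continuous cell counts; the
simulation is deterministic and contains no random number generation.
Every state operation accepts scalars or equal-length numpy arrays, so
the whole 1315-scenario grid advances through one shared course in
lockstep — the full sweep takes under a second.

### Initial state

Given a growth fraction GF and cell loss factor CLF:

* N_P(0) = GF·N₀ — the growth fraction is by definition the
  proliferating share;
* N_H(0) = CLF·GF·N₀ — loss scales with production, which scales with
  N_P; a higher CLF means a larger starving pool;
* N_I(0) = N₀ − N_P − N_H.

Capacities are frozen at the initial viable counts (cap_P = N_P(0),
cap_I = N_I(0)). The feasibility bound GF ≤ 1/(2+CLF) is algebraically
the requirement N_I ≥ N_P: the oxygen-poor but glucose-fed annulus is at
least as large as the well-perfused core. The grid lattice (GF step
0.01 from 0.01; CLF step 0.03 on 0.03…0.99) is enumerated with integer
arithmetic and a closed upper bound, yielding exactly 1315 scenarios;
floating-point step accumulation can never change membership.

### Kinetics (default time step dt = 1 h)

Each step applies, in order:

1. **Proliferation in P.** The in-cycle fraction is density-inhibited:
   100% at or below half capacity, 50% at full capacity, linear in
   between (occupancy counts viable + doomed cells — doomed cells are
   metabolically alive and consume resources until they die). The
   dividing cohort per step is pf·(2^(dt/T_c) − 1)·N_P with T_c = 2
   days, sized so that a fully proliferating population doubles in
   exactly one cell-cycle time irrespective of dt. (The naive pf·dt/T_c
   cohort would grow at rate 1/T_c — doubling in T_c·ln 2 ≈ 1.39 d —
   overdriving repopulation by ~44%.) Viable dividers add one viable
   daughter; doomed dividers attempt mitosis and die, leaving
   2 × 0.3 = 0.6 doomed progeny in expectation.
2. **Starvation in H.** Exponential loss with a 2-day half-time, viable
   and doomed alike.
3. **Recompartmentalization.** P fills its capacity deficit from I
   (reoxygenation), then I fills from H; overflow flows the reverse way
   (P→I→H). Transfers draw viable and doomed cells proportionally to
   their abundance in the source. Total cell number is conserved
   exactly (asserted to 1 part in 10⁹); an empty I is restocked from H
   one step before P can draw on it, preserving the P-from-I-first
   ordering.

Fractions (2 Gy, Monday–Friday) are delivered instantaneously at the
start of the treatment day, before that day's kinetics. Each fraction
moves viable_c·(1 − SF(d, OER_c)) cells to the doomed pool of
compartment c, with OER applied as a dose-modifying factor (d/OER in
both LQ terms) and β = α/(α/β) shared across compartments. OER_P = 1,
OER_I = 2, OER_H = 1.37 — chronically starving cells are assigned a
lower OER than the glucose-fed hypoxic cells because of their reduced
repair capacity.

### TD50

Survivors are assessed immediately after each fraction:
S(n) = 0.01 × total viable. Because the state after fraction n does not
depend on later fractions, one long course yields S(n) for every n. The
Poisson tumor control probability exp(−S) crosses 50% where S falls
through ln 2; the first integer bracket S(n_low) > ln 2 ≥ S(n_low+1) is
refined by log-linear interpolation of S in dose, which is exact for
exponential (no-repopulation) survival. TD50 is reported as total
physical dose at 2 Gy/fraction. Courses that fail to reach TCP = 0.5
within 200 fractions raise an error naming the scenario (none occur on
the default grid; the largest TD50 is 62.3 Gy).

Two estimator properties worth knowing:

* **Schedule scalloping.** The weekly pattern makes S(n) decrements
  day-of-week dependent (a Monday fraction follows a weekend of
  unopposed repopulation), so interpolated TD50 carries ripples of up
  to ~0.15 Gy on an otherwise clean trend. Monotonicity assertions in
  the tests therefore use a 0.2 Gy tolerance — one tenth of a fraction,
  the estimator's effective granularity.
* **Interpolation vs whole fractions.** TD50 could equally be defined
  as 2·n_high Gy, the first whole-fraction dose achieving TCP ≥ 0.5.
  Interpolation was chosen for smoothness; the whole-fraction
  convention shifts grid-level correlations by ~0.01 in R².

### FDG uptake

Uptake is scored on the pre-treatment state only (the analysis pairs one
baseline uptake value with one TD50 per microenvironment):
U = w_P·N_P + w_I·N_I + w_H·N_H, with pattern weights I = 1:1:0,
II = 3:1:0, III = 1:3:0, IV = 2:5:2, normalized to the grid maximum.
Within-compartment uptake gradients are deliberately collapsed to one
weight per compartment. Two algebraic identities follow from
N_P + N_I + N_H = N₀ and are asserted in the tests: pattern IV is an
affine function of N_I (so their TD50 R² values coincide exactly) and
pattern I is affine in N_H.

## Summary statistics

R² is the squared Pearson correlation over all 1315 raw scenario points
(not binned medians), computed identically for normalized and raw
uptake — R² is scale-invariant and the tests assert it. The high/low
dose ratio splits scenarios at the median normalized pattern-III uptake
(ties to the low group; with an odd count the single exactly-median row
is dropped) and takes the ratio of group means of TD50. The fixed-CLF
view subsets CLF = 0.9 (34 scenarios), bins by ascending uptake into
equal-count quintiles and reports TD50 quartiles and median GF per bin.
The OER sensitivity analysis repeats the entire TD50 sweep with
OER_H ∈ {1.37, 2, 3} and recorrelates N_I with TD50.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| volume × density | 64 × 10⁶ | mm³ × mm⁻³ | one PET voxel, N₀ = 6.4×10⁷ |
| clonogenic fraction | 0.01 | — | stem-like subset entering TCP |
| α_P, α/β | 0.382, 6.63 | Gy⁻¹, Gy | HNSCC radiosensitivity |
| OER P/I/H | 1 / 2 / 1.37 | — | dose-modifying factors |
| fraction dose, per week | 2, 5 | Gy, — | standard fractionation |
| progeny survival | 0.3 | — | per daughter of a doomed mitosis |
| H loss half-time | 2 | days | starvation kinetics |
| cell cycle time T_c | 2 | days | doubling interval of a cycling cell |
| dt | 1 | h | halving it moves TD50 by < 0.15% |
| proliferating fraction | 0.5–1.0 | — | linear in occupancy above 1/2 |

T_c is the one kinetic constant the compartment structure does not pin
down; 2 days is a fast-growing-carcinoma figure and is exposed in the
config (`params: {cell_cycle_time: ...}`) like every other field.

## What the scenario grid does and does not emulate

The grid is the synthetic input of the whole study: it spans *maximum*
microenvironmental heterogeneity — every feasible (GF, CLF) mix given
the resource-conservation constraint, weighted uniformly. Real tumors
occupy a correlated, much narrower band of (GF, CLF), so grid-level
correlation strengths and the ~19% high-vs-low dose ratio are
upper-bound-flavored estimates, not clinical predictions. The model also
omits: spatial structure within a tumorlet (uniform resource levels per
compartment), proliferation in the I-compartment, interfraction
sublethal-damage repair kinetics, tumor shrinkage feeding back into
capacities, per-cell stochasticity, and any conversion of the uptake
score to SUV or PET point-spread effects. Passing tests demonstrate the
mechanism — hypoxic-but-fed cells both resist radiation and take up
glucose — not calibrated clinical dosimetry.

## Numerical and degenerate-input choices

* Capacity/negativity checks use a 10⁻⁹ relative tolerance; transfers
  clamp only genuine float residue.
* A zero-capacity P (GF → 0 limit) is handled by defining occupancy 0;
  no births occur in an empty compartment.
* Untreated dynamics relax toward the compartmental steady state
  H* = pf_full·(T_loss/T_c)·N_P. The viable total is non-decreasing
  from t = 0 only for CLF ≤ pf_full·T_loss/T_c = 0.5; above that the
  initial H pool exceeds its equilibrium and shrinks first. The
  no-treatment growth test uses CLF = 0.45 for this reason.
* Identical inputs produce bit-identical trajectories (pure float
  arithmetic, no RNG, no threading).

## Known limitations

The compartment model reconstructed here matches every constraint the
study states (grid cardinality, parameter table, qualitative TD50
trends, correlation sign structure, the two affine R² identities), but
the upstream response model is only partly specified; choices such as
the within-step operation order, fraction-before-kinetics timing, and
proportional viable/doomed transfer draws are documented reconstructions.
The resulting TD50 surface is slightly *too* well explained by N_I
(R² ≈ 0.91 vs the reported 0.86 for the N_I-affine statistics), i.e.
the reconstruction underproduces TD50 variance orthogonal to the
I-compartment size, while the pattern I/II/III statistics land within
a few hundredths of the reported values.
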