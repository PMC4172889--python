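# tumorletfdg

Why do FDG-avid tumors fail radiotherapy more often? High uptake of
¹⁸F-fluorodeoxyglucose (FDG) on PET predicts local failure across many
tumor sites, but the radiobiological mechanism is unclear: FDG images
glucose consumption, not radioresistance. `tumorletfdg` is a mechanistic
model built to test which assumption about *where* the glucose goes can
reproduce the clinical association.

The package is aimed at radiation oncology physicists and radiobiology
modelers. It simulates a PET-voxel-sized tumor subvolume (a *tumorlet*,
64 mm³, 6.4×10⁷ cells) whose cells occupy three microenvironmental
compartments set by a locally constant blood supply:

| compartment | oxygen | glucose | behaviour | OER |
|---|---|---|---|---|
| **P** | ✓ | ✓ | proliferating (cycle time 2 d, density-inhibited) | 1 |
| **I** | ✗ | ✓ | metabolically active, non-proliferating, hypoxic | 2 |
| **H** | ✗ | ✗ | starving, dying (loss half-time 2 d) | 1.37 |

## The model

A course of 2 Gy fractions (5/week) is simulated in 1 h steps. Each
fraction converts viable cells to *doomed* cells per the
linear-quadratic model with the oxygen enhancement ratio as a
dose-modifying factor,

SF(d) = exp(−α·d/OER − β·(d/OER)²),  α = 0.382 Gy⁻¹, α/β = 6.63 Gy.

Doomed cells stay metabolically alive and die at a subsequent mitosis
(each progeny survives with probability 0.3); as they clear, the
P-compartment refills from I — emergent reoxygenation — and I refills
from H. The initial compartment mix is set by the growth fraction GF
(N_P = GF·N₀, N_H = CLF·GF·N₀, remainder in I), and every feasible
lattice point with GF ∈ {0.01, 0.02, …}, CLF ∈ {0.03, …, 0.99} and
GF ≤ 1/(2+CLF) is simulated — 1315 microenvironments. TD50, the dose at
which the Poisson tumor control probability exp(−surviving clonogens)
crosses 50%, is found per scenario (1% of viable cells are clonogens).

Baseline FDG uptake is scored under four hypotheses about the relative
per-cell uptake P : I : H — pattern I = 1:1:0, II = 3:1:0, III = 1:3:0,
IV = 2:5:2 — and correlated with TD50 across the grid.

## Worked example

```bash
$ tumorletfdg run-all --out out/
building grid and running TD50 sweep ...
  1315 scenarios; TD50 45.8-62.3 Gy
  pattern I: R^2 = 0.401 (r = +0.634)
  pattern II: R^2 = 0.744 (r = -0.863)
  pattern III: R^2 = 0.857 (r = +0.926)
  pattern IV: R^2 = 0.913 (r = +0.956)
```

TD50 spans 45.8–62.3 Gy: tumorlets with a low growth fraction hide most
of their cells in the radioresistant I-compartment and need the most
dose. Only the uptake patterns in which the glucose-only hypoxic
I-compartment dominates uptake (III, IV) produce a strong *positive*
uptake–TD50 correlation; assuming uptake tracks proliferation (II)
predicts the opposite sign, contradicting clinical observation. The
high-uptake half of the grid (pattern III median split) needs about 19%
more dose than the low half.

The same steps are available as a narrative pipeline under `analysis/`
(each script prints what it found and writes tables to `results/`):

```bash
python analysis/01_build_grid.py          # 1315 feasible (GF, CLF) scenarios
python analysis/02_td50_sweep.py          # TD50 per scenario
python analysis/03_uptake_correlations.py # pattern/compartment R^2, dose ratio
python analysis/04_fixed_clf_bins.py      # CLF = 0.9 uptake bins vs median GF
python analysis/05_oer_sensitivity.py     # raise OER_H to 2 and 3
```

As a library:

```python
from tumorletfdg import run_pipeline, correlate_patterns

df = run_pipeline()                  # one row per scenario
print(correlate_patterns(df)["III"]) # CorrelationReport(name='pattern III', r=0.926, r2=0.857, n=1315)
```

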