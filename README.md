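# retikin

Model-based compartmental analysis of plasma retinol tracer kinetics and
relative β-carotene bioefficacy.

## The problem

After a person swallows a small oral dose of [¹³C₁₀]retinyl acetate together
with [¹³C₁₀]β-carotene, the plasma concentrations of [¹³C₁₀]retinol and
[¹³C₅]retinol (the retinol cleaved from the labeled β-carotene) trace how the
body absorbs, stores, recycles, and irreversibly consumes vitamin A.  Fitting
a compartmental model to the two fraction-of-dose (FD) curves yields
quantities that no single blood sample can give: total-body vitamin A stores,
the disposal rate, plasma recycling numbers — and, from the ratio of the two
curves' areas, the fraction of the β-carotene dose that was absorbed and
converted to retinol (its *bioefficacy* relative to the retinol reference).

`retikin` implements this analysis for the standard two-week study design
(sampling at 0, 2, 4, 6, 8, 10, 12 h and 1, 2, 7, 14 d): preprocessing and
subject screening, two-stage weighted nonlinear least-squares fitting,
steady-state pool and residence-time computation, three bioefficacy
estimators, and a synthetic-cohort generator so the whole pipeline is
testable without access to raw study data.

## The model

Each tracer arm is a six-component chain with first-order fractional transfer
coefficients L(I,J) (fraction of compartment J moved to compartment I per
day) and a pure transport delay:

    gut (1) → enterocytes (2) → delay DT(3) → liver (4) → plasma (5) ⇄ stores (6) → loss
                     ↘ direct shunt L(5,2) ↗

Retinol absorption is fixed at 75% (L(0,1) = L(2,1)/3).  The β-carotene arm
(compartments 11–16) shares the exchange coefficients L(6,5), L(5,6), L(10,6)
and the gut forward coefficient; its non-converted fraction is governed by
the constant P(11) through L(0,11) = P(11)·L(12,11), so the fraction of the
carotene dose delivered to plasma as retinol is 1/(1+P(11)).

Derived per subject (M(5) = mean plasma [¹²C]retinol × 0.0435 L/kg × body
weight):

* steady state: M(6) = L(6,5)·M(5)/(L(5,6)+L(10,6)), disposal rate
  DR = L(10,6)·M(6), FCR(6,5) = DR/M(6)
* residence times from the negative inverse of the plasma/stores exchange
  matrix: T(5,5) = (L(5,6)+L(10,6))/(L(6,5)·L(10,6)), T(6,5) = 1/L(10,6)
* recycling: v(5) = T(5,5)/t½(5) − 1, tt(5) = T(6,5)/v(5); TTP50% = time for
  half the absorbed tracer's first arrival in plasma
* bioefficacy: T(15,11)/T(5,1) — analytically (1/(1+P(11)))/0.75 — plus a
  truncated trapezoidal AUC ratio and a single-sample day-2 isotope ratio.

## Worked example

```bash
retikin generate --out demo --n 6 --seed 11
echo '{"subjects_csv": "demo/subjects.csv", "curves_csv": "demo/curves.csv",
       "out_dir": "demo/out"}' > demo/config.json
retikin run --config demo/config.json
```

This simulates six subjects from the published population (parameters
lognormally dispersed around the cohort means, 5% proportional measurement
noise), screens them, fits both arms per subject, and writes `qc.csv`,
`params.csv`, `summary.csv`, `bioefficacy.csv` and `report.json` under
`demo/out/`.  For seed 11 the report contains (means ± SD over the six
subjects):

```
n_included: 6
M6             178.4 ± 63.2   μmol    vitamin A stores
DR               9.7 ± 4.5    μmol/d  disposal rate
FCR65          0.057 ± 0.021  1/d     fractional catabolic rate
days_of_stores  20.0 ± 8.6    d
v5              5.09 ± 2.73           recycling number
model_based     15.3 ± 6.8    %      bioefficacy (AUC ratio)
graphical       17.2 ± 8.5    %      bioefficacy (trapezoid, 0–14 d)
```

Small-cohort means scatter around the generating population (stores ≈ 123
μmol, DR ≈ 6.7 μmol/d, FCR ≈ 0.060/d, bioefficacy ≈ 13.5% for large n); the
per-subject values in `summary.csv` and `bioefficacy.csv` are the primary
output.

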