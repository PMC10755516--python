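# mirdose

Organ-level internal dosimetry for multi-cycle radioligand therapy with
^177Lu-labelled agents (e.g. ^177Lu-PSMA-617 in metastatic
castration-resistant prostate cancer), built around the MIRD schema.

The clinical workflow it implements: in treatment cycle 1 each organ is
imaged at several times after administration (2, 24, 48 and 168 h) and the
blood is sampled densely; in cycles 2–6 each organ is imaged **once**
(48 h). The package

1. fits cycle-1 organ time–activity curves A(t) = Σᵢ aᵢ·e^(−rᵢt) and
   integrates them to time-integrated activities (TIA, Ã, in MBq·h);
2. derives cycles 2–6 TIAs by single-time-point (STP) scaling,
   Ã_k = Ã₁ · A_k(t*) / Â₁(t*);
3. converts TIAs to absorbed doses D(target) = Σ_sources Ã(s)·S(target←s)
   with a supplied S-value matrix, a unit-density-sphere self-dose model
   for the lacrimal glands, and the standard blood-based method for red
   marrow (marrow concentration = RMBLR × blood concentration, plus a
   remainder-of-body cross term);
4. compares cumulative doses **predicted** from cycle 1
   (d₁ [Gy/GBq] × 44.4 GBq) with those **observed** over the actual
   cycles, per organ and per patient, using paired Hotelling T² tests
   across the at-risk organs (kidneys, lacrimal glands, salivary glands,
   red marrow) with Bonferroni adjustment;
5. performs a noncompartmental analysis (NCA) of the cycle-1 blood curve
   (Cmax, Tmax, λ_z, terminal half-life, geometric summaries).

A synthetic-cohort generator reproduces the study design this pipeline
targets — 30 patients, 7.4 GBq per cycle for up to 6 cycles, evaluable
counts 29/21/21/19/13/10 over cycles 1–6 — with lognormal inter-patient
organ kinetics calibrated to published ^177Lu-PSMA-617 dosimetry,
inter-cycle variability, and multiplicative measurement noise. It carries
exact ground truth (kinetic parameters, TIAs, doses) so every estimator in
the pipeline can be validated by parameter recovery.

## Worked example

```sh
mirdose simulate --out sim/ --seed 7          # synthetic cohort + ground truth
mirdose report --measurements sim/measurements.csv --format md
```

prints (abridged):

```
Lu-177 | 6 cycles x 7.4 GBq (planned total 44.4 GBq)

## Dose per unit activity (Gy/GBq)
| organ           | cycle 1 mean (SD) | cycles 2-6 mean (SD) |
| kidneys         | 0.393 (0.14)      | 0.366 (0.12)         |
| lacrimal_glands | 1.9 (0.38)        | 1.97 (0.49)          |
| red_marrow      | 0.0403 (0.017)    | 0.0396 (0.026)       |

## Cumulative dose (Gy)
| organ   | predicted mean | observed mean | rel. diff |
| kidneys | 17.5           | 15.9          | +9.5%     |

## Predicted vs observed (Hotelling T^2, Bonferroni-adjusted)
- cycle 6: n=10, T2=10.6, p_adj=1

Blood terminal half-life: geometric mean 50.8 h (geo CV 62%), n=29
```

Reading: the simulated cohort's mean kidney dose per unit activity in
cycle 1 is 0.393 Gy/GBq, so the cumulative kidney dose extrapolated over
six 7.4 GBq cycles is ≈17.5 Gy — below the historical 23 Gy kidney limit —
while the dose actually accumulated by the ten patients who completed all
six cycles is 15.9 Gy; the Hotelling tests find no significant
predicted-vs-observed difference in the at-risk organs. The blood
half-life summary comes from per-patient NCA of the cycle-1 samples.

The same steps are available as library calls (`generate_cohort`,
`fit_tac`, `tia`, `scale_tia`, `organ_dose`, `hotelling_paired`,
`run_pipeline`, ...) and as composable subcommands
(`simulate`/`fit`/`dose`/`cohort`/`report`).

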