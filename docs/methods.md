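# Methods

## Model and assumptions

**Kinetics.** Each source region's activity is modelled as a sum of
decaying exponentials, A(t) = Σᵢ aᵢ·e^(−rᵢt) (MBq, hours). Every rate
combines biological clearance with physical decay; the terminal rate is
clamped at the physical decay constant λ_phys = ln2/T_phys, because
biological processes can only shorten, never lengthen, the effective
half-life. The default nuclide is ^177Lu with T_phys = 6.647 d
(ICRP 107). Fits minimize *relative* residuals, (model−data)/data, since
organ activities span orders of magnitude and quantification noise is
multiplicative; a zero observation is floored at 10⁻¹² of the curve
maximum to keep weights finite.

**Time-integrated activity.** The default integrator is the closed form
Σᵢ aᵢ/rᵢ of the fitted curve ("analytic"). A "hybrid" integrator —
trapezoid over the observed time range, fitted-curve integral from 0 to
the first sample, analytic tail from the last measured activity at the
terminal rate — is provided as an option and converges to the analytic
value as sampling densifies. It is not the default because the plain
trapezoid overestimates a convex exponential decay by several percent at
the sparse clinical schedule (the 48–168 h segment alone contributes
≈(λΔt)²/12 ≈ 17% excess on that interval at a 60 h effective half-life);
the analytic integral of the fitted model has no such discretization
bias, which parameter-recovery simulations confirm.

**Model selection.** Fewer than 4 distinct time points: mono-exponential.
Exactly 4 points: the biexponential has 4 parameters and is *saturated* —
it can interpolate any 4 points, so residual-based criteria (any AIC
variant) degenerate and would select it on pure noise; selection is
therefore structural: the biexponential is chosen only for peak-shaped
data (monotone rise to a maximum followed by monotone decline — the
uptake–washout pattern a mono-exponential cannot represent). Five or more
points: corrected AIC (AICc) on the relative residuals, falling back to
plain AIC for all candidates when the small-sample correction term
2k(k+1)/(n−k−1) is undefined for any of them.

**Biexponential search.** Deterministic multi-start: a tail/residual
log-linear split start plus three fixed perturbations of the mono fit,
each refined by a damped Gauss–Newton (Levenberg–Marquardt) iteration
written in-package (the problems are 2–4 parameters over ≤10 points and
run tens of thousands of times in simulation studies; generic solver
overhead dominates otherwise). Near-interpolating solutions are polished
by undamped Gauss–Newton to machine precision so that later cycles scaled
by the fitted value reproduce noiseless data exactly. A candidate is
rejected when: the terminal amplitude is non-positive; a negative-
amplitude curve dips below zero anywhere on [0, 10·T_phys] (512-point
grid); or any term is negligible at every observed time
(|a|·e^(−r·t_min) < 10⁻⁹ of the data scale) — such a term is pure
extrapolation whose integral the data cannot constrain, and without this
guard a saturated interpolation can park a numerically invisible
component at the rate bound with an unbounded integral. Rates are bounded
to [λ_phys, 100 h⁻¹].

**Single-time-point scaling.** Cycle-k TIA = cycle-1 TIA × A_k(t*)/Â₁(t*)
with the *fitted* cycle-1 curve in the denominator (noise suppression,
and availability at the 24 h fallback time). The method is exact whenever
cycle-k kinetics are a scalar multiple of cycle 1; when only the washout
rate changes it errs by the computable factor (r_k/r₁)·e^(−(r_k−r₁)t*),
which the test suite checks against the closed form. Scaling refuses a
denominator below a configurable floor (default 10⁻⁹ MBq).

**Remainder of body.** The whole-body curve is a many-exponential mixture
that a biexponential cannot represent, so the pipeline subtracts the
summed organ activities from the whole-body activity *per time point* and
fits the remainder as its own region; whole-body TIA is then organs +
remainder. Non-positive residuals (late times, when the fast-clearing
remainder has decayed and the difference is noise-dominated) are dropped
from the remainder fit; a whole-body value below half the organ sum is
treated as a quantification inconsistency and raised as an error.

**Dose engine.** D(target) = Σ_s Ã(s)·S(target←s)/1000 Gy, strictly
linear in every TIA. The packaged S-matrix
(`data/s_matrix_lu177_adult_male_synthetic.csv`) is a synthetic
adult-male-like subset: self terms are the ^177Lu mean electron energy
per decay (0.1479 MeV, giving Δ_local = 0.0853 Gy·g/MBq·h) divided by
phantom organ masses, plus small photon cross terms; it is a stand-in for
a phantom-software S-value library, which is out of scope. Lacrimal
glands use the unit-density sphere model, dose = φ·Δ_local·Ã/m with
default mass 0.7 g (interpatient mass variation is large and the value is
config-overridable) and absorbed fraction 1.0. Red marrow uses the
blood-based method with RMBLR = 1.0 (no specific marrow binding),
marrow mass 1100 g, S(rm←rm) = Δ_local/1100 g, and a remainder-of-body
cross S-value of 1.1×10⁻⁴ mGy/MBq·h.

**Blood AUC.** The blood concentration TIA is a trapezoid over the
observed rise up to the first post-peak sample plus the analytic integral
of a sum-of-exponentials fit from that sample on. The peak sample itself
is excluded from the fit because it sits in the mixing/distribution
phase, which decaying exponentials cannot represent; the residual
approximation error (coarse trapezoid across the peak) is a few percent
of the AUC and cancels entirely in predicted-vs-observed comparisons,
where both sides share the same cycle-1 AUC. Cycles 2–6 blood TIAs are
the cycle-1 value scaled by the remainder-of-body imaging ratio, the
closest imaging surrogate for the circulating compartment.

**Cohort statistics.** Predicted cumulative dose = d₁ (Gy/GBq) × planned
total activity (default 6 × 7.4 = 44.4 GBq); observed = sum of per-cycle
doses; relative difference = 100·(predicted − observed)/observed, so
over-prediction is positive. The predicted column summarizes every
cycle-1-evaluable patient; the observed column only completers of all
planned cycles. Hotelling T² is the paired one-sample test on
d = predicted − observed across the at-risk organs:
T² = n·d̄ᵀΣ̂⁻¹d̄, F = T²(n−p)/(p(n−1)) ~ F(p, n−p); one test per
cumulative comparison at cycles 2–6, Bonferroni family size m = 5. A mean
difference below 10⁻⁹ of the data scale is treated as exactly zero
(T² = 0, p = 1) rather than fed to the quadratic form, which would
otherwise test floating-point round-off; a singular or near-singular
(condition number > 10¹⁴) difference covariance raises an error
suggesting a smaller organ subset.

**NCA.** Cmax/Tmax are the observed maxima. λ_z is the log-linear slope
over a contiguous post-peak tail of ≥3 points chosen to maximize adjusted
R² (ties broken toward the longer tail); pre-dose and ≤3 min samples are
excluded. Geometric summaries use geomean = e^(mean ln v) and
geo CV% = 100·√(e^(s²)−1) with s the sample SD of the logs.

## Synthetic cohort generator

The generator emulates the target study design: 30 patients, 7.4 GBq per
cycle, up to 6 cycles, cycle-1 imaging at {2, 24, 48, 168} h, one 48 h
image in cycles 2–6, cycle-1 blood samples at
{pre, 1 min, 20 min, 1, 2, 4, 24, 48, 72, 144 h}, and dosimetry-evaluable
counts 29/21/21/19/13/10 (dropout assigned by patient index, for
reproducibility over realism).

Organ kinetics are mono-exponential washout × physical decay (an optional
uptake-phase half-life per organ produces a rise-to-peak biexponential;
off by default). Uptake fractions are lognormal across patients with the
mean *calibrated at construction time* so that the implied mean cycle-1
dose per unit activity matches published ^177Lu-PSMA-617 organ dosimetry:
with these kinetics d = f·S_self/λ_eff Gy/GBq independent of the injected
activity, so f = d_target·λ_eff/S_self after subtracting the
remainder-of-body cross dose. Calibration targets (Gy/GBq) and median
biological half-lives (h): kidneys 0.43 / 120, lacrimal glands 2.1 / 90,
salivary glands 0.63 / 80, liver 0.090 / 150, spleen 0.067 / 150;
per-organ uptake CVs are set from the published SD/mean ratios
(0.22–0.57). The remainder compartment (median biological half-life 20 h,
the renal-excretion pathway) receives the mass balance 1 − Σf, which
guarantees whole body ≥ organs at every instant. Blood is biexponential
(fast half-life 0.5 h, slow fraction 0.02, volume 5 L) with a 0.12 h
mixing factor putting the peak ≈20 min post-injection, and a terminal
effective half-life sampled lognormally with geometric mean 41.6 h and
geometric CV 68.8%, per published pharmacokinetics of the agent.

Variability defaults: measurement noise multiplicative lognormal with
CV 10% (quantitative-SPECT level), mean-one; inter-cycle lognormal
multipliers with CV 20% on both uptake and washout rate (an
amplitude-only mode keeps later cycles exact scalar multiples of
cycle 1). All sampling flows from the single design seed; the same seed
reproduces the cohort exactly.

What the generator does **not** emulate: partial-volume and
reconstruction effects (noise is independent across regions and times,
real SPECT errors are correlated), organ-mass variation (phantom masses
are fixed), late-course kinetic drift (inter-cycle multipliers are
mean-one, so there is no systematic trend for the prediction to miss),
tumor sink effects, and informative dropout. Passing recovery tests
therefore show the estimators are unbiased under the stated noise model
at the clinical sampling schedule — not that real-data accuracy matches.

## Numerical and design choices

- Analytic TIA as the pipeline default, hybrid as an option (rationale
  above).
- Relative-residual weighting throughout fitting.
- Structural model selection at the saturated 4-point design (rationale
  above); the mono fit is the fallback whenever no valid biexponential
  candidate exists, and ties in AIC prefer the smaller model.
- The remainder-of-body terminal half-life estimate is biased upward by
  the positivity selection applied to its noise-dominated late points;
  its TIA (dominated by early times) is much less affected, and its dose
  role is limited to the small cross-dose term.
- Degenerate inputs raise typed errors: <2 distinct times
  (insufficient data), all-zero activities (degenerate input), organ sum
  grossly exceeding whole body (inconsistency), scaling denominator at
  the floor (unscalable), n ≤ p or singular covariance in the Hotelling
  test, no decreasing tail in NCA.
- The sphere-model dose constant and the S-matrix self terms share one
  energy-bookkeeping constant (0.1479 MeV/decay × 1.602×10⁻¹³ J/MeV ×
  3.6×10⁹ decays per MBq·h), centralizing unit conversions.

## Limitations

- The S-matrix fixture is synthetic; absolute doses are only as good as
  the S-values supplied, and no patient-specific mass rescaling is
  applied by default.
- Lacrimal dose is self-dose only; photon cross-fire into small glands is
  neglected.
- The STP method assumes shape-invariant kinetics across cycles; when
  washout genuinely changes, its error is the closed-form factor given
  above, and simulations with inter-cycle kinetic variability show the
  corresponding scatter in observed-vs-predicted doses.
- Blood AUC carries a small systematic approximation near the mixing
  peak; it cancels in predicted-vs-observed comparisons but not in
  absolute marrow dose.
- The cohort-level relative difference compares means over different
  patient sets (all evaluable vs completers), mirroring the target
  study's presentation; it is not a paired quantity.
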