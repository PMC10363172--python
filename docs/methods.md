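# Methods

## The study setting

The package targets small-cohort, single-dose pharmacokinetic studies of
extended-release (depot) formulations, as run when qualifying a long-acting
buprenorphine analgesic in a primate colony: four treatment arms (a
compounded sustained-release product at 0.15 mg/kg, n = 8, and a
pharmaceutical extended-release product at 0.1/0.15/0.2 mg/kg, n = 6/3/8),
plasma sampled at 0.25, 0.5, 1, 8, 24, 48 and 72 h post-dose, an LC–MS/MS
quantitation limit of 0.1 ng/mL for parent and metabolite, and a
0.1 ng/mL therapeutic plasma threshold.  Individual animal data from such
studies are rarely deposited, so every stage here is verifiable against a
simulator whose truth is known.

## Simulation model

**Structural model.** A subcutaneous dose splits between two first-order
absorption depots (fractions f and 1−f, rates ka₁ > ka₂) feeding a single
disposition compartment with first-order elimination ke = CL_F/V_F.  The
concentration is a superposition of two Bateman functions.  This is the
minimal mechanism producing both features of depot kinetics: quantifiable
drug at the first sample (15 min) and persistence beyond 72 h.  A single
depot is the f = 1 special case.  When absorption from the slow depot is
slower than elimination (ka₂ < ke) the terminal slope reflects ka₂, not ke
— flip-flop kinetics; the simulator's terminal rate is min(ke, ka₂) and all
recovery checks compare against that.

**Typical values** (all overridable): CL/F = 1.9 L/h/kg, V/F = 57.5 L/kg
(so ke ≈ 0.033 1/h, t½ ≈ 21 h), ka₁ = 0.6 1/h, ka₂ = 0.08 1/h, f = 0.8.
These were calibrated once so that the noise-free curves land inside the
ranges reported for this drug class and species: peak concentrations of
~1.3–2.6 ng/mL across 0.1–0.2 mg/kg (observed range 1.4–2.5), terminal
half-life in the 20–37 h band, clearance ≈ 2 L/h/kg, and concentrations
still above 0.1 ng/mL at 72 h.  They are calibration conveniences that make
the synthetic data realistic, never evidence about real animals.

**Variability.** Between-subject variability is log-normal around the
typical value (median-preserving, σ² = ln(1+CV²)), defaults CV 0.3 on
clearance and volume and 0.5 on both absorption rates; residual error is
proportional log-normal with CV 0.15.  These defaults produce
between-subject spreads comparable to the SDs such studies report.
`frac_fast` perturbs on the logit scale to stay in [0, 1].

**Metabolite.** A fraction fm = 0.5 of parent elimination forms a
metabolite (volume 80 L/kg, ke_m = 0.06 1/h) via the linear cascade
depot → parent → metabolite, evaluated by the three-exponential closed
form per depot and verified against tight-tolerance ODE integration to
< 1e−6 relative.  Defaults put the typical metabolite curve just above a
0.1 ng/mL LLOQ from ~8 h through 72 h, lagging the parent peak — the
plasma pattern reported for norbuprenorphine.  Noisy low concentrations
are censored, so early metabolite samples are routinely BLQ in simulated
tables, which deliberately exercises the censoring policies downstream.

**Degenerate rates.** The Bateman form is singular at ka = ke; rates within
1e−9 relative of each other are nudged apart by 1e−9 relative, far below
observable effect.

**Censoring dialect.** A record below the LLOQ keeps its time, carries
`blq = 1`, and stores *no* numeric value: the analysis layer, not the data
file, owns any imputation.  The boundary value (conc = LLOQ) is
quantifiable.

**Reproducibility.** One root seed; each subject draws from its own child
generator spawned deterministically (`numpy` SeedSequence), so changing one
group's size never perturbs another subject's data.  (seed, config) →
identical output bytes.

**Microsome assay.** The in-vitro depletion assay (10 µM substrate, samples
at 0–60 min) is modelled as parent(t) = c₀e^(−k_dep·t) and a metabolite
formed at branch rate k_form ≤ k_dep and cleared at k_out, with the
k_out = k_dep limiting form c₀·k_form·t·e^(−k_dep·t).  Shipped species
presets reproduce the qualitative pattern: marmoset/macaque parent
exhausted (< 1% of c₀) by 15 min, human parent persisting at 60 min,
macaque metabolite cleared by 45–60 min, marmoset metabolite plateauing and
persisting — the sustained-metabolite-exposure signature.  Rates are
qualitative emulations, not fitted constants.

## Noncompartmental analysis

All NCA operates in fixed units — hours, ng/mL (≡ µg/L), mg/kg, L/h/kg —
with converters confined to the I/O boundary.  The mg/kg→µg/kg dose
conversion makes CL/F = dose/AUC₀₋∞ come out in L/h/kg exactly.

**AUC.** Linear-up/log-down trapezoids: a rising, flat, or zero-touching
segment uses (c₁+c₂)Δt/2; a strictly declining positive segment uses the
exact area of the exponential interpolant, (c₁−c₂)Δt/ln(c₁/c₂).

**AUMC.** The first-moment curve uses the moment-trapezoid convention of
the standard commercial NCA tools: on non-declining segments the moment
t·C(t) is itself interpolated linearly, giving (t₁c₁+t₂c₂)Δt/2; on
declining segments the exact moment integral of the exponential
interpolant, (t₁c₁−t₂c₂)/k + (c₁−c₂)/k² with k = ln(c₁/c₂)/Δt.  Note the
linear branch is *not* the integral of t times the linear concentration
interpolant (which would be Δt·(2t₁c₁+t₁c₂+t₂c₁+2t₂c₂)/6); the two
conventions differ and this package deliberately follows the
moment-trapezoid one.  The quadrature oracle in the tests integrates the
declared per-branch interpolant and agrees to < 1e−9 relative.

**BLQ policy.** Leading BLQ samples (before the first quantifiable one)
enter the integration as zeros; embedded and trailing BLQ samples are
excluded from both AUC and the terminal fit.  A (0, 0) anchor is prepended
for extravascular dosing when the series starts after dose time.  Profiles
with no quantifiable point raise a dedicated error; the pipeline skips them
with a logged warning.

**Terminal slope.** λz selection follows the de-facto standard best-fit
rule: candidate windows are the suffixes of the strictly-post-Tmax
quantifiable points (the Cmax sample excluded), minimum three points; each
is fit by OLS of ln C on t; the maximum adjusted R² wins, and among
candidates within 1e−4 of the best, the one with more points.  A
non-negative slope in every candidate marks λz not estimable, and every
dependent parameter (t½, AUC₀₋∞, CL/F, MRT₀₋∞, extrapolated threshold
duration) is reported absent with a machine-readable flag — never a silent
zero.  λz is reported in 1/h; report tables in the literature occasionally
mislabel this unit as L/h, but the half-life identity t½ = ln 2/λz fixes
the dimension.

**Extrapolation.** AUC₀₋∞ adds Clast/λz using the *observed* Clast by
default (the regression-predicted Clast is available via
`clast_mode="predicted"`).  Profiles with more than 20% of AUC₀₋∞
extrapolated carry a quality flag; with only 72 h of sampling against a
20–37 h half-life this is expected for some subjects, so it is a warning,
never a failure.  MRT₀₋∞ adds the exponential tail moments
Clast·Tlast/λz + Clast/λz².

**Time above threshold.** Onset is the first *sampled* time at or above
threshold — never interpolated before the first sample, since absorption
before 15 min is unobserved.  A downward crossing between samples is
log-linearly interpolated; a curve still above threshold at Tlast is
extrapolated as Tlast + ln(Clast/θ)/λz when a terminal fit exists,
otherwise the duration is reported as a censored lower bound (Tlast −
onset).  The operation accepts any sampled curve, so it applies equally to
an individual profile or a group mean curve, and records which fit was
used.

## Group statistics

The report table carries ten parameters (Cmax, Tmax, Tlast, t½, AUC₀₋Tlast,
AUC₀₋∞, CL/F, λz, MRT, MRT₀₋∞) as mean ± n−1 sample SD per group, with n
counting only subjects for which the parameter was estimable.  Mean curves
average quantifiable values only and report per-point n (zero-imputation is
a config alternative); time points where every subject is censored are
omitted rather than shown as fabricated zeros.

Between-group comparison uses the two-sided Mann–Whitney U test.  For
combined n ≤ 20 the p-value is exact: U is computed with mid-ranks, and the
null distribution is built by enumerating all C(n₁+n₂, n₁) assignments of
the observed values (conditional on the tie pattern); the p-value is the
null probability of |U − n₁n₂/2| at least the observed deviation.  At the
group sizes here (3–8 per arm) exact enumeration is cheap and avoids the
normal approximation's small-sample anticonservatism; the exact test is
conservative (attained size ≤ nominal).  Larger samples use scipy's
tie-corrected normal approximation, and every result records its method
tag.  Bonferroni adjustment multiplies by an explicit, caller-declared
family size — the family is a study-design fact that cannot be inferred
from the data.

The dose-trend report across the extended-release arms is descriptive only:
whether group-mean Cmax and AUC increase strictly with dose, and the
log-log slope (1.0 under exact dose proportionality, which the linear PK
generator satisfies).

## What the simulations do and do not show

The generator reproduces the statistical structure the NCA layer must
survive — sparse sampling, censoring, log-normal spread, a lagging
metabolite, flip-flop absorption — so passing tests demonstrate the
estimators behave correctly *under that structure*.  They cannot establish
fidelity to real marmoset profiles: whether absorption is mono- or
bi-phasic in vivo, the true variability structure, assay error shape, and
any dose-nonlinearity are unknowable without individual animal data.  The
recovery experiment (replicated cohorts at the study design, 15% residual
CV) quantifies the sparse-schedule estimation bias — median absolute
relative bias ≈ 6% for CL/F and ≈ 12% for t½ under the defaults, shrinking
monotonically as residual error is removed; the residual noise-free bias is
the sampling-grid discretisation itself.

## Numerical and design choices

- Tmax tie-break: earliest time attaining the maximum.
- Segment formulas guard the log branch to strictly-declining positive
  pairs; equality or zeros fall to the linear branch.
- Candidate terminal fits within 1e−4 adjusted R² are treated as tied.
- The exact-test deviation comparison uses a 1e−12 absolute guard so
  mid-rank U values that are equal up to floating error count as tied.
- Problem sizes in the shipped verification runs — 1 000 quadrature
  segments, 200–500 replicate cohorts, 500–1 000 null replicates at
  n = 8 vs 8 — were chosen to give Monte-Carlo standard errors comfortably
  below the property margins being checked.
- The CSV dialect is deliberately plain (UTF-8, "." decimal, blq 0/1,
  blank concentration on censored rows) so fixtures stay human-auditable;
  reads validate duplicates, negative values and censoring consistency as
  hard errors.
- All outputs are byte-stable for a fixed seed and config; timestamps are
  confined to the log file.

## Known limitations

No physiologically based or compartmental fitting, no mixed-effects
(population) estimation, no bioequivalence statistics, no protein binding
or body-weight allometry, no enzyme-level metabolism modelling.  The
microsome presets are qualitative shapes, not parameter estimates.  The
threshold-duration extrapolation inherits all the fragility of a 3–4 point
terminal fit; the censored (non-extrapolated) bound is always reported
alongside it.
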