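# depotnca

Noncompartmental pharmacokinetic (NCA) analysis and study simulation for
extended-release depot formulations, built around the kind of small-cohort
single-dose study used to characterise long-acting buprenorphine analgesics
in laboratory primates: a handful of animals per dose group, seven sparse
plasma samples over 72 h, an assay quantitation limit of 0.1 ng/mL, and a
therapeutic plasma threshold of 0.1 ng/mL whose time-above-threshold drives
the redosing interval.

The package has three layers:

- **`depotnca.simulate`** — a mechanistic generator of realistic study data.
  A subcutaneous dose *D* (mg/kg) splits between a fast and a slow
  first-order depot feeding one disposition compartment, so the plasma
  concentration is a superposition of two Bateman functions:

  C(t) = (10³·D/V_F) · [ f·ka₁/(ka₁−ke)·(e^(−ke·t) − e^(−ka₁·t))
        + (1−f)·ka₂/(ka₂−ke)·(e^(−ke·t) − e^(−ka₂·t)) ],  ke = CL_F/V_F

  with log-normal between-subject variability, proportional residual error,
  LLOQ censoring, a first-order metabolite cascade (depot → parent →
  metabolite), and closed-form in-vitro liver-microsome time courses with
  marmoset/macaque/human presets.

- **`depotnca.nca`** — per-profile NCA for extravascular dosing: Cmax, Tmax,
  Tlast, Clast by observation; AUC₀₋Tlast by the linear-up/log-down
  trapezoidal rule; the terminal rate constant λz by a best-adjusted-R²
  log-linear suffix search (≥ 3 points past Tmax, Cmax excluded); t½ =
  ln 2/λz; AUC₀₋∞ = AUC₀₋Tlast + Clast/λz; CL/F = D/AUC₀₋∞; MRT = AUMC/AUC
  to Tlast and to infinity; and time above a therapeutic threshold with
  log-linear interpolation or extrapolation of the downward crossing.

- **`depotnca.groups`** — mean ± SD concentration curves, the ten-parameter
  mean ± SD report table per group, the *exact* two-sided Mann–Whitney U
  test by full enumeration of the permutation null (mid-ranks, ties
  included; normal approximation beyond combined n = 20), Bonferroni
  adjustment with an explicit family size, and a descriptive dose-trend
  report across the extended-release arms.

A thin `depotnca` command-line tool (`simulate`, `nca`, `summarize`,
`compare`, `microsome`, `all`) wires the layers together over a plain CSV
interchange format; `examples/` holds narrative scripts, one per capability.

## Worked example

```sh
python examples/02_single_profile_nca.py
```

analyses one noise-free profile (0.15 mg/kg, typical parameters) sampled on
the sparse 0.25–72 h study schedule and prints:

```
Cmax  = 1.891 ng/mL at Tmax = 8 h
Tlast = 72 h, Clast = 0.284 ng/mL
lambda_z = 0.0312 1/h over 3 points (24-72 h), adj R2 = 0.99937
t1/2 = 22.2 h   (simulator truth: 21.0 h)
AUC0-Tlast = 67.5 ng*h/mL, AUC0-inf = 76.6 ng*h/mL (11.9% extrapolated)
CL/F = 1.96 L/h/kg   (truth: 1.90)
MRT = 26.6 h, MRT0-inf = 35.8 h
above 0.1 ng/mL from 0.25 h to 105.5 h (duration 105.2 h, extrapolated=True)
```

Cmax lands mid-way in the 1.4–2.5 ng/mL range typical for these doses; the
terminal fit uses the three post-peak samples, and the ~6% upward bias of
t½ against the generator truth is the cost of seven-sample sparse sampling,
quantified (never hidden) by the recovery experiment below.  The profile
stays above the 0.1 ng/mL efficacy floor from the first sample to an
extrapolated crossing at ~105 h — the reason depot formulations are dosed
every few days.

The end-to-end pipeline on the shipped four-arm design:

```sh
depotnca all --seed 7 --outdir out/
```

writes the concentration table, per-subject NCA results, the
ten-parameter × four-group summary, group mean curves, exact Mann–Whitney
comparisons, and the fully resolved configuration, byte-identically for a
fixed seed.

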