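# Methods

## Scope and model

`mstbind` analyses equilibrium titrations of a fluorescently labeled
receptor R with an unlabeled titrant, read out by microscale
thermophoresis (MST). The physical model is 1:1 mass action at
equilibrium; MST's temperature-jump physics is not modelled — the
observable is taken to be a linear two-state mix of a free-state and a
bound-state signal, weighted by the occupancy of the labeled species.
Cooperative/multi-site schemes and kinetics are out of scope.

All concentrations are μmol/l internally; `units.to_umol_per_l`
normalizes nmol/l and mmol/l inputs at the boundary.

## Equilibrium solvers

**Binary.** `[RL]` is the physical ("−") root of
`x² − (R_t+L_t+Kd)x + R_t·L_t = 0`. It is evaluated in the conjugate
form `2·R_t·L_t / (s + sqrt(s² − 4·R_t·L_t))`, `s = R_t+L_t+Kd`, because
the textbook `(s − sqrt(·))/2` form loses up to half the significand to
cancellation when `[RL] ≪ s` (relative errors ~1e−8 appear already at
concentration ratios of 1e3, which titration ladders reach routinely).
Free species are likewise computed with cancellation-free algebraic
rearrangements rather than by subtraction, so detailed balance
(`[RL] = R·L/Kd`) holds to better than 1e−8 relative across the tested
range (totals and Kd log-uniform in [1e−3, 1e3] μmol/l). The root is
asserted to lie in `[0, min(R_t, L_t)]` rather than selected by
inspection.

**Competition.** Two ligands mutually exclusive for one site reduce to a
single monotone equation in free receptor R on `[0, R_t]`, solved with
Brent's method to near machine precision, and mass conservation is
verified to 1e−10 relative after the solve. The closed-form cubic is
*not* used in the implementation — for extreme concentration ratios the
companion-matrix root finder is less reliable than monotone bracketing —
but it serves as an independent oracle in the test suite, together with
raw-residual bisection for the binary case.

**Non-binders.** Pairs where no complex forms are an explicit sentinel
(`NON_BINDER`), never an infinite float Kd; the solver returns exactly
zero complex for them.

## Fitting

Fits are unweighted least squares of linear signal against the
log-spaced ladder, with deterministic initialization: plateaus from the
mean of the first/last ladder deciles, midpoint from the first
half-range crossing, Hill slope 1. The midpoint is bounded to
`[ladder_min/100, ladder_max·100]` and the Hill slope (when free) to
`[0.2, 6]`. No random restarts: a given series always produces the same
fit. Standard errors come from the Jacobian-based covariance.

The logistic model's Hill slope is free by default (`fix_hill=True` pins
h = 1); the depletion model has three parameters (Kd and the two
plateaus) and needs the labeled total, taken from the series metadata.
The depletion fit is the analysis default throughout the pipeline
because with the labeled species at 0.1 μmol/l and Kds down to
0.3 μmol/l, titrant depletion shifts the EC50 by `R_t/2` — a 17% bias
for the tightest interactions. Whether the original curve fits accounted
for depletion is not documented; both readings are implemented and the
difference (EC50 = Kd + R_t/2 at exact half-occupancy) is exposed rather
than resolved.

**Classification** operationalizes the affinity table's footnotes, which
are otherwise undefined:

- `no_binding` — the series is numerically flat, or the fitted
  |amplitude| < 3 × residual SD (the negative-control shape);
- `cannot_determine` ("cnd") — the midpoint is not resolved by the
  ladder: its upper 95% bound exceeds the top concentration, *or* the
  estimate lies in the ladder's last decade (EC50 > top/10, i.e. the
  observed curve never reaches ~91% saturation, so the bound plateau is
  extrapolation). The second trigger is needed because a smooth
  least-squares fit can report a deceptively small standard error on an
  extrapolated midpoint;
- `binder` otherwise.

Aggregation pools ≥2 converged binder replicates into mean ± SEM
(`SD/√n`); mixed classifications raise rather than silently dropping
replicates.

**Statistics.** Group comparisons use the Welch (unequal-variance)
two-tailed t test. Many-to-one comparisons (wild-type vs the three HCM
variants) are approximated by Welch tests with Bonferroni correction — a
deliberate, slightly conservative stand-in for Dunnett's procedure,
whose exact critical values are out of scope.

## Synthetic data

The generator emulates the study design, not the instrument: a fixed
labeled total of 0.1 μmol/l, a 16-point two-fold serial dilution
(standard 16-capillary format), signals from the exact forward model
plus i.i.d. Gaussian noise on the normalized scale, and small replicate
sets with seeds derived as `base_seed + replicate_index`.

Parameter choices:

- **Ladder top = 50 × Kd, clipped at 500 μmol/l.** 50 × Kd puts the top
  ladder point at ≥98% occupancy, anchoring the bound plateau; the
  500 μmol/l cap reflects realistic stock solubility and makes the
  weakest tabulated interactions (Kd ≥ ~90 μmol/l) honestly unresolvable,
  reproducing the table's "cnd" behaviour instead of hiding it. Series
  with top < 10 × Kd carry a `saturation unreachable` flag.
- **Noise SD 0.03** on the normalized signal. No noise magnitude is
  reported for the source data; 0.03 was chosen once so that simulated
  replicate SEMs at n = 3–8 are of the same order as the published SEMs
  (a few percent of the mean for mid-range Kds).
- **Replicate counts** follow the published per-interaction n where
  printed (head–tail n = 8, C0C2 × S1 n = 4, several miniHMM pairs
  n = 3) and default to 4 (the middle of the pooled "n = 3–7" range)
  elsewhere.
- **Competition observable.** MST cannot distinguish which unlabeled
  partner occupies the receptor, yet the reported competition titration
  shows a sigmoid, not a flat line — so the two complexes cannot
  contribute identically. The generator therefore gives RA and RB
  distinct bound-state amplitudes (defaults 0.35 and 1.0 on the
  normalized scale, configurable). This is the largest unstated
  assumption of the competition experiment and is surfaced as an
  explicit parameter rather than hidden.
- **Competitor concentration 1.5 μmol/l** in the competition preset:
  not printed in the source; back-computed from the reported EC50 shift
  (≈0.8 → ≈3.8 μmol/l) via Cheng–Prusoff and labelled as inferred.

What the generator does *not* emulate — raw thermophoresis time traces,
photobleaching, capillary adsorption, labeling-efficiency variation,
systematic (non-Gaussian, concentration-correlated) errors. Passing
parameter-recovery tests therefore demonstrate estimator correctness
under the stated statistical model, not robustness to instrument
artifacts.

## Interaction map

The map replays the published row/column vocabulary verbatim so diffs
against the table are mechanical. Cells are mean ± SEM with n, or one of
two sentinels: `cnd` and `—` (untested). In the end-to-end synthetic
replay, cells whose replicates do not all classify as binders become
`cnd`; with the default capped ladder this affects every cell with
generating Kd ≳ 60 μmol/l — by design, since those estimates would be
extrapolations. Derived quantities: Kd ratios with delta-method SEs
(`fold·sqrt((s₁/k₁)² + (s₂/k₂)²)`), occupancy of the limiting species at
arbitrary totals via the exact binary solve, and competition EC50
predictions via root-finding over the ternary equilibrium. No rounding
is baked into computations; rounding happens only in report text.

## Problem sizes and determinism

Test and acceptance runs use the presets at their native replicate
counts (3–8 series of 16 points; property checks use 1,000 randomized
systems, the classifier check 100 seeded runs, the null-uniformity check
2,000 simulated tests), which keeps the full suite in the tens of
seconds on one CPU while leaving every statistical check comfortably
powered. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the end-to-end map replay is
bit-reproducible for a fixed master seed.

## Known limitations

- Fitted-Kd noise bias: with noise SD 0.03 the nonlinear depletion fit
  underestimates mid-range Kds by ~5% on average at n = 4–8; this is
  ordinary finite-noise bias of nonlinear least squares, well inside the
  replicate scatter, and shrinks with n.
- The `cnd` rule's top/10 decade threshold is a convention; published
  cells with Kd between ~60 and 500 μmol/l were presumably measured with
  higher-concentration ladders than the capped default and classify as
  `cnd` in the synthetic replay.
- The competition observable's amplitude split is an assumption (see
  above); fitted competition EC50s inherit it, while
  `predict_competition_ec50` does not (it is defined on occupancy, not
  signal).
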