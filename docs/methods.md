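# Methods

## Survival reduction and error model

A clonogenic record is one flask: `cells_seeded`, `colonies`, a dose and a
condition label.  Replicate counts at each (condition, dose) are summarized
by their mean and the standard error of the mean.  Counting statistics set
a lower bound on the believable error of a count: the observed SEM is
floored at √(mean/n), the Poisson standard error of the mean of n counts
(for a single flask this is the familiar √k).  Real assays carry additional
error sources (dilution, pipetting), so the observed spread normally
exceeds this floor; when it does not — likely with only four replicates —
the observed SEM understates the counting error and the floor is used.
The floor can be disabled (`apply_poisson_floor=False`).

Plating efficiency is the 0 Gy ratio PE = X̄_colonies / X̄_cells with the
first-order ratio-propagation SE.  The surviving fraction at dose D is
(X̄_colonies/X̄_cells)_D / PE; its SE carries two terms, colony counting and
SE(PE), with the mean number of cells seeded treated as exact because its
counting error is already inside SE(PE).  Both propagation formulas are
validated against Monte-Carlo perturbation oracles (10⁶ Gaussian draws) to
within 5% for input CVs ≤ 10%; first-order propagation degrades, as it
must, when parameter CVs grow much beyond that.

## LQ fitting and model selection

SF = exp(−αD − βD²) is fitted by weighted nonlinear least squares in linear
SF space (Levenberg–Marquardt / trust-region through
`scipy.optimize.curve_fit`), weights 1/se². Three choices matter and were
validated by simulation (500 replicate synthetic assays at a
pure-exponential truth of α = 0.705 Gy⁻¹):

- **The 0 Gy point is excluded from the fitted set.**  Its surviving
  fraction is 1 by construction and the model passes through (0, 1) for
  every parameter value, so it carries no information; counting it only
  distorts the residual degrees of freedom.
- **Parameter covariance is taken unscaled** (`absolute_sigma=True`): the
  supplied se values are absolute standard errors produced by the
  propagation chain, not relative weights, so rescaling the covariance by
  the reduced χ² would discard that calibration.  With the Poisson-floored
  errors and the unscaled covariance the nominal 95% Wald intervals for α
  cover the generating truth 96% of the time; the residual-scaled
  alternative covers only ~75%, because the per-fit residual scatter does
  not see the error component shared through the common PE normalization.
- **β-equivalence-to-zero rule**: the unconstrained fit runs first; if
  β̂ ≤ 0, β̂ is numerically nil (< 10⁻⁶ Gy⁻²) or β̂/σ_β < 1.96 (two-sided
  95%), the curve is refitted with β ≡ 0 and reported as pure exponential.
  Under a pure-exponential truth this selects the exponential form in 99%
  of simulated assays.  Final reported parameters are constrained ≥ 0
  (radiobiological convention).

Recovery at the simulated design (4 replicate flasks per dose, doses
0–4 Gy, PE 0.60, 1000 cells per flask): bias of α̂ ≈ 0.0003 Gy⁻¹ —
statistically zero over 3000 replicates and far below the mean reported
standard error of 0.013 Gy⁻¹.

Independent experiments can be combined before fitting with
`pool_survival_points` (per-dose inverse-variance weighted means), the
conventional treatment when plotting weighted means of several assays.

## Isoeffective doses and DMF

αD + βD² = −ln(SF_level) is solved with the cancellation-free positive
root 2L/(α + √(α² + 4βL)), stable as β → 0.  Its standard error uses the
implicit-function derivatives ∂D/∂α = −D/(α+2βD), ∂D/∂β = −D²/(α+2βD),
combined in quadrature; the α–β covariance is deliberately omitted — it is
negative for survival fits, and keeping it would shrink the dose error.
The DMF at a level is D_ref/D_test with σ_DMF = DMF·√((σ_ref/D_ref)² +
(σ_test/D_test)²), the two curves treated as independent.  A Monte-Carlo
perturbation oracle (`sigma_dmf_oracle`) cross-checks the closed form; the
low-dose limit DMF_max = α_test/α_ref is provided separately and refuses a
reference curve whose α is statistically equivalent to zero (ratio of an
estimate to noise).

## Aberration analysis

Frequencies are per-cell means with Poisson SE √k/N — per-cell aberration
counts are treated as independent Poisson, which is exactly the assumption
the scoring statistics rest on.  The yield fit Y = Y₀ + αD + βD² keeps Y₀
fixed to the measured unirradiated baseline of the same condition (a
shared-baseline policy is available in the pipeline config); only
irradiated points enter the fit.  α is dropped (purely quadratic refit)
under the same 1.96·σ equivalence rule, mirroring responses with no
measurable linear component.

Weights built from *observed* Poisson errors are correlated with the noise
(a downward-fluctuating count gets a smaller SE and more weight), which
biases the curvature low by ~1.5% at realistic scoring depths; one
reweighting pass with model-predicted Poisson errors removes this (the
scoring depth is recovered from N = freq/se²).  After reweighting, β̂
conditional on the quadratic-only form being selected is unbiased over 500
simulated mFISH experiments; the unconditional mean retains a small (<2%)
offset from the ~3% of replicates that spuriously keep a linear term —
an intrinsic property of any estimate-then-select procedure.

Damage-level DMFs solve each curve at a fixed yield (aberrations per cell,
levels above both baselines) and propagate parameter errors through
central finite differences of the root.  Complex-exchange metrics count
translocations + dicentrics + rings (+ incomplete exchanges) as simple
exchanges by default — rings behave as simple exchanges even though some
category conventions name only translocations and dicentrics — with both
inclusions toggleable; acentric fragments are not exchanges and never
enter either denominator.

## Synthetic data

`simulate_clonogenic` draws colonies per flask as Binomial(cells_seeded,
PE·SF(D)): the number of trials is fixed per flask, so binomial is the
exact noise model and Poisson its large-N limit (available as a toggle).
Defaults mirror the standard design: doses {0, 0.5, 1, 2, 3, 4} Gy, 4
replicate flasks per dose, PE 0.6, 1000 cells per flask — chosen so
expected colony counts stay in the tens-to-hundreds where fits are stable.

`simulate_aberrations` draws each dose's total aberration count as
Poisson(N·Y(D)), assigns complex exchanges by a per-dose probability
(default rising 30% → 42% over 0.5–4 Gy, the range typical of densely
ionizing exposures) and splits the remainder among simple categories by a
fixed multinomial.  Scoring depths default to 500 spreads per dose (200
for mFISH configs), 1500 for unirradiated controls.  An optional
negative-binomial mode introduces overdispersion for robustness studies;
it is not the default because the downstream statistics assume Poisson.

What the generators deliberately do not emulate: inter-experiment
variability beyond counting noise, dose-rate or cell-cycle effects, scorer
bias, overdispersion of aberration counts (outside the explicit NB mode),
and any microdosimetric track-structure detail.  Passing recovery tests
therefore demonstrates that the estimation chain is correct and calibrated
under its own assumptions — not that those assumptions exhaust real assay
variability.

## Numerical and interface choices

Default simulation seed 20180118; all generators take explicit seeds and
are bit-reproducible.  Zero-SE points in mixed datasets receive the
smallest nonzero SE present (largest finite weight).  Zero surviving
fractions are flagged degenerate and excluded from fits rather than
entering log space.  Effect levels are decimals everywhere in code and
JSON (0.1, never "10%"); the CLI accepts both spellings.  Problem sizes in
the recovery tests and the acceptance script (500 replicates; 10⁵–10⁶
Monte-Carlo draws) give sampling errors comfortably below the tolerances
they are checked against.

## Known limitations

First-order error propagation is inaccurate for parameter CVs ≳ 20% (the
damage-level DMF errors for shallow curves, for instance, are then only
indicative).  The DMF machinery compares two curves measured independently;
it does not model shared systematic dosimetry error, which would cancel in
the ratio.  No relative-biological-effectiveness computation against a
photon reference is included — DMF within one beam quality only.
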