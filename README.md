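# radioassay

Quantitative analysis of radiosensitizer experiments: clonogenic cell
survival, chromosome aberration dose responses, and Dose-Modifying Factors
(DMF) with full error propagation.

The package is written for radiobiologists analysing paired dose-response
experiments — cells irradiated with and without a sensitizing agent (for
example a boron compound under therapeutic proton beams) — who need the
complete chain from raw colony or aberration counts to a DMF with a
defensible uncertainty.

## The models

**Cell survival.** The surviving fraction after a dose *D* follows the
linear-quadratic (LQ) model

    SF(D) = exp(−αD − βD²),

with α (Gy⁻¹) the initial slope and β (Gy⁻²) the curvature.  Raw data are
colony counts from replicate flasks; the reduction divides mean colonies by
mean cells seeded and normalizes by the 0 Gy plating efficiency PE, with
standard errors propagated through each step (counting errors are floored at
their Poisson expectation).  When the fitted β is statistically equivalent
to zero the curve is refitted as a pure exponential — the shape high-LET
radiation produces.

**Dose-Modifying Factor.** At an effect level (e.g. 10% survival), the DMF
is the ratio of isoeffective doses

    DMF = D_reference / D_sensitized ,

with σ_DMF from the relative dose errors in quadrature; each dose error is
propagated from the fit parameter errors with the α–β covariance
deliberately neglected (it is negative for survival fits, and dropping it
avoids underestimating the error).

**Chromosome aberrations.** Aberration frequencies per cell (translocations,
dicentrics, rings, acentric fragments, incomplete and complex exchanges)
carry Poisson standard errors √k/N and are fitted to

    Y(D) = Y₀ + αD + βD²

with the baseline Y₀ fixed to the measured unirradiated frequency.  DMFs
are evaluated at fixed damage levels, and complex-exchange fractions and
complex:simple ratios — the cytogenetic signature of densely ionizing
radiation — are reported per sample.

**Synthetic assays.** Because the package is validated by parameter
recovery, it ships generators for both assays: binomial colony counts per
flask under LQ survival, and Poisson per-cell aberration counts with a
dose-dependent complex-exchange share.  `coverage_experiment` replays
simulate → reduce → fit hundreds of times and reports bias, RMSE and the
empirical coverage of the nominal 95% intervals.

## Worked example

```
radioassay replay --seed 20180118 --out-dir results/
```

simulates a reference and a boron-sensitized condition for both assays
(truth values at the published scale: survival α=0.314 Gy⁻¹, β=0.035 Gy⁻²
vs a pure-exponential α=0.705 Gy⁻¹; aberration yields Y₀=0.027, β=0.051
Gy⁻² vs Y₀=0.023, α=0.154 Gy⁻¹, β=0.034 Gy⁻²), runs the full pipeline and
prints:

```
## Survival fits

| condition | model | alpha (Gy^-1) | beta (Gy^-2) |
|---|---|---|---|
| B11_80ppm | pure_exponential | 0.701 ± 0.012 | — |
| noBSH | linear_quadratic | 0.283 ± 0.029 | 0.038 ± 0.009 |

## Survival DMFs

- B11_80ppm at SF=0.1: DMF = 1.49 ± 0.12 (D_ref 4.90 Gy, D_test 3.28 Gy)

## Aberration yield fits

- B11_80ppm: Y0 = 0.020, alpha = 0.193 ± 0.025 Gy^-1, beta = 0.023 ± 0.008 Gy^-2
- noBSH: Y0 = 0.032, alpha = 0 (equiv. zero) Gy^-1, beta = 0.052 ± 0.002 Gy^-2

## Aberration DMFs

- B11_80ppm at 0.2 aberrations/cell: DMF = 2.12 ± 0.24
- B11_80ppm at 0.4 aberrations/cell: DMF = 1.62 ± 0.17
```

Reading the output: the sensitized survival curve is purely exponential and
about twice as steep as the reference, giving a DMF of ~1.5 at 10% survival
— the sensitizer lets you reach the same cell kill with two-thirds of the
dose.  The reference aberration yield is purely quadratic (no measurable
linear term), while the sensitized curve gains a linear component, the
hallmark of densely ionizing damage; at 20 aberrations per 100 cells the
damage-level DMF is ~2.

Machine-readable JSON artifacts (one per fit and per DMF) and
`complex_metrics.csv` are written next to `report.md`.  The other
subcommands (`simulate`, `fit-survival`, `fit-ca`, `dmf`, `metrics`) expose
the individual pipeline stages; every CLI action is a thin wrapper over the
`radioassay` library API shown in the module docstrings.

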