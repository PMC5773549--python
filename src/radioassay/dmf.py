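"""Dose-Modifying Factors from pairs of fitted dose-response curves.

The DMF at an effect level is the ratio of isoeffective doses of a reference
curve (no sensitizer) and a test curve (with sensitizer):

    DMF = D_ref / D_test   at the stated effect level.

Its uncertainty treats the two curves as independent and combines the
relative dose errors in quadrature:

    sigma_DMF = DMF * sqrt( (sigma_Dref/D_ref)^2 + (sigma_Dtest/D_test)^2 )

A Monte-Carlo perturbation oracle is provided as an independent check of the
first-order propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .survival import LQFitResult, dose_uncertainty, isoeffective_dose

__all__ = ["DMFResult", "dmf_at_survival", "dmf_max", "sigma_dmf_oracle"]


@dataclass(frozen=True)
class DMFResult:
    """Dose-modifying factor at a stated effect level, with uncertainty.

    ``level`` is a surviving fraction (survival curves) or an aberration
    frequency per cell (cytogenetic curves).  ``d_ref`` and ``d_test`` are the
    two isoeffective doses in Gy; ``dmf`` equals their ratio exactly.
    """

    level: float
    dmf: float
    sigma_dmf: float
    d_ref: float
    d_test: float

    def __post_init__(self) -> None:
        if self.dmf <= 0:
            raise ValueError("dmf must be positive")
        if self.sigma_dmf < 0:
            raise ValueError("sigma_dmf must be >= 0")
        if not math.isclose(self.dmf, self.d_ref / self.d_test, rel_tol=1e-12):
            raise ValueError("dmf must equal d_ref / d_test")


def combine_dose_errors(
    level: float, d_ref: float, s_ref: float, d_test: float, s_test: float
) -> DMFResult:
    """Assemble a DMFResult from two isoeffective doses and their errors."""
    dmf = d_ref / d_test
    sigma = dmf * math.sqrt((s_ref / d_ref) ** 2 + (s_test / d_test) ** 2)
    return DMFResult(level=level, dmf=dmf, sigma_dmf=sigma, d_ref=d_ref, d_test=d_test)


def dmf_at_survival(
    fit_ref: LQFitResult, fit_test: LQFitResult, sf_level: float = 0.1
) -> DMFResult:
    """DMF at a survival level from two fitted LQ curves.

    Isoeffective doses come from inverting each curve at ``sf_level``; their
    standard errors from first-order propagation of the fit uncertainties
    (parameter covariance neglected); the DMF error from the quadrature
    combination of relative dose errors.
    """
    d_ref = isoeffective_dose(fit_ref, sf_level)
    d_test = isoeffective_dose(fit_test, sf_level)
    if d_ref <= 0 or d_test <= 0:
        raise ValueError("isoeffective doses must be positive; lower the level")
    s_ref = dose_uncertainty(fit_ref, d_ref)
    s_test = dose_uncertainty(fit_test, d_test)
    return combine_dose_errors(sf_level, d_ref, s_ref, d_test, s_test)


def dmf_max(
    fit_ref: LQFitResult, fit_test: LQFitResult, z_threshold: float = 1.96
) -> tuple[float, float]:
    """Maximum DMF: the ratio of the linear (alpha) components.

    In the low-dose limit the quadratic term vanishes and the DMF tends to
    alpha_test / alpha_ref.  Undefined when the reference alpha is
    statistically equivalent to zero (a purely quadratic reference response).

    Returns ``(dmf_max, sigma)`` with the error propagated in quadrature from
    the two alpha standard errors.
    """
    for name, fit in (("reference", fit_ref), ("test", fit_test)):
        a, s = fit.alpha, fit.sigma_alpha
        if a <= 0 or (s > 0 and a / s < z_threshold):
            raise ValueError(
                f"{name} alpha is statistically equivalent to zero; "
                "dmf_max is undefined"
            )
    ratio = fit_test.alpha / fit_ref.alpha
    sigma = ratio * math.sqrt(
        (fit_ref.sigma_alpha / fit_ref.alpha) ** 2
        + (fit_test.sigma_alpha / fit_test.alpha) ** 2
    )
    return ratio, sigma


def sigma_dmf_oracle(
    fit_ref: LQFitResult,
    fit_test: LQFitResult,
    sf_level: float = 0.1,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo estimate of sigma_DMF by Gaussian parameter perturbation.

    Draws independent Gaussian perturbations of (alpha, beta) for both fits
    (matching the no-covariance convention of the analytic propagation),
    recomputes the DMF per draw and returns the sample standard deviation.
    Draws yielding an invalid curve (non-positive slope everywhere, or no
    positive isoeffective dose) are rejected; if more than 10% are rejected a
    warning is emitted.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10_000 for a stable estimate")
    rng = np.random.default_rng(seed)
    level = -math.log(sf_level)

    def draw_doses(fit: LQFitResult) -> np.ndarray:
        a = rng.normal(fit.alpha, fit.sigma_alpha, n_draws)
        b = rng.normal(fit.beta, fit.sigma_beta, n_draws)
        with np.errstate(invalid="ignore", divide="ignore"):
            disc = a * a + 4 * b * level
            d = np.where(
                b == 0, level / a, (-a + np.sqrt(np.abs(disc))) / (2 * b)
            )
            d = np.where(disc < 0, np.nan, d)
        d[~np.isfinite(d) | (d <= 0)] = np.nan
        return d

    d_ref = draw_doses(fit_ref)
    d_test = draw_doses(fit_test)
    valid = np.isfinite(d_ref) & np.isfinite(d_test)
    n_rejected = n_draws - int(valid.sum())
    if n_rejected > 0.10 * n_draws:
        warnings.warn(
            f"{n_rejected}/{n_draws} perturbation draws produced invalid "
            "curves; the Monte-Carlo sigma may be biased",
            stacklevel=2,
        )
    dmf = d_ref[valid] / d_test[valid]
    return float(dmf.std(ddof=1))
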