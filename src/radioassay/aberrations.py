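"""Chromosome aberration dose-response analysis.

Cytogenetic damage is scored as aberrations per cell in chromosome spreads
(conventional FISH on painted pairs, or whole-karyotype mFISH).  Scored
categories: translocations, dicentrics, rings, acentric fragments, incomplete
exchanges and complex exchanges.  Per-cell counts are treated as Poisson, so
a frequency from N cells with total count k has standard error sqrt(k)/N.

The dose response is fitted to Y = Y0 + alpha*D + beta*D^2 with the baseline
Y0 fixed to the measured frequency of the matching unirradiated sample (it is
not a free parameter).  DMFs between two fitted curves are evaluated at fixed
damage levels (aberrations per cell) by solving each curve for its
isoeffective dose.  Complex exchanges — involving three or more breaks in two
or more chromosomes — are the cytogenetic signature of densely ionizing
radiation, and are summarized as a fraction of total exchanges and as a
complex-to-simple ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dmf import DMFResult, combine_dose_errors

__all__ = [
    "CATEGORIES",
    "AberrationSample",
    "FrequencyPoint",
    "AberrationFitResult",
    "ComplexMetrics",
    "frequency",
    "fit_ca",
    "ca_isoeffective_dose",
    "dmf_at_damage_level",
    "complex_metrics",
]

CATEGORIES = (
    "translocation",
    "dicentric",
    "ring",
    "acentric_fragment",
    "incomplete_exchange",
    "complex_exchange",
)


@dataclass(frozen=True)
class AberrationSample:
    """Aberration counts by category for one condition/dose scoring session."""

    condition: str
    assay: str  # conventional_FISH | mFISH | none
    dose: float
    cells_scored: int
    counts: dict

    def __post_init__(self) -> None:
        if self.cells_scored < 1:
            raise ValueError("cells_scored must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown aberration categories: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FrequencyPoint:
    """Aberrations per cell at one dose, with Poisson standard error."""

    dose: float
    freq: float
    se_freq: float

    def __post_init__(self) -> None:
        if self.freq < 0 or self.se_freq < 0:
            raise ValueError("frequency and its SE must be >= 0")


@dataclass(frozen=True)
class AberrationFitResult:
    """Fitted Y = Y0 + alpha*D + beta*D^2 with Y0 fixed, not fitted."""

    y0: float
    alpha: float
    sigma_alpha: float
    beta: float
    sigma_beta: float
    alpha_zero: bool  # alpha statistically equivalent to zero, dropped
    n_points: int
    residual_stat: float

    def __post_init__(self) -> None:
        if self.y0 < 0:
            raise ValueError("y0 must be >= 0")
        if self.alpha_zero and (self.alpha != 0 or self.sigma_alpha != 0):
            raise ValueError("alpha_zero requires alpha = sigma_alpha = 0")


@dataclass(frozen=True)
class ComplexMetrics:
    """Complex-exchange share of total exchanges and complex:simple ratio."""

    complex_fraction: float
    complex_to_simple_ratio: float
    defined: bool = True


def frequency(sample: AberrationSample, categories="all") -> FrequencyPoint:
    """Aberration frequency per cell for a category subset, with Poisson SE.

    freq = (sum of selected counts) / cells scored;
    se   = sqrt(sum of selected counts) / cells scored.
    """
    if categories == "all":
        selected = CATEGORIES
    else:
        selected = tuple(categories)
        unknown = set(selected) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown aberration categories: {sorted(unknown)}")
    total = sum(sample.counts.get(c, 0) for c in selected)
    n = sample.cells_scored
    return FrequencyPoint(
        dose=sample.dose, freq=total / n, se_freq=math.sqrt(total) / n
    )


def _se_sigma(se: np.ndarray) -> np.ndarray | None:
    nonzero = se[se > 0]
    if nonzero.size == 0:
        return None
    out = se.copy()
    out[out == 0] = nonzero.min()
    return out


def fit_ca(points, y0: float, z_threshold: float = 1.96) -> AberrationFitResult:
    """Weighted least-squares fit of Y = Y0 + alpha*D + beta*D^2, Y0 fixed.

    Only irradiated points (dose > 0) enter the fit; the baseline is supplied
    as ``y0`` from the matching unirradiated sample.  Weights are 1/se^2.
    An unconstrained fit is run first; if alpha is statistically equivalent to
    zero (alpha_hat <= 0 or alpha_hat/sigma below ``z_threshold``) the curve
    is refitted as purely quadratic and alpha is reported as zero — the
    behaviour of a response with no measurable linear component.  Reported
    parameters are constrained non-negative.  Parameter covariance is taken
    unscaled when Poisson standard errors are supplied, since those are
    absolute errors rather than relative weights.

    Weights based on *observed* counts are correlated with the noise (a
    downward-fluctuating count gets a smaller SE, hence more weight), which
    biases the fit low.  After the initial fit the Poisson weights are
    therefore recomputed once from the model-predicted frequencies and the
    fit repeated; the scoring depth needed for this is recovered from the
    Poisson relation N = freq / se^2.
    """
    if y0 < 0:
        raise ValueError("y0 must be >= 0")
    pts = sorted((p for p in points if p.dose > 0), key=lambda p: p.dose)
    if len(pts) < 2:
        raise ValueError("need at least 2 irradiated dose points")
    d = np.array([p.dose for p in pts])
    f = np.array([p.freq for p in pts])
    y = f - y0
    se = np.array([p.se_freq for p in pts])
    sigma = _se_sigma(se)

    def full(x, a, b):
        return a * x + b * x * x

    def quad(x, b):
        return b * x * x

    def run(fn, p0, bounds, sig):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                fn, d, y, p0=p0, sigma=sig,
                absolute_sigma=sig is not None,
                bounds=bounds, maxfev=10000,
            )
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        resid = y - fn(d, *popt)
        if sig is not None:
            resid = resid / sig
        return popt, perr, float(np.sum(resid**2))

    def select_and_fit(sig):
        popt, perr, _ = run(full, (0.1, 0.02), (-np.inf, np.inf), sig)
        a_hat, s_a = popt[0], perr[0]
        alpha_zero = a_hat <= 1e-6 or (s_a > 0 and a_hat / s_a < z_threshold)
        if alpha_zero:
            popt, perr, wssr = run(quad, (0.02,), (0, np.inf), sig)
            return AberrationFitResult(
                y0=y0, alpha=0.0, sigma_alpha=0.0,
                beta=float(popt[0]), sigma_beta=float(perr[0]),
                alpha_zero=True, n_points=len(pts), residual_stat=wssr,
            )
        popt, perr, wssr = run(
            full, np.clip(popt, 1e-12, None), ([0, 0], [np.inf, np.inf]), sig
        )
        return AberrationFitResult(
            y0=y0, alpha=float(popt[0]), sigma_alpha=float(perr[0]),
            beta=float(popt[1]), sigma_beta=float(perr[1]),
            alpha_zero=False, n_points=len(pts), residual_stat=wssr,
        )

    fit = select_and_fit(sigma)
    if sigma is None or not np.all((f > 0) & (se > 0)):
        return fit
    # one reweighting pass with model-predicted Poisson errors
    n_cells = f / se**2
    pred = fit.y0 + fit.alpha * d + fit.beta * d * d
    sigma = np.sqrt(np.maximum(pred, 1e-12) / n_cells)
    return select_and_fit(sigma)


def ca_isoeffective_dose(fit: AberrationFitResult, level: float) -> float:
    """Dose at which Y0 + alpha*D + beta*D^2 reaches ``level`` (positive root)."""
    if level <= fit.y0:
        raise ValueError(
            f"damage level {level} must exceed the baseline {fit.y0}"
        )
    excess = level - fit.y0
    a, b = fit.alpha, fit.beta
    if a == 0 and b == 0:
        raise ValueError("isoeffective dose undefined for a flat response")
    # positive quadratic root, cancellation-free form (valid for b = 0)
    return 2 * excess / (a + math.sqrt(a * a + 4 * b * excess))


def _fd_dose_sigma(fit: AberrationFitResult, level: float) -> float:
    """sigma_D by central finite differences of the root w.r.t. alpha, beta."""
    def root(a: float, b: float) -> float:
        shifted = AberrationFitResult(
            y0=fit.y0, alpha=max(a, 0.0), sigma_alpha=0.0, beta=max(b, 0.0),
            sigma_beta=0.0, alpha_zero=False, n_points=fit.n_points,
            residual_stat=0.0,
        )
        return ca_isoeffective_dose(shifted, level)

    var = 0.0
    for which, s in (("a", fit.sigma_alpha), ("b", fit.sigma_beta)):
        if s == 0:
            continue
        h = 1e-6 * max(1.0, fit.alpha if which == "a" else fit.beta)
        if which == "a":
            grad = (root(fit.alpha + h, fit.beta) - root(fit.alpha - h, fit.beta)) / (2 * h)
        else:
            grad = (root(fit.alpha, fit.beta + h) - root(fit.alpha, fit.beta - h)) / (2 * h)
        var += grad * grad * s * s
    return math.sqrt(var)


def dmf_at_damage_level(
    fit_ref: AberrationFitResult, fit_test: AberrationFitResult, level: float
) -> DMFResult:
    """DMF at a fixed damage level (aberrations per cell).

    Each curve is solved for the dose producing ``level`` aberrations per
    cell; the DMF is D_ref/D_test with the usual quadrature error from the
    two dose uncertainties, here obtained by finite-difference sensitivity of
    the root to each fitted parameter.
    """
    d_ref = ca_isoeffective_dose(fit_ref, level)
    d_test = ca_isoeffective_dose(fit_test, level)
    s_ref = _fd_dose_sigma(fit_ref, level)
    s_test = _fd_dose_sigma(fit_test, level)
    return combine_dose_errors(level, d_ref, s_ref, d_test, s_test)


def complex_metrics(
    sample: AberrationSample,
    include_rings: bool = True,
    include_incomplete: bool = True,
) -> ComplexMetrics:
    """Complex-exchange fraction and complex:simple ratio for one sample.

    Simple exchanges are translocations and dicentrics, by default also
    rings, and (controllable) incomplete exchanges.  Acentric fragments are
    not exchanges and never enter either denominator.  With no exchanges at
    all the metrics are undefined and returned as NaN with ``defined=False``.
    """
    simple_cats = ["translocation", "dicentric"]
    if include_rings:
        simple_cats.append("ring")
    if include_incomplete:
        simple_cats.append("incomplete_exchange")
    simple = sum(sample.counts.get(c, 0) for c in simple_cats)
    cx = sample.counts.get("complex_exchange", 0)
    if simple + cx == 0:
        warnings.warn("no exchanges scored; complex metrics undefined", stacklevel=2)
        return ComplexMetrics(math.nan, math.nan, defined=False)
    fraction = cx / (cx + simple)
    ratio = cx / simple if simple > 0 else math.inf
    return ComplexMetrics(complex_fraction=fraction, complex_to_simple_ratio=ratio)
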