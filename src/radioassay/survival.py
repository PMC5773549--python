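"""Clonogenic survival analysis: count reduction, error propagation, LQ fitting.

The clonogenic assay measures the fraction of cells that retain colony-forming
ability after irradiation.  Raw data are colony counts from replicate flasks at
each dose.  The reduction chain is:

1. replicate counts -> mean and standard error, with a Poisson floor on the SE
   (counting statistics set a lower bound on the believable error of a count);
2. the 0 Gy flasks define the plating efficiency PE = colonies / cells seeded,
   with its SE propagated from both count summaries;
3. each dose's surviving fraction SF(D) = (colonies/cells)_D / PE, with the
   mean number of cells seeded treated as error-free (its counting error is
   already absorbed into SE(PE));
4. the dose response is fitted to the linear-quadratic model
   SF = exp(-alpha*D - beta*D^2) by weighted nonlinear least squares.

Isoeffective doses (the dose producing a stated survival level) and their
uncertainties are derived from the fit; the parameter covariance is
deliberately neglected in the dose uncertainty, because alpha and beta are
anti-correlated in survival fits and dropping the (negative) covariance term
avoids underestimating the error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ClonogenicRecord",
    "CountSummary",
    "PlatingEfficiency",
    "SurvivalPoint",
    "LQFitResult",
    "summarize_counts",
    "plating_efficiency",
    "surviving_fraction",
    "lq_survival",
    "fit_lq",
    "isoeffective_dose",
    "dose_uncertainty",
    "reduce_clonogenic",
    "pool_survival_points",
]


@dataclass(frozen=True)
class ClonogenicRecord:
    """One flask of a clonogenic assay: colonies counted out of cells seeded."""

    dose: float
    cells_seeded: int
    colonies: int
    replicate_id: str = "r1"
    condition: str = "default"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0 Gy, got {self.dose}")
        if self.cells_seeded <= 0:
            raise ValueError(f"cells_seeded must be positive, got {self.cells_seeded}")
        if self.colonies < 0:
            raise ValueError(f"colonies must be >= 0, got {self.colonies}")
        if self.colonies > self.cells_seeded:
            raise ValueError(
                f"colonies ({self.colonies}) cannot exceed cells seeded "
                f"({self.cells_seeded})"
            )


@dataclass(frozen=True)
class CountSummary:
    """Mean and standard error of replicate counts."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass(frozen=True)
class PlatingEfficiency:
    """Fraction of unirradiated seeded cells forming colonies, with SE."""

    pe: float
    se_pe: float

    def __post_init__(self) -> None:
        if not 0 < self.pe <= 1:
            raise ValueError(f"plating efficiency must be in (0, 1], got {self.pe}")
        if self.se_pe < 0:
            raise ValueError("se_pe must be >= 0")


@dataclass(frozen=True)
class SurvivalPoint:
    """Surviving fraction at one dose with its propagated standard error.

    ``degenerate`` marks a point with zero surviving fraction (no colonies and
    no counting spread): such points cannot enter log-space or weighted fits.
    """

    dose: float
    sf: float
    se_sf: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.se_sf < 0:
            raise ValueError("se_sf must be >= 0")
        if self.sf <= 0 and not self.degenerate:
            raise ValueError("sf must be > 0 unless the point is flagged degenerate")


@dataclass(frozen=True)
class LQFitResult:
    """Fitted linear-quadratic survival parameters.

    ``model_form`` is ``"linear_quadratic"`` or ``"pure_exponential"``; the
    latter means the quadratic coefficient was statistically equivalent to zero
    (or forced off) and the curve was refitted with beta identically 0.
    ``residual_stat`` is the weighted sum of squared residuals of the reported
    fit.
    """

    alpha: float
    sigma_alpha: float
    beta: float
    sigma_beta: float
    model_form: str
    n_points: int
    residual_stat: float

    def __post_init__(self) -> None:
        if self.model_form not in ("linear_quadratic", "pure_exponential"):
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0 in a reported fit")
        if self.model_form == "pure_exponential" and (
            self.beta != 0 or self.sigma_beta != 0
        ):
            raise ValueError("pure_exponential requires beta = sigma_beta = 0")


def summarize_counts(counts, apply_poisson_floor: bool = True) -> CountSummary:
    """Reduce replicate counts to mean and standard error of the mean.

    The observed SE (sample SD / sqrt(n)) is floored at the Poisson-implied
    standard error of the mean of n counts, sqrt(mean / n).  Sources of
    error beyond counting (dilution, pipetting) make the observed spread
    normally exceed the Poisson expectation; when it does not — as happens
    by chance with few replicates — the observed SE understates the real
    counting error and the floor is used instead.  For a single flask the
    floor reduces to the familiar sqrt(k) counting error.

    Parameters
    ----------
    counts
        Non-empty sequence of non-negative integer counts, one per replicate.
    apply_poisson_floor
        Disable to obtain the plain sample SEM.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    n = int(arr.size)
    mean = float(arr.mean())
    observed_se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    se = observed_se
    if apply_poisson_floor and mean > 0:
        floor = math.sqrt(mean / n)  # Poisson SE of the mean of n counts
        se = max(observed_se, floor)
    if mean == 0:
        warnings.warn("all counts are zero; summary is degenerate", stacklevel=2)
        se = 0.0
    return CountSummary(mean=mean, se=se, n=n)


def plating_efficiency(
    colonies_0gy: CountSummary, cells_0gy: CountSummary
) -> PlatingEfficiency:
    """Plating efficiency PE = mean colonies / mean cells at 0 Gy, with SE.

    The SE is propagated from both count summaries by the standard first-order
    formula for a ratio of two means:

        SE(PE) = sqrt( (SE_col / X_cells)^2 + (X_col / X_cells^2)^2 * SE_cells^2 )
    """
    if cells_0gy.mean <= 0:
        raise ValueError("mean number of cells seeded at 0 Gy must be positive")
    pe = colonies_0gy.mean / cells_0gy.mean
    se_pe = math.sqrt(
        (colonies_0gy.se / cells_0gy.mean) ** 2
        + (colonies_0gy.mean / cells_0gy.mean**2) ** 2 * cells_0gy.se**2
    )
    return PlatingEfficiency(pe=pe, se_pe=se_pe)


def surviving_fraction(
    colonies_d: CountSummary,
    cells_d: CountSummary,
    pe: PlatingEfficiency,
    dose: float,
) -> SurvivalPoint:
    """Surviving fraction at a dose, normalized by plating efficiency.

    SF(D) = (mean colonies / mean cells)_D / PE.  The mean number of cells
    seeded is treated as exact — its counting error is already carried by
    SE(PE) — so the propagated error has two terms, colony counting and PE:

        SE(SF) = sqrt( (1/PE)^2 (SE_col/X_cells)^2 + (sf_raw/PE^2)^2 SE(PE)^2 )

    with sf_raw the unnormalized ratio (colonies/cells)_D.
    """
    if cells_d.mean <= 0:
        raise ValueError("mean number of cells seeded must be positive")
    sf_raw = colonies_d.mean / cells_d.mean
    sf = sf_raw / pe.pe
    se_sf = math.sqrt(
        (1.0 / pe.pe) ** 2 * (colonies_d.se / cells_d.mean) ** 2
        + (sf_raw / pe.pe**2) ** 2 * pe.se_pe**2
    )
    degenerate = sf == 0.0 and se_sf == 0.0
    if sf == 0.0:
        warnings.warn(
            f"zero surviving fraction at {dose} Gy; point flagged degenerate",
            stacklevel=2,
        )
        degenerate = True
    return SurvivalPoint(dose=dose, sf=sf, se_sf=se_sf, degenerate=degenerate)


def lq_survival(dose, alpha: float, beta: float):
    """Linear-quadratic survival SF = exp(-alpha*D - beta*D^2).

    Accepts scalar or array dose; returns the same shape.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = np.exp(-alpha * d - beta * d * d)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def _fit_weights(se: np.ndarray) -> np.ndarray | None:
    """Return per-point sigmas for curve_fit, or None for an unweighted fit.

    Exact points (se = 0) in a mixed dataset receive the smallest nonzero
    sigma present, so they carry the largest finite weight.
    """
    nonzero = se[se > 0]
    if nonzero.size == 0:
        return None
    out = se.copy()
    out[out == 0] = nonzero.min()
    return out


def _beta_equivalent_zero(beta_hat: float, sigma_beta: float, z: float) -> bool:
    if beta_hat <= 1e-6:  # numerically nil (also covers perfect-fit sigma collapse)
        return True
    if sigma_beta > 0:
        return beta_hat / sigma_beta < z
    return False


def fit_lq(
    points,
    force_pure_exponential: bool = False,
    z_threshold: float = 1.96,
) -> LQFitResult:
    """Fit SF = exp(-alpha*D - beta*D^2) to survival points.

    Weighted nonlinear least squares in linear SF space with weights
    1/se_sf^2 (Levenberg–Marquardt via :func:`scipy.optimize.curve_fit`).
    The unconstrained fit is run first; if the fitted beta is statistically
    equivalent to zero (beta_hat <= 0 or beta_hat/sigma_beta below
    ``z_threshold``, a two-sided 95% criterion by default) or
    ``force_pure_exponential`` is set, the curve is refitted with beta
    identically zero and reported as pure exponential.  The reported
    parameters are constrained non-negative.

    Because the supplied se_sf are absolute standard errors from the
    propagation chain (not relative weights), parameter covariance is taken
    unscaled from the weighted fit; when no point carries an error the
    residual-scaled covariance is the only option and is used.

    Degenerate points (sf = 0) are excluded, as is the 0 Gy anchor: its
    surviving fraction is 1 by construction and the model passes through
    (0, 1) for every parameter value, so it carries no information about
    alpha or beta.  At least one more point than free parameters is
    required.
    """
    usable = [p for p in points if not p.degenerate and p.sf > 0 and p.dose > 0]
    usable.sort(key=lambda p: p.dose)
    d = np.array([p.dose for p in usable])
    sf = np.array([p.sf for p in usable])
    se = np.array([p.se_sf for p in usable])
    sigma = _fit_weights(se)

    def lq(x, a, b):
        return np.exp(-a * x - b * x * x)

    def pure(x, a):
        return np.exp(-a * x)

    def run(fn, p0, bounds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                fn, d, sf, p0=p0, sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=bounds, maxfev=10000,
            )
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        resid = sf - fn(d, *popt)
        if sigma is not None:
            resid = resid / sigma
        return popt, perr, float(np.sum(resid**2))

    pure_exp = force_pure_exponential
    if not pure_exp:
        if len(usable) < 3:
            raise ValueError("need at least 3 non-degenerate points for an LQ fit")
        try:
            popt, perr, _ = run(lq, (0.3, 0.03), (-np.inf, np.inf))
        except RuntimeError as exc:
            raise RuntimeError(f"LQ fit did not converge: {exc}") from exc
        pure_exp = _beta_equivalent_zero(popt[1], perr[1], z_threshold)

    if pure_exp:
        if len(usable) < 2:
            raise ValueError("need at least 2 non-degenerate points")
        popt, perr, wssr = run(pure, (0.3,), (0, np.inf))
        return LQFitResult(
            alpha=float(popt[0]), sigma_alpha=float(perr[0]),
            beta=0.0, sigma_beta=0.0,
            model_form="pure_exponential",
            n_points=len(usable), residual_stat=wssr,
        )

    popt, perr, wssr = run(lq, np.clip(popt, 1e-12, None), ([0, 0], [np.inf, np.inf]))
    return LQFitResult(
        alpha=float(popt[0]), sigma_alpha=float(perr[0]),
        beta=float(popt[1]), sigma_beta=float(perr[1]),
        model_form="linear_quadratic",
        n_points=len(usable), residual_stat=wssr,
    )


def isoeffective_dose(fit: LQFitResult, sf_level: float) -> float:
    """Dose at which the fitted curve reaches the given surviving fraction.

    Solves alpha*D + beta*D^2 = -ln(sf_level) for the non-negative root.
    """
    if not 0 < sf_level <= 1:
        raise ValueError("sf_level must be in (0, 1]")
    alpha, beta = fit.alpha, fit.beta
    if alpha == 0 and beta == 0:
        raise ValueError("isoeffective dose undefined for alpha = beta = 0")
    level = -math.log(sf_level)
    # positive quadratic root in the cancellation-free form, valid for beta = 0
    return 2 * level / (alpha + math.sqrt(alpha * alpha + 4 * beta * level))


def dose_uncertainty(fit: LQFitResult, dose: float) -> float:
    """Standard error of an isoeffective dose from the fit uncertainties.

    First-order propagation through the implicit relation
    alpha*D + beta*D^2 = const:

        dD/dalpha = -D / (alpha + 2*beta*D)
        dD/dbeta  = -D^2 / (alpha + 2*beta*D)
        sigma_D   = sqrt( (dD/dalpha)^2 sigma_alpha^2
                        + (dD/dbeta)^2 sigma_beta^2 )

    The alpha–beta covariance (negative for survival fits) is omitted so the
    error is not underestimated.
    """
    denom = fit.alpha + 2 * fit.beta * dose
    if denom <= 0:
        raise ValueError("alpha + 2*beta*D must be positive")
    dd_da = -dose / denom
    dd_db = -(dose * dose) / denom
    return math.sqrt(
        dd_da * dd_da * fit.sigma_alpha**2 + dd_db * dd_db * fit.sigma_beta**2
    )


def reduce_clonogenic(
    records, apply_poisson_floor: bool = True
) -> dict[str, list[SurvivalPoint]]:
    """Reduce raw flask records to per-condition survival points.

    Groups records by (condition, dose), summarizes colony and cell counts
    across replicates, derives PE from each condition's 0 Gy group and
    normalizes every dose by it.  Returns survival points sorted by dose
    (the 0 Gy point, SF = 1 by construction, is included).
    """
    by_cond: dict[str, dict[float, list[ClonogenicRecord]]] = {}
    for r in records:
        by_cond.setdefault(r.condition, {}).setdefault(r.dose, []).append(r)

    out: dict[str, list[SurvivalPoint]] = {}
    for cond, by_dose in by_cond.items():
        if 0.0 not in by_dose:
            raise ValueError(f"condition {cond!r} has no 0 Gy records (PE undefined)")
        summaries = {
            dose: (
                summarize_counts([r.colonies for r in recs], apply_poisson_floor),
                summarize_counts([r.cells_seeded for r in recs], apply_poisson_floor),
            )
            for dose, recs in by_dose.items()
        }
        pe = plating_efficiency(*summaries[0.0])
        pts = [
            surviving_fraction(col, cel, pe, dose)
            for dose, (col, cel) in sorted(summaries.items())
        ]
        out[cond] = pts
    return out


def pool_survival_points(experiments) -> list[SurvivalPoint]:
    """Inverse-variance weighted pooling of survival points across experiments.

    Takes an iterable of per-experiment point lists; at each dose present, the
    pooled SF is the weighted mean with weights 1/se^2 and pooled SE
    1/sqrt(sum of weights).  Exact points (se = 0) are given the smallest
    nonzero se at that dose; if every point at a dose is exact, the plain mean
    is used with se 0.
    """
    by_dose: dict[float, list[SurvivalPoint]] = {}
    for exp in experiments:
        for p in exp:
            if not p.degenerate:
                by_dose.setdefault(p.dose, []).append(p)
    pooled = []
    for dose, pts in sorted(by_dose.items()):
        sf = np.array([p.sf for p in pts])
        se = np.array([p.se_sf for p in pts])
        sigma = _fit_weights(se)
        if sigma is None:
            pooled.append(SurvivalPoint(dose=dose, sf=float(sf.mean()), se_sf=0.0))
        else:
            w = 1.0 / sigma**2
            pooled.append(
                SurvivalPoint(
                    dose=dose,
                    sf=float(np.sum(w * sf) / np.sum(w)),
                    se_sf=float(1.0 / math.sqrt(np.sum(w))),
                )
            )
    return pooled
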