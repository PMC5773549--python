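"""CSV/JSON/YAML readers and writers, validation, and the analysis pipeline.

Canonical machine-readable output is JSON; the markdown report is derived
from it.  All frequencies and fractions are serialized as decimals (0.1,
never "10%").  Logging goes to stderr; results go to files only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import survival as sv
from .aberrations import (
    AberrationFitResult,
    AberrationSample,
    CATEGORIES,
    complex_metrics,
    dmf_at_damage_level,
    fit_ca,
    frequency,
)
from .dmf import DMFResult, dmf_at_survival
from .survival import ClonogenicRecord, LQFitResult

log = logging.getLogger("radioassay")

CLONOGENIC_COLUMNS = ["condition", "dose_gy", "replicate", "cells_seeded", "colonies"]
ABERRATION_COLUMNS = ["condition", "assay", "dose_gy", "cells_scored", *CATEGORIES]


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Options controlling the end-to-end analysis.

    ``dmf_levels`` are surviving fractions; ``ca_damage_levels`` are
    aberrations per cell.  ``baseline_policy`` selects the fixed Y0 of each
    yield fit: ``"per_condition"`` (the condition's own 0 Gy sample) or
    ``"shared"`` (the reference condition's baseline for every curve).
    ``reference_condition`` names the curve used as DMF denominator-free
    reference; every other condition is compared against it.
    """

    reference_condition: str = "noBSH"
    dmf_levels: tuple = (0.1,)
    ca_damage_levels: tuple = (0.20, 0.40)
    baseline_policy: str = "per_condition"
    beta_z_threshold: float = 1.96
    apply_poisson_floor: bool = True

    def __post_init__(self) -> None:
        if any(not 0 < lvl < 1 for lvl in self.dmf_levels):
            raise ValueError("dmf_levels must be survival fractions in (0, 1)")
        if any(lvl <= 0 for lvl in self.ca_damage_levels):
            raise ValueError("ca_damage_levels must be positive")
        if self.baseline_policy not in ("per_condition", "shared"):
            raise ValueError("baseline_policy must be 'per_condition' or 'shared'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("dmf_levels", "ca_damage_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_clonogenic_csv(path) -> list[ClonogenicRecord]:
    """Read and validate a clonogenic CSV (one row per flask)."""
    df = pd.read_csv(path)
    missing = set(CLONOGENIC_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        log.warning("%s: no data rows", path)
        return []
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ClonogenicRecord(
                    dose=float(row["dose_gy"]),
                    cells_seeded=int(row["cells_seeded"]),
                    colonies=int(row["colonies"]),
                    replicate_id=str(row["replicate"]),
                    condition=str(row["condition"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}, row {idx + 2}: {exc}") from exc
    return records


def read_aberrations_csv(path) -> list[AberrationSample]:
    """Read and validate an aberration CSV (one row per scoring session)."""
    df = pd.read_csv(path)
    missing = set(ABERRATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for idx, row in df.iterrows():
        try:
            samples.append(
                AberrationSample(
                    condition=str(row["condition"]),
                    assay=str(row["assay"]),
                    dose=float(row["dose_gy"]),
                    cells_scored=int(row["cells_scored"]),
                    counts={c: int(row[c]) for c in CATEGORIES},
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}, row {idx + 2}: {exc}") from exc
    return samples


def write_clonogenic_csv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "condition": r.condition,
                "dose_gy": r.dose,
                "replicate": r.replicate_id,
                "cells_seeded": r.cells_seeded,
                "colonies": r.colonies,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_aberrations_csv(samples, path) -> None:
    pd.DataFrame(
        [
            {
                "condition": s.condition,
                "assay": s.assay,
                "dose_gy": s.dose,
                "cells_scored": s.cells_scored,
                **{c: s.counts.get(c, 0) for c in CATEGORIES},
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def fit_to_dict(fit: LQFitResult, condition: str, points=None) -> dict:
    out = {
        "condition": condition,
        "model_form": fit.model_form,
        "alpha": fit.alpha,
        "sigma_alpha": fit.sigma_alpha,
        "beta": fit.beta,
        "sigma_beta": fit.sigma_beta,
        "n_points": fit.n_points,
        "residual_stat": fit.residual_stat,
    }
    if points is not None:
        out["points"] = [
            {"dose": p.dose, "sf": p.sf, "se_sf": p.se_sf, "degenerate": p.degenerate}
            for p in points
        ]
    return out


def fit_from_dict(d: dict) -> LQFitResult:
    return LQFitResult(
        alpha=d["alpha"], sigma_alpha=d["sigma_alpha"],
        beta=d["beta"], sigma_beta=d["sigma_beta"],
        model_form=d["model_form"], n_points=d["n_points"],
        residual_stat=d["residual_stat"],
    )


def dmf_to_dict(res: DMFResult) -> dict:
    return dataclasses.asdict(res)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _survival_section(records, config, out_dir: Path):
    grouped = sv.reduce_clonogenic(records, config.apply_poisson_floor)
    fits: dict[str, LQFitResult] = {}
    for cond, points in grouped.items():
        fit = sv.fit_lq(points, z_threshold=config.beta_z_threshold)
        fits[cond] = fit
        write_json(fit_to_dict(fit, cond, points), out_dir / f"fit_survival_{cond}.json")
    dmfs = {}
    ref = config.reference_condition
    if ref in fits and len(fits) > 1:
        for cond, fit in fits.items():
            if cond == ref:
                continue
            for level in config.dmf_levels:
                res = dmf_at_survival(fits[ref], fit, level)
                dmfs[(cond, level)] = res
                write_json(
                    dmf_to_dict(res), out_dir / f"dmf_survival_{cond}_{level}.json"
                )
    elif len(fits) > 1:
        log.warning(
            "reference condition %r not found; skipping survival DMFs", ref
        )
    return grouped, fits, dmfs


def _aberration_section(samples, config, out_dir: Path):
    by_cond: dict[str, list[AberrationSample]] = {}
    for s in samples:
        by_cond.setdefault(s.condition, []).append(s)
    baselines = {}
    for cond, ss in by_cond.items():
        controls = [s for s in ss if s.dose == 0]
        baselines[cond] = (
            frequency(controls[0]).freq if controls else 0.0
        )
    if config.baseline_policy == "shared":
        shared = baselines.get(config.reference_condition, 0.0)
        baselines = {c: shared for c in baselines}
    fits: dict[str, AberrationFitResult] = {}
    metrics = {}
    for cond, ss in by_cond.items():
        points = [frequency(s) for s in ss if s.dose > 0]
        if len(points) >= 2:
            fit = fit_ca(points, y0=baselines[cond])
            fits[cond] = fit
            write_json(
                {
                    "condition": cond,
                    "y0": fit.y0,
                    "alpha": fit.alpha, "sigma_alpha": fit.sigma_alpha,
                    "beta": fit.beta, "sigma_beta": fit.sigma_beta,
                    "alpha_zero": fit.alpha_zero,
                    "n_points": fit.n_points,
                    "residual_stat": fit.residual_stat,
                },
                out_dir / f"fit_ca_{cond}.json",
            )
        for s in ss:
            if s.dose > 0:
                m = complex_metrics(s)
                metrics[(cond, s.dose)] = m
    if metrics:
        pd.DataFrame(
            [
                {
                    "condition": cond,
                    "dose_gy": dose,
                    "complex_fraction": m.complex_fraction,
                    "complex_to_simple_ratio": m.complex_to_simple_ratio,
                    "defined": m.defined,
                }
                for (cond, dose), m in sorted(metrics.items())
            ]
        ).to_csv(out_dir / "complex_metrics.csv", index=False)
    dmfs = {}
    ref = config.reference_condition
    if ref in fits:
        for cond, fit in fits.items():
            if cond == ref:
                continue
            for level in config.ca_damage_levels:
                try:
                    res = dmf_at_damage_level(fits[ref], fit, level)
                except ValueError as exc:
                    log.warning("CA DMF at %s skipped: %s", level, exc)
                    continue
                dmfs[(cond, level)] = res
                write_json(dmf_to_dict(res), out_dir / f"dmf_ca_{cond}_{level}.json")
    return fits, dmfs, metrics


def _report(out_dir: Path, sv_fits, sv_dmfs, ca_fits, ca_dmfs) -> str:
    lines = ["# Analysis report", "", "## Survival fits", ""]
    if sv_fits:
        lines += [
            "| condition | model | alpha (Gy^-1) | beta (Gy^-2) |",
            "|---|---|---|---|",
        ]
        for cond, f in sorted(sv_fits.items()):
            beta = (
                "—" if f.model_form == "pure_exponential"
                else f"{f.beta:.3f} ± {f.sigma_beta:.3f}"
            )
            lines.append(
                f"| {cond} | {f.model_form} | "
                f"{f.alpha:.3f} ± {f.sigma_alpha:.3f} | {beta} |"
            )
    if sv_dmfs:
        lines += ["", "## Survival DMFs", ""]
        for (cond, level), r in sorted(sv_dmfs.items()):
            lines.append(
                f"- {cond} at SF={level}: DMF = {r.dmf:.2f} ± {r.sigma_dmf:.2f}"
                f" (D_ref {r.d_ref:.2f} Gy, D_test {r.d_test:.2f} Gy)"
            )
    if ca_fits:
        lines += ["", "## Aberration yield fits", ""]
        for cond, f in sorted(ca_fits.items()):
            alpha = "0 (equiv. zero)" if f.alpha_zero else (
                f"{f.alpha:.3f} ± {f.sigma_alpha:.3f}"
            )
            lines.append(
                f"- {cond}: Y0 = {f.y0:.3f}, alpha = {alpha} Gy^-1, "
                f"beta = {f.beta:.3f} ± {f.sigma_beta:.3f} Gy^-2"
            )
    if ca_dmfs:
        lines += ["", "## Aberration DMFs", ""]
        for (cond, level), r in sorted(ca_dmfs.items()):
            lines.append(
                f"- {cond} at {level} aberrations/cell: "
                f"DMF = {r.dmf:.2f} ± {r.sigma_dmf:.2f}"
            )
    text = "\n".join(lines) + "\n"
    (out_dir / "report.md").write_text(text)
    return text


def run_pipeline(
    config: AnalysisConfig,
    clonogenic_path=None,
    aberrations_path=None,
    out_dir="results",
) -> dict:
    """Run the full analysis: reduce, fit, DMF, metrics, report.

    Either input may be omitted; the corresponding report section is then
    skipped.  Returns a bundle dict mirroring the files written to
    ``out_dir``.  Raises on malformed input before writing anything.
    """
    records = read_clonogenic_csv(clonogenic_path) if clonogenic_path else []
    samples = read_aberrations_csv(aberrations_path) if aberrations_path else []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sv_fits: dict = {}
    sv_dmfs: dict = {}
    ca_fits: dict = {}
    ca_dmfs: dict = {}
    ca_metrics: dict = {}
    if records:
        _, sv_fits, sv_dmfs = _survival_section(records, config, out)
    if samples:
        ca_fits, ca_dmfs, ca_metrics = _aberration_section(samples, config, out)
    report = _report(out, sv_fits, sv_dmfs, ca_fits, ca_dmfs)
    return {
        "survival_fits": sv_fits,
        "survival_dmfs": sv_dmfs,
        "ca_fits": ca_fits,
        "ca_dmfs": ca_dmfs,
        "complex_metrics": ca_metrics,
        "report": report,
    }
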