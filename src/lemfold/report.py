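"""Pipeline orchestration: batch fitting of curve tables, replicate
summaries shaped like the printed parameter tables, population profiles,
and a log of every analysis setting in effect.

Outputs are plain TSV/JSON without timestamps, so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import DenaturationCurve, curves_from_tsv
from .fitting import (
    FitError,
    FitResult,
    ReplicateSummary,
    aggregate_replicates,
    fit_thermal,
    fit_three_state,
    fit_two_state,
    select_model,
)
from .models import (
    Conditions,
    R_KCAL,
    ThreeStateParams,
    celsius_to_kelvin,
    population_profile,
)

__all__ = [
    "CurveSpec",
    "RunConfig",
    "ReportBundle",
    "run_stability_analysis",
    "fit_curve_set",
    "summary_table",
    "write_population_tsv",
]

# report precision: 2 decimals for free energies / m-values / midpoints,
# 1 decimal for melting temperatures
_FMT2 = "{:.2f}"
_FMT1 = "{:.1f}"

_SUMMARY_COLUMNS = {
    "two_state": ["Dm", "m", "dG0"],
    "three_state": [
        "Dm_NI",
        "Dm_NU",
        "dG_NI0",
        "dG_NU0",
        "dG_IU0",
        "m_NI",
        "m_NU",
        "m_IU",
    ],
    "thermal": ["Tm_C", "dH_vH"],
}


@dataclass
class CurveSpec:
    """One curve table to analyze: path + model policy (fixed or 'auto')."""

    path: str
    model: str = "auto"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("two_state", "three_state", "thermal", "auto"):
            raise ValueError(f"unknown model policy {self.model!r}")
        if self.label is None:
            self.label = Path(self.path).stem


@dataclass
class RunConfig:
    """Configuration of a full stability-analysis run."""

    curves: list[CurveSpec]
    out_dir: str = "lemfold_report"
    temperature_c: float = 25.0
    seed: int = 42
    population_step: float = 0.05
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        curves = [CurveSpec(**c) for c in raw.pop("curves")]
        return cls(curves=curves, **raw)

    @property
    def conditions(self) -> Conditions:
        return Conditions(temperature=celsius_to_kelvin(self.temperature_c))


@dataclass
class ReportBundle:
    """In-memory result of a run: per-curve fits, summaries, failures."""

    fits: dict = field(default_factory=dict)  # label -> list[FitResult]
    summaries: dict = field(default_factory=dict)  # label -> ReplicateSummary
    selections: dict = field(default_factory=dict)  # label -> chosen model name
    failures: dict = field(default_factory=dict)  # label -> error message

    @property
    def all_failed(self) -> bool:
        return bool(self.failures) and not self.fits


def _fit_one(curve: DenaturationCurve, model: str, cond: Conditions) -> tuple[FitResult, str]:
    if model == "thermal" or (model == "auto" and curve.is_thermal):
        return fit_thermal(curve), "thermal"
    if model == "two_state":
        return fit_two_state(curve, cond), "two_state"
    if model == "three_state":
        return fit_three_state(curve, cond), "three_state"
    sel = select_model(curve, cond)
    if sel.recommended is None:
        raise FitError(f"model selection failed: {sel.errors}")
    chosen = sel.two_state if sel.recommended == "two_state" else sel.three_state
    return chosen, sel.recommended


def fit_curve_set(
    curves: list[DenaturationCurve], model: str, cond: Conditions
) -> tuple[list[FitResult], str]:
    """Fit every replicate of a curve set under one model policy."""
    results = []
    chosen = None
    for curve in curves:
        result, used = _fit_one(curve, model, cond)
        if chosen is None:
            chosen = used
        elif used != chosen:
            # 'auto' flipped between replicates: refit everything under the
            # majority-free deterministic policy of the first replicate
            result, used = _fit_one(curve, chosen, cond)
        results.append(result)
    return results, chosen


def _fmt(value: float, fmt: str) -> str:
    return fmt.format(value)


def summary_table(summary: ReplicateSummary, label: str) -> pd.DataFrame:
    """Replicate mean +/- SEM, column layout mirroring the parameter tables."""
    cols = _SUMMARY_COLUMNS[summary.model]
    row: dict = {"curve": label, "n": summary.n_replicates}
    for name in cols:
        fmt = _FMT1 if name == "Tm_C" else _FMT2
        mean = _fmt(summary.mean[name], fmt)
        if summary.sem is not None:
            row[name] = f"{mean} ± {_fmt(summary.sem[name], fmt)}"
        else:
            row[name] = f"{mean} ± n/a"
    return pd.DataFrame([row])


def write_population_tsv(
    params: ThreeStateParams,
    path,
    cond: Conditions,
    c_max: float = 6.0,
    step: float = 0.05,
) -> None:
    """Species-fraction profile on a regular grid, argmax of f_I in the header."""
    grid = np.arange(0.0, c_max + step / 2, step)
    profile = population_profile(params, grid, cond)
    with open(path, "w") as fh:
        fh.write(f"# argmax_f_I = {profile.argmax_I:.6g}\n")
        fh.write(f"# max_f_I = {profile.max_f_I:.6g}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _settings_log(cfg: RunConfig) -> dict:
    """Every analysis convention in effect, for the run log."""
    return {
        "lemfold_version": __version__,
        "gas_constant_kcal_per_mol_K": R_KCAL,
        "temperature_C": cfg.temperature_c,
        "seed": cfg.seed,
        "baseline_init_points": 3,
        "multi_start": "8 starts, midpoints at 20/35/50/65/80% of the x-range",
        "three_state_constraint": "dG_NU0 = dG_NI0 + delta, delta >= 0",
        "weighting": "unweighted least squares",
        "uncertainties": "per-fit covariance stderr; replicate SEM = SD/sqrt(n)",
        "thermal_model": "van't Hoff two-state, dCp = 0, linear T-baselines",
        "population_grid_step_M": cfg.population_step,
        "report_precision": "2 decimals (dG, m, Dm), 1 decimal (Tm)",
    }


def run_stability_analysis(cfg: RunConfig) -> ReportBundle:
    """Run the whole pipeline and write the report bundle to cfg.out_dir.

    Per-curve failures are isolated and recorded; the bundle reports
    whether everything failed (the CLI turns that into a nonzero exit).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cond = cfg.conditions
    bundle = ReportBundle()
    fit_rows = []
    summary_frames: dict[str, list[pd.DataFrame]] = {m: [] for m in _SUMMARY_COLUMNS}

    for spec in cfg.curves:
        try:
            curves = curves_from_tsv(spec.path)
            if not curves:
                raise ValueError(f"no curves in {spec.path}")
            results, chosen = fit_curve_set(curves, spec.model, cond)
            summary = aggregate_replicates(results)
            bundle.fits[spec.label] = results
            bundle.summaries[spec.label] = summary
            bundle.selections[spec.label] = chosen
            for r in results:
                row = {"curve": spec.label}
                row.update(r.to_dict())
                fit_rows.append(row)
            summary_frames[summary.model].append(summary_table(summary, spec.label))
            if chosen == "three_state":
                mean_params = ThreeStateParams(
                    dG_NI0=summary.mean["dG_NI0"],
                    m_NI=summary.mean["m_NI"],
                    dG_NU0=summary.mean["dG_NU0"],
                    m_NU=summary.mean["m_NU"],
                )
                write_population_tsv(
                    mean_params,
                    out / f"populations_{spec.label}.tsv",
                    cond,
                    c_max=float(max(c.x.max() for c in curves)),
                    step=cfg.population_step,
                )
        except (FitError, ValueError, OSError) as exc:
            bundle.failures[spec.label] = str(exc)

    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "fits.tsv", sep="\t", index=False)
    for model, frames in summary_frames.items():
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"summary_{model}.tsv", sep="\t", index=False
            )
    (out / "settings.json").write_text(json.dumps(_settings_log(cfg), indent=2) + "\n")
    (out / "failures.json").write_text(json.dumps(bundle.failures, indent=2) + "\n")
    return bundle
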