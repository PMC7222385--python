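"""CSV schemas, the end-to-end pipeline and the structured report.

Kinetics CSV schema (comma-separated, UTF-8, header mandatory, dot decimal,
times always in seconds):

    condition, response, temperature_C, time_s, yield_pct
    # or, instead of yield_pct:
    condition, response, temperature_C, time_s, concentration, c_max

Rows at t = 0 are accepted (and excluded from MRE computation downstream).
Equilibrium yields are derived from each curve's terminal-time rows unless
the optional column ``equilibrium_yield_pct`` supplies them.

Calorimetry CSV schema: columns ``time_s, temperature_C``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .equilibrium import equilibrium_yield, extraction_yield, ConcentrationRecord
from .evaluation import mean_relative_error, round_half_up, summarize_mre
from .kinetics import ExtractionCurve, KineticsDataset
from .model import FitConfig, WeibullArrheniusResults, fit_weibull_arrhenius

logger = logging.getLogger("sonoextract")

__all__ = [
    "RunConfig",
    "StructuredReport",
    "load_kinetics_csv",
    "write_kinetics_csv",
    "dataset_from_frame",
    "datasets_from_frame",
    "dataset_to_frame",
    "load_calorimetry_csv",
    "run_pipeline",
]

_KINETICS_KEY = ["condition", "response", "temperature_C", "time_s"]


def dataset_to_frame(dataset: KineticsDataset) -> pd.DataFrame:
    """Long-format DataFrame view of a dataset (the CSV schema)."""
    rows = []
    for curve in dataset.curves:
        for t, y in zip(curve.times, curve.yields):
            rows.append(
                {
                    "condition": curve.condition,
                    "response": curve.response,
                    "temperature_C": curve.temperature_C,
                    "time_s": t,
                    "yield_pct": y,
                    "equilibrium_yield_pct": curve.equilibrium_yield,
                }
            )
    return pd.DataFrame(rows)


def write_kinetics_csv(
    datasets: KineticsDataset | Iterable[KineticsDataset], path: str | Path
) -> None:
    if isinstance(datasets, KineticsDataset):
        datasets = [datasets]
    frame = pd.concat([dataset_to_frame(d) for d in datasets], ignore_index=True)
    frame.to_csv(path, index=False)


def _yields_from_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Ensure a ``yield_pct`` column, converting concentrations if needed."""
    frame = frame.copy()
    if "yield_pct" in frame.columns:
        return frame
    if {"concentration", "c_max"}.issubset(frame.columns):
        frame["yield_pct"] = [
            extraction_yield(
                ConcentrationRecord(
                    response=str(r.response),
                    concentration=float(r.concentration),
                    c_max=float(r.c_max),
                    time_s=float(r.time_s),
                    temperature_C=float(r.temperature_C),
                    condition=str(r.condition),
                )
            )
            for r in frame.itertuples()
        ]
        return frame
    raise ValueError(
        "need a yield_pct column or concentration + c_max columns"
    )


def datasets_from_frame(frame: pd.DataFrame) -> list[KineticsDataset]:
    """Group a long-format frame into one dataset per (condition, response)."""
    missing = [c for c in _KINETICS_KEY if c not in frame.columns]
    if missing:
        raise ValueError(f"kinetics table is missing columns: {missing}")
    for col in ("temperature_C", "time_s"):
        bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col} in rows {list(bad.index[:5])}"
            )
    frame = _yields_from_columns(frame)
    datasets = []
    for (cond, resp), sub in frame.groupby(["condition", "response"], sort=True):
        curves = []
        for T, curve_rows in sub.groupby("temperature_C", sort=True):
            curve_rows = curve_rows.sort_values("time_s")
            times = curve_rows["time_s"].to_numpy(float)
            yields = curve_rows["yield_pct"].to_numpy(float)
            if "equilibrium_yield_pct" in curve_rows.columns:
                y_eq = float(curve_rows["equilibrium_yield_pct"].iloc[-1])
            else:
                y_eq = equilibrium_yield(times, yields)
                logger.info(
                    "derived Y_eq=%.2f%% for %s/%s at %g degC from the "
                    "terminal sampling time",
                    y_eq, cond, resp, T,
                )
            curves.append(
                ExtractionCurve(
                    condition=str(cond),
                    response=str(resp),
                    temperature_C=float(T),
                    times=tuple(times),
                    yields=tuple(yields),
                    equilibrium_yield=y_eq,
                )
            )
        datasets.append(KineticsDataset(tuple(curves)))
    return datasets


def dataset_from_frame(frame: pd.DataFrame) -> KineticsDataset:
    """Single-dataset variant; the frame must hold one condition/response."""
    datasets = datasets_from_frame(frame)
    if len(datasets) != 1:
        keys = [(d.condition, d.response) for d in datasets]
        raise ValueError(
            f"expected one (condition, response) group, found {keys}"
        )
    return datasets[0]


def load_kinetics_csv(path: str | Path) -> list[KineticsDataset]:
    """Load and validate extraction curves from the kinetics CSV schema."""
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    return datasets_from_frame(frame)


def load_calorimetry_csv(path: str | Path):
    """Load a calorimetry trace CSV with columns time_s, temperature_C."""
    from .calorimetry import CalorimetryTrace

    frame = pd.read_csv(path)
    missing = [c for c in ("time_s", "temperature_C") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return CalorimetryTrace(
        tuple(frame["time_s"].astype(float)),
        tuple(frame["temperature_C"].astype(float)),
        probe_id=str(path),
    )


@dataclass(frozen=True)
class RunConfig:
    """Settings for :func:`run_pipeline`."""

    input_path: str | Path
    output_dir: str | Path
    conditions: tuple[str, ...] | None = None
    responses: tuple[str, ...] | None = None
    fit: FitConfig = dataclass_field(default_factory=FitConfig)
    report_name: str = "report"


@dataclass
class StructuredReport:
    """Machine-readable pipeline output mirroring the usual results tables."""

    fits: dict[str, dict]
    mre: dict[str, float]
    seed: int
    version: str = __version__
    failures: list[str] = dataclass_field(default_factory=list)

    def to_dict(self) -> dict:
        mean, sd = (
            summarize_mre(list(self.mre.values())) if self.mre else (np.nan, np.nan)
        )
        return {
            "version": self.version,
            "seed": self.seed,
            "fits": self.fits,
            "mre_percent": self.mre,
            "mre_overall": {
                "mean": round_half_up(mean) if self.mre else None,
                "sd": round_half_up(sd) if self.mre else None,
            },
            "failures": self.failures,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @property
    def ok(self) -> bool:
        return not self.failures


def _fit_record(res: WeibullArrheniusResults) -> dict:
    ci = res.conf_int(0.95)
    names = res.param_names
    est = [res.params.alpha0, res.params.Ea, res.params.beta]
    units = {"alpha0": "s", "Ea": "J/mol", "beta": "1"}
    return {
        "params": {
            n: {
                "estimate": float(e),
                "std_err": float(se),
                "ci95_low": float(lo),
                "ci95_high": float(hi),
                "unit": units[n],
            }
            for n, e, se, (lo, hi) in zip(names, est, res.bse, ci)
        },
        "rss": float(res.ssr),
        "n_obs": int(res.nobs),
        "dof": int(res.df_resid),
        "converged": bool(res.converged),
        "mre_percent": float(res.mre()),
    }


def run_pipeline(config: RunConfig) -> StructuredReport:
    """Fit every selected dataset, evaluate MRE and write the report.

    Writes ``<report_name>.json`` (machine-readable) and
    ``<report_name>.txt`` (the summary tables) into ``output_dir``.
    Non-converged fits are recorded under ``failures`` rather than raised.
    """
    datasets = load_kinetics_csv(config.input_path)
    if config.conditions is not None:
        datasets = [d for d in datasets if d.condition in config.conditions]
    if config.responses is not None:
        datasets = [d for d in datasets if d.response in config.responses]
    if not datasets:
        logger.info("selection matched no datasets; writing an empty report")

    report = StructuredReport(fits={}, mre={}, seed=config.fit.seed)
    summaries = []
    for ds in datasets:
        key = f"{ds.condition}/{ds.response}"
        try:
            res = fit_weibull_arrhenius(ds, config.fit)
        except Exception as exc:  # keep going; report partial results
            logger.error("fit failed for %s: %s", key, exc)
            report.failures.append(f"{key}: {exc}")
            continue
        if not res.converged:
            report.failures.append(f"{key}: optimiser did not converge")
        report.fits[key] = _fit_record(res)
        report.mre[key] = float(res.mre())
        summaries.append(res.summary())

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / f"{config.report_name}.json")
    (out / f"{config.report_name}.txt").write_text(
        "\n\n".join(summaries) if summaries else "no datasets selected\n"
    )
    return report


def mre_against_fit(
    dataset: KineticsDataset, res: WeibullArrheniusResults
) -> float:
    """MRE of observed yields against the fitted model, t = 0 excluded."""
    y_obs, y_fit = [], []
    for curve in dataset.curves:
        pred = res.predict(curve.times, curve.temperature_C, curve.equilibrium_yield)
        keep = curve.times_array() > 0
        y_obs.append(curve.yields_array()[keep])
        y_fit.append(pred[keep])
    return mean_relative_error(np.concatenate(y_obs), np.concatenate(y_fit))
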