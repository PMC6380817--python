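"""CSV/JSON readers and writers, run configuration, and the pipeline runner.

The pipeline mirrors the study workflow: fit a basic GM(1,1) on a fixed
calendar window, optionally roll it forward metabolically or correct it with
the Markov ratio-state layer, then emit a fitted/forecast table (CSV), a
model summary (JSON) and, for hybrid runs, the state and transition tables.
All numeric CSV output is formatted at 4 decimal places so identical
configurations produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import diagnostics, markov, metabolic
from .exceptions import ConfigError, ParseError
from .grey_core import GM11Model, ObservedSeries, fit_gm11, forecast, prediction_length_class
from .synthetic_data import GeneratorConfig, generate

__all__ = ["RunConfig", "read_series", "write_series", "run_pipeline", "simulate_to_csv"]

log = logging.getLogger("greymarkov")

_FMT = "%.4f"  # stable CSV number formatting


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input: str | Path | None = None
    window_start: int | None = None
    window_end: int | None = None
    model: Literal["gm11", "metabolic", "hybrid"] = "gm11"
    n_states: int = 3
    partition_method: Literal["equal_width", "custom"] = "equal_width"
    custom_boundaries: tuple[float, ...] | None = None
    metabolic_steps: int = 3
    metabolic_source: Literal["forecast", "actual"] = "forecast"
    horizon: int = 1
    alpha: float = 0.05
    small_error_constant: float = diagnostics.DEFAULT_SMALL_ERROR_CONSTANT
    m_step_method: Literal["power", "empirical"] = "power"
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ConfigError("forecast horizon must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.model not in ("gm11", "metabolic", "hybrid"):
            raise ConfigError(f"unknown model '{self.model}'")
        if self.partition_method == "custom" and self.custom_boundaries is None:
            raise ConfigError("custom partition requires custom_boundaries")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def read_series(path: str | Path) -> ObservedSeries:
    """Read a `year,value` CSV into an :class:`ObservedSeries`.

    Raises :class:`ParseError` naming the offending row for missing headers,
    non-numeric fields or non-positive values.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pandas raises several types for bad files
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc
    if list(frame.columns[:2]) != ["year", "value"]:
        raise ParseError(f"{path}: expected header 'year,value', got {list(frame.columns)}")
    years = pd.to_numeric(frame["year"], errors="coerce")
    values = pd.to_numeric(frame["value"], errors="coerce")
    for idx in frame.index:
        row = idx + 2  # 1-based, after header
        if pd.isna(years[idx]) or years[idx] != int(years[idx]):
            raise ParseError(f"{path}: row {row}: year '{frame['year'][idx]}' is not an integer")
        if pd.isna(values[idx]):
            raise ParseError(f"{path}: row {row}: value '{frame['value'][idx]}' is not numeric")
        if values[idx] <= 0:
            raise ParseError(f"{path}: row {row}: value {values[idx]} is not positive")
    return ObservedSeries(years.to_numpy(dtype=int), values.to_numpy(dtype=float))


def write_series(series: ObservedSeries, path: str | Path) -> None:
    pd.DataFrame({"year": series.labels, "value": series.values}).to_csv(
        path, index=False, float_format=_FMT
    )


def simulate_to_csv(config: GeneratorConfig, path: str | Path, truth_path: str | Path | None = None) -> ObservedSeries:
    """Write a simulated series; optionally a sidecar truth file (trend, state)."""
    series, trend, states = generate(config)
    write_series(series, path)
    if truth_path is not None:
        pd.DataFrame(
            {"year": series.labels, "trend": trend, "state": states + 1}
        ).to_csv(truth_path, index=False, float_format=_FMT)
    return series


def _select_window(series: ObservedSeries, config: RunConfig) -> ObservedSeries:
    start = config.window_start if config.window_start is not None else int(series.labels[0])
    end = config.window_end if config.window_end is not None else int(series.labels[-1])
    if start < series.labels[0] or end > series.labels[-1] or start >= end:
        raise ConfigError(
            f"window {start}-{end} outside input range "
            f"{series.labels[0]}-{series.labels[-1]}"
        )
    return series.window(start, end)


def _fitted_table(model: GM11Model, states: np.ndarray | None, labels: Sequence[str] | None) -> pd.DataFrame:
    rel = diagnostics.relative_errors(model.actual, model.fitted)
    table = pd.DataFrame(
        {
            "year": model.window_labels,
            "actual": model.actual,
            "fitted": model.fitted,
            "relative_error_pct": 100.0 * rel,
            "state": "",
        }
    )
    if states is not None and labels is not None:
        table["state"] = [labels[s] for s in states]
    return table


def _log_defaults(config: RunConfig) -> None:
    log.info(
        "defaults in effect: sd convention=population, small-error constant=%s, "
        "partition method=%s, m-step method=%s, alpha=%s",
        config.small_error_constant,
        config.partition_method,
        config.m_step_method,
        config.alpha,
    )


def run_pipeline(config: RunConfig, series: ObservedSeries | None = None) -> dict:
    """Execute the configured model chain; return results and write files.

    Returns a dict with keys ``model`` (the final fitted GM11Model),
    ``report`` (FitReport over the final window, hybrid-corrected for hybrid
    runs), ``fitted_table``, ``forecast_table`` and, per model kind, the
    chain or Markov artefacts.  If ``config.outdir`` is set the tables are
    written as CSV and the summary as JSON.
    """
    _log_defaults(config)
    if series is None:
        if config.input is None:
            raise ConfigError("either an input path or an in-memory series is required")
        series = read_series(config.input)
    window = _select_window(series, config)

    results: dict = {"config": config}
    base = fit_gm11(window)
    final = base
    states = state_labels = None

    if config.model == "metabolic":
        chain = metabolic.metabolic_chain(
            series,
            window=window.n,
            n_steps=config.metabolic_steps,
            source=config.metabolic_source,
        )
        final = chain.final_model
        results["chain"] = chain
        results["chain_table"] = pd.DataFrame(
            [
                {
                    "step": i,
                    "window_start": int(m.window_labels[0]),
                    "window_end": int(m.window_labels[-1]),
                    "a": m.a,
                    "u": m.u,
                    "appended_value": np.nan if i == 0 else chain.steps[i - 1].appended_value,
                    "source": "" if i == 0 else chain.steps[i - 1].source,
                    "fitting_are": diagnostics.average_relative_error(m.actual, m.fitted),
                }
                for i, m in enumerate(chain.models)
            ]
        )

    fitted_for_report = final.fitted
    if config.model == "hybrid":
        ratios = markov.ratio_series(base)
        partition = markov.partition_states(
            ratios,
            n_states=config.n_states,
            method=config.partition_method,
            custom_boundaries=config.custom_boundaries,
        )
        states = markov.assign_states(ratios, partition)
        transitions = markov.estimate_transitions(
            states, n_states=partition.n_states, m_step_method=config.m_step_method
        )
        test = markov.markov_property_test(states, alpha=config.alpha, n_states=partition.n_states)
        n_recent = min(3, len(states))
        recent = [(int(states[-1 - i]), i + 1) for i in range(n_recent)]
        state_fc = markov.forecast_state(transitions, recent)
        state_labels = partition.labels
        results.update(
            partition=partition,
            states=states,
            transitions=transitions,
            markov_test=test,
            state_forecast=state_fc,
        )
        results["state_forecast_table"] = pd.DataFrame(
            [
                {
                    "source_year": int(base.window_labels[-m]),
                    "source_state": state_labels[s],
                    "transfer_step": m,
                    **{state_labels[j]: row[j] for j in range(partition.n_states)},
                }
                for s, m, row in state_fc.sources
            ]
        )
        fitted_for_report = markov.hybrid_fitted(base, partition, states)

    report = diagnostics.fit_report(
        final.actual, fitted_for_report, c=config.small_error_constant
    )
    results["model"] = final
    results["report"] = report
    results["fitted_table"] = _fitted_table(final, states, state_labels)
    if config.model == "hybrid":
        results["fitted_table"]["fitted"] = fitted_for_report
        results["fitted_table"]["relative_error_pct"] = 100.0 * report.relative_errors

    if config.horizon > 0:
        grey_fc = forecast(final, config.horizon)
        fc_years = final.window_labels[-1] + 1 + np.arange(config.horizon)
        fc_table = pd.DataFrame({"year": fc_years, "forecast": grey_fc})
        if config.model == "hybrid":
            interval = results["partition"].intervals[results["state_forecast"].predicted_state]
            fc_table["revised"] = [
                markov.revise_forecast(float(v), interval) for v in grey_fc
            ]
        results["forecast_table"] = fc_table

    summary = {
        **final.to_dict(),
        **report.to_dict(),
        "model_kind": config.model,
        "class": prediction_length_class(final.a),
        "sd_convention": "population",
        "partition_method": config.partition_method,
        "m_step_method": config.m_step_method,
    }
    if config.model == "hybrid":
        summary["markov_statistic"] = results["markov_test"].statistic
        summary["markov_suitable"] = bool(results["markov_test"].markov_suitable)
        summary["predicted_state"] = state_labels[results["state_forecast"].predicted_state]
    results["summary"] = summary

    if config.outdir is not None:
        _write_outputs(results, Path(config.outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["fitted_table"].to_csv(outdir / "fitted.csv", index=False, float_format=_FMT)
    if "forecast_table" in results:
        results["forecast_table"].to_csv(outdir / "forecast.csv", index=False, float_format=_FMT)
    if "chain_table" in results:
        results["chain_table"].to_csv(outdir / "chain.csv", index=False, float_format=_FMT)
    if "transitions" in results:
        tm = results["transitions"]
        payload = {
            "boundaries": [round(float(b), 6) for b in results["partition"].boundaries],
            "P1": np.round(tm.P1, 6).tolist(),
            "P2": np.round(tm.m_step(2), 6).tolist(),
            "P3": np.round(tm.m_step(3), 6).tolist(),
            "marginals": np.round(tm.marginals, 6).tolist(),
            "markov_test": results["markov_test"]._asdict(),
        }
        (outdir / "transitions.json").write_text(json.dumps(payload, indent=2) + "\n")
        results["state_forecast_table"].to_csv(
            outdir / "state_forecast.csv", index=False, float_format=_FMT
        )
    summary = {
        k: (round(v, 10) if isinstance(v, float) else v)
        for k, v in results["summary"].items()
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
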