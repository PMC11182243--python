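"""Pipeline orchestration and structured run reports.

``run_pipeline`` chains the full analysis — simulate (or accept existing
summaries), baseline-subtract, summarize, two-way ANOVA per channel,
Monte Carlo spurious-trend sweep, sensor-limit flags — and returns a
:class:`RunReport` whose rendered body is byte-identical across runs with
the same seed (timestamps live only in the provenance sidecar).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import AnovaModel, AnovaTable, anova_from_summary, anova_two_way
from .core_io import (
    CellSummary,
    Channel,
    DeltaRecord,
    DesignConfig,
    MeasurementRecord,
    ValidationError,
    write_deltas,
    write_measurements,
    write_summaries,
)
from .monte_carlo import MCConfig, MonteCarloResult, mc_spurious_trend
from .sensor_limits import SensorSpec, flag_below_accuracy
from .summary_stats import compute_deltas, format_table, summarize_cells
from .synthetic_data import NoiseModel, generate_experiment, table1_noise_model

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_run_config", "write_report"]

logger = logging.getLogger("puffnull")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; defaults are the study conditions."""

    design: DesignConfig = field(default_factory=DesignConfig)
    noise: NoiseModel = field(default_factory=table1_noise_model)
    mc: MCConfig = field(default_factory=MCConfig)
    sensor: SensorSpec = field(default_factory=SensorSpec)
    seed: int = 0
    anova_model: AnovaModel = AnovaModel.MAIN_EFFECTS


@dataclass(frozen=True)
class RunReport:
    config: RunConfig
    measurements: tuple[MeasurementRecord, ...]
    deltas: tuple[DeltaRecord, ...]
    summaries: tuple[CellSummary, ...]
    anova_tables: dict[Channel, AnovaTable]
    mc_results: tuple[MonteCarloResult, ...]
    sensor_flags: tuple[tuple[CellSummary, bool], ...]
    provenance: dict

    def body(self) -> str:
        """Deterministic human-readable report (no timestamps)."""
        lines = [
            "puffnull run report",
            "===================",
            f"seed: {self.config.seed}",
            f"records: {len(self.measurements)}  deltas: {len(self.deltas)}  "
            f"summary cells: {len(self.summaries)}",
            "",
            format_table(self.summaries),
        ]
        for ch in Channel:
            lines.append(str(self.anova_tables[ch]))
            lines.append("")
        lines.append(
            "Monte Carlo spurious positive-trend probability per (location, channel):"
        )
        lines.append(
            f"{'location':<16}{'channel':<8}{'criterion':<28}"
            f"{'p_hat':>8}{'mc_se':>8}"
        )
        for r in self.mc_results:
            lines.append(
                f"{r.location.value:<16}{r.channel.value:<8}{r.criterion.value:<28}"
                f"{r.p_hat:>8.4f}{r.mc_se:>8.4f}"
            )
        lines.append("")
        n_flagged = sum(flag for _, flag in self.sensor_flags)
        lines.append(
            f"Sensor-limit flags: {n_flagged}/{len(self.sensor_flags)} cells have "
            "|mean dPM| below the instrument's nominal accuracy band"
        )
        return "\n".join(lines) + "\n"


def _mc_sweep_from_summaries(
    summaries: Sequence[CellSummary], config: MCConfig
) -> list[MonteCarloResult]:
    """One Monte Carlo run per (location, channel) present in the
    summaries, with substream seeds derived in canonical order."""
    combos = sorted(
        {(s.location, s.channel) for s in summaries},
        key=lambda c: (c[0].value, c[1].value),
    )
    children = np.random.SeedSequence(config.seed).spawn(len(combos))
    results = []
    for (loc, ch), ss in zip(combos, children):
        cells = [s for s in summaries if s.location is loc and s.channel is ch]
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        results.append(mc_spurious_trend(cells, replace(config, seed=sub_seed)))
    return results


def run_pipeline(
    config: RunConfig | None = None,
    summaries: Sequence[CellSummary] | None = None,
) -> RunReport:
    """Execute the full pipeline.

    With ``summaries`` given (summary-input mode) the simulation and
    baseline-subtraction stages are skipped: ANOVA uses the
    summary-statistics path and the Monte Carlo sweep draws from the given
    cells — this is how the study's printed table is analysed directly.
    """
    config = config or RunConfig()
    try:
        if summaries is None:
            logger.info("stage simulate: generating synthetic experiment")
            measurements = tuple(
                generate_experiment(config.design, config.noise, config.seed)
            )
            logger.info("stage deltas: baseline subtraction")
            deltas = tuple(compute_deltas(measurements))
            logger.info("stage summarize: per-cell statistics")
            cell_summaries = tuple(summarize_cells(deltas))
            logger.info("stage anova: both channels")
            anova_tables = {
                ch: anova_two_way(deltas, ch, config.anova_model) for ch in Channel
            }
        else:
            logger.info("stage summarize: using provided cell summaries")
            measurements = ()
            deltas = ()
            cell_summaries = tuple(summaries)
            logger.info("stage anova: summary-statistics path, both channels")
            anova_tables = {
                ch: anova_from_summary(cell_summaries, ch, config.anova_model)
                for ch in Channel
            }
        logger.info("stage monte_carlo: spurious-trend sweep")
        mc_results = tuple(
            _mc_sweep_from_summaries(cell_summaries, replace(config.mc, seed=config.seed))
        )
        logger.info("stage sensor_limits: accuracy flags")
        flags = tuple(flag_below_accuracy(cell_summaries, config.sensor))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    provenance = {
        "seed": config.seed,
        "package_version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    return RunReport(
        config=config,
        measurements=measurements,
        deltas=deltas,
        summaries=cell_summaries,
        anova_tables=anova_tables,
        mc_results=mc_results,
        sensor_flags=flags,
        provenance=provenance,
    )


def write_report(report: RunReport, outdir: str | Path) -> Path:
    """Write the CSV bundle + text report; returns the output directory.

    ``report.txt`` is byte-identical for identical seeds; timestamps are
    confined to ``provenance.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if report.measurements:
        write_measurements(report.measurements, outdir / "measurements.csv")
    if report.deltas:
        write_deltas(report.deltas, outdir / "deltas.csv")
    write_summaries(report.summaries, outdir / "summaries.csv")
    for ch, table in report.anova_tables.items():
        pd.DataFrame(
            [
                {"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms,
                 "f": r.f, "p": r.p}
                for r in table.rows
            ]
        ).to_csv(outdir / f"anova_{ch.value}.csv", index=False)
    pd.DataFrame(
        [
            {
                "location": r.location.value,
                "channel": r.channel.value,
                "criterion": r.criterion.value,
                "p_hat": r.p_hat,
                "mc_se": r.mc_se,
                "n_replicates": r.n_replicates,
                "samples_per_cell": r.samples_per_cell,
                "draw_scale": r.draw_scale.value,
                "seed": r.seed,
            }
            for r in report.mc_results
        ]
    ).to_csv(outdir / "mc_results.csv", index=False)
    pd.DataFrame(
        [
            {
                "iop_mmHg": s.iop,
                "location": s.location.value,
                "channel": s.channel.value,
                "mean_ugm3": s.mean,
                "below_accuracy": flag,
            }
            for s, flag in report.sensor_flags
        ]
    ).to_csv(outdir / "sensor_flags.csv", index=False)
    (outdir / "report.txt").write_text(report.body())
    (outdir / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
    return outdir


# ---------------------------------------------------------------------------
# flat key-value run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "iop_levels", "tests_per_cell", "baseline_mean", "baseline_sd",
    "n_replicates", "samples_per_cell", "criterion", "draw_scale", "alpha",
    "accuracy_pm25", "accuracy_pm10", "update_interval", "resolution",
    "anova_model",
}


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat key-value (YAML mapping) config file.

    Recognised keys mirror the design, noise, Monte Carlo and sensor
    dataclass fields; unknown keys are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")

    design = DesignConfig(
        iop_levels=tuple(raw.get("iop_levels", (6, 13, 43))),
        tests_per_cell=int(raw.get("tests_per_cell", 4)),
    )
    noise = table1_noise_model(
        baseline_mean=float(raw.get("baseline_mean", 2.0)),
        baseline_sd=float(raw.get("baseline_sd", 0.3)),
    )
    mc = MCConfig(
        n_replicates=int(raw.get("n_replicates", 10_000)),
        samples_per_cell=int(raw.get("samples_per_cell", 4)),
        criterion=raw.get("criterion", "slope_positive"),
        alpha=float(raw.get("alpha", 0.05)),
        draw_scale=raw.get("draw_scale", "sd"),
    )
    sensor = SensorSpec(
        accuracy_pm25=float(raw.get("accuracy_pm25", 10.0)),
        accuracy_pm10=float(raw.get("accuracy_pm10", 15.0)),
        update_interval=float(raw.get("update_interval", 3.0)),
        resolution=float(raw.get("resolution", 0.1)),
    )
    return RunConfig(
        design=design,
        noise=noise,
        mc=mc,
        sensor=sensor,
        seed=int(raw.get("seed", 0)),
        anova_model=AnovaModel(raw.get("anova_model", "main_effects")),
    )
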