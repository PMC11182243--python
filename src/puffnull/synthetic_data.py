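"""Synthetic measurement generator.

Emulates the phantom tonometry experiment: for every cell of the design
(IOP level × sensor location), repeated tests each produce a baseline AQI
reading and a during-puff reading.  The phantoms are inert, so there is no
true aerosol signal; the during reading differs from its baseline only by
Gaussian sensor noise whose per-cell mean and SD are taken from the study's
ΔPM results table.  The delta — not the raw pair — carries the cell
statistics, because the study reports only delta means/SDs; baselines get
independent small jitter around a low ambient level so they are
non-degenerate.

Raw readings are clipped at zero (a mass concentration cannot be negative);
deltas are not clipped (the results table contains negative cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    Channel,
    DesignConfig,
    Location,
    MeasurementRecord,
    ValidationError,
)

__all__ = [
    "CellNoise",
    "NoiseModel",
    "table1_noise_model",
    "generate_experiment",
    "phantom_calibration",
    "calibration_agreement",
]

# Ambient baseline level: the study reports readings "consistently around
# 1-3 µg/m³"; 2.0 is the midpoint.  Baseline spread is not reported; 0.3
# µg/m³ keeps baselines non-degenerate without dominating the deltas.
DEFAULT_BASELINE_MEAN = 2.0
DEFAULT_BASELINE_SD = 0.3

# Per-cell ΔPM mean ± sample SD (µg/m³, n=4 tests each) as printed in the
# study's results table: {channel: {location: {iop: (mean, sd)}}}.
TABLE1_DELTA_STATS: dict[Channel, dict[Location, dict[float, tuple[float, float]]]] = {
    Channel.PM25: {
        Location.UPPER_SAME: {6.0: (0.0, 0.4), 13.0: (-0.1, 0.1), 43.0: (0.0, 0.3)},
        Location.LOWER_SAME: {6.0: (0.1, 0.4), 13.0: (0.2, 0.3), 43.0: (0.1, 0.2)},
        Location.UPPER_OPPOSITE: {6.0: (0.0, 0.2), 13.0: (-0.3, 0.3), 43.0: (0.1, 0.3)},
        Location.LOWER_OPPOSITE: {6.0: (0.1, 0.2), 13.0: (-0.1, 0.2), 43.0: (0.1, 0.2)},
    },
    Channel.PM10: {
        Location.UPPER_SAME: {6.0: (0.2, 0.7), 13.0: (0.1, 0.1), 43.0: (0.4, 0.4)},
        Location.LOWER_SAME: {6.0: (0.2, 0.6), 13.0: (0.2, 0.4), 43.0: (0.5, 0.3)},
        Location.UPPER_OPPOSITE: {6.0: (-0.2, 0.4), 13.0: (-0.7, 0.3), 43.0: (0.2, 0.5)},
        Location.LOWER_OPPOSITE: {6.0: (0.1, 0.3), 13.0: (0.1, 0.3), 43.0: (0.1, 0.2)},
    },
}

# Phantom calibration: mean ± SD of corneal-compensated IOP (IOPcc, mmHg)
# over 36 tonometer tests per phantom vs the manufacturer-assigned value.
PHANTOM_CALIBRATION: dict[str, dict[str, float]] = {
    "Blue": {"iopcc_mean": 5.9, "iopcc_sd": 0.4, "nominal_iop": 6.0, "n": 36},
    "White": {"iopcc_mean": 11.5, "iopcc_sd": 0.4, "nominal_iop": 13.0, "n": 36},
    "Red": {"iopcc_mean": 43.0, "iopcc_sd": 0.6, "nominal_iop": 43.0, "n": 36},
}


@dataclass(frozen=True)
class CellNoise:
    """Noise parameters for one (IOP, location, channel) cell, µg/m³."""

    baseline_mean: float
    delta_mean: float
    delta_sd: float

    def __post_init__(self) -> None:
        if self.delta_sd < 0:
            raise ValidationError(f"delta_sd must be >= 0, got {self.delta_sd}")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian sensor-noise model over all design cells.

    ``cell_params`` maps (iop, location, channel) → :class:`CellNoise`.
    ``baseline_sd`` is shared: the study never reports baseline variance.
    """

    cell_params: dict[tuple[float, Location, Channel], CellNoise]
    baseline_sd: float = DEFAULT_BASELINE_SD
    seed: int = 0

    def cell(self, iop: float, location: Location, channel: Channel) -> CellNoise:
        key = (float(iop), Location(location), Channel(channel))
        try:
            return self.cell_params[key]
        except KeyError:
            raise ValidationError(f"no noise parameters for cell {key}") from None


def table1_noise_model(
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    baseline_sd: float = DEFAULT_BASELINE_SD,
) -> NoiseModel:
    """The packaged noise fixture: 12 cells × 2 channels with the study's
    printed ΔPM means/SDs and a flat ambient baseline."""
    params = {
        (iop, loc, ch): CellNoise(baseline_mean, mean, sd)
        for ch, by_loc in TABLE1_DELTA_STATS.items()
        for loc, by_iop in by_loc.items()
        for iop, (mean, sd) in by_iop.items()
    }
    return NoiseModel(cell_params=params, baseline_sd=baseline_sd)


def _cell_rngs(
    design: DesignConfig, seed: int
) -> dict[tuple[float, Location], np.random.Generator]:
    """One substream per (iop, location) cell, derived from the master seed
    in canonical cell order so generation order cannot affect draws."""
    cells = [(iop, loc) for iop in design.iop_levels for loc in design.locations]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    return {cell: np.random.default_rng(ss) for cell, ss in zip(cells, children)}


def generate_experiment(
    design: DesignConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[MeasurementRecord]:
    """Simulate a complete experiment.

    For each test, both channels share one baseline draw
    ``max(0, N(baseline_mean, baseline_sd))`` per channel, and the during
    reading is ``max(0, baseline + N(delta_mean, delta_sd))`` with the
    channel's cell parameters.  Deterministic for a given ``seed``.

    Defaults reproduce the study conditions: 3 phantoms × 4 locations × 4
    tests × 2 phases = 96 records with the printed-table noise model.
    """
    design = design or DesignConfig()
    noise = noise or table1_noise_model()

    # fail fast if any design cell lacks parameters
    for iop in design.iop_levels:
        for loc in design.locations:
            for ch in Channel:
                noise.cell(iop, loc, ch)

    rngs = _cell_rngs(design, seed)
    records: list[MeasurementRecord] = []
    for iop in design.iop_levels:
        phantom = design.phantom_id(iop)
        for loc in design.locations:
            rng = rngs[(iop, loc)]
            n = design.tests_per_cell
            base = {}
            delta = {}
            for ch in Channel:
                p = noise.cell(iop, loc, ch)
                base[ch] = np.clip(
                    rng.normal(p.baseline_mean, noise.baseline_sd, size=n), 0.0, None
                )
                delta[ch] = rng.normal(p.delta_mean, p.delta_sd, size=n)
            during = {
                ch: np.clip(base[ch] + delta[ch], 0.0, None) for ch in Channel
            }
            for t in range(n):
                records.append(
                    MeasurementRecord(
                        phantom, iop, loc, t + 1, "baseline",
                        float(base[Channel.PM25][t]), float(base[Channel.PM10][t]),
                    )
                )
                records.append(
                    MeasurementRecord(
                        phantom, iop, loc, t + 1, "during",
                        float(during[Channel.PM25][t]), float(during[Channel.PM10][t]),
                    )
                )
    return records


def phantom_calibration() -> dict[str, dict[str, float]]:
    """The packaged phantom calibration fixture (IOPcc vs nominal IOP)."""
    return {k: dict(v) for k, v in PHANTOM_CALIBRATION.items()}


def calibration_agreement(tolerance_mmhg: float = 2.0) -> bool:
    """Simple agreement check: measured IOPcc preserves the nominal ordering
    and every phantom's mean IOPcc is within ``tolerance_mmhg`` of nominal."""
    cal = phantom_calibration()
    pairs = sorted(
        (v["nominal_iop"], v["iopcc_mean"]) for v in cal.values()
    )
    measured = [m for _, m in pairs]
    ordered = all(a < b for a, b in zip(measured, measured[1:]))
    close = all(abs(n - m) <= tolerance_mmhg for n, m in pairs)
    return ordered and close
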