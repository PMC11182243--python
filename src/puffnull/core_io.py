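"""Shared domain types and table I/O.

The experiment this package models is a negative control for aerosol
detection during noncontact tonometry (NCT): an air-quality indicator (AQI)
reports PM2.5/PM10 mass concentrations before (``baseline``) and during
(``during``) an NCT air puff fired at inert rubber corneal phantoms that
mimic intraocular pressures (IOP) of 6, 13 and 43 mmHg.  The phantoms have
no liquid component, so the true aerosol signal is zero by construction and
any IOP- or location-dependent structure in the readings is a sensor
artifact.

Data flow through the pipeline as long-format tables: one AQI reading per
row (:class:`MeasurementRecord`), one baseline-subtracted change per test
(:class:`DeltaRecord`), and one per-cell mean/SD summary
(:class:`CellSummary`) in the layout of the study's results table.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Location",
    "Channel",
    "Phase",
    "MeasurementRecord",
    "DeltaRecord",
    "CellSummary",
    "DesignConfig",
    "SchemaError",
    "ValidationError",
    "PairingError",
    "CompletenessWarning",
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_deltas",
    "write_deltas",
    "read_summaries",
    "write_summaries",
    "check_completeness",
]

# Default phantom calibration values (mmHg) assigned by the manufacturer.
DEFAULT_IOP_LEVELS: tuple[float, ...] = (6.0, 13.0, 43.0)

# Reporting resolution of the AQI display, in µg/m³.  The device manual does
# not state it; 0.1 is inferred from the one-decimal precision of the
# reported tables and the instrument display, and is only applied on write
# when explicitly requested.
DISPLAY_RESOLUTION = 0.1


class Location(str, enum.Enum):
    """Sensor placement relative to the tested phantom eye.

    ``upper``/``lower`` refer to height (eye level vs slightly below);
    ``same``/``opposite`` to the side relative to the eye under test.
    """

    UPPER_SAME = "upper_same"
    LOWER_SAME = "lower_same"
    UPPER_OPPOSITE = "upper_opposite"
    LOWER_OPPOSITE = "lower_opposite"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Channel(str, enum.Enum):
    """Particulate-matter size channel reported by the AQI."""

    PM25 = "pm25"
    PM10 = "pm10"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Phase(str, enum.Enum):
    """Whether a reading was taken before or during the air puff."""

    BASELINE = "baseline"
    DURING = "during"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SchemaError(ValueError):
    """A table does not have the documented column layout."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


class PairingError(ValueError):
    """A test lacks its baseline or during reading."""


class CompletenessWarning(UserWarning):
    """A dataset read from file has unpaired baseline/during readings."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One AQI reading.

    Parameters
    ----------
    phantom_id
        Label of the corneal phantom (e.g. ``"P06"``).
    iop
        Equivalent intraocular pressure of the phantom, mmHg.
    location
        AQI placement, one of the four :class:`Location` values.
    test_index
        1-based repeat index within the (phantom, location) cell.
    phase
        ``baseline`` (before the puff) or ``during``.
    pm25, pm10
        Reported mass concentrations, µg/m³; raw readings are non-negative.
    """

    phantom_id: str
    iop: float
    location: Location
    test_index: int
    phase: Phase
    pm25: float
    pm10: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", Location(self.location))
        object.__setattr__(self, "phase", Phase(self.phase))
        if self.iop <= 0:
            raise ValidationError(f"iop must be positive, got {self.iop}")
        if self.test_index < 1:
            raise ValidationError(
                f"test_index must be a positive integer, got {self.test_index}"
            )
        for name in ("pm25", "pm10"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"{name} must be a finite non-negative concentration, "
                    f"got {value}"
                )

    @property
    def key(self) -> tuple[str, Location, int]:
        """The (phantom, location, test) triple identifying one test."""
        return (self.phantom_id, self.location, self.test_index)


@dataclass(frozen=True)
class DeltaRecord:
    """Baseline-subtracted change in reported PM for one test.

    Deltas may be negative: a reading can drop below its baseline.
    """

    phantom_id: str
    iop: float
    location: Location
    test_index: int
    d_pm25: float
    d_pm10: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", Location(self.location))

    def value(self, channel: Channel) -> float:
        return self.d_pm25 if Channel(channel) is Channel.PM25 else self.d_pm10


@dataclass(frozen=True)
class CellSummary:
    """Per-cell summary: n, mean and sample SD of ΔPM for one
    (IOP, location, channel) combination — one cell of the results table.

    ``sd`` is the n−1 (sample) standard deviation and is NaN for n = 1,
    where it is undefined.
    """

    iop: float
    location: Location
    channel: Channel
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", Location(self.location))
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.n == 1:
            if not math.isnan(self.sd):
                raise ValidationError("sd is undefined for n=1; use NaN")
        elif not (self.sd >= 0):
            raise ValidationError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class DesignConfig:
    """The factorial design: IOP levels × sensor locations × repeats.

    Defaults reproduce the study design: 3 phantoms × 4 locations × 4
    repeated tests × 2 readings per test (baseline + during) = 96 readings.
    """

    iop_levels: tuple[float, ...] = DEFAULT_IOP_LEVELS
    locations: tuple[Location, ...] = tuple(Location)
    tests_per_cell: int = 4
    readings_per_test: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "locations", tuple(Location(loc) for loc in self.locations)
        )
        object.__setattr__(self, "iop_levels", tuple(float(i) for i in self.iop_levels))
        if self.tests_per_cell < 1:
            raise ValidationError("tests_per_cell must be >= 1")
        if self.readings_per_test != 2:
            raise ValidationError(
                "readings_per_test is fixed at 2 (baseline + during)"
            )
        if len(set(self.iop_levels)) != len(self.iop_levels):
            raise ValidationError("iop_levels must be distinct")

    @property
    def n_records(self) -> int:
        """Total reading count: |IOP| × |locations| × tests × 2."""
        return (
            len(self.iop_levels)
            * len(self.locations)
            * self.tests_per_cell
            * self.readings_per_test
        )

    def phantom_id(self, iop: float) -> str:
        """Canonical phantom label for an IOP level, e.g. 6.0 → ``"P06"``."""
        return f"P{int(round(iop)):02d}"


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "phantom_id",
    "iop_mmHg",
    "location",
    "test_index",
    "phase",
    "pm25_ugm3",
    "pm10_ugm3",
)

DELTA_COLUMNS = (
    "phantom_id",
    "iop_mmHg",
    "location",
    "test_index",
    "d_pm25_ugm3",
    "d_pm10_ugm3",
)

SUMMARY_COLUMNS = ("iop_mmHg", "location", "channel", "n", "mean_ugm3", "sd_ugm3")


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    got = tuple(df.columns)
    if got != tuple(expected):
        raise SchemaError(
            f"{path}: expected columns {list(expected)}, got {list(got)}"
        )


def check_completeness(
    records: Iterable[MeasurementRecord],
) -> list[tuple[str, Location, int]]:
    """Return the (phantom, location, test) keys lacking a baseline/during pair."""
    phases: dict[tuple[str, Location, int], set[Phase]] = {}
    for rec in records:
        seen = phases.setdefault(rec.key, set())
        if rec.phase in seen:
            raise ValidationError(
                f"duplicate {rec.phase.value} reading for {rec.key}"
            )
        seen.add(rec.phase)
    return sorted(
        (key for key, seen in phases.items() if len(seen) != 2),
        key=lambda k: (k[0], k[1].value, k[2]),
    )


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a long-format measurement CSV (one AQI reading per row).

    Raises :class:`SchemaError` on a wrong header and
    :class:`ValidationError` on invalid field values; emits a
    :class:`CompletenessWarning` naming every test missing its baseline or
    during reading.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    records = [
        MeasurementRecord(
            phantom_id=str(row.phantom_id),
            iop=float(row.iop_mmHg),
            location=Location(row.location),
            test_index=int(row.test_index),
            phase=Phase(row.phase),
            pm25=float(row.pm25_ugm3),
            pm10=float(row.pm10_ugm3),
        )
        for row in df.itertuples(index=False)
    ]
    unpaired = check_completeness(records)
    if unpaired:
        warnings.warn(
            "unpaired baseline/during readings for: "
            + ", ".join(f"({p}, {loc.value}, test {t})" for p, loc, t in unpaired),
            CompletenessWarning,
            stacklevel=2,
        )
    return records


def write_measurements(
    records: Sequence[MeasurementRecord],
    path: str | Path,
    *,
    quantize: bool = False,
) -> Path:
    """Write measurements as CSV in the canonical column order.

    With ``quantize=True`` PM values are rounded to the display resolution
    (0.1 µg/m³); otherwise values round-trip at full float precision.
    """
    path = Path(path)

    def _q(x: float) -> float:
        return round(x / DISPLAY_RESOLUTION) * DISPLAY_RESOLUTION if quantize else x

    df = pd.DataFrame(
        {
            "phantom_id": [r.phantom_id for r in records],
            "iop_mmHg": [r.iop for r in records],
            "location": [r.location.value for r in records],
            "test_index": [r.test_index for r in records],
            "phase": [r.phase.value for r in records],
            "pm25_ugm3": [_q(r.pm25) for r in records],
            "pm10_ugm3": [_q(r.pm10) for r in records],
        },
        columns=list(MEASUREMENT_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_deltas(deltas: Sequence[DeltaRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "phantom_id": [d.phantom_id for d in deltas],
            "iop_mmHg": [d.iop for d in deltas],
            "location": [d.location.value for d in deltas],
            "test_index": [d.test_index for d in deltas],
            "d_pm25_ugm3": [d.d_pm25 for d in deltas],
            "d_pm10_ugm3": [d.d_pm10 for d in deltas],
        },
        columns=list(DELTA_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_deltas(path: str | Path) -> list[DeltaRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DELTA_COLUMNS, path)
    return [
        DeltaRecord(
            phantom_id=str(row.phantom_id),
            iop=float(row.iop_mmHg),
            location=Location(row.location),
            test_index=int(row.test_index),
            d_pm25=float(row.d_pm25_ugm3),
            d_pm10=float(row.d_pm10_ugm3),
        )
        for row in df.itertuples(index=False)
    ]


def write_summaries(summaries: Sequence[CellSummary], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "iop_mmHg": [s.iop for s in summaries],
            "location": [s.location.value for s in summaries],
            "channel": [s.channel.value for s in summaries],
            "n": [s.n for s in summaries],
            "mean_ugm3": [s.mean for s in summaries],
            "sd_ugm3": [s.sd for s in summaries],
        },
        columns=list(SUMMARY_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_summaries(path: str | Path) -> list[CellSummary]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SUMMARY_COLUMNS, path)
    return [
        CellSummary(
            iop=float(row.iop_mmHg),
            location=Location(row.location),
            channel=Channel(row.channel),
            n=int(row.n),
            mean=float(row.mean_ugm3),
            sd=float(row.sd_ugm3),
        )
        for row in df.itertuples(index=False)
    ]
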