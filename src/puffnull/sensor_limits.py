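"""Instrument-limits model for a quasi-static particulate sensor.

Two quantitative arguments for why a consumer AQI cannot resolve an NCT
air puff:

* **Nominal accuracy** — the manufacturer quotes ±10 µg/m³ (PM2.5) and
  ±15 µg/m³ (PM10), while the observed per-cell ΔPM means sit around
  0.1–0.7 µg/m³: every reported change is far inside the instrument's own
  error band (:func:`flag_below_accuracy`).

* **Transient undersampling** — the sensor updates every ~3 s while the
  air puff lasts ~30 ms.  Modelling the update interval as a time-averaging
  window, a transient pulse is attenuated by its duty factor
  min(duration, window)/window — 1/100 for the nominal puff — before it can
  ever be displayed (:func:`window_response`).

The time-average reading is one defensible model of the 3 s update; whether
the real device integrates or samples-and-holds is not documented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .core_io import CellSummary, Channel, ValidationError

__all__ = [
    "SensorSpec",
    "PulseEvent",
    "PulseShape",
    "window_response",
    "attenuation_factor",
    "flag_below_accuracy",
]


@dataclass(frozen=True)
class SensorSpec:
    """Nominal AQI characteristics from the device manual.

    accuracy_* are half-widths of the quoted error band (±µg/m³);
    ``update_interval`` is the display refresh period in seconds;
    ``resolution`` the display step in µg/m³.
    """

    accuracy_pm25: float = 10.0
    accuracy_pm10: float = 15.0
    update_interval: float = 3.0
    resolution: float = 0.1

    def __post_init__(self) -> None:
        for name in ("accuracy_pm25", "accuracy_pm10", "update_interval", "resolution"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def accuracy(self, channel: Channel) -> float:
        return (
            self.accuracy_pm25
            if Channel(channel) is Channel.PM25
            else self.accuracy_pm10
        )


@dataclass(frozen=True)
class PulseEvent:
    """A transient concentration pulse: an NCT air puff is ~30 ms long."""

    duration: float = 0.030
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")


class PulseShape(str, enum.Enum):
    """Pulse waveform; ``amplitude`` is always the peak concentration.

    The study gives only a duration, so the rectangle is the default; the
    triangle (linear rise/fall) is offered for sensitivity — its time
    average over the pulse is half the peak.
    """

    RECTANGULAR = "rectangular"
    TRIANGULAR = "triangular"


_SHAPE_MEAN = {PulseShape.RECTANGULAR: 1.0, PulseShape.TRIANGULAR: 0.5}


def attenuation_factor(
    duration: float, update_interval: float, shape: PulseShape | str = PulseShape.RECTANGULAR
) -> float:
    """Duty-factor attenuation of a pulse averaged over one update window:
    shape-mean × min(duration, window)/window, in (0, 1], equal to the
    shape mean when the pulse fills the window."""
    if update_interval <= 0:
        raise ValidationError("update_interval must be > 0")
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    duty = min(duration, update_interval) / update_interval
    return _SHAPE_MEAN[PulseShape(shape)] * duty


def window_response(
    pulse: PulseEvent,
    sensor: SensorSpec = SensorSpec(),
    shape: PulseShape | str = PulseShape.RECTANGULAR,
    quantize: bool = False,
) -> float:
    """Concentration change the sensor reports for a pulse fully contained
    in one update window: the pulse's time average over the window.

    For the nominal 30 ms rectangular puff in a 3 s window this is
    amplitude/100.  With ``quantize`` the average is rounded to the display
    resolution (applied after averaging, modelling the readout step).
    """
    reported = pulse.amplitude * attenuation_factor(
        pulse.duration, sensor.update_interval, shape
    )
    if quantize:
        reported = round(reported / sensor.resolution) * sensor.resolution
    return reported


def flag_below_accuracy(
    summaries: Sequence[CellSummary], sensor: SensorSpec = SensorSpec()
) -> list[tuple[CellSummary, bool]]:
    """Flag every cell whose |mean ΔPM| is smaller than the channel's
    nominal accuracy band — i.e. a reported change the instrument itself
    does not claim to resolve.  All cells of the study's table are flagged
    under the default spec."""
    return [
        (s, abs(s.mean) < sensor.accuracy(s.channel)) for s in summaries
    ]
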