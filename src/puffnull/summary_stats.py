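"""Baseline subtraction and per-cell summaries.

Turns paired raw readings into per-test ΔPM values (during − baseline, per
channel) and aggregates them into the mean ± sample-SD cell layout of the
study's results table.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    CellSummary,
    Channel,
    DeltaRecord,
    Location,
    MeasurementRecord,
    PairingError,
    Phase,
)

__all__ = ["compute_deltas", "summarize_cells", "summaries_as_grid", "format_table"]


def compute_deltas(records: Iterable[MeasurementRecord]) -> list[DeltaRecord]:
    """Pair baseline/during readings by (phantom, location, test) and return
    one signed ΔPM record per test.

    Raises :class:`PairingError` naming the first key that lacks a complete
    baseline/during pair.
    """
    by_key: dict[tuple, dict[Phase, MeasurementRecord]] = defaultdict(dict)
    for rec in records:
        if rec.phase in by_key[rec.key]:
            raise PairingError(f"duplicate {rec.phase.value} reading for {rec.key}")
        by_key[rec.key][rec.phase] = rec

    deltas = []
    for key in sorted(by_key, key=lambda k: (k[0], k[1].value, k[2])):
        pair = by_key[key]
        if len(pair) != 2:
            missing = (Phase.BASELINE if Phase.DURING in pair else Phase.DURING).value
            phantom, loc, test = key
            raise PairingError(
                f"missing {missing} reading for ({phantom}, {loc.value}, test {test})"
            )
        base, during = pair[Phase.BASELINE], pair[Phase.DURING]
        deltas.append(
            DeltaRecord(
                phantom_id=base.phantom_id,
                iop=base.iop,
                location=base.location,
                test_index=base.test_index,
                d_pm25=during.pm25 - base.pm25,
                d_pm10=during.pm10 - base.pm10,
            )
        )
    return deltas


def summarize_cells(deltas: Iterable[DeltaRecord]) -> list[CellSummary]:
    """Per (IOP, location, channel): n, sample mean and sample SD (n−1
    denominator) of ΔPM.  For a singleton cell the SD is NaN (undefined)."""
    groups: dict[tuple[float, Location], list[DeltaRecord]] = defaultdict(list)
    for d in deltas:
        groups[(d.iop, d.location)].append(d)

    summaries = []
    for (iop, loc) in sorted(groups, key=lambda k: (k[0], k[1].value)):
        cell = groups[(iop, loc)]
        for ch in Channel:
            vals = np.array([d.value(ch) for d in cell])
            sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else math.nan
            summaries.append(
                CellSummary(
                    iop=iop, location=loc, channel=ch,
                    n=len(vals), mean=float(vals.mean()), sd=sd,
                )
            )
    return summaries


def summaries_as_grid(
    summaries: Sequence[CellSummary], channel: Channel
) -> dict[Location, dict[float, CellSummary]]:
    """Index summaries of one channel as {location: {iop: summary}}."""
    channel = Channel(channel)
    grid: dict[Location, dict[float, CellSummary]] = defaultdict(dict)
    for s in summaries:
        if s.channel is channel:
            grid[s.location][s.iop] = s
    return dict(grid)


def format_table(summaries: Sequence[CellSummary], decimals: int = 1) -> str:
    """Plain-text rendering in the layout of the study's results table:
    one block per channel, locations as rows, IOP levels as columns,
    cells as ``mean ± sd`` rounded only for display."""
    lines = []
    for ch in Channel:
        grid = summaries_as_grid(summaries, ch)
        if not grid:
            continue
        iops = sorted({iop for by_iop in grid.values() for iop in by_iop})
        header = ["Location".ljust(16)] + [f"{iop:g} mmHg".rjust(12) for iop in iops]
        lines.append(f"Delta {ch.value.upper()} (ug/m3), mean +/- SD per cell")
        lines.append("  ".join(header))
        for loc in Location:
            if loc not in grid:
                continue
            row = [loc.value.ljust(16)]
            for iop in iops:
                s = grid[loc].get(iop)
                if s is None:
                    row.append("-".rjust(12))
                else:
                    sd = "NA" if math.isnan(s.sd) else f"{s.sd:.{decimals}f}"
                    row.append(f"{s.mean:.{decimals}f} +/- {sd}".rjust(12))
            lines.append("  ".join(row))
        lines.append("")
    return "\n".join(lines)
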