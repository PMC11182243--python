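"""Two-factor fixed-effects ANOVA for the balanced phantom design.

Both factors are categorical: IOP (3 phantom levels) and sensor location
(4 levels), with equal replication per cell, so the factor sums of squares
are orthogonal and the Type I/II/III distinction vanishes.  Two entry
points produce identical tables:

* :func:`anova_two_way` — from raw per-test ΔPM records;
* :func:`anova_from_summary` — from per-cell n/mean/SD only, using the
  balanced-design identities (factor SS from cell means, within-cell SS
  = Σ (n−1)·sd²), so the study's printed results table suffices as input.

The default model is main effects only (one p-value per factor, matching
how the study reports its analysis); an interaction model is available for
sensitivity checks.  F tail probabilities are delegated to
``scipy.stats.f``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import CellSummary, Channel, DeltaRecord, Location, ValidationError
from .summary_stats import summaries_as_grid

__all__ = ["AnovaModel", "AnovaRow", "AnovaTable", "anova_two_way", "anova_from_summary"]

ALPHA = 0.05  # significance threshold used throughout the study


class AnovaModel(str, enum.Enum):
    MAIN_EFFECTS = "main_effects"
    WITH_INTERACTION = "with_interaction"


@dataclass(frozen=True)
class AnovaRow:
    """One line of an ANOVA table; ``f``/``p`` are NaN where undefined
    (residual and total rows, or a zero residual mean square)."""

    source: str  # iop | location | interaction | residual | total
    df: int
    ss: float
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    channel: Channel
    model: AnovaModel
    rows: tuple[AnovaRow, ...]

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def p_value(self, source: str) -> float:
        return self.row(source).p

    def significant(self, source: str, alpha: float = ALPHA) -> bool:
        p = self.p_value(source)
        return (not math.isnan(p)) and p < alpha

    def __str__(self) -> str:
        lines = [
            f"Two-way ANOVA ({self.model.value}) on delta "
            f"{self.channel.value.upper()}",
            f"{'source':<12}{'df':>4}{'SS':>12}{'MS':>12}{'F':>10}{'p':>10}",
        ]
        for r in self.rows:
            f = "" if math.isnan(r.f) else f"{r.f:.4f}"
            p = "" if math.isnan(r.p) else f"{r.p:.4f}"
            ms = "" if math.isnan(r.ms) else f"{r.ms:.4f}"
            lines.append(
                f"{r.source:<12}{r.df:>4}{r.ss:>12.4f}{ms:>12}{f:>10}{p:>10}"
            )
        return "\n".join(lines)


def _assemble(
    channel: Channel,
    model: AnovaModel,
    ss_iop: float,
    ss_loc: float,
    ss_inter: float,
    ss_within: float,
    a: int,
    b: int,
    n: int,
) -> AnovaTable:
    """Build the table from the orthogonal SS pieces of an a×b design with
    n replicates per cell.  Under the main-effects model the interaction SS
    is pooled into the residual."""
    N = a * b * n
    df_iop, df_loc, df_inter = a - 1, b - 1, (a - 1) * (b - 1)
    ss_total = ss_iop + ss_loc + ss_inter + ss_within

    if model is AnovaModel.MAIN_EFFECTS:
        ss_res = ss_inter + ss_within
        df_res = N - 1 - df_iop - df_loc
        factor_rows = [("iop", df_iop, ss_iop), ("location", df_loc, ss_loc)]
    else:
        if n < 2:
            raise ValidationError(
                "with_interaction model needs n >= 2 per cell (no residual df)"
            )
        ss_res = ss_within
        df_res = N - a * b
        factor_rows = [
            ("iop", df_iop, ss_iop),
            ("location", df_loc, ss_loc),
            ("interaction", df_inter, ss_inter),
        ]

    ms_res = ss_res / df_res
    rows = []
    for source, df, ss in factor_rows:
        ms = ss / df
        if ms_res > 0:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        else:  # all responses identical: F undefined, flagged as NaN
            f = p = math.nan
        rows.append(AnovaRow(source, df, ss, ms, f, p))
    rows.append(AnovaRow("residual", df_res, ss_res, ms_res, math.nan, math.nan))
    rows.append(AnovaRow("total", N - 1, ss_total, math.nan, math.nan, math.nan))
    return AnovaTable(channel=channel, model=model, rows=tuple(rows))


def anova_two_way(
    deltas: Iterable[DeltaRecord],
    channel: Channel,
    model: AnovaModel | str = AnovaModel.MAIN_EFFECTS,
) -> AnovaTable:
    """ANOVA from raw per-test ΔPM records.

    Requires a balanced design: every (IOP, location) cell present with the
    same number of tests, n ≥ 2.  Sums of squares are computed directly
    from the observations (grand/marginal/cell means and within-cell
    deviations).
    """
    channel = Channel(channel)
    model = AnovaModel(model)
    deltas = list(deltas)
    if not deltas:
        raise ValidationError("no delta records")

    iops = sorted({d.iop for d in deltas})
    locs = sorted({d.location for d in deltas}, key=lambda l: l.value)
    a, b = len(iops), len(locs)
    if a < 2 or b < 2:
        raise ValidationError("both factors need at least 2 levels")

    cells: dict[tuple[float, Location], list[float]] = {
        (i, l): [] for i in iops for l in locs
    }
    for d in deltas:
        cells[(d.iop, d.location)].append(d.value(channel))
    sizes = {len(v) for v in cells.values()}
    if len(sizes) != 1:
        raise ValidationError(
            f"unbalanced design: cell sizes {sorted(sizes)}; equal n required"
        )
    n = sizes.pop()
    if n < 2:
        raise ValidationError("need n >= 2 tests per cell")

    y = np.array([[cells[(i, l)] for l in locs] for i in iops])  # a × b × n
    grand = y.mean()
    iop_means = y.mean(axis=(1, 2))
    loc_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)

    ss_iop = b * n * float(((iop_means - grand) ** 2).sum())
    ss_loc = a * n * float(((loc_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_iop - ss_loc
    ss_within = float(((y - cell_means[:, :, None]) ** 2).sum())
    return _assemble(channel, model, ss_iop, ss_loc, ss_inter, ss_within, a, b, n)


def anova_from_summary(
    cells: Sequence[CellSummary],
    channel: Channel,
    model: AnovaModel | str = AnovaModel.MAIN_EFFECTS,
) -> AnovaTable:
    """ANOVA reconstructed from per-cell summaries alone.

    For a balanced design the raw data enter the ANOVA only through cell
    means and within-cell SS, and the latter is Σ_cells (n−1)·sd², so a
    printed mean ± SD table with known n reproduces the raw-data ANOVA
    exactly.
    """
    channel = Channel(channel)
    model = AnovaModel(model)
    grid = summaries_as_grid(cells, channel)
    if not grid:
        raise ValidationError(f"no summaries for channel {channel.value}")

    locs = sorted(grid, key=lambda l: l.value)
    iops = sorted({iop for by_iop in grid.values() for iop in by_iop})
    missing = [
        (iop, loc.value) for loc in locs for iop in iops if iop not in grid[loc]
    ]
    if missing:
        raise ValidationError(f"missing cells: {missing}")
    a, b = len(iops), len(locs)
    if a < 2 or b < 2:
        raise ValidationError("both factors need at least 2 levels")

    ns = {grid[loc][iop].n for loc in locs for iop in iops}
    if len(ns) != 1:
        raise ValidationError(f"unequal cell n: {sorted(ns)}; balanced design required")
    n = ns.pop()
    if n < 2:
        raise ValidationError("need n >= 2 per cell (SD undefined otherwise)")

    means = np.array([[grid[loc][iop].mean for loc in locs] for iop in iops])
    sds = np.array([[grid[loc][iop].sd for loc in locs] for iop in iops])
    grand = means.mean()
    ss_iop = b * n * float(((means.mean(axis=1) - grand) ** 2).sum())
    ss_loc = a * n * float(((means.mean(axis=0) - grand) ** 2).sum())
    ss_cells = n * float(((means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_iop - ss_loc
    ss_within = (n - 1) * float((sds**2).sum())
    return _assemble(channel, model, ss_iop, ss_loc, ss_inter, ss_within, a, b, n)
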