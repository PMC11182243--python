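"""Parametric Monte Carlo estimation of spurious IOP–PM trends.

The question the estimator answers: if the sensor produces only Gaussian
noise with the per-phantom means and SDs actually observed at one location
(no aerosol source exists — the phantoms are inert), how often does a
*positive* trend of ΔPM on IOP appear by chance?  Each replicate draws
simulated ΔPM values for the three phantoms (IOP 6/13/43 mmHg), evaluates
a trend statistic of value on numeric IOP, and the estimate is the fraction
of replicates meeting the positivity criterion, with the binomial Monte
Carlo standard error sqrt(p(1−p)/R).

The positivity criterion is configurable because "a positive correlation"
admits several operational readings:

* ``slope_positive`` (default) — OLS slope of ΔPM on IOP > 0;
* ``pearson_positive`` — Pearson r > 0 (sign-identical to the slope, kept
  as an explicit variant);
* ``slope_significant_positive`` — slope > 0 and two-sided trend p < α.

Two further axes are exposed for sensitivity analysis: the number of draws
per phantom per replicate (default 4, the experiment's repeat count) and
the draw scale — the cell SD (simulating individual tests) or the standard
error of the mean sd/√n (simulating the reported per-cell estimate).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import CellSummary, Channel, Location, ValidationError
from .synthetic_data import NoiseModel

__all__ = [
    "TrendCriterion",
    "DrawScale",
    "MCConfig",
    "TrendStat",
    "MonteCarloResult",
    "trend_statistic",
    "mc_spurious_trend",
    "mc_sweep",
    "slope_sign_probability",
    "mc_variants",
]


class TrendCriterion(str, enum.Enum):
    SLOPE_POSITIVE = "slope_positive"
    PEARSON_POSITIVE = "pearson_positive"
    SLOPE_SIGNIFICANT_POSITIVE = "slope_significant_positive"


class DrawScale(str, enum.Enum):
    """Scale of the per-draw Gaussian: the cell SD (a simulated test) or
    the standard error of the mean sd/√n (a simulated cell estimate)."""

    SD = "sd"
    SEM = "sem"


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    ``samples_per_cell`` draws are taken per phantom per replicate; with
    ``iop_as_rank`` the trend is evaluated against IOP ranks 1/2/3 instead
    of mmHg values.
    """

    n_replicates: int = 10_000
    samples_per_cell: int = 4
    criterion: TrendCriterion = TrendCriterion.SLOPE_POSITIVE
    alpha: float = 0.05
    seed: int = 0
    draw_scale: DrawScale = DrawScale.SD
    iop_as_rank: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", TrendCriterion(self.criterion))
        object.__setattr__(self, "draw_scale", DrawScale(self.draw_scale))
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        min_k = 3 if self.criterion is TrendCriterion.SLOPE_SIGNIFICANT_POSITIVE else 1
        if self.samples_per_cell < min_k:
            raise ValidationError(
                f"samples_per_cell must be >= {min_k} for {self.criterion.value}"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TrendStat:
    """OLS slope, Pearson r and two-sided trend p for (IOP, value) points.

    ``pearson_r``/``p_two_sided`` are NaN when undefined (zero response
    variance, or fewer than 3 points for the p-value)."""

    slope: float
    pearson_r: float
    p_two_sided: float


@dataclass(frozen=True)
class MonteCarloResult:
    location: Location | None
    channel: Channel | None
    criterion: TrendCriterion
    p_hat: float
    mc_se: float
    n_replicates: int
    seed: int
    samples_per_cell: int
    draw_scale: DrawScale

    def __post_init__(self) -> None:
        if not 0 <= self.p_hat <= 1:
            raise ValidationError(f"p_hat must be in [0,1], got {self.p_hat}")


def trend_statistic(points: Sequence[tuple[float, float]]) -> TrendStat:
    """OLS slope of value on IOP, Pearson correlation, and the two-sided
    p-value of the slope's t statistic with n−2 df.

    Requires at least two distinct IOP values.  With constant response the
    slope is 0 and r/p are NaN (flagged undefined).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValidationError("need >= 2 (iop, value) points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValidationError("all IOP values identical; trend undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    slope = sxy / sxx
    if syy == 0:
        return TrendStat(slope=slope, pearson_r=math.nan, p_two_sided=math.nan)
    r = sxy / math.sqrt(sxx * syy)
    m = len(pts)
    if m < 3 or abs(r) >= 1.0:
        p = math.nan
    else:
        t = r * math.sqrt((m - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), m - 2))
    return TrendStat(slope=slope, pearson_r=r, p_two_sided=p)


def _cell_arrays(cells: Sequence[CellSummary]) -> tuple[np.ndarray, ...]:
    """Validate one summary per IOP level and return (iops, means, sigmas, ns)
    sorted by IOP."""
    if len(cells) < 2:
        raise ValidationError("need one cell per IOP level, >= 2 levels")
    iops = [c.iop for c in cells]
    if len(set(iops)) != len(iops):
        raise ValidationError(f"duplicate IOP levels in cells: {sorted(iops)}")
    locs = {c.location for c in cells}
    chans = {c.channel for c in cells}
    if len(locs) != 1 or len(chans) != 1:
        raise ValidationError("cells must share one location and one channel")
    cells = sorted(cells, key=lambda c: c.iop)
    for c in cells:
        if math.isnan(c.sd):
            raise ValidationError(f"cell (iop={c.iop:g}) has undefined SD (n=1)")
    return (
        np.array([c.iop for c in cells]),
        np.array([c.mean for c in cells]),
        np.array([c.sd for c in cells]),
        np.array([c.n for c in cells]),
    )


def _draw_sigmas(sds: np.ndarray, ns: np.ndarray, scale: DrawScale) -> np.ndarray:
    return sds / np.sqrt(ns) if scale is DrawScale.SEM else sds


def mc_spurious_trend(
    cells: Sequence[CellSummary], config: MCConfig = MCConfig()
) -> MonteCarloResult:
    """Estimate the chance probability of a positive IOP–ΔPM trend.

    ``cells`` holds one per-phantom summary (same location and channel).
    Per replicate, ``samples_per_cell`` values are drawn per phantom from
    Normal(mean, σ) with σ set by ``draw_scale``; the criterion is
    evaluated on the pooled (IOP, value) points.  Bit-for-bit reproducible
    given (seed, config).
    """
    iops, means, sds, ns = _cell_arrays(cells)
    sigmas = _draw_sigmas(sds, ns, config.draw_scale)
    x_levels = (
        np.argsort(np.argsort(iops)) + 1.0 if config.iop_as_rank else iops
    )
    k = config.samples_per_cell
    R = config.n_replicates

    dx = x_levels - x_levels.mean()
    sxx_full = k * float((dx**2).sum())

    rng = np.random.default_rng(config.seed)
    # draws: (R, levels, k)
    y = rng.normal(means[None, :, None], sigmas[None, :, None], size=(R, len(iops), k))
    slope = (dx[None, :] * y.sum(axis=2)).sum(axis=1) / sxx_full

    if config.criterion is TrendCriterion.SLOPE_POSITIVE:
        hits = slope > 0
    elif config.criterion is TrendCriterion.PEARSON_POSITIVE:
        # r has the slope's sign wherever the response varies at all
        syy = ((y - y.mean(axis=(1, 2), keepdims=True)) ** 2).sum(axis=(1, 2))
        hits = (slope > 0) & (syy > 0)
    else:  # slope significant and positive
        m = len(iops) * k
        sxy = slope * sxx_full
        syy = ((y - y.mean(axis=(1, 2), keepdims=True)) ** 2).sum(axis=(1, 2))
        ss_res = syy - sxy * slope
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(ss_res / (m - 2) / sxx_full)
            t = slope / se
            p = 2 * stats.t.sf(np.abs(t), m - 2)
        hits = (slope > 0) & (p < config.alpha)

    if np.all(sigmas == 0):
        warnings.warn(
            "all cell SDs are zero: the trend is deterministic and p_hat is "
            "degenerate (0 or 1)",
            UserWarning,
            stacklevel=2,
        )

    p_hat = float(hits.mean())
    return MonteCarloResult(
        location=cells[0].location,
        channel=cells[0].channel,
        criterion=config.criterion,
        p_hat=p_hat,
        mc_se=math.sqrt(p_hat * (1 - p_hat) / R),
        n_replicates=R,
        seed=config.seed,
        samples_per_cell=k,
        draw_scale=config.draw_scale,
    )


def slope_sign_probability(
    cells: Sequence[CellSummary], config: MCConfig = MCConfig()
) -> float:
    """Closed-form P(OLS slope > 0) for Gaussian cells.

    The slope is a fixed linear combination of independent Gaussians, so
    P(slope > 0) = Φ(E[slope] / SD[slope]) exactly.  Serves as the analytic
    cross-check for the sign criteria; degenerate (all-zero SD) cells give
    a step function of the mean slope.
    """
    iops, means, sds, ns = _cell_arrays(cells)
    sigmas = _draw_sigmas(sds, ns, config.draw_scale)
    x_levels = (
        np.argsort(np.argsort(iops)) + 1.0 if config.iop_as_rank else iops
    )
    k = config.samples_per_cell
    dx = x_levels - x_levels.mean()
    sxx = float((dx**2).sum())
    e_slope = float((dx * means).sum()) / sxx
    var_slope = float((dx**2 * sigmas**2).sum()) / (k * sxx**2)
    if var_slope == 0:
        return 1.0 if e_slope > 0 else 0.0
    return float(stats.norm.cdf(e_slope / math.sqrt(var_slope)))


def _noise_cells(
    noise: NoiseModel,
    location: Location,
    channel: Channel,
    iop_levels: Iterable[float],
    n: int,
) -> list[CellSummary]:
    return [
        CellSummary(
            iop=iop,
            location=location,
            channel=channel,
            n=n,
            mean=noise.cell(iop, location, channel).delta_mean,
            sd=noise.cell(iop, location, channel).delta_sd,
        )
        for iop in iop_levels
    ]


def mc_sweep(
    noise: NoiseModel,
    config: MCConfig = MCConfig(),
    iop_levels: Sequence[float] = (6.0, 13.0, 43.0),
    locations: Sequence[Location] = tuple(Location),
    channels: Sequence[Channel] = tuple(Channel),
    n_per_cell: int = 4,
) -> list[MonteCarloResult]:
    """Run :func:`mc_spurious_trend` for every (location, channel): 8
    results under the default design.  Each combination gets its own
    substream derived from the master seed in canonical order, so results
    do not depend on evaluation order."""
    combos = [(loc, ch) for loc in locations for ch in channels]
    children = np.random.SeedSequence(config.seed).spawn(len(combos))
    results = []
    for (loc, ch), ss in zip(combos, children):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        cells = _noise_cells(noise, loc, ch, iop_levels, n_per_cell)
        results.append(mc_spurious_trend(cells, replace(config, seed=sub_seed)))
    return results


def mc_variants(
    cells: Sequence[CellSummary],
    n_replicates: int = 10_000,
    seed: int = 0,
    criteria: Sequence[TrendCriterion] = (
        TrendCriterion.SLOPE_POSITIVE,
        TrendCriterion.PEARSON_POSITIVE,
    ),
    samples: Sequence[int] = (1, 4),
    scales: Sequence[DrawScale] = (DrawScale.SD, DrawScale.SEM),
) -> dict[tuple[TrendCriterion, int, DrawScale], MonteCarloResult]:
    """Sensitivity grid over the under-specified simulation choices.

    Runs every (criterion × samples_per_cell × draw scale) combination with
    substream seeds derived from ``seed`` in grid order, and returns the
    results keyed by variant.  Used to report how strongly the estimated
    spurious-trend probability depends on the operational reading of
    "a positive correlation".
    """
    grid = [
        (crit, k, scale) for crit in criteria for k in samples for scale in scales
    ]
    children = np.random.SeedSequence(seed).spawn(len(grid))
    out = {}
    for (crit, k, scale), ss in zip(grid, children):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        cfg = MCConfig(
            n_replicates=n_replicates,
            samples_per_cell=k,
            criterion=crit,
            seed=sub_seed,
            draw_scale=scale,
        )
        out[(crit, k, scale)] = mc_spurious_trend(cells, cfg)
    return out
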