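"""Time-lapse relocalization: Final/Initial ratio on a percent-length axis.

Live-cell spindle fluorescence profiles from an initial (pre-treatment)
and a final (post-treatment) timepoint are resampled onto a common
0-100 % spindle-length grid so cells of different sizes can be compared,
then divided pointwise.  A motor that leaves the mid-spindle and piles up
at the poles gives a ratio < 1 centrally and > 1 near 0 %/100 %; the area
under the ratio curve (and the area of |ratio - 1|, which is zero for a
cell that did not relocalize) summarize the magnitude of the change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import IntensityProfile

#: Percent-spindle-length grid: 0, 1, ..., 100.
PERCENT_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class RelocalizationResult:
    """Final/Initial ratio curve on the percent-length grid, plus AUCs."""

    percent_positions: np.ndarray
    ratio: np.ndarray  # NaN where masked
    mask: np.ndarray  # True where initial signal fell below the floor
    auc: float | None = None  # trapezoid of ratio above baseline 0
    deviation_auc: float | None = None  # trapezoid of |ratio - 1|
    initial_time: float | None = None  # min relative to treatment
    final_time: float | None = None
    cell_id: str | None = None

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())


def percent_length_resample(
    p: IntensityProfile, n_points: int = 101
) -> IntensityProfile:
    """Linearly interpolate a profile onto the fixed 0-100 % grid.

    The profile's first sample maps to 0 % and its last to 100 %.
    Idempotent on a profile already on the grid.
    """
    if len(p.positions) < 2:
        raise ValueError("need at least 2 samples to resample")
    grid = np.linspace(0.0, 100.0, n_points)
    span = p.positions[-1] - p.positions[0]
    src_pct = 100.0 * (p.positions - p.positions[0]) / span
    values = {
        role: np.interp(grid, src_pct, v) for role, v in p.values.items()
    }
    return IntensityProfile(grid, values, width_px=p.width_px, cell_id=p.cell_id)


def _on_percent_grid(p: IntensityProfile) -> bool:
    return len(p.positions) >= 2 and np.allclose(
        p.positions, np.linspace(0.0, 100.0, len(p.positions))
    )


def final_initial_ratio(
    initial: IntensityProfile,
    final: IntensityProfile,
    channel: str | None = None,
    floor_frac: float = 0.01,
    initial_time: float | None = None,
    final_time: float | None = None,
) -> RelocalizationResult:
    """Pointwise Final/Initial ratio on the percent grid.

    Both profiles must already be percent-length resampled to the same
    grid.  Positions where the initial signal is at or below
    ``floor_frac`` times its maximum are masked (NaN ratio) rather than
    divided; a fully masked curve is an error.
    """
    if not _on_percent_grid(initial) or not _on_percent_grid(final):
        raise ValueError("profiles must be percent-length resampled first")
    if len(initial.positions) != len(final.positions):
        raise ValueError("initial and final grids differ in length")
    ini = initial.channel(channel)
    fin = final.channel(channel)
    eps = floor_frac * float(ini.max())
    mask = ini <= eps
    if mask.all():
        raise ValueError("initial profile below floor everywhere; no ratio defined")
    ratio = np.full_like(ini, np.nan)
    ratio[~mask] = fin[~mask] / ini[~mask]
    return RelocalizationResult(
        percent_positions=initial.positions.copy(),
        ratio=ratio,
        mask=mask,
        initial_time=initial_time,
        final_time=final_time,
        cell_id=initial.cell_id or final.cell_id,
    )


def ratio_auc(r: RelocalizationResult, min_coverage: float = 0.9) -> float:
    """Trapezoidal areas of the ratio curve over 0-100 %.

    Fills and returns ``r.auc`` (area above baseline 0; 100 for a ratio
    identically 1) and fills ``r.deviation_auc`` (area of |ratio - 1|;
    0 for a cell with unchanged localization).  Masked positions are
    excluded from the trapezoid; coverage below ``min_coverage`` of the
    grid is an error.
    """
    valid = ~r.mask
    coverage = valid.mean()
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of the percent grid has a defined ratio "
            f"(minimum {min_coverage:.0%})"
        )
    x = r.percent_positions[valid]
    y = r.ratio[valid]
    r.auc = float(np.trapezoid(y, x))
    r.deviation_auc = float(np.trapezoid(np.abs(y - 1.0), x))
    return r.auc
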