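"""Per-condition population statistics.

Counting metrics (mitotic index, multipolar-spindle fraction) operate on
manually scored count tables; proliferation metrics on cell-count time
series; expression metrics on background-subtracted ROI intensities.
Labels (mitotic / pole counts) are inputs, scored by eye upstream —
nothing here touches pixels except the ROI intensity means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imio import CountTable, SpindleImage


def mitotic_index(t: CountTable) -> tuple[float, pd.Series]:
    """Pooled mitotic index in percent, with per-field values for plotting.

    Pooled index = 100 * sum(mitotic) / sum(total) over all fields.
    """
    total = int(t.fields["total_cells"].sum())
    if total == 0:
        raise ValueError("no cells counted: total is zero")
    pooled = 100.0 * float(t.fields["mitotic_cells"].sum()) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        per_field = 100.0 * t.fields["mitotic_cells"] / t.fields["total_cells"]
    per_field.index = t.fields["field_id"]
    return pooled, per_field


def multipolar_fraction(t: CountTable) -> float:
    """Percent of scored mitotic cells with more than two spindle poles.

    Monopolar cells (n_poles == 1) count toward the denominator but never
    the numerator.
    """
    n_mitotic = len(t.pole_counts)
    if n_mitotic == 0:
        raise ValueError("no mitotic cells with scored pole counts")
    n_multi = int((t.pole_counts["n_poles"] > 2).sum())
    return 100.0 * n_multi / n_mitotic


def fold_change(times: np.ndarray, counts: np.ndarray) -> float:
    """count(final) / count(first) for one well's growth series."""
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two timepoints")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    if counts[0] <= 0:
        raise ValueError("first-timepoint count must be positive")
    return float(counts[-1] / counts[0])


def normalized_fold_change(
    growth: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Per-well fold change normalized to the control mean within each batch.

    ``growth`` is tidy with columns ``well_id, condition, batch, time_h,
    count`` (a missing ``batch`` column means one batch).  Each well's
    final/first count ratio is divided by the mean ratio of the control
    wells of the same batch, so the control mean is exactly 1 per batch.
    """
    df = growth.copy()
    if "batch" not in df.columns:
        df["batch"] = 0
    rows = []
    for (batch, well), g in df.groupby(["batch", "well_id"], sort=False):
        g = g.sort_values("time_h")
        rows.append(
            {
                "batch": batch,
                "well_id": well,
                "condition": g["condition"].iloc[0],
                "fold_change": fold_change(
                    g["time_h"].to_numpy(), g["count"].to_numpy()
                ),
            }
        )
    out = pd.DataFrame(rows)
    normalized = []
    for batch, g in out.groupby("batch", sort=False):
        ctrl = g.loc[g["condition"] == control_condition, "fold_change"]
        if ctrl.empty:
            raise ValueError(
                f"batch {batch!r} has no wells of control condition "
                f"{control_condition!r}"
            )
        normalized.append(g["fold_change"] / ctrl.mean())
    out["normalized_fold_change"] = pd.concat(normalized)
    return out


@dataclass
class ExpressionRecord:
    """Background-subtracted spindle-ROI intensity for one cell."""

    cell_id: str
    spindle_mean: float
    background_mean: float
    corrected: float  # spindle_mean - background_mean
    normalized: float | None = None  # corrected / mean control corrected


def _roi_mean(image: SpindleImage, roi: tuple[int, int, int, int],
              channel: str) -> float:
    """Mean intensity in a rectangular ROI (x0, y0, x1, y1), end-exclusive."""
    x0, y0, x1, y1 = roi
    ny, nx = image.shape
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ValueError(f"ROI {roi} outside raster of shape {image.shape}")
    return float(image.channel(channel)[y0:y1, x0:x1].mean())


def _rois_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def expression_level(
    image: SpindleImage,
    spindle_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    channel: str = "kif18a",
    cell_id: str = "",
) -> ExpressionRecord:
    """Mean spindle-ROI intensity minus mean background-ROI intensity.

    ROIs are ``(x0, y0, x1, y1)`` pixel rectangles and must not overlap.
    A background brighter than the spindle yields a negative corrected
    value, kept but warned about.
    """
    if _rois_overlap(spindle_roi, background_roi):
        raise ValueError("spindle and background ROIs overlap")
    spindle = _roi_mean(image, spindle_roi, channel)
    background = _roi_mean(image, background_roi, channel)
    corrected = spindle - background
    if corrected < 0:
        warnings.warn(
            f"cell {cell_id!r}: background mean ({background:.1f}) exceeds "
            f"spindle mean ({spindle:.1f}); corrected value is negative",
            stacklevel=2,
        )
    return ExpressionRecord(cell_id, spindle, background, corrected)


def normalize_to_control(
    records: list[ExpressionRecord], control_ids: set[str] | list[str]
) -> list[ExpressionRecord]:
    """Divide every corrected value by the mean control corrected value."""
    control_ids = set(control_ids)
    ctrl = [r.corrected for r in records if r.cell_id in control_ids]
    if not ctrl:
        raise ValueError("no control records found for normalization")
    denom = float(np.mean(ctrl))
    if denom == 0:
        raise ValueError("control mean corrected intensity is zero")
    for r in records:
        r.normalized = r.corrected / denom
    return records
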