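"""Intensity-profile extraction and normalization.

Two extraction geometries are supported, mirroring the manual ImageJ-style
workflow the metrics assume:

* a wide *line scan* — samples every pixel along a start->end segment,
  averaging over ``width_px`` perpendicular offsets spaced one pixel apart
  and symmetric about the line (a 10 px wide scan averages offsets
  -4.5 ... +4.5 px);
* a *boxed pole-to-pole profile* — the same machinery with the scan axis
  fixed to the pole-pole segment and the perpendicular extent given in
  micrometres (the box height).

Off-grid samples are bilinearly interpolated.  Sample spacing along the
scan axis is one pixel, reported in micrometres from the scan start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .imio import SpindleImage


@dataclass
class IntensityProfile:
    """Intensities sampled along a scan axis.

    ``positions`` are micrometres from the scan start, strictly increasing
    with uniform spacing; ``values`` maps channel role to the per-position
    mean intensity.
    """

    positions: np.ndarray
    values: dict[str, np.ndarray]
    width_px: int = 1
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        d = np.diff(self.positions)
        if len(self.positions) < 2 or not (d > 0).all():
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("positions must be uniformly spaced")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        for role, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.positions.shape:
                raise ValueError(
                    f"channel {role!r}: {v.shape} values for "
                    f"{self.positions.shape} positions"
                )
            self.values[role] = v

    @property
    def spacing(self) -> float:
        """Sample spacing in micrometres."""
        return float(self.positions[1] - self.positions[0])

    def channel(self, role: str | None = None) -> np.ndarray:
        """Values for ``role``; if None the profile must be single-channel."""
        if role is None:
            if len(self.values) != 1:
                raise ValueError(
                    f"profile has channels {sorted(self.values)}; specify one"
                )
            return next(iter(self.values.values()))
        if role not in self.values:
            raise KeyError(f"channel {role!r} not in profile")
        return self.values[role]


def _sample_grid(
    start: np.ndarray,
    end: np.ndarray,
    n_samples: int,
    offsets_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-coordinate sampling grid: (rows, cols), each (n_offsets, n_samples)."""
    axis = end - start
    length = float(np.hypot(*axis))
    u = axis / length
    normal = np.array([-u[1], u[0]])
    t = np.linspace(0.0, 1.0, n_samples)
    centers = start[None, :] + t[:, None] * axis[None, :]  # (n_samples, 2) x,y
    pts = centers[None, :, :] + offsets_px[:, None, None] * normal[None, None, :]
    cols = pts[..., 0]
    rows = pts[..., 1]
    return rows, cols


def _check_in_bounds(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> None:
    ny, nx = shape
    eps = 1e-9
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > ny - 1 + eps
        or cols.max() > nx - 1 + eps
    ):
        raise ValueError(
            "scan region exits the raster "
            f"(rows {rows.min():.2f}..{rows.max():.2f}, "
            f"cols {cols.min():.2f}..{cols.max():.2f}, shape {shape})"
        )


def _extract(
    image: SpindleImage,
    start: tuple[float, float],
    end: tuple[float, float],
    offsets_px: np.ndarray,
    channels: list[str],
    reduce: str,
    width_px: int,
    cell_id: str | None,
) -> IntensityProfile:
    start_a = np.asarray(start, dtype=float)
    end_a = np.asarray(end, dtype=float)
    if np.allclose(start_a, end_a):
        raise ValueError("scan start and end coincide")
    length_px = float(np.hypot(*(end_a - start_a)))
    length_um = length_px * image.pixel_size
    n_samples = int(round(length_px)) + 1
    if n_samples < 2:
        raise ValueError("scan shorter than one pixel")
    rows, cols = _sample_grid(start_a, end_a, n_samples, offsets_px)
    _check_in_bounds(rows, cols, image.shape)
    positions = np.linspace(0.0, length_um, n_samples)
    agg = np.mean if reduce == "mean" else np.sum
    values = {}
    for role in channels:
        arr = np.asarray(image.channel(role), dtype=float)
        sampled = map_coordinates(arr, [rows, cols], order=1, mode="nearest")
        values[role] = agg(sampled, axis=0)
    return IntensityProfile(positions, values, width_px=width_px, cell_id=cell_id)


def extract_line_profile(
    image: SpindleImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 10,
    channels: list[str] | None = None,
    cell_id: str | None = None,
) -> IntensityProfile:
    """Wide line scan from ``start`` to ``end`` (pixel coordinates, x-y).

    Each sample is the mean of bilinearly interpolated intensities at
    ``width_px`` perpendicular offsets spaced 1 px apart, symmetric about
    the line.  Sample spacing along the line is one pixel; positions are
    micrometres from ``start``.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if channels is None:
        channels = list(image.channels)
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    return _extract(image, start, end, offsets, channels, "mean", width_px, cell_id)


def extract_box_profile(
    image: SpindleImage,
    pole_a: tuple[float, float],
    pole_b: tuple[float, float],
    box_height_um: float = 5.0,
    channel: str = "kinetochore",
    reduce: str = "mean",
    cell_id: str | None = None,
) -> IntensityProfile:
    """Boxed profile along the pole-pole axis.

    The box axis runs pole_a -> pole_b; each axial sample reduces (mean by
    default, optionally sum for live-cell ROI totals) the intensity across
    the box height.  The profile spans exactly pole_a -> pole_b.
    """
    if box_height_um <= 0:
        raise ValueError("box_height_um must be positive")
    if reduce not in ("mean", "sum"):
        raise ValueError("reduce must be 'mean' or 'sum'")
    n_off = max(int(round(box_height_um / image.pixel_size)), 1)
    offsets = np.arange(n_off, dtype=float) - (n_off - 1) / 2.0
    return _extract(
        image, pole_a, pole_b, offsets, [channel], reduce, n_off, cell_id
    )


def normalize_profile(p: IntensityProfile) -> IntensityProfile:
    """Divide each channel by its own maximum (internal normalization).

    The output maximum of every channel is exactly 1; positions are
    unchanged.  Idempotent.  A channel whose maximum is not positive
    (flat-zero or negative profile) is rejected.
    """
    values = {}
    for role, v in p.values.items():
        m = float(v.max())
        if m <= 0:
            raise ValueError(
                f"channel {role!r}: maximum {m} is not positive; cannot normalize"
            )
        values[role] = v / m
    return IntensityProfile(
        p.positions.copy(), values, width_px=p.width_px, cell_id=p.cell_id
    )
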