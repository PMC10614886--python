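"""Image, annotation and result-table I/O.

Rasters are exchanged as multi-page TIFF (one page per channel for fixed
cells, TCYX stacks for time lapse) with a JSON sidecar recording the
channel order, pixel size and frame interval.  Channels are identified by
named *role* (``gamma_tubulin``, ``alpha_tubulin``, ``kinetochore``,
``kif18a``), never by page index alone.

Annotation coordinates are 0-based pixel units with sub-pixel floats,
``(x, y)`` with x along columns and y along rows; they are converted to
micrometres internally via the pixel size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Channel roles produced by the synthetic generator and consumed by the
#: metrics modules.  Real data may carry any subset.
CHANNEL_ROLES = ("gamma_tubulin", "alpha_tubulin", "kinetochore", "kif18a")


class ChannelError(KeyError):
    """A required channel role is absent from an image or mapping."""


@dataclass
class SpindleImage:
    """Multi-channel 2D fluorescence raster of a single mitotic cell.

    Parameters
    ----------
    channels
        Mapping of channel role to a 2D intensity array (arbitrary units,
        non-negative).  All rasters must share one shape.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    frame_time
        Interval between frames in seconds; only meaningful for images
        that are members of a time-lapse stack.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_time: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SpindleImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channel rasters must be 2D, got shape {shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ChannelError(
                f"channel role {role!r} missing; available: {sorted(self.channels)}"
            ) from None


@dataclass
class TimelapseStack:
    """Ordered frames of a live-cell acquisition (constant channel set)."""

    frames: list[SpindleImage]
    frame_time: float  # seconds between frames

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty time-lapse stack")
        roles = set(self.frames[0].channels)
        for f in self.frames:
            if set(f.channels) != roles:
                raise ValueError("all frames must carry the same channel roles")

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PoleAnnotation:
    """Manual per-cell annotation: spindle pole centers, optional scan line.

    Positions are ``(x, y)`` in 0-based pixels; sub-pixel floats allowed.
    """

    cell_id: str
    pole_a: tuple[float, float]
    pole_b: tuple[float, float]
    line_start: tuple[float, float] | None = None
    line_end: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if tuple(self.pole_a) == tuple(self.pole_b):
            raise ValueError(f"cell {self.cell_id!r}: pole_a and pole_b coincide")

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        """Raise if any annotated position lies outside the raster."""
        ny, nx = shape
        points = [("pole_a", self.pole_a), ("pole_b", self.pole_b)]
        if self.line_start is not None:
            points.append(("line_start", self.line_start))
        if self.line_end is not None:
            points.append(("line_end", self.line_end))
        bad = [
            name
            for name, (x, y) in points
            if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1)
        ]
        if bad:
            raise ValueError(
                f"cell {self.cell_id!r}: positions outside raster bounds: {bad}"
            )


@dataclass
class CountTable:
    """Per-field mitotic counts plus per-mitotic-cell pole counts.

    ``fields`` has columns ``field_id, total_cells, mitotic_cells``;
    ``pole_counts`` has columns ``field_id, cell_id, n_poles`` with one row
    per scored mitotic cell (may be empty when poles were not scored).
    """

    fields: pd.DataFrame
    pole_counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["field_id", "cell_id", "n_poles"]
        )
    )

    def __post_init__(self) -> None:
        required = {"field_id", "total_cells", "mitotic_cells"}
        if not required.issubset(self.fields.columns):
            raise ValueError(f"fields table needs columns {sorted(required)}")
        f = self.fields
        if (f["total_cells"] < 0).any() or (f["mitotic_cells"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (f["mitotic_cells"] > f["total_cells"]).any():
            raise ValueError("mitotic_cells exceeds total_cells in some field")
        if len(self.pole_counts) and (self.pole_counts["n_poles"] < 1).any():
            raise ValueError("n_poles must be >= 1")


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: SpindleImage, path: str | Path) -> Path:
    """Write one page per channel plus a JSON sidecar; returns the TIFF path."""
    path = Path(path)
    roles = list(image.channels)
    pages = np.stack([image.channels[r] for r in roles])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "channels": roles,
        "pixel_size_um": image.pixel_size,
        "frame_time_s": image.frame_time,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(
    path: str | Path, channel_map: dict[str, int] | None = None
) -> SpindleImage:
    """Read a multi-page TIFF written by :func:`write_image`.

    ``channel_map`` (role -> page index) overrides the sidecar; one of the
    two must resolve every requested role, and every mapped page must exist.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = _sidecar_path(path)
    if channel_map is None:
        if not sidecar.exists():
            raise ChannelError(
                f"{path}: no sidecar JSON and no channel_map given; cannot "
                "resolve page -> role"
            )
        meta = json.loads(sidecar.read_text())
        channel_map = {role: i for i, role in enumerate(meta["channels"])}
        pixel_size = float(meta["pixel_size_um"])
        frame_time = meta.get("frame_time_s")
    else:
        if not sidecar.exists():
            raise ChannelError(f"{path}: sidecar JSON required for pixel size")
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta["pixel_size_um"])
        frame_time = meta.get("frame_time_s")
    missing = [r for r, i in channel_map.items() if i >= len(pages)]
    if missing:
        raise ChannelError(
            f"{path}: TIFF has {len(pages)} page(s) but mapping requires "
            f"role(s) {missing} at out-of-range page indices"
        )
    channels = {role: pages[i] for role, i in channel_map.items()}
    return SpindleImage(channels, pixel_size, frame_time)


def write_stack(stack: TimelapseStack, path: str | Path) -> Path:
    """Write a TCYX-ordered TIFF stack plus sidecar."""
    path = Path(path)
    roles = list(stack.frames[0].channels)
    arr = np.stack(
        [np.stack([f.channels[r] for r in roles]) for f in stack.frames]
    )  # T, C, Y, X
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "channels": roles,
        "pixel_size_um": stack.pixel_size,
        "frame_time_s": stack.frame_time,
        "axes": "TCYX",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> TimelapseStack:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    roles = meta["channels"]
    if arr.ndim == 3:  # single frame
        arr = arr[None]
    frames = [
        SpindleImage(
            {r: arr[t, c] for c, r in enumerate(roles)},
            float(meta["pixel_size_um"]),
            meta.get("frame_time_s"),
        )
        for t in range(arr.shape[0])
    ]
    return TimelapseStack(frames, float(meta["frame_time_s"]))


# ---------------------------------------------------------------------------
# Annotation and count-table CSV I/O

_ANNOTATION_COLUMNS = [
    "cell_id",
    "pole_a_x",
    "pole_a_y",
    "pole_b_x",
    "pole_b_y",
    "line_start_x",
    "line_start_y",
    "line_end_x",
    "line_end_y",
]


def write_annotations(annotations: list[PoleAnnotation], path: str | Path) -> Path:
    rows = []
    for a in annotations:
        row: dict[str, object] = {
            "cell_id": a.cell_id,
            "pole_a_x": a.pole_a[0],
            "pole_a_y": a.pole_a[1],
            "pole_b_x": a.pole_b[0],
            "pole_b_y": a.pole_b[1],
        }
        if a.line_start is not None:
            row["line_start_x"], row["line_start_y"] = a.line_start
        if a.line_end is not None:
            row["line_end_x"], row["line_end_y"] = a.line_end
        rows.append(row)
    df = pd.DataFrame(rows).reindex(columns=_ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_annotations(
    path: str | Path, shape: tuple[int, int] | None = None
) -> list[PoleAnnotation]:
    """Read an annotation CSV; validates bounds if a raster shape is given."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        line_start = line_end = None
        if "line_start_x" in df.columns and pd.notna(r.get("line_start_x")):
            line_start = (float(r["line_start_x"]), float(r["line_start_y"]))
            line_end = (float(r["line_end_x"]), float(r["line_end_y"]))
        ann = PoleAnnotation(
            cell_id=str(r["cell_id"]),
            pole_a=(float(r["pole_a_x"]), float(r["pole_a_y"])),
            pole_b=(float(r["pole_b_x"]), float(r["pole_b_y"])),
            line_start=line_start,
            line_end=line_end,
        )
        if shape is not None:
            ann.validate_bounds(shape)
        out.append(ann)
    return out


def write_count_table(table: CountTable, fields_path: str | Path,
                      poles_path: str | Path | None = None) -> None:
    table.fields.to_csv(fields_path, index=False)
    if poles_path is not None:
        table.pole_counts.to_csv(poles_path, index=False)


def read_count_table(
    fields_path: str | Path, poles_path: str | Path | None = None
) -> CountTable:
    fields = pd.read_csv(fields_path)
    if poles_path is not None:
        poles = pd.read_csv(poles_path)
    else:
        poles = pd.DataFrame(columns=["field_id", "cell_id", "n_poles"])
    return CountTable(fields, poles)


# ---------------------------------------------------------------------------
# Result tables


def write_results(
    records: pd.DataFrame | list[dict],
    path: str | Path,
    metadata: dict[str, str] | None = None,
) -> Path:
    """Write a flat result CSV, one row per cell/scan/well.

    ``metadata`` (e.g. config hash, package version) is embedded as ``#``
    comment lines before the header so round-trips with
    ``pd.read_csv(..., comment='#')`` are lossless.
    """
    df = pd.DataFrame(records)
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
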