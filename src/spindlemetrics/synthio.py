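"""Synthetic spindle data with known ground truth.

Every analysis stage in this package is verified by parameter recovery on
data from this module: multi-channel spindle rasters, time-lapse
relocalization stacks, dose-response plates, exponential growth curves
and binomial count tables, each generated from explicit parameters that
are returned as ground truth.

Render model (one raster per channel role):

* ``gamma_tubulin`` — two isotropic 2D Gaussian puncta (sigma 0.4 µm) at
  the spindle poles;
* ``alpha_tubulin`` — a stadium-shaped density: Gaussian falloff of the
  distance to the pole-pole segment;
* ``kinetochore`` — a metaphase plate: Gaussian along the pole axis
  centered at the spindle midpoint (sigma = ``kinetochore_sigma``) times
  a fixed-width lateral envelope;
* ``kif18a`` — two mirrored axial Gaussian peaks ``kif18a_peak_distance``
  µm from each pole (0 renders a pole-accumulated, inhibited-like motor)
  with the same lateral envelope, plus a faint lattice term.

Noise, when enabled, is Poisson shot noise on the expected counts followed
by additive Gaussian read noise, clipped at zero.  Positions are
continuous micrometres; rasters sample pixel centers, index (0, 0) at the
top-left, 0-based, so pixel (r, c) sits at (x, y) = (c, r) * pixel_size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import FWHM_FACTOR
from .imio import CountTable, PoleAnnotation, SpindleImage, TimelapseStack

#: Point-spread-like width of a pole punctum, µm.
POLE_SIGMA_UM = 0.4
#: Lateral Gaussian width of the spindle body (alpha-tubulin, lattice), µm.
SPINDLE_HALFWIDTH_UM = 1.0
#: Lateral envelope width of the kinetochore plate and motor peaks, µm.
PLATE_HALFWIDTH_UM = 1.5
#: Axial width of each plus-end motor accumulation peak, µm.
MOTOR_PEAK_SIGMA_UM = 0.5
#: Faint motor signal along the whole lattice, relative to the peak term.
MOTOR_LATTICE_FRACTION = 0.1

DEFAULT_AMPLITUDES = {
    "gamma_tubulin": 150.0,
    "alpha_tubulin": 80.0,
    "kinetochore": 120.0,
    "kif18a": 150.0,
}


@dataclass
class NoiseModel:
    """Poisson shot noise on expected counts plus Gaussian read noise."""

    shot: bool = True
    read_sd: float = 2.0

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = rng.poisson(expected).astype(float) if self.shot else expected.copy()
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, size=out.shape)
        return np.clip(out, 0.0, None)

    @property
    def enabled(self) -> bool:
        return self.shot or self.read_sd > 0


@dataclass
class SpindleScene:
    """Parameters of one synthetic metaphase spindle.

    Defaults describe a ~12 µm bipolar spindle at 0.1083 µm/px (a typical
    60x sCMOS scale) with amplitudes giving peak SNR near 10 under the
    default noise model.
    """

    pole_a: tuple[float, float] = (3.0, 5.0)  # µm, (x, y)
    pole_b: tuple[float, float] = (15.0, 5.0)
    kinetochore_sigma: float = 1.5  # µm, plate dispersion along the axis
    kif18a_peak_distance: float = 4.0  # µm from each pole to the motor peak
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    background: float = 10.0  # a.u.
    noise: NoiseModel = field(default_factory=NoiseModel)
    pixel_size: float = 0.1083  # µm/px
    image_shape: tuple[int, int] = (93, 167)  # (ny, nx) px
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.pole_a) == tuple(self.pole_b):
            raise ValueError("pole_a and pole_b coincide")
        if self.kinetochore_sigma <= 0:
            raise ValueError("kinetochore_sigma must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        half = self.spindle_length / 2.0
        if not (0.0 <= self.kif18a_peak_distance <= half):
            raise ValueError(
                "kif18a_peak_distance must lie in [0, half the pole distance] "
                f"([0, {half:.2f}] µm)"
            )

    @property
    def spindle_length(self) -> float:
        return math.hypot(
            self.pole_b[0] - self.pole_a[0], self.pole_b[1] - self.pole_a[1]
        )

    def annotation(self, cell_id: str = "synthetic") -> PoleAnnotation:
        """Ground-truth pole annotation in pixel coordinates."""
        return PoleAnnotation(
            cell_id=cell_id,
            pole_a=(self.pole_a[0] / self.pixel_size, self.pole_a[1] / self.pixel_size),
            pole_b=(self.pole_b[0] / self.pixel_size, self.pole_b[1] / self.pixel_size),
        )


@dataclass
class GroundTruth:
    """Closed-form recovery targets implied by the generating parameters."""

    true_fwhm: float | None = None  # µm, 2*sqrt(2 ln 2) * kinetochore_sigma
    true_spindle_length: float | None = None  # µm
    true_peak_distance: float | None = None  # µm
    true_ic50: float | None = None  # nM
    true_hill: float | None = None
    true_growth_rate: float | None = None  # per hour
    true_mitotic_fraction: float | None = None
    true_multipolar_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("true_mitotic_fraction", "true_multipolar_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Spindle raster rendering


def _scene_geometry(scene: SpindleScene):
    """Per-pixel axial/lateral coordinates relative to the spindle axis (µm)."""
    ny, nx = scene.image_shape
    xs = np.arange(nx) * scene.pixel_size
    ys = np.arange(ny) * scene.pixel_size
    x, y = np.meshgrid(xs, ys)
    a = np.asarray(scene.pole_a)
    b = np.asarray(scene.pole_b)
    length = scene.spindle_length
    u = (b - a) / length
    dx = x - a[0]
    dy = y - a[1]
    axial = dx * u[0] + dy * u[1]  # signed distance along axis from pole_a
    lateral = dx * (-u[1]) + dy * u[0]  # signed perpendicular distance
    r_a2 = dx**2 + dy**2
    r_b2 = (x - b[0]) ** 2 + (y - b[1]) ** 2
    # distance to the pole-pole segment (stadium geometry)
    clamped = np.clip(axial, 0.0, length)
    seg2 = (axial - clamped) ** 2 + lateral**2
    return axial, lateral, r_a2, r_b2, seg2, length


def render_expected(scene: SpindleScene) -> dict[str, np.ndarray]:
    """Deterministic noise-free expected intensity per channel (background included)."""
    axial, lateral, r_a2, r_b2, seg2, length = _scene_geometry(scene)
    amps = scene.channel_amplitudes
    two_sp2 = 2.0 * POLE_SIGMA_UM**2
    poles = np.exp(-r_a2 / two_sp2) + np.exp(-r_b2 / two_sp2)
    lattice = np.exp(-seg2 / (2.0 * SPINDLE_HALFWIDTH_UM**2))
    plate_env = np.exp(-(lateral**2) / (2.0 * PLATE_HALFWIDTH_UM**2))
    channels: dict[str, np.ndarray] = {}
    if "gamma_tubulin" in amps:
        channels["gamma_tubulin"] = amps["gamma_tubulin"] * poles
    if "alpha_tubulin" in amps:
        channels["alpha_tubulin"] = amps["alpha_tubulin"] * lattice
    if "kinetochore" in amps:
        axial_band = np.exp(
            -((axial - length / 2.0) ** 2) / (2.0 * scene.kinetochore_sigma**2)
        )
        channels["kinetochore"] = amps["kinetochore"] * axial_band * plate_env
    if "kif18a" in amps:
        d = scene.kif18a_peak_distance
        two_sm2 = 2.0 * MOTOR_PEAK_SIGMA_UM**2
        peaks = np.exp(-((axial - d) ** 2) / two_sm2) + np.exp(
            -((axial - (length - d)) ** 2) / two_sm2
        )
        channels["kif18a"] = amps["kif18a"] * (
            peaks * plate_env + MOTOR_LATTICE_FRACTION * lattice
        )
    return {k: v + scene.background for k, v in channels.items()}


def _check_pole_margins(scene: SpindleScene, margin_um: float = 2.0) -> None:
    ny, nx = scene.image_shape
    x_max = (nx - 1) * scene.pixel_size
    y_max = (ny - 1) * scene.pixel_size
    for name, (px, py) in (("pole_a", scene.pole_a), ("pole_b", scene.pole_b)):
        if not (0.0 <= px <= x_max and 0.0 <= py <= y_max):
            raise ValueError(f"{name} at ({px}, {py}) µm lies outside the image")
        if min(px, py, x_max - px, y_max - py) < margin_um:
            raise ValueError(
                f"{name} closer than {margin_um} µm to the image edge; "
                "enlarge image_shape"
            )


def ground_truth_of(scene: SpindleScene) -> GroundTruth:
    return GroundTruth(
        true_fwhm=FWHM_FACTOR * scene.kinetochore_sigma,
        true_spindle_length=scene.spindle_length,
        true_peak_distance=scene.kif18a_peak_distance,
    )


def generate_spindle_image(scene: SpindleScene) -> tuple[SpindleImage, GroundTruth]:
    """Render one fixed-cell multi-channel image (seeded noise if enabled)."""
    _check_pole_margins(scene)
    expected = render_expected(scene)
    if scene.noise.enabled:
        rng = np.random.default_rng(scene.seed)
        channels = {k: scene.noise.apply(v, rng) for k, v in expected.items()}
    else:
        channels = expected
    return SpindleImage(channels, scene.pixel_size), ground_truth_of(scene)


# ---------------------------------------------------------------------------
# Time-lapse relocalization


def generate_timelapse(
    scene: SpindleScene,
    gap_halfwidth_by_frame: list[float],
    frame_time_s: float = 30.0,
) -> tuple[TimelapseStack, GroundTruth]:
    """Render a relocalization stack with an expanding mid-spindle motor gap.

    Frame ``t`` suppresses the motor channel within ±``gap_halfwidth[t]``
    µm of the spindle midpoint (axially) and deposits the removed
    intensity at the poles, so total motor intensity above background is
    conserved per frame.  Gap half-widths must be non-decreasing and below
    half the spindle length.  All other channels are static.
    """
    _check_pole_margins(scene)
    gaps = [float(g) for g in gap_halfwidth_by_frame]
    if not gaps:
        raise ValueError("need at least one frame")
    if any(b < a for a, b in zip(gaps, gaps[1:])):
        raise ValueError("gap half-widths must be non-decreasing")
    half = scene.spindle_length / 2.0
    if any(g < 0 or g >= half for g in gaps):
        raise ValueError(f"gap half-widths must lie in [0, {half:.2f}) µm")

    expected0 = render_expected(scene)
    motor0 = expected0["kif18a"] - scene.background
    axial, _, r_a2, r_b2, _, length = _scene_geometry(scene)
    two_sp2 = 2.0 * POLE_SIGMA_UM**2
    pole_kernel = np.exp(-r_a2 / two_sp2) + np.exp(-r_b2 / two_sp2)
    pole_kernel = pole_kernel / pole_kernel.sum()

    rng = np.random.default_rng(scene.seed)
    frames = []
    for g in gaps:
        suppressed = np.abs(axial - length / 2.0) < g
        motor = np.where(suppressed, 0.0, motor0)
        removed = motor0.sum() - motor.sum()
        motor = motor + removed * pole_kernel
        expected = dict(expected0)
        expected["kif18a"] = motor + scene.background
        if scene.noise.enabled:
            channels = {k: scene.noise.apply(v, rng) for k, v in expected.items()}
        else:
            channels = {k: v.copy() for k, v in expected.items()}
        frames.append(SpindleImage(channels, scene.pixel_size, frame_time_s))
    return TimelapseStack(frames, frame_time_s), ground_truth_of(scene)


# ---------------------------------------------------------------------------
# Dose-response plates


def fourfold_dilution(top_nM: float = 1000.0, n_points: int = 8) -> np.ndarray:
    """4-fold serial dilution series from ``top_nM`` downward."""
    if top_nM <= 0 or n_points < 1:
        raise ValueError("top concentration and point count must be positive")
    return top_nM / 4.0 ** np.arange(n_points)


def generate_dose_response(
    true_ic50: float,
    hill: float = 1.0,
    concentrations: np.ndarray | None = None,
    cv: float = 0.05,
    n_reps: int = 2,
    seed: int = 0,
    positive_signal: float = 10000.0,
    negative_signal: float = 500.0,
    n_controls: int = 4,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one ATPase plate as a tidy well table.

    Sample luminescence follows the 4PL inhibition model between the
    positive (uninhibited) and negative (no-enzyme) control levels, with
    multiplicative Gaussian noise of coefficient of variation ``cv``.
    Control wells are included with the same noise.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if concentrations is None:
        concentrations = fourfold_dilution()
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("empty concentration list")
    if (concentrations <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)

    def noisy(mean: float, n: int) -> np.ndarray:
        vals = np.full(n, mean)
        if cv > 0:
            vals = vals * (1.0 + rng.normal(0.0, cv, size=n))
        return vals

    rows = []
    for c in concentrations:
        frac = 1.0 / (1.0 + (true_ic50 / c) ** hill)  # fractional inhibition
        mean = positive_signal + (negative_signal - positive_signal) * frac
        for s in noisy(mean, n_reps):
            rows.append({"concentration_nM": c, "signal": s, "role": "sample"})
    for s in noisy(positive_signal, n_controls):
        rows.append({"concentration_nM": 0.0, "signal": s, "role": "positive_control"})
    for s in noisy(negative_signal, n_controls):
        rows.append({"concentration_nM": 0.0, "signal": s, "role": "negative_control"})
    plate = pd.DataFrame(rows)
    return plate, GroundTruth(true_ic50=true_ic50, true_hill=hill)


# ---------------------------------------------------------------------------
# Growth curves and count tables


def generate_growth_series(
    rate_per_hour: float,
    n0: float,
    hours: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
    well_id: str = "w0",
    condition: str = "treated",
    batch: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential growth counts n0 * exp(rate * t) with multiplicative noise."""
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    if not math.isfinite(rate_per_hour):
        raise ValueError("growth rate must be finite")
    hours = np.asarray(hours, dtype=float)
    counts = n0 * np.exp(rate_per_hour * hours)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        counts = counts * (1.0 + rng.normal(0.0, noise_cv, size=counts.shape))
        counts = np.clip(counts, 0.0, None)
    df = pd.DataFrame(
        {
            "well_id": well_id,
            "condition": condition,
            "batch": batch,
            "time_h": hours,
            "count": counts,
        }
    )
    return df, GroundTruth(true_growth_rate=rate_per_hour)


def generate_count_table(
    n_fields: int,
    cells_per_field: int,
    mitotic_fraction: float,
    multipolar_fraction: float,
    seed: int = 0,
) -> tuple[CountTable, GroundTruth]:
    """Binomial mitotic counts per field, with per-mitotic-cell pole counts.

    Each field scores ``cells_per_field`` cells of which Binomial(n, p)
    are mitotic; each mitotic cell is multipolar (3 poles) with the given
    probability, else bipolar.
    """
    if not (0.0 <= mitotic_fraction <= 1.0 and 0.0 <= multipolar_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if n_fields < 1 or cells_per_field < 1:
        raise ValueError("need at least one field and one cell per field")
    rng = np.random.default_rng(seed)
    mitotic = rng.binomial(cells_per_field, mitotic_fraction, size=n_fields)
    fields = pd.DataFrame(
        {
            "field_id": [f"f{i}" for i in range(n_fields)],
            "total_cells": cells_per_field,
            "mitotic_cells": mitotic,
        }
    )
    rows = []
    for i, m in enumerate(mitotic):
        multi = rng.random(m) < multipolar_fraction
        for j, is_multi in enumerate(multi):
            rows.append(
                {"field_id": f"f{i}", "cell_id": f"f{i}c{j}",
                 "n_poles": 3 if is_multi else 2}
            )
    poles = pd.DataFrame(rows, columns=["field_id", "cell_id", "n_poles"])
    gt = GroundTruth(
        true_mitotic_fraction=mitotic_fraction,
        true_multipolar_fraction=multipolar_fraction,
    )
    return CountTable(fields, poles), gt
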