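"""ATPase-screen analysis: percent inhibition and 4PL IC50 fitting.

Raw plate luminescence is converted to percent inhibition against the
plate's own controls,

    inhibition = 100 * (positive - sample) / (positive - negative),

where the positive control is the uninhibited (no compound) reaction and
the negative control the no-enzyme background.  Dose-response points are
then fitted with the four-parameter logistic (variable-slope) model on
log10 concentration,

    y(x) = bottom + (top - bottom) / (1 + (ic50 / x)^hill),

whose inflection on the log axis sits at the IC50 with y = (bottom+top)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def percent_inhibition(
    sample: float | np.ndarray, positive_mean: float, negative_mean: float
) -> float | np.ndarray:
    """Percent inhibition of a well against the plate controls.

    Maps the positive control to exactly 0 and the negative control to
    exactly 100.  Values outside [0, 100] are legitimate assay noise and
    are returned as-is (callers may flag beyond [-20, 120]).
    """
    span = positive_mean - negative_mean
    if span == 0:
        raise ValueError("positive and negative control means are equal")
    return 100.0 * (positive_mean - np.asarray(sample, dtype=float)) / span


def plate_inhibition(plate: pd.DataFrame, flag_range=(-20.0, 120.0)) -> pd.DataFrame:
    """Per-well percent inhibition for a plate table.

    ``plate`` has columns ``concentration_nM, signal, role`` with roles in
    {sample, positive_control, negative_control}; controls are aggregated
    by mean within the plate (never shared across plates).  Adds
    ``inhibition_pct`` and a ``flagged`` column for wells outside
    ``flag_range``.
    """
    pos = plate.loc[plate["role"] == "positive_control", "signal"]
    neg = plate.loc[plate["role"] == "negative_control", "signal"]
    if pos.empty or neg.empty:
        raise ValueError("plate needs at least one positive and one negative control")
    samples = plate[plate["role"] == "sample"].copy()
    inhib = percent_inhibition(
        samples["signal"].to_numpy(), float(pos.mean()), float(neg.mean())
    )
    samples["inhibition_pct"] = inhib
    samples["flagged"] = (inhib < flag_range[0]) | (inhib > flag_range[1])
    return samples


@dataclass
class FourPLFit:
    """Four-parameter logistic (variable slope) dose-response fit."""

    bottom: float  # percent inhibition asymptote at zero dose
    top: float  # asymptote at saturating dose
    ic50: float  # nM
    hill: float
    rss: float
    converged: bool
    stderr: dict[str, float] = field(default_factory=dict)
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ic50 / c) ** self.hill
        )


def _logistic(logc: np.ndarray, bottom: float, top: float, log_ic50: float,
              hill: float) -> np.ndarray:
    # (ic50/x)^hill == 10^(hill * (log_ic50 - log x)); stable on log axis
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


HILL_BOUNDS = (0.1, 10.0)


def fit_4pl(
    concentrations_nM: np.ndarray, inhibition_pct: np.ndarray
) -> FourPLFit:
    """Least-squares 4PL fit on log10 concentration.

    Initialization: bottom = min y, top = max y, IC50 = concentration of
    the point nearest 50 % response, hill = 1.  Hill is bounded to
    [0.1, 10] and the IC50 to within two decades of the tested range; a
    fit pinned at a bound or failing to converge is flagged, not raised.
    """
    c = np.asarray(concentrations_nM, dtype=float)
    y = np.asarray(inhibition_pct, dtype=float)
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) < 5:
        raise ValueError("need at least 5 distinct concentrations for a 4PL fit")
    logc = np.log10(c)
    y_lo, y_hi = float(y.min()), float(y.max())
    mid = 0.5 * (y_lo + y_hi)
    log_ic50_0 = float(logc[np.argmin(np.abs(y - mid))])
    lo_b = logc.min() - 2.0
    hi_b = logc.max() + 2.0
    p0 = [y_lo, y_hi, np.clip(log_ic50_0, lo_b, hi_b), 1.0]
    bounds = (
        [-np.inf, -np.inf, lo_b, HILL_BOUNDS[0]],
        [np.inf, np.inf, hi_b, HILL_BOUNDS[1]],
    )
    try:
        popt, pcov = curve_fit(
            _logistic, logc, y, p0=p0, bounds=bounds, maxfev=10000
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((4, 4), np.nan)
        converged = False
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    ic50 = 10.0**log_ic50
    perr = np.sqrt(np.diag(pcov))
    stderr = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        # delta method: se(ic50) = ln(10) * ic50 * se(log10 ic50)
        "ic50": float(np.log(10.0) * ic50 * perr[2]),
        "hill": float(perr[3]),
    }
    at_bound = (
        np.isclose(log_ic50, lo_b)
        or np.isclose(log_ic50, hi_b)
        or np.isclose(hill, HILL_BOUNDS[0])
        or np.isclose(hill, HILL_BOUNDS[1])
    )
    resid = y - _logistic(logc, *popt)
    return FourPLFit(
        bottom=bottom,
        top=top,
        ic50=ic50,
        hill=hill,
        rss=float((resid**2).sum()),
        converged=converged and not at_bound,
        stderr=stderr,
        at_bound=bool(at_bound),
    )


def fit_plate(plate: pd.DataFrame) -> tuple[FourPLFit, pd.DataFrame]:
    """Percent inhibition then 4PL fit for one plate table."""
    samples = plate_inhibition(plate)
    fit = fit_4pl(
        samples["concentration_nM"].to_numpy(),
        samples["inhibition_pct"].to_numpy(),
    )
    return fit, samples
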