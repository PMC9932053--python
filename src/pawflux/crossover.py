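"""Scaling-crossover localization and asymptotic exponent estimation.

Fluctuation functions of open-field trajectories show two power-law
regimes (steep growth at small scales, near-diffusive growth at large
scales).  The crossover scale is located at the maximum of the rotated
curve F(s) / s**rho, with rho chosen between the two asymptotic slopes
(5/4 for the 2 vs 1/2 pair), refined off-grid by parabolic interpolation
of log F~ against log s around the grid maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fluctuation import FluctuationMatrix

__all__ = ["CrossoverEstimate", "locate_crossover", "fit_exponents", "crossover_table"]

DEFAULT_RHO = 1.25


@dataclass
class CrossoverEstimate:
    """Result of rotated-curve crossover localization for one F(s)."""

    s_cross_frames: float
    s_cross_seconds: float
    rho: float
    boundary: bool
    h_small: float  # NaN when undefined
    h_large: float
    fit_range_small: tuple[float, float] | None = None
    fit_range_large: tuple[float, float] | None = None


def locate_crossover(
    scales,
    fluct,
    rho: float = DEFAULT_RHO,
    fps: float = 30.0,
    guard: float = 2.0,
) -> CrossoverEstimate:
    """Locate the crossover of one fluctuation function.

    Parameters
    ----------
    scales : array of scales s (frames), >= 5 entries, increasing.
    fluct : F(s) values (not squared), strictly positive.
    rho : rotation exponent dividing F(s) by s**rho.
    fps : frames per second for the seconds conversion.
    guard : guard-band factor handed to :func:`fit_exponents`.

    The boundary flag is set when the grid argmax sits at either end of
    the scale grid (no interior maximum — e.g. a pure power law).
    """
    scales = np.asarray(scales, dtype=float)
    fluct = np.asarray(fluct, dtype=float)
    if scales.size < 5:
        raise ParameterError("need at least 5 scales to locate a crossover")
    if scales.shape != fluct.shape:
        raise ParameterError("scales and fluctuation values differ in length")
    if np.any(fluct <= 0) or np.any(~np.isfinite(fluct)):
        raise ParameterError("fluctuation values must be positive and finite")

    log_s = np.log(scales)
    rotated = np.log(fluct) - rho * log_s
    k = int(np.argmax(rotated))
    boundary = k == 0 or k == scales.size - 1
    if boundary:
        s_cross = float(scales[k])
    else:
        # parabolic vertex through the three points around the maximum
        x0, x1, x2 = log_s[k - 1 : k + 2]
        y0, y1, y2 = rotated[k - 1 : k + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a < 0:
            vertex = -b / (2 * a)
            vertex = min(max(vertex, x0), x2)
            s_cross = float(np.exp(vertex))
        else:  # degenerate (collinear) — keep the grid value
            s_cross = float(scales[k])
    h_small, h_large, rng_small, rng_large = fit_exponents(
        scales, fluct, s_cross, guard=guard, _return_ranges=True
    )
    return CrossoverEstimate(
        s_cross_frames=s_cross,
        s_cross_seconds=s_cross / fps,
        rho=rho,
        boundary=boundary,
        h_small=h_small,
        h_large=h_large,
        fit_range_small=rng_small,
        fit_range_large=rng_large,
    )


def fit_exponents(
    scales,
    fluct,
    s_cross: float,
    guard: float = 2.0,
    min_points: int = 3,
    _return_ranges: bool = False,
):
    """Asymptotic slopes of log F vs log s on either side of the crossover.

    Guard bands of factor ``guard`` around ``s_cross`` are excluded so the
    smeared crossover region does not bias the fits; a side with fewer
    than ``min_points`` scales yields NaN (undefined).
    """
    scales = np.asarray(scales, dtype=float)
    fluct = np.asarray(fluct, dtype=float)
    small = scales < s_cross / guard
    large = scales > s_cross * guard

    def _slope(mask):
        if mask.sum() < min_points:
            return float("nan"), None
        sl = np.polyfit(np.log(scales[mask]), np.log(fluct[mask]), 1)[0]
        return float(sl), (float(scales[mask].min()), float(scales[mask].max()))

    h_small, rng_small = _slope(small)
    h_large, rng_large = _slope(large)
    if _return_ranges:
        return h_small, h_large, rng_small, rng_large
    return h_small, h_large


def crossover_table(
    fm: FluctuationMatrix,
    rho: float = DEFAULT_RHO,
    animal_id: str = "",
) -> pd.DataFrame:
    """Per-series crossover estimates for the diagonal of a FluctuationMatrix.

    Series labels of the form ``part:axis`` are split into part and axis
    columns; others land in the part column with an empty axis.
    """
    fl = fm.fluctuations()
    rows = []
    for j, label in enumerate(fm.labels):
        part, _, axis = label.partition(":")
        est = locate_crossover(fm.scales, fl[:, j], rho=rho, fps=fm.fps)
        rows.append(
            (
                animal_id,
                part,
                axis,
                est.s_cross_frames,
                est.s_cross_seconds,
                est.h_small,
                est.h_large,
                est.boundary,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal",
            "part",
            "axis",
            "s_x_frames",
            "s_x_seconds",
            "H_small",
            "H_large",
            "boundary_flag",
        ],
    )
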