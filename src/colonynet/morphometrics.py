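"""Shape descriptors of segmented nuclei: area, perimeter, eccentricity, roundness.

Eccentricity is that of the ellipse with the same normalized second central
moments as the region, e = sqrt(1 - (b/a)^2) = (distance between foci) /
(major axis length); 0 for a circle.  Roundness is the isoperimetric ratio
4*pi*area / perimeter^2; 1 for a perfect circle, < 1 otherwise.  Area is the
raw pixel count and perimeter the chain-code boundary estimate, so both are
expressed in pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "roundness",
    "eccentricity_from_axis_ratio",
    "region_eccentricity",
    "summarize_morphology",
    "ECCENTRICITY_CAP",
]

#: Eccentricity reported for degenerate (collinear) regions, kept strictly < 1.
ECCENTRICITY_CAP = 1.0 - 1e-12

_DESCRIPTORS = ("area", "perimeter", "eccentricity", "roundness")


@dataclass
class CellRecord:
    """One segmented nucleus."""

    cell_id: int
    x: float
    y: float
    area: float
    perimeter: float
    eccentricity: float
    roundness: float


def roundness(area: float, perimeter: float) -> float:
    """Isoperimetric roundness 4*pi*A/P**2 (1 for a circle)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    if area <= 0:
        raise ValueError("area must be > 0")
    return 4.0 * math.pi * area / (perimeter * perimeter)


def eccentricity_from_axis_ratio(axis_ratio: float) -> float:
    """Eccentricity of an ellipse with major/minor axis ratio q: sqrt(1 - 1/q^2)."""
    if axis_ratio < 1:
        raise ValueError("axis_ratio must be >= 1")
    return math.sqrt(1.0 - 1.0 / (axis_ratio * axis_ratio))


def region_eccentricity(region: np.ndarray) -> float:
    """Eccentricity of a rasterized region from its second central moments.

    ``region`` is a boolean mask of the region's pixels.  The covariance of
    the pixel coordinates (plus the 1/12 term for unit-square pixels) gives
    the moment ellipse; eccentricity follows from its eigenvalues.  Collinear
    regions are capped at :data:`ECCENTRICITY_CAP`.
    """
    mask = np.asarray(region, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise ValueError("region must have at least 3 pixels")
    x = xs - xs.mean()
    y = ys - ys.mean()
    n = len(xs)
    # 1/12 = second moment of a unit square pixel about its own center
    mxx = (x @ x) / n + 1.0 / 12.0
    myy = (y @ y) / n + 1.0 / 12.0
    mxy = (x @ y) / n
    common = math.sqrt((mxx - myy) ** 2 + 4.0 * mxy * mxy)
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    if lam1 <= 0:
        raise ValueError("degenerate region: zero second moments")
    if lam2 <= 0:
        return ECCENTRICITY_CAP
    return min(math.sqrt(1.0 - lam2 / lam1), ECCENTRICITY_CAP)


def summarize_morphology(records: list[CellRecord]) -> pd.DataFrame:
    """Per-image mean and sample standard deviation of the four descriptors.

    Returns a DataFrame indexed by descriptor with columns ``mean``/``sd``/``n``.
    With a single record the standard deviation is reported as 0 (with a
    warning) so group statistics downstream never see NaN.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if len(records) == 1:
        warnings.warn("single-record summary: standard deviations set to 0", stacklevel=2)
    out = {}
    for name in _DESCRIPTORS:
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[name] = {"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)}
    return pd.DataFrame(out).T[["mean", "sd", "n"]]
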