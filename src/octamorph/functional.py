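"""Functional endpoints: microperimetry mean sensitivity and visual acuity.

Microperimetry samples retinal sensitivity (dB) on a 61-point grid over
the central 20° (1 central point + 15 points in each of the four
quadrants delimited by the 45° diagonals).  The device's exact point
coordinates are proprietary, so a documented default layout on concentric
rings is shipped and any user layout with the same membership structure
is accepted — the quadrant mean sensitivities depend only on membership.

Best-corrected visual acuity converts from Snellen fractions to logMAR:
logMAR = log₁₀(denominator/numerator) = −log₁₀(decimal acuity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SensitivityGrid", "default_layout", "build_grid",
           "mean_sensitivity", "snellen_to_logmar"]

N_POINTS = 61
N_PER_QUADRANT = 15
DB_RANGE = (0.0, 36.0)
_QUADS = ("T", "S", "N", "I")


@dataclass
class SensitivityGrid:
    """Validated 61-point grid with optional attached sensitivities.

    ``points`` columns: point_id, x_deg, y_deg, quadrant
    ('center'/'T'/'S'/'N'/'I') and, once attached, ``db``.
    """

    points: pd.DataFrame

    def with_sensitivities(self, db) -> "SensitivityGrid":
        """Attach dB values (sequence aligned to point order, or a mapping
        point_id → dB).  Values must lie in [0, 36]; NaN marks missing."""
        df = self.points.copy()
        if isinstance(db, dict):
            df["db"] = df["point_id"].map(db)
        else:
            vals = np.asarray(db, float)
            if len(vals) != len(df):
                raise ValueError(f"expected {len(df)} dB values")
            df["db"] = vals
        ok = df["db"].dropna()
        if ((ok < DB_RANGE[0]) | (ok > DB_RANGE[1])).any():
            raise ValueError("sensitivities must lie in [0, 36] dB")
        return SensitivityGrid(df)


def default_layout() -> pd.DataFrame:
    """Default 61-point layout: 1 centre + 15 points per quadrant.

    Points sit on five concentric rings (2°, 4°, 6°, 8°, 10° eccentricity)
    at three angles per quadrant, away from the diagonal boundaries.
    Horizontal quadrants are labelled in the right-eye convention
    (temporal at x < 0); pass a custom layout for other conventions.
    """
    rows = [{"point_id": 0, "x_deg": 0.0, "y_deg": 0.0, "quadrant": "center"}]
    centers = {"N": 0.0, "S": 90.0, "T": 180.0, "I": 270.0}
    pid = 1
    for quad in _QUADS:
        for r in (2.0, 4.0, 6.0, 8.0, 10.0):
            for off in (-22.5, 0.0, 22.5):
                a = np.deg2rad(centers[quad] + off)
                rows.append({"point_id": pid,
                             "x_deg": round(r * np.cos(a), 4),
                             "y_deg": round(r * np.sin(a), 4),
                             "quadrant": quad})
                pid += 1
    return pd.DataFrame(rows)


def build_grid(layout: pd.DataFrame | None = None) -> SensitivityGrid:
    """Validate a grid layout (61 points, 15 per quadrant, 1 centre).

    The layout needs columns point_id, x_deg, y_deg, quadrant; all points
    must lie within 10° of fixation (the central 20° field).
    """
    df = default_layout() if layout is None else pd.DataFrame(layout).copy()
    required = {"point_id", "x_deg", "y_deg", "quadrant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout missing columns {sorted(missing)}")
    if len(df) != N_POINTS:
        raise ValueError(f"layout must have exactly {N_POINTS} points, "
                         f"got {len(df)}")
    counts = df["quadrant"].value_counts()
    if counts.get("center", 0) != 1:
        raise ValueError("layout must have exactly one centre point")
    for q in _QUADS:
        if counts.get(q, 0) != N_PER_QUADRANT:
            raise ValueError(f"quadrant {q} must have exactly "
                             f"{N_PER_QUADRANT} points, got {counts.get(q, 0)}")
    ecc = np.hypot(df["x_deg"], df["y_deg"])
    if (ecc > 10.0 + 1e-9).any():
        raise ValueError("all points must lie within the central 20° "
                         "(eccentricity ≤ 10°)")
    return SensitivityGrid(df.reset_index(drop=True))


def mean_sensitivity(grid: SensitivityGrid, region: str = "all") -> float:
    """Arithmetic mean sensitivity (dB) of a region.

    ``region="all"`` averages all 61 points; a quadrant letter averages
    its 15 points (the centre point belongs to no quadrant).  Missing
    values are excluded with the count reported in a warning.
    """
    df = grid.points
    if "db" not in df.columns:
        raise ValueError("no sensitivities attached; use with_sensitivities()")
    if region == "all":
        vals = df["db"]
    elif region in _QUADS:
        vals = df.loc[df["quadrant"] == region, "db"]
    else:
        raise ValueError(f"region must be 'all' or one of {_QUADS}")
    n_missing = int(vals.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing sensitivity value(s) excluded "
                      f"from region {region!r}")
    vals = vals.dropna()
    if len(vals) == 0:
        raise ValueError(f"no sensitivity values available in region {region!r}")
    return float(vals.mean())


def snellen_to_logmar(acuity) -> float:
    """Convert visual acuity to logMAR.

    Accepts a Snellen string ("20/40", "6/60"), a (numerator, denominator)
    pair, or a decimal acuity.  logMAR = log₁₀(den/num) = −log₁₀(decimal).
    """
    if isinstance(acuity, str):
        parts = acuity.split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse Snellen fraction {acuity!r}")
        num, den = float(parts[0]), float(parts[1])
    elif isinstance(acuity, (tuple, list)):
        num, den = float(acuity[0]), float(acuity[1])
    else:
        num, den = float(acuity), 1.0
    if num <= 0 or den <= 0:
        raise ValueError("acuity terms must be positive")
    return float(np.log10(den / num))
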