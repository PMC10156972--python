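"""Macular analysis zone: 6-mm disc and temporal/superior/nasal/inferior quadrants.

The disc is centred on the fovea (raster centre by default) and split by
the two 45° diagonals into four quadrants, the standard T/S/N/I reading of
macular sectorization.  Assignment is by dominant axis: pixels whose
vertical offset from the centre exceeds the horizontal offset go to the
superior/inferior quadrants, all others (including pixels exactly on a
diagonal) to the horizontal quadrants; the centre pixel goes to superior.
This rule partitions the disc exactly and — unlike a half-open angular
rule — is exactly invariant under left-right mirroring with laterality
flipped, because mirroring maps each diagonal ray onto the other.

Horizontal quadrants are labelled temporal/nasal by laterality: for a
right eye (OD) temporal is left of centre, for a left eye (OS) it is right
of centre.  Unknown laterality falls back to the OD convention with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import VesselBranch

__all__ = ["SectorSet", "make_sectors", "assign_branch", "label_branches",
           "QUADRANTS"]

QUADRANTS = ("T", "S", "N", "I")


@dataclass
class SectorSet:
    """Disc mask plus four disjoint quadrant masks that tile it exactly."""

    center: tuple[int, int]          # (row, col) pixel
    diameter_mm: float
    scale: float
    laterality: str
    disc: np.ndarray                 # bool
    quadrants: dict[str, np.ndarray]  # keys T, S, N, I

    @property
    def radius_px(self) -> float:
        return self.diameter_mm / 2.0 / self.scale

    def area_mm2(self) -> float:
        return float(self.disc.sum()) * self.scale ** 2


def make_sectors(shape: tuple[int, int], center: tuple[int, int] | None,
                 diameter_mm: float, scale: float,
                 laterality: str = "unknown") -> SectorSet:
    """Build the circular analysis zone and its four quadrant masks.

    Parameters
    ----------
    shape : (H, W)
        Raster shape the masks must match.
    center : (row, col) or None
        Fovea centre; None uses the raster centre (fovea-centred scans).
    diameter_mm : float
        Zone diameter, 6 mm for the macular zone.
    scale : float
        mm per pixel.
    laterality : {"OD", "OS", "unknown"}
    """
    h, w = shape
    if center is None:
        center = (h // 2, w // 2)
    cr, cc = center
    r_px = diameter_mm / 2.0 / scale
    # pixel centres span 0..dim-1; allow the disc to touch the raster edge
    # (a 6-mm zone exactly fills a 6-mm field of view) but not exceed it
    if cr - r_px < -1 or cc - r_px < -1 or cr + r_px > h or cc + r_px > w:
        raise ValueError(
            f"disc of radius {r_px:.1f} px at {center} exceeds raster {shape}")

    if laterality == "unknown":
        warnings.warn("unknown laterality; using OD (temporal = left) convention")
        lat = "OD"
    elif laterality in ("OD", "OS"):
        lat = laterality
    else:
        raise ValueError("laterality must be 'OD', 'OS' or 'unknown'")

    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cr
    dc = cols - cc
    disc = (dr * dr + dc * dc) <= r_px * r_px

    vertical = np.abs(dr) > np.abs(dc)
    sup = disc & (vertical & (dr < 0) | ((dr == 0) & (dc == 0)))
    inf = disc & vertical & (dr > 0)
    left = disc & ~vertical & (dc < 0)
    right = disc & ~vertical & (dc > 0)

    if lat == "OD":
        quads = {"T": left, "N": right}
    else:
        quads = {"T": right, "N": left}
    quads["S"] = sup
    quads["I"] = inf

    return SectorSet((cr, cc), diameter_mm, scale, lat, disc,
                     {k: quads[k] for k in QUADRANTS})


def assign_branch(branch: VesselBranch, sectors: SectorSet) -> str:
    """Assign a branch to a quadrant label, or "outside".

    A branch with fewer than 50% of its path pixels inside the disc is
    "outside"; otherwise it goes to the quadrant containing the majority
    of its in-disc pixels, ties broken by the quadrant of the path's
    midpoint pixel (and by T, S, N, I order if the midpoint is outside).
    """
    path = branch.path
    rr, cc = path[:, 0], path[:, 1]
    in_disc = sectors.disc[rr, cc]
    if in_disc.sum() < 0.5 * len(path):
        return "outside"
    counts = {q: int(sectors.quadrants[q][rr, cc].sum()) for q in QUADRANTS}
    best = max(counts.values())
    tied = [q for q in QUADRANTS if counts[q] == best]
    if len(tied) == 1:
        return tied[0]
    mid = tuple(path[len(path) // 2])
    for q in tied:
        if sectors.quadrants[q][mid]:
            return q
    return tied[0]


def label_branches(branches: list[VesselBranch], sectors: SectorSet) -> list[VesselBranch]:
    """Set the ``sector`` field of every branch in place; returns the list."""
    for b in branches:
        b.sector = assign_branch(b, sectors)
    return branches
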