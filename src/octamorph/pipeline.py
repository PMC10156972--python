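"""End-to-end per-image morphometry: raster → per-region vascular indices."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .metrics import (FAZ_CLOSING_RADIUS, faz_metrics, vessel_density,
                      vessel_tortuosity)
from .sectors import QUADRANTS, label_branches, make_sectors
from .segmentation import GrayscaleImage, segment_vessels
from .skeleton import build_graph, prune_spurs, skeletonize

__all__ = ["analyze_image", "run_images"]


def analyze_image(img: GrayscaleImage, fovea: tuple[int, int] | None = None,
                  segmentation: str = "ridge-otsu", threshold: float | None = None,
                  scales: tuple[float, ...] = (1.0, 2.0, 3.0),
                  diameter_mm: float = 6.0,
                  closing_radius_px: int = FAZ_CLOSING_RADIUS,
                  prune_spurs_px: float = 0.0,
                  layer: str = "SCP") -> dict:
    """Measure one en-face angiogram.

    Runs segmentation → skeletonization → branch graph → sector
    assignment and returns a flat dict: macular and per-quadrant VT and
    VD, FAZ area/perimeter/acircularity, and branch counts.  Metrics are
    suffixed ``_T``/``_S``/``_N``/``_I`` per quadrant.
    """
    mask = segment_vessels(img, method=segmentation, scales=scales,
                           threshold=threshold)
    skel = skeletonize(mask)
    graph = build_graph(skel)
    if prune_spurs_px > 0:
        graph = prune_spurs(graph, prune_spurs_px)
    sectors = make_sectors(img.shape, fovea, diameter_mm, img.scale,
                           img.laterality)
    label_branches(graph.branches, sectors)

    vd_key = "scp_vd" if layer == "SCP" else "dcp_vd"
    out: dict = {"n_branches": len(graph.branches),
                 "n_nodes": len(graph.nodes)}

    res = vessel_tortuosity(graph.branches, "macular")
    out["vt"] = res.vt
    out["vt_n_excluded"] = res.n_excluded
    out[vd_key] = vessel_density(mask, sectors.disc, "macular", layer).vd
    for q in QUADRANTS:
        out[f"vt_{q}"] = vessel_tortuosity(graph.branches, q).vt
        out[f"{vd_key}_{q}"] = vessel_density(mask, sectors.quadrants[q],
                                              q, layer).vd
    faz = faz_metrics(mask, fovea, closing_radius_px)
    out["faza"] = faz.faza_mm2
    out["fazp"] = faz.fazp_mm
    out["ai"] = faz.ai
    if faz.implausible:
        warnings.warn("FAZ covers the whole raster; metrics implausible")
    return out


def run_images(meta: pd.DataFrame, images_dir, **kwargs) -> pd.DataFrame:
    """Analyze every image listed in a metadata table.

    ``meta`` columns: eye_id, group, visit, laterality, image_path and
    optionally fovea_x, fovea_y (pixel coordinates overriding the raster
    centre) plus pass-through tabular inputs (rt_um, bcva_snellen, ...).
    Returns one metrics row per input row, merged with the metadata.
    """
    images_dir = Path(images_dir)
    records = []
    for _, row in meta.iterrows():
        img = _io.read_image(images_dir / row["image_path"],
                             laterality=row.get("laterality", "unknown"))
        fovea = None
        if "fovea_x" in row and "fovea_y" in row \
                and pd.notna(row.get("fovea_x")) and pd.notna(row.get("fovea_y")):
            fovea = (int(row["fovea_y"]), int(row["fovea_x"]))
        rec = dict(row)
        rec.update(analyze_image(img, fovea=fovea, **kwargs))
        records.append(rec)
    return pd.DataFrame.from_records(records)
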