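"""Skeletonization and branch-graph extraction.

A binary vessel mask is thinned to 1-px centerlines; junction pixels are
clustered into nodes, branches are traced between nodes, and each branch
carries three lengths:

``geodesic_mm``
    chain-code length: 1 step for orthogonal moves, √2 for diagonal moves,
    times the pixel scale (the "actual branch length" convention of
    skeleton-analysis tools);
``chord_mm``
    Euclidean distance between the branch's two end pixels;
``arc_mm``
    length of the Gaussian-smoothed branch polyline (σ = 2 px, endpoints
    pinned).  The chain code systematically overestimates smooth digital
    curves by ~5% because every step is quantized to 45°; the smoothed
    polyline removes that staircase bias and is what the tortuosity ratio
    uses by default (see octamorph.metrics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter1d
from skimage.morphology import skeletonize as _sk_skeletonize

from .segmentation import VesselMask

__all__ = [
    "Skeleton",
    "SkeletonNode",
    "VesselBranch",
    "SkeletonGraph",
    "skeletonize",
    "build_graph",
    "geodesic_length",
    "chord_length",
    "smooth_path_length",
    "prune_spurs",
]

_EIGHT = np.ones((3, 3), dtype=int)
_SQRT2 = float(np.sqrt(2.0))

#: default Gaussian σ (px) for the smoothed branch polyline
SMOOTH_SIGMA = 2.0


@dataclass
class Skeleton:
    """1-px-wide, 8-connected thinning of a vessel mask."""

    pixels: np.ndarray  # bool raster
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SkeletonNode:
    """Endpoint or junction of the skeleton.

    Junction pixels that are mutually 8-adjacent are merged into a single
    node whose representative pixel is the member closest to the cluster
    centroid (ties broken in row-major order).  ``kind`` is ``"endpoint"``
    (exactly one skeleton neighbour), ``"junction"`` (≥3 neighbours, or
    8-adjacent to such a pixel), or ``"cycle"`` for the anchor pixel of an
    isolated loop with no junction.
    """

    id: int
    kind: str
    pixel: tuple[int, int]
    pixels: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class VesselBranch:
    """Ordered pixel path between two nodes (possibly coincident)."""

    id: int
    path: np.ndarray            # (n, 2) int pixel coordinates, consecutive 8-neighbours
    nodes: tuple[int, int]      # end node ids
    geodesic_mm: float
    chord_mm: float
    arc_mm: float
    sector: str | None = None   # filled by sector assignment


@dataclass
class SkeletonGraph:
    nodes: list[SkeletonNode]
    branches: list[VesselBranch]
    scale: float
    shape: tuple[int, int]
    image_id: str | None = None

    @property
    def n_junctions(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    def to_frames(self):
        """Export as (nodes, branches) pandas DataFrames for CSV output."""
        import pandas as pd
        nodes = pd.DataFrame(
            [{"node_id": n.id, "kind": n.kind, "row": n.pixel[0],
              "col": n.pixel[1], "n_pixels": len(n.pixels)}
             for n in self.nodes])
        branches = pd.DataFrame(
            [{"branch_id": b.id, "node_a": b.nodes[0], "node_b": b.nodes[1],
              "n_pixels": len(b.path), "geodesic_mm": b.geodesic_mm,
              "chord_mm": b.chord_mm, "arc_mm": b.arc_mm, "sector": b.sector}
             for b in self.branches])
        return nodes, branches

    def overlay(self) -> np.ndarray:
        """RGB raster for visual QC: branches green, junctions red,
        endpoints blue."""
        rgb = np.zeros(self.shape + (3,), dtype=np.uint8)
        for b in self.branches:
            rgb[b.path[:, 0], b.path[:, 1], 1] = 255
        for n in self.nodes:
            ch = 0 if n.kind == "junction" else 2
            for p in n.pixels:
                rgb[p[0], p[1]] = 0
                rgb[p[0], p[1], ch] = 255
        return rgb


def skeletonize(mask: VesselMask) -> Skeleton:
    """Topology-preserving thinning of a vessel mask to 1-px tracks."""
    if not mask.mask.any():
        warnings.warn("empty vessel mask; skeleton is empty")
        return Skeleton(np.zeros(mask.shape, bool), mask.scale)
    return Skeleton(_sk_skeletonize(mask.mask), mask.scale)


def geodesic_length(path: np.ndarray, scale: float = 1.0) -> float:
    """Chain-code length of an ordered pixel path, in mm.

    Each orthogonal step contributes ``scale`` and each diagonal step
    ``√2·scale``; a single-pixel path has length 0.  Consecutive pixels
    must be 8-adjacent.
    """
    p = np.asarray(path)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) == 0:
        raise ValueError("path must be an (n, 2) array of ≥1 pixels")
    if len(p) == 1:
        return 0.0
    d = np.abs(np.diff(p, axis=0))
    if (d.max(axis=1) != 1).any():
        raise ValueError("consecutive path pixels must be 8-adjacent")
    steps = np.where(d.sum(axis=1) == 2, _SQRT2, 1.0)
    return float(steps.sum() * scale)


def chord_length(path: np.ndarray, scale: float = 1.0) -> float:
    """Euclidean distance between the path's end pixels, in mm (0 for loops)."""
    p = np.asarray(path, dtype=float)
    return float(np.linalg.norm(p[-1] - p[0]) * scale)


def smooth_path_length(path: np.ndarray, scale: float = 1.0,
                       sigma: float = SMOOTH_SIGMA) -> float:
    """Length of the Gaussian-smoothed branch polyline, in mm.

    Interior coordinates are filtered with a 1-D Gaussian (σ in px); the
    end pixels are pinned so the smoothed polyline shares the branch's
    endpoints, which guarantees length ≥ chord.  Paths shorter than 5 px
    fall back to the chain-code length.
    """
    p = np.asarray(path, dtype=float)
    if len(p) < 5 or sigma <= 0:
        return geodesic_length(path, scale)
    sm = gaussian_filter1d(p, sigma, axis=0, mode="nearest")
    sm[0] = p[0]
    sm[-1] = p[-1]
    seg = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    return float(seg.sum() * scale)


def _neighbors(pix: tuple[int, int], inside: np.ndarray):
    r, c = pix
    h, w = inside.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and inside[rr, cc]:
                yield (rr, cc)


def build_graph(skel: Skeleton, image_id: str | None = None) -> SkeletonGraph:
    """Extract nodes (junction clusters, endpoints) and branches.

    Every skeleton pixel outside junction clusters belongs to exactly one
    branch path; branch paths include their terminal node pixels.  Isolated
    cycles with no junction become a single branch whose two end nodes
    coincide (a ``"cycle"`` node anchors them), so their chord is 0.
    """
    S = skel.pixels
    scale = skel.scale
    if not S.any():
        return SkeletonGraph([], [], scale, S.shape, image_id)

    deg = ndi.convolve(S.astype(int), _EIGHT, mode="constant") - S.astype(int)
    deg[~S] = 0

    junction_mask = S & (deg >= 3)
    labels, n_clusters = ndi.label(junction_mask, structure=_EIGHT)

    nodes: list[SkeletonNode] = []
    node_of: dict[tuple[int, int], int] = {}

    for lab in range(1, n_clusters + 1):
        member = [tuple(p) for p in np.argwhere(labels == lab)]
        member.sort()  # row-major; stabilizes tie-breaks
        centroid = np.mean(member, axis=0)
        rep = min(member, key=lambda p: (np.hypot(p[0] - centroid[0], p[1] - centroid[1]), p))
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "junction", rep, member))
        for p in member:
            node_of[p] = nid

    for p in map(tuple, np.argwhere(S & (deg == 1))):
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "endpoint", p, [p]))
        node_of[p] = nid

    # isolated single pixels (degree 0): endpoint node + 1-px branch
    isolated = [tuple(p) for p in np.argwhere(S & (deg == 0))]

    branches: list[VesselBranch] = []
    visited = np.zeros(S.shape, dtype=bool)  # interior (non-node) pixels consumed
    direct_pairs: set[frozenset] = set()

    def add_branch(path_list: list[tuple[int, int]], u: int, v: int) -> None:
        path = np.asarray(path_list, dtype=int)
        g = geodesic_length(path, scale)
        branches.append(VesselBranch(
            id=len(branches), path=path, nodes=(u, v),
            geodesic_mm=g, chord_mm=chord_length(path, scale),
            arc_mm=smooth_path_length(path, scale)))

    node_pixels = set(node_of)

    for node in nodes:
        for start in node.pixels:
            for q in _neighbors(start, S):
                if q in node_pixels:
                    u, v = node_of[start], node_of[q]
                    if u == v:
                        continue  # intra-cluster adjacency, not a branch
                    key = frozenset((start, q))
                    if key not in direct_pairs:
                        direct_pairs.add(key)
                        add_branch([start, q], u, v)
                    continue
                if visited[q]:
                    continue
                # walk through degree-2 pixels until the next node pixel
                path = [start, q]
                visited[q] = True
                prev, cur = start, q
                while True:
                    nxt = None
                    for nb in _neighbors(cur, S):
                        if nb == prev or (nb in node_pixels and nb == start and len(path) == 2):
                            continue
                        if nb in node_pixels:
                            nxt = nb
                            break
                        if not visited[nb]:
                            nxt = nb
                    if nxt is None:
                        # dead end without an endpoint node (should not occur
                        # on clean skeletons); terminate at the last pixel
                        u = node_of[start]
                        v = node_of.get(cur, u)
                        add_branch(path, u, v)
                        break
                    if nxt in node_pixels:
                        path.append(nxt)
                        add_branch(path, node_of[start], node_of[nxt])
                        break
                    visited[nxt] = True
                    path.append(nxt)
                    prev, cur = cur, nxt

    for p in isolated:
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "endpoint", p, [p]))
        node_of[p] = nid
        add_branch([p], nid, nid)

    # isolated cycles: degree-2 pixels not consumed by any branch
    remaining = S & (deg == 2) & ~visited
    for p in map(tuple, np.argwhere(remaining)):
        if visited[p]:
            continue
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "cycle", p, [p]))
        path = [p]
        visited[p] = True
        prev, cur = None, p
        while True:
            nxt = None
            for nb in _neighbors(cur, S):
                if nb == prev:
                    continue
                if nb == p and len(path) > 2:
                    nxt = p
                    break
                if not visited[nb] and deg[nb] == 2:
                    nxt = nb
                    break
            if nxt is None:
                break
            path.append(nxt)
            if nxt == p:
                break
            visited[nxt] = True
            prev, cur = cur, nxt
        add_branch(path, nid, nid)

    return SkeletonGraph(nodes, branches, scale, S.shape, image_id)


def prune_spurs(graph: SkeletonGraph, min_length_px: float) -> SkeletonGraph:
    """Drop endpoint branches shorter than ``min_length_px`` pixels.

    Intended for noisy masks; the default pipeline applies no pruning.
    """
    keep = []
    endpoint_ids = {n.id for n in graph.nodes if n.kind == "endpoint"}
    for b in graph.branches:
        is_spur = (b.nodes[0] in endpoint_ids) != (b.nodes[1] in endpoint_ids)
        if is_spur and b.geodesic_mm / graph.scale < min_length_px:
            continue
        keep.append(b)
    return SkeletonGraph(graph.nodes, keep, graph.scale, graph.shape, graph.image_id)
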