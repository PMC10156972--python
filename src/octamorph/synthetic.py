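"""Synthetic angiograms and cohorts with known ground truth.

Three generators provide a fully self-contained test surface for the
morphometry pipeline:

``gen_curve_image``
    renders a single parametric curve (line, L-path, semicircle, sinusoid)
    as a bright stroke and returns its analytic arc/chord tortuosity;
``gen_network_image``
    grows a seeded branching vessel network with a controllable wiggle
    (tortuosity), an avascular centre of known area/perimeter, and
    optional background/speckle noise;
``gen_cohort``
    draws per-eye, per-visit records from correlated normals (optionally
    log-normals for skewed metrics) whose moments default to the published
    iERM surgical cohort values, so the statistics stage can be exercised
    and calibrated against known effect sizes.

All randomness flows from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from skimage.morphology import dilation, disk

__all__ = [
    "CurveSpec",
    "NetworkSpec",
    "CohortSpec",
    "MetricMoments",
    "GroundTruth",
    "gen_curve_image",
    "gen_network_image",
    "gen_cohort",
    "default_cohort_spec",
    "control_cohort_spec",
    "IERM_MOMENTS",
    "CONTROL_MOMENTS",
]


# --------------------------------------------------------------------------
# published cohort moments (mean, SD) used as generator defaults
# --------------------------------------------------------------------------

#: iERM surgical group, macular zone and quadrants: (baseline, 3-month)
IERM_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "vt": ((1.1165, 0.0226), (1.0978, 0.0239)),
    "scp_vd": ((48.06, 5.96), (45.17, 4.11)),
    "dcp_vd": ((45.14, 6.43), (48.32, 4.86)),
    "faza": ((0.07, 0.10), (0.08, 0.05)),
    "fazp": ((1.04, 0.53), (1.17, 0.38)),
    "ai": ((1.25, 0.20), (1.19, 0.13)),
    "rt": ((359.93, 52.58), (298.24, 26.87)),
    "ms": ((22.27, 3.87), (22.79, 2.63)),
    "bcva": ((0.49, 0.38), (0.22, 0.26)),
    # per-quadrant VT
    "vt_T": ((1.0957, 0.0219), (1.1105, 0.1070)),
    "vt_S": ((1.0962, 0.0214), (1.0831, 0.0249)),
    "vt_N": ((1.0993, 0.0153), (1.0906, 0.0212)),
    "vt_I": ((1.0914, 0.0199), (1.0830, 0.0236)),
    # per-quadrant SCP VD
    "scp_vd_T": ((44.02, 6.18), (41.48, 4.75)),
    "scp_vd_S": ((47.72, 6.31), (44.56, 5.36)),
    "scp_vd_N": ((49.82, 7.26), (47.11, 4.68)),
    "scp_vd_I": ((47.57, 6.77), (43.98, 4.42)),
    # per-quadrant RT
    "rt_T": ((366.81, 76.93), (286.33, 30.33)),
    "rt_S": ((387.06, 74.05), (306.71, 29.51)),
    "rt_N": ((388.79, 56.41), (332.34, 28.68)),
    "rt_I": ((357.69, 78.07), (299.42, 28.97)),
    # per-quadrant MS
    "ms_T": ((22.52, 4.05), (22.46, 4.33)),
    "ms_S": ((22.00, 4.18), (23.61, 2.26)),
    "ms_N": ((22.27, 4.25), (22.98, 2.46)),
    "ms_I": ((22.43, 3.72), (22.72, 2.52)),
}

#: healthy control group, baseline only
CONTROL_MOMENTS: dict[str, tuple[float, float]] = {
    "vt": (1.1072, 0.0129),
    "scp_vd": (48.51, 3.76),
    "dcp_vd": (48.06, 5.37),
    "faza": (0.30, 0.11),
    "fazp": (2.12, 0.38),
    "ai": (1.12, 0.06),
    "rt": (284.44, 15.91),
    "ms": (26.18, 1.93),
    "bcva": (0.01, 0.04),
}


@dataclass
class GroundTruth:
    """Analytic truth attached to a generated raster."""

    tortuosity: float | None = None       # continuous arc/chord ratio (≥ 1)
    arc_mm: float | None = None
    chord_mm: float | None = None
    vessel_fraction: float | None = None  # clean-mask pixel fraction of raster
    faz_area_mm2: float | None = None
    faz_perimeter_mm: float | None = None
    mask: np.ndarray | None = None        # clean boolean vessel mask


# --------------------------------------------------------------------------
# parametric curves
# --------------------------------------------------------------------------

@dataclass
class CurveSpec:
    """One parametric curve rendered as a bright stroke.

    Geometry is given in mm in raster coordinates (row, col), row growing
    downward.  Supported kinds and their parameters:

    - ``line``: ``start`` → ``end``;
    - ``L``: ``start`` → ``corner`` → ``end`` (two segments);
    - ``semicircle``: upper half-circle of ``radius`` around ``center``,
      chord horizontal;
    - ``sinusoid``: ``n_periods`` periods of amplitude ``amplitude`` and
      wavelength ``period`` starting at ``start``, running horizontally.
    """

    kind: str
    shape: tuple[int, int] = (304, 304)
    scale: float = 6.0 / 304            # mm per pixel
    stroke_width: int = 3               # px
    start: tuple[float, float] | None = None
    end: tuple[float, float] | None = None
    corner: tuple[float, float] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None
    amplitude: float | None = None
    period: float | None = None
    n_periods: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("line", "L", "semicircle", "sinusoid"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.stroke_width < 1:
            raise ValueError("stroke width must be ≥ 1 px")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def _curve_points(spec: CurveSpec) -> tuple[np.ndarray, float, float]:
    """Dense (row, col) samples in mm plus analytic arc and chord (mm)."""
    if spec.kind == "line":
        p0, p1 = np.asarray(spec.start, float), np.asarray(spec.end, float)
        arc = chord = float(np.linalg.norm(p1 - p0))
        t = np.linspace(0, 1, _n_samples(arc, spec.scale))[:, None]
        pts = p0 + t * (p1 - p0)
    elif spec.kind == "L":
        p0 = np.asarray(spec.start, float)
        pc = np.asarray(spec.corner, float)
        p1 = np.asarray(spec.end, float)
        l1 = float(np.linalg.norm(pc - p0))
        l2 = float(np.linalg.norm(p1 - pc))
        arc = l1 + l2
        chord = float(np.linalg.norm(p1 - p0))
        t1 = np.linspace(0, 1, _n_samples(l1, spec.scale))[:, None]
        t2 = np.linspace(0, 1, _n_samples(l2, spec.scale))[:, None]
        pts = np.vstack([p0 + t1 * (pc - p0), pc + t2 * (p1 - pc)])
    elif spec.kind == "semicircle":
        c = np.asarray(spec.center, float)
        r = float(spec.radius)
        arc = np.pi * r
        chord = 2.0 * r
        t = np.linspace(0, np.pi, _n_samples(arc, spec.scale))
        pts = np.stack([c[0] - r * np.sin(t), c[1] + r * np.cos(t)], axis=1)
    else:  # sinusoid
        p0 = np.asarray(spec.start, float)
        a, lam, k = float(spec.amplitude), float(spec.period), float(spec.n_periods)
        length_x = k * lam
        w = 2.0 * np.pi / lam
        arc = quad(lambda x: np.sqrt(1.0 + (a * w * np.cos(w * x)) ** 2),
                   0.0, length_x, limit=200)[0]
        chord = length_x
        x = np.linspace(0, length_x, _n_samples(arc, spec.scale))
        pts = np.stack([p0[0] - a * np.sin(w * x), p0[1] + x], axis=1)
    return pts, float(arc), float(chord)


def _n_samples(length_mm: float, scale: float) -> int:
    # sampling step ≤ 0.25 px guarantees 8-connected rasterization
    return max(int(np.ceil(length_mm / scale / 0.25)) + 1, 2)


def gen_curve_image(spec: CurveSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a curve as a bright stroke on black; returns (uint8 raster, truth).

    The curve is densely sampled (step ≤ 0.25 px), rasterized, then
    dilated to the stroke width, which guarantees 8-connected continuity.
    The analytic tortuosity is the continuous arc length over the chord.
    A curve whose stroke would leave the raster raises ``ValueError``.
    """
    pts_mm, arc, chord = _curve_points(spec)
    pix = pts_mm / spec.scale
    r_stroke = (spec.stroke_width - 1) // 2
    h, w = spec.shape
    lo = pix.min(axis=0)
    hi = pix.max(axis=0)
    if (lo < r_stroke).any() or hi[0] > h - 1 - r_stroke or hi[1] > w - 1 - r_stroke:
        raise ValueError("curve (with stroke) exits the raster")

    mask = np.zeros(spec.shape, dtype=bool)
    ij = np.round(pix).astype(int)
    mask[ij[:, 0], ij[:, 1]] = True
    if r_stroke > 0:
        mask = dilation(mask, disk(r_stroke))

    truth = GroundTruth(tortuosity=arc / chord if chord > 0 else None,
                        arc_mm=arc, chord_mm=chord,
                        vessel_fraction=float(mask.mean()), mask=mask)
    return (mask.astype(np.uint8) * 255), truth


# --------------------------------------------------------------------------
# branching vessel networks
# --------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Seeded random branching network with an avascular centre.

    Walkers perform a persistent random walk: at each step the heading
    receives Gaussian jitter plus a sinusoidal wiggle whose amplitude
    (radians) maps monotonically to the achieved tortuosity.  Walkers die
    on leaving the raster, on entering the avascular disc, or after
    ``max_steps``; with probability ``branch_prob`` per step a walker
    spawns a child at ±(40–70)°.
    """

    seed: int = 0
    n_trees: int = 12
    branch_prob: float = 0.04
    step_px: float = 2.0
    jitter_deg: float = 6.0
    wiggle: float = 0.25                # radians of sinusoidal heading sway
    wiggle_period_px: float = 40.0
    avascular_radius_mm: float = 0.30
    background: int = 20                # 0–255 background level
    speckle_sd: float = 0.0             # Gaussian noise SD (gray levels)
    stroke_width: int = 3
    shape: tuple[int, int] = (304, 304)
    scale: float = 6.0 / 304
    max_steps: int = 190
    max_walkers: int = 140

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        half_width_mm = min(self.shape) / 2.0 * self.scale
        if self.avascular_radius_mm >= half_width_mm:
            raise ValueError("avascular radius must be smaller than the "
                             "image half-width")
        if self.n_trees < 0:
            raise ValueError("n_trees must be ≥ 0")


def gen_network_image(spec: NetworkSpec) -> tuple[np.ndarray, GroundTruth]:
    """Grow a reproducible vessel network; returns (uint8 raster, truth).

    The ground truth records the clean vessel mask and its pixel fraction,
    and the analytic area (πr²) and perimeter (2πr) of the avascular disc.
    A zero-tree spec returns an empty image with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    r_faz_px = spec.avascular_radius_mm / spec.scale
    r_stop = r_faz_px + (spec.stroke_width - 1) / 2.0 + 1.0

    mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_trees == 0:
        warnings.warn("degenerate spec (zero trees): empty image")
    else:
        walkers = []
        for _ in range(spec.n_trees):
            # roots on a ring well outside the avascular centre
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.55, 0.95) * min(h, w) / 2.0
            pos = np.array([cr + rad * np.sin(ang), cc + rad * np.cos(ang)])
            heading = rng.uniform(0, 2 * np.pi)
            walkers.append((pos, heading, rng.uniform(0, 2 * np.pi)))
        jitter = np.deg2rad(spec.jitter_deg)
        omega = 2 * np.pi * spec.step_px / spec.wiggle_period_px
        n_spawned = len(walkers)
        while walkers:
            pos, heading, phase = walkers.pop()
            for _ in range(spec.max_steps):
                heading = heading + jitter * rng.standard_normal() \
                    + spec.wiggle * np.sin(phase)
                phase += omega
                new = pos + spec.step_px * np.array([np.sin(heading), np.cos(heading)])
                if not (0 <= new[0] <= h - 1 and 0 <= new[1] <= w - 1):
                    break
                if np.hypot(new[0] - cr, new[1] - cc) < r_stop:
                    break
                # draw the segment densely
                n = max(int(np.ceil(spec.step_px / 0.25)) + 1, 2)
                seg = pos + np.linspace(0, 1, n)[:, None] * (new - pos)
                ij = np.round(seg).astype(int)
                mask[ij[:, 0], ij[:, 1]] = True
                pos = new
                if spec.branch_prob > 0 and n_spawned < spec.max_walkers \
                        and rng.random() < spec.branch_prob:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    child = heading + sign * np.deg2rad(rng.uniform(40, 70))
                    walkers.append((pos.copy(), child, rng.uniform(0, 2 * np.pi)))
                    n_spawned += 1
        r_stroke = (spec.stroke_width - 1) // 2
        if r_stroke > 0 and mask.any():
            mask = dilation(mask, disk(r_stroke))
        # enforce a clean avascular disc after dilation
        rows, cols = np.mgrid[0:h, 0:w]
        mask &= ((rows - cr) ** 2 + (cols - cc) ** 2) > r_faz_px ** 2

    img = np.full(spec.shape, float(spec.background))
    img[mask] = 255.0
    if spec.speckle_sd > 0:
        img = img + rng.normal(0.0, spec.speckle_sd, size=spec.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        vessel_fraction=float(mask.mean()),
        faz_area_mm2=float(np.pi * spec.avascular_radius_mm ** 2),
        faz_perimeter_mm=float(2 * np.pi * spec.avascular_radius_mm),
        mask=mask)
    return img, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class MetricMoments:
    """Marginal moments of one metric: (mean, SD) at baseline and follow-up.

    ``followup=None`` keeps the baseline moments at every visit.  With
    ``lognormal=True`` the metric is drawn from a log-normal whose mean
    and SD match the given moments exactly (for right-skewed quantities
    such as FAZ area).
    """

    baseline: tuple[float, float]
    followup: tuple[float, float] | None = None
    lognormal: bool = False

    def __post_init__(self) -> None:
        for pair in (self.baseline, self.followup):
            if pair is not None and not pair[1] > 0:
                raise ValueError("SDs must be positive")


@dataclass
class CohortSpec:
    """Sampling design for a synthetic per-eye, per-visit cohort.

    ``visit_rho`` is the within-eye correlation of a metric across visits
    (shared-factor construction, so the full correlation over
    metric × visit pairs is R_metrics ⊗ equicorr(ρ)); ``cross_corr`` is an
    optional metrics × metrics correlation matrix (default: identity).
    Intermediate visits use linearly interpolated moments.
    """

    n_eyes: int
    metrics: dict[str, MetricMoments]
    visit_rho: float = 0.5
    cross_corr: np.ndarray | None = None
    group: str = "iERM"
    visits: tuple[str, ...] = ("baseline", "1M", "3M")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be ≥ 1")
        if not 0.0 <= self.visit_rho <= 1.0:
            raise ValueError("inadmissible correlation: visit_rho must be "
                             "in [0, 1]")
        m = len(self.metrics)
        if self.cross_corr is not None:
            R = np.asarray(self.cross_corr, float)
            if R.shape != (m, m):
                raise ValueError("cross_corr must be metrics × metrics")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("inadmissible correlation matrix: must be "
                                 "symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("inadmissible correlation matrix: not "
                                 "positive semidefinite")


def _visit_moments(mom: MetricMoments, visits: tuple[str, ...]):
    base = mom.baseline
    follow = mom.followup if mom.followup is not None else mom.baseline
    out = []
    k = len(visits)
    for i in range(k):
        f = i / (k - 1) if k > 1 else 0.0
        out.append((base[0] + f * (follow[0] - base[0]),
                    base[1] + f * (follow[1] - base[1])))
    return out


def gen_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a cohort table: one row per (eye, visit), one column per metric.

    Standard-normal scores are generated as Z_v = √ρ·Z0 + √(1−ρ)·E_v with
    a shared per-eye factor Z0, so the within-eye correlation across
    visits is exactly ρ (and eyes with ρ = 1 repeat their scores exactly).
    Cross-metric correlation is applied to all score layers via the
    Cholesky factor of ``cross_corr``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    names = list(spec.metrics)
    m = len(names)
    n = spec.n_eyes
    k = len(spec.visits)

    if spec.cross_corr is not None:
        R = np.asarray(spec.cross_corr, float)
        evals, evecs = np.linalg.eigh(R)
        L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    else:
        L = None

    def draw_scores() -> np.ndarray:
        z = rng.standard_normal((n, m))
        return z @ L.T if L is not None else z

    z0 = draw_scores()
    rho = spec.visit_rho
    scores = [np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * draw_scores()
              for _ in range(k)]

    rows = []
    for j, name in enumerate(names):
        mom = spec.metrics[name]
        per_visit = _visit_moments(mom, spec.visits)
        cols = []
        for v in range(k):
            mean, sd = per_visit[v]
            z = scores[v][:, j]
            if mom.lognormal:
                if mean <= 0:
                    raise ValueError(f"lognormal metric {name!r} needs a "
                                     "positive mean")
                s2 = np.log(1.0 + (sd / mean) ** 2)
                mu = np.log(mean) - s2 / 2.0
                cols.append(np.exp(mu + np.sqrt(s2) * z))
            else:
                cols.append(mean + sd * z)
        rows.append(cols)

    records = []
    for i in range(n):
        for v, visit in enumerate(spec.visits):
            rec = {"eye_id": f"{spec.group}-{i:03d}", "group": spec.group,
                   "visit": visit}
            for j, name in enumerate(names):
                rec[name] = rows[j][v][i]
            records.append(rec)
    return pd.DataFrame.from_records(records)


def default_cohort_spec(n_eyes: int = 41, visit_rho: float = 0.5,
                        seed: int | None = None,
                        metrics: list[str] | None = None) -> CohortSpec:
    """iERM surgical cohort spec with the published baseline/3M moments."""
    names = metrics if metrics is not None else list(IERM_MOMENTS)
    moms = {name: MetricMoments(*IERM_MOMENTS[name]) for name in names}
    return CohortSpec(n_eyes=n_eyes, metrics=moms, visit_rho=visit_rho,
                      group="iERM", seed=seed)


def control_cohort_spec(n_eyes: int = 41, seed: int | None = None) -> CohortSpec:
    """Healthy-control cohort spec (baseline visit only)."""
    moms = {name: MetricMoments(mom) for name, mom in CONTROL_MOMENTS.items()}
    return CohortSpec(n_eyes=n_eyes, metrics=moms, visit_rho=0.5,
                      group="control", visits=("baseline",), seed=seed)
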