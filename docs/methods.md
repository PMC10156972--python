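# Methods

## Scope and model

The package measures macular microvascular morphology from en-face OCTA
rasters and runs the group/visit/quadrant statistics of a pre/post
surgical cohort design.  Device-side steps (slab segmentation, retinal
thickness, the vendor's proprietary VD and FAZ tools) are out of scope:
retinal thickness enters as tabular input, while VD and FAZ are
re-implemented from the binarized vessel mask with explicitly documented
definitions, so absolute agreement with any vendor's numbers is not
claimed — only internal consistency and recovery of analytic ground
truth on synthetic data.

## Segmentation

The original workflow used an interactively trained pixel classifier,
which is neither published nor deterministic to retrain.  The default
segmenter here is *ridge-guided reconstruction*: Otsu's threshold is
applied twice, once to the raw intensities (candidate vessel pixels at
full calibre) and once to the multiscale Sato tubeness response
(centerline seeds, σ = 1, 2, 3 px); the mask keeps the 8-connected
candidate components that contain at least one seed.  This preserves
vessel width (Otsu on the ridge response alone thins strokes and loses
~25% of stroke pixels) while rejecting non-tubular bright speckle.  A
pure-Otsu fast path and a fixed threshold are available
(`--segmentation {ridge-otsu,otsu,fixed}`).  Otsu uses the full-image
256-bin histogram; the dark FAZ region therefore shifts the threshold
slightly, which is accepted for determinism.  Boundary convention:
`otsu` masks pixels strictly above the computed threshold (the upper
Otsu class), `fixed` masks pixels ≥ the user threshold.  Quality gating
(low signal strength) is a metadata flag, not image analysis.

## Skeleton graph and branch lengths

Masks are thinned with topology-preserving skeletonization.  Pixels with
≥3 skeleton neighbours are junction pixels; mutually 8-adjacent junction
pixels merge into one node (representative: member nearest the cluster
centroid, row-major tie-break).  Note that even a simple orthogonal
cross produces a 5-pixel junction cluster in 8-connectivity, because the
four arm-root pixels touch the centre diagonally; cluster-internal
contacts are node structure and carry no branch length.  Branches are
maximal paths through degree-2 pixels between node pixels; isolated
cycles become a single branch with coincident end nodes (chord 0).  No
spur pruning is applied by default (optional `--prune-spurs L`).

Each branch carries three lengths:

- `geodesic_mm` — chain code, 1 per orthogonal step, √2 per diagonal
  step (the convention of standard skeleton-analysis tools);
- `chord_mm` — Euclidean distance between the end pixels;
- `arc_mm` — length of the branch polyline smoothed with a 1-D Gaussian
  (σ = 2 px), end pixels pinned.

The tortuosity ratio uses `arc_mm` by default.  Rationale: the chain
code quantizes direction to 45° and therefore overestimates the length
of smooth digital curves by up to 8% (≈5.5% averaged over orientations);
measured on a rasterized semicircle of radius 60 px it yields VT 1.649
against the analytic π/2 ≈ 1.571, an error no increase in resolution
removes.  The σ = 2 px smoothed polyline recovers the semicircle to
0.1% and a one-period sinusoid oracle to 0.2%, while pinned endpoints
guarantee `arc ≥ chord`, hence VT ≥ 1, and collinear paths remain exact
(straight vessels measure VT = 1 to machine precision).  The raw chain
variant remains available (`method="chain"`); per-branch chain lengths
and chords are exact by construction and are what the L-path example
(VT = √2) asserts.  Zero-chord branches (closed loops) are excluded
from the VT sums and counted; a region with no usable branch reports
VT = None rather than a fabricated value.

## Sectors

The analysis zone is a 6-mm disc centred on the fovea (raster centre by
default, per-image override via `fovea_x`/`fovea_y`).  Quadrants are
bounded by the 45° diagonals and assigned by dominant axis:
`|Δrow| > |Δcol|` → superior/inferior, otherwise temporal/nasal, with
exact-diagonal pixels going to the horizontal quadrants and the centre
pixel to superior.  This partitions the disc exactly and is exactly
invariant under left-right mirroring with laterality flipped (a half-open
angular rule is not, because mirroring exchanges the two diagonals).
Temporal is left of centre for OD, right for OS; unknown laterality
falls back to OD with a warning.  Branches go to the quadrant holding
the majority of their path pixels (tie: the midpoint pixel's quadrant);
branches with <50% of pixels inside the disc are "outside".  No
disc-fovea axis rotation is applied.

## FAZ

The FAZ is the background connected component (4-connectivity, the dual
of 8-connected vessels) containing the fovea after morphological closing
of the vessel mask with a 3-px disc (configurable); this closing is the
deterministic stand-in for the device's proprietary FAZ tool.  Area is
pixel count × scale².  Perimeter is the 0.5-level marching-squares
contour length measured on the mask pre-smoothed with a Gaussian of
σ = 0.8 px: on binary rasters marching squares overestimates a digital
disc's perimeter by 6–8% (staircase bias), while with the 0.8-px
pre-smoothing a disc of radius 10–50 px measures within 1.3% and a
50-px square within 1.4% of 4s (its AI measuring 1.113 against the
analytic 2/√π ≈ 1.128).  Crofton-formula perimeters were rejected
because they underestimate axis-aligned shapes by ~6%.  Regions too
small for the smoothed field to reach 0.5 fall back to the binary
contour, keeping FAZp > 0 whenever FAZa > 0.

## Microperimetry grid and acuity

The 61-point grid is 1 central point plus 15 per quadrant; the vendor's
exact coordinates are unpublished, so the shipped default places 3
angles × 5 rings (2°–10° eccentricity) per quadrant, and any layout CSV
with the same membership structure is accepted — quadrant means depend
only on membership.  The centre point belongs to no quadrant
(61 = 1 + 4×15 forces this).  Overall MS is the mean of all 61 points;
missing values are excluded with a reported count.  Acuity converts as
logMAR = log₁₀(denominator/numerator).

## Statistics

All tests follow the classical definitions: Pearson chi-square on 2×2
tables *without* continuity correction (the corrected statistic does not
reproduce the reference p = 0.557 on the 8/33 vs 6/35 sex table; the
uncorrected one does); two-sided Wilcoxon signed-rank with zeros
dropped, exact enumeration for ≤25 informative untied pairs and the
tie-corrected normal approximation above; equal-variance Student t;
Kruskal–Wallis with tie correction for 2+ groups; Spearman's ρ with
average ranks and the t-approximation p; OLS on z-scored variables so
coefficients are standardized βs (invariant to predictor rescaling),
with adjusted R².  Missing data are handled complete-case per analysis
cell with logged exclusion counts, and no multiple-testing adjustment is
applied anywhere (raw p-values per cell; the report footnote states
this).  `run_study` emits the five standard tables: baseline group
comparison (t and rank p-values both reported, since which was used per
row in the reference design is not specified), paired baseline/3M
macular comparison, per-quadrant paired (P1) and cross-quadrant (P2)
comparisons, Spearman change correlations, and per-region standardized
regressions of ΔMS on ΔVT/ΔVD/ΔRT.

## Synthetic data

*Curves* are sampled parametrically at ≤0.25-px steps (guaranteeing an
8-connected rasterization), dilated to the stroke width, and carry their
continuous arc/chord ratio as ground truth.  *Networks* grow by a
persistent random walk: per 2-px step the heading receives Gaussian
jitter (6°) plus a sinusoidal sway whose amplitude (`wiggle`, default
0.25 rad over a 40-px period) maps monotonically — documented, not
calibrated — to the achieved tortuosity; walkers branch with probability
0.04/step at ±40–70°, die at the raster edge or at the avascular disc
(default radius 0.30 mm, matched to a small post-traction FAZ), and the
defaults (12 seed trees, 190 steps, ≤140 walkers) were chosen so the
clean mask's 6-mm-disc vessel density sits near 48%, the level reported
for superficial-plexus scans of this kind.  Optional constant background
and Gaussian speckle provide a segmentation challenge; physically
realistic OCTA decorrelation noise and 3-D vasculature are non-goals,
so segmentation fidelity on real angiograms is *not* demonstrated by
these tests — only metric-level fidelity given a faithful mask.

*Cohorts* draw per-eye, per-visit records with exact factor structure
`X_v = μ_v + σ_v(√ρ·Z₀ + √(1−ρ)·E_v)`: within-eye visit correlation
exactly ρ (default 0.5; ρ = 1 reproduces identical scores, so equal
moments give change exactly 0), optional cross-metric correlation via
the Cholesky factor of a user matrix (full structure R_m ⊗ equicorr(ρ)),
and ρ < 0 rejected as inadmissible for this construction.  Marginals are
normal with the published group moments as defaults (intermediate visits
linearly interpolated); a moment-matched log-normal option serves
right-skewed metrics such as FAZ area.  Normal marginals are acceptable
even where the real metrics are skewed because the downstream battery is
rank-based.  At the study size (41 eyes, ρ = 0.5) the default moments
imply a paired-change effect of d ≈ 0.8 for tortuosity and d ≈ 0.16 for
mean sensitivity, which is what the power checks exercise.

## Numerical choices and limitations

- All randomness flows from a single user-supplied seed per generator;
  identical seeds give bit-identical rasters and tables.
- Grayscale conversion is min–max to [0, 255]; a constant image maps to
  zero, and 8-bit single-channel input passes through unchanged.
- Degenerate inputs fail loudly: empty rasters, constant images under
  Otsu, zero marginals, constant samples, all-zero paired differences
  (flagged, no p-value), rank-deficient designs (collinear columns
  named).
- The problem sizes used by the validation suite and the acceptance
  script (304-px rasters, 41-eye cohorts, 200 power replicates, 2000
  null replicates) are the package's chosen validation conditions; the
  power figures quoted above are computed, not assumed.
- Equivalence with any interactively segmented reference masks cannot be
  claimed (the original classifier is unavailable); claims are limited
  to recovery of analytic truth on synthetic inputs.
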