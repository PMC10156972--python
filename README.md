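# octamorph

Quantitative morphometry of the macular microvasculature from en-face
OCT angiography (OCTA), with the cohort statistics used in pre/post
surgical studies of the idiopathic epiretinal membrane (iERM).

iERM traction distorts the retinal capillaries; after vitrectomy with
membrane peeling the vessels straighten and perfusion remodels.  This
package measures that remodeling from en-face angiograms and relates it
to visual function:

- **Vessel tortuosity (VT)** — the angiogram is binarized, thinned to
  1-px centerlines, and decomposed into a branch/node graph; per region
  `VT = Σ Lᵢ / Σ Cᵢ` where `Lᵢ` is the path length of branch *i* and `Cᵢ`
  the straight-line (chord) distance between its end nodes.  `VT = 1`
  means perfectly straight vessels.
- **Vessel density (VD)** — the vessel-pixel area fraction of a region
  (percent).
- **FAZ metrics** — foveal avascular zone area `FAZa` (mm²), sub-pixel
  perimeter `FAZp` (mm) and acircularity index
  `AI = FAZp / (2·√(π·FAZa))` (1 for a perfect circle).
- **Sectors** — a 6-mm circular macular zone split by the 45° diagonals
  into temporal/superior/nasal/inferior quadrants, with laterality-aware
  T/N labelling.
- **Function** — 61-point microperimetry mean sensitivity (overall and
  15 points per quadrant) and Snellen → logMAR acuity conversion.
- **Cohort statistics** — Shapiro–Wilk, chi-square (no continuity
  correction), Wilcoxon signed-rank (exact below 26 informative pairs),
  Student t, Kruskal–Wallis, Spearman rank correlation, and standardized
  multivariate OLS of ΔMS on ΔVT/ΔVD/ΔRT, assembled into the five
  standard report tables by `run_study`.

Everything is validated against synthetic inputs with analytic ground
truth: parametric curves of known arc/chord ratio, seeded branching
vessel networks with a known avascular centre, and simulated cohorts
with prescribed means, SDs and within-eye correlations.

## Worked example

```python
import octamorph as om

# render a semicircular vessel (analytic tortuosity = π/2) and measure it
img, truth = om.gen_curve_image(
    om.CurveSpec("semicircle", center=(3.5, 3.0), radius=1.5))
gray  = om.to_grayscale8(img)                 # 304×304, 6 mm field of view
mask  = om.segment_vessels(gray)              # ridge-guided Otsu
graph = om.build_graph(om.skeletonize(mask))
vt    = om.vessel_tortuosity(graph.branches, "all")
print(f"measured VT {vt.vt:.4f}  analytic {truth.tortuosity:.4f}")
# measured VT 1.5673  analytic 1.5708

# simulate a 41-eye surgical cohort with the published moments and test it
cohort = om.gen_cohort(om.default_cohort_spec(n_eyes=41, seed=7))
report = om.run_study(cohort)
print(report.tables["table2_paired_macular"].head(2).to_string(index=False))
# parameter       baseline             m3        p
#        vt 1.114 ± 0.0217 1.093 ± 0.0238 0.000001
#    scp_vd   49.87 ± 5.95    45.73 ± 4.2 0.000068
```

The paired VT reduction (here p ≈ 1e-6) reflects the simulated effect
size d ≈ 0.8 built into the generator's default baseline/3-month moments;
`scp_vd` behaves accordingly, while weak-effect metrics such as mean
sensitivity usually stay non-significant at n = 41.

A CLI mirrors the library: `octamorph simulate`, `octamorph run`,
`octamorph stats` (see `--help`).

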