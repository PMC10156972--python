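"""Cohort statistics: the study's full testing battery and table outputs.

Wraps the classical tests (Shapiro–Wilk, Pearson chi-square without
continuity correction, Wilcoxon signed-rank, Student t, Kruskal–Wallis,
Spearman rank correlation, standardized multivariate OLS) behind uniform
result objects, and orchestrates them over a cohort table into the five
report tables of a baseline-vs-follow-up surgical cohort analysis:

1. baseline group comparison (patients vs controls),
2. baseline vs 3-month paired comparison,
3. per-quadrant paired (P1) and cross-quadrant (P2) comparisons,
4. Spearman correlations of per-eye changes,
5. multivariate regression of ΔMS on ΔVT, ΔVD, ΔRT per region.

No multiple-testing adjustment is applied anywhere: the battery reports
raw per-cell p-values, and the report footnote says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RegressionResult",
    "StudyReport",
    "normality_check",
    "chi_square_2x2",
    "paired_compare",
    "unpaired_compare",
    "spearman_corr",
    "standardized_ols",
    "change_table",
    "run_study",
]

#: paired tests switch from exact enumeration to the tie-corrected normal
#: approximation above this many informative pairs
EXACT_LIMIT = 25


@dataclass
class TestResult:
    """Uniform container for a hypothesis-test outcome.

    ``pvalue`` is None when the test is degenerate (e.g. all paired
    differences zero), with the reason in ``note``.  ``direction`` is the
    sign of the effect (+1, -1 or 0) where meaningful.
    """

    name: str
    statistic: float | None
    pvalue: float | None
    n: int
    direction: int | None = None
    note: str = ""

    @property
    def degenerate(self) -> bool:
        return self.pvalue is None


@dataclass
class RegressionResult:
    """Standardized OLS fit: β per predictor on z-scored variables."""

    outcome: str
    predictors: list[str]
    beta: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    n: int


def normality_check(values) -> TestResult:
    """Shapiro–Wilk test of departure from normality (n ≥ 3)."""
    x = np.asarray(values, float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("Shapiro–Wilk requires n ≥ 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p), len(x))


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2×2 count table, df = 1, no continuity
    correction (Σ(O−E)²/E against χ²₁)."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult("chi-square", float(chi2), float(p), int(t.sum()))


def paired_compare(before, after) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; with ≤ 25 informative untied pairs the
    exact null enumeration is used, otherwise the normal approximation
    with tie correction.  All-zero differences yield a degenerate result
    (no p-value) rather than a fabricated one.
    """
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    informative = d[d != 0]
    n_inf = len(informative)
    if n_inf == 0:
        return TestResult("wilcoxon", None, None, len(d), 0,
                          "degenerate: all paired differences are zero")
    if n_inf < 5:
        raise ValueError("need ≥ 5 informative (nonzero) pairs")
    ranks = sps.rankdata(np.abs(informative))
    has_ties = len(np.unique(ranks)) < n_inf
    method = "exact" if (n_inf <= EXACT_LIMIT and not has_ties) else "approx"
    stat, p = sps.wilcoxon(informative, zero_method="wilcox", method=method)
    direction = int(np.sign(np.median(informative)))
    return TestResult("wilcoxon", float(stat), float(p), n_inf, direction,
                      f"method={method}")


def unpaired_compare(*groups, kind: str = "rank") -> TestResult:
    """Compare independent groups.

    ``kind="t"``: Student's two-sided equal-variance t-test (2 groups).
    ``kind="rank"``: Kruskal–Wallis H with tie correction (2+ groups;
    equivalent to a Mann–Whitney-style comparison for 2 groups).
    """
    gs = [np.asarray(g, float) for g in groups]
    gs = [g[~np.isnan(g)] for g in gs]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n ≥ 2")
    n = sum(len(g) for g in gs)
    if kind == "t":
        if len(gs) != 2:
            raise ValueError("t-test compares exactly two groups")
        if np.ptp(gs[0]) == 0 and np.ptp(gs[1]) == 0:
            raise ValueError("zero variance in both groups: t undefined")
        stat, p = sps.ttest_ind(gs[0], gs[1], equal_var=True)
        direction = int(np.sign(np.mean(gs[0]) - np.mean(gs[1])))
        return TestResult("t", float(stat), float(p), n, direction)
    if kind == "rank":
        pooled = np.concatenate(gs)
        if np.ptp(pooled) == 0:
            # all observations identical in every group: H is exactly 0
            return TestResult("kruskal-wallis", 0.0, 1.0, n, 0,
                              "all observations tied")
        stat, p = sps.kruskal(*gs)
        return TestResult("kruskal-wallis", float(stat), float(p), n)
    raise ValueError(f"unknown kind {kind!r}")


def spearman_corr(x, y) -> TestResult:
    """Spearman's rank correlation (average ranks for ties), two-sided p
    via the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("Spearman correlation requires n ≥ 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rs, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rs), float(p), len(x),
                      int(np.sign(rs)))


def standardized_ols(outcome, predictors: pd.DataFrame | dict,
                     outcome_name: str = "y") -> RegressionResult:
    """OLS on z-scored outcome and predictors.

    Reports the standardized β (raw coefficient × SD_x/SD_y by
    construction), per-coefficient two-sided p, and adjusted R².  A
    rank-deficient design raises, naming the collinear columns.
    """
    X = pd.DataFrame(predictors)
    y = np.asarray(outcome, float)
    if len(y) != len(X):
        raise ValueError("outcome and predictors must have equal length")
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y = y[keep]
    X = X.loc[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant predictor column(s): {bad}")
    if np.std(y, ddof=1) == 0:
        raise ValueError("constant outcome")
    Z = (X - X.mean()) / sds
    zy = (y - y.mean()) / np.std(y, ddof=1)

    r = np.linalg.matrix_rank(Z.to_numpy())
    if r < p:
        _, R = np.linalg.qr(Z.to_numpy())
        bad = [X.columns[i] for i in range(p) if abs(R[i, i]) < 1e-8 * n]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")

    model = sm.OLS(zy, sm.add_constant(Z)).fit()
    beta = {c: float(model.params[c]) for c in X.columns}
    pvals = {c: float(model.pvalues[c]) for c in X.columns}
    return RegressionResult(outcome_name, list(X.columns), beta, pvals,
                            float(model.rsquared_adj), n)


def change_table(cohort: pd.DataFrame, metrics: list[str] | None = None,
                 baseline: str = "baseline", followup: str = "3M") -> pd.DataFrame:
    """Per-eye changes (follow-up − baseline) for each metric.

    Eyes missing either visit are excluded; their ids and count are
    recorded in the returned frame's ``attrs`` under ``excluded_eyes``
    and ``n_excluded``.
    """
    df = pd.DataFrame(cohort)
    if metrics is None:
        metrics = [c for c in df.columns
                   if c not in ("eye_id", "group", "visit")
                   and pd.api.types.is_numeric_dtype(df[c])]
    b = df[df["visit"] == baseline].set_index("eye_id")
    f = df[df["visit"] == followup].set_index("eye_id")
    common = b.index.intersection(f.index)
    excluded = sorted(set(b.index).symmetric_difference(f.index))
    out = pd.DataFrame(index=common)
    for m in metrics:
        out[f"d_{m}"] = f.loc[common, m] - b.loc[common, m]
    out.attrs["n_excluded"] = len(excluded)
    out.attrs["excluded_eyes"] = excluded
    return out


# --------------------------------------------------------------------------
# study orchestration
# --------------------------------------------------------------------------

_MACULAR_METRICS = ["vt", "scp_vd", "dcp_vd", "faza", "fazp", "ai", "rt",
                    "ms", "bcva"]
_QUADRANT_METRICS = ["vt", "scp_vd", "rt", "ms"]
_QUADS = ("T", "S", "N", "I")


@dataclass
class StudyReport:
    """Bundle of report tables with the exclusions log and run parameters."""

    tables: dict[str, pd.DataFrame]
    exclusions: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in self.tables.items():
            tbl.to_csv(out / f"{name}.csv", index=False)
        (out / "report.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = ["Cohort morphometry study report", "=" * 34, ""]
        for name, tbl in self.tables.items():
            lines += [name, "-" * len(name), tbl.to_string(index=False), ""]
        if self.exclusions:
            lines += ["Exclusions:"] + [f"  - {e}" for e in self.exclusions]
        lines += ["", "Note: p-values are raw; no multiple-testing "
                  "adjustment is applied."]
        return "\n".join(lines)


def _fmt_mean_sd(values) -> str:
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    return f"{v.mean():.4g} ± {v.std(ddof=1):.3g}"


def _validate_cohort(df: pd.DataFrame) -> list[str]:
    errors = []
    if len(df) == 0:
        errors.append("cohort table is empty")
        return errors
    for col in ("eye_id", "group", "visit"):
        if col not in df.columns:
            errors.append(f"missing required column {col!r}")
    if errors:
        return errors
    bad_visits = set(df["visit"]) - {"baseline", "1M", "3M"}
    if bad_visits:
        errors.append(f"unknown visit labels: {sorted(bad_visits)}")
    metric_cols = [c for c in df.columns
                   if c not in ("eye_id", "group", "visit")
                   and pd.api.types.is_numeric_dtype(df[c])]
    if not metric_cols:
        errors.append("no numeric metric columns found")
    return errors


def run_study(cohort: pd.DataFrame, patient_group: str = "iERM",
              control_group: str = "control") -> StudyReport:
    """Run the full statistical battery on a cohort table.

    The table needs one row per (eye, visit) with columns ``eye_id``,
    ``group``, ``visit`` plus numeric metrics (macular metrics such as
    ``vt``, ``scp_vd``, ``rt``, ``ms`` and quadrant variants suffixed
    ``_T``/``_S``/``_N``/``_I``).  Emits the five report tables; every
    exclusion (missing visits, degenerate cells) is logged.
    """
    df = pd.DataFrame(cohort)
    errors = _validate_cohort(df)
    if errors:
        raise ValueError("invalid cohort table:\n  " + "\n  ".join(errors))

    exclusions: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    metric_cols = [c for c in df.columns
                   if c not in ("eye_id", "group", "visit")
                   and pd.api.types.is_numeric_dtype(df[c])]

    patients = df[df["group"] == patient_group]
    controls = df[df["group"] == control_group]
    base_p = patients[patients["visit"] == "baseline"]
    base_c = controls[controls["visit"] == "baseline"]

    # ---- table 1: baseline group comparison --------------------------------
    if len(base_c):
        rows = []
        for m in metric_cols:
            if m not in base_c.columns:
                continue
            a = base_p[m].dropna()
            b = base_c[m].dropna()
            if len(a) < 2 or len(b) < 2:
                exclusions.append(f"table1/{m}: insufficient data")
                continue
            row = {"parameter": m,
                   "patients": _fmt_mean_sd(a), "controls": _fmt_mean_sd(b)}
            try:
                row["p_t"] = unpaired_compare(a, b, kind="t").pvalue
            except ValueError as e:
                row["p_t"] = np.nan
                exclusions.append(f"table1/{m}: t-test skipped ({e})")
            try:
                row["p_rank"] = unpaired_compare(a, b, kind="rank").pvalue
            except ValueError as e:
                row["p_rank"] = np.nan
                exclusions.append(f"table1/{m}: rank test skipped ({e})")
            rows.append(row)
        tables["table1_baseline_groups"] = pd.DataFrame(rows)

    # ---- table 2: baseline vs 3M paired, macular metrics -------------------
    rows = []
    macular = [m for m in metric_cols
               if not m.endswith(tuple(f"_{q}" for q in _QUADS))]
    ch = change_table(patients, metrics=macular)
    if ch.attrs["n_excluded"]:
        exclusions.append(
            f"paired analyses: {ch.attrs['n_excluded']} eye(s) missing a "
            f"visit excluded: {ch.attrs['excluded_eyes']}")
    pb = patients[patients["visit"] == "baseline"].set_index("eye_id")
    pf = patients[patients["visit"] == "3M"].set_index("eye_id")
    paired_ids = pb.index.intersection(pf.index)
    for m in macular:
        b = pb.loc[paired_ids, m]
        f = pf.loc[paired_ids, m]
        row = {"parameter": m, "baseline": _fmt_mean_sd(b), "m3": _fmt_mean_sd(f)}
        try:
            res = paired_compare(b, f)
            row["p"] = res.pvalue
            if res.degenerate:
                exclusions.append(f"table2/{m}: {res.note}")
        except ValueError as e:
            row["p"] = np.nan
            exclusions.append(f"table2/{m}: paired test skipped ({e})")
        rows.append(row)
    tables["table2_paired_macular"] = pd.DataFrame(rows)

    # ---- table 3: quadrants ------------------------------------------------
    rows = []
    for m in _QUADRANT_METRICS:
        qcols = [f"{m}_{q}" for q in _QUADS]
        if not all(c in df.columns for c in qcols):
            continue
        for q in _QUADS:
            col = f"{m}_{q}"
            b = pb.loc[paired_ids, col]
            f = pf.loc[paired_ids, col]
            try:
                p1 = paired_compare(b, f).pvalue
            except ValueError as e:
                p1 = np.nan
                exclusions.append(f"table3/{col}: paired test skipped ({e})")
            rows.append({"parameter": m, "quadrant": q,
                         "baseline": _fmt_mean_sd(b), "m3": _fmt_mean_sd(f),
                         "p1": p1})
        for visit, frame in (("baseline", pb), ("3M", pf)):
            groups = [frame.loc[paired_ids, f"{m}_{q}"].dropna() for q in _QUADS]
            try:
                p2 = unpaired_compare(*groups, kind="rank").pvalue
            except ValueError as e:
                p2 = np.nan
                exclusions.append(f"table3/{m}@{visit}: cross-quadrant test "
                                  f"skipped ({e})")
            rows.append({"parameter": m, "quadrant": f"P2@{visit}",
                         "baseline": "", "m3": "", "p1": p2})
    tables["table3_quadrants"] = pd.DataFrame(rows)

    # ---- tables 4 & 5: change correlations and regressions -----------------
    regions = [("macular", "")] + [(q, f"_{q}") for q in _QUADS]
    ch_all = change_table(patients)
    rows4, rows5 = [], []
    for label, suffix in regions:
        ms_col = f"d_ms{suffix}"
        if ms_col not in ch_all.columns:
            continue
        predictors = {}
        for m in ("vt", "scp_vd", "rt"):
            c = f"d_{m}{suffix}"
            if c not in ch_all.columns:
                continue
            predictors[c] = ch_all[c]
            try:
                res = spearman_corr(ch_all[c], ch_all[ms_col])
                rows4.append({"quadrant": label, "parameter": f"{m} change",
                              "rs": res.statistic, "p": res.pvalue})
            except ValueError as e:
                exclusions.append(f"table4/{label}/{m}: correlation skipped ({e})")
        if len(predictors) >= 1:
            try:
                reg = standardized_ols(ch_all[ms_col], pd.DataFrame(predictors),
                                       outcome_name=ms_col)
                for i, (c, beta) in enumerate(reg.beta.items()):
                    rows5.append({"quadrant": label,
                                  "parameter": c.replace("d_", "") + " change",
                                  "std_beta": beta, "p": reg.pvalues[c],
                                  "adj_r2": reg.adj_r2 if i == 0 else np.nan})
            except ValueError as e:
                exclusions.append(f"table5/{label}: regression skipped ({e})")
    tables["table4_change_correlations"] = pd.DataFrame(rows4)
    tables["table5_change_regression"] = pd.DataFrame(rows5)

    return StudyReport(tables, exclusions,
                       params={"patient_group": patient_group,
                               "control_group": control_group,
                               "n_patient_eyes": int(base_p["eye_id"].nunique()),
                               "n_control_eyes": int(base_c["eye_id"].nunique())})
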