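import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octamorph import (change_table, chi_square_2x2, gen_cohort,
                       default_cohort_spec, control_cohort_spec,
                       normality_check, paired_compare, run_study,
                       spearman_corr, standardized_ols, unpaired_compare)

from .oracles import chi2_2x2_p, wilcoxon_exact_p


class TestNormality:
    def test_skewed_sample_rejected_reliably(self):
        hits = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).standard_normal(50))
            hits += normality_check(x).pvalue < 0.05
        assert hits >= 95

    def test_null_pvalues_uniform(self):
        ps = [normality_check(np.random.default_rng(s).standard_normal(50)).pvalue
              for s in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.001

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            normality_check([3.0] * 10)


class TestChiSquare:
    def test_identical_rows_no_association(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_perfect_association(self):
        assert chi_square_2x2([[20, 0], [0, 20]]).pvalue < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, (2, 2))
        assert chi_square_2x2(t).pvalue == pytest.approx(chi2_2x2_p(t),
                                                         abs=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestPairedCompare:
    def test_uniform_shift_strongly_significant(self):
        before = np.arange(20, dtype=float)
        res = paired_compare(before, before + 1.0)
        assert res.pvalue < 0.001
        assert res.direction == 1

    def test_identical_pairs_degenerate(self):
        x = np.arange(10, dtype=float)
        res = paired_compare(x, x)
        assert res.degenerate and res.pvalue is None

    def test_too_few_informative_pairs_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            paired_compare([1.0, 2, 3, 4], [2.0, 3, 4, 5])

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_mode_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        before = rng.normal(size=n)
        after = before + rng.normal(0.4, 1.0, size=n)
        res = paired_compare(before, after)
        assert "exact" in res.note
        oracle = wilcoxon_exact_p(after - before)
        assert abs(res.pvalue - oracle) < 1e-6

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=40)
        res = paired_compare(b, b + rng.normal(0.1, 1.0, size=40))
        assert "approx" in res.note


class TestUnpairedCompare:
    def test_identical_groups_rank(self):
        x = np.arange(10, dtype=float)
        res = unpaired_compare(x, x, kind="rank")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        assert unpaired_compare(a, b, kind="t").pvalue < 0.001
        assert unpaired_compare(a, b, kind="rank").pvalue < 0.001

    def test_four_identical_groups(self):
        g = [3.0] * 10
        res = unpaired_compare(g, g, g, g, kind="rank")
        assert res.statistic == 0.0

    def test_zero_variance_t_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            unpaired_compare([2.0] * 5, [2.0] * 5, kind="t")


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10, dtype=float)
        assert spearman_corr(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_null_correlation_stays_small(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rs = spearman_corr(rng.normal(size=41), rng.normal(size=41)).statistic
            hits += abs(rs) < 0.31
        assert hits >= 95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0] * 10, np.arange(10))


class TestStandardizedOLS:
    def test_dominant_predictor_beta_near_one(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"x1": rng.normal(size=200),
                          "x2": rng.normal(size=200)})
        y = 2.0 * x["x1"] + rng.normal(0, 1e-6, 200)
        res = standardized_ols(y, x)
        assert res.beta["x1"] == pytest.approx(1.0, abs=1e-3)
        assert res.beta["x2"] == pytest.approx(0.0, abs=1e-3)

    def test_single_predictor_equals_pearson_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = standardized_ols(y, pd.DataFrame({"x": x}))
        assert res.beta["x"] == pytest.approx(np.corrcoef(x, y)[0, 1],
                                              abs=1e-12)

    def test_rescaling_predictor_leaves_betas_unchanged(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = X["a"] - X["b"] + rng.normal(size=50)
        base = standardized_ols(y, X)
        scaled = standardized_ols(y, X.assign(a=X["a"] * 1000.0))
        for c in ("a", "b"):
            assert scaled.beta[c] == pytest.approx(base.beta[c], abs=1e-10)
            assert scaled.pvalues[c] == pytest.approx(base.pvalues[c], abs=1e-10)

    def test_null_adjusted_r2_not_positive_on_average(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"a": rng.normal(size=41),
                              "b": rng.normal(size=41)})
            vals.append(standardized_ols(rng.normal(size=41), X).adj_r2)
        assert np.mean(vals) < 0.02

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(ValueError, match="twice_a"):
            standardized_ols(rng.normal(size=30), X)


class TestChangeTable:
    def _cohort(self):
        rows = []
        for i in range(5):
            rows.append({"eye_id": f"e{i}", "group": "iERM",
                         "visit": "baseline", "vt": 1.12, "ms": 22.0})
            if i != 3:  # eye e3 misses its 3M visit
                rows.append({"eye_id": f"e{i}", "group": "iERM",
                             "visit": "3M", "vt": 1.10, "ms": 23.0})
        return pd.DataFrame(rows)

    def test_changes_and_exclusions(self):
        ch = change_table(self._cohort())
        assert len(ch) == 4
        assert ch.attrs["n_excluded"] == 1 and ch.attrs["excluded_eyes"] == ["e3"]
        assert ch["d_vt"].unique() == pytest.approx([-0.02])
        assert ch["d_ms"].unique() == pytest.approx([1.0])

    def test_identical_visits_zero_change(self):
        df = self._cohort()
        df.loc[df["visit"] == "3M", ["vt", "ms"]] = [1.12, 22.0]
        ch = change_table(df)
        assert (ch[["d_vt", "d_ms"]] == 0).all().all()


class TestRunStudy:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_study(pd.DataFrame())

    def test_schema_violations_itemized(self):
        with pytest.raises(ValueError, match="visit"):
            run_study(pd.DataFrame({"eye_id": ["a"], "group": ["iERM"],
                                    "visit": ["6M"], "vt": [1.1]}))

    def test_tables_have_expected_shape(self):
        pat = gen_cohort(default_cohort_spec(n_eyes=30, seed=21))
        ctl = gen_cohort(control_cohort_spec(n_eyes=30, seed=22))
        rep = run_study(pd.concat([pat, ctl], ignore_index=True))
        t1 = rep.tables["table1_baseline_groups"]
        assert set(ctl.columns) - {"eye_id", "group", "visit"} \
            <= set(t1["parameter"])
        t2 = rep.tables["table2_paired_macular"]
        assert {"vt", "ms", "bcva"} <= set(t2["parameter"])
        assert ((t2["p"].dropna() >= 0) & (t2["p"].dropna() <= 1)).all()
        t3 = rep.tables["table3_quadrants"]
        assert set(t3["parameter"]) == {"vt", "scp_vd", "rt", "ms"}
        t5 = rep.tables["table5_change_regression"]
        assert {"macular", "T", "S", "N", "I"} == set(t5["quadrant"])

    def test_detects_published_effect_pattern(self):
        # with the published moments, the paired VT change is strong
        # (d ≈ 0.8) and the MS change weak (d ≈ 0.16)
        pat = gen_cohort(default_cohort_spec(n_eyes=41, seed=7))
        rep = run_study(pat)
        t2 = rep.tables["table2_paired_macular"].set_index("parameter")
        assert t2.loc["vt", "p"] < 0.05

    def test_summary_mentions_no_adjustment(self):
        pat = gen_cohort(default_cohort_spec(n_eyes=10, seed=1,
                                             metrics=["vt", "ms"]))
        rep = run_study(pat)
        assert "no multiple-testing" in rep.summary()

    def test_missing_visit_logged(self):
        pat = gen_cohort(default_cohort_spec(n_eyes=10, seed=2,
                                             metrics=["vt", "ms"]))
        pat = pat[~((pat["eye_id"] == "iERM-000") & (pat["visit"] == "3M"))]
        rep = run_study(pat)
        assert any("missing a visit" in e for e in rep.exclusions)
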