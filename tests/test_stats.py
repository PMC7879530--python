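"""Statistical engine: normality, RM-ANOVA, post-hoc, paired t, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import wristmorph as wm
from wristmorph.stats import (
    ICC_FORMS,
    PairedRatings,
    icc,
    normality,
    paired_t,
    posthoc_pairwise,
    rm_anova_one_way,
    summarize_cohort,
)


def brute_force_rm_anova(m):
    """Independent sums-of-squares oracle via explicit loops."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_cond = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (m[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = sum(
        (m[i, j] - m[i, :].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return f, sps.f.sf(f, k - 1, (k - 1) * (n - 1))


def brute_force_icc(m, form):
    """Variance-components oracle: mean squares computed independently."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    ms_rows = k * sum((m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    ms_cols = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ss_err = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = sum(
        (m[i, j] - m[i].mean()) ** 2 for i in range(n) for j in range(k)
    ) / (n * (k - 1))
    if form == "oneway_1_1":
        return (ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within)
    if form == "twoway_consistency_3_1":
        return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


class TestNormality:
    def test_matches_scipy_reference(self, rng):
        x = rng.normal(size=63)
        w, p = normality(x)
        w_ref, p_ref = sps.shapiro(x)
        assert w == pytest.approx(w_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)
        assert w <= 1.0

    def test_constant_sample_rejected(self):
        with pytest.raises(wm.StatsError):
            normality(np.full(20, 3.0))

    def test_tiny_sample_rejected(self):
        with pytest.raises(wm.StatsError):
            normality(np.array([1.0, 2.0]))


class TestRMANOVA:
    def test_identical_conditions_give_f_zero(self, rng):
        col = rng.normal(size=12)
        m = np.column_stack([col, col, col])
        f, df1, df2, p = rm_anova_one_way(m)
        assert f == pytest.approx(0.0, abs=1e-20)
        assert (df1, df2) == (2, 22)

    def test_two_conditions_equal_squared_paired_t(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 15))
            f, _, _, p_f = rm_anova_one_way(np.column_stack([a, b]))
            t, _, p_t = paired_t(a, b)
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_toy_matrix_matches_brute_force_oracle(self):
        m = np.array([[3.0, 5.0, 4.0], [6.0, 7.0, 8.0], [2.0, 4.0, 3.0], [7.0, 9.0, 9.0]])
        f, df1, df2, p = rm_anova_one_way(m)
        f_ref, p_ref = brute_force_rm_anova(m)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(size=(10, 4))
        f, df1, df2, p = rm_anova_one_way(m)
        long = pd.DataFrame(
            {
                "y": m.ravel(),
                "subject": np.repeat(np.arange(10), 4),
                "cond": np.tile(np.arange(4), 10),
            }
        )
        ref = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-12)

    def test_incomplete_matrix_rejected(self):
        m = np.ones((5, 3))
        m[0, 0] = np.nan
        with pytest.raises(wm.StatsError):
            rm_anova_one_way(m)


class TestPosthoc:
    def test_identical_columns_all_corrected_p_one(self, rng):
        col = rng.normal(size=10)
        table = posthoc_pairwise(np.column_stack([col, col, col]))
        assert (table["p_corr"] == 1.0).all()

    def test_correction_monotone(self, rng):
        m = rng.normal(size=(15, 4))
        for correction in ("holm", "bonferroni"):
            table = posthoc_pairwise(m, correction=correction)
            assert (table["p_corr"] >= table["p_raw"] - 1e-15).all()

    def test_number_of_pairs(self, rng):
        table = posthoc_pairwise(rng.normal(size=(8, 4)), labels=list("abcd"))
        assert len(table) == 6
        assert table["pair"].iloc[0] == "a vs b"


class TestPairedT:
    def test_closed_form_example(self):
        b = np.zeros(3)
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = paired_t(a, b)
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), rel=1e-12)
        assert df == 2

    def test_sign_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 20))
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_zero_variance_differences_rejected(self, rng):
        a = rng.normal(size=10)
        with pytest.raises(wm.StatsError):
            paired_t(a, a + 5.0)


class TestICC:
    def test_perfect_agreement_gives_one(self, rng):
        a = rng.normal(size=12)
        pairs = PairedRatings(a, a.copy())
        for form in ICC_FORMS:
            assert icc(pairs, form=form).estimate == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_separates_consistency_from_agreement(self, rng):
        a = rng.normal(size=20)
        pairs = PairedRatings(a, a + 2.0)
        assert icc(pairs, form="twoway_consistency_3_1").estimate == pytest.approx(1.0, abs=1e-9)
        assert icc(pairs, form="twoway_agreement_2_1").estimate < 1.0

    def test_toy_table_matches_variance_components_oracle(self):
        # 6-subject table (classic inter-rater layout, two raters)
        m = np.array([[9.0, 2.0], [4.5, 4.0], [7.0, 6.0], [5.0, 3.0], [8.5, 7.0], [6.0, 5.5]])
        pairs = PairedRatings(m[:, 0], m[:, 1])
        for form in ICC_FORMS:
            assert icc(pairs, form=form).estimate == pytest.approx(
                brute_force_icc(m, form), abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.normal(size=25)
        b = 0.7 * a + rng.normal(scale=0.6, size=25)
        pairs = PairedRatings(a, b)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(25), 2),
                "rater": np.repeat(["A", "B"], 25),
                "y": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(data=long, targets="subject", raters="rater", ratings="y")
        ref = ref.set_index("Type")
        for form, ref_type in [
            ("oneway_1_1", "ICC(1,1)"),
            ("twoway_agreement_2_1", "ICC(A,1)"),
            ("twoway_consistency_3_1", "ICC(C,1)"),
        ]:
            res = icc(pairs, form=form)
            assert res.estimate == pytest.approx(float(ref.loc[ref_type, "ICC"]), abs=1e-9)
            ci_ref = ref.loc[ref_type, "CI95"]
            assert res.ci_low == pytest.approx(float(ci_ref[0]), abs=0.011)
            assert res.ci_high == pytest.approx(float(ci_ref[1]), abs=0.011)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(wm.StatsError):
            icc(PairedRatings(np.full(8, 1.0), np.full(8, 1.0)))

    def test_unknown_form_rejected(self, rng):
        a = rng.normal(size=10)
        with pytest.raises(wm.StatsError):
            icc(PairedRatings(a, a), form="icc_9_9")


class TestSummarizeCohort:
    @staticmethod
    def _metrics_df(rng, n=20):
        cases, _ = wm.sample_cohort(n, wm.GeneratorConfig(with_meshes=False), seed=77)
        rows = [
            wm.quick_case_metrics(plan, post, gt.scene_transform).to_dict()
            for plan, post, gt in cases
        ]
        return pd.DataFrame(rows)

    def test_means_and_sds_equal_two_pass_oracle(self, rng):
        df = self._metrics_df(rng)
        summary = summarize_cohort(df)
        for col in df.columns:
            mean = sum(df[col]) / len(df)
            sd = np.sqrt(sum((x - mean) ** 2 for x in df[col]) / (len(df) - 1))
            assert summary.means[col] == pytest.approx(mean, rel=1e-12)
            assert summary.sds[col] == pytest.approx(sd, rel=1e-12)

    def test_identical_cases_reported_with_diagnostics(self):
        row = {
            "d1": 0.0, "d2": 0.0, "d3": 0.0, "d_bary": 0.0,
            "area_plan": 160.0, "area_post": 160.0,
            "volar_tilt_plan": 10.0, "volar_tilt_post": 10.0,
            "radial_inclination_plan": 20.0, "radial_inclination_post": 20.0,
        }
        df = pd.DataFrame([row] * 6)
        summary = summarize_cohort(df)
        assert all(summary.means[k] == 0.0 for k in ("d1", "d2", "d3", "d_bary"))
        assert summary.diagnostics  # ICC / Shapiro degeneracies surfaced, not hidden
        assert not summary.icc_volar_tilt

    def test_report_serialises(self, rng):
        summary = summarize_cohort(self._metrics_df(rng))
        payload = summary.to_dict()
        assert set(payload["icc_volar_tilt"]) == set(ICC_FORMS)
        assert "Reduction reproducibility summary" in summary.to_markdown()
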