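"""Cohort-level reproducibility statistics.

The statistical layer mirrors standard practice for plan-versus-outcome
agreement studies: Shapiro-Wilk normality screening, a one-way
repeated-measures ANOVA over the four distance measures (three reference
points plus their barycenter) with post-hoc pairwise paired-t contrasts under
a family-wise correction, a paired t-test for the triangle plane area, and
single-rater intraclass correlation coefficients (Shrout-Fleiss forms) for
volar tilt and radial inclination between plan and post-op.

The RM-ANOVA and the ICC forms are computed from explicit mean squares; the
Shapiro-Wilk test and p-value machinery delegate to scipy, the family-wise
corrections to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import StatsError
from .metrics import CaseMetrics

__all__ = [
    "PairedRatings",
    "ICCResult",
    "CohortSummary",
    "normality",
    "rm_anova_one_way",
    "posthoc_pairwise",
    "paired_t",
    "icc",
    "summarize_cohort",
]

ICC_FORMS = ("oneway_1_1", "twoway_agreement_2_1", "twoway_consistency_3_1")


@dataclass(frozen=True)
class PairedRatings:
    """Paired measurements (plan vs post-op) for n subjects, same units."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).ravel()
        b = np.asarray(self.b, dtype=float).ravel()
        if len(a) != len(b):
            raise StatsError("paired ratings must have equal length")
        if len(a) < 3:
            raise StatsError("paired ratings need at least 3 subjects")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise StatsError("paired ratings must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.a, self.b])


@dataclass(frozen=True)
class ICCResult:
    form: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


def normality(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic W and p-value."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3:
        raise StatsError("Shapiro-Wilk requires n >= 3")
    if len(x) > 5000:
        raise StatsError("Shapiro-Wilk is unreliable for n > 5000")
    if np.ptp(x) == 0:
        raise StatsError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _validate_matrix(values: np.ndarray) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise StatsError("values must be a subjects x conditions matrix")
    n, k = m.shape
    if k < 2:
        raise StatsError("need at least 2 conditions")
    if n < 3:
        raise StatsError("need at least 3 subjects")
    if not np.isfinite(m).all():
        raise StatsError("values matrix contains missing or non-finite cells")
    return m


def rm_anova_one_way(values: np.ndarray) -> tuple[float, int, int, float]:
    """Classical one-way within-subject (repeated measures) ANOVA.

    *values* is an (n subjects, k conditions) matrix.  Returns
    ``(F, df1, df2, p)`` with ``df1 = k - 1`` and ``df2 = (k - 1)(n - 1)``;
    the error term is the subject-by-condition interaction.
    """
    m = _validate_matrix(values)
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_err = ss_err / df2
    eps = 1e-12 * max(ss_total, 1e-300)
    if ms_err <= eps:
        # residual variation exhausted: F is 0/0 when the condition effect is
        # also null, +inf when it is not
        f = 0.0 if ss_cond <= eps else np.inf
    else:
        f = (ss_cond / df1) / ms_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 2:
        raise StatsError("paired t requires two equal-length samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise StatsError("paired t undefined: zero variance of the differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def posthoc_pairwise(
    values: np.ndarray,
    correction: str = "holm",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """All pairwise paired-t contrasts between conditions with a family-wise
    correction ('holm' or 'bonferroni').  Returns a table with columns
    (pair, t, df, p_raw, p_corr)."""
    if correction not in ("holm", "bonferroni"):
        raise StatsError(f"unknown correction {correction!r}")
    m = _validate_matrix(values)
    k = m.shape[1]
    labels = labels if labels is not None else [f"c{j}" for j in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = m[:, i] - m[:, j]
            if np.allclose(d.std(ddof=1), 0.0):
                t, df, p = 0.0, m.shape[0] - 1, 1.0
            else:
                t, df, p = paired_t(m[:, i], m[:, j])
            rows.append({"pair": f"{labels[i]} vs {labels[j]}", "t": t, "df": df, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_corr"] = multipletests(table["p_raw"].to_numpy(), method=correction)[1]
    return table


def _two_way_mean_squares(m: np.ndarray) -> tuple[float, float, float, float]:
    """(MS_rows, MS_cols, MS_error, MS_within) for an n x k two-way layout
    with one observation per cell."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = (ss_cols + ss_err) / (n * (k - 1))
    return ms_rows, ms_cols, ms_err, ms_within


def icc(
    pairs: PairedRatings,
    form: str = "twoway_agreement_2_1",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-rater intraclass correlation (Shrout-Fleiss forms).

    Forms: ``oneway_1_1`` = ICC(1,1); ``twoway_agreement_2_1`` = ICC(2,1),
    two-way random effects, absolute agreement; ``twoway_consistency_3_1`` =
    ICC(3,1), two-way mixed, consistency.  The 95% CI and the F-test p-value
    follow the standard mean-squares formulas.
    """
    if form not in ICC_FORMS:
        raise StatsError(f"unknown ICC form {form!r}; choose one of {ICC_FORMS}")
    m = pairs.as_matrix()
    n, k = m.shape
    if n < 5:
        warnings.warn("ICC with fewer than 5 subjects is unstable", stacklevel=2)
    bms, jms, ems, wms = _two_way_mean_squares(m)
    scale = m.var()
    eps = 1e-12 * max(scale, 1e-300)
    ems = max(ems, 0.0)
    wms = max(wms, 0.0)
    if bms <= eps:
        raise StatsError("degenerate variance structure: no between-subject variance")

    fq = sps.f.ppf  # quantile helper

    def f_to_icc(f_bound: float) -> float:
        # perfect agreement sends the F bound to +inf; its ICC limit is 1
        return 1.0 if not np.isfinite(f_bound) else (f_bound - 1) / (f_bound + k - 1)

    if form == "oneway_1_1":
        denom = bms + (k - 1) * wms
        est = (bms - wms) / denom
        f_obs = bms / wms if wms > eps else np.inf
        df1, df2 = n - 1, n * (k - 1)
        fl = f_obs / fq(1 - alpha / 2, df1, df2)
        fu = f_obs * fq(1 - alpha / 2, df2, df1)
        ci = (f_to_icc(fl), f_to_icc(fu))
        p = float(sps.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0
    elif form == "twoway_consistency_3_1":
        est = (bms - ems) / (bms + (k - 1) * ems)
        f_obs = bms / ems if ems > eps else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / fq(1 - alpha / 2, df1, df2)
        fu = f_obs * fq(1 - alpha / 2, df2, df1)
        ci = (f_to_icc(fl), f_to_icc(fu))
        p = float(sps.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0
    else:  # twoway_agreement_2_1
        est = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
        # Shrout-Fleiss approximate CI via Satterthwaite df
        icc_hat = max(min(est, 1 - 1e-12), -1 + 1e-12)
        a = k * icc_hat / (n * (1 - icc_hat))
        b = 1 + k * icc_hat * (n - 1) / (n * (1 - icc_hat))
        v_num = (a * jms + b * ems) ** 2
        v_den = (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
        f_star = fq(1 - alpha / 2, n - 1, v)
        f_star_l = fq(1 - alpha / 2, v, n - 1)
        ci_low = n * (bms - f_star * ems) / (
            f_star * (k * jms + (k * n - k - n) * ems) + n * bms
        )
        ci_high = n * (f_star_l * bms - ems) / (
            k * jms + (k * n - k - n) * ems + n * f_star_l * bms
        )
        ci = (ci_low, ci_high)
        # significance against ICC = 0 via the subjects F test
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_obs = bms / ems if ems > eps else np.inf
        p = float(sps.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    return ICCResult(
        form=form,
        estimate=float(est),
        ci_low=float(min(ci)),
        ci_high=float(max(ci)),
        p_value=p,
    )


DISTANCE_COLUMNS = ("d1", "d2", "d3", "d_bary")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level report of the reduction-reproducibility analysis."""

    n: int
    means: dict
    sds: dict
    shapiro: dict  # metric -> (W, p)
    rm_anova: tuple  # (F, df1, df2, p) over (d1, d2, d3, d_bary)
    posthoc: pd.DataFrame
    paired_t_area: tuple  # (t, df, p)
    icc_volar_tilt: dict  # form -> ICCResult
    icc_radial_inclination: dict
    icc_form: str
    diagnostics: tuple = field(default=())

    def to_dict(self) -> dict:
        def icc_block(d):
            return {
                form: {
                    "estimate": r.estimate,
                    "ci95": [r.ci_low, r.ci_high],
                    "p": r.p_value,
                }
                for form, r in d.items()
            }

        return {
            "n": self.n,
            "means": self.means,
            "sds": self.sds,
            "shapiro_wilk": {k: {"W": w, "p": p} for k, (w, p) in self.shapiro.items()},
            "rm_anova_distances": dict(
                zip(("F", "df1", "df2", "p"), self.rm_anova)
            ),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "paired_t_area": dict(zip(("t", "df", "p"), self.paired_t_area)),
            "icc_form_selected": self.icc_form,
            "icc_volar_tilt": icc_block(self.icc_volar_tilt),
            "icc_radial_inclination": icc_block(self.icc_radial_inclination),
            "diagnostics": list(self.diagnostics),
        }

    def to_markdown(self) -> str:
        f, df1, df2, p = self.rm_anova
        t, tdf, tp = self.paired_t_area
        sel = self.icc_form
        lines = [
            "# Reduction reproducibility summary",
            f"Cases: {self.n}",
            "",
            "## Plan-to-post distances (mm)",
        ]
        for k in DISTANCE_COLUMNS:
            lines.append(f"- {k}: {self.means[k]:.2f} (SD {self.sds[k]:.2f})")
        lines += [
            "",
            f"RM-ANOVA over distances: F({df1},{df2}) = {f:.3f}, p = {p:.4g}",
            "",
            "## Post-hoc pairwise contrasts",
            self.posthoc.to_string(index=False),
            "",
            "## Plane area (mm²)",
            f"- plan: {self.means['area_plan']:.1f} (SD {self.sds['area_plan']:.1f})",
            f"- post: {self.means['area_post']:.1f} (SD {self.sds['area_post']:.1f})",
            f"- paired t: t({tdf}) = {t:.3f}, p = {tp:.4g}",
            "",
            "## Angles (degrees)",
            f"- volar tilt plan/post: {self.means['volar_tilt_plan']:.1f} / {self.means['volar_tilt_post']:.1f}",
            f"- radial inclination plan/post: {self.means['radial_inclination_plan']:.1f} / {self.means['radial_inclination_post']:.1f}",
            "",
            f"## ICC (selected form: {sel})",
        ]
        for label, block in (
            ("volar tilt", self.icc_volar_tilt),
            ("radial inclination", self.icc_radial_inclination),
        ):
            if sel in block:
                r = block[sel]
                lines.append(
                    f"- {label}: {r.estimate:.2f} (95% CI {r.ci_low:.2f}..{r.ci_high:.2f}, p = {r.p_value:.4g})"
                )
            else:
                lines.append(f"- {label}: not estimable (degenerate variance)")
        if self.diagnostics:
            lines += ["", "## Diagnostics"] + [f"- {d}" for d in self.diagnostics]
        return "\n".join(lines)


def summarize_cohort(
    metrics: list[CaseMetrics] | pd.DataFrame,
    icc_form: str = "twoway_agreement_2_1",
    correction: str = "holm",
) -> CohortSummary:
    """Aggregate per-case metrics into the full cohort report."""
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:
        df = pd.DataFrame([m.to_dict() for m in metrics])
    if len(df) < 3:
        raise StatsError("cohort summary requires at least 3 cases")

    numeric = [c for c in df.columns if df[c].dtype.kind in "fi"]
    means = {c: float(df[c].mean()) for c in numeric}
    sds = {c: float(df[c].std(ddof=1)) for c in numeric}

    diagnostics: list[str] = []
    shapiro: dict = {}
    for c in numeric:
        try:
            shapiro[c] = normality(df[c].to_numpy())
        except StatsError as exc:
            diagnostics.append(f"shapiro({c}): {exc}")

    dist = df[list(DISTANCE_COLUMNS)].to_numpy()
    anova = rm_anova_one_way(dist)
    posthoc = posthoc_pairwise(dist, correction=correction, labels=list(DISTANCE_COLUMNS))

    try:
        t_area = paired_t(df["area_post"].to_numpy(), df["area_plan"].to_numpy())
    except StatsError as exc:
        diagnostics.append(f"paired_t(area): {exc}")
        t_area = (float("nan"), len(df) - 1, float("nan"))

    def icc_all(col_a: str, col_b: str) -> dict:
        pairs_dict = {}
        try:
            pairs = PairedRatings(df[col_a].to_numpy(), df[col_b].to_numpy())
            for form in ICC_FORMS:
                pairs_dict[form] = icc(pairs, form=form)
        except StatsError as exc:
            diagnostics.append(f"icc({col_a} vs {col_b}): {exc}")
        return pairs_dict

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_vt = icc_all("volar_tilt_plan", "volar_tilt_post")
        icc_ri = icc_all("radial_inclination_plan", "radial_inclination_post")

    return CohortSummary(
        n=len(df),
        means=means,
        sds=sds,
        shapiro=shapiro,
        rm_anova=anova,
        posthoc=posthoc,
        paired_t_area=t_area,
        icc_volar_tilt=icc_vt,
        icc_radial_inclination=icc_ri,
        icc_form=icc_form,
        diagnostics=tuple(diagnostics),
    )
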