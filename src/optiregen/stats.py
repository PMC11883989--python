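"""Statistical tests shared by the quantification modules.

These are the standard procedures of the study design: normality screening
(Kolmogorov-Smirnov with estimated parameters), Brown-Forsythe equality of
variances, pooled two-tailed t, one-way ANOVA with Bonferroni post hoc,
two-way ANOVA with Fisher's LSD post hoc, and mixed (repeated-measures)
two-way ANOVA with Bonferroni post hoc.  Numerics are delegated to scipy,
statsmodels and pingouin; the contracts here (error behaviour on degenerate
designs, adjusted-p conventions) are what this package owns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import kstest_normal

__all__ = [
    "TestResult",
    "TwoWayResult",
    "normality_ks",
    "variance_bf",
    "t_two_tailed",
    "anova_oneway_bonferroni",
    "anova_twoway_lsd",
    "rm_anova_bonferroni",
    "bonferroni",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    df: tuple | None = None
    pairwise: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


@dataclass
class TwoWayResult:
    anova: pd.DataFrame
    lsd: pd.DataFrame
    mse: float
    df_resid: int
    method: str = "two-way ANOVA + Fisher LSD"


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, m * p)."""
    return min(1.0, float(p) * m)


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise ValueError("input contains NaN")
    return a


def normality_ks(sample) -> TestResult:
    """One-sample KS test against a normal with the sample mean and SD
    (Lilliefors-corrected p-value)."""
    x = _as1d(sample)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = kstest_normal(x, dist="norm")
    return TestResult(float(stat), float(min(p, 1.0)),
                      "KS normality (Lilliefors)")


def variance_bf(*groups) -> TestResult:
    """Brown-Forsythe (median-centred Levene) equality-of-variances test."""
    gs = [_as1d(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    stat, p = sps.levene(*gs, center="median")
    k = len(gs)
    n = sum(g.size for g in gs)
    return TestResult(float(stat), float(p), "Brown-Forsythe",
                      df=(k - 1, n - k))


def t_two_tailed(a, b) -> TestResult:
    """Pooled-variance two-sample two-tailed Student's t-test."""
    x, y = _as1d(a), _as1d(b)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    stat, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(stat), float(p), "two-tailed t (pooled)",
                      df=(x.size + y.size - 2,))


def anova_oneway_bonferroni(*groups) -> TestResult:
    """One-way ANOVA; pairwise pooled t-tests with Bonferroni adjustment."""
    gs = [_as1d(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    stat, p = sps.f_oneway(*gs)
    pairs = list(itertools.combinations(range(len(gs)), 2))
    rows = []
    for i, j in pairs:
        t, pp = sps.ttest_ind(gs[i], gs[j], equal_var=True)
        rows.append({"group_i": i, "group_j": j, "t": float(t),
                     "p": float(pp), "adjusted_p": bonferroni(pp, len(pairs))})
    k = len(gs)
    n = sum(g.size for g in gs)
    return TestResult(float(stat), float(p), "one-way ANOVA + Bonferroni",
                      df=(k - 1, n - k), pairwise=pd.DataFrame(rows))


def anova_twoway_lsd(values, factor_a, factor_b) -> TwoWayResult:
    """Two-way fixed-effects ANOVA with interaction; Fisher LSD post hoc.

    The LSD table compares the levels of ``factor_a`` pairwise within each
    level of ``factor_b`` using unadjusted t statistics built on the ANOVA
    mean squared error (columns ``level_b``, ``a1``, ``a2``, ``t``, ``p``).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = _as1d(values)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    df = pd.DataFrame({"y": y, "a": fa.astype(str), "b": fb.astype(str)})
    cell_sizes = df.groupby(["a", "b"]).size()
    if (cell_sizes < 2).any():
        raise ValueError("interaction model needs >= 2 observations per "
                         "cell (single observation per cell is degenerate)")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(table.loc["Residual", "sum_sq"]
                / table.loc["Residual", "df"])
    df_resid = int(table.loc["Residual", "df"])
    rows = []
    # keep factor-b levels in order of first appearance (positions, dpi, ...)
    b_levels = list(dict.fromkeys(df["b"]))
    a_levels = sorted(df["a"].unique())
    for bl in b_levels:
        sub = df[df["b"] == bl]
        for a1, a2 in itertools.combinations(a_levels, 2):
            g1 = sub.loc[sub["a"] == a1, "y"]
            g2 = sub.loc[sub["a"] == a2, "y"]
            se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
            t = (g1.mean() - g2.mean()) / se
            p = 2 * sps.t.sf(abs(t), df_resid)
            rows.append({"level_b": bl, "a1": a1, "a2": a2,
                         "t": float(t), "p": float(p)})
    return TwoWayResult(anova=table, lsd=pd.DataFrame(rows), mse=mse,
                        df_resid=df_resid)


def rm_anova_bonferroni(data: pd.DataFrame, dv: str, subject: str,
                        within: str, between: str) -> TestResult:
    """Mixed two-way ANOVA (within x between) with Bonferroni post hoc.

    Complete cases only: every subject must be observed at every within
    level (no imputation).  Post hoc: pooled two-sample t between the two
    groups at each within level, Bonferroni-multiplied by the number of
    within levels.  No sphericity correction is applied.
    """
    import pingouin as pg

    for col in (dv, subject, within, between):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data[dv].isna().any():
        raise ValueError("missing values in the response (no imputation)")
    levels = sorted(data[within].unique())
    counts = data.groupby(subject)[within].nunique()
    if (counts != len(levels)).any():
        raise ValueError("incomplete subjects: every subject must be "
                         "observed at every within level (no imputation)")
    dup = data.groupby([subject, within]).size()
    if (dup != 1).any():
        raise ValueError("each (subject, within level) must appear once")
    groups = data.groupby(subject)[between].first()
    if groups.value_counts().min() < 2 or groups.nunique() < 2:
        raise ValueError("need at least 2 subjects in each of 2 groups")

    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between)
    inter = aov.loc[aov["Source"] == "Interaction"]
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    stat = float(inter["F"].iloc[0])
    p = float(inter[pcol].iloc[0])
    glabels = sorted(data[between].unique())
    rows = []
    for lv in levels:
        sub = data[data[within] == lv]
        g1 = sub.loc[sub[between] == glabels[0], dv]
        g2 = sub.loc[sub[between] == glabels[1], dv]
        t, pp = sps.ttest_ind(g1, g2, equal_var=True)
        rows.append({"level": lv, "t": float(t), "p": float(pp),
                     "adjusted_p": bonferroni(pp, len(levels))})
    return TestResult(stat, p, "RM two-way ANOVA + Bonferroni",
                      pairwise=pd.DataFrame(rows),
                      notes={"anova": aov, "sphericity_correction": "none"})
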