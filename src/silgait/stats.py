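"""Evaluation statistics for scaling quality and genotype effects.

Three layers of analysis:

* Pearson correlations between a body-size factor and each (scaled) gait
  parameter — a good scaling removes the correlation;
* one-way repeated-measures ANOVA over age points (within-subject) and
  mixed ANOVA with genotype as the between-subject factor; within-subject
  p values are additionally reported with the most conservative sphericity
  correction, the lower bound ε = 1/(k−1), which reduces the numerator
  degrees of freedom of a within effect to its between-levels count;
* per-age-point two-sample t tests with Bonferroni correction, summarised
  as signed −log10(p) heat-map tables (positive when the transgenic group
  is higher).

Within-subject analyses use complete cases only: animals measured at every
age point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ParameterError

#: display floor for vanishingly small p values (comparison logic is never floored)
P_DISPLAY_FLOOR = 1e-300


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p_unadjusted: float
    p_lower_bound: float | None = None  # within-subject effects only


@dataclass(frozen=True)
class PostHocTable:
    """Per-age-point transgenic-vs-wildtype comparisons.

    ``sign`` is the direction of (test group − control group); untestable
    cells (a group with fewer than two animals) carry NaN."""

    parameter: str
    ages: tuple[float, ...]
    mean_diff: tuple[float, ...]
    p_raw: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    sign: tuple[float, ...]
    test_group: str
    control_group: str


@dataclass
class LongitudinalDataset:
    """Animal × age-point table with a genotype column.

    ``data`` must carry one row per animal per age point with at least the
    ``subject``, ``within`` and ``between`` columns plus parameter columns.
    """

    data: pd.DataFrame
    subject: str = "animal_id"
    within: str = "age"
    between: str = "genotype"

    @property
    def ages(self) -> tuple[float, ...]:
        return tuple(sorted(self.data[self.within].unique()))

    def complete_cases(self) -> "LongitudinalDataset":
        """Restrict to animals present at all age points."""
        ages = set(self.ages)
        counts = self.data.groupby(self.subject)[self.within].apply(
            lambda s: set(s) == ages
        )
        keep = counts[counts].index
        return LongitudinalDataset(
            self.data[self.data[self.subject].isin(keep)].copy(),
            subject=self.subject, within=self.within, between=self.between,
        )

    def pivot(self, parameter: str) -> pd.DataFrame:
        """Subjects × age points matrix of one parameter (complete cases)."""
        wide = self.complete_cases().data.pivot_table(
            index=self.subject, columns=self.within, values=parameter
        )
        return wide.sort_index(axis=1)

    def genotype_of(self) -> pd.Series:
        return (
            self.data.drop_duplicates(self.subject)
            .set_index(self.subject)[self.between]
        )


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def pearson_with_p(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided p value from the exact
    t reference distribution on n−2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n=n)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def _f_p(F: float, dfn: float, dfd: float) -> float:
    if not np.isfinite(F):
        return 0.0
    return float(sps.f.sf(F, dfn, dfd))


def repeated_measures_anova(values) -> AnovaResult:
    """One-way within-subject ANOVA on a complete subjects × levels matrix.

    F = MS_levels / MS_(levels × subject); the lower-bound-adjusted p uses
    ε = 1/(k−1), i.e. reference dfs (1, n−1).
    """
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise DesignError("expected a 2-D subjects × levels matrix")
    if np.isnan(values).any():
        raise DesignError("matrix has missing cells; within-subject "
                          "analysis needs complete cases")
    n, k = values.shape
    if n < 2 or k < 2:
        raise DesignError(f"need >=2 subjects and >=2 levels, got {n}x{k}")
    grand = values.mean()
    ss_subj = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_time = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_time
    df_time = k - 1
    df_err = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    if ms_time <= 0:
        F = 0.0
    elif ms_err <= 0:
        F = np.inf
    else:
        F = float(ms_time / ms_err)
    eps = 1.0 / (k - 1)
    return AnovaResult(
        effect="age",
        F=F,
        df_num=df_time,
        df_den=df_err,
        p_unadjusted=_f_p(F, df_time, df_err),
        p_lower_bound=_f_p(F, eps * df_time, eps * df_err),
    )


def mixed_anova(dataset: LongitudinalDataset, parameter: str) -> list[AnovaResult]:
    """Mixed (split-plot) ANOVA: genotype (between) × age (within).

    Returns results for the age effect, the genotype × age interaction
    (both tested against the within-subject error and also reported with
    the lower-bound adjustment) and the genotype effect (tested against
    between-subject variation).  Complete cases only.
    """
    cc = dataset.complete_cases()
    wide = cc.pivot(parameter)
    geno = cc.genotype_of().loc[wide.index]
    groups = sorted(geno.unique())
    if len(groups) < 2:
        raise DesignError(f"need >=2 genotype groups, got {groups}")
    sizes = geno.value_counts()
    if (sizes < 2).any():
        raise DesignError(f"each group needs >=2 complete-case animals: {dict(sizes)}")

    y = wide.to_numpy(float)
    n_total, k = y.shape
    g = len(groups)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_geno = 0.0
    ss_cells = 0.0
    for lab in groups:
        sel = (geno == lab).to_numpy()
        n_g = sel.sum()
        ss_geno += k * n_g * (y[sel].mean() - grand) ** 2
        ss_cells += n_g * np.sum((y[sel].mean(axis=0) - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_geno
    ss_time = n_total * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_inter = ss_cells - ss_geno - ss_time
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_between_subj - ss_time - ss_inter

    df_geno = g - 1
    df_subj = n_total - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (n_total - g) * (k - 1)
    eps = 1.0 / (k - 1)

    def _ratio(ss_num, df_num, ss_den, df_den):
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        if ms_num <= 0:
            return 0.0
        if ms_den <= 0:
            return np.inf
        return float(ms_num / ms_den)

    f_time = _ratio(ss_time, df_time, ss_err, df_err)
    f_inter = _ratio(ss_inter, df_inter, ss_err, df_err)
    f_geno = _ratio(ss_geno, df_geno, ss_subj_within, df_subj)

    return [
        AnovaResult("age", f_time, df_time, df_err,
                    _f_p(f_time, df_time, df_err),
                    _f_p(f_time, eps * df_time, eps * df_err)),
        AnovaResult("genotype * age", f_inter, df_inter, df_err,
                    _f_p(f_inter, df_inter, df_err),
                    _f_p(f_inter, eps * df_inter, eps * df_err)),
        AnovaResult("genotype", f_geno, df_geno, df_subj,
                    _f_p(f_geno, df_geno, df_subj), None),
    ]


# --------------------------------------------------------------------------
# post hoc comparisons and heat maps
# --------------------------------------------------------------------------

def bonferroni_posthoc(
    dataset: LongitudinalDataset,
    parameter: str,
    test_group: str = "TG",
    control_group: str = "WT",
    equal_var: bool = True,
) -> PostHocTable:
    """Per-age-point two-sided two-sample t tests (pooled variance by
    default) of test group vs control group, Bonferroni-corrected over the
    number of age points.  Cells where either group has fewer than two
    animals are flagged untestable (NaN)."""
    df = dataset.data
    for lab in (test_group, control_group):
        if lab not in set(df[dataset.between]):
            raise DesignError(f"group {lab!r} absent from dataset")
    ages = dataset.ages
    m = len(ages)
    mean_diff, p_raw, p_adj, sign = [], [], [], []
    for age in ages:
        sub = df[df[dataset.within] == age]
        a = sub.loc[sub[dataset.between] == test_group, parameter].dropna().to_numpy()
        b = sub.loc[sub[dataset.between] == control_group, parameter].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            mean_diff.append(np.nan)
            p_raw.append(np.nan)
            p_adj.append(np.nan)
            sign.append(np.nan)
            continue
        diff = float(a.mean() - b.mean())
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # identical constant groups: no evidence of difference
        else:
            p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
        mean_diff.append(diff)
        p_raw.append(p)
        p_adj.append(min(1.0, p * m))
        sign.append(float(np.sign(diff)))
    return PostHocTable(
        parameter=parameter, ages=ages,
        mean_diff=tuple(mean_diff), p_raw=tuple(p_raw),
        p_adjusted=tuple(p_adj), sign=tuple(sign),
        test_group=test_group, control_group=control_group,
    )


def heatmap_table(posthocs: list[PostHocTable]) -> pd.DataFrame:
    """Signed-significance matrix: −log10(adjusted p) with positive sign
    when the test (transgenic) group is higher than control, negative when
    lower; 0 when p = 1; NaN for untestable cells."""
    if not posthocs:
        raise DesignError("no post hoc tables given")
    ages = posthocs[0].ages
    rows = {}
    for t in posthocs:
        if t.ages != ages:
            raise DesignError("post hoc tables cover different age points")
        vals = []
        for p, s in zip(t.p_adjusted, t.sign):
            if np.isnan(p):
                vals.append(np.nan)
            else:
                p_f = max(p, P_DISPLAY_FLOOR)
                vals.append(0.0 if p >= 1.0 else -s * np.log10(p_f))
        rows[t.parameter] = vals
    df = pd.DataFrame(rows, index=list(ages)).T
    df.index.name = "parameter"
    df.columns.name = "age"
    return df


def plot_heatmap(table: pd.DataFrame, path: str) -> None:
    """Export the signed heat map as a figure (blue = transgenic lower,
    red = transgenic higher).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.nanmax(np.abs(table.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.8 * table.shape[1], 0.8 + 0.4 * table.shape[0])
    )
    im = ax.imshow(table.to_numpy(), cmap="bwr", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(table.shape[1]), [str(c) for c in table.columns])
    ax.set_yticks(range(table.shape[0]), list(table.index))
    ax.set_xlabel("age (weeks)")
    fig.colorbar(im, ax=ax, label="signed -log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
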