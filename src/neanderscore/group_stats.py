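"""Assumption-gated group comparisons, post hocs and two-factor ANCOVA.

The dispatch rule: Shapiro-Wilk normality per group and Brown-Forsythe
(median-centered Levene) homogeneity across groups, both at alpha = 0.05.
All groups normal with equal variances -> pooled t (two groups) or one-way
ANOVA + Tukey HSD (three or more); normal with unequal variances -> Welch
t; any non-normal group -> Mann-Whitney U or Kruskal-Wallis +
Games-Howell.  Effect size is classical eta-squared for ANOVA and
eta2_H = (H - k + 1)/(n - k) for Kruskal-Wallis.  Shapiro-Wilk is capped
at n = 5,000 by seeded subsampling (the test is undefined/overpowered
beyond that).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .enrichment import bh_adjust, carrier_contingency

ALPHA_ASSUME_DEFAULT = 0.05
SHAPIRO_CAP = 5000
_SHAPIRO_SUBSAMPLE_SEED = 1729


class StatsError(ValueError):
    pass


@dataclass
class AssumptionReport:
    shapiro_p: list[float]
    levene_p: float
    all_normal: bool
    equal_variance: bool


@dataclass
class GroupTestResult:
    test_name: str  # pooled_t | welch_t | mann_whitney | anova | kruskal
    statistic: float
    df: float | tuple | None
    p_value: float
    effect_size: float | None
    assumption_report: AssumptionReport
    posthoc: list[tuple[tuple, float, float]] = field(default_factory=list)
    group_means: list[float] = field(default_factory=list)
    group_sds: list[float] = field(default_factory=list)
    group_ns: list[int] = field(default_factory=list)


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) > SHAPIRO_CAP:
        rng = np.random.default_rng(_SHAPIRO_SUBSAMPLE_SEED)
        x = rng.choice(x, size=SHAPIRO_CAP, replace=False)
    if np.ptp(x) == 0:
        return 0.0  # constant sample: treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def check_assumptions(groups: Sequence[np.ndarray],
                      alpha: float = ALPHA_ASSUME_DEFAULT) -> AssumptionReport:
    shapiro = [_shapiro_p(g) for g in groups]
    levene = float(stats.levene(*groups, center="median").pvalue)
    return AssumptionReport(
        shapiro_p=shapiro,
        levene_p=levene,
        all_normal=all(p >= alpha for p in shapiro),
        equal_variance=levene >= alpha,
    )


def _summaries(groups):
    return ([float(np.mean(g)) for g in groups],
            [float(np.std(g, ddof=1)) for g in groups],
            [len(g) for g in groups])


def dispatch_two_groups(
    a: Sequence[float], b: Sequence[float],
    alpha_assume: float = ALPHA_ASSUME_DEFAULT,
) -> GroupTestResult:
    """Two-group comparison with the assumption-gated test choice."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise StatsError("each group needs n >= 3 (Shapiro-Wilk undefined below)")
    report = check_assumptions([a, b], alpha_assume)
    means, sds, ns = _summaries([a, b])
    if report.all_normal and report.equal_variance:
        res = stats.ttest_ind(a, b, equal_var=True)
        name, df = "pooled_t", float(len(a) + len(b) - 2)
        stat, p = float(res.statistic), float(res.pvalue)
    elif report.all_normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        name, df = "welch_t", float(res.df)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        name, df = "mann_whitney", None
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupTestResult(name, stat, df, p, None, report,
                           group_means=means, group_sds=sds, group_ns=ns)


def dispatch_multi_groups(
    groups: Sequence[Sequence[float]],
    alpha_assume: float = ALPHA_ASSUME_DEFAULT,
    alpha_posthoc: float = 0.05,
    labels: Sequence[str] | None = None,
) -> GroupTestResult:
    """Omnibus test for >= 3 groups with assumption-gated post hocs.

    Post hoc pairs are reported only when the omnibus p < alpha_posthoc:
    Tukey HSD after ANOVA, Games-Howell after Kruskal-Wallis.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise StatsError("need >= 3 groups; use dispatch_two_groups")
    if any(len(g) < 3 for g in groups):
        raise StatsError("each group needs n >= 3")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    report = check_assumptions(groups, alpha_assume)
    means, sds, ns = _summaries(groups)
    k = len(groups)
    n = sum(ns)

    values = np.concatenate(groups)
    codes = np.concatenate([[labels[i]] * len(g) for i, g in enumerate(groups)])

    if report.all_normal and report.equal_variance:
        f, p = stats.f_oneway(*groups)
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_total = float(((values - grand) ** 2).sum())
        eta2 = ss_between / ss_total if ss_total > 0 else 0.0
        result = GroupTestResult("anova", float(f), (float(k - 1), float(n - k)),
                                 float(p), float(eta2), report,
                                 group_means=means, group_sds=sds, group_ns=ns)
        if p < alpha_posthoc:
            tk = pairwise_tukeyhsd(values, codes)
            pairs = [(tk.groupsunique[i], tk.groupsunique[j])
                     for i in range(k) for j in range(i + 1, k)]
            for (g1, g2), stat, adj in zip(pairs, tk.meandiffs, tk.pvalues):
                result.posthoc.append(((str(g1), str(g2)), float(stat), float(adj)))
    else:
        h, p = stats.kruskal(*groups)
        eta2 = (h - k + 1) / (n - k)
        result = GroupTestResult("kruskal", float(h), float(k - 1), float(p),
                                 float(eta2), report,
                                 group_means=means, group_sds=sds, group_ns=ns)
        if p < alpha_posthoc:
            df = pd.DataFrame({"value": values, "grp": codes})
            gh = pg.pairwise_gameshowell(data=df, dv="value", between="grp")
            for row in gh.itertuples(index=False):
                result.posthoc.append(((str(row.A), str(row.B)),
                                       float(row.T), float(row.pval)))
    return result


def eta_squared_h(h: float, k: int, n: int) -> float:
    """Rank-based effect size for Kruskal-Wallis: (H - k + 1) / (n - k)."""
    return (h - k + 1) / (n - k)


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass
class AncovaResult:
    terms: pd.DataFrame          # index: term; columns: sum_sq, df, F, p_value
    cell_means: pd.DataFrame     # mean response per factor-level cell
    dropped_interaction: bool


def ancova_interaction(
    data: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> AncovaResult:
    """Two-way linear model with interaction, type-II sums of squares.

    Degenerate designs: a constant factor reduces to the one-way model on
    the other factor; an empty design cell drops the interaction term with
    a warning.  The cell-means table supports statements like "X% of
    multiplex individuals with epilepsy carried the variant" when the
    response is carrier status.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    if df.empty:
        raise StatsError("no complete observations")
    df.columns = ["y", "A", "B"]
    lev_a, lev_b = df["A"].nunique(), df["B"].nunique()
    if lev_a < 2 and lev_b < 2:
        raise StatsError("both factors are constant")

    dropped = False
    if lev_a < 2 or lev_b < 2:
        keep = "B" if lev_a < 2 else "A"
        model = smf.ols(f"y ~ C({keep})", data=df).fit()
        dropped = True
    else:
        cells = df.groupby(["A", "B"], observed=True).size().unstack()
        if cells.isna().any().any() or (cells == 0).any().any():
            warnings.warn("empty design cell: interaction term dropped", stacklevel=2)
            model = smf.ols("y ~ C(A) + C(B)", data=df).fit()
            dropped = True
        else:
            model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise StatsError("design matrix is rank deficient")

    anova = sm.stats.anova_lm(model, typ=2)
    rename = {"C(A)": factor_a, "C(B)": factor_b,
              "C(A):C(B)": f"{factor_a}:{factor_b}",
              f"C({'B' if lev_a < 2 else 'A'})": factor_b if lev_a < 2 else factor_a}
    anova = anova.rename(index=rename).rename(columns={"PR(>F)": "p_value"})
    cell_means = (
        df.groupby(["A", "B"], observed=True)["y"].agg(["mean", "count"])
        .rename_axis([factor_a, factor_b]).reset_index()
    )
    return AncovaResult(terms=anova, cell_means=cell_means, dropped_interaction=dropped)


# ---------------------------------------------------------------------------
# Phenotype association battery


def associate_phenotypes(
    matrix,
    meta: pd.DataFrame,
    snp_rsids: Sequence[str],
    phenotypes: Sequence[str],
    carrier: str = "any",
) -> pd.DataFrame:
    """Carrier-by-phenotype contingency screen over candidate SNPs.

    One chi-square/OR test per (phenotype, SNP); BH correction applied
    within each phenotype family.  Returns a tidy table, one row per test,
    usable directly as an edge list (SNP -- phenotype, weighted by
    adjusted p).
    """
    sub = matrix.subset_samples(
        [s for s in meta["sample_id"] if s in set(matrix.sample_ids)]
    )
    col = {r: j for j, r in enumerate(sub.snps.rsids)}
    rows = []
    for pheno in phenotypes:
        y = pd.to_numeric(meta.set_index("sample_id").loc[sub.sample_ids, pheno])
        pvals, partial = [], []
        for rsid in snp_rsids:
            if rsid not in col:
                continue
            res = carrier_contingency(sub.dosage[:, col[rsid]], y.to_numpy(),
                                      carrier=carrier)
            partial.append((pheno, rsid, res))
            pvals.append(res.p_value)
        adj = bh_adjust(pvals) if pvals else []
        for (pheno_, rsid, res), q in zip(partial, adj):
            rows.append({
                "phenotype": pheno_, "rsid": rsid,
                "chi_square": res.chi_square, "p_value": res.p_value,
                "bh_adj_p": float(q), "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "haldane_corrected": res.haldane_corrected,
            })
    return pd.DataFrame(rows)
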