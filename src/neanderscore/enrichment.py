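"""Per-SNP case-vs-control enrichment screen and genotype contingency tests.

Workflow order per ethnic stratum: absolute frequency-difference cutoff
(case minus control allele frequency >= 5% for BNH/WNH, >= 10% for WHS by
default), pooled two-proportion Z test on allele counts for the SNPs
passing the cutoff, Benjamini-Hochberg correction within the stratum's
passing set, and finally an annotation filter retaining only candidates
flagged as brain-expressed QTLs in a user-supplied table.  A zygosity
breakdown compares per-individual heterozygous and homozygous carrier
counts over a candidate set between two groups with rank-sum tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import GenotypeMatrix

logger = logging.getLogger("neanderscore")

DEFAULT_CUTOFFS = {"BNH": 0.05, "WHS": 0.10, "WNH": 0.05}


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Elementary statistics


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float, bool]:
    """Pooled two-proportion Z test, two-sided.

    Z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Trials are allele counts (2 x samples) in the enrichment screen.
    Returns (z, p, degenerate); a pooled proportion of exactly 0 or 1 is
    degenerate (both samples constant) and reported as z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise EnrichmentError("both trial counts must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise EnrichmentError("success counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0, True
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    # two-sided normal p; erfc form == 2 * norm.sf(|z|)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, min(p, 1.0), False


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Screen


def group_allele_counts(matrix: GenotypeMatrix, sample_ids: Sequence[str]
                        ) -> tuple[np.ndarray, int]:
    """(per-SNP archaic-allele counts, allele trials 2n) for a sample set."""
    idx = matrix.sample_index(sample_ids)
    g = matrix.dosage[idx]
    if (g < 0).any():
        raise EnrichmentError("matrix contains missing calls")
    return g.sum(axis=0, dtype=np.int64), 2 * len(idx)


def frequency_screen(
    case: GenotypeMatrix,
    control: GenotypeMatrix,
    stratum: str,
    cutoff: float,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Retain SNPs whose case-minus-control allele-frequency difference
    meets ``cutoff`` (inclusive).

    ``mode='absolute'`` screens the percentage-point difference
    (case_freq - control_freq >= cutoff); ``mode='relative'`` screens the
    ratio (case_freq / control_freq >= 1 + cutoff).  Depletion never
    passes.  Returns the full per-SNP table with a ``passed_cutoff``
    column.
    """
    if case.snps.rsids != control.snps.rsids:
        raise EnrichmentError("case and control matrices must share one SNP set")
    if not 0.0 < cutoff < 1.0:
        raise EnrichmentError(f"cutoff must be in (0, 1), got {cutoff}")
    if mode not in ("absolute", "relative"):
        raise EnrichmentError(f"unknown screen mode {mode!r}")
    x1, n1 = group_allele_counts(case, case.sample_ids)
    x2, n2 = group_allele_counts(control, control.sample_ids)
    case_freq = x1 / n1
    control_freq = x2 / n2
    diff = case_freq - control_freq
    if mode == "absolute":
        # inclusive bound, robust to float representation of e.g. 0.5 - 0.45
        passed = diff >= cutoff - 1e-12
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(control_freq > 0, case_freq / control_freq, np.inf)
        passed = (ratio >= 1.0 + cutoff) & (diff > 0)
    return pd.DataFrame(
        {
            "rsid": case.snps.rsids,
            "stratum": stratum,
            "case_freq": case_freq,
            "control_freq": control_freq,
            "freq_diff": diff,
            "case_alleles": x1,
            "case_trials": n1,
            "control_alleles": x2,
            "control_trials": n2,
            "passed_cutoff": passed,
        }
    )


def enrichment_screen(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    stratum: str,
    cutoff: float | None = None,
    alpha: float = 0.05,
    annotation: pd.DataFrame | None = None,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Full per-stratum screen: cutoff -> Z test -> BH -> annotation filter.

    BH is applied within the stratum over the SNPs passing the cutoff,
    matching the workflow order.  Returns one row per SNP with frequencies,
    z, p, BH-adjusted p and the three pass flags (``passed_annotation`` is
    NaN-free only when an annotation table is given).
    """
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS.get(stratum, 0.05)
    ids = {
        g: meta.loc[
            (meta["group"] == g) & (meta["ethnicity"] == stratum), "sample_id"
        ].tolist()
        for g in ("case", "control")
    }
    for g, s in ids.items():
        if not s:
            raise EnrichmentError(f"no {g} samples in stratum {stratum!r}")
    case = matrix.subset_samples([s for s in ids["case"] if s in set(matrix.sample_ids)])
    control = matrix.subset_samples(
        [s for s in ids["control"] if s in set(matrix.sample_ids)]
    )
    table = frequency_screen(case, control, stratum, cutoff, mode=mode)

    z = np.full(len(table), np.nan)
    p = np.full(len(table), np.nan)
    degenerate = np.zeros(len(table), dtype=bool)
    sel = table.index[table["passed_cutoff"]]
    for i in sel:
        row = table.loc[i]
        z[i], p[i], degenerate[i] = two_proportion_z(
            int(row.case_alleles), int(row.case_trials),
            int(row.control_alleles), int(row.control_trials),
        )
    table["z_stat"] = z
    table["p_value"] = p
    table["degenerate"] = degenerate
    adj = np.full(len(table), np.nan)
    if len(sel):
        adj[sel] = bh_adjust(p[sel])
    table["bh_adj_p"] = adj
    table["passed_bh"] = table["passed_cutoff"] & (table["bh_adj_p"] < alpha)

    if annotation is not None:
        final = annotation_filter(table, annotation)
        table["passed_annotation"] = table["rsid"].isin(final["rsid"])
    else:
        table["passed_annotation"] = pd.NA
    return table


def annotation_filter(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep BH-significant candidates annotated as brain-expressed QTLs.

    ``annotation`` maps rsid -> brain_qtl (boolean).  Candidates absent
    from the table are dropped with a warning — only verified brain QTLs
    are retained.
    """
    if "rsid" not in annotation.columns or "brain_qtl" not in annotation.columns:
        raise EnrichmentError("annotation table needs columns rsid, brain_qtl")
    candidates = results.loc[results["passed_bh"] == True]  # noqa: E712 (NaN-safe)
    ann = annotation.drop_duplicates("rsid").set_index("rsid")["brain_qtl"]
    known = candidates["rsid"].isin(ann.index)
    if (~known).any():
        logger.warning(
            "%d BH-significant SNPs absent from the annotation table; dropped "
            "(conservative)", int((~known).sum()),
        )
    keep = candidates.loc[known]
    is_qtl = keep["rsid"].map(ann).astype(bool)
    return keep.loc[is_qtl.to_numpy()].copy()


# ---------------------------------------------------------------------------
# Zygosity enrichment


@dataclass
class ZygosityClassResult:
    computable: bool
    w_stat: float = float("nan")
    p_value: float = float("nan")
    counts_a: np.ndarray = field(default_factory=lambda: np.array([]))
    counts_b: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ZygosityResult:
    """Rank-sum comparison of het / hom carrier counts over a SNP set."""

    het: ZygosityClassResult
    hom: ZygosityClassResult


def zygosity_enrichment(
    matrix: GenotypeMatrix,
    snp_rsids: Sequence[str],
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
) -> ZygosityResult:
    """Compare per-individual het (dosage 1) and hom (dosage 2) counts
    within ``snp_rsids`` between two groups.

    Two-sided Mann-Whitney/Wilcoxon rank-sum with tie-corrected normal
    approximation; W is the rank-sum-derived U statistic of group A.  A
    class with zero carriers in both groups is flagged not computable
    (a rank test on all-zero counts is meaningless).
    """
    if not len(snp_rsids):
        raise EnrichmentError("snp_set is empty")
    if not len(group_a_ids) or not len(group_b_ids):
        raise EnrichmentError("both groups must be nonempty")
    sub = matrix.subset_snps(snp_rsids)
    if sub.n_snps != len(set(snp_rsids)):
        raise EnrichmentError("some requested SNPs are not in the matrix")
    ga = sub.dosage[sub.sample_index(group_a_ids)]
    gb = sub.dosage[sub.sample_index(group_b_ids)]

    def one_class(value: int) -> ZygosityClassResult:
        ca = (ga == value).sum(axis=1)
        cb = (gb == value).sum(axis=1)
        if ca.sum() == 0 and cb.sum() == 0:
            return ZygosityClassResult(False, counts_a=ca, counts_b=cb)
        res = stats.mannwhitneyu(ca, cb, alternative="two-sided", method="asymptotic")
        return ZygosityClassResult(True, float(res.statistic), float(res.pvalue), ca, cb)

    return ZygosityResult(het=one_class(1), hom=one_class(2))


# ---------------------------------------------------------------------------
# Carrier contingency


@dataclass
class ContingencyResult:
    """2x2 carrier-by-label test: Pearson chi-square (no continuity
    correction), odds ratio, 95% Woolf (log-OR) CI."""

    table: np.ndarray
    chi_square: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


def carrier_contingency(
    dosages: Sequence[int],
    labels: Sequence[int],
    carrier: str = "any",
) -> ContingencyResult:
    """Association of carrier status with a binary label for one SNP.

    ``carrier='any'`` defines carriers as dosage >= 1, ``'hom'`` as
    dosage == 2.  Table rows are carrier/non-carrier, columns label 1/0.
    OR = ad/bc with the Woolf CI exp(ln OR +/- 1.96 * sqrt(sum 1/cell));
    any zero cell triggers the Haldane-Anscombe +0.5 correction for the
    OR and CI (flagged), the chi-square uses the raw table.
    """
    g = np.asarray(dosages)
    y = np.asarray(labels)
    if g.shape != y.shape:
        raise EnrichmentError("dosages and labels differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise EnrichmentError("labels must be binary 0/1")
    if carrier == "any":
        carrier_mask = g >= 1
    elif carrier == "hom":
        carrier_mask = g == 2
    else:
        raise EnrichmentError(f"carrier must be 'any' or 'hom', got {carrier!r}")

    a = int(np.sum(carrier_mask & (y == 1)))
    b = int(np.sum(carrier_mask & (y == 0)))
    c = int(np.sum(~carrier_mask & (y == 1)))
    d = int(np.sum(~carrier_mask & (y == 0)))
    table = np.array([[a, b], [c, d]], dtype=float)

    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0  # degenerate margin: no association testable
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)

    corrected = min(a, b, c, d) == 0
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    orr = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo, hi = math.exp(math.log(orr) - 1.96 * se), math.exp(math.log(orr) + 1.96 * se)
    return ContingencyResult(
        table=np.array([[a, b], [c, d]]),
        chi_square=float(chi2), p_value=float(p),
        odds_ratio=float(orr), ci_low=float(lo), ci_high=float(hi),
        haldane_corrected=corrected,
    )
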