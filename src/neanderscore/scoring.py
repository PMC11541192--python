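"""Rare/common stratification and per-individual NeanderScores.

Each retained SNP is classified within an ethnic stratum by its archaic
allele frequency in that stratum's *controls only*: rare if f < 1%, common
if f >= 1% (the boundary is inclusive on the common side).  A given SNP may
therefore be rare in one stratum and common in another.  An individual's
NeanderScore over a SNP class is the mean archaic dosage across that
class — the 0/1/2 tally divided by the number of SNPs — so scores live in
[0, 2].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog_io import GenotypeMatrix

RARE_THRESHOLD_DEFAULT = 0.01


class ScoringError(ValueError):
    pass


def control_allele_frequencies(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    stratum: str,
    rare_threshold: float = RARE_THRESHOLD_DEFAULT,
    freq_mode: str = "allele",
) -> pd.DataFrame:
    """Per-SNP control frequency and rare/common class for one stratum.

    ``freq_mode='allele'`` (default) uses the allele frequency
    sum(g) / 2n; ``'carrier'`` uses the carrier fraction #(g >= 1) / n.
    Cases and siblings never contribute.  Requires a complete
    (missing-free) matrix.
    """
    if matrix.missing_mask().any():
        raise ScoringError("matrix contains missing calls; run drop_incomplete_snps first")
    if freq_mode not in ("allele", "carrier"):
        raise ScoringError(f"freq_mode must be 'allele' or 'carrier', got {freq_mode!r}")
    controls = meta.loc[
        (meta["group"] == "control") & (meta["ethnicity"] == stratum), "sample_id"
    ]
    controls = [s for s in controls if s in set(matrix.sample_ids)]
    if not controls:
        raise ScoringError(f"no control samples in stratum {stratum!r}")
    idx = matrix.sample_index(controls)
    g = matrix.dosage[idx].astype(float)
    n = len(controls)
    if freq_mode == "allele":
        freq = g.sum(axis=0) / (2.0 * n)
    else:
        freq = (g >= 1).sum(axis=0) / float(n)
    return pd.DataFrame(
        {
            "stratum": stratum,
            "rsid": matrix.snps.rsids,
            "control_freq": freq,
            "n_controls": n,
            "snp_class": np.where(freq < rare_threshold, "rare", "common"),
        }
    )


def neander_scores(
    matrix: GenotypeMatrix, classes: pd.DataFrame, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Total / Rare / Common NeanderScores per individual.

    ``classes`` is the frequency-class table for the individuals' stratum;
    it must cover every matrix SNP.  Scores are mean dosages over the
    class; an empty class yields NaN with the ``*_defined`` flag False,
    never a silent 0.
    """
    if matrix.missing_mask().any():
        raise ScoringError("matrix contains missing calls; run drop_incomplete_snps first")
    cls = classes.set_index("rsid")["snp_class"]
    missing = [r for r in matrix.snps.rsids if r not in cls.index]
    if missing:
        raise ScoringError(
            f"{len(missing)} matrix SNPs absent from the class table, e.g. {missing[:3]}"
        )
    cls = cls.reindex(matrix.snps.rsids)
    rare_mask = (cls == "rare").to_numpy()
    common_mask = ~rare_mask

    g = matrix.dosage.astype(float)
    n_rare, n_common = int(rare_mask.sum()), int(common_mask.sum())
    n_total = matrix.n_snps

    def class_mean(mask: np.ndarray, n: int) -> np.ndarray:
        if n == 0:
            return np.full(matrix.n_samples, np.nan)
        return g[:, mask].sum(axis=1) / n

    out = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "total_score": g.sum(axis=1) / n_total,
            "rare_score": class_mean(rare_mask, n_rare),
            "common_score": class_mean(common_mask, n_common),
            "n_total_snps": n_total,
            "n_rare_snps": n_rare,
            "n_common_snps": n_common,
            "rare_defined": n_rare > 0,
            "common_defined": n_common > 0,
        }
    )
    if meta is not None:
        out = out.merge(
            meta[["sample_id", "group", "ethnicity"]], on="sample_id", how="left"
        )
        out.insert(1, "stratum", out.pop("ethnicity"))
    return out


def score_cohort(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    rare_threshold: float = RARE_THRESHOLD_DEFAULT,
    freq_mode: str = "allele",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify and score every stratum present in ``meta``.

    Returns (frequency-class table over all strata, score table over all
    samples).  Strata without controls raise, since classification is
    control-anchored.
    """
    class_tables, score_tables = [], []
    for stratum in sorted(meta["ethnicity"].unique()):
        sub_ids = meta.loc[meta["ethnicity"] == stratum, "sample_id"]
        sub_ids = [s for s in sub_ids if s in set(matrix.sample_ids)]
        sub = matrix.subset_samples(sub_ids)
        classes = control_allele_frequencies(
            sub, meta, stratum, rare_threshold=rare_threshold, freq_mode=freq_mode
        )
        scores = neander_scores(sub, classes, meta=meta)
        class_tables.append(classes)
        score_tables.append(scores)
    return (
        pd.concat(class_tables, ignore_index=True),
        pd.concat(score_tables, ignore_index=True),
    )
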