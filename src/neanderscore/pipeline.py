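"""End-to-end orchestration: simulate/ingest -> score -> enrich -> permtest
-> associate, with a run manifest and a machine-readable summary.

Every stochastic stage derives from the single root seed in the config, so
one config + seed reproduces a run byte-for-byte.  Counts at every filter
(SNPs removed per reason, samples per group) are logged and written, so
catalog-to-retained accounting is auditable.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog_io import (
    CatalogError,
    check_meta_matches_matrix,
    drop_incomplete_snps,
    genotypes_from_vcf,
    read_sample_meta,
    read_snp_catalog,
)
from .enrichment import DEFAULT_CUTOFFS, enrichment_screen
from .group_stats import associate_phenotypes
from .randomization import randomization_test
from .scoring import score_cohort
from .simulate import SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger("neanderscore")

PHENOTYPES_DEFAULT = [
    "epilepsy", "intellectual_disability", "language_delay", "language_regression",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``simulate`` (mapping of stratum label -> SimConfig overrides)
    or ``inputs`` (paths: catalog, vcfs, meta, optional annotation) must be
    given.  Thresholds: ``rare_threshold`` (default 1%), per-stratum
    enrichment ``cutoffs`` (defaults 5%/10%/5% for BNH/WHS/WNH),
    ``perm_reps`` (default 10,000) and the root ``seed``.
    """

    out_dir: str = "runs/out"
    seed: int = 0
    rare_threshold: float = 0.01
    freq_mode: str = "allele"
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    screen_alpha: float = 0.05
    perm_reps: int = 10_000
    perm_alternative: str = "greater"
    perm_class: str = "rare_score"
    assumption_alpha: float = 0.05
    phenotypes: list[str] = field(default_factory=lambda: list(PHENOTYPES_DEFAULT))
    simulate: dict[str, dict] | None = None
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.rare_threshold < 1.0:
            raise ValueError(f"rare_threshold must be in (0, 1), got {self.rare_threshold}")
        for s, c in self.cutoffs.items():
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff for {s} must be in (0, 1), got {c}")
        if self.perm_reps < 1:
            raise ValueError("perm_reps must be >= 1")
        if not 0.0 < self.assumption_alpha < 1.0:
            raise ValueError("assumption_alpha must be in (0, 1)")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be configured")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(**raw)


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        matrices, metas = [], []
        truths = {}
        for i, (stratum, overrides) in enumerate(sorted(config.simulate.items())):
            sim = SimConfig(**{**overrides, "stratum": stratum,
                               "seed": int(config.seed) * 1000 + i})
            matrix, meta, truth = simulate_cohort(sim)
            write_cohort(out / "simulated" / stratum, matrix, meta, truth)
            matrices.append(matrix)
            metas.append(meta)
            truths[stratum] = truth
        if len(matrices) > 1:
            # strata are simulated on distinct synthetic catalogs; analyses
            # are per-stratum, so matrices are kept separate
            pass
        return matrices, pd.concat(metas, ignore_index=True), truths, None
    paths = config.inputs or {}
    catalog = read_snp_catalog(paths["catalog"])
    matrix = genotypes_from_vcf(paths["vcfs"], catalog)
    meta = read_sample_meta(paths["meta"])
    annotation = (
        pd.read_csv(paths["annotation"], sep="\t") if paths.get("annotation") else None
    )
    return [matrix], meta, {}, annotation


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write per-stage TSVs, the manifest and a summary.

    Returns the summary dict (also written as ``summary.json``).  Raises on
    any stage failure after logging the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        matrices, meta, truths, annotation = _load_inputs(config, out)
        meta = meta.loc[~meta["excluded"].astype(bool)].reset_index(drop=True)

        summary: dict[str, Any] = {
            "seed": int(config.seed),
            "strata": {},
            "filter_accounting": {},
        }

        stage = "missing-data filter"
        filtered = []
        removal_frames = []
        for m in matrices:
            kept, removed = drop_incomplete_snps(m)
            check_meta_matches_matrix(kept, meta)
            filtered.append(kept)
            removal_frames.append(kept.removal_log)
            summary["filter_accounting"].setdefault("snps_input", 0)
            summary["filter_accounting"]["snps_input"] += m.n_snps
            summary["filter_accounting"].setdefault("snps_removed", 0)
            summary["filter_accounting"]["snps_removed"] += len(removed)
            summary["filter_accounting"].setdefault("snps_retained", 0)
            summary["filter_accounting"]["snps_retained"] += kept.n_snps
        pd.concat(removal_frames, ignore_index=True).to_csv(
            out / "removal_log.tsv", sep="\t", index=False
        )

        stage = "scoring"
        class_frames, score_frames = [], []
        for m in filtered:
            strata_here = sorted(
                meta.loc[meta["sample_id"].isin(m.sample_ids), "ethnicity"].unique()
            )
            sub_meta = meta.loc[meta["ethnicity"].isin(strata_here)]
            classes, scores = score_cohort(
                m, sub_meta, rare_threshold=config.rare_threshold,
                freq_mode=config.freq_mode,
            )
            class_frames.append(classes)
            score_frames.append(scores)
        class_table = pd.concat(class_frames, ignore_index=True)
        score_table = pd.concat(score_frames, ignore_index=True)
        class_table.to_csv(out / "frequency_classes.tsv", sep="\t", index=False)
        score_table.to_csv(out / "scores.tsv", sep="\t", index=False)

        stage = "enrichment"
        enrich_frames = []
        for m in filtered:
            for stratum in sorted(
                meta.loc[meta["sample_id"].isin(m.sample_ids), "ethnicity"].unique()
            ):
                table = enrichment_screen(
                    m, meta, stratum,
                    cutoff=config.cutoffs.get(stratum),
                    alpha=config.screen_alpha,
                    annotation=annotation,
                )
                enrich_frames.append(table)
        enrich_table = pd.concat(enrich_frames, ignore_index=True)
        enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "randomization"
        perm_results = {}
        rng = np.random.default_rng(int(config.seed) + 17)
        for stratum in sorted(score_table["stratum"].dropna().unique()):
            sub = score_table.loc[score_table["stratum"] == stratum]
            if not {"case", "control"} <= set(sub["group"]):
                continue
            res = randomization_test(
                sub[config.perm_class].to_numpy(),
                sub["group"].to_numpy(), "case", "control",
                n_reps=config.perm_reps,
                seed=int(rng.integers(2**31)),
                alternative=config.perm_alternative,
            )
            perm_results[stratum] = res
        with open(out / "randomization.json", "w") as fh:
            json.dump({s: vars(r) for s, r in perm_results.items()},
                      fh, indent=1, sort_keys=True)

        stage = "association"
        assoc_frames = []
        for m in filtered:
            for stratum in sorted(
                meta.loc[meta["sample_id"].isin(m.sample_ids), "ethnicity"].unique()
            ):
                sub = enrich_table.query("stratum == @stratum")
                candidates = sub.loc[sub["passed_bh"] == True, "rsid"].tolist()  # noqa: E712
                if not candidates:
                    continue
                case_meta = meta.loc[
                    (meta["ethnicity"] == stratum) & (meta["group"] == "case")
                ]
                case_ids = [s for s in case_meta["sample_id"] if s in set(m.sample_ids)]
                if not case_ids:
                    continue
                assoc = associate_phenotypes(
                    m.subset_samples(case_ids), case_meta,
                    candidates, config.phenotypes,
                )
                if len(assoc):
                    assoc.insert(0, "stratum", stratum)
                    assoc_frames.append(assoc)
        assoc_table = (
            pd.concat(assoc_frames, ignore_index=True) if assoc_frames
            else pd.DataFrame(columns=["stratum", "phenotype", "rsid", "chi_square",
                                       "p_value", "bh_adj_p", "odds_ratio",
                                       "ci_low", "ci_high", "haldane_corrected"])
        )
        assoc_table.to_csv(out / "associations.tsv", sep="\t", index=False)
        # edge-list export (SNP -- phenotype network)
        assoc_table.loc[assoc_table["bh_adj_p"] < 0.05,
                        ["rsid", "phenotype", "bh_adj_p"]].to_csv(
            out / "association_edges.tsv", sep="\t", index=False)

        stage = "summary"
        for stratum in sorted(score_table["stratum"].dropna().unique()):
            sub = score_table.loc[score_table["stratum"] == stratum]
            enr = enrich_table.query("stratum == @stratum")
            entry: dict[str, Any] = {"groups": {}, "enrichment": {
                "n_passed_cutoff": int(enr["passed_cutoff"].sum()),
                "n_passed_bh": int((enr["passed_bh"] == True).sum()),  # noqa: E712
                "n_final_candidates": (
                    int((enr["passed_annotation"] == True).sum())  # noqa: E712
                    if enr["passed_annotation"].notna().any() else None
                ),
            }}
            for group, gsub in sub.groupby("group"):
                entry["groups"][str(group)] = {
                    "n": int(len(gsub)),
                    **{
                        f"{c}_{s}": round(float(getattr(gsub[c], s)()), 10)
                        for c in ("total_score", "rare_score", "common_score")
                        for s in ("mean", "std")
                    },
                }
            if stratum in perm_results:
                r = perm_results[stratum]
                entry["randomization"] = {
                    "observed_diff": r.observed_diff,
                    "perm_diffs_mean": r.perm_diffs_mean,
                    "n_reps": r.n_reps,
                    "p_value": r.p_value,
                }
            entry["n_associations_tested"] = int(
                (assoc_table["stratum"] == stratum).sum()
            ) if len(assoc_table) else 0
            summary["strata"][stratum] = entry

        manifest = {
            "version": __version__,
            "python": platform.python_version(),
            "seed": int(config.seed),
            "config": _jsonable(vars(config)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
        return summary
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
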