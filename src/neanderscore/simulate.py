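"""Synthetic case/sibling/control cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a control allele-frequency spectrum mixing rare (< 1%) and common
(>= 1%) SNPs, Hardy-Weinberg genotype sampling (dosage ~ Binomial(2, f)),
a case-side absolute frequency shift injected on a chosen SNP subset,
siblings shifted an intermediate fraction of the way, optional
two-subpopulation admixture at a configurable mixing ratio, uniform
per-call missingness, and binary phenotypes driven by a logistic model on
realized dosages.  Everything derives from one root seed.

SNPs are sampled independently (no linkage disequilibrium) — a documented
limitation; no pipeline stage consumes LD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_io import (
    MISSING,
    GenotypeMatrix,
    SnpCatalog,
    SnpRecord,
    write_sample_meta,
    write_snp_catalog,
    write_vcf,
)

_DEFAULT_PHENOTYPES: dict[str, dict] = {
    # intercepts on the log-odds scale; weights are per-SNP dosage log-odds.
    # Defaults give genotype-independent phenotypes at field-plausible base
    # rates so association tests can be validated for type-I error.
    "epilepsy": {"intercept": -1.1, "weights": {}},           # ~25%
    "intellectual_disability": {"intercept": -0.85, "weights": {}},  # ~30%
    "language_delay": {"intercept": -0.4, "weights": {}},     # ~40%
    "language_regression": {"intercept": -1.4, "weights": {}},  # ~20%
}


@dataclass
class SimConfig:
    """Parameters of one simulated stratum.

    Frequencies are archaic-allele frequencies in controls.  ``effect_delta``
    is the absolute case-side allele-frequency shift applied to a random
    ``enriched_snp_fraction`` of SNPs; siblings receive
    ``sibling_fraction * effect_delta`` (default 0.5, midway between cases
    and controls).  ``admix_ratio`` mixes two subpopulations (e.g. 1:6)
    whose frequency vectors diverge by ``admix_divergence`` around the
    configured spectrum.
    """

    n_cases: int = 200
    n_siblings: int = 0
    n_controls: int = 200
    n_snps: int = 1000
    freqs: Sequence[float] | None = None  # explicit control spectrum, else generated:
    rare_fraction: float = 348 / 1288
    rare_range: tuple[float, float] = (0.0005, 0.01)
    common_range: tuple[float, float] = (0.01, 0.5)
    enriched_snp_fraction: float = 0.0
    effect_delta: float = 0.0
    sibling_fraction: float = 0.5
    missing_rate: float = 0.0
    admix_ratio: tuple[float, float] | None = None  # e.g. (1, 6) for 1:6
    admix_divergence: float = 0.1
    subpop_freqs: tuple[Sequence[float], Sequence[float]] | None = None
    phenotype_model: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PHENOTYPES.items()}
    )
    male_fraction: float = 0.5
    multiplex_fraction: float = 0.35
    stratum: str = "WNH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freqs is not None:
            f = np.asarray(self.freqs, dtype=float)
            if f.ndim != 1 or ((f < 0) | (f > 1)).any():
                raise ValueError("freqs must be a 1-D vector in [0, 1]")
            self.n_snps = len(f)
        for name in ("rare_fraction", "enriched_snp_fraction", "missing_rate",
                     "sibling_fraction", "male_fraction", "multiplex_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ValueError("effect_delta must be in [0, 1]")
        if self.admix_ratio is not None:
            w = np.asarray(self.admix_ratio, dtype=float)
            if w.shape != (2,) or (w <= 0).any():
                raise ValueError("admix_ratio must be two positive weights")


@dataclass
class SimTruth:
    """Ground truth stored alongside simulated outputs for recovery tests."""

    enriched_rsids: list[str]
    control_freqs: dict[str, float]
    effect_delta: float
    sibling_fraction: float
    phenotype_model: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @staticmethod
    def from_json(path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return SimTruth(**json.load(fh))


def sample_hwe_genotypes(freq: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` dosages under Hardy-Weinberg equilibrium at allele freq ``freq``.

    Dosage ~ Binomial(2, freq), i.e. P(2) = f^2, P(1) = 2f(1-f),
    P(0) = (1-f)^2.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {freq}")
    if n < 0:
        raise ValueError("n must be >= 0")
    return rng.binomial(2, freq, size=n).astype(np.int8)


def draw_frequency_spectrum(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Control allele-frequency spectrum: explicit, or a rare/common mixture.

    ``round(rare_fraction * n_snps)`` SNPs get frequencies uniform on the
    rare range [0.0005, 0.01) and the rest uniform on the common range
    [0.01, 0.5]; positions of rare SNPs are randomized.
    """
    if config.freqs is not None:
        return np.asarray(config.freqs, dtype=float)
    n_rare = int(round(config.rare_fraction * config.n_snps))
    freqs = np.empty(config.n_snps)
    freqs[:n_rare] = rng.uniform(*config.rare_range, size=n_rare)
    freqs[n_rare:] = rng.uniform(*config.common_range, size=config.n_snps - n_rare)
    rng.shuffle(freqs)
    return freqs


def synthetic_catalog(n_snps: int, rng: np.random.Generator,
                      chrom_count: int = 22) -> SnpCatalog:
    """A synthetic archaic-SNP catalog with plausible coordinates and rsIDs."""
    bases = np.array(list("ACGT"))
    chroms = rng.integers(1, chrom_count + 1, size=n_snps)
    pos = rng.integers(10_000, 100_000_000, size=n_snps)
    records = []
    used = set()
    for i in range(n_snps):
        key = (str(chroms[i]), int(pos[i]))
        while key in used:  # avoid coordinate collisions
            key = (key[0], key[1] + 1)
        used.add(key)
        anc, arc = rng.choice(4, size=2, replace=False)
        records.append(
            SnpRecord(
                chrom=key[0], pos=key[1],
                ancestral_allele=str(bases[anc]), archaic_allele=str(bases[arc]),
                rsid=f"rs{900_000_000 + i}", europe_specific=True,
            )
        )
    return SnpCatalog(records)


def _group_freqs(control_freqs: np.ndarray, enriched: np.ndarray,
                 shift: float) -> np.ndarray:
    f = control_freqs.copy()
    f[enriched] = np.clip(f[enriched] + shift, 0.0, 1.0)
    return f


def _sample_group(freqs_by_subpop: list[np.ndarray], weights: np.ndarray,
                  n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample n individuals; each draws a subpopulation then HWE genotypes."""
    n_snps = len(freqs_by_subpop[0])
    subpop = rng.choice(len(freqs_by_subpop), size=n, p=weights)
    out = np.empty((n, n_snps), dtype=np.int8)
    for k, fk in enumerate(freqs_by_subpop):
        rows = np.flatnonzero(subpop == k)
        if rows.size:
            out[rows] = rng.binomial(2, fk, size=(rows.size, n_snps)).astype(np.int8)
    return out, subpop


def simulate_cohort(
    config: SimConfig, catalog: SnpCatalog | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate one stratum's genotype matrix, sample metadata and truth.

    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if catalog is None:
        catalog = synthetic_catalog(config.n_snps, rng)
    elif len(catalog) != config.n_snps:
        raise ValueError(
            f"catalog has {len(catalog)} SNPs but config.n_snps = {config.n_snps}"
        )

    control_f = draw_frequency_spectrum(config, rng)
    n_enriched = int(round(config.enriched_snp_fraction * config.n_snps))
    enriched = np.zeros(config.n_snps, dtype=bool)
    if n_enriched:
        enriched[rng.choice(config.n_snps, size=n_enriched, replace=False)] = True

    # per-subpopulation control spectra
    if config.admix_ratio is not None:
        if config.subpop_freqs is not None:
            subpops = [np.asarray(f, float) for f in config.subpop_freqs]
        else:
            # jitter the base spectrum on the logit-free scale, sd scaled to
            # binomial variability, to emulate drift between subpopulations
            subpops = []
            for _ in range(2):
                sd = config.admix_divergence * np.sqrt(control_f * (1 - control_f))
                subpops.append(np.clip(control_f + rng.normal(0, 1, config.n_snps) * sd,
                                       0.0, 1.0))
        weights = np.asarray(config.admix_ratio, float)
        weights = weights / weights.sum()
    else:
        subpops = [control_f]
        weights = np.array([1.0])

    shifts = {
        "control": 0.0,
        "sibling": config.sibling_fraction * config.effect_delta,
        "case": config.effect_delta,
    }
    counts = {"case": config.n_cases, "sibling": config.n_siblings,
              "control": config.n_controls}

    blocks, rows = [], []
    for group in ("case", "sibling", "control"):
        n = counts[group]
        if n == 0:
            continue
        gf = [_group_freqs(f, enriched, shifts[group]) for f in subpops]
        dose, subpop = _sample_group(gf, weights, n, rng)
        blocks.append(dose)
        for i in range(n):
            rows.append((group, int(subpop[i])))
    dosage = np.vstack(blocks)
    n_total = dosage.shape[0]
    sample_ids = [f"{config.stratum}_{g[:4]}_{i:05d}"
                  for i, (g, _) in enumerate(rows)]

    # phenotypes from the logistic model on realized (pre-missingness) dosages
    col = {r: j for j, r in enumerate(catalog.rsids)}
    pheno_cols: dict[str, np.ndarray] = {}
    for name, model in config.phenotype_model.items():
        eta = np.full(n_total, float(model.get("intercept", 0.0)))
        for rsid, w in dict(model.get("weights", {})).items():
            if rsid not in col:
                raise ValueError(f"phenotype model references unknown SNP {rsid}")
            eta += float(w) * dosage[:, col[rsid]]
        pheno_cols[name] = (rng.random(n_total) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage = dosage.copy()
        dosage[mask] = MISSING

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [g for g, _ in rows],
            "ethnicity": config.stratum,
            "sex": np.where(rng.random(n_total) < config.male_fraction,
                            "male", "female"),
            "epilepsy": pheno_cols.get("epilepsy", np.zeros(n_total, int)),
            "intellectual_disability": pheno_cols.get(
                "intellectual_disability", np.zeros(n_total, int)),
            "language_delay": pheno_cols.get("language_delay", np.zeros(n_total, int)),
            "language_regression": pheno_cols.get(
                "language_regression", np.zeros(n_total, int)),
            "family_type": np.where(rng.random(n_total) < config.multiplex_fraction,
                                    "multiplex", "simplex"),
            "diagnosis": rng.choice(
                ["autism", "asperger", "pdd_nos", "autism_spectrum"], size=n_total),
            "excluded": False,
            "exclusion_reason": "",
        }
    )

    truth = SimTruth(
        enriched_rsids=[catalog.rsids[j] for j in np.flatnonzero(enriched)],
        control_freqs={r: float(f) for r, f in zip(catalog.rsids, control_f)},
        effect_delta=config.effect_delta,
        sibling_fraction=config.sibling_fraction,
        phenotype_model={k: dict(v) for k, v in config.phenotype_model.items()},
        seed=config.seed,
    )
    matrix = GenotypeMatrix(sample_ids, catalog, dosage)
    return matrix, meta, truth


def write_cohort(outdir: str | Path, matrix: GenotypeMatrix,
                 meta: pd.DataFrame, truth: SimTruth) -> dict[str, Path]:
    """Emit catalog TSV + VCF + metadata TSV + truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "vcf": outdir / "genotypes.vcf",
        "meta": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_snp_catalog(matrix.snps, paths["catalog"])
    write_vcf(matrix, paths["vcf"])
    write_sample_meta(meta, paths["meta"])
    truth.to_json(paths["truth"])
    return paths
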