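"""Archaic-SNP catalog and cohort genotype ingestion.

The scoring universe is a catalog of biallelic SNVs at which the derived
(archaic) allele is attributed to Neanderthal introgression.  Cohort
genotypes arrive as VCF; each call is recoded as the archaic-allele dosage
g in {0, 1, 2} (0 = homozygous ancestral, 1 = heterozygous, 2 = homozygous
archaic).  Any SNP carrying at least one missing call across the pooled
cohort is dropped before analysis, so every downstream group comparison is
made on one shared, complete SNP set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neanderscore")

#: Sentinel for a missing genotype call in the dosage matrix (int8).
MISSING: int = -1

_BASES = frozenset("ACGT")

GROUPS = ("case", "sibling", "control")
REMOVAL_REASONS = ("missing_call", "absent_from_vcf", "allele_mismatch")

#: Required columns of the sample-metadata table.
META_COLUMNS = [
    "sample_id", "group", "ethnicity", "sex",
    "epilepsy", "intellectual_disability", "language_delay",
    "language_regression", "family_type", "diagnosis",
    "excluded", "exclusion_reason",
]


class CatalogError(ValueError):
    """Raised when a catalog or VCF violates a structural invariant."""


@dataclass(frozen=True)
class SnpRecord:
    """One surveyed archaic SNP.

    ``ancestral_allele`` is the pre-introgression (modern-human reference
    lineage) base, ``archaic_allele`` the introgressed one; dosage counts
    copies of the latter.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ancestral_allele: str
    archaic_allele: str
    rsid: str
    europe_specific: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CatalogError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        for name in ("ancestral_allele", "archaic_allele"):
            a = getattr(self, name)
            if a not in _BASES:
                raise CatalogError(
                    f"{self.rsid}: {name} must be a single base in ACGT, got {a!r}"
                )
        if self.ancestral_allele == self.archaic_allele:
            raise CatalogError(f"{self.rsid}: ancestral and archaic alleles are equal")

    @property
    def locus(self) -> str:
        """``chrom:pos:ancestral>archaic`` locus string."""
        return f"{self.chrom}:{self.pos}:{self.ancestral_allele}>{self.archaic_allele}"


_LOCUS_RE = re.compile(r"^([^:]+):(\d+):([ACGT])>([ACGT])$")


def parse_locus(locus: str, rsid: str = "", europe_specific: bool = True) -> SnpRecord:
    """Parse a ``chrom:pos:ancestral>archaic`` locus string into a record."""
    m = _LOCUS_RE.match(locus.strip())
    if m is None:
        raise CatalogError(f"cannot parse locus string {locus!r}")
    chrom, pos, anc, arc = m.groups()
    return SnpRecord(chrom, int(pos), anc, arc, rsid or locus, europe_specific)


class SnpCatalog:
    """Ordered, validated collection of :class:`SnpRecord`.

    Order is significant: it fixes the column order of every genotype
    matrix built against the catalog.
    """

    def __init__(self, records: Iterable[SnpRecord]):
        self.records: list[SnpRecord] = list(records)
        self._validate()

    def _validate(self) -> None:
        seen_rsid: dict[str, int] = {}
        seen_triple: dict[tuple, int] = {}
        dup_rsids, dup_triples = [], []
        for i, r in enumerate(self.records):
            if r.rsid in seen_rsid:
                dup_rsids.append(f"{r.rsid} (rows {seen_rsid[r.rsid]}, {i})")
            seen_rsid.setdefault(r.rsid, i)
            triple = (r.chrom, r.pos, r.archaic_allele)
            if triple in seen_triple:
                dup_triples.append(f"{triple} (rows {seen_triple[triple]}, {i})")
            seen_triple.setdefault(triple, i)
        msgs = []
        if dup_rsids:
            msgs.append("duplicate rsid: " + "; ".join(dup_rsids))
        if dup_triples:
            msgs.append("duplicate (chrom, pos, archaic) triple: " + "; ".join(dup_triples))
        if msgs:
            raise CatalogError("; ".join(msgs))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SnpCatalog(self.records[i])
        return self.records[i]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def subset(self, rsids: Sequence[str]) -> "SnpCatalog":
        """Catalog restricted to ``rsids``, original order preserved."""
        keep = set(rsids)
        return SnpCatalog([r for r in self.records if r.rsid in keep])

    def by_position(self) -> dict[tuple[str, int], SnpRecord]:
        return {(r.chrom, r.pos): r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ancestral": [r.ancestral_allele for r in self.records],
                "archaic": [r.archaic_allele for r in self.records],
                "rsid": self.rsids,
                "europe_specific": [r.europe_specific for r in self.records],
            }
        )


def read_snp_catalog(path: str | Path, europe_specific_only: bool = True) -> SnpCatalog:
    """Read a catalog TSV (chrom, pos, ancestral, archaic, rsid, europe_specific).

    With ``europe_specific_only`` (the default, matching the survey the
    catalog derives from) rows flagged ``europe_specific=false`` are
    excluded before validation of the retained set.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ancestral", "archaic", "rsid", "europe_specific"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CatalogError(f"catalog {path}: missing columns {sorted(missing_cols)}")
    records = [
        SnpRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ancestral_allele=str(row.ancestral).upper(),
            archaic_allele=str(row.archaic).upper(),
            rsid=str(row.rsid),
            europe_specific=_parse_bool(row.europe_specific),
        )
        for row in df.itertuples(index=False)
    ]
    if europe_specific_only:
        n0 = len(records)
        records = [r for r in records if r.europe_specific]
        if len(records) < n0:
            logger.info("catalog: excluded %d non-Europe-specific SNPs", n0 - len(records))
    return SnpCatalog(records)


def write_snp_catalog(catalog: SnpCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise CatalogError(f"cannot parse boolean value {x!r}")


# ---------------------------------------------------------------------------
# Genotype matrix


@dataclass
class GenotypeMatrix:
    """samples x SNPs archaic-allele dosage matrix.

    ``dosage`` is int8 with values in {0, 1, 2, MISSING}; rows follow
    ``sample_ids``, columns follow ``snps`` (a :class:`SnpCatalog` subset).
    """

    sample_ids: list[str]
    snps: SnpCatalog
    dosage: np.ndarray
    removal_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise CatalogError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise CatalogError(f"dosage values outside {{0,1,2,{MISSING}}}: {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CatalogError("duplicate sample ids in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise CatalogError(f"sample {e.args[0]!r} not in matrix") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(list(sample_ids), self.snps, self.dosage[idx].copy())

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        col = {r: j for j, r in enumerate(self.snps.rsids)}
        keep = [r for r in self.snps.rsids if r in set(rsids)]
        idx = np.array([col[r] for r in keep], dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids), self.snps.subset(keep), self.dosage[:, idx].copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snps.rsids)

    @staticmethod
    def concat_samples(matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack cohorts (e.g. case/sibling/control files) sharing one SNP set."""
        if not matrices:
            raise CatalogError("no matrices to concatenate")
        ref = matrices[0].snps.rsids
        for m in matrices[1:]:
            if m.snps.rsids != ref:
                raise CatalogError("cannot concatenate matrices with different SNP sets")
        ids = [s for m in matrices for s in m.sample_ids]
        logs = pd.concat([m.removal_log for m in matrices], ignore_index=True)
        return GenotypeMatrix(
            ids, matrices[0].snps, np.vstack([m.dosage for m in matrices]),
            removal_log=logs.drop_duplicates().reset_index(drop=True),
        )


def genotypes_from_vcf(
    vcf_paths: str | Path | Sequence[str | Path], catalog: SnpCatalog
) -> GenotypeMatrix:
    """Build the dosage matrix for catalog SNPs from one or more VCFs.

    Per catalog SNP found in a file with matching alleles, dosage is the
    archaic-allele count of the GT call (phase ignored).  A record whose
    REF/ALT pair is the catalog pair in swapped orientation is complemented
    (REF carries the archaic allele, so dosage = number of REF copies).
    Catalog SNPs absent from a file are MISSING for all of that file's
    samples; allele mismatches yield MISSING with a logged warning.
    Samples from multiple files are stacked in input order.
    """
    from cyvcf2 import VCF

    if len(catalog) == 0:
        raise CatalogError("catalog is empty")
    if isinstance(vcf_paths, (str, Path)):
        vcf_paths = [vcf_paths]

    by_pos = catalog.by_position()
    col = {r.rsid: j for j, r in enumerate(catalog)}
    parts: list[GenotypeMatrix] = []

    for path in vcf_paths:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        dosage = np.full((len(samples), len(catalog)), MISSING, dtype=np.int8)
        seen: set[str] = set()
        log_rows: list[tuple[str, str]] = []

        for variant in vcf:
            rec = by_pos.get((str(variant.CHROM), int(variant.POS)))
            if rec is None:
                continue
            j = col[rec.rsid]
            alts = [a for a in variant.ALT if a]
            ref = variant.REF
            if len(ref) != 1 or any(len(a) != 1 for a in alts):
                raise CatalogError(
                    f"{rec.locus}: non-SNV record (REF={ref}, ALT={alts}); "
                    "only biallelic SNVs are supported"
                )
            alt_index, complemented = _match_alleles(rec, ref, alts)
            if alt_index is None:
                logger.warning(
                    "%s: VCF alleles %s>%s do not match catalog %s>%s; coded missing",
                    rec.rsid, ref, ",".join(alts), rec.ancestral_allele, rec.archaic_allele,
                )
                log_rows.append((rec.rsid, "allele_mismatch"))
                seen.add(rec.rsid)
                continue
            genos = variant.genotypes  # [allele1, allele2, phased] per sample
            for i, g in enumerate(genos):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    dosage[i, j] = MISSING
                    continue
                if complemented:
                    d = int(a == 0) + int(b == 0)  # REF carries the archaic allele
                else:
                    d = int(a == alt_index) + int(b == alt_index)
                    # a call carrying a non-matching ALT cannot be expressed
                    # as a biallelic dosage -> missing
                    if any(x not in (0, alt_index) for x in (a, b)):
                        d = MISSING
                dosage[i, j] = d
            seen.add(rec.rsid)

        absent = [r for r in catalog.rsids if r not in seen]
        log_rows.extend((r, "absent_from_vcf") for r in absent)
        if absent:
            logger.info("%s: %d catalog SNPs absent, coded missing", path, len(absent))
        parts.append(
            GenotypeMatrix(
                samples, catalog, dosage,
                removal_log=pd.DataFrame(log_rows, columns=["rsid", "reason"]),
            )
        )
    return GenotypeMatrix.concat_samples(parts)


def _match_alleles(rec: SnpRecord, ref: str, alts: list[str]):
    """Return (alt_index, complemented) for a catalog/VCF allele match.

    alt_index is the 1-based GT allele index carrying the archaic allele
    (or 0 meaning REF is archaic, returned as complemented=True);
    (None, False) when the pair cannot be matched in either orientation.
    """
    if ref == rec.ancestral_allele and rec.archaic_allele in alts:
        return alts.index(rec.archaic_allele) + 1, False
    if ref == rec.archaic_allele and rec.ancestral_allele in alts:
        if len(alts) > 1:
            raise CatalogError(
                f"{rec.locus}: multi-allelic record in swapped orientation "
                "cannot be decomposed"
            )
        return 0, True
    return None, False


def drop_incomplete_snps(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, list[SnpRecord]]:
    """Remove every SNP with >= 1 missing call across the pooled samples.

    The filter is strict and pooled: a single no-call in any individual of
    any group removes the SNP for the whole analysis, so all groups share
    one complete SNP set.  Returns the filtered matrix (zero missing
    entries) and the removed records; the matrix removal log gains one
    ``missing_call`` row per removed SNP not already logged as absent or
    mismatched.
    """
    if matrix.n_snps == 0:
        raise CatalogError("matrix has no SNPs")
    any_missing = matrix.missing_mask().any(axis=0)
    keep = ~any_missing
    if not keep.any():
        raise CatalogError(
            "all SNPs carry missing data; the catalog and VCF inputs are incompatible"
        )
    removed = [r for r, drop in zip(matrix.snps, any_missing) if drop]
    kept_rsids = [r.rsid for r, ok in zip(matrix.snps, keep) if ok]

    already = set(matrix.removal_log["rsid"])
    new_rows = [(r.rsid, "missing_call") for r in removed if r.rsid not in already]
    log = pd.concat(
        [matrix.removal_log, pd.DataFrame(new_rows, columns=["rsid", "reason"])],
        ignore_index=True,
    )
    out = GenotypeMatrix(
        list(matrix.sample_ids),
        matrix.snps.subset(kept_rsids),
        matrix.dosage[:, keep].copy(),
        removal_log=log,
    )
    logger.info(
        "missing-data filter: %d of %d SNPs removed, %d retained",
        len(removed), matrix.n_snps, out.n_snps,
    )
    return out, removed


# ---------------------------------------------------------------------------
# VCF / metadata writers


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as a minimal VCF v4.2 (GT only).

    REF is the ancestral allele and ALT the archaic one, so re-reading
    with :func:`genotypes_from_vcf` reproduces dosages exactly.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(r.chrom for r in matrix.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids) + "\n"
        )
        for j, rec in enumerate(matrix.snps):
            calls = "\t".join(gt_map[int(d)] for d in matrix.dosage[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.rsid}\t{rec.ancestral_allele}\t"
                f"{rec.archaic_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    return validate_sample_meta(df)


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"sample metadata: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise CatalogError(f"sample metadata: duplicate sample_id {dups}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise CatalogError(f"sample metadata: unknown group labels {sorted(bad)}")
    return df


def write_sample_meta(df: pd.DataFrame, path: str | Path) -> None:
    validate_sample_meta(df).to_csv(path, sep="\t", index=False)


def check_meta_matches_matrix(matrix: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Every matrix sample must have exactly one metadata row."""
    meta_ids = set(meta["sample_id"])
    orphans = [s for s in matrix.sample_ids if s not in meta_ids]
    if orphans:
        raise CatalogError(f"samples without metadata: {orphans[:5]}"
                           + ("..." if len(orphans) > 5 else ""))
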