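"""Readers and writers for the formats the pipeline touches, plus variant-level filters.

Coordinates are 1-based inclusive everywhere inside the package (the VCF
convention); BED's half-open 0-based intervals are converted at the boundary.
Genotypes are dosage-coded: the number of copies of the (first) alternate
allele carried by a diploid individual, with ``MISSING`` (-1) for uncalled
genotypes. ``MISSING`` is never used in arithmetic — every statistic downstream
works on non-missing calls only.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Distinguished dosage code for an uncalled genotype.
MISSING: int = -1

VALID_SEX = {"F", "M", "NA"}


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class PloidyError(ValueError):
    """Raised for genotype calls that are not diploid."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant: contig, 1-based position, ref allele and alt allele(s)."""

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, tuple[str, ...]]:
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with coordinates and sample metadata.

    ``dosage`` is an integer array of shape (n_samples, n_variants) with values
    in {0, 1, 2, MISSING}.  ``sample_meta`` (optional) is a DataFrame indexed by
    sample id with at least a ``population`` column; ``sex``, ``batch`` and
    numeric trait columns may follow.
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.sample_meta is not None:
            self._check_meta(self.sample_meta)

    def _check_meta(self, meta: pd.DataFrame) -> None:
        missing = [s for s in self.samples if s not in meta.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        if "population" not in meta.columns:
            raise ValueError("sample metadata must have a 'population' column")
        pops = meta.loc[self.samples, "population"]
        if pops.isna().any() or (pops.astype(str).str.len() == 0).any():
            raise ValueError("empty population label in metadata")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return np.array([v.pos for v in self.variants], dtype=np.int64)
        return np.array([v.pos for v in self.variants if v.chrom == chrom], dtype=np.int64)

    def variant_indices(self, chrom: str) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.variants) if v.chrom == chrom], dtype=np.int64)

    def find_variant(self, variant_id: str) -> int:
        """Index of the variant with the given id (or ``chrom:pos`` key)."""
        for i, v in enumerate(self.variants):
            if v.id == variant_id or f"{v.chrom}:{v.pos}" == variant_id:
                return i
        raise KeyError(f"variant {variant_id!r} not found")

    @property
    def populations(self) -> list[str]:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        pops = self.sample_meta.loc[self.samples, "population"]
        seen: dict[str, None] = {}
        for p in pops:
            seen.setdefault(str(p), None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to ``population``."""
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        pops = self.sample_meta.loc[self.samples, "population"].astype(str).to_numpy()
        idx = np.flatnonzero(pops == population)
        if idx.size == 0:
            raise KeyError(f"unknown population label {population!r}")
        return idx

    # -- derived views -----------------------------------------------------

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.int64)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx].copy(),
            sample_meta=self.sample_meta,
        )

    def attach_metadata(self, meta: pd.DataFrame) -> "GenotypeMatrix":
        self._check_meta(meta)
        return replace(self, sample_meta=meta)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields are coded as the count of non-reference alleles;
    ``./.`` and half-calls become :data:`MISSING`.  Multiallelic records are
    retained (they are removed by :func:`filter_variants`, not here).
    """
    path = str(path)
    try:
        vcf = VCF(path, lazy=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    try:
        for lineno, var in enumerate(vcf, start=1):
            alts = tuple(var.ALT) if var.ALT else ()
            variants.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alts,
                    id=None if var.ID in (None, ".") else var.ID,
                )
            )
            col = np.empty(len(samples), dtype=np.int16)
            for k, gt in enumerate(var.genotypes):
                # cyvcf2 yields [allele_1, ..., allele_ploidy, phased_flag]
                if len(gt) != 3:
                    raise PloidyError(
                        f"{path}: record {lineno} sample {samples[k]}: "
                        f"only diploid GT supported"
                    )
                a1, a2 = gt[0], gt[1]
                if a1 < 0 or a2 < 0:
                    col[k] = MISSING
                else:
                    col[k] = int(a1 > 0) + int(a2 > 0)
            columns.append(col)
    except PloidyError:
        raise
    except Exception as exc:
        raise VCFParseError(f"malformed VCF record in {path}: {exc}") from exc
    dosage = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF, sorted by (contig, position).

    Contigs keep their order of first appearance.  Duplicate
    (chrom, pos, alt) records are an error.
    """
    order_of: dict[str, int] = {}
    for v in gm.variants:
        order_of.setdefault(v.chrom, len(order_of))
    idx = sorted(range(gm.n_variants), key=lambda i: (order_of[gm.variants[i].chrom], gm.variants[i].pos))
    keys = [gm.variants[i].key for i in idx]
    if len(set(keys)) != len(keys):
        dups = pd.Series(keys)[pd.Series(keys).duplicated()].tolist()
        raise ValueError(f"duplicate variant records: {dups[:3]}")

    gt_code = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in order_of:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i in idx:
            v = gm.variants[i]
            gts = "\t".join(gt_code[int(d)] for d in gm.dosage[:, i])
            alt = ",".join(v.alt) if v.alt else "."
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Sample metadata and gene annotation


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Required columns: ``sample``, ``population``.  Optional: ``sex`` (F/M/NA),
    ``batch``, and any number of numeric trait columns.  Returns a DataFrame
    indexed by sample id.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "population"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample id(s) in metadata: {dup}")
    if "sex" in meta.columns:
        bad = set(meta["sex"].fillna("NA").astype(str)) - VALID_SEX
        if bad:
            raise ValueError(f"sex values outside {{F,M,NA}}: {sorted(bad)}")
    meta = meta.set_index("sample")
    return meta


def read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from a BED4+ file (0-based half-open -> 1-based inclusive)."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path} line {lineno}: BED needs >= 4 columns")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start0 >= end0:
                raise ValueError(f"{path} line {lineno}: start >= end in BED interval")
            strand = parts[5] if len(parts) >= 6 else "."
            if name in seen:
                raise ValueError(f"{path} line {lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneAnnotation(gene_id=name, chrom=chrom, start=start0 + 1, end=end0, strand=strand))
    return genes


def write_bed_genes(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Variant filtering


def filter_variants(
    gm: GenotypeMatrix,
    max_missing_ok: float = 0.9,
    maf_min: float = 0.05,
    keep_ids: Iterable[str] = (),
) -> GenotypeMatrix:
    """Keep biallelic variants with call rate >= ``max_missing_ok`` and
    minor allele frequency >= ``maf_min``.

    MAF is computed over non-missing calls only; ties at the threshold are
    kept (>= semantics).  Variants whose id is in ``keep_ids`` bypass the
    call-rate and MAF filters (but not the biallelic requirement), which is
    how structural deletion loci with extreme frequencies survive the scan
    filter.  Order is preserved; the result may be empty.
    """
    keep_ids = set(keep_ids)
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    call_rate = np.divide(n_called, gm.n_samples) if gm.n_samples else np.zeros(gm.n_variants)
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    biallelic = np.array([v.is_biallelic for v in gm.variants], dtype=bool)
    passes = biallelic & (call_rate >= max_missing_ok) & (maf >= maf_min)
    kept_by_id = np.array([v.id in keep_ids for v in gm.variants], dtype=bool)
    return gm.subset_variants(passes | (biallelic & kept_by_id))
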