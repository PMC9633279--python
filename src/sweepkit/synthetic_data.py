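"""Two-population synthetic genotype + trait datasets with a planted sweep.

The generator emulates, at desk scale, the statistical structure the scan and
association stages consume:

* background differentiation between two populations via the Balding–Nichols
  model — each population's allele frequency is a Beta draw around a shared
  ancestral frequency, parameterised by a differentiation coefficient F;
* one genomic region of locally elevated differentiation and reduced
  diversity in a swept (focal) population, produced by redrawing in-region
  frequencies with a much larger F and pushing them toward fixation;
* one or more biallelic deletion loci whose dosage affects a quantitative
  trait under the additive linear model y = b0 + Σ b·g + sex + batch + e,
  optionally with a two-locus product (interaction) term.

No linkage, recombination or demography is simulated: loci are independent
given their population frequencies, which is exactly the structure the
frequency-based scan statistics respond to.  All outputs are a pure function
of (config, seed).
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import yaml

from .io_formats import (
    MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    VariantRecord,
    write_bed_genes,
    write_vcf,
)

__all__ = [
    "SweepParams",
    "DeletionLocus",
    "TraitParams",
    "SimulationConfig",
    "SimTruth",
    "balding_nichols_freqs",
    "plant_sweep",
    "sample_genotypes",
    "simulate_trait",
    "simulate_dataset",
    "SimFreqs",
]


@dataclass(frozen=True)
class SweepParams:
    """Planted sweep: region, redraw differentiation, push toward fixation."""

    contig: str = "chr1"
    start: int = 4_850_000
    end: int = 5_150_000
    f_sweep: float = 0.6
    fixation_push: float = 0.9
    swept_population: str = "pop1"


@dataclass(frozen=True)
class DeletionLocus:
    """A trait-linked biallelic deletion with per-population frequencies."""

    contig: str = "chr1"
    pos: int = 5_000_000
    freq_pop1: float = 0.8
    freq_pop2: float = 0.15
    effect: float = 0.3  # trait units per deletion copy
    id: str = "del1"


@dataclass(frozen=True)
class TraitParams:
    """Additive trait model: intercept, sex/batch effects, residual SD, optional epistasis."""

    intercept: float = 15.0  # e.g. mean fibre diameter, micrometres
    sex_effect: float = 0.5  # added for males
    batch_effects: tuple[float, ...] = (0.0, 0.3)  # two phenotyping recorders
    residual_sd: float = 1.0
    interaction_effect: float | None = None  # product-term coefficient for the first two loci
    name: str = "trait"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_pop1: int = 50
    n_pop2: int = 50
    pop_labels: tuple[str, str] = ("pop1", "pop2")
    contigs: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    n_snps: int = 20_000
    f_background: float = 0.10
    sweep: SweepParams | None = field(default_factory=SweepParams)
    deletion_loci: tuple[DeletionLocus, ...] = (
        DeletionLocus(),
        DeletionLocus(contig="chr1", pos=8_000_000, freq_pop1=0.5, freq_pop2=0.4, effect=0.2, id="del2"),
    )
    trait: TraitParams = field(default_factory=TraitParams)
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.f_background < 1):
            raise ValueError("f_background must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.trait.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        lengths = dict(self.contigs)
        if self.sweep is not None:
            L = lengths.get(self.sweep.contig)
            if L is None or not (1 <= self.sweep.start <= self.sweep.end <= L):
                raise ValueError("sweep interval not within its contig")
        for dl in self.deletion_loci:
            if not (0 <= dl.freq_pop1 <= 1 and 0 <= dl.freq_pop2 <= 1):
                raise ValueError(f"deletion {dl.id}: frequencies must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth written alongside every simulated dataset."""

    seed: int
    sweep_region: tuple[str, int, int] | None
    swept_population: str | None
    deletion_effects: dict[str, float]
    interaction_effect: float | None
    deletion_freqs: dict[str, tuple[float, float]]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["sweep_region"] = tuple(raw["sweep_region"]) if raw["sweep_region"] else None
        raw["deletion_freqs"] = {k: tuple(v) for k, v in raw["deletion_freqs"].items()}
        return cls(**raw)


@dataclass
class SimFreqs:
    """Per-contig SNP positions with ancestral and per-population frequencies."""

    contig: str
    positions: np.ndarray  # sorted, 1-based
    p_anc: np.ndarray
    pop_freqs: dict[str, np.ndarray]


def balding_nichols_freqs(p_anc, F: float, n_pops: int, rng: np.random.Generator):
    """Per-population frequencies from the Balding–Nichols Beta model.

    Each population draws independently from
    Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is p and variance p(1−p)F.
    Returns an array of shape (n_pops,) for scalar ``p_anc`` or
    (n_pops, len(p_anc)) otherwise.
    """
    if not (0 < F < 1):
        raise ValueError("F must be strictly inside (0, 1)")
    p = np.asarray(p_anc, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops,) + p.shape)


def plant_sweep(freqs: SimFreqs, sweep: SweepParams, rng: np.random.Generator) -> SimFreqs:
    """Redraw the swept population's in-region frequencies with ``f_sweep`` and
    push them toward the nearer of {0, 1} by ``fixation_push``.

    p' = p·(1−push) for p < 0.5, else 1 − (1−p)·(1−push).  The other
    population is untouched.  A region containing no SNPs warns and is a
    no-op.
    """
    if freqs.contig != sweep.contig:
        return freqs
    in_region = (freqs.positions >= sweep.start) & (freqs.positions <= sweep.end)
    if not in_region.any():
        warnings.warn(f"sweep region {sweep.contig}:{sweep.start}-{sweep.end} contains no SNPs")
        return freqs
    p = balding_nichols_freqs(freqs.p_anc[in_region], sweep.f_sweep, 1, rng)[0]
    push = sweep.fixation_push
    p = np.where(p < 0.5, p * (1.0 - push), 1.0 - (1.0 - p) * (1.0 - push))
    out = dict(freqs.pop_freqs)
    swept = out[sweep.swept_population].copy()
    swept[in_region] = p
    out[sweep.swept_population] = swept
    return SimFreqs(freqs.contig, freqs.positions, freqs.p_anc, out)


def sample_genotypes(
    freq_sets: list[SimFreqs],
    sample_sizes: dict[str, int],
    missing_rate: float,
    rng: np.random.Generator,
    ref_alt: tuple[str, str] = ("A", "C"),
) -> GenotypeMatrix:
    """Draw dosages ~ Binomial(2, p_pop) per individual (HWE) with missingness.

    Samples are named ``<pop>_<k>``; variants take their positions from the
    frequency sets (already sorted within each contig).
    """
    for pop, n in sample_sizes.items():
        if n <= 0:
            raise ValueError(f"sample size for {pop} must be positive")
    samples: list[str] = []
    pops: list[str] = []
    for pop, n in sample_sizes.items():
        samples.extend(f"{pop}_{k:03d}" for k in range(1, n + 1))
        pops.extend([pop] * n)
    variants: list[VariantRecord] = []
    blocks: list[np.ndarray] = []
    for fs in freq_sets:
        m = len(fs.positions)
        block = np.empty((len(samples), m), dtype=np.int16)
        row = 0
        for pop, n in sample_sizes.items():
            block[row : row + n] = rng.binomial(2, fs.pop_freqs[pop], size=(n, m))
            row += n
        blocks.append(block)
        variants.extend(
            VariantRecord(chrom=fs.contig, pos=int(p), ref=ref_alt[0], alt=(ref_alt[1],))
            for p in fs.positions
        )
    dosage = np.concatenate(blocks, axis=1) if blocks else np.empty((len(samples), 0), dtype=np.int16)
    if missing_rate > 0 and dosage.size:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING
    meta = pd.DataFrame({"population": pops}, index=pd.Index(samples, name="sample"))
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage, sample_meta=meta)


def simulate_trait(
    gm: GenotypeMatrix,
    trait: TraitParams,
    deletion_loci: "list[DeletionLocus] | tuple[DeletionLocus, ...]",
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Attach sexes, batches and the simulated quantitative trait to the metadata.

    y = b0 + Σ b_k·g_k (+ b12·g1·g2) + sex_effect·1[male] + batch_effect + ε
    with ε ~ Normal(0, σ²).  Sexes are drawn 50/50 and batches uniformly over
    the configured batch effects (labels ``b1..bK``) unless the metadata
    already has those columns.  A sample with MISSING dosage at any causal
    locus gets a missing trait value.  Raises KeyError when a causal locus id
    is absent from the matrix.
    """
    ids = [dl.id for dl in deletion_loci]
    effects = {dl.id: dl.effect for dl in deletion_loci}
    return _simulate_trait_with_effects(gm, trait, ids, effects, rng)


@dataclass
class SimResult:
    gm: GenotypeMatrix
    truth: SimTruth
    genes: list[GeneAnnotation]
    config: SimulationConfig
    paths: dict[str, str] = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig, out_dir: str | Path | None = None) -> SimResult:
    """Run the full generator; optionally write VCF + metadata TSV + BED + truth JSON.

    Deterministic given (config, seed): a single seeded generator is consumed
    in a fixed documented order (ancestral frequencies, per-population
    Balding–Nichols draws, sweep redraw, positions, genotypes, missingness,
    deletion genotypes, sexes/batches, trait noise).
    """
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.contigs)
    pop1, pop2 = config.pop_labels
    # SNP counts per contig, proportional to length
    total_len = sum(lengths.values())
    freq_sets: list[SimFreqs] = []
    remaining = config.n_snps
    contig_names = list(lengths)
    for ci, contig in enumerate(contig_names):
        m = remaining if ci == len(contig_names) - 1 else int(round(config.n_snps * lengths[contig] / total_len))
        m = min(m, remaining)
        remaining -= m
        taken = {dl.pos for dl in config.deletion_loci if dl.contig == contig}
        pos = rng.choice(lengths[contig], size=m + len(taken), replace=False) + 1
        pos = np.sort(np.array([p for p in pos if p not in taken][:m], dtype=np.int64))
        p_anc = rng.uniform(0.05, 0.95, size=m)
        bn = balding_nichols_freqs(p_anc, config.f_background, 2, rng)
        fs = SimFreqs(contig, pos, p_anc, {pop1: bn[0], pop2: bn[1]})
        if config.sweep is not None and config.sweep.contig == contig:
            fs = plant_sweep(fs, config.sweep, rng)
        freq_sets.append(fs)
    gm = sample_genotypes(
        freq_sets,
        {pop1: config.n_pop1, pop2: config.n_pop2},
        config.missing_rate,
        rng,
    )
    # deletion loci: explicit per-population frequencies, HWE draws, indel-style alleles
    del_variants: list[VariantRecord] = []
    del_cols: list[np.ndarray] = []
    n1, n2 = config.n_pop1, config.n_pop2
    for dl in config.deletion_loci:
        col = np.concatenate(
            [
                rng.binomial(2, dl.freq_pop1, size=n1),
                rng.binomial(2, dl.freq_pop2, size=n2),
            ]
        ).astype(np.int16)
        if config.missing_rate > 0:
            col[rng.random(n1 + n2) < config.missing_rate] = MISSING
        del_cols.append(col)
        del_variants.append(VariantRecord(chrom=dl.contig, pos=dl.pos, ref="TA", alt=("T",), id=dl.id))
    if del_variants:
        variants = gm.variants + del_variants
        dosage = np.concatenate([gm.dosage] + [c[:, None] for c in del_cols], axis=1)
        order = sorted(
            range(len(variants)),
            key=lambda i: (contig_names.index(variants[i].chrom), variants[i].pos),
        )
        gm = GenotypeMatrix(
            variants=[variants[i] for i in order],
            samples=gm.samples,
            dosage=dosage[:, order],
            sample_meta=gm.sample_meta,
        )
    # trait
    deletion_ids = [dl.id for dl in config.deletion_loci]
    effect_by_id = {dl.id: dl.effect for dl in config.deletion_loci}
    gm = _simulate_trait_with_effects(gm, config.trait, deletion_ids, effect_by_id, rng)
    # fixture genes: one inside the sweep, one within 500 kb of it, one far beyond
    genes = _fixture_genes(config)
    truth = SimTruth(
        seed=config.seed,
        sweep_region=(
            (config.sweep.contig, config.sweep.start, config.sweep.end) if config.sweep else None
        ),
        swept_population=config.sweep.swept_population if config.sweep else None,
        deletion_effects=effect_by_id,
        interaction_effect=config.trait.interaction_effect,
        deletion_freqs={dl.id: (dl.freq_pop1, dl.freq_pop2) for dl in config.deletion_loci},
    )
    paths: dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(out / "genotypes.vcf"),
            "meta": str(out / "samples.tsv"),
            "bed": str(out / "genes.bed"),
            "truth": str(out / "truth.json"),
        }
        write_vcf(gm, paths["vcf"])
        gm.sample_meta.reset_index().rename(columns={"index": "sample"}).to_csv(
            paths["meta"], sep="\t", index=False, float_format="%.10g"
        )
        write_bed_genes(genes, paths["bed"])
        truth.to_json(paths["truth"])
    return SimResult(gm=gm, truth=truth, genes=genes, config=config, paths=paths)


def _simulate_trait_with_effects(
    gm: GenotypeMatrix,
    trait: TraitParams,
    deletion_ids: list[str],
    effect_by_id: dict[str, float],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    meta = gm.sample_meta.copy() if gm.sample_meta is not None else pd.DataFrame(index=gm.samples)
    n = gm.n_samples
    if "sex" not in meta.columns:
        meta["sex"] = np.where(rng.random(n) < 0.5, "F", "M")
    if "batch" not in meta.columns:
        meta["batch"] = [f"b{k + 1}" for k in rng.integers(0, len(trait.batch_effects), size=n)]
    batch_effect = np.array(
        [trait.batch_effects[int(str(b)[1:]) - 1] for b in meta.loc[gm.samples, "batch"]]
    )
    y = np.full(n, trait.intercept, dtype=float)
    dosages = []
    ok = np.ones(n, dtype=bool)
    for vid in deletion_ids:
        vi = gm.find_variant(vid)
        g = gm.dosage[:, vi].astype(float)
        miss = gm.dosage[:, vi] == MISSING
        ok &= ~miss
        g[miss] = 0.0
        dosages.append(g)
        y += effect_by_id[vid] * g
    if trait.interaction_effect is not None and len(dosages) >= 2:
        y += trait.interaction_effect * dosages[0] * dosages[1]
    y += np.where(meta.loc[gm.samples, "sex"].to_numpy() == "M", trait.sex_effect, 0.0)
    y += batch_effect
    y += rng.normal(0.0, trait.residual_sd, size=n)
    y[~ok] = np.nan
    meta[trait.name] = y
    return gm.attach_metadata(meta)


def _fixture_genes(config: SimulationConfig) -> list[GeneAnnotation]:
    if config.sweep is None:
        contig, L = config.contigs[0]
        return [GeneAnnotation("geneA", contig, 1_000_000, 1_050_000)]
    sw = config.sweep
    L = dict(config.contigs)[sw.contig]
    mid = (sw.start + sw.end) // 2
    genes = [
        GeneAnnotation("gene_in_sweep", sw.contig, mid - 25_000, mid + 25_000),
        GeneAnnotation("gene_near_sweep", sw.contig, min(sw.end + 250_000, L - 60_000), min(sw.end + 300_000, L - 10_000)),
        GeneAnnotation("gene_far_from_sweep", sw.contig, min(sw.end + 2_500_000, L - 60_000), min(sw.end + 2_550_000, L - 10_000)),
    ]
    return genes


# ---------------------------------------------------------------------------
# Config file round-trip (YAML key-value mirror of SimulationConfig)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "sweep" in raw and raw["sweep"] is not None:
        raw["sweep"] = SweepParams(**raw["sweep"])
    if "trait" in raw:
        tr = dict(raw["trait"])
        if "batch_effects" in tr:
            tr["batch_effects"] = tuple(tr["batch_effects"])
        raw["trait"] = TraitParams(**tr)
    if "deletion_loci" in raw:
        raw["deletion_loci"] = tuple(DeletionLocus(**d) for d in raw["deletion_loci"])
    if "contigs" in raw:
        raw["contigs"] = tuple((str(c), int(l)) for c, l in raw["contigs"])
    if "pop_labels" in raw:
        raw["pop_labels"] = tuple(raw["pop_labels"])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    # json round trip turns nested tuples into YAML-representable lists
    plain = json.loads(json.dumps(dataclasses.asdict(config)))
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(plain, fh, sort_keys=False)
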