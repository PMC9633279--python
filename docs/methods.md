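# Methods

This note records the statistical definitions the package implements, the
choices made where more than one convention exists, what the synthetic-data
generator does and does not emulate, and the numerical policies for edge
cases.

## Scan statistics

**Nucleotide diversity (θπ).** Per site, with j alternate alleles among n
non-missing alleles, π = 2j(n−j)/(n(n−1)) — the unbiased average pairwise
difference. A window's value is the sum of site π over in-window SNPs divided
by the window size in bp (so windows are comparable regardless of SNP
density). This matches the semantics of the widely used VCF windowed-π tools.
Sites where a population has fewer than two called alleles contribute
nothing for that population.

**F<sub>ST</sub>.** The Weir & Cockerham (1984) moment estimator for two
populations. Per site we compute the among-population component *a* and the
total *a + b + c* from (n̄, n_c, p̄, s², h̄) over non-missing genotypes; the
window estimate is the ratio of sums Σa / Σ(a+b+c) ("weighted" F<sub>ST</sub>),
never the mean of per-site ratios — the two differ whenever site information
varies, and a dedicated test asserts the difference on a crafted fixture.
Negative estimates are retained as computed so the genome-wide
Z-transformation sees the full distribution shape. Sites are skipped when a
population has no calls or when n̄ ≤ 1 (the b component's factor
n̄/(n̄−1) is undefined for one-individual-per-population sites).

**ZF<sub>ST</sub>.** (x − mean)/SD with sample SD (ddof = 1), computed over
retained windows genome-wide. Windows flagged `BELOW_MIN_SNPS` (fewer than
`min_snps` SNPs, default 10 — a policy knob, exposed in `WindowSpec`) are
excluded from the mean/SD and get no Z-score.

**log2 θπ ratio.** log2(θπ_focal / θπ_reference); the focal population is
always the scan's `pop_a`. Windows where either diversity is exactly zero are
flagged `RATIO_UNDEFINED` and excluded from ranking. Outlier calling uses the
absolute value, so sweeps in either population can be detected; the sign then
identifies the swept side (negative = focal).

**Tajima's D.** D = (π̂ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
constants (a₁ = Σ1/i, a₂ = Σ1/i², b₁ = (n+1)/(3(n−1)),
b₂ = 2(n²+n+3)/(9n(n−1)), c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁²,
e₁ = c₁/a₁, e₂ = c₂/(a₁²+a₂)); π̂ is the absolute (not per-bp) sum of site π.
The constants assume a fixed number of sampled chromosomes, but missingness
makes n vary by site; we use the window's **minimum** per-site n, a
conservative single-n approximation. D is undefined (NaN) when S = 0 or the
minimum n < 4. The implementation is cross-checked against an independent
published implementation of the same constants (dendropy) and a from-scratch
harmonic-sum oracle.

**LD decay.** r² is the squared Pearson correlation of unphased dosage
vectors over pairwise-complete samples (no phasing or haplotype EM — the
genotype-correlation surrogate standard for unphased data). Pairs are binned
by physical distance (bin k covers ((k−1)w, kw]); for independent loci the
expected r² is ≈ 1/n, which the tests verify.

## Outlier calling and annotation

Windows start at 1 + k·step and are kept only if they fit entirely inside
the contig. Thresholds are the (1−q) quantiles (linear interpolation between
order statistics, numpy's default "type 7" — pinned for reproducibility) of
ZF<sub>ST</sub> and |log2 ratio| over retained windows, with q = 0.01; a
window is an outlier when it meets **both** thresholds, ties included
(≥ semantics). Outlier windows that overlap or are separated by at most
`max_gap` (default one step) merge into regions. A gene is a candidate for a
region when the gene interval extended by the flank (default 500 kb on each
side) intersects the region. The fine-scale confirmation profile uses
nonoverlapping windows (size = step = 10 kb) computed genome-wide and
Z-standardised over their own genome-wide distribution, not the 150-kb one —
scale-consistent standardisation.

The thresholds are always recomputed from the data at hand and logged; on
real genome-scale data they land near the familiar single-digit
ZF<sub>ST</sub> / sub-1 |log2 ratio| range, while on the 10-Mb synthetic toy
genome they are larger because a 300-kb sweep is a much bigger fraction of
986 windows than any real sweep is of a whole genome.

## Distances and trees

The p-distance between two diploid individuals is the mean over
pairwise-complete sites of |gᵢ − gⱼ|/2: opposite homozygotes differ by 1,
homozygote vs heterozygote by 1/2, and two heterozygotes by 0. The het–het
convention is not universal (an allele-mismatch-probability table gives 0.5);
it is exposed as `het_het=` and defaults to the plain dosage-difference form.
A sample pair sharing no called site is an error rather than a silent NaN.

Neighbor joining is the Saitou–Nei agglomeration on the Q criterion
Q(i,j) = (r−2)d(i,j) − Rᵢ − Rⱼ, with the standard branch-length formulas,
ties broken by the lexicographically smallest pair of subtree labels
(deterministic output), and negative branch lengths clamped to zero without
redistribution. NJ is exact on additive matrices; the tests verify exact
recovery of distances from random binary trees and agreement with
scikit-bio's implementation. The tree is left unrooted (outgroup rooting is
the consumer's choice); Newick output quotes labels containing
metacharacters and prints branch lengths at 6 significant digits.

## Association model

`y = b0 + b·x + sex + batch + e` with x the 0/1/2 dosage of the deletion
allele — additive coding only, no dominance term. Covariates: sex as F/M,
batch as an unordered categorical one-hot encoded against the first level.
Fitting is ordinary least squares via `lstsq`, SEs from s²(XᵀX)⁻¹ with
s² = SSE/(n − rank), two-sided p from Student t. Analysis is complete-case
(no imputation); a covariate that is constant in the analysed subset — e.g.
sex in an all-female production panel — is dropped with a note instead of
crashing the fit. A numerically perfect fit reports p = 0 with a
`PERFECT_FIT` flag rather than NaN. Rank deficiency is an error that names
the collinear columns. The two-locus model adds g₁·g₂ and reports the
product term. A `log_transform` flag fits log(y) for right-skewed traits; it
is offered, not endorsed — raw scale is the default.

## The synthetic generator

The generator emulates exactly the statistical structure the scan and the
association stage consume, and nothing more:

- **Background divergence** — Balding–Nichols: each population's frequency at
  a locus is Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
  p ~ Uniform(0.05, 0.95) (keeps loci informative after the MAF filter; site
  frequency spectrum realism is not a goal), with F_background = 0.10 by
  default. Genotypes are Binomial(2, p_pop) per individual (HWE), positions
  uniform without replacement, 2% of cells missing at random.
- **The sweep** — emulated at the allele-frequency level: in-region
  frequencies of the swept population are redrawn with F_sweep = 0.6 and
  pushed toward the nearer of {0, 1} by a factor 0.9
  (p′ = p(1−push) for p < 0.5, else 1 − (1−p)(1−push)). No forward
  simulation of selection, linkage or recombination: the scan consumes only
  frequency/diversity patterns, and this transform produces the defining
  signature (locally elevated differentiation, crushed focal diversity,
  negative focal Tajima's D) at desk-scale cost.
- **Geometry** — one 10-Mb contig, 20,000 SNPs, 50+50 individuals, sweep at
  chr1:4,850,000–5,150,000. The 300-kb width keeps the planted sweep a small
  multiple of the scan's top-1% window budget, the same relation real sweeps
  (≈ 1 Mb in a multi-Gb genome) have to a genome-wide scan; a sweep spanning
  ten percent of the toy genome would swamp the joint top-1% criterion in a
  way that is an artifact of miniaturisation, not a property of the method.
- **Deletions and trait** — two deletion loci with explicit per-population
  frequencies (defaults 0.8/0.15 inside the sweep and 0.5/0.4 elsewhere,
  echoing the high-in-swept/low-in-reference contrast of real causative
  deletions), per-copy effects 0.3 and 0.2 trait units (placeholders for
  recovery tests, not estimates of any real effect), intercept 15, sex
  effect 0.5, two batches (0, 0.3) mirroring a two-recorder phenotyping
  design, residual SD 1, optional product-term effect. Sexes 50/50, batches
  uniform.
- **Fixture genes** — one gene inside the sweep, one 250 kb beyond its edge
  (within the 500-kb annotation flank), one 2.5 Mb away (outside it), so the
  annotation flank logic is testable end to end.

Everything is a pure function of (config, seed): one `numpy` Generator
consumed in a fixed order (ancestral frequencies, per-population draws,
sweep redraw, positions, genotypes, missingness, deletion genotypes,
sexes/batches, trait noise), and the same seed reproduces byte-identical
output files.

**What passing tests do and do not show.** The generator has no linkage
disequilibrium between SNPs, no demography, no selection dynamics, no
genotyping error beyond random missingness, and a flat recombination-free
genome. Tests against it therefore demonstrate that the estimators and the
outlier logic are implemented correctly and calibrated under their model
assumptions — not that the scan has any particular power or false-positive
behaviour on real resequencing data, where LD, complex demography and
uneven SNP density all matter.

## Numerical and policy details

- Coordinates are 1-based inclusive everywhere internally; BED's 0-based
  half-open intervals are converted at the boundary.
- `MISSING` (−1) is a distinguished dosage code, excluded from every
  denominator exactly; phased (`|`) and unphased (`/`) separators are
  equivalent since dosage coding is phase-free.
- The variant filter keeps biallelic sites with call rate ≥ 0.9 and minor
  allele frequency ≥ 0.05 over non-missing calls, ties kept (≥); it is
  idempotent. Multiallelic records are parsed and carried, and removed only
  by the filter (parsing and policy are separate). A keep-list exempts named
  variants (the deletion loci, whose frequencies are legitimately extreme)
  from the call-rate/MAF rules but not from the biallelic rule.
- Flagged windows are removed before quantile ranking, and the counts are
  recorded in the call set; the `q = 1` degenerate case selects every
  retained window.
- Problem sizes in the test-suite calibrations — 20 simulation seeds for
  sweep recovery, 2,000 null replicates (n = 200) for type-I error, 200
  replicates for CI coverage (n = 500 single-locus, n = 800 interaction),
  100 random fixtures for oracle equivalence — were chosen so the binomial
  noise of each check sits well inside its asserted tolerance while the
  whole suite stays desk-scale.

## Known limitations

- Two populations only; no multi-population F<sub>ST</sub>, no
  haplotype-based statistics (iHS, XP-EHH), no composite-likelihood sweep
  methods.
- Tajima's D under heavy, uneven missingness is conservative because of the
  minimum-n constants policy.
- The association stage fits fixed-effects OLS only — no kinship/mixed-model
  correction, so it is appropriate for the designed two-candidate-locus
  setting, not for genome-wide scans in structured samples.
- NJ is O(n³) in pure Python/numpy; fine for hundreds of samples, not for
  tens of thousands.
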