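"""Per-site and windowed population-genetic statistics.

Implements the scan's building blocks: per-site nucleotide diversity
(θπ, the unbiased pairwise-heterozygosity estimator), the Weir & Cockerham
(1984) two-population Fst variance components windowed as a ratio of sums,
Tajima's D, genome-wide Z-standardisation, log2 diversity ratios, and
dosage-correlation r² with distance-binned LD decay.

Missing genotypes are excluded site-by-site: per-site allele counts n are
the non-missing allele counts of the population at that site.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "WindowSpec",
    "site_pi",
    "windowed_pi",
    "wc_fst_site",
    "windowed_fst",
    "tajimas_d",
    "tajima_constants",
    "zscore",
    "log2_pi_ratio",
    "dosage_r2",
    "ld_decay",
    "population_site_counts",
    "per_site_components",
]

Window = tuple[str, int, int]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window size, step and minimum SNP count."""

    size: int = 150_000
    step: int = 10_000
    min_snps: int = 10

    def __post_init__(self) -> None:
        if not (self.size >= self.step >= 1):
            raise ValueError(f"need size >= step >= 1, got size={self.size} step={self.step}")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


# ---------------------------------------------------------------------------
# Per-site primitives


def site_pi(alt_count, called_n):
    """Unbiased per-site nucleotide diversity 2j(n−j)/(n(n−1)).

    ``alt_count`` j is the number of alternate alleles among ``called_n`` n
    non-missing alleles.  Accepts scalars or arrays; n < 2 raises for scalars
    and yields NaN for arrays.
    """
    j = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_n, dtype=float)
    if np.any(j < 0) or np.any(j > n):
        raise ValueError("need 0 <= alt_count <= called_n")
    scalar = j.ndim == 0 and n.ndim == 0
    if scalar and n < 2:
        raise ValueError("site undefined: fewer than 2 called alleles")
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * j * (n - j) / (n * (n - 1)), np.nan)
    return float(pi) if scalar else pi


def population_site_counts(gm: GenotypeMatrix, sample_idx: np.ndarray):
    """Per-variant (alt allele count j, called allele count n, het genotype count)."""
    d = gm.dosage[np.asarray(sample_idx)]
    called = d != MISSING
    n = 2 * called.sum(axis=0)
    j = np.where(called, d, 0).sum(axis=0)
    het = (d == 1).sum(axis=0)
    return j.astype(np.int64), n.astype(np.int64), het.astype(np.int64)


def wc_fst_site(n_a, p_a, h_a, n_b, p_b, h_b):
    """Weir & Cockerham (1984) two-population per-site variance components.

    Inputs are per population: ``n`` called individuals, ``p`` alternate
    allele frequency, ``h`` observed heterozygote proportion (all over
    non-missing genotypes).  Returns ``(a, a + b + c)``: the among-population
    component and the total.  Site Fst is ``a / (a + b + c)`` where the total
    is non-zero.  Sites where either population has no calls, or where
    n̄ <= 1 (the b component is undefined), yield NaN components and are
    skipped by callers.  Vectorised over arrays.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    r = 2.0
    n_tot = n_a + n_b
    n_bar = n_tot / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n_tot - (n_a**2 + n_b**2) / n_tot) / (r - 1.0)
        p_bar = (n_a * p_a + n_b * p_b) / n_tot
        s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n_a * h_a + n_b * h_b) / n_tot
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        total = a + b + c
    bad = (n_a < 1) | (n_b < 1) | (n_bar <= 1.0) | ~np.isfinite(total)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, total)
    if a.ndim == 0:
        return float(a), float(total)
    return a, total


def per_site_components(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-variant table of everything the windowed scan consumes.

    Columns: chrom, pos, ``pi_a``/``pi_b`` (per-site π, NaN when a population
    has < 2 called alleles), ``fst_a``/``fst_d`` (W&C a and a+b+c components,
    NaN for skipped sites), ``n_a``/``n_b`` (called allele counts) and
    ``seg_a``/``seg_b`` (segregating within each population).
    """
    ia = gm.sample_indices(pop_a)
    ib = gm.sample_indices(pop_b)
    j_a, n_a, het_a = population_site_counts(gm, ia)
    j_b, n_b, het_b = population_site_counts(gm, ib)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(n_a > 0, j_a / n_a, np.nan)
        p_b = np.where(n_b > 0, j_b / n_b, np.nan)
        hprop_a = np.where(n_a > 0, het_a / (n_a / 2.0), np.nan)
        hprop_b = np.where(n_b > 0, het_b / (n_b / 2.0), np.nan)
    a, d = wc_fst_site(n_a / 2.0, p_a, hprop_a, n_b / 2.0, p_b, hprop_b)
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "pi_a": site_pi(j_a, n_a),
            "pi_b": site_pi(j_b, n_b),
            "fst_a": a,
            "fst_d": d,
            "n_a": n_a,
            "n_b": n_b,
            "seg_a": (j_a > 0) & (j_a < n_a),
            "seg_b": (j_b > 0) & (j_b < n_b),
        }
    )


# ---------------------------------------------------------------------------
# Windowed statistics (single-window reference API)


def _window_sites(gm: GenotypeMatrix, window: Window) -> np.ndarray:
    chrom, start, end = window
    return np.array(
        [i for i, v in enumerate(gm.variants) if v.chrom == chrom and start <= v.pos <= end],
        dtype=np.int64,
    )


def windowed_pi(gm: GenotypeMatrix, population: str, window: Window) -> float:
    """Per-bp nucleotide diversity of one window: Σ site π / window size (bp)."""
    chrom, start, end = window
    idx = _window_sites(gm, window)
    if idx.size == 0:
        return 0.0
    j, n, _ = population_site_counts(gm, gm.sample_indices(population))
    pi = site_pi(j[idx], n[idx])
    return float(np.nansum(pi)) / (end - start + 1)


def windowed_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str, window: Window) -> float:
    """Weighted (ratio-of-sums) Weir–Cockerham Fst of one window.

    Σa / Σ(a+b+c) over usable in-window sites; NaN when no site is usable.
    Negative values are retained as computed.
    """
    comp = per_site_components(gm, pop_a, pop_b)
    chrom, start, end = window
    sel = (comp["chrom"] == chrom) & (comp["pos"] >= start) & (comp["pos"] <= end)
    a = comp.loc[sel, "fst_a"].to_numpy()
    d = comp.loc[sel, "fst_d"].to_numpy()
    ok = np.isfinite(d)
    denom = d[ok].sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1,a2,b1,b2,c1,c2,e1,e2 constants of Tajima's D for sample size n alleles."""
    if n < 2:
        raise ValueError("need n >= 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(gm: GenotypeMatrix, population: str, window: Window) -> float:
    """Tajima's D over the window's sites for one population.

    D = (π̂ − S/a1) / sqrt(e1·S + e2·S(S−1)) with π̂ the absolute sum of
    per-site π.  Per-site called allele counts vary with missingness; the
    constants use the window's minimum per-site n (a conservative fixed-n
    approximation).  Undefined (NaN) when S = 0 or the minimum n < 4.
    """
    idx = _window_sites(gm, window)
    if idx.size == 0:
        return float("nan")
    j, n, _ = population_site_counts(gm, gm.sample_indices(population))
    j, n = j[idx], n[idx]
    usable = n >= 2
    if not usable.any():
        return float("nan")
    j, n = j[usable], n[usable]
    s = int(np.sum((j > 0) & (j < n)))
    n_min = int(n.min())
    if s == 0 or n_min < 4:
        return float("nan")
    pi_hat = float(np.sum(site_pi(j, n)))
    k = tajima_constants(n_min)
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    return (pi_hat - theta_w) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Transforms


def zscore(values) -> np.ndarray:
    """Standardise to zero mean, unit sample SD (ddof=1) over finite entries.

    NaN entries (flagged windows) pass through as NaN and do not contribute
    to the mean/SD.  Raises on fewer than 2 finite values or zero spread.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 retained values to Z-transform")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: Z-transform undefined")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def log2_pi_ratio(pi_a: float, pi_b: float) -> float:
    """log2(pi_a / pi_b); NaN (ratio undefined) unless both are > 0."""
    if pi_a < 0 or pi_b < 0:
        raise ValueError("diversities must be non-negative")
    if pi_a == 0 or pi_b == 0:
        return float("nan")
    return float(np.log2(pi_a / pi_b))


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def dosage_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete samples.

    NaN when fewer than 2 complete pairs or either locus has zero variance.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay(
    gm: GenotypeMatrix,
    population: str | None = None,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
) -> pd.DataFrame:
    """Distance-binned LD decay: mean r² of same-contig variant pairs.

    Pairs at distance d fall in bin ``ceil(d / bin_width)``; the table reports
    every bin up to ``max_dist`` with its midpoint, mean r² (NaN when empty)
    and pair count.  Restricted to one population when given.
    """
    if population is not None:
        rows = gm.sample_indices(population)
    else:
        rows = np.arange(gm.n_samples)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in gm.chroms:
        idx = gm.variant_indices(chrom)
        pos = np.array([gm.variants[i].pos for i in idx])
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        for ii in range(len(idx)):
            jj = ii + 1
            while jj < len(idx) and pos[jj] - pos[ii] <= max_dist:
                d = int(pos[jj] - pos[ii])
                if d > 0:
                    r2 = dosage_r2(gm.dosage[rows, idx[ii]], gm.dosage[rows, idx[jj]])
                    if np.isfinite(r2):
                        b = (d - 1) // bin_width
                        sums[b] += r2
                        counts[b] += 1
                jj += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_width
    return pd.DataFrame({"dist_mid": mids, "mean_r2": mean_r2, "n_pairs": counts})
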