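"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit loops, pair
enumeration, closed forms, or third-party libraries) and deliberately shares
no code with the package paths it checks.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

MISSING = -1


# -- nucleotide diversity ----------------------------------------------------


def site_pi_pairs(alt_count: int, called_n: int) -> float:
    """Per-site pi by explicit enumeration of allele pairs."""
    alleles = [1] * alt_count + [0] * (called_n - alt_count)
    pairs = list(combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def window_pi_brute(gm, population: str, window) -> float:
    chrom, start, end = window
    rows = gm.sample_indices(population)
    total = 0.0
    for vi, v in enumerate(gm.variants):
        if v.chrom != chrom or not (start <= v.pos <= end):
            continue
        calls = [int(gm.dosage[r, vi]) for r in rows if gm.dosage[r, vi] != MISSING]
        n = 2 * len(calls)
        if n < 2:
            continue
        j = sum(calls)
        total += site_pi_pairs(j, n)
    return total / (end - start + 1)


# -- Weir & Cockerham Fst ----------------------------------------------------


def wc_site_brute(calls_a: list[int], calls_b: list[int]):
    """Per-site W&C (1984) variance components from raw dosage lists.

    Returns (a, a+b+c) or None for a skipped site (no calls in a population,
    or n_bar <= 1).
    """
    n_a, n_b = len(calls_a), len(calls_b)
    if n_a < 1 or n_b < 1 or (n_a + n_b) / 2.0 <= 1.0:
        return None
    r = 2
    p_a = sum(calls_a) / (2.0 * n_a)
    p_b = sum(calls_b) / (2.0 * n_b)
    h_a = sum(1 for c in calls_a if c == 1) / n_a
    h_b = sum(1 for c in calls_b if c == 1) / n_b
    n_bar = (n_a + n_b) / 2.0
    n_c = (n_a + n_b - (n_a**2 + n_b**2) / (n_a + n_b)) / (r - 1)
    p_bar = (n_a * p_a + n_b * p_b) / (n_a + n_b)
    s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n_a * h_a + n_b * h_b) / (n_a + n_b)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    if not np.isfinite(a + b + c):
        return None
    return a, a + b + c


def window_fst_brute(gm, pop_a: str, pop_b: str, window) -> float:
    chrom, start, end = window
    ra = gm.sample_indices(pop_a)
    rb = gm.sample_indices(pop_b)
    num = den = 0.0
    any_site = False
    for vi, v in enumerate(gm.variants):
        if v.chrom != chrom or not (start <= v.pos <= end):
            continue
        ca = [int(gm.dosage[r, vi]) for r in ra if gm.dosage[r, vi] != MISSING]
        cb = [int(gm.dosage[r, vi]) for r in rb if gm.dosage[r, vi] != MISSING]
        comp = wc_site_brute(ca, cb)
        if comp is None:
            continue
        any_site = True
        num += comp[0]
        den += comp[1]
    if not any_site or den == 0:
        return float("nan")
    return num / den


# -- Tajima's D --------------------------------------------------------------


def tajimas_d_brute(seg_js: list[int], pi_hat: float, n: int) -> float:
    """D from explicit harmonic sums at fixed n; seg_js are the segregating counts."""
    s = len(seg_js)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_hat - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def window_tajd_brute(gm, population: str, window) -> float:
    chrom, start, end = window
    rows = gm.sample_indices(population)
    js, ns, pis = [], [], []
    for vi, v in enumerate(gm.variants):
        if v.chrom != chrom or not (start <= v.pos <= end):
            continue
        calls = [int(gm.dosage[r, vi]) for r in rows if gm.dosage[r, vi] != MISSING]
        n = 2 * len(calls)
        if n < 2:
            continue
        j = sum(calls)
        js.append(j)
        ns.append(n)
        pis.append(site_pi_pairs(j, n))
    if not ns:
        return float("nan")
    seg = [j for j, n in zip(js, ns) if 0 < j < n]
    n_min = min(ns)
    if not seg or n_min < 4:
        return float("nan")
    return tajimas_d_brute(seg, sum(pis), n_min)


# -- r², p-distance, OLS -----------------------------------------------------


def r2_brute(g1, g2) -> float:
    g1, g2 = np.asarray(g1), np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok].astype(float), g2[ok].astype(float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic ** 2)


def pdist_brute(gm) -> np.ndarray:
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0
            for vi in range(gm.n_variants):
                gi, gj = int(gm.dosage[i, vi]), int(gm.dosage[j, vi])
                if gi == MISSING or gj == MISSING:
                    continue
                num += abs(gi - gj) / 2.0
                den += 1
            d[i, j] = num / den
    return d


def simple_ols_brute(x, y):
    """Closed-form simple regression: slope, intercept, SE(slope), t, p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = b / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    return b, a, se, t, p
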