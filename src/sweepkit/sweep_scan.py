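"""Genome scan for selective sweeps between two populations.

Tiles each contig into sliding windows (150 kb / 10 kb steps by default),
computes per-window diversity (θπ for both populations), weighted
Weir–Cockerham Fst, Tajima's D, then Z-standardises Fst genome-wide and forms
log2 θπ ratios (focal population in the numerator).  Windows in the joint top
quantile of ZFst and |log2 ratio| are candidate sweep outliers; adjacent
outliers merge into regions, which are annotated with genes overlapping the
region or lying within a flank (500 kb by default).  A nonoverlapping
fine-window profile (10 kb) over a region provides the confirmation view:
in a genuine focal-population sweep, ZFst spikes while focal diversity and
Tajima's D drop.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GenotypeMatrix
from .popgen_stats import (
    WindowSpec,
    per_site_components,
    tajima_constants,
    zscore,
)

__all__ = [
    "SweepCallSet",
    "make_windows",
    "scan_windows",
    "select_joint_outliers",
    "merge_outlier_regions",
    "annotate_candidate_genes",
    "fine_scale_profile",
]

FLAG_BELOW_MIN_SNPS = "BELOW_MIN_SNPS"
FLAG_RATIO_UNDEFINED = "RATIO_UNDEFINED"

#: Window-statistic TSV column order.
STAT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_snps",
    "pi_a",
    "pi_b",
    "fst",
    "zfst",
    "log2_ratio",
    "tajd_a",
    "tajd_b",
    "flags",
]


@dataclass
class SweepCallSet:
    """Joint top-quantile outlier call: thresholds, windows, regions, genes."""

    window_spec: WindowSpec
    q: float
    zfst_cut: float
    abs_log2_cut: float
    outliers: pd.DataFrame
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: list[list[str]] = field(default_factory=list)
    comparison: str = ""

    def summary(self) -> dict:
        return {
            "comparison": self.comparison,
            "q": self.q,
            "zfst_cut": self.zfst_cut,
            "abs_log2_cut": self.abs_log2_cut,
            "n_outlier_windows": int(len(self.outliers)),
            "n_regions": int(len(self.regions)),
            "regions": self.regions.to_dict(orient="records") if len(self.regions) else [],
            "genes": self.genes,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, default=str)


def make_windows(contig_lengths: Mapping[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Windows starting at 1 + k·step, kept only when fully inside the contig."""
    rows = []
    for chrom, length in contig_lengths.items():
        if length < spec.size:
            warnings.warn(f"contig {chrom} ({length} bp) shorter than window size {spec.size}")
            continue
        n = (length - spec.size) // spec.step + 1
        starts = 1 + spec.step * np.arange(n, dtype=np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + spec.size - 1}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def _contig_lengths_from_gm(gm: GenotypeMatrix) -> dict[str, int]:
    return {chrom: int(gm.positions(chrom).max()) for chrom in gm.chroms}


def _scan_engine(
    comp: pd.DataFrame,
    windows: pd.DataFrame,
    min_snps: int,
    window_size: int,
) -> pd.DataFrame:
    """Vectorised window aggregation of the per-site component table."""
    out = {
        "n_snps": np.zeros(len(windows), dtype=np.int64),
        "pi_a": np.zeros(len(windows)),
        "pi_b": np.zeros(len(windows)),
        "fst": np.full(len(windows), np.nan),
        "tajd_a": np.full(len(windows), np.nan),
        "tajd_b": np.full(len(windows), np.nan),
    }
    for chrom, wsel in windows.groupby("chrom", sort=False).groups.items():
        sub = comp[comp["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        pi_a = np.nan_to_num(sub["pi_a"].to_numpy()[order])
        pi_b = np.nan_to_num(sub["pi_b"].to_numpy()[order])
        fa = sub["fst_a"].to_numpy()[order]
        fd = sub["fst_d"].to_numpy()[order]
        fst_ok = np.isfinite(fd)
        n_a = sub["n_a"].to_numpy()[order]
        n_b = sub["n_b"].to_numpy()[order]
        seg_a = sub["seg_a"].to_numpy()[order]
        seg_b = sub["seg_b"].to_numpy()[order]
        widx = np.asarray(wsel)
        starts = windows.loc[widx, "start"].to_numpy()
        ends = windows.loc[widx, "end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for w, (i0, i1) in zip(widx, zip(lo, hi)):
            if i1 <= i0:
                continue
            out["n_snps"][w] = i1 - i0
            out["pi_a"][w] = pi_a[i0:i1].sum() / window_size
            out["pi_b"][w] = pi_b[i0:i1].sum() / window_size
            d_sum = np.nansum(fd[i0:i1])
            if fst_ok[i0:i1].any() and d_sum != 0:
                out["fst"][w] = np.nansum(fa[i0:i1]) / d_sum
            out["tajd_a"][w] = _tajd_window(n_a[i0:i1], seg_a[i0:i1], pi_a[i0:i1])
            out["tajd_b"][w] = _tajd_window(n_b[i0:i1], seg_b[i0:i1], pi_b[i0:i1])
    stats = windows.copy()
    for k, v in out.items():
        stats[k] = v
    flags = np.where(stats["n_snps"] < min_snps, FLAG_BELOW_MIN_SNPS, "")
    stats["flags"] = flags
    retained = stats["flags"] == ""
    # ZFst over retained windows with a defined Fst, genome-wide
    z = np.full(len(stats), np.nan)
    zin = retained & np.isfinite(stats["fst"])
    if zin.sum() >= 2 and np.nanstd(stats.loc[zin, "fst"]) > 0:
        z[zin.to_numpy()] = zscore(stats.loc[zin, "fst"].to_numpy())
    stats["zfst"] = z
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (stats["pi_a"] > 0) & (stats["pi_b"] > 0),
            np.log2(stats["pi_a"] / stats["pi_b"]),
            np.nan,
        )
    stats["log2_ratio"] = ratio
    undef = retained & ~np.isfinite(stats["log2_ratio"])
    stats.loc[undef, "flags"] = np.where(
        stats.loc[undef, "flags"] == "", FLAG_RATIO_UNDEFINED,
        stats.loc[undef, "flags"] + ";" + FLAG_RATIO_UNDEFINED,
    )
    return stats[STAT_COLUMNS]


def _tajd_window(n: np.ndarray, seg: np.ndarray, pi_sites: np.ndarray) -> float:
    usable = n >= 2
    if not usable.any():
        return np.nan
    n, seg, pi_sites = n[usable], seg[usable], pi_sites[usable]
    s = int(seg.sum())
    n_min = int(n.min())
    if s == 0 or n_min < 4:
        return np.nan
    k = tajima_constants(n_min)
    pi_hat = float(pi_sites.sum())
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    return (pi_hat - s / k["a1"]) / np.sqrt(var)


def scan_windows(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    spec: WindowSpec = WindowSpec(),
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Run the two-population windowed scan.

    Population A is the focal population: ``log2_ratio`` is
    log2(θπ_A / θπ_B), strongly negative where A has swept.  ``zfst`` is the
    genome-wide Z-transform of the weighted window Fst over retained
    (>= min_snps) windows.  Windows are flagged rather than dropped.
    """
    for pop in (pop_a, pop_b):
        if gm.sample_indices(pop).size < 2:
            raise ValueError(f"population {pop!r} needs >= 2 individuals")
    if contig_lengths is None:
        contig_lengths = _contig_lengths_from_gm(gm)
    windows = make_windows(contig_lengths, spec)
    comp = per_site_components(gm, pop_a, pop_b)
    if windows.empty:
        empty = windows.copy()
        for c in STAT_COLUMNS:
            if c not in empty:
                empty[c] = []
        return empty[STAT_COLUMNS]
    return _scan_engine(comp, windows, spec.min_snps, spec.size)


def select_joint_outliers(
    stats: pd.DataFrame,
    q: float = 0.01,
    spec: WindowSpec | None = None,
    comparison: str = "",
) -> SweepCallSet:
    """Call the windows in the joint top-q tails of ZFst and |log2 ratio|.

    Thresholds are the (1−q) linear-interpolation quantiles over retained
    windows; a window is an outlier when zfst >= zfst_cut AND
    |log2_ratio| >= abs_log2_cut (ties included).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    retained = stats[~stats["flags"].str.contains(FLAG_BELOW_MIN_SNPS, na=False)]
    if retained.empty:
        raise ValueError("all windows flagged below the SNP minimum; nothing to rank")
    if len(retained) < 1 / q:
        warnings.warn(f"only {len(retained)} retained windows for q={q}; thresholds unstable")
    zvals = retained["zfst"].to_numpy()
    rvals = np.abs(retained["log2_ratio"].to_numpy())
    zvals = zvals[np.isfinite(zvals)]
    rvals = rvals[np.isfinite(rvals)]
    if zvals.size == 0 or rvals.size == 0:
        raise ValueError("no finite ZFst / log2 ratio values to rank")
    zfst_cut = float(np.quantile(zvals, 1 - q))
    abs_log2_cut = float(np.quantile(rvals, 1 - q))
    sel = (
        (retained["zfst"] >= zfst_cut)
        & (np.abs(retained["log2_ratio"]) >= abs_log2_cut)
    ).fillna(False)
    outliers = retained[sel].sort_values(["chrom", "start"]).reset_index(drop=True)
    return SweepCallSet(
        window_spec=spec or WindowSpec(),
        q=q,
        zfst_cut=zfst_cut,
        abs_log2_cut=abs_log2_cut,
        outliers=outliers,
        comparison=comparison,
    )


def merge_outlier_regions(outliers: pd.DataFrame, max_gap: int = 10_000) -> pd.DataFrame:
    """Union outlier windows that overlap or lie within ``max_gap`` bp into regions."""
    if outliers.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    rows = []
    for chrom, sub in outliers.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        n = 0
        for _, w in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, n = int(w["start"]), int(w["end"]), 1
            elif w["start"] <= cur_end + max_gap + 1:
                cur_end = max(cur_end, int(w["end"]))
                n += 1
            else:
                rows.append((chrom, cur_start, cur_end, n))
                cur_start, cur_end, n = int(w["start"]), int(w["end"]), 1
        rows.append((chrom, cur_start, cur_end, n))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_candidate_genes(
    regions: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    flank: int = 500_000,
) -> list[list[str]]:
    """Candidate genes per region: gene ± flank intersects the region.

    Returns one position-sorted, deduplicated gene-id list per region row.
    """
    out: list[list[str]] = []
    for _, reg in regions.iterrows():
        hits = [
            g
            for g in genes
            if g.chrom == reg["chrom"]
            and g.start - flank <= reg["end"]
            and g.end + flank >= reg["start"]
        ]
        hits = sorted(set(hits), key=lambda g: (g.start, g.end, g.gene_id))
        out.append([g.gene_id for g in hits])
    return out


def fine_scale_profile(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    region: tuple[str, int, int],
    fine_size: int = 10_000,
    contig_lengths: Mapping[str, int] | None = None,
    full: bool = False,
) -> pd.DataFrame:
    """Nonoverlapping fine-window confirmation profile over a region.

    Fine windows (size = step = ``fine_size``) are computed genome-wide and
    Z-standardised over their own genome-wide distribution, then the rows
    overlapping ``region`` are returned (all rows when ``full``).
    """
    spec = WindowSpec(size=fine_size, step=fine_size, min_snps=1)
    stats = scan_windows(gm, pop_a, pop_b, spec, contig_lengths=contig_lengths)
    if full:
        return stats
    chrom, start, end = region
    sel = (stats["chrom"] == chrom) & (stats["end"] >= start) & (stats["start"] <= end)
    return stats[sel].reset_index(drop=True)


def write_stats_tsv(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_stats_tsv(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t")
    stats["flags"] = stats["flags"].fillna("")
    return stats
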