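"""Windowed nucleotide diversity (θπ) and LD decay.

Per-site π uses the unbiased count form C(n_c,2) − Σ_a C(n_a,2) over
C(n_c,2); window θπ divides the summed per-site π by the window span in bp
(full span, not callable sites), matching the familiar windowed-pi output of
VCF toolchains.  LD is phased haplotype r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeMatrix, assign_sites


def site_pi(alleles: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference; NaN where < 2 calls."""
    miss = alleles == MISSING
    n_c = (~miss).sum(axis=1).astype(float)
    alt = np.where(miss, 0, alleles).sum(axis=1).astype(float)
    ref = n_c - alt
    pairs = n_c * (n_c - 1) / 2.0
    same = alt * (alt - 1) / 2.0 + ref * (ref - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, (pairs - same) / pairs, np.nan)
    return pi


def window_pi(matrix: HaplotypeMatrix, windows) -> pd.DataFrame:
    """θπ per bp for each window; windows without usable sites are dropped."""
    pi = site_pi(matrix.alleles)
    usable = ~np.isnan(pi)
    rows = []
    for w, idx in zip(windows, assign_sites(windows, matrix.positions)):
        if w.chrom != matrix.chrom:
            continue
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        rows.append((w.chrom, w.start, w.end, idx.size, pi[idx].sum() / w.span))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray  # nbins+1 bp distances, bins are (lo, hi]
    mean_r2: np.ndarray
    n_pairs: np.ndarray


def _pair_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Haplotype r² between two allele columns (complete haplotypes only)."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    a, b = col_a[ok].astype(float), col_b[ok].astype(float)
    n = a.size
    if n < 2:
        return np.nan
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return np.nan
    d = (a * b).mean() - pa * pb
    return d * d / (va * vb)


def ld_decay(matrix: HaplotypeMatrix, max_dist=50_000, bin_width=1_000) -> LDDecayCurve:
    """Mean haplotype r² in distance bins for all site pairs within max_dist."""
    matrix.require_phased("LD decay")
    if max_dist <= 0 or bin_width <= 0 or max_dist % bin_width:
        raise ValueError("max_dist must be a positive multiple of bin_width")
    n_bins = max_dist // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    pos = matrix.positions
    for i in range(matrix.n_sites):
        j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        for j in range(i + 1, j_hi):
            r2 = _pair_r2(matrix.alleles[i], matrix.alleles[j])
            if np.isnan(r2):
                continue
            b = int((pos[j] - pos[i] - 1) // bin_width)
            sums[b] += r2
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    return LDDecayCurve(edges, mean, counts)


def ld_curve_frame(curve: LDDecayCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "bin_start": curve.bin_edges[:-1],
        "bin_end": curve.bin_edges[1:],
        "mean_r2": curve.mean_r2,
        "n_pairs": curve.n_pairs,
    })
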