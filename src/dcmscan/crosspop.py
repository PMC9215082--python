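"""Weir–Cockerham F_ST and EHH / XP-EHH between two populations.

F_ST uses the 1984 variance-component estimator (a: among populations,
b: among individuals within populations, c: within individuals), with the
weighted ratio-of-sums Σa/Σ(a+b+c) per window.  XP-EHH integrates the
whole-sample extended haplotype homozygosity curve (trapezoid over physical
bp, cutoff 0.05, maximum extension 1 Mb) on each side of every core site in
both populations and reports ln(iHH_A/iHH_B), standardised genome-wide.
Population A (the target breed) is the numerator, so positive scores mean
longer haplotypes — more recent selection — in A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import ihh_side
from .core import MISSING, HaplotypeMatrix, assign_sites

EHH_CUTOFF = 0.05
MAX_EXTEND = 1_000_000


# ---------------------------------------------------------------- F_ST ----

def _genotype_summaries(alleles: np.ndarray):
    """Per-site (n complete genotypes, alt frequency, het fraction)."""
    a0 = alleles[:, 0::2]
    a1 = alleles[:, 1::2]
    ok = (a0 != MISSING) & (a1 != MISSING)
    n = ok.sum(axis=1).astype(float)
    alt = np.where(ok, a0 + a1, 0).sum(axis=1).astype(float)
    het = (ok & (a0 != a1)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_fst_wc(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components for two populations.

    Arguments are per-site arrays: sample size in diploid individuals, alt
    allele frequency and observed heterozygote fraction for each population.
    Returns (a, b, c, fst) with fst = a/(a+b+c), NaN where the denominator
    is zero or a population has fewer than two genotypes.
    """
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c, fst):
        arr[bad] = np.nan
    return a, b, c, fst


@dataclass
class FstComponents:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fst: np.ndarray  # per-site a/(a+b+c)


def fst_components(matrix_a: HaplotypeMatrix, matrix_b: HaplotypeMatrix) -> FstComponents:
    if not np.array_equal(matrix_a.positions, matrix_b.positions):
        raise ValueError("populations must share the same site list")
    n1, p1, h1 = _genotype_summaries(matrix_a.alleles)
    n2, p2, h2 = _genotype_summaries(matrix_b.alleles)
    return FstComponents(*site_fst_wc(n1, p1, h1, n2, p2, h2))


def window_fst(comp: FstComponents, positions, windows) -> pd.DataFrame:
    """Weighted (ratio-of-sums) and mean-of-ratios F_ST per window."""
    usable = ~(np.isnan(comp.a) | np.isnan(comp.b) | np.isnan(comp.c))
    rows = []
    for w, idx in zip(windows, assign_sites(windows, positions)):
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        denom = (comp.a[idx] + comp.b[idx] + comp.c[idx]).sum()
        weighted = comp.a[idx].sum() / denom if denom != 0 else np.nan
        per_site = comp.fst[idx]
        mean_ratio = np.nanmean(per_site) if np.any(~np.isnan(per_site)) else np.nan
        rows.append((w.chrom, w.start, w.end, idx.size, weighted, mean_ratio))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "fst", "fst_mean"])


# --------------------------------------------------------- EHH / XP-EHH ----

@dataclass
class EHHCurve:
    core_position: int
    direction: str  # 'left' or 'right'
    offsets: np.ndarray  # bp distances from the core, increasing
    ehh: np.ndarray


def ehh(matrix: HaplotypeMatrix, core_index: int, direction: str,
        max_extend=MAX_EXTEND) -> EHHCurve:
    """Whole-sample EHH extending site by site from a core.

    At offset x the haplotype partition uses every site from the core through
    x inclusive; EHH(0) = 1 by the zero-length-interval convention.
    """
    matrix.require_phased("EHH")
    step = {"right": 1, "left": -1}[direction]
    n_hap = matrix.n_haplotypes
    if n_hap < 2:
        raise ValueError("EHH needs at least two haplotypes")
    total_pairs = n_hap * (n_hap - 1) / 2.0
    keys = [tuple(matrix.alleles[core_index])]
    offsets, values = [0], [1.0]
    j = core_index + step
    while 0 <= j < matrix.n_sites:
        d = abs(int(matrix.positions[j]) - int(matrix.positions[core_index]))
        if d > max_extend:
            break
        keys.append(tuple(matrix.alleles[j]))
        _, counts = np.unique(np.array(keys).T, axis=0, return_counts=True)
        e = (counts * (counts - 1) / 2.0).sum() / total_pairs
        offsets.append(d)
        values.append(e)
        j += step
    return EHHCurve(int(matrix.positions[core_index]), direction,
                    np.array(offsets), np.array(values))


def ihh(matrix: HaplotypeMatrix, core_index: int,
        cutoff=EHH_CUTOFF, max_extend=MAX_EXTEND) -> float:
    """Two-sided integrated EHH (bp) around a core site."""
    matrix.require_phased("iHH")
    alleles = np.ascontiguousarray(matrix.alleles)
    left = ihh_side(alleles, matrix.positions, core_index, -1, cutoff, max_extend)
    right = ihh_side(alleles, matrix.positions, core_index, 1, cutoff, max_extend)
    return float(left + right)


def xpehh(matrix_a: HaplotypeMatrix, matrix_b: HaplotypeMatrix,
          cutoff=EHH_CUTOFF, max_extend=MAX_EXTEND) -> pd.DataFrame:
    """Raw (unstandardised) XP-EHH at every core site of one contig.

    Returns columns (pos, ihh_a, ihh_b, xpehh_raw); cores where either iHH
    is zero are dropped.  Standardisation is genome-wide and therefore done
    by the caller across contigs (:func:`standardize_xpehh`).
    """
    for m in (matrix_a, matrix_b):
        m.require_phased("XP-EHH")
    if not np.array_equal(matrix_a.positions, matrix_b.positions):
        raise ValueError("populations must share the same site list")
    aa = np.ascontiguousarray(matrix_a.alleles)
    bb = np.ascontiguousarray(matrix_b.alleles)
    pos = matrix_a.positions
    rows = []
    for i in range(len(pos)):
        ia = ihh_side(aa, pos, i, -1, cutoff, max_extend) + \
            ihh_side(aa, pos, i, 1, cutoff, max_extend)
        ib = ihh_side(bb, pos, i, -1, cutoff, max_extend) + \
            ihh_side(bb, pos, i, 1, cutoff, max_extend)
        if ia <= 0.0 or ib <= 0.0:
            continue
        # log difference, not log of the ratio: keeps population swap
        # exactly antisymmetric in floating point
        rows.append((int(pos[i]), ia, ib, np.log(ia) - np.log(ib)))
    return pd.DataFrame(rows, columns=["pos", "ihh_a", "ihh_b", "xpehh_raw"])


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardisation; all-zero (with warning) if degenerate."""
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0.0:
        import warnings
        warnings.warn("XP-EHH scores have zero variance; reporting zeros")
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def window_xpehh(core_pos, std_scores, windows) -> pd.DataFrame:
    """Per-window mean of standardised XP-EHH core scores."""
    core_pos = np.asarray(core_pos)
    std_scores = np.asarray(std_scores)
    rows = []
    for w, idx in zip(windows, assign_sites(windows, core_pos)):
        if idx.size == 0:
            continue
        rows.append((w.chrom, w.start, w.end, std_scores[idx].mean()))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "xpehh"])
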