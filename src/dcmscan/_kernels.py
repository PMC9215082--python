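"""Numba inner loops for the forward simulator and haplotype homozygosity."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def assemble_gametes(haps, parents, starts, bp_counts, bp_sites, out):
    """Build gametes by copying parental segments between crossover points.

    haps : (2N, S) int8 parental haplotypes (site columns position-sorted)
    parents : (G,) parent individual index per gamete
    starts : (G,) which parental haplotype (0/1) the gamete starts on
    bp_counts : (G,) crossovers per gamete
    bp_sites : flat crossover site indices, sorted within each gamete
    out : (G, S) int8 output
    """
    ptr = 0
    n_sites = out.shape[1]
    for g in range(out.shape[0]):
        p = parents[g]
        h = starts[g]
        prev = 0
        for _ in range(bp_counts[g]):
            idx = bp_sites[ptr]
            ptr += 1
            row = haps[2 * p + h]
            for j in range(prev, idx):
                out[g, j] = row[j]
            h = 1 - h
            prev = idx
        row = haps[2 * p + h]
        for j in range(prev, n_sites):
            out[g, j] = row[j]


@numba.njit(cache=True)
def colsum_int8(mat, out):
    """Accumulate per-column sums of an int8 matrix into ``out`` (int64)."""
    for i in range(mat.shape[0]):
        row = mat[i]
        for j in range(row.shape[0]):
            out[j] += row[j]


@numba.njit(cache=True)
def rebuild_columns(mat, srcidx, mut_rows, out):
    """Reorder/select columns and splice new single-carrier mutation columns.

    ``srcidx[j] >= 0``: output column j copies input column srcidx[j];
    ``srcidx[j] < 0``: output column j is a fresh mutation column, all zero
    except row ``mut_rows[-srcidx[j] - 1]`` (−1 when the mutation belongs to
    the other population).  Row-major traversal keeps every pass sequential.
    """
    for i in range(mat.shape[0]):
        row = mat[i]
        orow = out[i]
        for j in range(srcidx.shape[0]):
            s = srcidx[j]
            if s >= 0:
                orow[j] = row[s]
            else:
                orow[j] = 1 if mut_rows[-s - 1] == i else 0


@numba.njit(cache=True)
def ihh_side(alleles, positions, core, step, cutoff, max_extend):
    """One-sided integrated EHH (trapezoid over bp) from a core site.

    The haplotype partition at each offset is refined by every site from the
    core (inclusive) through the offset; EHH at zero length is 1 by
    convention.  Integration adds the segment leading to each new point and
    stops once EHH falls below ``cutoff`` (the crossing segment is included)
    or the extension exceeds ``max_extend`` bp or the contig ends.
    """
    n_sites, n_hap = alleles.shape
    total_pairs = n_hap * (n_hap - 1) / 2.0
    if total_pairs == 0:
        return 0.0
    labels = np.zeros(n_hap, dtype=np.int64)
    mapbuf = np.full(3 * n_hap, -1, dtype=np.int64)
    counts = np.zeros(n_hap, dtype=np.int64)
    touched = np.empty(n_hap, dtype=np.int64)
    # partition by the core column itself
    n_labels = _refine(alleles, core, labels, mapbuf, touched)
    prev_d = 0.0
    prev_e = 1.0
    ihh = 0.0
    j = core + step
    while 0 <= j < n_sites:
        d = abs(positions[j] - positions[core])
        if d > max_extend:
            break
        n_labels = _refine(alleles, j, labels, mapbuf, touched)
        for i in range(n_labels):
            counts[i] = 0
        for i in range(n_hap):
            counts[labels[i]] += 1
        pairs = 0.0
        for i in range(n_labels):
            pairs += counts[i] * (counts[i] - 1) / 2.0
        e = pairs / total_pairs
        ihh += (prev_e + e) / 2.0 * (d - prev_d)
        if e < cutoff:
            break
        prev_d = d
        prev_e = e
        j += step
    return ihh


@numba.njit(cache=True)
def _refine(alleles, site, labels, mapbuf, touched):
    """Split partition ``labels`` by the allele column at ``site`` in place."""
    n_hap = labels.shape[0]
    n_new = 0
    for i in range(n_hap):
        a = alleles[site, i]
        key = labels[i] * 3 + (a + 1)  # allele in {-1, 0, 1}
        if mapbuf[key] < 0:
            mapbuf[key] = n_new
            touched[n_new] = key
            n_new += 1
        labels[i] = mapbuf[key]
    for k in range(n_new):
        mapbuf[touched[k]] = -1
    return n_new
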