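"""Core genomic data types: haplotype matrices, window grids, regions.

Coordinates are 1-based inclusive throughout (VCF convention); BED export
converts to 0-based half-open at the writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing haplotype call

#: canonical column order of the per-window statistics table
STAT_COLUMNS = [
    "chrom", "start", "end", "n_sites",
    "pi", "clr", "fst", "xpehh",
    "p_pi", "p_clr", "p_fst", "p_xpehh",
    "dcms", "p_dcms", "q",
]


class HaplotypeMatrix:
    """Phased biallelic alleles for one population on one contig.

    ``alleles`` is a sites x haplotypes int8 array with values 0, 1 or
    :data:`MISSING`.  Haplotype columns come in consecutive pairs, one pair
    per sample in ``sample_ids`` order.
    """

    def __init__(self, chrom, positions, alleles, sample_ids, phased=True):
        positions = np.asarray(positions, dtype=np.int64)
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites x haplotypes)")
        if positions.shape[0] != alleles.shape[0]:
            raise ValueError("positions and alleles disagree on site count")
        if positions.size > 1 and not np.all(np.diff(positions) > 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        if alleles.shape[1] != 2 * len(sample_ids):
            raise ValueError("haplotype count must be 2 x sample count")
        if alleles.shape[0] and (alleles != MISSING).sum(axis=1).min() < 1:
            raise ValueError("every site needs at least one non-missing call")
        self.chrom = str(chrom)
        self.positions = positions
        self.alleles = alleles
        self.sample_ids = list(sample_ids)
        self.phased = bool(phased)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def take_sites(self, index) -> "HaplotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        return HaplotypeMatrix(
            self.chrom, self.positions[index], self.alleles[index],
            self.sample_ids, self.phased,
        )

    def require_phased(self, statistic: str) -> None:
        if not self.phased:
            raise ValueError(
                f"{statistic} requires phased haplotypes but {self.chrom} is unphased"
            )

    def __repr__(self):  # pragma: no cover
        return (f"HaplotypeMatrix({self.chrom}, {self.n_sites} sites, "
                f"{len(self.sample_ids)} samples, phased={self.phased})")


@dataclass(frozen=True)
class Window:
    """1-based inclusive genomic interval of the sliding grid."""
    chrom: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window {self.chrom}:{self.start}-{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class Region:
    """Union of overlapping/abutting significant windows, plus its genes."""
    chrom: str
    start: int
    end: int
    min_q: float
    member_windows: list = field(default_factory=list)
    genes: list = field(default_factory=list)


def make_windows(contig_lengths, window_size=50_000, step=20_000):
    """Sliding windows of ``window_size`` every ``step`` bp per contig.

    Windows start at 1, 1+step, ... while the start lies on the contig; the
    last windows are truncated at the contig end (their θπ denominator later
    uses the actual span).
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    windows = []
    for chrom, length in contig_lengths.items():
        length = int(length)
        for start in range(1, length + 1, step):
            windows.append(Window(str(chrom), start, min(start + window_size - 1, length)))
    return windows


def assign_sites(windows, positions):
    """Per-window index arrays into ``positions`` (all windows same contig)."""
    positions = np.asarray(positions)
    out = []
    for w in windows:
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="right")
        out.append(np.arange(lo, hi))
    return out


def merge_significant_windows(stats: pd.DataFrame, q_threshold=0.05, merge=True):
    """Merge windows with q below threshold into candidate regions.

    Selected windows on one contig that overlap or abut (gap of 0 bp) are
    unioned; ``min_q`` is the minimum member q.  With ``merge=False`` each
    significant window becomes its own region.
    """
    if "q" not in stats.columns or stats["q"].isna().any():
        raise ValueError("q must be present for all windows")
    sig = stats.loc[stats["q"] < q_threshold].sort_values(["chrom", "start", "end"])
    regions: list[Region] = []
    for row in sig.itertuples():
        w = (row.chrom, int(row.start), int(row.end), float(row.q))
        if (merge and regions and regions[-1].chrom == w[0]
                and w[1] <= regions[-1].end + 1):
            r = regions[-1]
            r.end = max(r.end, w[2])
            r.min_q = min(r.min_q, w[3])
            r.member_windows.append(w)
        else:
            regions.append(Region(w[0], w[1], w[2], w[3], member_windows=[w]))
    return regions
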