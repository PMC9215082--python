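"""Site-level filtering.

Mirrors the usual VCFtools semantics: ``--maf 0.05`` keeps sites with minor
allele frequency >= 0.05 (boundary inclusive, MAF computed on non-missing
haplotypes) and ``--max-missing 0.9`` keeps sites with at least 90% of calls
present, i.e. a missing rate of at most 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, HaplotypeMatrix


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    max_missing_rate: float = 0.1
    biallelic_only: bool = True  # enforced upstream by the VCF reader

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")


def site_frequencies(alleles: np.ndarray):
    """Per-site (alt frequency, missing rate) over non-missing haplotypes."""
    miss = alleles == MISSING
    n_called = (~miss).sum(axis=1)
    alt = np.where(miss, 0, alleles).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    miss_rate = miss.sum(axis=1) / alleles.shape[1]
    return freq, miss_rate


def apply_site_filters(matrix: HaplotypeMatrix, cfg: FilterConfig | None = None,
                       extra_alleles: np.ndarray | None = None):
    """Filter sites by MAF and missingness; returns (matrix, removal counts).

    ``extra_alleles`` (same site order) lets the MAF be computed on a pooled
    two-population sample while filtering this population's matrix, keeping
    site sets aligned for the cross-population statistics.

    Criteria are checked in a fixed order (missingness first, then MAF) and
    each removed site is charged to the first criterion it fails, so the
    counts plus the retained total always sum to the input count.
    """
    cfg = cfg or FilterConfig()
    if extra_alleles is not None:
        pooled = np.concatenate([matrix.alleles, extra_alleles], axis=1)
    else:
        pooled = matrix.alleles
    freq, _ = site_frequencies(pooled)
    _, miss_rate = site_frequencies(matrix.alleles)
    maf = np.minimum(freq, 1.0 - freq)

    fail_miss = miss_rate > cfg.max_missing_rate
    fail_maf = ~fail_miss & ((maf < cfg.maf_min) | np.isnan(maf))
    keep = ~(fail_miss | fail_maf)
    counts = {
        "input": matrix.n_sites,
        "removed_missing": int(fail_miss.sum()),
        "removed_maf": int(fail_maf.sum()),
        "retained": int(keep.sum()),
    }
    if matrix.n_sites and counts["retained"] == 0:
        import warnings
        warnings.warn(f"all {matrix.n_sites} sites removed by filters on "
                      f"{matrix.chrom}")
    return matrix.take_sites(np.flatnonzero(keep)), counts
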