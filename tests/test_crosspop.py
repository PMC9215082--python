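"""Weir–Cockerham F_ST and EHH / XP-EHH oracles and symmetries."""

import numpy as np
import pytest

from dcmscan.core import HaplotypeMatrix, make_windows
from dcmscan.crosspop import (ehh, fst_components, ihh, site_fst_wc,
                              standardize_xpehh, window_fst, window_xpehh,
                              xpehh)
from tests.conftest import random_matrix


# ------------------------------------------------------------------ F_ST ---

def wc84_components(samples):
    """Independent transcription of Weir & Cockerham (1984), eqns 2-4.

    ``samples`` is a list of (n_i diploids, p_i alt frequency, h_i observed
    heterozygote fraction), one tuple per population.  Plain-Python sums so
    the arithmetic shares nothing with the vectorised implementation.
    """
    r = len(samples)
    nbar = sum(n for n, _, _ in samples) / r
    nc = (r * nbar - sum(n * n for n, _, _ in samples) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in samples) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in samples) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in samples) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_fixed_difference_gives_fst_exactly_one():
    a, b, c, fst = site_fst_wc([10.0], [1.0], [0.0], [10.0], [0.0], [0.0])
    assert fst[0] == 1.0
    assert b[0] == 0.0 and c[0] == 0.0


def test_equal_frequencies_give_nonpositive_estimate():
    a, b, c, fst = site_fst_wc([10.0], [0.5], [0.5], [10.0], [0.5], [0.5])
    assert a[0] <= 0.0
    assert fst[0] <= 0.0


def test_components_match_independent_wc84_transcription(rng):
    for _ in range(50):
        n1, n2 = 10.0, 10.0
        c1 = rng.integers(0, 21)  # alt allele count among 2n
        c2 = rng.integers(0, 21)
        het1 = rng.integers(0, min(c1, 20 - c1) + 1)
        het2 = rng.integers(0, min(c2, 20 - c2) + 1)
        args = (n1, c1 / 20, het1 / 10, n2, c2 / 20, het2 / 10)
        a, b, c, _ = site_fst_wc(*[[v] for v in args])
        oa, ob, oc = wc84_components([(n1, c1 / 20, het1 / 10),
                                      (n2, c2 / 20, het2 / 10)])
        assert a[0] == pytest.approx(oa, abs=1e-12)
        assert b[0] == pytest.approx(ob, abs=1e-12)
        assert c[0] == pytest.approx(oc, abs=1e-12)


def test_fst_invariant_to_allele_relabel_and_population_swap():
    args = ([8.0], [0.7], [0.3], [9.0], [0.2], [0.4])
    _, _, _, fst = site_fst_wc(*args)
    _, _, _, fst_rel = site_fst_wc([8.0], [0.3], [0.3], [9.0], [0.8], [0.4])
    _, _, _, fst_swap = site_fst_wc([9.0], [0.2], [0.4], [8.0], [0.7], [0.3])
    assert fst[0] == pytest.approx(fst_rel[0], abs=1e-12)
    assert fst[0] == pytest.approx(fst_swap[0], abs=1e-12)


def _pop(alleles, chrom="1", positions=None):
    alleles = np.asarray(alleles, np.int8)
    positions = positions if positions is not None else np.arange(1, len(alleles) + 1)
    n_samp = alleles.shape[1] // 2
    return HaplotypeMatrix(chrom, positions, alleles,
                           [f"s{i}" for i in range(n_samp)])


def test_window_of_fixed_differences_has_fst_one():
    a = _pop(np.ones((5, 8)))
    b = _pop(np.zeros((5, 8)))
    comp = fst_components(a, b)
    df = window_fst(comp, a.positions, make_windows({"1": 10}, 10, 10))
    assert df.fst.iloc[0] == pytest.approx(1.0, abs=1e-15)


def test_single_site_window_equals_per_site_estimate(rng):
    a = random_matrix(rng, n_sites=1, n_samples=6, max_pos=10)
    b = random_matrix(rng, n_sites=1, n_samples=6, max_pos=10)
    b = _pop(b.alleles, positions=a.positions)
    comp = fst_components(a, b)
    df = window_fst(comp, a.positions, make_windows({"1": 10}, 10, 10))
    if np.isnan(comp.fst[0]):
        assert len(df) == 0 or np.isnan(df.fst.iloc[0])
    else:
        assert df.fst.iloc[0] == pytest.approx(comp.fst[0], abs=1e-12)


def test_mismatched_site_lists_rejected(rng):
    a = random_matrix(rng, n_sites=5, n_samples=3, max_pos=100)
    b = random_matrix(rng, n_sites=5, n_samples=3, max_pos=200)
    while np.array_equal(a.positions, b.positions):  # pragma: no cover
        b = random_matrix(rng, n_sites=5, n_samples=3, max_pos=200)
    with pytest.raises(ValueError):
        fst_components(a, b)


# ------------------------------------------------------------- EHH / iHH ---

def brute_force_ehh(alleles, core, j):
    """Fraction of haplotype pairs identical over sites core..j inclusive."""
    lo, hi = min(core, j), max(core, j)
    seg = alleles[lo:hi + 1]
    n = seg.shape[1]
    same = sum(1 for x in range(n) for y in range(x + 1, n)
               if np.array_equal(seg[:, x], seg[:, y]))
    return same / (n * (n - 1) / 2)


def test_identical_haplotypes_keep_ehh_at_one():
    col = np.zeros((6, 4), np.int8)
    m = _pop(col)
    curve = ehh(m, 2, "right")
    assert np.allclose(curve.ehh, 1.0)


def test_four_haplotypes_splitting_in_two_pairs_give_one_third():
    alleles = np.array([[0, 0, 1, 1],
                        [0, 0, 1, 1]], np.int8)  # split at flanking site
    alleles[1] = [0, 1, 0, 1]
    m = _pop(alleles)
    curve = ehh(m, 0, "right")
    assert curve.ehh[0] == 1.0  # zero-length convention... core column only
    # core splits {0,0,1,1} into two pairs: but EHH(0)=1 by convention;
    # at the flanking site the partition refines to singletons except pairs
    oracle = brute_force_ehh(m.alleles, 0, 1)
    assert curve.ehh[1] == pytest.approx(oracle, abs=1e-15)


def test_ehh_matches_pair_count_oracle_on_random_toys(rng):
    for _ in range(40):
        n_hap = int(rng.integers(4, 9))
        n_sites = int(rng.integers(3, 10))
        alleles = rng.integers(0, 2, size=(n_sites, 2 * ((n_hap + 1) // 2)))
        alleles = alleles[:, :n_hap - (n_hap % 2) or None]
        if alleles.shape[1] % 2:
            continue
        m = _pop(alleles)
        core = int(rng.integers(0, n_sites))
        for direction, step in (("right", 1), ("left", -1)):
            curve = ehh(m, core, direction)
            for k, off in enumerate(curve.offsets):
                if k == 0:
                    assert curve.ehh[0] == 1.0
                    continue
                j = core + step * k
                oracle = brute_force_ehh(m.alleles, core, j)
                assert curve.ehh[k] == pytest.approx(oracle, abs=1e-15)


def test_ehh_is_non_increasing(rng):
    for _ in range(10):
        m = random_matrix(rng, n_sites=12, n_samples=4, max_pos=2_000)
        curve = ehh(m, 5, "right")
        # EHH(0)=1 is a convention and may exceed the core-site value; the
        # partition-refinement values themselves never increase
        assert (np.diff(curve.ehh[1:]) <= 1e-15).all()


def ihh_oracle(m, core, cutoff=0.05, max_extend=1_000_000):
    """Trapezoid integral of the two-sided EHH curve with cutoff semantics."""
    total = 0.0
    for direction in ("left", "right"):
        curve = ehh(m, core, direction, max_extend=max_extend)
        prev_d, prev_e = 0.0, 1.0
        for d, e in zip(curve.offsets[1:], curve.ehh[1:]):
            total += (prev_e + e) / 2 * (d - prev_d)
            if e < cutoff:
                break
            prev_d, prev_e = d, e
    return total


def test_ihh_kernel_matches_pure_python_integration(rng):
    for _ in range(20):
        m = random_matrix(rng, n_sites=15, n_samples=4, max_pos=3_000)
        core = int(rng.integers(0, m.n_sites))
        assert ihh(m, core) == pytest.approx(ihh_oracle(m, core), abs=1e-9)


def test_ihh_positive_with_at_least_two_haplotypes(rng):
    m = random_matrix(rng, n_sites=10, n_samples=3, max_pos=1_000)
    assert ihh(m, 5) > 0


# ---------------------------------------------------------------- XP-EHH ---

def test_identical_populations_give_raw_zero_and_warned_zeros(rng):
    m = random_matrix(rng, n_sites=20, n_samples=4, max_pos=10_000)
    raw = xpehh(m, m)
    assert np.allclose(raw.xpehh_raw, 0.0)
    with pytest.warns(UserWarning, match="zero variance"):
        std = standardize_xpehh(raw.xpehh_raw.to_numpy())
    assert np.allclose(std, 0.0)


def test_population_swap_negates_every_raw_score_exactly(rng):
    a = random_matrix(rng, n_sites=25, n_samples=4, max_pos=20_000)
    b = random_matrix(rng, n_sites=25, n_samples=4, max_pos=20_000)
    b = _pop(b.alleles, positions=a.positions)
    ab = xpehh(a, b)
    ba = xpehh(b, a)
    assert np.array_equal(ab.pos.to_numpy(), ba.pos.to_numpy())
    assert np.array_equal(ab.xpehh_raw.to_numpy(), -ba.xpehh_raw.to_numpy())


def test_standardized_scores_have_zero_mean_unit_variance(rng):
    raw = rng.normal(size=500)
    std = standardize_xpehh(raw)
    assert std.mean() == pytest.approx(0.0, abs=1e-12)
    assert std.std() == pytest.approx(1.0, abs=1e-12)


def test_window_xpehh_averages_core_scores():
    windows = make_windows({"1": 100}, 50, 50)
    df = window_xpehh([10, 20, 70], [1.0, 3.0, 5.0], windows)
    assert df[df.start == 1].xpehh.iloc[0] == pytest.approx(2.0)
    assert df[df.start == 51].xpehh.iloc[0] == pytest.approx(5.0)
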