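"""Composite likelihood ratio sweep scan.

The model follows the classic composite-likelihood sweep test: a sweep at a
grid position distorts the genome-wide ("background") site frequency
spectrum at nearby sites.  Each of the n sampled lineages escapes the sweep
independently with probability p_e = 1 − exp(−α·d) at distance d bp; escaped
lineages plus the single hitchhiking ancestor form a pre-sweep sample whose
allele counts follow the background spectrum, and all non-escaped lineages
copy the hitchhiker's allele.  α is a compound sweep-intensity parameter
(absorbing s and the local recombination rate); the CLR at a grid point is
twice the maximised log-likelihood gain over the neutral model, floored at 0.

Spectra are folded (minor-allele classes) by default — appropriate when no
outgroup polarises ancestral states — with an unfolded option.  Because the
input contains only segregating sites, mass the sweep model places on
monomorphic outcomes is dropped and the polymorphic classes renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BackgroundSFS:
    """Empirical frequency-class probabilities of the genome-wide spectrum.

    Folded: ``probs[k-1]`` is the probability of minor count k, k = 1..⌊n/2⌋.
    Unfolded: ``probs[k-1]`` is the probability of derived count k, k = 1..n−1.
    """
    n: int
    probs: np.ndarray
    folded: bool = True

    def class_index(self, x):
        """Class array index for derived/minor count(s) x."""
        x = np.asarray(x)
        k = np.minimum(x, self.n - x) if self.folded else x
        return k - 1


def background_sfs(counts, sample_sizes, folded=True, projection="project"):
    """Empirical background SFS from per-site allele counts.

    Sites whose sample size differs from the most common one are either
    hypergeometrically down-projected onto it (``projection='project'``) or
    dropped (``'reject'``).  Counts are derived-allele counts; with
    ``folded`` they are folded to minor counts.
    """
    counts = np.asarray(counts, dtype=np.int64)
    sample_sizes = np.asarray(sample_sizes, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("background SFS needs at least one polymorphic site")
    poly = (counts > 0) & (counts < sample_sizes)
    counts, sample_sizes = counts[poly], sample_sizes[poly]
    if counts.size == 0:
        raise ValueError("no polymorphic sites for the background SFS")
    ns, freq = np.unique(sample_sizes, return_counts=True)
    n = int(ns[np.argmax(freq)])
    n_classes = n // 2 if folded else n - 1
    tally = np.zeros(n_classes)

    same = sample_sizes == n
    k = np.minimum(counts[same], n - counts[same]) if folded else counts[same]
    np.add.at(tally, k - 1, 1.0)

    other = ~same
    if other.any():
        if projection == "reject":
            pass
        elif projection == "project":
            for x, m in zip(counts[other], sample_sizes[other]):
                if m < n:
                    continue  # cannot project up
                t = np.arange(0, n + 1)
                w = sps.hypergeom.pmf(t, m, x, n)
                w[0] = w[-1] = 0.0
                if w.sum() == 0:
                    continue
                w = w / w.sum()
                for j in range(1, n):
                    cls = min(j, n - j) if folded else j
                    tally[cls - 1] += w[j]
        else:
            raise ValueError("projection must be 'project' or 'reject'")
    if tally.sum() == 0:
        raise ValueError("no sites usable for the background SFS")
    return BackgroundSFS(n, tally / tally.sum(), folded)


class SweepSpectrumModel:
    """Precomputed sweep-distorted spectra for one background SFS."""

    def __init__(self, bg: BackgroundSFS):
        self.bg = bg
        n = bg.n
        # unfold to derived counts 1..n-1 (symmetric split when folded)
        u = np.zeros(n + 1)
        if bg.folded:
            for m in range(1, n // 2 + 1):
                if m == n - m:
                    u[m] = bg.probs[m - 1]
                else:
                    u[m] = u[n - m] = bg.probs[m - 1] / 2.0
        else:
            u[1:n] = bg.probs
        self._u = u
        # V[j, k] = P(final derived count j | k of n lineages escape)
        V = np.zeros((n + 1, n + 1))
        V[:, n] = u  # all escape: plain background sample
        xs = np.arange(1, n)
        for k in range(n):
            m = k + 1
            t = np.arange(0, m + 1)
            # P(t derived among a pre-sweep sample of size m)
            H = sps.hypergeom.pmf(t[:, None], n, xs[None, :], m)
            pt = H @ u[1:n]
            frac = t / m
            # hitchhiker ancestral: j = t; hitchhiker derived: j = t-1 + (n-k)
            np.add.at(V[:, k], t, pt * (1 - frac))
            np.add.at(V[:, k], t - 1 + (n - k), pt * frac)
        self._V = V
        self.n = n

    def class_probs(self, p_e: float) -> np.ndarray:
        """Sweep-distorted class probabilities (same classes as the bg)."""
        if not 0.0 <= p_e <= 1.0:
            raise ValueError("escape probability must lie in [0, 1]")
        n = self.n
        bk = sps.binom.pmf(np.arange(n + 1), n, p_e)
        pj = self._V @ bk
        pj[0] = pj[n] = 0.0  # condition on polymorphism
        tot = pj.sum()
        if tot <= 0:
            return np.zeros(len(self.bg.probs))
        pj = pj / tot
        if self.bg.folded:
            out = np.empty(n // 2)
            for m in range(1, n // 2 + 1):
                out[m - 1] = pj[m] if m == n - m else pj[m] + pj[n - m]
            return out
        return pj[1:n]

    def log_prob_table(self, pe_grid: np.ndarray) -> np.ndarray:
        """log class probabilities, shape (n_classes, len(pe_grid))."""
        cols = [self.class_probs(pe) for pe in pe_grid]
        with np.errstate(divide="ignore"):
            return np.log(np.column_stack(cols))


def sweep_spectrum(bg: BackgroundSFS, p_e: float) -> np.ndarray:
    """Class probabilities under a sweep with per-lineage escape prob p_e."""
    return SweepSpectrumModel(bg).class_probs(p_e)


def default_alpha_grid(grid_step=50_000, n_alpha=40):
    """Log-spaced α spanning p_e ∈ [0.01, 0.99] at distance = grid_step."""
    lo = -np.log1p(-0.01) / grid_step
    hi = -np.log1p(-0.99) / grid_step
    return np.geomspace(lo, hi, n_alpha)


def _pe_grid():
    g = np.concatenate([np.geomspace(1e-6, 0.5, 200),
                        1.0 - np.geomspace(1e-6, 0.5, 200), [1.0]])
    return np.unique(g)


def clr_scan(positions, counts, sample_sizes, bg: BackgroundSFS,
             contig_length, grid_step=50_000, alpha_grid=None) -> pd.DataFrame:
    """CLR over a regular grid of positions on one contig.

    Grid points sit at the centres of consecutive ``grid_step`` blocks.
    Returns columns (grid_pos, clr, alpha_hat); clr ≥ 0, alpha_hat is the
    maximising α (inf when the neutral model is best).
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(grid_step)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha_grid must be non-empty")
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    # the model conditions on polymorphism: keep polymorphic sites whose
    # sample size matches the background spectrum
    ok = ((np.asarray(sample_sizes) == bg.n) & (counts > 0) & (counts < bg.n))
    positions, cls = positions[ok], bg.class_index(counts[ok])

    model = SweepSpectrumModel(bg)
    pe_grid = _pe_grid()
    logP = model.log_prob_table(pe_grid)  # classes x pe
    with np.errstate(divide="ignore"):
        log_bg = np.log(bg.probs)
    l0 = log_bg[cls].sum()

    grid = np.arange(grid_step // 2, contig_length + 1, grid_step, dtype=np.int64)
    rows = []
    for g in grid:
        d = np.abs(positions - g)[None, :].astype(float)
        pe = 1.0 - np.exp(-alpha_grid[:, None] * d)
        np.clip(pe, pe_grid[0], 1.0, out=pe)
        # linear interpolation on the precomputed p_e grid
        idx = np.clip(np.searchsorted(pe_grid, pe) - 1, 0, len(pe_grid) - 2)
        lo, hi = pe_grid[idx], pe_grid[idx + 1]
        w = (pe - lo) / (hi - lo)
        cc = np.broadcast_to(cls[None, :], idx.shape)
        ll = (1 - w) * logP[cc, idx] + w * logP[cc, idx + 1]
        l1 = ll.sum(axis=1)
        best = int(np.argmax(l1))
        clr = 2.0 * (l1[best] - l0)
        if clr <= 0.0:
            rows.append((int(g), 0.0, np.inf))
        else:
            rows.append((int(g), float(clr), float(alpha_grid[best])))
    return pd.DataFrame(rows, columns=["grid_pos", "clr", "alpha_hat"])


def map_clr_to_windows(clr_df: pd.DataFrame, windows) -> pd.DataFrame:
    """Window value = mean CLR of the grid points the window contains."""
    gp = clr_df["grid_pos"].to_numpy()
    vals = clr_df["clr"].to_numpy()
    rows = []
    for w in windows:
        lo = np.searchsorted(gp, w.start, side="left")
        hi = np.searchsorted(gp, w.end, side="right")
        if hi > lo:
            rows.append((w.chrom, w.start, w.end, vals[lo:hi].mean()))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "clr"])
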