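"""Two-population Wright–Fisher simulator with an optional hard sweep.

Neutral contigs are drawn from the exactly equivalent two-population split
coalescent (msprime: ancestral population of size N_anc splitting into A and
B ``split_gen`` generations ago, infinite-sites biallelic mutation,
uniform recombination).  Contigs carrying a sweep are simulated forward in
discrete Wright–Fisher generations from an msprime-equilibrium ancestral
population: per-generation gamete formation with Poisson crossovers,
infinite-sites mutation, and additive selection on the focal derived allele
(genotype fitness 1, 1+s, 1+2s).  A lost focal allele is re-injected at
frequency 1/(2N) — the conditional-on-establishment convention — so every
sweep run carries a genuine sweep; setting s = 0 disables the machinery
entirely and the contig is routed to the neutral path.

Defaults are the "desk" preset used throughout the test-bed: 3 contigs of
2 Mb, diploid N = 500 per population, 30 + 30 sampled individuals,
mutation 2.5e-7 /bp/gen (equilibrium diversity 4Nμ = 5e-4 /bp),
recombination 1e-7 /bp/gen and a 300-generation split: neutral LD then
decays over a few kb while a fixed s = 0.05 sweep leaves a footprint on the
~100 kb scale of the analysis windows.  The sweep starts 250 generations
before present so that fixation (establishment-conditioned duration
~180–245 generations at these parameters) completes shortly before
sampling — the recently-selected-breed scenario the scan targets.  If a
sweep has not completed by generation 0, both populations continue evolving
until it fixes (sample-at-fixation convention, capped), so every sweep run
carries a completed, recent sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from ._kernels import assemble_gametes, colsum_int8, rebuild_columns
from .core import HaplotypeMatrix


#: hard cap on post-split generations added while waiting for sweep fixation
MAX_EXTRA_SWEEP_GENERATIONS = 1000


@dataclass
class SweepConfig:
    contig: str = "1"
    position: int = 1_000_000
    s: float = 0.05
    start_gen: int = 250  # generations before present; clipped to the split
    population: str = "A"


@dataclass
class SimConfig:
    seed: int = 0
    N_anc: int = 500
    N_a: int = 500
    N_b: int = 500
    split_gen: int = 300
    mu: float = 2.5e-7
    rho: float = 1e-7
    L: int = 2_000_000
    n_contigs: int = 3
    sample_a: int = 30
    sample_b: int = 30
    sweep: SweepConfig | None = None

    def __post_init__(self):
        if min(self.N_anc, self.N_a, self.N_b, self.sample_a, self.sample_b) < 2:
            raise ValueError("population and sample sizes must be >= 2")
        if self.sample_a > self.N_a or self.sample_b > self.N_b:
            raise ValueError("cannot sample more individuals than the population holds")
        if self.sweep is not None:
            if not 0.0 <= self.sweep.s <= 1.0:
                raise ValueError("selection coefficient must lie in [0, 1]")
            if not 1 <= self.sweep.position <= self.L:
                raise ValueError("sweep position outside [1, L]")


@dataclass
class SweepTruth:
    contig: str
    position: int
    s: float
    fixed: bool
    final_frequency: float


def desk_preset(seed=0, sweep=True):
    """The default 3 x 2 Mb test-bed, optionally with one central sweep."""
    sw = SweepConfig() if sweep else None
    return SimConfig(seed=seed, sweep=sw)


def simulate(cfg: SimConfig):
    """Run the simulator.

    Returns ``(pops, truths, contig_lengths)`` where ``pops`` maps "A"/"B"
    to dicts of per-contig :class:`HaplotypeMatrix` (both populations share
    each contig's site list) and ``truths`` lists one :class:`SweepTruth`
    per swept contig.
    """
    pops = {"A": {}, "B": {}}
    truths = []
    contig_lengths = {}
    for c in range(cfg.n_contigs):
        chrom = str(c + 1)
        rng = np.random.default_rng([int(cfg.seed), c + 1])
        sweep = cfg.sweep if (cfg.sweep and cfg.sweep.contig == chrom
                              and cfg.sweep.s > 0) else None
        if sweep is None:
            mat_a, mat_b = _neutral_contig(cfg, chrom, rng)
            truth = None
        else:
            mat_a, mat_b, truth = _sweep_contig(cfg, chrom, sweep, rng)
        pops["A"][chrom] = mat_a
        pops["B"][chrom] = mat_b
        contig_lengths[chrom] = cfg.L
        if truth is not None:
            truths.append(truth)
    return pops, truths, contig_lengths


def _integer_sites(ts):
    """Integerised strictly-increasing positions + site keep mask."""
    pos = np.floor(ts.tables.sites.position).astype(np.int64) + 1
    keep = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.zeros(0, bool)
    return pos[keep], keep


def _sample_ids(n_a, n_b):
    return ([f"A{i:03d}" for i in range(n_a)], [f"B{i:03d}" for i in range(n_b)])


def _neutral_contig(cfg, chrom, rng):
    """Sample both populations from the split-demography coalescent."""
    ms_seed = int(rng.integers(1, 2**31 - 1))
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=cfg.N_a)
    dem.add_population(name="B", initial_size=cfg.N_b)
    dem.add_population(name="ANC", initial_size=cfg.N_anc)
    dem.add_population_split(time=cfg.split_gen, derived=["A", "B"], ancestral="ANC")
    ts = msprime.sim_ancestry(
        samples={"A": cfg.sample_a, "B": cfg.sample_b}, demography=dem, ploidy=2,
        sequence_length=cfg.L, recombination_rate=cfg.rho, random_seed=ms_seed)
    ts = msprime.sim_mutations(ts, rate=cfg.mu, model=msprime.BinaryMutationModel(),
                               discrete_genome=False, random_seed=ms_seed + 1)
    geno = ts.genotype_matrix()  # sites x (2·sample_a + 2·sample_b)
    pos, keep = _integer_sites(ts)
    geno = geno[keep].astype(np.int8)
    ga, gb = geno[:, :2 * cfg.sample_a], geno[:, 2 * cfg.sample_a:]
    tot = geno.sum(axis=1)
    poly = (tot > 0) & (tot < geno.shape[1])
    ids_a, ids_b = _sample_ids(cfg.sample_a, cfg.sample_b)
    return (HaplotypeMatrix(chrom, pos[poly], ga[poly], ids_a),
            HaplotypeMatrix(chrom, pos[poly], gb[poly], ids_b))


def _sweep_contig(cfg, chrom, sweep, rng):
    """Equilibrium ancestral population + forward WF split with selection."""
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=cfg.N_anc, population_size=cfg.N_anc, ploidy=2,
        sequence_length=cfg.L, recombination_rate=cfg.rho, random_seed=ms_seed)
    ts = msprime.sim_mutations(ts, rate=cfg.mu, model=msprime.BinaryMutationModel(),
                               discrete_genome=False, random_seed=ms_seed + 1)
    pos, keep = _integer_sites(ts)
    anc = np.ascontiguousarray(ts.genotype_matrix()[keep].T.astype(np.int8))

    state = _ForwardState(pos, anc, cfg, rng)
    sweep_live = False
    focal_fixed = False

    def step_with_selection():
        nonlocal focal_fixed
        s_now = sweep.s if (sweep_live and not focal_fixed) else 0.0
        state.step(s_now if sweep.population == "A" else 0.0,
                   s_now if sweep.population == "B" else 0.0)
        if sweep_live and not focal_fixed:
            freq = state.focal_frequency(sweep.population)
            if freq == 0.0:
                state.reinject_focal(sweep.population)
            elif freq == 1.0:
                focal_fixed = True

    for gen in range(cfg.split_gen, 0, -1):
        if not sweep_live and gen <= min(sweep.start_gen, cfg.split_gen):
            state.inject_focal(sweep.position, sweep.population)
            sweep_live = True
        step_with_selection()

    # sample-at-fixation convention: if the sweep has not completed by
    # generation 0, both populations keep evolving until it fixes (capped),
    # so every sweep replicate carries a completed, recent sweep
    extra = 0
    while not focal_fixed and extra < MAX_EXTRA_SWEEP_GENERATIONS:
        step_with_selection()
        extra += 1

    freq = state.focal_frequency(sweep.population)
    truth = SweepTruth(chrom, state.focal_pos, sweep.s, freq == 1.0, freq)
    mat_a, mat_b = state.sample(chrom, cfg.sample_a, cfg.sample_b)
    return mat_a, mat_b, truth


class _ForwardState:
    """Whole-population haplotypes of A and B sharing one sorted site list.

    Matrices are haplotype-major (2N x S, int8, C-contiguous) so that gamete
    assembly is segment memcpy; site columns are kept position-sorted by a
    single vectorised rebuild per generation.
    """

    def __init__(self, positions, ancestral, cfg, rng):
        self.cfg = cfg
        self.rng = rng
        self.positions = positions
        self.A = np.ascontiguousarray(ancestral)
        self.B = ancestral.copy()
        self.focal_pos = -1

    @property
    def focal_idx(self):
        if self.focal_pos < 0:
            return -1
        i = np.searchsorted(self.positions, self.focal_pos)
        if i < len(self.positions) and self.positions[i] == self.focal_pos:
            return int(i)
        return -1

    def inject_focal(self, position, population):
        # place the focal column, stepping off any occupied position
        while True:
            i = np.searchsorted(self.positions, position)
            if i >= len(self.positions) or self.positions[i] != position:
                break
            position += 1
        self.focal_pos = int(position)
        self.positions = np.insert(self.positions, i, position)
        self.A = np.ascontiguousarray(np.insert(self.A, i, 0, axis=1))
        self.B = np.ascontiguousarray(np.insert(self.B, i, 0, axis=1))
        self.reinject_focal(population)

    def reinject_focal(self, population):
        mat = self.A if population == "A" else self.B
        mat[self.rng.integers(0, mat.shape[0]), self.focal_idx] = 1

    def focal_frequency(self, population):
        mat = self.A if population == "A" else self.B
        return float(mat[:, self.focal_idx].mean())

    def step(self, s_a, s_b):
        self.A = self._reproduce(self.A, self.cfg.N_a, s_a)
        self.B = self._reproduce(self.B, self.cfg.N_b, s_b)
        self._mutate_and_clean()

    def _reproduce(self, haps, n_next, s):
        rng = self.rng
        n_parents = haps.shape[0] // 2
        n_gametes = 2 * n_next
        if s > 0.0 and self.focal_idx >= 0:
            col = haps[:, self.focal_idx]
            w = 1.0 + s * (col[0::2] + col[1::2])
            parents = rng.choice(n_parents, size=n_gametes, p=w / w.sum())
        else:
            parents = rng.integers(0, n_parents, size=n_gametes)
        starts = rng.integers(0, 2, size=n_gametes)
        k = rng.poisson(self.cfg.rho * self.cfg.L, size=n_gametes)
        bp = rng.uniform(1.0, self.cfg.L + 1.0, size=int(k.sum()))
        bp_sites = np.searchsorted(self.positions, bp.astype(np.int64))
        gid = np.repeat(np.arange(n_gametes), k)
        bp_sites = bp_sites[np.lexsort((bp_sites, gid))]
        out = np.empty((n_gametes, haps.shape[1]), dtype=np.int8)
        assemble_gametes(haps, parents.astype(np.int64), starts.astype(np.int64),
                         k.astype(np.int64), np.ascontiguousarray(bp_sites), out)
        return out

    def _draw_mutation_positions(self, m):
        """m fresh integer positions avoiding existing sites and each other."""
        rng = self.rng
        pos = rng.integers(1, self.cfg.L + 1, size=m)
        while True:
            i = np.searchsorted(self.positions, pos)
            i = np.minimum(i, len(self.positions) - 1)
            clash = self.positions[i] == pos
            _, first = np.unique(pos, return_index=True)
            dup = np.ones(m, dtype=bool)
            dup[first] = False
            bad = clash | dup
            if not bad.any():
                return pos
            pos[bad] = rng.integers(1, self.cfg.L + 1, size=int(bad.sum()))

    def _mutate_and_clean(self):
        cfg, rng = self.cfg, self.rng
        m_a = rng.poisson(self.A.shape[0] * cfg.mu * cfg.L)
        m_b = rng.poisson(self.B.shape[0] * cfg.mu * cfg.L)
        m = m_a + m_b
        new_pos = self._draw_mutation_positions(m) if m else np.empty(0, np.int64)
        mut_rows_a = np.full(m, -1, dtype=np.int64)
        mut_rows_b = np.full(m, -1, dtype=np.int64)
        if m_a:
            mut_rows_a[:m_a] = rng.integers(0, self.A.shape[0], size=m_a)
        if m_b:
            mut_rows_b[m_a:] = rng.integers(0, self.B.shape[0], size=m_b)

        tot = np.zeros(self.A.shape[1], dtype=np.int64)
        colsum_int8(self.A, tot)
        colsum_int8(self.B, tot)
        n_hap = self.A.shape[0] + self.B.shape[0]
        keep = (tot > 0) & (tot < n_hap)
        fi = self.focal_idx
        if fi >= 0:
            keep[fi] = True

        kept = np.flatnonzero(keep)
        merged = np.concatenate([self.positions[kept], new_pos])
        src = np.concatenate([kept, -(np.arange(m, dtype=np.int64) + 1)])
        order = np.argsort(merged, kind="stable")
        self.positions = merged[order]
        srcidx = np.ascontiguousarray(src[order])
        new_a = np.empty((self.A.shape[0], srcidx.size), dtype=np.int8)
        new_b = np.empty((self.B.shape[0], srcidx.size), dtype=np.int8)
        rebuild_columns(self.A, srcidx, mut_rows_a, new_a)
        rebuild_columns(self.B, srcidx, mut_rows_b, new_b)
        self.A, self.B = new_a, new_b

    def sample(self, chrom, n_a, n_b):
        rng = self.rng
        ia = rng.choice(self.cfg.N_a, size=n_a, replace=False)
        ib = rng.choice(self.cfg.N_b, size=n_b, replace=False)
        rows_a = np.stack([2 * ia, 2 * ia + 1], axis=1).ravel()
        rows_b = np.stack([2 * ib, 2 * ib + 1], axis=1).ravel()
        sub_a, sub_b = self.A[rows_a], self.B[rows_b]
        tot = sub_a.sum(axis=0, dtype=np.int64) + sub_b.sum(axis=0, dtype=np.int64)
        poly = (tot > 0) & (tot < sub_a.shape[0] + sub_b.shape[0])
        pos = self.positions[poly]
        ids_a, ids_b = _sample_ids(n_a, n_b)
        return (HaplotypeMatrix(chrom, pos, np.ascontiguousarray(sub_a[:, poly].T), ids_a),
                HaplotypeMatrix(chrom, pos, np.ascontiguousarray(sub_b[:, poly].T), ids_b))


def write_truth_tsv(truths, path):
    with open(path, "w") as fh:
        fh.write("contig\tposition\ts\tfixed\tfinal_frequency\n")
        for t in truths:
            fh.write(f"{t.contig}\t{t.position}\t{t.s:g}\t{int(t.fixed)}\t"
                     f"{t.final_frequency:.6g}\n")
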