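"""Reading and writing the pipeline's on-disk formats.

VCF input goes through cyvcf2; output VCFs are written as plain VCFv4.2 text
with phased GT fields so that a write/read cycle is lossless.  GFF3 gene rows
are parsed with gffutils' line parser.  All tabular outputs are TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from gffutils.feature import feature_from_line

from .core import MISSING, STAT_COLUMNS, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+', '-' or '?'


def read_vcf(path, sample_ids=None, require_pass=False):
    """Read a phased VCF into one :class:`HaplotypeMatrix` per contig.

    Only biallelic SNP records are retained; everything else is counted in
    the returned skip log.  Returns ``(dict chrom -> HaplotypeMatrix,
    dict of skip counts)``.

    Parameters
    ----------
    sample_ids : list of str, optional
        Subset of samples to load, in this order.  All samples when omitted.
    require_pass : bool
        Drop records whose FILTER is neither PASS nor '.'.
    """
    vcf = VCF(str(path), gts012=False)
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(vcf.samples))
        if missing:
            raise KeyError(f"samples not in VCF: {', '.join(missing)}")
        vcf.set_samples(list(sample_ids))
    samples = vcf.samples

    per_chrom: dict[str, list] = {}
    skip = {"multiallelic": 0, "non_snp": 0, "filter_fail": 0, "duplicate_pos": 0}
    phased_all = True
    for v in vcf:
        if len(v.ALT) != 1:
            skip["multiallelic"] += 1
            continue
        if not v.is_snp:
            skip["non_snp"] += 1
            continue
        if require_pass and v.FILTER is not None:
            skip["filter_fail"] += 1
            continue
        rows = per_chrom.setdefault(v.CHROM, [])
        if rows and rows[-1][0] == v.POS:
            skip["duplicate_pos"] += 1
            log.warning("duplicate position %s:%d dropped", v.CHROM, v.POS)
            continue
        gts = v.genotypes  # per sample: [allele0, allele1, phased]
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            alleles[2 * i] = a0 if a0 >= 0 else MISSING
            alleles[2 * i + 1] = a1 if a1 >= 0 else MISSING
            if not g[2] and (a0 >= 0 or a1 >= 0):
                phased_all = False
        rows.append((v.POS, alleles))

    out = {}
    for chrom, rows in per_chrom.items():
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        mat = np.vstack([r[1] for r in rows]) if rows else np.empty((0, 2 * len(samples)), np.int8)
        out[chrom] = HaplotypeMatrix(chrom, positions, mat, samples, phased=phased_all)
    return out, skip


def write_vcf(pops: dict, path, contig_lengths=None):
    """Write populations sharing one site list as a phased VCFv4.2 text file.

    ``pops`` maps population label -> dict chrom -> HaplotypeMatrix; samples
    of all populations appear as columns (population order preserved).
    """
    if not pops:
        raise ValueError("no populations to write")
    chroms = None
    for mats in pops.values():
        keys = list(mats.keys())
        if chroms is None:
            chroms = keys
        elif keys != chroms:
            raise ValueError("populations disagree on contigs")
    for chrom in chroms:
        ref = None
        for mats in pops.values():
            pos = mats[chrom].positions
            if ref is None:
                ref = pos
            elif not np.array_equal(ref, pos):
                raise ValueError(f"populations disagree on site list for {chrom}")

    sample_names = [s for mats in pops.values() for s in mats[chroms[0]].sample_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dcmscan\n")
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={int(contig_lengths[chrom])}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for chrom in chroms:
            mats = [p[chrom] for p in pops.values()]
            positions = mats[0].positions
            for i, pos in enumerate(positions):
                cells = []
                for m in mats:
                    row = m.alleles[i]
                    for s in range(len(m.sample_ids)):
                        a0, a1 = row[2 * s], row[2 * s + 1]
                        c0 = "." if a0 == MISSING else str(int(a0))
                        c1 = "." if a1 == MISSING else str(int(a1))
                        cells.append(f"{c0}|{c1}")
                fh.write(f"{chrom}\t{int(pos)}\t.\tA\tT\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n")


def read_gff3(path):
    """Parse GFF3 ``gene`` rows into :class:`GeneRecord` objects.

    Gene names prefer the ``Name`` attribute, then ``ID``, else a coordinate
    placeholder.  Malformed rows are skipped with a warning; mRNA/exon/etc.
    rows are ignored.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            # gffutils pads short lines instead of rejecting them, so check
            # the column count ourselves
            if len(line.split("\t")) < 9:
                log.warning("skipping malformed GFF3 line %d: expected 9 "
                            "tab-separated columns", lineno)
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                log.warning("skipping malformed GFF3 line %d: %s", lineno, exc)
                continue
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            gene_id = attrs["ID"][0] if "ID" in attrs else f"unnamed:{feat.seqid}:{feat.start}-{feat.end}"
            name = attrs["Name"][0] if "Name" in attrs else gene_id
            strand = feat.strand if feat.strand in ("+", "-") else "?"
            genes.append(GeneRecord(gene_id, name, feat.seqid, feat.start, feat.end, strand))
    return genes


def write_stat_table(stats: pd.DataFrame, path):
    cols = [c for c in STAT_COLUMNS if c in stats.columns]
    stats.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")


def write_regions_tsv(regions, path):
    rows = [{
        "chrom": r.chrom, "start": r.start, "end": r.end, "min_q": r.min_q,
        "n_windows": len(r.member_windows),
        "genes": ",".join(g.gene_name for g in r.genes),
    } for r in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "min_q", "n_windows", "genes"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions, path):
    """Regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.min_q:.6g}\n")
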