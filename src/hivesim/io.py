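"""Plain-text interchange: phased VCF, 0/1 haplotype matrices, pedigree CSV.

Reading phased VCFs goes through cyvcf2; writing emits minimal VCF 4.2
records directly, since every record is fully synthetic (abstract biallelic
sites with placeholder REF/ALT bases).
"""

from __future__ import annotations

import csv
from typing import Optional

import numpy as np

from .errors import ConfigError, FormatError


def write_phased_vcf(haplo: np.ndarray, spec, sample_ids, path) -> None:
    """Write phased diploid samples (rows paired per individual) as VCF."""
    haplo = np.asarray(haplo)
    if haplo.shape[0] != 2 * len(sample_ids):
        raise ConfigError("two haplotype rows per sample id are required")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hivesim\n")
        for c in range(spec.n_chr):
            fh.write(f"##contig=<ID={c + 1},length={int(spec.bp_length[c])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in sample_ids) + "\n")
        col = 0
        for c in range(spec.n_chr):
            for j, pos in enumerate(spec.loci_pos[c]):
                gts = "\t".join(
                    f"{haplo[2 * i, col]}|{haplo[2 * i + 1, col]}" for i in range(len(sample_ids))
                )
                fh.write(f"{c + 1}\t{int(pos) + 1}\t{c + 1}_{j + 1}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
                col += 1


def read_phased_vcf(path):
    """Read a phased VCF into (haplotype matrix, per-chromosome positions,
    chromosome names). Unphased or mixed-ploidy records are format errors."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    by_chrom: dict[str, list] = {}
    pos_by_chrom: dict[str, list] = {}
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise FormatError("VCF contains no samples")
    for var in vcf:
        gts = var.genotypes  # [a, b, phased] per sample
        row = np.empty(2 * n_samples, dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise FormatError(f"sample {vcf.samples[i]} is not diploid at {var.CHROM}:{var.POS}")
            a, b, phased = g
            if not phased:
                raise FormatError(f"unphased genotype at {var.CHROM}:{var.POS}")
            if a < 0 or b < 0:
                raise FormatError(f"missing genotype at {var.CHROM}:{var.POS}")
            row[2 * i], row[2 * i + 1] = a, b
        by_chrom.setdefault(var.CHROM, []).append(row)
        pos_by_chrom.setdefault(var.CHROM, []).append(var.POS - 1)
    if not by_chrom:
        raise FormatError("VCF contains no variant records")
    chroms = list(by_chrom)
    haplo = np.hstack([np.array(by_chrom[c]).T for c in chroms]).astype(np.uint8)
    positions = [np.array(pos_by_chrom[c], dtype=np.int64) for c in chroms]
    return haplo, positions, chroms


def write_haplotype_matrix(haplo: np.ndarray, spec, path, sites_path) -> None:
    """Whitespace-delimited 0/1 matrix plus a sidecar site-position file."""
    np.savetxt(path, np.asarray(haplo, dtype=int), fmt="%d")
    with open(sites_path, "w") as fh:
        fh.write("chrom\tpos_bp\n")
        for c in range(spec.n_chr):
            for pos in spec.loci_pos[c]:
                fh.write(f"{c + 1}\t{int(pos)}\n")


def read_haplotype_matrix(path, sites_path):
    """Inverse of :func:`write_haplotype_matrix`."""
    haplo = np.loadtxt(path, dtype=np.uint8, ndmin=2)
    chroms, pos = [], []
    with open(sites_path) as fh:
        next(fh)
        for line in fh:
            c, p = line.split()
            chroms.append(int(c))
            pos.append(int(p))
    chroms, pos = np.array(chroms), np.array(pos, dtype=np.int64)
    positions = [pos[chroms == c] for c in sorted(set(chroms.tolist()))]
    return haplo, positions


def write_pedigree(sp, path) -> None:
    """Three-column pedigree CSV: id, mother, father (empty if unknown)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "mother", "father"])
        for ind_id, (m, f) in sp.pedigree.items():
            w.writerow([ind_id, "" if m is None else m, "" if f is None else f])
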