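"""Haplotype/genotype/IBD extraction and genomic relationship matrices.

Matrices are returned as labeled pandas DataFrames: haplotype rows are
``individual_haplotype`` (drones contribute a single row), genotype rows
are individual ids with drones scored 0/2 under the doubled-haploid
convention, and columns are ``chromosome_locus``. The relationship matrix
is VanRaden method 1: centered dosages cross-multiplied and scaled by
2 * sum p(1 - p), with allele frequencies taken from the supplied matrix
unless base-population frequencies are passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .castes import Individual, Population
from .errors import ConfigError, StateError
from .params import SimParamBee, resolve_sp


@dataclass
class SnpChip:
    """Marker panel: tracked site indices, disjoint from the QTL."""

    loci: np.ndarray


def add_snp_chip(sp: Optional[SimParamBee], n_snp_per_chr: int) -> SnpChip:
    """Sample a SNP chip uniformly per chromosome, avoiding QTL and the csd window."""
    sp = resolve_sp(sp)
    spec = sp.spec
    excluded = set(spec.csd_cols().tolist())
    if sp.traits is not None:
        excluded |= set(sp.traits.qtl_idx.tolist())
    loci = []
    for c in range(spec.n_chr):
        sl = spec.chr_slice(c)
        candidates = np.array([i for i in range(sl.start, sl.stop) if i not in excluded])
        if n_snp_per_chr > candidates.size:
            raise ConfigError(
                f"chromosome {c + 1}: {n_snp_per_chr} chip loci requested but only "
                f"{candidates.size} eligible sites"
            )
        loci.append(np.sort(sp.rng.choice(candidates, size=int(n_snp_per_chr), replace=False)))
    chip = SnpChip(loci=np.concatenate(loci))
    sp.snp_chip = chip
    return chip


def _site_columns(sp: SimParamBee, which: str) -> np.ndarray:
    which = which.lower()
    if which == "segsite":
        return np.arange(sp.spec.total_sites)
    if which == "snp":
        if sp.snp_chip is None:
            raise StateError("no SNP chip defined; call add_snp_chip first")
        return sp.snp_chip.loci
    if which == "qtl":
        if sp.traits is None:
            raise StateError("no traits defined; call add_trait_a first")
        return sp.traits.qtl_idx
    raise ConfigError("which must be 'segsite', 'snp' or 'qtl'")


def _collect(target, caste: Optional[str]) -> Population:
    from .colony import Colony
    from .multicolony import MultiColony

    if isinstance(target, Individual):
        return Population([target])
    if isinstance(target, Population):
        return target
    if isinstance(target, Colony):
        if caste is None:
            raise ConfigError("a caste is required when extracting from a Colony")
        return target.get_caste_pop(caste)
    if isinstance(target, MultiColony):
        if caste is None:
            raise ConfigError("a caste is required when extracting from a MultiColony")
        out = Population()
        for c in target.non_null():
            out.extend(c.get_caste_pop(caste))
        return out
    raise ConfigError("unsupported extraction target")


def get_haplo(target, which: str = "segsite", caste: Optional[str] = None,
              sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """Phased haplotypes (one row per haplotype; drones contribute one row)."""
    sp = resolve_sp(sp)
    cols = _site_columns(sp, which)
    labels = np.array(sp.spec.site_labels())[cols]
    pop = _collect(target, caste)
    rows, index = [], []
    for ind in pop:
        for k in range(ind.ploidy):
            rows.append(ind.haplo[k, cols])
            index.append(f"{ind.id}_{k + 1}")
    data = np.array(rows, dtype=int) if rows else np.empty((0, cols.size), dtype=int)
    return pd.DataFrame(data, index=index, columns=labels)


def get_geno(target, which: str = "segsite", caste: Optional[str] = None,
             sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """Genotype dosages (0/1/2); drones are doubled haploids, so 0/2 only."""
    sp = resolve_sp(sp)
    cols = _site_columns(sp, which)
    labels = np.array(sp.spec.site_labels())[cols]
    pop = _collect(target, caste)
    data = np.array([ind.dosage()[cols] for ind in pop], dtype=int) if len(pop) else (
        np.empty((0, cols.size), dtype=int)
    )
    return pd.DataFrame(data, index=pop.ids, columns=labels)


def get_ibd_haplo(target, caste: Optional[str] = None,
                  sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """Founder-haplotype origin labels, one row per haplotype per site."""
    sp = resolve_sp(sp)
    labels = sp.spec.site_labels()
    pop = _collect(target, caste)
    rows, index = [], []
    for ind in pop:
        if ind.ibd is None:
            raise StateError(f"individual {ind.id} carries no IBD labels")
        for k in range(ind.ploidy):
            rows.append(ind.ibd[k])
            index.append(f"{ind.id}_{k + 1}")
    data = np.array(rows, dtype=int) if rows else np.empty((0, len(labels)), dtype=int)
    return pd.DataFrame(data, index=index, columns=labels)


def calc_grm(geno, base_freq: Optional[np.ndarray] = None):
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 * sum p (1 - p)) with Z the dosage matrix centered at 2p.
    Frequencies default to those of the supplied matrix. Monomorphic loci
    carry no information and are excluded from the scaling; an all-
    monomorphic input is an error.
    """
    is_frame = isinstance(geno, pd.DataFrame)
    M = np.asarray(geno, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ConfigError("calc_grm requires a 2-D dosage matrix with >= 2 individuals")
    p = (M.mean(axis=0) / 2.0) if base_freq is None else np.asarray(base_freq, dtype=float)
    if p.size != M.shape[1]:
        raise ConfigError("one allele frequency per locus is required")
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ConfigError("all loci are monomorphic; the relationship matrix is undefined")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = Z @ Z.T / denom
    if is_frame:
        return pd.DataFrame(G, index=geno.index, columns=geno.index)
    return G
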