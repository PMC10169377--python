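"""Founder genomes, the genetic map, csd editing, and the meiosis engine.

The honeybee genome is physically small (~250 Mbp) but genetically long
because of an extreme recombination rate of 2.3e-7 crossovers per bp per
meiosis. Tracked loci are abstract biallelic segregating sites placed on a
physical map; genetic positions (Morgans) are bp x rate, except inside the
csd window, whose sites share one genetic position so that csd alleles are
co-inherited intact (zero genetic width instead of rejection sampling).

Founder haplotypes come either from a coalescent simulation of a
three-subspecies split model (msprime) or from user-supplied phased
haplotypes (VCF or a plain 0/1 matrix). Inheritance everywhere goes through
:func:`meiosis` — a Haldane model (Poisson crossover count with no
interference, no obligate chiasma) — or :func:`drone_gamete`, since drone
sperm is clonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

#: Crossovers per bp per meiosis (the honeybee's unusually high rate).
DEFAULT_RECOMB_RATE = 2.3e-7

#: Full genome reference dimensions: 16 chromosomes summing to 250 Mbp.
FULL_GENOME_N_CHR = 16
FULL_GENOME_BP = 250_000_000

SUBSPECIES = ("ligustica", "carnica", "mellifera")


# ---------------------------------------------------------------------------
# Genome specification


@dataclass
class GenomeSpec:
    """Physical and genetic map of the tracked segregating sites.

    Attributes
    ----------
    bp_length : (n_chr,) array
        Physical chromosome lengths in bp.
    recomb_rate : float
        Expected crossovers per bp per meiosis.
    loci_pos : list of arrays
        Per chromosome, strictly increasing physical positions (bp).
    map_pos : list of arrays
        Genetic positions (Morgans) of the same sites; non-decreasing, and
        constant across the csd window.
    csd_chr, csd_start, csd_len
        0-based chromosome index, first-site index and length (sites) of
        the csd window; None until a SimParamBee places the window.
    """

    bp_length: np.ndarray
    recomb_rate: float
    loci_pos: list
    map_pos: list = field(default=None)
    csd_chr: Optional[int] = None
    csd_start: Optional[int] = None
    csd_len: Optional[int] = None

    def __post_init__(self):
        self.bp_length = np.asarray(self.bp_length, dtype=np.int64)
        self.loci_pos = [np.asarray(p, dtype=np.int64) for p in self.loci_pos]
        if len(self.loci_pos) != self.n_chr:
            raise ConfigError("loci_pos must have one entry per chromosome")
        for c, pos in enumerate(self.loci_pos):
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ConfigError(f"loci positions on chromosome {c + 1} are not strictly increasing")
            if pos.size and (pos[0] < 0 or pos[-1] > self.bp_length[c]):
                raise ConfigError(f"loci positions outside chromosome {c + 1}")
        if self.map_pos is None:
            self.map_pos = [pos.astype(float) * self.recomb_rate for pos in self.loci_pos]
        else:
            self.map_pos = [np.asarray(m, dtype=float) for m in self.map_pos]
        self._offsets = np.concatenate([[0], np.cumsum([p.size for p in self.loci_pos])])

    # -- shape helpers ------------------------------------------------------

    @property
    def n_chr(self) -> int:
        return len(self.bp_length)

    @property
    def n_sites_per_chr(self) -> np.ndarray:
        return np.diff(self._offsets)

    @property
    def total_sites(self) -> int:
        return int(self._offsets[-1])

    def chr_slice(self, c: int) -> slice:
        return slice(int(self._offsets[c]), int(self._offsets[c + 1]))

    def chr_lengths_morgans(self) -> np.ndarray:
        """Expected crossovers per chromosome per meiosis (bp x rate)."""
        return self.bp_length.astype(float) * self.recomb_rate

    def site_labels(self) -> list:
        """``chromosome_locus`` labels (both 1-based), matching printout conventions."""
        out = []
        for c, pos in enumerate(self.loci_pos):
            out.extend(f"{c + 1}_{j + 1}" for j in range(pos.size))
        return out

    # -- csd window ---------------------------------------------------------

    def set_csd_window(self, chrom: int, start: int, length: int) -> None:
        """Place the csd window and collapse its genetic width to zero."""
        if not 0 <= chrom < self.n_chr:
            raise ConfigError(f"csd chromosome index {chrom} outside genome")
        n = self.n_sites_per_chr[chrom]
        if not (0 <= start and start + length <= n):
            raise ConfigError("csd window outside chromosome's tracked sites")
        self.csd_chr, self.csd_start, self.csd_len = int(chrom), int(start), int(length)
        m = self.map_pos[chrom]
        m[start : start + length] = m[start]
        if np.any(np.diff(m) < 0):  # cannot happen for increasing loci, guard anyway
            raise ConfigError("map positions became decreasing after csd placement")

    def csd_cols(self) -> np.ndarray:
        """Global column indices of the csd window sites."""
        if self.csd_chr is None:
            raise ConfigError("csd window not set; create a SimParamBee first")
        first = self._offsets[self.csd_chr] + self.csd_start
        return np.arange(first, first + self.csd_len)


# ---------------------------------------------------------------------------
# Founder genomes


@dataclass
class FounderGenomes:
    """Phased founder haplotypes: 2*n_ind rows by total tracked sites.

    Row ``2*i`` and ``2*i + 1`` are founder ``i``'s two haplotypes; entries
    are 0 (ancestral) / 1 (derived). Row index doubles as the
    identity-by-descent label of that founder haplotype.
    """

    spec: GenomeSpec
    haplo: np.ndarray
    subspecies: list

    def __post_init__(self):
        self.haplo = np.asarray(self.haplo, dtype=np.uint8)
        if self.haplo.ndim != 2 or self.haplo.shape[0] % 2 != 0:
            raise ConfigError("founder haplotype matrix must have an even number of rows")
        if self.haplo.shape[1] != self.spec.total_sites:
            raise ConfigError("haplotype matrix width does not match the genome spec")
        if len(self.subspecies) != self.n_ind:
            raise ConfigError("one subspecies label per founder is required")

    @property
    def n_ind(self) -> int:
        return self.haplo.shape[0] // 2

    def individual_haplo(self, i: int) -> np.ndarray:
        return self.haplo[2 * i : 2 * i + 2]

    def ibd_labels(self, i: int) -> np.ndarray:
        S = self.spec.total_sites
        lab = np.empty((2, S), dtype=np.int32)
        lab[0] = 2 * i
        lab[1] = 2 * i + 1
        return lab


# ---------------------------------------------------------------------------
# Coalescent founder simulation


@dataclass
class SplitDemography:
    """Configurable stand-in three-subspecies demography.

    An ancestral population splits into the mellifera (M) lineage and the
    common ancestor of ligustica and carnica (the C lineage), which later
    splits into the two C-lineage subspecies. Effective sizes and split
    times (generations) are deliberately exposed because published point
    estimates vary; defaults are round numbers of a plausible magnitude.
    """

    ne: float = 3_000.0
    ne_ancestral: float = 3_000.0
    t_split_lig_car: float = 1_000.0
    t_split_m_c: float = 3_000.0

    def to_msprime(self):
        import msprime

        dem = msprime.Demography()
        for name in ("ligustica", "carnica", "mellifera"):
            dem.add_population(name=name, initial_size=self.ne)
        dem.add_population(name="lineageC", initial_size=self.ne_ancestral)
        dem.add_population(name="ancestral", initial_size=self.ne_ancestral)
        dem.add_population_split(
            time=self.t_split_lig_car, derived=["ligustica", "carnica"], ancestral="lineageC"
        )
        dem.add_population_split(
            time=self.t_split_m_c, derived=["lineageC", "mellifera"], ancestral="ancestral"
        )
        return dem


def simulate_founder_genomes(
    n_car: int = 0,
    n_lig: int = 0,
    n_mel: int = 0,
    *,
    n_chr: int = 3,
    n_seg_sites: int = 100,
    bp_per_chr: int = 1_000_000,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    demography: Optional[SplitDemography] = None,
    seed: Optional[int] = None,
) -> FounderGenomes:
    """Simulate phased founder haplotypes under the three-subspecies model.

    Chromosomes are simulated independently with msprime under the split
    demography; mutations are layered on with an adaptively chosen rate and
    the segregating sites are uniformly thinned to exactly ``n_seg_sites``
    per chromosome. Genetic map positions are assigned as bp x recomb_rate.

    The default ``bp_per_chr`` of 1 Mbp is a demonstration scale (0.23 M per
    chromosome); full-genome work uses ``FULL_GENOME_BP / FULL_GENOME_N_CHR``
    per chromosome.
    """
    import msprime

    counts = {"carnica": int(n_car), "ligustica": int(n_lig), "mellifera": int(n_mel)}
    if min(counts.values()) < 0:
        raise ConfigError("subspecies counts must be >= 0")
    n_ind = sum(counts.values())
    if n_ind == 0:
        raise ConfigError("at least one founder individual is required")
    if n_seg_sites <= 0:
        raise ConfigError("n_seg_sites must be positive")
    if n_chr <= 0:
        raise ConfigError("n_chr must be positive")

    demography = demography or SplitDemography()
    dem = demography.to_msprime()
    samples = [msprime.SampleSet(c, population=p, ploidy=2) for p, c in counts.items() if c > 0]

    # Watterson-based starting mutation rate aimed at ~3x the sites we need.
    a_n = sum(1.0 / k for k in range(1, max(2 * n_ind, 2)))
    theta_needed = 3.0 * n_seg_sites / a_n
    mu = theta_needed / (4.0 * demography.ne * bp_per_chr)

    ss = np.random.SeedSequence(seed)
    chr_seeds = ss.generate_state(2 * n_chr, dtype=np.uint32) % (2**31 - 1) + 1

    haplos, loci = [], []
    for c in range(n_chr):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=bp_per_chr,
            recombination_rate=recomb_rate,
            random_seed=int(chr_seeds[2 * c]),
        )
        rate, mts = mu, None
        for _ in range(6):
            mts = msprime.sim_mutations(
                ts,
                rate=rate,
                random_seed=int(chr_seeds[2 * c + 1]),
                model=msprime.BinaryMutationModel(),
                discrete_genome=True,
                keep=False,
            )
            if mts.num_sites >= n_seg_sites:
                break
            rate *= 2.0
        G = mts.genotype_matrix()  # sites x haplotypes
        pos = np.array([s.position for s in mts.sites()], dtype=np.int64)
        # keep strictly biallelic segregating sites at unique positions
        seg = (G.min(axis=1) == 0) & (G.max(axis=1) == 1)
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        keep = np.flatnonzero(seg & uniq)
        if keep.size < n_seg_sites:
            raise ConfigError(
                f"chromosome {c + 1}: only {keep.size} segregating sites produced; "
                "increase bp_per_chr or the demography's effective size"
            )
        if keep.size > n_seg_sites:
            pick = np.round(np.linspace(0, keep.size - 1, n_seg_sites)).astype(int)
            keep = keep[pick]
        haplos.append(G[keep].T.astype(np.uint8))
        loci.append(pos[keep])

    spec = GenomeSpec(
        bp_length=np.full(n_chr, bp_per_chr, dtype=np.int64),
        recomb_rate=recomb_rate,
        loci_pos=loci,
    )
    # msprime diploid samples are consecutive haplotype pairs in sample order
    labels = []
    for p, c in counts.items():
        labels.extend([p] * c)
    return FounderGenomes(spec=spec, haplo=np.hstack(haplos), subspecies=labels)


# ---------------------------------------------------------------------------
# Haplotype import


def import_haplotypes(
    source,
    *,
    positions: Optional[Sequence[np.ndarray]] = None,
    bp_length: Optional[Sequence[int]] = None,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    haploid_drones: bool = False,
    subspecies: str = "carnica",
) -> FounderGenomes:
    """Build founder genomes from user haplotypes instead of the coalescent.

    ``source`` is either a path to a phased VCF or a 0/1 matrix of shape
    (haplotypes, sites) accompanied by per-chromosome ``positions``.
    Haplotypes are paired into diploid founders; with ``haploid_drones=True``
    each haplotype is a drone genome and is duplicated into a fully
    homozygous founder. Non-segregating sites are dropped (count logged).
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        from .io import read_phased_vcf

        haplo, positions, chrom_names = read_phased_vcf(source)
    else:
        haplo = np.asarray(source)
        if positions is None:
            raise ConfigError("positions (one array per chromosome) are required with a matrix source")
        positions = [np.asarray(p, dtype=np.int64) for p in positions]
    if haplo.ndim != 2 or not np.isin(haplo, (0, 1)).all():
        raise FormatError("haplotype matrix must be 2-D with 0/1 entries")
    haplo = haplo.astype(np.uint8)
    if sum(p.size for p in positions) != haplo.shape[1]:
        raise ConfigError("positions do not match the number of haplotype columns")

    if haploid_drones:
        haplo = np.repeat(haplo, 2, axis=0)
    elif haplo.shape[0] % 2 != 0:
        raise FormatError(
            "odd number of haplotypes; pair them into diploids or pass haploid_drones=True"
        )

    # drop non-segregating sites per chromosome
    new_pos, kept_cols, offset, n_dropped = [], [], 0, 0
    for pos in positions:
        block = haplo[:, offset : offset + pos.size]
        seg = (block.min(axis=0) == 0) & (block.max(axis=0) == 1)
        n_dropped += int((~seg).sum())
        kept_cols.append(np.flatnonzero(seg) + offset)
        new_pos.append(pos[seg])
        offset += pos.size
    if n_dropped:
        logger.info("import_haplotypes: dropped %d non-segregating site(s)", n_dropped)
    haplo = haplo[:, np.concatenate(kept_cols)] if kept_cols else haplo

    if bp_length is None:
        bp_length = [int(p[-1]) + 1 if p.size else 1 for p in new_pos]
    spec = GenomeSpec(bp_length=np.asarray(bp_length), recomb_rate=recomb_rate, loci_pos=new_pos)
    n_ind = haplo.shape[0] // 2
    return FounderGenomes(spec=spec, haplo=haplo, subspecies=[subspecies] * n_ind)


# ---------------------------------------------------------------------------
# csd founder editing


def edit_csd_alleles(founders: FounderGenomes, n_csd_alleles: int) -> FounderGenomes:
    """Overwrite founder csd-window haplotypes to a balanced allele set.

    The ``n_csd_alleles`` distinct alleles are the binary words of the
    integers 0..n-1 over the window length. Words are dealt round-robin along
    the haplotype sequence, so frequencies are as uniform as integer counts
    allow, every allele occurs whenever 2*n_ind >= n_csd_alleles, and each
    founder receives two consecutive (hence distinct) words — every founder
    is csd-heterozygous. Edits in place and returns the same object.
    """
    spec = founders.spec
    if spec.csd_chr is None:
        raise ConfigError("csd window not set on the genome spec")
    if n_csd_alleles < 2:
        raise ConfigError("at least 2 csd alleles are required")
    L = spec.csd_len
    if n_csd_alleles > 2**L:
        raise ConfigError(f"{n_csd_alleles} alleles do not fit a {L}-SNP window")
    n_hap = founders.haplo.shape[0]
    if n_csd_alleles > n_hap:
        warnings.warn(
            f"requested {n_csd_alleles} csd alleles but only {n_hap} founder haplotypes; "
            "not all alleles will be represented",
            stacklevel=2,
        )
    cols = spec.csd_cols()
    words = ((np.arange(n_csd_alleles)[:, None] >> np.arange(L - 1, -1, -1)) & 1).astype(np.uint8)
    founders.haplo[:, cols] = words[np.arange(n_hap) % n_csd_alleles]
    return founders


# ---------------------------------------------------------------------------
# Meiosis


@dataclass
class Gamete:
    """One meiotic product: alleles, founder-origin labels, crossover count."""

    alleles: np.ndarray  # (total_sites,) uint8
    ibd: np.ndarray  # (total_sites,) int32 founder-haplotype labels
    n_crossovers: int = 0


def meiosis(haplo: np.ndarray, ibd: np.ndarray, spec: GenomeSpec, rng: np.random.Generator) -> Gamete:
    """Recombine and segregate a diploid genome into one gamete.

    Haldane model, per chromosome: the crossover count is Poisson with mean
    equal to the chromosome's genetic length (bp x rate, in Morgans),
    crossover positions are uniform on the genetic map, there is no
    interference and no obligate chiasma, and the starting haplotype is
    chosen with probability 1/2. Sites of the csd window share one genetic
    position, so a parental csd word is always transmitted intact.
    """
    haplo = np.asarray(haplo)
    if haplo.ndim != 2 or haplo.shape[0] != 2:
        raise ConfigError("meiosis requires a diploid genome (2 x sites); use drone_gamete for drones")
    S = spec.total_sites
    alleles = np.empty(S, dtype=np.uint8)
    ibd_out = np.empty(S, dtype=np.int32)
    lengths = spec.chr_lengths_morgans()
    total_xo = 0
    for c in range(spec.n_chr):
        sl = spec.chr_slice(c)
        m = spec.map_pos[c]
        lam = lengths[c]
        k = int(rng.poisson(lam)) if lam > 0 else 0
        start = int(rng.integers(2))
        if k == 0:
            idx = np.full(m.size, start, dtype=np.intp)
        else:
            xo = np.sort(rng.uniform(0.0, lam, size=k))
            idx = (start + np.searchsorted(xo, m, side="right")) % 2
        cols = np.arange(m.size)
        alleles[sl] = haplo[:, sl][idx, cols]
        ibd_out[sl] = np.asarray(ibd)[:, sl][idx, cols]
        total_xo += k
    return Gamete(alleles=alleles, ibd=ibd_out, n_crossovers=total_xo)


def drone_gamete(drone) -> Gamete:
    """Clonal gamete of a haploid drone: an exact copy of his single genome."""
    from .castes import Individual

    if isinstance(drone, Individual):
        if drone.ploidy != 1:
            raise ConfigError("drone_gamete requires a haploid individual; use meiosis for diploids")
        return Gamete(alleles=drone.haplo[0].copy(), ibd=drone.ibd[0].copy(), n_crossovers=0)
    haplo = np.asarray(drone)
    if haplo.ndim != 1:
        raise ConfigError("drone_gamete requires a haploid genome")
    return Gamete(alleles=haplo.astype(np.uint8).copy(), ibd=np.zeros(haplo.size, dtype=np.int32))
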