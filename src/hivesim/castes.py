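"""Individuals, caste populations, and brood creation.

Females (queens, workers, virgin queens) are proper diploids; drones are
haploid and carry a single meiotic gamete of their mother — they have no
father. Worker and virgin-queen genomes combine a maternal meiotic gamete
with the clonal gamete of a father drawn uniformly from the queen's
spermatheca, and every fertilised egg is screened at the csd locus:
homozygotes are removed (killed by workers), so a requested brood size is
an upper bound, never topped up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from . import params as P
from .errors import ConfigError, StateError
from .genome import FounderGenomes, Gamete, drone_gamete, meiosis
from .params import SimParamBee, resolve_count, resolve_sp


@dataclass
class Individual:
    """One honeybee: identity, pedigree, genome, caste, bookkeeping.

    ``haplo`` has shape (ploidy, total_sites); for diploids row 0 is the
    maternal and row 1 the paternal haplotype. ``ibd`` holds the
    founder-haplotype label of origin, site by site. Queens additionally
    carry their stored ``fathers`` (the spermatheca) and accumulate the
    realized count of csd-homozygous brood in ``misc['n_hom_brood']``.
    """

    id: int
    mother_id: Optional[int]
    father_id: Optional[int]
    ploidy: int
    haplo: np.ndarray
    ibd: np.ndarray
    caste: str
    misc: dict = field(default_factory=dict)
    fathers: Optional["Population"] = None
    alive: bool = True
    mated: bool = False

    def dosage(self) -> np.ndarray:
        """Allele dosage per site; haploid drones are scored as doubled
        haploids (0/2), keeping the diploid dosage scale."""
        d = self.haplo.sum(axis=0, dtype=np.int16)
        return 2 * d if self.ploidy == 1 else d

    def __repr__(self):
        return f"<Individual {self.id} {self.caste} ploidy={self.ploidy}>"


class Population:
    """Ordered collection of individuals of one role."""

    def __init__(self, individuals: Optional[Iterable[Individual]] = None):
        self.members: list[Individual] = list(individuals or [])
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate individual ids within a population")

    # -- container protocol -------------------------------------------------

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Population(self.members[i])
        return self.members[i]

    @property
    def ids(self) -> list[int]:
        return [m.id for m in self.members]

    def by_id(self, ind_id: int) -> Individual:
        for m in self.members:
            if m.id == ind_id:
                return m
        raise ConfigError(f"individual id {ind_id} not in population")

    def append(self, ind: Individual) -> None:
        if ind.id in set(self.ids):
            raise ConfigError(f"individual id {ind.id} already in population")
        self.members.append(ind)

    def extend(self, inds: Iterable[Individual]) -> None:
        for ind in inds:
            self.append(ind)

    def sample(self, n: int, rng: np.random.Generator, remove: bool = False) -> "Population":
        """Uniform sample without replacement; with ``remove`` the sampled
        individuals are pulled out of this population."""
        if n > len(self):
            raise ConfigError(f"cannot sample {n} of {len(self)} individuals")
        idx = rng.choice(len(self), size=n, replace=False)
        chosen = [self.members[i] for i in sorted(idx)]
        if remove:
            keep = set(idx)
            self.members = [m for i, m in enumerate(self.members) if i not in keep]
        return Population(chosen)

    def remove_ids(self, ids: Iterable[int]) -> "Population":
        ids = set(ids)
        removed = [m for m in self.members if m.id in ids]
        if len(removed) != len(ids):
            raise ConfigError("some ids to remove are not in the population")
        self.members = [m for m in self.members if m.id not in ids]
        return Population(removed)

    def __repr__(self):
        return f"<Population n={len(self)}>"


# ---------------------------------------------------------------------------
# Creation


def _new_individual(sp, caste, ploidy, haplo, ibd, mother_id, father_id, **misc) -> Individual:
    ind = Individual(
        id=sp.new_id(),
        mother_id=mother_id,
        father_id=father_id,
        ploidy=ploidy,
        haplo=np.atleast_2d(haplo).astype(np.uint8),
        ibd=np.atleast_2d(ibd).astype(np.int32),
        caste=caste,
        misc=dict(misc),
    )
    sp.register(ind.id, caste, mother_id, father_id)
    return ind


def _csd_words_rows(haplo: np.ndarray, spec) -> list:
    cols = spec.csd_cols()
    return ["".join(map(str, row)) for row in haplo[:, cols]]


def base_virgin_queen_genome(
    founders: FounderGenomes, i: int, spec, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the diploid genome of a base virgin queen derived from founder i:
    two meiotic gametes of the founder, redrawn until csd-heterozygous
    (founders are heterozygous, so half of the gamete pairs would be
    homozygous and inviable). Returns (haplo, ibd)."""
    fh, fi = founders.individual_haplo(i), founders.ibd_labels(i)
    for _ in range(1000):
        g1 = meiosis(fh, fi, spec, rng)
        g2 = meiosis(fh, fi, spec, rng)
        haplo = np.stack([g1.alleles, g2.alleles])
        if len(set(_csd_words_rows(haplo, spec))) == 2:
            return haplo, np.stack([g1.ibd, g2.ibd])
    raise StateError("could not produce a csd-heterozygous base virgin queen")  # pragma: no cover


def _base_virgin_queen(sp: SimParamBee, founders: FounderGenomes, i: int, rng) -> Individual:
    haplo, ibd = base_virgin_queen_genome(founders, i, sp.spec, rng)
    return _new_individual(sp, P.VIRGIN_QUEEN, 2, haplo, ibd, None, None, founder=i)


def create_virgin_queens(
    source, n_ind, sp: Optional[SimParamBee] = None, rng: Optional[np.random.Generator] = None
) -> Population:
    """Create virgin queens from founder genomes (base population) or from
    a colony's mated queen (csd-screened brood).

    From founders, queen ``i`` derives from founder ``i`` — at most one base
    virgin queen per simulated founder genome.
    """
    from .colony import Colony

    sp = resolve_sp(sp)
    rng = rng if rng is not None else sp.rng
    n = resolve_count(n_ind, rng)
    if isinstance(source, FounderGenomes):
        if n > source.n_ind:
            raise ConfigError(f"requested {n} virgin queens but only {source.n_ind} founder genomes")
        return Population([_base_virgin_queen(sp, source, i, rng) for i in range(n)])
    if isinstance(source, Colony):
        if source.queen is None:
            raise StateError("colony has no mated queen to produce virgin queens from")
        brood, _ = make_brood(source.queen, n, P.VIRGIN_QUEEN, sp, rng)
        return brood
    raise ConfigError("source must be FounderGenomes or a Colony")


def create_drones(
    source, n_ind, sp: Optional[SimParamBee] = None, rng: Optional[np.random.Generator] = None
) -> Population:
    """Create haploid drones from a (virgin) queen or a colony's queen.

    A virgin queen may mother drones — that is how a simulation is
    bootstrapped before any queen has mated. Drone eggs are unfertilised:
    each drone genome is a single meiotic gamete of the mother and there is
    no csd screen and no father.
    """
    from .colony import Colony

    sp = resolve_sp(sp)
    rng = rng if rng is not None else sp.rng
    n = resolve_count(n_ind, rng)
    if isinstance(source, Colony):
        if source.queen is None:
            raise StateError("colony has no queen to produce drones from")
        mother = source.queen
    elif isinstance(source, Individual):
        mother = source
    else:
        raise ConfigError("source must be a female Individual or a Colony")
    if mother.caste not in (P.QUEEN, P.VIRGIN_QUEEN):
        raise ConfigError(f"drones can only be mothered by a queen or virgin queen, not a {mother.caste}")
    out = []
    for _ in range(n):
        g = meiosis(mother.haplo, mother.ibd, sp.spec, rng)
        out.append(_new_individual(sp, P.DRONE, 1, g.alleles, g.ibd, mother.id, None))
    return Population(out)


def make_brood(
    queen: Individual,
    n_eggs: int,
    caste: str,
    sp: SimParamBee,
    rng: np.random.Generator,
) -> tuple[Population, int]:
    """Lay ``n_eggs`` fertilised eggs and keep the csd-viable ones.

    Per egg the father is drawn uniformly from the spermatheca, the
    maternal gamete by meiosis, and the paternal gamete clonally. The csd
    screen removes homozygotes, increments the queen's cumulative
    ``n_hom_brood`` counter, and does not top the brood back up.
    """
    from .csd import filter_csd_viable

    if queen.caste != P.QUEEN or queen.fathers is None or len(queen.fathers) == 0:
        raise StateError("brood requires a mated queen with stored fathers")
    zygotes = []
    fathers = queen.fathers.members
    for _ in range(n_eggs):
        father = fathers[int(rng.integers(len(fathers)))]
        gm = meiosis(queen.haplo, queen.ibd, sp.spec, rng)
        gp = drone_gamete(father)
        zygotes.append(
            (np.stack([gm.alleles, gp.alleles]), np.stack([gm.ibd, gp.ibd]), father.id)
        )
    survivors, n_removed = filter_csd_viable(zygotes, queen, sp=sp)
    pop = Population(
        [
            _new_individual(sp, caste, 2, haplo, ibd, queen.id, fid)
            for haplo, ibd, fid in survivors
        ]
    )
    return pop, n_removed


def create_workers(
    colony, n_ind, sp: Optional[SimParamBee] = None, rng: Optional[np.random.Generator] = None
) -> tuple[Population, int]:
    """Create workers in a colony; returns (workers, number of csd-homozygous
    brood removed). Fewer workers than requested may result."""
    from .colony import Colony

    sp = resolve_sp(sp)
    if not isinstance(colony, Colony):
        raise ConfigError("create_workers requires a Colony")
    if colony.queen is None:
        raise StateError("colony has no mated queen")
    rng = rng if rng is not None else colony._rng
    n = resolve_count(n_ind, rng)
    return make_brood(colony.queen, n, P.WORKER, sp, rng)


# ---------------------------------------------------------------------------
# Caste predicates


def check_caste(target, caste: str, sp: Optional[SimParamBee] = None):
    """Boolean per individual: does it currently belong to ``caste``?"""
    if caste not in P.CASTES:
        raise ConfigError(f"unknown caste {caste!r}")
    sp = resolve_sp(sp)
    if isinstance(target, Individual):
        return sp.get_caste(target.id) == caste
    if isinstance(target, Population):
        return np.array([sp.get_caste(m.id) == caste for m in target])
    return np.array([sp.get_caste(i) == caste for i in target])


def is_queen(target, sp=None):
    return check_caste(target, P.QUEEN, sp)


def is_virgin_queen(target, sp=None):
    return check_caste(target, P.VIRGIN_QUEEN, sp)


def is_worker(target, sp=None):
    return check_caste(target, P.WORKER, sp)


def is_drone(target, sp=None):
    return check_caste(target, P.DRONE, sp)


def is_father(target, sp=None):
    return check_caste(target, P.FATHER, sp)
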