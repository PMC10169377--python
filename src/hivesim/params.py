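"""Global simulation parameters, castes, and stochastic samplers.

A single :class:`SimParamBee` object holds everything that is shared across
a simulation: the founder genomes and their genetic map, the csd-locus
specification, default caste sizes and event proportions, the trait
architecture, the global caste registry and pedigree, and the root random
seed. Following the common global-context pattern of breeding simulators,
the most recently created ``SimParamBee`` is registered as the implicit
context, so library functions accept ``sp=None`` and fall back to it;
explicit passing always works too.

Caste sizes and event proportions can be given either as plain numbers or
as *samplers* — small callable objects that draw a count (Poisson,
zero-truncated Poisson, fixed) or a proportion (fixed, uniform, or a
strength-dependent beta). Any operation that takes a count or proportion
argument accepts a sampler in its place, which makes the corresponding
step stochastic.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Union

import numpy as np
from scipy import stats

from .errors import ConfigError, StateError

# ---------------------------------------------------------------------------
# Castes

QUEEN = "queen"
FATHER = "father"
WORKER = "worker"
DRONE = "drone"
VIRGIN_QUEEN = "virginQueen"

CASTES = frozenset({QUEEN, FATHER, WORKER, DRONE, VIRGIN_QUEEN})

#: The only caste transitions that can occur during a honeybee's life:
#: a virgin queen is promoted to queen at mating, and a drone that mates
#: becomes a father (and dies).
ALLOWED_CASTE_TRANSITIONS = frozenset({(VIRGIN_QUEEN, QUEEN), (DRONE, FATHER)})


# ---------------------------------------------------------------------------
# Samplers


class Sampler:
    """Base class for callable stochastic samplers."""

    kind: str = "abstract"

    def __call__(self, rng: np.random.Generator, **kwargs):
        raise NotImplementedError


class CountSampler(Sampler):
    """Sampler returning a non-negative integer count."""


class ProportionSampler(Sampler):
    """Sampler returning a proportion in [0, 1]."""


class FixedCount(CountSampler):
    kind = "fixed"

    def __init__(self, n: int):
        n = int(n)
        if n < 0:
            raise ConfigError(f"fixed count must be >= 0, got {n}")
        self.n = n

    def __call__(self, rng, **kwargs) -> int:
        return self.n


class PoissonCount(CountSampler):
    kind = "poisson"

    def __init__(self, mean: float):
        if mean < 0:
            raise ConfigError(f"Poisson mean must be >= 0, got {mean}")
        self.mean = float(mean)

    def __call__(self, rng, **kwargs) -> int:
        return int(rng.poisson(self.mean))


class TruncPoissonCount(CountSampler):
    """Zero-truncated Poisson: counts are >= 1 with mean mu/(1 - e^-mu).

    Sampled by inverse-CDF restricted to the positive support, so a single
    uniform draw per call keeps streams reproducible.
    """

    kind = "truncPoisson"

    def __init__(self, mean: float):
        if mean <= 0:
            raise ConfigError(f"truncated-Poisson mean must be > 0, got {mean}")
        self.mean = float(mean)

    def __call__(self, rng, **kwargs) -> int:
        p0 = math.exp(-self.mean)
        u = rng.uniform()
        return int(stats.poisson.ppf(p0 + u * (1.0 - p0), self.mean))


class FixedProportion(ProportionSampler):
    kind = "fixed"

    def __init__(self, p: float):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"proportion must be in [0, 1], got {p}")
        self.p = float(p)

    def __call__(self, rng, strength=None, **kwargs) -> float:
        return self.p


class UniformProportion(ProportionSampler):
    kind = "uniform"

    def __init__(self, low: float, high: float):
        if not (0.0 <= low <= high <= 1.0):
            raise ConfigError(f"uniform bounds must satisfy 0 <= low <= high <= 1, got ({low}, {high})")
        self.low = float(low)
        self.high = float(high)

    def __call__(self, rng, strength=None, **kwargs) -> float:
        return float(rng.uniform(self.low, self.high))


class BetaStrengthProportion(ProportionSampler):
    """Beta-distributed proportion whose mean grows with colony strength.

    The contract is monotonicity: stronger colonies (more workers) swarm
    with a larger worker share. The mean follows a saturating curve
    ``p_max * s / (s + half_strength)`` and the draw is Beta with that mean
    and a fixed precision (a + b = precision).

    Parameters
    ----------
    p_max : float
        Asymptotic proportion as strength -> infinity.
    half_strength : float
        Strength at which the mean reaches p_max / 2. A natural choice is
        half the full-size worker count, so a full-strength colony sits at
        two-thirds of ``p_max``.
    precision : float
        Beta concentration; larger values give draws closer to the mean.
    """

    kind = "betaStrength"

    def __init__(self, p_max: float = 0.7, half_strength: float = 50.0, precision: float = 10.0):
        if not 0.0 < p_max <= 1.0:
            raise ConfigError(f"p_max must be in (0, 1], got {p_max}")
        if half_strength <= 0 or precision <= 0:
            raise ConfigError("half_strength and precision must be > 0")
        self.p_max = float(p_max)
        self.half_strength = float(half_strength)
        self.precision = float(precision)

    def mean_at(self, strength: float) -> float:
        """Expected proportion for a colony of the given strength."""
        s = max(float(strength), 0.0)
        return self.p_max * s / (s + self.half_strength)

    def __call__(self, rng, strength=None, **kwargs) -> float:
        if strength is None:
            strength = 2.0 * self.half_strength  # reference full-size colony
        m = min(max(self.mean_at(strength), 1e-9), 1.0 - 1e-9)
        a = m * self.precision
        b = (1.0 - m) * self.precision
        return float(rng.beta(a, b))


_COUNT_SAMPLERS = {
    "fixed": FixedCount,
    "poisson": PoissonCount,
    "truncPoisson": TruncPoissonCount,
}

_PROPORTION_SAMPLERS = {
    "fixed": FixedProportion,
    "uniform": UniformProportion,
    "betaStrength": BetaStrengthProportion,
}


def make_count_sampler(kind: str, **params) -> CountSampler:
    """Build a count sampler: ``fixed(n)``, ``poisson(mean)`` or ``truncPoisson(mean)``."""
    try:
        cls = _COUNT_SAMPLERS[kind]
    except KeyError:
        raise ConfigError(f"unknown count sampler kind {kind!r}; choose from {sorted(_COUNT_SAMPLERS)}")
    return cls(**params)


def make_proportion_sampler(kind: str, **params) -> ProportionSampler:
    """Build a proportion sampler: ``fixed(p)``, ``uniform(low, high)`` or ``betaStrength(...)``."""
    try:
        cls = _PROPORTION_SAMPLERS[kind]
    except KeyError:
        raise ConfigError(f"unknown proportion sampler kind {kind!r}; choose from {sorted(_PROPORTION_SAMPLERS)}")
    return cls(**params)


def resolve_count(value: Union[int, CountSampler], rng: np.random.Generator) -> int:
    """Turn an int-or-sampler argument into a concrete non-negative count."""
    if isinstance(value, Sampler):
        n = int(value(rng))
    else:
        n = int(value)
    if n < 0:
        raise ConfigError(f"count must be >= 0, got {n}")
    return n


def resolve_proportion(value, rng: np.random.Generator, strength=None) -> float:
    """Turn a float-or-sampler argument into a concrete proportion in (0, 1)."""
    if isinstance(value, Sampler):
        p = float(value(rng, strength=strength))
    else:
        p = float(value)
    if not 0.0 < p < 1.0:
        raise ConfigError(f"proportion must be strictly within (0, 1), got {p}")
    return p


# ---------------------------------------------------------------------------
# SimParamBee


def _check_open_proportion(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ConfigError(f"{name} must be strictly within (0, 1), got {p}")
    return p


class SimParamBee:
    """Global honeybee-simulation parameters and shared registries.

    Parameters
    ----------
    founders : FounderGenomes
        Simulated or imported founder genomes; the csd window is placed on
        their genetic map and (by default) their csd haplotypes are edited
        to the requested allelic diversity.
    n_workers, n_drones, n_virgin_queens : int or CountSampler
        Default caste sizes of a full-size colony.
    n_fathers : int or CountSampler
        Default number of drones a queen mates with (polyandry level).
    swarm_p, split_p, downsize_p : float or ProportionSampler
        Default worker proportions leaving in a swarm, removed in a split,
        and removed in an autumn downsize.
    n_csd_alleles : int
        Number of distinct csd alleles, a power of two >= 2; the csd locus
        is a window of log2(n_csd_alleles) non-recombining SNPs.
    csd_chr : int, optional
        1-based chromosome carrying the csd locus. Defaults to chromosome 3
        when the genome has at least three chromosomes (the locus's physical
        home), else the last chromosome.
    csd_pos : float, optional
        Relative position (0..1) of the window on the chromosome; default
        centered.
    seed : int
        Root seed; every stochastic operation draws from streams derived
        from it, so a whole trace is reproducible.
    edit_csd : bool
        Edit founder csd haplotypes to the requested allele count
        (round-robin, balancing frequencies, every founder heterozygous).
    activate : bool
        Register this object as the implicit global context.
    """

    def __init__(
        self,
        founders,
        *,
        n_workers=100,
        n_drones=10,
        n_virgin_queens=10,
        n_fathers=15,
        swarm_p=0.5,
        split_p=0.3,
        downsize_p=0.85,
        n_csd_alleles: int = 32,
        csd_chr: Optional[int] = None,
        csd_pos: Optional[float] = None,
        seed: int = 0,
        edit_csd: bool = True,
        activate: bool = True,
    ):
        from .genome import FounderGenomes, edit_csd_alleles  # local import, avoids cycle

        if not isinstance(founders, FounderGenomes):
            raise ConfigError("founders must be a FounderGenomes object")

        if n_csd_alleles < 2 or (n_csd_alleles & (n_csd_alleles - 1)) != 0:
            raise ConfigError(f"n_csd_alleles must be a power of two >= 2, got {n_csd_alleles}")
        self.n_csd_alleles = int(n_csd_alleles)
        self.csd_len = int(round(math.log2(n_csd_alleles)))

        spec = founders.spec
        if csd_chr is None:
            csd_chr = 3 if spec.n_chr >= 3 else spec.n_chr
        if not 1 <= csd_chr <= spec.n_chr:
            raise ConfigError(f"csd chromosome {csd_chr} outside genome with {spec.n_chr} chromosomes")
        n_sites = spec.n_sites_per_chr[csd_chr - 1]
        if n_sites < self.csd_len:
            raise ConfigError(
                f"chromosome {csd_chr} has {n_sites} tracked sites, fewer than the "
                f"{self.csd_len}-SNP csd window"
            )
        rel = 0.5 if csd_pos is None else float(csd_pos)
        if not 0.0 <= rel <= 1.0:
            raise ConfigError(f"csd_pos must be within [0, 1], got {csd_pos}")
        start = int(round(rel * (n_sites - self.csd_len)))
        spec.set_csd_window(csd_chr - 1, start, self.csd_len)

        # caste-size defaults (ints or samplers)
        for name, v in [("n_workers", n_workers), ("n_virgin_queens", n_virgin_queens), ("n_fathers", n_fathers)]:
            if not isinstance(v, Sampler) and int(v) <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if not isinstance(n_drones, Sampler) and int(n_drones) < 0:
            raise ConfigError(f"n_drones must be >= 0, got {n_drones}")
        self.n_workers = n_workers if isinstance(n_workers, Sampler) else int(n_workers)
        self.n_drones = n_drones if isinstance(n_drones, Sampler) else int(n_drones)
        self.n_virgin_queens = n_virgin_queens if isinstance(n_virgin_queens, Sampler) else int(n_virgin_queens)
        self.n_fathers = n_fathers if isinstance(n_fathers, Sampler) else int(n_fathers)
        self.swarm_p = swarm_p if isinstance(swarm_p, Sampler) else _check_open_proportion("swarm_p", swarm_p)
        self.split_p = split_p if isinstance(split_p, Sampler) else _check_open_proportion("split_p", split_p)
        self.downsize_p = (
            downsize_p if isinstance(downsize_p, Sampler) else _check_open_proportion("downsize_p", downsize_p)
        )

        self.founders = founders
        self.spec = spec
        self.traits = None  # TraitArchitecture, set by quantgen.add_trait_a
        self.snp_chip = None  # SnpChip, set by genomics.add_snp_chip

        self.caste_registry: dict[int, str] = {}
        self.pedigree: dict[int, tuple[Optional[int], Optional[int]]] = {}

        self.seed = int(seed)
        self._seed_seq = np.random.SeedSequence(self.seed)
        self.rng = np.random.default_rng(self._seed_seq.spawn(1)[0])

        self._next_id = 1
        self._next_colony_id = 1

        if edit_csd:
            edit_csd_alleles(founders, self.n_csd_alleles)

        if activate:
            set_sim_param(self)

    # -- identifiers --------------------------------------------------------

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def new_ids(self, n: int) -> list[int]:
        return [self.new_id() for _ in range(n)]

    def new_colony_id(self) -> int:
        i = self._next_colony_id
        self._next_colony_id += 1
        return i

    def colony_rng(self, colony_id: int) -> np.random.Generator:
        """Dedicated RNG substream for one colony, keyed by its id.

        Vectorized multi-colony operations and the equivalent colony-by-colony
        loop therefore consume identical streams and produce identical traces.
        """
        return np.random.default_rng(np.random.SeedSequence([self.seed, 0xC0107, int(colony_id)]))

    # -- caste registry and pedigree ----------------------------------------

    def register(self, ind_id: int, caste: str, mother_id=None, father_id=None) -> None:
        if caste not in CASTES:
            raise ConfigError(f"unknown caste {caste!r}")
        if ind_id in self.caste_registry:
            raise StateError(f"individual id {ind_id} already registered")
        self.caste_registry[ind_id] = caste
        self.pedigree[ind_id] = (mother_id, father_id)

    def set_caste(self, ind_id: int, caste: str) -> None:
        """Transition an individual's caste; only virginQueen->queen and
        drone->father are biologically possible."""
        try:
            current = self.caste_registry[ind_id]
        except KeyError:
            raise ConfigError(f"unknown individual id {ind_id}")
        if current == caste:
            return
        if (current, caste) not in ALLOWED_CASTE_TRANSITIONS:
            raise StateError(f"caste transition {current} -> {caste} is not allowed (id {ind_id})")
        self.caste_registry[ind_id] = caste

    def get_caste(self, ids: Union[int, Iterable[int]]):
        """Caste label(s) for registered individual id(s), in input order."""
        if np.isscalar(ids):
            try:
                return self.caste_registry[int(ids)]
            except KeyError:
                raise ConfigError(f"unknown individual id {ids}")
        return [self.get_caste(i) for i in ids]


# ---------------------------------------------------------------------------
# Implicit global context

_ACTIVE_SP: Optional[SimParamBee] = None


def set_sim_param(sp: Optional[SimParamBee]) -> None:
    """Register (or clear, with None) the implicit global SimParamBee."""
    global _ACTIVE_SP
    _ACTIVE_SP = sp


def get_sim_param() -> SimParamBee:
    if _ACTIVE_SP is None:
        raise StateError("no active SimParamBee; create one or pass sp= explicitly")
    return _ACTIVE_SP


def resolve_sp(sp: Optional[SimParamBee]) -> SimParamBee:
    return sp if sp is not None else get_sim_param()


def new_sim_param_bee(founders, **options) -> SimParamBee:
    """Create and activate global simulation parameters (thin constructor alias)."""
    return SimParamBee(founders, **options)


def get_caste(target, sp: Optional[SimParamBee] = None):
    """Caste labels for ids, an individual, or a population, in input order."""
    sp = resolve_sp(sp)
    from .castes import Individual, Population

    if isinstance(target, Individual):
        return sp.get_caste(target.id)
    if isinstance(target, Population):
        return sp.get_caste([ind.id for ind in target])
    return sp.get_caste(target)
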