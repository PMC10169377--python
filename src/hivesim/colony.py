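"""The Colony container and colony events.

A colony holds at most one queen (with her stored fathers), plus worker,
drone and virgin-queen populations, a location, and event flags. Events
mirror apicultural reality: build-up to full size, swarming (the queen
leaves with part of the workers), splitting (a beekeeper removes workers
to found a new colony), supersedure (queen replacement), downsizing for
winter, combining a weak colony into a strong one, and collapse. A
collapsed colony keeps its members for post-mortem analysis but admits no
further simulation.

Production status marks whether production phenotypes (e.g. honey yield)
can be collected: it turns on at build-up and off when the colony swarms,
collapses, is downsized, or is split off from another colony.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import params as P
from .castes import Individual, Population, create_drones, create_workers, make_brood
from .errors import ConfigError, StateError
from .params import SimParamBee, resolve_count, resolve_proportion, resolve_sp


class Colony:
    """One honeybee colony; construct via :func:`create_colony` or events."""

    def __init__(self, sp: SimParamBee, colony_id: Optional[int] = None):
        self.sp = sp
        self.id = sp.new_colony_id() if colony_id is None else int(colony_id)
        self.location: Optional[tuple[float, float]] = None
        self.queen: Optional[Individual] = None
        self.workers = Population()
        self.drones = Population()
        self.virgin_queens = Population()
        self.swarmed = False
        self.split = False
        self.superseded = False
        self.collapsed = False
        self.productive = False
        self._rng = sp.colony_rng(self.id)

    # -- guards -------------------------------------------------------------

    def _check_mutable(self):
        if self.collapsed:
            raise StateError(f"colony {self.id} has collapsed; further simulation is not allowed")

    def _require_queen(self):
        if self.queen is None:
            raise StateError(f"colony {self.id} has no queen")

    # -- counting and access -------------------------------------------------

    def _caste_pop(self, caste: str) -> Population:
        if caste == P.WORKER:
            return self.workers
        if caste == P.DRONE:
            return self.drones
        if caste == P.VIRGIN_QUEEN:
            return self.virgin_queens
        if caste == P.QUEEN:
            return Population([self.queen] if self.queen is not None else [])
        if caste == P.FATHER:
            if self.queen is None or self.queen.fathers is None:
                return Population()
            return self.queen.fathers
        raise ConfigError(f"unknown caste {caste!r}")

    def count_caste(self, caste: str) -> int:
        return len(self._caste_pop(caste))

    @property
    def n_workers(self) -> int:
        return len(self.workers)

    @property
    def n_drones(self) -> int:
        return len(self.drones)

    @property
    def n_virgin_queens(self) -> int:
        return len(self.virgin_queens)

    @property
    def n_fathers(self) -> int:
        return self.count_caste(P.FATHER)

    def get_caste_pop(self, caste: str) -> Population:
        """Copy-out access: the colony is left unchanged."""
        return Population(list(self._caste_pop(caste)))

    def pull_caste_pop(self, caste: str, n: int) -> Population:
        """Remove and return ``n`` uniformly sampled members of a caste."""
        self._check_mutable()
        pop = self._caste_pop(caste)
        if caste in (P.QUEEN, P.FATHER):
            raise ConfigError(f"cannot pull from the {caste} slot")
        if n > len(pop):
            raise ConfigError(f"cannot pull {n} of {len(pop)} {caste}s from colony {self.id}")
        return pop.sample(n, self._rng, remove=True)

    def add_caste_pop(self, caste: str, individuals: Population) -> "Colony":
        self._check_mutable()
        if caste == P.QUEEN:
            raise ConfigError("use re_queen to install a queen")
        for ind in individuals:
            if ind.caste != caste:
                raise ConfigError(f"individual {ind.id} is a {ind.caste}, not a {caste}")
        self._caste_pop(caste).extend(individuals)
        return self

    def remove_caste_pop(self, caste: str, n: Optional[int] = None) -> "Colony":
        self._check_mutable()
        if n is None:
            if caste == P.WORKER:
                self.workers = Population()
            elif caste == P.DRONE:
                self.drones = Population()
            elif caste == P.VIRGIN_QUEEN:
                self.virgin_queens = Population()
            else:
                raise ConfigError(f"cannot remove the {caste} slot wholesale")
        else:
            self.pull_caste_pop(caste, n)
        return self

    def replace_caste_pop(self, caste: str, n) -> "Colony":
        """Remove a caste entirely and create ``n`` fresh members from the queen."""
        self._check_mutable()
        self.remove_caste_pop(caste)
        n = resolve_count(n, self._rng)
        if caste == P.WORKER:
            new, _ = create_workers(self, n, sp=self.sp)
            self.workers = new
        elif caste == P.DRONE:
            self.drones = create_drones(self, n, sp=self.sp, rng=self._rng)
        elif caste == P.VIRGIN_QUEEN:
            self._require_queen()
            new, _ = make_brood(self.queen, n, P.VIRGIN_QUEEN, self.sp, self._rng)
            self.virgin_queens = new
        else:
            raise ConfigError(f"cannot replace the {caste} slot")
        return self

    # -- status -------------------------------------------------------------

    def is_queen_present(self) -> bool:
        return self.queen is not None

    def is_virgin_queens_present(self) -> bool:
        return len(self.virgin_queens) > 0

    def is_workers_present(self) -> bool:
        return len(self.workers) > 0

    def is_drones_present(self) -> bool:
        return len(self.drones) > 0

    def is_fathers_present(self) -> bool:
        return self.n_fathers > 0

    def is_productive(self) -> bool:
        return self.productive

    def has_swarmed(self) -> bool:
        return self.swarmed

    def has_split(self) -> bool:
        return self.split

    def has_superseded(self) -> bool:
        return self.superseded

    def has_collapsed(self) -> bool:
        return self.collapsed

    def summary(self) -> dict:
        return {
            "id": self.id,
            "location": self.location,
            "queen_id": self.queen.id if self.queen else None,
            "n_fathers": self.n_fathers,
            "n_workers": self.n_workers,
            "n_drones": self.n_drones,
            "n_virgin_queens": self.n_virgin_queens,
            "swarmed": self.swarmed,
            "split": self.split,
            "superseded": self.superseded,
            "collapsed": self.collapsed,
            "productive": self.productive,
        }

    def __repr__(self):
        s = self.summary()
        loc = "NA" if s["location"] is None else f"{s['location']}"
        q = "NA" if s["queen_id"] is None else s["queen_id"]
        return (
            f"Colony id: {s['id']}\n"
            f"Location: {loc}\n"
            f"Queen: {q}\n"
            f"Number of fathers: {s['n_fathers']}\n"
            f"Number of workers: {s['n_workers']}\n"
            f"Number of drones: {s['n_drones']}\n"
            f"Number of virgin queens: {s['n_virgin_queens']}\n"
            f"Has swarmed: {s['swarmed']}\n"
            f"Has split: {s['split']}\n"
            f"Has superseded: {s['superseded']}\n"
            f"Has collapsed: {s['collapsed']}\n"
            f"Is productive: {s['productive']}"
        )

    # -- internal helpers ---------------------------------------------------

    def _fresh_virgin_queens(self, mother_queen: Individual, n=None) -> Population:
        n = resolve_count(self.sp.n_virgin_queens if n is None else n, self._rng)
        vqs, _ = make_brood(mother_queen, n, P.VIRGIN_QUEEN, self.sp, self._rng)
        return vqs

    @staticmethod
    def _round_half_even(x: float) -> int:
        # deterministic, unbiased rounding of p * n_workers
        return int(round(x))

    # -- events --------------------------------------------------------------

    def build_up(self, n_workers=None, n_drones=None) -> "Colony":
        """Top the colony up to full size and switch production on.

        Targets default to the SimParamBee caste sizes; only the shortfall
        is created, so repeating build-up with the same targets is a no-op.
        csd-homozygous brood may leave the worker count below target.
        """
        self._check_mutable()
        self._require_queen()
        target_w = resolve_count(self.sp.n_workers if n_workers is None else n_workers, self._rng)
        target_d = resolve_count(self.sp.n_drones if n_drones is None else n_drones, self._rng)
        need_w = target_w - self.n_workers
        if need_w > 0:
            new, _ = create_workers(self, need_w, sp=self.sp)
            self.workers.extend(new)
        need_d = target_d - self.n_drones
        if need_d > 0:
            self.drones.extend(create_drones(self, need_d, sp=self.sp, rng=self._rng))
        self.productive = True
        return self

    def swarm(self, p=None, n_virgin_queens=None) -> tuple["Colony", "Colony"]:
        """Swarm: the queen leaves with a share ``p`` of the workers.

        Returns ``(swarm, remnant)``. The swarm keeps this colony's id (the
        identity follows the queen) and holds the old queen plus
        round(p * n_workers) workers and no drones. The remnant gets a fresh
        id, the remaining workers, all drones, and freshly raised virgin
        queens that are daughters of the departed queen. Both are flagged as
        swarmed and non-productive.
        """
        self._check_mutable()
        self._require_queen()
        p = resolve_proportion(
            self.sp.swarm_p if p is None else p, self._rng, strength=self.n_workers
        )
        n_leave = self._round_half_even(p * self.n_workers)
        leaving = self.workers.sample(n_leave, self._rng, remove=True)

        vqs = self._fresh_virgin_queens(self.queen, n_virgin_queens)

        swarm_colony = Colony(self.sp, colony_id=self.id)
        swarm_colony.location = self.location
        swarm_colony.queen = self.queen
        swarm_colony.workers = leaving
        swarm_colony.swarmed = True
        swarm_colony.productive = False

        remnant = Colony(self.sp)
        remnant.location = self.location
        remnant.workers = self.workers
        remnant.drones = self.drones
        remnant.virgin_queens = vqs
        remnant.swarmed = True
        remnant.productive = False

        self._invalidate()
        return swarm_colony, remnant

    def do_split(self, p=None, n_virgin_queens=None) -> tuple["Colony", "Colony"]:
        """Split: a share ``p`` of workers is removed to found a new colony.

        Returns ``(split, remnant)``. The split colony (fresh id) receives
        the removed workers plus fresh virgin queens and is non-productive;
        the remnant keeps this colony's id, queen, remaining workers and all
        drones and stays productive. Both record the split event.
        """
        self._check_mutable()
        self._require_queen()
        p = resolve_proportion(
            self.sp.split_p if p is None else p, self._rng, strength=self.n_workers
        )
        n_taken = self._round_half_even(p * self.n_workers)
        taken = self.workers.sample(n_taken, self._rng, remove=True)

        vqs = self._fresh_virgin_queens(self.queen, n_virgin_queens)

        split_colony = Colony(self.sp)
        split_colony.location = self.location
        split_colony.workers = taken
        split_colony.virgin_queens = vqs
        split_colony.split = True
        split_colony.productive = False

        remnant = Colony(self.sp, colony_id=self.id)
        remnant.location = self.location
        remnant.queen = self.queen
        remnant.workers = self.workers
        remnant.drones = self.drones
        remnant.virgin_queens = self.virgin_queens
        remnant.split = True
        remnant.productive = self.productive

        self._invalidate()
        return split_colony, remnant

    def supersede(self, n_virgin_queens=None) -> "Colony":
        """Remove the queen and raise her daughter virgin queens; the colony
        keeps working, so productivity is unchanged."""
        self._check_mutable()
        self._require_queen()
        old_queen = self.queen
        vqs = self._fresh_virgin_queens(old_queen, n_virgin_queens)
        old_queen.alive = False
        self.queen = None
        self.virgin_queens.extend(vqs)
        self.superseded = True
        return self

    def collapse(self) -> "Colony":
        """Mark the colony as collapsed; members are kept but all further
        mutating operations error."""
        if self.collapsed:
            raise StateError(f"colony {self.id} has already collapsed")
        self.collapsed = True
        self.productive = False
        return self

    def downsize(self, p=None) -> "Colony":
        """Remove a share ``p`` of workers (default downsize_p), all drones
        and all virgin queens; production stops."""
        self._check_mutable()
        p = resolve_proportion(
            self.sp.downsize_p if p is None else p, self._rng, strength=self.n_workers
        )
        n_remove = self._round_half_even(p * self.n_workers)
        self.workers.sample(n_remove, self._rng, remove=True)
        self.drones = Population()
        self.virgin_queens = Population()
        self.productive = False
        return self

    def combine(self, weak: "Colony") -> "Colony":
        """Absorb a weak colony's workers and drones; the strong colony's
        queen, id and flags are retained and the weak queen is discarded."""
        self._check_mutable()
        weak._check_mutable()
        self.workers.extend(weak.workers)
        self.drones.extend(weak.drones)
        if weak.queen is not None:
            weak.queen.alive = False
        weak._invalidate()
        return self

    def re_queen(self, new_queen: Individual) -> "Colony":
        """Install a new (virgin) queen, removing the current one.

        A mated queen takes the queen slot and the virgin queens are
        cleared; a virgin queen leaves the colony queenless with her as the
        single candidate.
        """
        self._check_mutable()
        if new_queen.caste not in (P.QUEEN, P.VIRGIN_QUEEN):
            raise ConfigError(f"re_queen requires a queen or virgin queen, not a {new_queen.caste}")
        if self.queen is not None:
            self.queen.alive = False
            self.queen = None
        if new_queen.caste == P.QUEEN:
            self.queen = new_queen
            self.virgin_queens = Population()
        else:
            self.virgin_queens = Population([new_queen])
        return self

    def _invalidate(self):
        # detach populations after a partition event so the old handle
        # cannot alias individuals that moved into the offspring colonies
        self.queen = None
        self.workers = Population()
        self.drones = Population()
        self.virgin_queens = Population()


# -- module-level wrappers (functional style) --------------------------------


def build_up(colony: "Colony", n_workers=None, n_drones=None) -> "Colony":
    return colony.build_up(n_workers, n_drones)


def swarm(colony: "Colony", p=None, n_virgin_queens=None):
    return colony.swarm(p, n_virgin_queens)


def split(colony: "Colony", p=None, n_virgin_queens=None):
    return colony.do_split(p, n_virgin_queens)


def supersede(colony: "Colony", n_virgin_queens=None) -> "Colony":
    return colony.supersede(n_virgin_queens)


def collapse(colony: "Colony") -> "Colony":
    return colony.collapse()


def downsize(colony: "Colony", p=None) -> "Colony":
    return colony.downsize(p)


def combine(strong: "Colony", weak: "Colony") -> "Colony":
    return strong.combine(weak)


def re_queen(colony: "Colony", new_queen: Individual) -> "Colony":
    return colony.re_queen(new_queen)


def create_colony(female=None, sp: Optional[SimParamBee] = None) -> Colony:
    """Create a colony from one virgin queen or one mated queen."""
    sp = resolve_sp(sp)
    col = Colony(sp)
    if female is None:
        return col
    if isinstance(female, Population):
        if len(female) != 1:
            raise ConfigError("create_colony takes exactly one female")
        female = female[0]
    if not isinstance(female, Individual):
        raise ConfigError("create_colony requires an Individual (virgin) queen")
    if female.caste == P.VIRGIN_QUEEN:
        col.virgin_queens = Population([female])
    elif female.caste == P.QUEEN:
        if female.fathers is None or len(female.fathers) == 0:
            raise StateError("a mated queen must carry stored fathers")
        col.queen = female
    else:
        raise ConfigError(f"cannot found a colony with a {female.caste}")
    return col
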