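"""Drone congregation areas, mating stations, cross plans, and mating.

A virgin queen mates once, with several drones (typically 6–24), and
stores their sperm for life. Here a DCA is a pooled drone population,
either open (drones from many colonies) or a mating station (drones from
sister daughter queens of one sire colony). Mating promotes the virgin
queen to queen, stores the drones as her fathers, and kills the drones —
a drone id can never appear in two spermathecae.
"""

from __future__ import annotations

import csv
from typing import Optional, Union

import numpy as np

from . import params as P
from .castes import Individual, Population, create_drones, create_virgin_queens
from .colony import Colony
from .errors import ConfigError, StateError
from .multicolony import MultiColony
from .params import SimParamBee, resolve_count, resolve_sp


def create_dca(sources, n_per_source=None, sp: Optional[SimParamBee] = None,
               rng: Optional[np.random.Generator] = None) -> Population:
    """Pool drones into a DCA.

    ``sources`` may be colonies (their queens produce ``n_per_source``
    drones each; defaults to the SimParamBee drone count) or existing drone
    populations (pooled as-is). Drones keep their origin pedigree.
    """
    sp = resolve_sp(sp)
    rng = rng if rng is not None else sp.rng
    if isinstance(sources, (Colony, Population)):
        sources = [sources]
    sources = list(sources)
    if not sources:
        raise ConfigError("create_dca requires at least one source")
    dca = Population()
    for src in sources:
        if isinstance(src, Colony):
            n = resolve_count(sp.n_drones if n_per_source is None else n_per_source, rng)
            dca.extend(create_drones(src, n, sp=sp, rng=rng))
        elif isinstance(src, Population):
            for d in src:
                if d.caste != P.DRONE:
                    raise ConfigError(f"individual {d.id} in a DCA source is not a drone")
            dca.extend(src)
        else:
            raise ConfigError("DCA sources must be colonies or drone populations")
    return dca


def create_mating_station_dca(sire_colony: Colony, n_dpq: int, n_drones_per_dpq: int,
                              sp: Optional[SimParamBee] = None) -> Population:
    """Mating-station DCA: drones from ``n_dpq`` sister drone-producing
    queens (daughters of the sire colony's queen), ``n_drones_per_dpq``
    each. Every drone is a grandson of the sire queen."""
    sp = resolve_sp(sp)
    if sire_colony.queen is None:
        raise StateError("mating station requires a sire colony with a mated queen")
    if int(n_dpq) <= 0:
        raise ConfigError("n_dpq must be positive")
    dpqs = create_virgin_queens(sire_colony, int(n_dpq), sp=sp)
    dca = Population()
    for dpq in dpqs:
        dca.extend(create_drones(dpq, int(n_drones_per_dpq), sp=sp))
    return dca


def pull_drone_groups_from_dca(dca: Population, n_groups: int, n_fathers=None,
                               sp: Optional[SimParamBee] = None,
                               rng: Optional[np.random.Generator] = None) -> list[Population]:
    """Sample ``n_groups`` disjoint drone groups, removing them from the DCA.

    Group sizes come from ``n_fathers`` (int or count sampler; defaults to
    the SimParamBee polyandry level)."""
    sp = resolve_sp(sp)
    rng = rng if rng is not None else sp.rng
    groups = []
    for _ in range(int(n_groups)):
        k = resolve_count(sp.n_fathers if n_fathers is None else n_fathers, rng)
        if k > len(dca):
            raise ConfigError(f"DCA exhausted: {k} drones requested, {len(dca)} left")
        groups.append(dca.sample(k, rng, remove=True))
    return groups


class CrossPlan(dict):
    """Mapping virgin-queen id -> list of drone ids; drones are disjoint."""

    def validate(self):
        seen = set()
        for q, ds in self.items():
            for d in ds:
                if d in seen:
                    raise ConfigError(f"drone {d} assigned to two queens in the cross plan")
                seen.add(d)
        return self

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["queen_id", "drone_id"])
            for q, ds in self.items():
                for d in ds:
                    w.writerow([q, d])

    @classmethod
    def from_csv(cls, path):
        plan = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                plan.setdefault(int(row["queen_id"]), []).append(int(row["drone_id"]))
        return plan.validate()


def create_random_cross_plan(virgin_queen_ids, dca: Population, n_drones,
                             sp: Optional[SimParamBee] = None,
                             rng: Optional[np.random.Generator] = None) -> CrossPlan:
    """Assign each virgin queen a disjoint uniform sample of DCA drone ids."""
    sp = resolve_sp(sp)
    rng = rng if rng is not None else sp.rng
    ids = list(virgin_queen_ids)
    if len(ids) * int(n_drones) > len(dca):
        raise ConfigError(
            f"cross plan needs {len(ids) * int(n_drones)} drones but the DCA holds {len(dca)}"
        )
    pool = np.array(dca.ids)
    chosen = rng.choice(pool.size, size=len(ids) * int(n_drones), replace=False)
    plan = CrossPlan()
    for j, q in enumerate(ids):
        plan[q] = pool[chosen[j * int(n_drones) : (j + 1) * int(n_drones)]].tolist()
    return plan.validate()


def _mate(virgin_queen: Individual, drones: Population, sp: SimParamBee) -> Individual:
    """Promote a virgin queen to queen, store the drones as her fathers, and
    mark them dead; the spermatheca never changes afterwards."""
    if virgin_queen.caste == P.QUEEN:
        raise StateError(f"queen {virgin_queen.id} has already mated")
    if virgin_queen.caste != P.VIRGIN_QUEEN:
        raise ConfigError(f"cannot cross a {virgin_queen.caste}")
    if len(drones) == 0:
        raise ConfigError("cannot cross with an empty drone group")
    for d in drones:
        if d.mated:
            raise StateError(f"drone {d.id} has already mated")
        if d.caste != P.DRONE:
            raise ConfigError(f"individual {d.id} in the drone group is not a drone")
    for d in drones:
        d.mated = True
        d.alive = False
        sp.set_caste(d.id, P.FATHER)
        d.caste = P.FATHER
    sp.set_caste(virgin_queen.id, P.QUEEN)
    virgin_queen.caste = P.QUEEN
    virgin_queen.fathers = Population(list(drones))
    virgin_queen.misc.setdefault("n_hom_brood", 0)
    return virgin_queen


def cross(target, drones=None, cross_plan: Optional[CrossPlan] = None,
          dca: Optional[Population] = None, sp: Optional[SimParamBee] = None):
    """Mate virgin queens to drones.

    ``target`` is a Colony (its first virgin queen mates), a virgin-queen
    Individual, or a MultiColony with one drone group per colony. With a
    ``cross_plan`` plus a shared ``dca``, drones are looked up by id and
    removed from the DCA — the fast batch path for many queens.
    """
    sp = resolve_sp(sp)

    if isinstance(target, MultiColony):
        cols = target.non_null()
        if cross_plan is not None:
            for c in cols:
                cross(c, cross_plan=cross_plan, dca=dca, sp=sp)
        else:
            if drones is None or len(drones) != len(cols):
                raise ConfigError("provide one drone group per colony")
            for c, grp in zip(cols, drones):
                cross(c, drones=grp, sp=sp)
        return target

    if isinstance(target, Colony):
        target._check_mutable()
        if target.queen is not None:
            raise StateError(f"colony {target.id} already has a mated queen")
        if len(target.virgin_queens) == 0:
            raise StateError(f"colony {target.id} has no virgin queen to mate")
        vq = target.virgin_queens[0]
        if cross_plan is not None:
            if dca is None:
                raise ConfigError("a cross plan requires the DCA it refers to")
            if vq.id not in cross_plan:
                raise ConfigError(f"virgin queen {vq.id} not in the cross plan")
            drones = dca.remove_ids(cross_plan[vq.id])
        if drones is None:
            raise ConfigError("provide drones or a cross plan")
        queen = _mate(vq, drones, sp)
        target.queen = queen
        target.virgin_queens = Population()
        return target

    if isinstance(target, Individual):
        if drones is None and cross_plan is not None:
            if dca is None:
                raise ConfigError("a cross plan requires the DCA it refers to")
            drones = dca.remove_ids(cross_plan[target.id])
        return _mate(target, drones, sp)

    raise ConfigError("cross target must be a Colony, MultiColony, or virgin queen")
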