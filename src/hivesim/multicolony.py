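"""Ordered collections of colonies (apiaries, regions, age groups).

A MultiColony is a list of colony slots; a slot may hold a colony, an
*empty* colony (no members), or be a NULL placeholder. Every colony-level
operation has a vectorized counterpart here. Because each colony draws
from its own id-keyed RNG substream, a vectorized call and the equivalent
colony-by-colony loop produce identical traces.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Union

import numpy as np

from .castes import Population
from .colony import Colony, create_colony
from .errors import ConfigError, StateError
from .params import SimParamBee, resolve_sp


class MultiColony:
    def __init__(self, colonies: Optional[Iterable[Optional[Colony]]] = None):
        self.colonies: list[Optional[Colony]] = list(colonies or [])
        ids = [c.id for c in self.colonies if c is not None]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate colony ids in MultiColony")

    # -- container ----------------------------------------------------------

    def __len__(self):
        return len(self.colonies)

    def __iter__(self):
        return iter(self.colonies)

    def __getitem__(self, i) -> Optional[Colony]:
        if isinstance(i, slice):
            return MultiColony(self.colonies[i])
        return self.colonies[i]

    @property
    def ids(self) -> list:
        return [c.id if c is not None else None for c in self.colonies]

    def non_null(self) -> list[Colony]:
        return [c for c in self.colonies if c is not None]

    @property
    def n_null(self) -> int:
        return sum(c is None for c in self.colonies)

    @property
    def n_empty(self) -> int:
        return sum(
            c is not None
            and c.queen is None
            and not (len(c.workers) or len(c.drones) or len(c.virgin_queens))
            for c in self.colonies
        )

    def by_id(self, colony_id) -> Colony:
        for c in self.non_null():
            if c.id == colony_id:
                return c
        raise ConfigError(f"colony id {colony_id} not in MultiColony")

    def __repr__(self):
        n = len(self)
        events = {
            "swarmed": sum(c.swarmed for c in self.non_null()),
            "split": sum(c.split for c in self.non_null()),
            "superseded": sum(c.superseded for c in self.non_null()),
            "collapsed": sum(c.collapsed for c in self.non_null()),
            "productive": sum(c.productive for c in self.non_null()),
        }
        ev = ", ".join(f"{k}: {v}" for k, v in events.items())
        return f"MultiColony with {n} colonies ({self.n_empty} empty, {self.n_null} NULL)\nEvents — {ev}"

    # -- partitioning and selection -----------------------------------------

    def pull(self, n=None, ids=None, predicate: Optional[Callable[[Colony], bool]] = None,
             rng: Optional[np.random.Generator] = None) -> tuple["MultiColony", "MultiColony"]:
        """Partition into (pulled, remnant), preserving relative order.

        Exactly one of ``n`` (uniform sample), ``ids``, or ``predicate``
        selects the pulled colonies.
        """
        given = sum(x is not None for x in (n, ids, predicate))
        if given != 1:
            raise ConfigError("provide exactly one of n, ids, predicate")
        if n is not None:
            if n > len(self):
                raise ConfigError(f"cannot pull {n} of {len(self)} colonies")
            if rng is None:
                sp = resolve_sp(None)
                rng = sp.rng
            chosen = set(rng.choice(len(self), size=int(n), replace=False).tolist())
            mask = [i in chosen for i in range(len(self))]
        elif ids is not None:
            want = set(ids)
            have = set(cid for cid in self.ids if cid is not None)
            unknown = want - have
            if unknown:
                raise ConfigError(f"unknown colony ids: {sorted(unknown)}")
            mask = [c is not None and c.id in want for c in self.colonies]
        else:
            mask = [c is not None and bool(predicate(c)) for c in self.colonies]
        pulled = MultiColony([c for c, m in zip(self.colonies, mask) if m])
        remnant = MultiColony([c for c, m in zip(self.colonies, mask) if not m])
        return pulled, remnant

    def select(self, n: int, use) -> "MultiColony":
        """Keep the ``n`` colonies with the highest values in ``use``
        (one value per colony, in order); ties break toward the smaller
        colony id. Order of the selected colonies is preserved."""
        use = np.asarray(use, dtype=float)
        if use.ndim != 1 or use.size != len(self):
            raise ConfigError("use must supply exactly one value per colony")
        if n > len(self):
            raise ConfigError(f"cannot select {n} of {len(self)} colonies")
        order = sorted(
            range(len(self)),
            key=lambda i: (-use[i], self.colonies[i].id if self.colonies[i] is not None else np.inf),
        )
        keep = set(order[: int(n)])
        return MultiColony([c for i, c in enumerate(self.colonies) if i in keep])

    def bind(self, other: "MultiColony") -> "MultiColony":
        """Concatenate two id-disjoint MultiColony objects, preserving order."""
        return MultiColony(self.colonies + other.colonies)

    # -- vectorized colony operations ---------------------------------------

    def _per_colony(self, arg, name):
        cols = self.non_null()
        if isinstance(arg, (list, tuple, np.ndarray)):
            if len(arg) != len(cols):
                raise ConfigError(f"{name}: expected {len(cols)} per-colony values, got {len(arg)}")
            return list(arg)
        return [arg] * len(cols)

    def _wrap(self, fn, colony: Colony, *args):
        try:
            return fn(colony, *args)
        except (ConfigError, StateError) as e:
            raise type(e)(f"colony {colony.id}: {e}") from e

    def build_up(self, n_workers=None, n_drones=None) -> "MultiColony":
        cols = self.non_null()
        for c, w, d in zip(cols, self._per_colony(n_workers, "n_workers"),
                           self._per_colony(n_drones, "n_drones")):
            self._wrap(lambda col, w=w, d=d: col.build_up(w, d), c)
        return self

    def cross(self, drone_groups=None, cross_plan=None, dca=None) -> "MultiColony":
        from .crossing import cross as _cross

        _cross(self, drones=drone_groups, cross_plan=cross_plan, dca=dca)
        return self

    def swarm(self, p=None) -> tuple["MultiColony", "MultiColony"]:
        cols = self.non_null()
        ps = self._per_colony(p, "p")
        pairs = [self._wrap(lambda col, pp=pp: col.swarm(pp), c) for c, pp in zip(cols, ps)]
        return MultiColony([s for s, _ in pairs]), MultiColony([r for _, r in pairs])

    def split(self, p=None) -> tuple["MultiColony", "MultiColony"]:
        cols = self.non_null()
        ps = self._per_colony(p, "p")
        pairs = [self._wrap(lambda col, pp=pp: col.do_split(pp), c) for c, pp in zip(cols, ps)]
        return MultiColony([s for s, _ in pairs]), MultiColony([r for _, r in pairs])

    def supersede(self) -> "MultiColony":
        for c in self.non_null():
            self._wrap(lambda col: col.supersede(), c)
        return self

    def downsize(self, p=None) -> "MultiColony":
        ps = self._per_colony(p, "p")
        for c, pp in zip(self.non_null(), ps):
            self._wrap(lambda col, pp=pp: col.downsize(pp), c)
        return self

    def collapse(self) -> "MultiColony":
        for c in self.non_null():
            self._wrap(lambda col: col.collapse(), c)
        return self


def create_multi_colony(source=None, n: Optional[int] = None,
                        sp: Optional[SimParamBee] = None) -> MultiColony:
    """Create a MultiColony from virgin queens (one colony each) or as ``n``
    NULL placeholder slots."""
    sp = resolve_sp(sp)
    if source is None:
        return MultiColony([None] * int(n or 0))
    if isinstance(source, Population):
        return MultiColony([create_colony(vq, sp=sp) for vq in source])
    raise ConfigError("source must be a Population of virgin queens or None with n")
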