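"""Trait architecture, genetic and phenotypic values, colony values.

Traits are strictly additive: each of ``n_qtl_per_chr`` QTL per chromosome
carries a per-trait effect, drawn from a multivariate normal with the
requested genetic correlation structure and then centered and rescaled so
that the *base virgin-queen population* — the individuals actually entering
a simulation — has the target means and additive variances. Haploid drones
are scored as doubled haploids (dosage 0/2), so their values sit on the
same scale as diploids.

Colony-level values follow the additive mapping used for traits like honey
yield: the queen contributes her queen-effect value, the workers the sum
of their worker-effect values. The mapping is pluggable — any callable of
(queen values, worker values, colony) may replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import params as P
from .castes import Individual, Population
from .errors import ConfigError, StateError
from .genome import meiosis
from .params import SimParamBee, resolve_sp


@dataclass
class TraitArchitecture:
    """Additive trait architecture shared by all individuals.

    ``qtl_idx`` are global site indices (disjoint from the csd window and
    any SNP chip); ``effects`` is (n_qtl, n_traits); ``intercept`` shifts
    each trait to its target base mean. ``var_e``/``cor_e`` parameterize the
    environmental deviates drawn by :func:`set_pheno`.
    """

    qtl_idx: np.ndarray
    effects: np.ndarray
    intercept: np.ndarray
    target_mean: np.ndarray
    target_var: np.ndarray
    cor_a: np.ndarray
    var_e: np.ndarray
    cor_e: np.ndarray

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]


def _check_correlation(name: str, C: np.ndarray, T: int) -> np.ndarray:
    C = np.eye(T) if C is None else np.asarray(C, dtype=float)
    if C.shape != (T, T):
        raise ConfigError(f"{name} must be {T}x{T}")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ConfigError(f"{name} must be symmetric with unit diagonal")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8:
        raise ConfigError(f"{name} is not positive semi-definite")
    return C


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _sym_sqrt(C: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric (inverse) matrix square root via the eigendecomposition."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-12, None)
    d = 1.0 / np.sqrt(w) if inverse else np.sqrt(w)
    return V @ np.diag(d) @ V.T


def add_trait_a(
    sp: Optional[SimParamBee],
    n_qtl_per_chr: int,
    means: Sequence[float],
    vars: Sequence[float],
    cor_a: Optional[np.ndarray] = None,
    var_e: Optional[Sequence[float]] = None,
    cor_e: Optional[np.ndarray] = None,
    n_scale: int = 2000,
) -> SimParamBee:
    """Define correlated additive traits on the active simulation.

    QTL are sampled uniformly among tracked sites (excluding the csd
    window); raw per-QTL effect vectors are i.i.d. multivariate normal with
    correlation ``cor_a``. Effects are then linearly transformed so that a
    Monte-Carlo sample (``n_scale`` genomes) of the base virgin-queen
    distribution — meiotic gamete pairs of the founders — realizes exactly
    the target (co)variance matrix, and intercepts set the target means.
    """
    sp = resolve_sp(sp)
    means = np.atleast_1d(np.asarray(means, dtype=float))
    vars_ = np.atleast_1d(np.asarray(vars, dtype=float))
    T = means.size
    if vars_.size != T:
        raise ConfigError("means and vars must have equal length")
    if np.any(vars_ <= 0):
        raise ConfigError("target variances must be positive")
    cor_a = _check_correlation("cor_a", cor_a, T)
    cor_e = _check_correlation("cor_e", cor_e, T)
    var_e_ = np.zeros(T) if var_e is None else np.atleast_1d(np.asarray(var_e, dtype=float))
    if var_e_.size != T or np.any(var_e_ < 0):
        raise ConfigError("var_e must be length n_traits and non-negative")

    spec = sp.spec
    csd = set(spec.csd_cols().tolist())
    rng = sp.rng
    qtl = []
    for c in range(spec.n_chr):
        sl = spec.chr_slice(c)
        candidates = np.array([i for i in range(sl.start, sl.stop) if i not in csd])
        if n_qtl_per_chr > candidates.size:
            raise ConfigError(
                f"chromosome {c + 1}: {n_qtl_per_chr} QTL requested but only "
                f"{candidates.size} eligible sites"
            )
        qtl.append(np.sort(rng.choice(candidates, size=int(n_qtl_per_chr), replace=False)))
    qtl_idx = np.concatenate(qtl)

    L = _mvn_factor(cor_a)
    effects = rng.standard_normal((qtl_idx.size, T)) @ L.T

    # scale on the base virgin-queen genotype distribution (including the
    # csd-heterozygosity screen, which matters for window-linked QTL)
    from .castes import base_virgin_queen_genome

    founders = sp.founders
    reps = max(1, int(np.ceil(n_scale / founders.n_ind)))
    dosages = np.empty((reps * founders.n_ind, qtl_idx.size), dtype=np.int16)
    r = 0
    for _ in range(reps):
        for i in range(founders.n_ind):
            haplo, _ = base_virgin_queen_genome(founders, i, spec, rng)
            dosages[r] = haplo[:, qtl_idx].sum(axis=0, dtype=np.int16)
            r += 1
    G = dosages @ effects
    Gc = G - G.mean(axis=0)
    C = Gc.T @ Gc / (G.shape[0] - 1)
    # whiten the realized covariance, then colour to the target covariance:
    # with symmetric roots, A' C A = target_cov exactly on the scaling sample
    target_cov = np.sqrt(vars_)[:, None] * cor_a * np.sqrt(vars_)[None, :]
    A = _sym_sqrt(C, inverse=True) @ _sym_sqrt(target_cov)
    effects = effects @ A
    intercept = means - (dosages @ effects).mean(axis=0)

    sp.traits = TraitArchitecture(
        qtl_idx=qtl_idx,
        effects=effects,
        intercept=intercept,
        target_mean=means,
        target_var=vars_,
        cor_a=cor_a,
        var_e=var_e_,
        cor_e=cor_e,
    )
    return sp


# ---------------------------------------------------------------------------
# Values


def _require_traits(sp: SimParamBee) -> TraitArchitecture:
    if sp.traits is None:
        raise StateError("no traits defined; call add_trait_a first")
    return sp.traits


def gv(target, sp: Optional[SimParamBee] = None) -> np.ndarray:
    """Genetic values, shape (n_individuals, n_traits).

    gv = intercept + sum over QTL of effect x dosage; drones are scored with
    doubled dosage (doubled-haploid convention)."""
    sp = resolve_sp(sp)
    tr = _require_traits(sp)
    pop = Population([target]) if isinstance(target, Individual) else target
    out = np.empty((len(pop), tr.n_traits))
    for i, ind in enumerate(pop):
        out[i] = tr.intercept + ind.dosage()[tr.qtl_idx] @ tr.effects
    return out


def set_pheno(target, sp: Optional[SimParamBee] = None,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw phenotypes: pheno = gv + environmental deviate.

    Deviates are multivariate normal with variances ``var_e`` and
    correlation ``cor_e``; each call redraws and stores the result on the
    individuals (``misc['pheno']``)."""
    sp = resolve_sp(sp)
    tr = _require_traits(sp)
    rng = rng if rng is not None else sp.rng
    pop = Population([target]) if isinstance(target, Individual) else target
    g = gv(pop, sp)
    Le = np.diag(np.sqrt(tr.var_e)) @ _mvn_factor(tr.cor_e)
    e = rng.standard_normal((len(pop), tr.n_traits)) @ Le.T
    ph = g + e
    for i, ind in enumerate(pop):
        ind.misc["pheno"] = ph[i]
    return ph


def _pheno_of(pop: Population, sp: SimParamBee) -> np.ndarray:
    """Stored phenotypes; individuals without one get a single lazy draw."""
    missing = Population([ind for ind in pop if "pheno" not in ind.misc])
    if len(missing):
        set_pheno(missing, sp)
    tr = _require_traits(sp)
    return np.array([ind.misc["pheno"] for ind in pop]).reshape(len(pop), tr.n_traits)


def _collect_caste(target, caste: Optional[str]):
    """(colony_id, Population) blocks for a Colony/MultiColony/Population."""
    from .colony import Colony
    from .multicolony import MultiColony

    if isinstance(target, MultiColony):
        return [(c.id, c.get_caste_pop(caste)) for c in target.non_null()]
    if isinstance(target, Colony):
        return [(target.id, target.get_caste_pop(caste))]
    if isinstance(target, Population):
        return [(None, target)]
    if isinstance(target, Individual):
        return [(None, Population([target]))]
    raise ConfigError("unsupported target type")


def _values_frame(target, caste, sp, kind: str) -> pd.DataFrame:
    import warnings

    sp = resolve_sp(sp)
    tr = _require_traits(sp)
    blocks = _collect_caste(target, caste)
    frames = []
    for cid, pop in blocks:
        if len(pop) == 0:
            warnings.warn(f"caste {caste!r} absent" + (f" in colony {cid}" if cid else ""),
                          stacklevel=3)
            continue
        vals = gv(pop, sp) if kind == "gv" else _pheno_of(pop, sp)
        idx = pd.MultiIndex.from_arrays(
            [[cid] * len(pop), pop.ids], names=["colony", "id"]
        )
        frames.append(pd.DataFrame(vals, index=idx,
                                   columns=[f"trait{t + 1}" for t in range(tr.n_traits)]))
    if not frames:
        return pd.DataFrame(columns=[f"trait{t + 1}" for t in range(tr.n_traits)])
    return pd.concat(frames)


def get_gv(target, caste: Optional[str] = None, sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """Genetic values of a caste within a Colony/MultiColony (or of a
    Population), indexed by (colony, individual id)."""
    return _values_frame(target, caste, sp, "gv")


def get_pheno(target, caste: Optional[str] = None, sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """Latest stored phenotypes of a caste (drawn lazily once if absent)."""
    return _values_frame(target, caste, sp, "pheno")


# ---------------------------------------------------------------------------
# Colony values


def default_colony_value(queen_values: np.ndarray, worker_values: np.ndarray, colony) -> float:
    """Additive queen-plus-workers mapping.

    Trait 1 is the queen effect, trait 2 (when present) the worker effect;
    the colony value is the queen's queen-effect value plus the *sum* of the
    workers' worker-effect values. Linear, hence invariant to worker order
    and additive under worker-set union.
    """
    wt = 1 if queen_values.shape[-1] >= 2 else 0
    return float(queen_values[0]) + float(worker_values[:, wt].sum())


def mean_colony_value(queen_values: np.ndarray, worker_values: np.ndarray, colony) -> float:
    """Variant using the workers' mean instead of their sum."""
    wt = 1 if queen_values.shape[-1] >= 2 else 0
    return float(queen_values[0]) + float(worker_values[:, wt].mean())


def calc_colony_value(target, mapping: Optional[Callable] = None, on: str = "gv",
                      sp: Optional[SimParamBee] = None):
    """Map individual values to colony value(s).

    For a Colony returns a float; for a MultiColony a Series indexed by
    colony id. ``on`` selects genetic values or stored phenotypes. The
    default mapping requires a queen (and uses her workers, possibly none).
    """
    from .colony import Colony
    from .multicolony import MultiColony

    sp = resolve_sp(sp)
    _require_traits(sp)
    if on not in ("gv", "pheno"):
        raise ConfigError("on must be 'gv' or 'pheno'")
    mapping = mapping or default_colony_value

    if isinstance(target, MultiColony):
        vals = {c.id: calc_colony_value(c, mapping, on, sp) for c in target.non_null()}
        return pd.Series(vals, name=f"colony_{on}")
    if not isinstance(target, Colony):
        raise ConfigError("target must be a Colony or MultiColony")
    if target.queen is None and mapping is default_colony_value:
        raise StateError(f"colony {target.id}: default colony value requires a queen")
    qpop = target.get_caste_pop(P.QUEEN)
    wpop = target.get_caste_pop(P.WORKER)
    if on == "gv":
        qv = gv(qpop, sp) if len(qpop) else np.empty((0, sp.traits.n_traits))
        wv = gv(wpop, sp) if len(wpop) else np.empty((0, sp.traits.n_traits))
    else:
        qv = _pheno_of(qpop, sp) if len(qpop) else np.empty((0, sp.traits.n_traits))
        wv = _pheno_of(wpop, sp) if len(wpop) else np.empty((0, sp.traits.n_traits))
    qv1 = qv[0] if len(qpop) else np.zeros(sp.traits.n_traits)
    return mapping(qv1, wv, target)
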