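"""Complementary sex determination: allele inspection and brood viability.

The csd locus is a window of non-recombining biallelic SNPs; the binary
word read along the window is the csd allele. Fertilised eggs heterozygous
at csd develop into females; homozygotes are killed by the workers, so a
queen's realized brood falls short of the number of eggs laid. The
theoretical shortfall is ``p_hom_brood``; the realized cumulative count is
kept on the queen and returned by ``n_hom_brood``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import params as P
from .errors import ConfigError, StateError
from .params import SimParamBee, resolve_sp


def _window_words(haplo: np.ndarray, spec) -> list[str]:
    cols = spec.csd_cols()
    return ["".join(map(str, row)) for row in np.atleast_2d(haplo)[:, cols]]


def csd_words(individual, sp: Optional[SimParamBee] = None) -> tuple[str, ...]:
    """The csd allele word(s) of one individual: two for diploids, one for drones."""
    sp = resolve_sp(sp)
    return tuple(_window_words(individual.haplo, sp.spec))


def get_csd_alleles(target, sp: Optional[SimParamBee] = None) -> pd.DataFrame:
    """csd-window haplotypes as a 0/1 table.

    Rows are labeled ``individual_haplotype`` (two rows per diploid, one per
    haploid drone) and columns ``chromosome_locus``, matching the printout
    convention of the colony summaries.
    """
    from .castes import Individual, Population

    sp = resolve_sp(sp)
    spec = sp.spec
    cols = spec.csd_cols()
    labels = [spec.site_labels()[c] for c in cols]
    if isinstance(target, Individual):
        target = Population([target])
    rows, index = [], []
    for ind in target:
        h = np.atleast_2d(ind.haplo)[:, cols]
        for k in range(h.shape[0]):
            rows.append(h[k])
            index.append(f"{ind.id}_{k + 1}")
    return pd.DataFrame(np.array(rows, dtype=int), index=index, columns=labels)


def is_csd_heterozygous(target, sp: Optional[SimParamBee] = None):
    """True per diploid individual iff its two csd words differ; haploids error."""
    from .castes import Individual, Population

    sp = resolve_sp(sp)
    single = isinstance(target, Individual)
    pop = Population([target]) if single else target
    out = []
    for ind in pop:
        if ind.ploidy != 2:
            raise ConfigError(f"individual {ind.id} is haploid; csd heterozygosity is undefined")
        w = _window_words(ind.haplo, sp.spec)
        out.append(w[0] != w[1])
    return out[0] if single else np.array(out)


def p_hom_brood_words(queen_words, father_words) -> float:
    """Theoretical csd-homozygous brood proportion from allele words.

    With queen words {a1, a2} and k fathers used with equal probability,
    each egg draws one queen allele (p = 1/2 each) and one father; the egg
    is homozygous iff the father's word equals the drawn queen allele:

        p = (1 / (2k)) * sum_j ( [f_j == a1] + [f_j == a2] )
    """
    a1, a2 = queen_words
    k = len(father_words)
    if k == 0:
        raise ConfigError("at least one father is required")
    return sum((f == a1) + (f == a2) for f in father_words) / (2.0 * k)


def p_hom_brood(queen, sp: Optional[SimParamBee] = None) -> float:
    """Theoretical brood homozygosity of a mated queen (in [0, 1/2])."""
    sp = resolve_sp(sp)
    if queen.caste != P.QUEEN or queen.fathers is None or len(queen.fathers) == 0:
        raise StateError("p_hom_brood requires a mated queen with stored fathers")
    qw = _window_words(queen.haplo, sp.spec)
    fw = [_window_words(f.haplo, sp.spec)[0] for f in queen.fathers]
    return p_hom_brood_words(qw, fw)


def n_hom_brood(queen) -> int:
    """Cumulative realized csd-homozygous offspring since mating."""
    if queen.caste != P.QUEEN:
        raise StateError("n_hom_brood requires a mated queen")
    return int(queen.misc.get("n_hom_brood", 0))


def filter_csd_viable(zygotes, queen, sp: Optional[SimParamBee] = None):
    """Keep csd-heterozygous zygotes; count and record the removals.

    ``zygotes`` are candidate diploid genomes as (haplo, ibd, father_id)
    triples, produced from the queen and her stored fathers. The removed
    homozygotes increment the queen's cumulative ``n_hom_brood`` counter.
    The requested brood size is *not* topped up after removal.
    """
    sp = resolve_sp(sp)
    survivors = []
    for haplo, ibd, fid in zygotes:
        w = _window_words(haplo, sp.spec)
        if w[0] != w[1]:
            survivors.append((haplo, ibd, fid))
    n_removed = len(zygotes) - len(survivors)
    queen.misc["n_hom_brood"] = int(queen.misc.get("n_hom_brood", 0)) + n_removed
    return survivors, n_removed
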