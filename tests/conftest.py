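import copy

import numpy as np
import pytest

import hivesim as hs


@pytest.fixture(scope="session")
def founders16():
    """Session-wide founder genomes: 16 carnica, 3 chromosomes, 100 sites each.

    16 founders give 32 haplotypes, enough to represent all 32 default csd
    alleles. Individual tests deep-copy before mutating (csd editing)."""
    return hs.simulate_founder_genomes(
        n_car=16, n_chr=3, n_seg_sites=100, bp_per_chr=500_000, seed=42
    )


@pytest.fixture(scope="session")
def founders_tiny():
    """Very small genome for high-repetition fuzzing."""
    return hs.simulate_founder_genomes(
        n_car=6, n_chr=2, n_seg_sites=30, bp_per_chr=200_000, seed=3
    )


@pytest.fixture
def make_sim(founders16):
    """Factory: fresh (SimParamBee, FounderGenomes) on a private founder copy."""

    def _make(seed=1, founders=None, **opts):
        f = copy.deepcopy(founders if founders is not None else founders16)
        sp = hs.SimParamBee(f, seed=seed, **opts)
        return sp, f

    return _make


@pytest.fixture
def make_crossed_colony(make_sim):
    """Factory: a colony whose queen mated to drones with disjoint csd alleles.

    The queen descends from founder 0 and the fathers from founder 1; with the
    round-robin csd editing their allele sets are disjoint, so the queen's
    brood suffers no csd losses.
    """

    def _make(seed=1, n_fathers=15, founders=None, **opts):
        sp, f = make_sim(seed=seed, founders=founders, **opts)
        vqs = hs.create_virgin_queens(f, min(4, f.n_ind), sp=sp)
        col = hs.create_colony(vqs[0], sp=sp)
        drones = hs.create_drones(vqs[1], max(40, 2 * n_fathers), sp=sp)
        group = drones.sample(n_fathers, sp.rng, remove=True)
        hs.cross(col, drones=group, sp=sp)
        return sp, f, col, vqs

    return _make
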