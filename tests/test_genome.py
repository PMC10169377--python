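"""Founder simulation, haplotype import, csd editing, and meiosis."""

import copy

import numpy as np
import pytest

import hivesim as hs
from hivesim.genome import GenomeSpec, edit_csd_alleles, meiosis


def _diploid_spec(n_sites=50, bp=1_000_000, rate=1e-6):
    """Single-chromosome spec with evenly spaced sites; bp*rate Morgans."""
    pos = np.linspace(1, bp - 1, n_sites).astype(np.int64)
    return GenomeSpec(bp_length=[bp], recomb_rate=rate, loci_pos=[pos])


class TestFounderSimulation:
    def test_dimensions(self, founders16):
        assert founders16.haplo.shape == (32, 300)
        assert list(founders16.spec.n_sites_per_chr) == [100, 100, 100]
        assert founders16.n_ind == 16

    def test_all_sites_segregating(self, founders16):
        assert founders16.haplo.min(axis=0).max() == 0
        assert founders16.haplo.max(axis=0).min() == 1

    def test_positions_strictly_increasing(self, founders16):
        for pos in founders16.spec.loci_pos:
            assert np.all(np.diff(pos) > 0)

    def test_map_positions_from_rate(self, founders16):
        spec = founders16.spec
        # founders16 predates csd placement, so map = bp * rate everywhere
        for c in range(spec.n_chr):
            assert np.allclose(spec.map_pos[c], spec.loci_pos[c] * spec.recomb_rate)

    def test_single_founder_haplotypes_differ(self):
        f = hs.simulate_founder_genomes(n_car=1, n_chr=1, n_seg_sites=20, bp_per_chr=200_000, seed=5)
        assert (f.haplo[0] != f.haplo[1]).any()

    def test_no_founders_rejected(self):
        with pytest.raises(hs.ConfigError):
            hs.simulate_founder_genomes(n_car=0, n_lig=0, n_mel=0)

    def test_between_subspecies_distance_exceeds_within(self):
        """Across replicates, mean allele-sharing distance between subspecies
        is at least the mean distance within a subspecies."""
        within, between = [], []
        for rep in range(20):
            f = hs.simulate_founder_genomes(
                n_car=4, n_lig=4, n_chr=1, n_seg_sites=40, bp_per_chr=200_000, seed=1000 + rep
            )
            car = f.haplo[:8].astype(int)  # 4 carnica diploids first
            lig = f.haplo[8:].astype(int)
            d_within = [
                np.abs(g[i] - g[j]).mean()
                for g in (car, lig)
                for i in range(8)
                for j in range(i + 1, 8)
            ]
            d_between = [np.abs(car[i] - lig[j]).mean() for i in range(8) for j in range(8)]
            within.append(np.mean(d_within))
            between.append(np.mean(d_between))
        assert np.mean(between) >= np.mean(within)


class TestImportHaplotypes:
    def test_pairing_into_diploids(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(4, 10)).astype(np.uint8)
        H[0] = 0
        H[1] = 1  # keep all sites segregating
        f = hs.import_haplotypes(H, positions=[np.arange(1, 11) * 100])
        assert f.n_ind == 2
        assert f.haplo.shape == (4, 10)

    def test_haploid_drone_duplication(self):
        rng = np.random.default_rng(1)
        H = rng.integers(0, 2, size=(3, 8)).astype(np.uint8)
        H[0] = 0
        H[1] = 1
        f = hs.import_haplotypes(H, positions=[np.arange(1, 9) * 50], haploid_drones=True)
        assert f.n_ind == 3
        for i in range(3):
            pair = f.individual_haplo(i)
            assert (pair[0] == pair[1]).all()  # fully homozygous
            assert (pair[0] == H[i][_segregating_mask(H)]).all()

    def test_monomorphic_sites_dropped(self):
        H = np.array([[0, 1, 1], [1, 1, 0], [0, 1, 1], [1, 1, 0]], dtype=np.uint8)
        f = hs.import_haplotypes(H, positions=[np.array([10, 20, 30])])
        assert f.spec.total_sites == 2
        assert list(f.spec.loci_pos[0]) == [10, 30]

    def test_odd_haplotype_count_rejected(self):
        H = np.zeros((3, 4), dtype=np.uint8)
        H[0] = 1
        with pytest.raises(hs.FormatError):
            hs.import_haplotypes(H, positions=[np.arange(1, 5)])

    def test_vcf_round_trip(self, founders_tiny, tmp_path):
        from hivesim.io import write_phased_vcf

        path = tmp_path / "founders.vcf"
        write_phased_vcf(
            founders_tiny.haplo,
            founders_tiny.spec,
            [f"F{i}" for i in range(founders_tiny.n_ind)],
            path,
        )
        f2 = hs.import_haplotypes(path)
        assert (f2.haplo == founders_tiny.haplo).all()
        for c in range(founders_tiny.spec.n_chr):
            assert (f2.spec.loci_pos[c] == founders_tiny.spec.loci_pos[c]).all()


def _segregating_mask(H):
    return (H.min(axis=0) == 0) & (H.max(axis=0) == 1)


class TestEditCsdAlleles:
    def test_balanced_allele_frequencies(self, founders16, make_sim):
        sp, f = make_sim(n_csd_alleles=4)
        words = {tuple(row) for row in f.haplo[:, f.spec.csd_cols()]}
        assert len(words) == 4
        # 32 haplotypes over 4 alleles -> each frequency exactly 8
        cols = f.spec.csd_cols()
        counts = {}
        for row in f.haplo[:, cols]:
            counts[tuple(row)] = counts.get(tuple(row), 0) + 1
        assert set(counts.values()) == {8}

    def test_every_founder_heterozygous(self, make_sim):
        sp, f = make_sim(n_csd_alleles=32)
        cols = f.spec.csd_cols()
        for i in range(f.n_ind):
            pair = f.individual_haplo(i)[:, cols]
            assert (pair[0] != pair[1]).any()

    def test_two_alleles_single_heterozygote(self, make_sim):
        sp, f = make_sim(n_csd_alleles=2)
        cols = f.spec.csd_cols()
        for i in range(f.n_ind):
            pair = f.individual_haplo(i)[:, cols]
            assert {int(pair[0][0]), int(pair[1][0])} == {0, 1}

    def test_warning_when_alleles_exceed_haplotypes(self, founders_tiny):
        f = copy.deepcopy(founders_tiny)  # 12 haplotypes
        with pytest.warns(UserWarning, match="csd alleles"):
            hs.SimParamBee(f, n_csd_alleles=16, seed=0)
        words = {tuple(row) for row in f.haplo[:, f.spec.csd_cols()]}
        assert len(words) == 12

    def test_too_few_alleles_rejected(self, founders_tiny):
        f = copy.deepcopy(founders_tiny)
        f.spec.set_csd_window(0, 0, 2)
        with pytest.raises(hs.ConfigError):
            edit_csd_alleles(f, 1)


class TestMeiosis:
    def test_crossover_count_matches_map_length(self):
        spec = _diploid_spec(bp=1_000_000, rate=1e-6)  # 1 Morgan
        rng = np.random.default_rng(11)
        parent = rng.integers(0, 2, size=(2, 50)).astype(np.uint8)
        ibd = np.array([np.zeros(50), np.ones(50)], dtype=np.int32)
        n = 10_000
        xo = np.array([meiosis(parent, ibd, spec, rng).n_crossovers for _ in range(n)])
        se = np.sqrt(1.0 / n)  # Poisson(1) variance
        assert abs(xo.mean() - 1.0) < 3 * se

    def test_zero_length_chromosome_copies_one_haplotype(self):
        spec = _diploid_spec(rate=0.0)
        rng = np.random.default_rng(2)
        parent = np.array([np.zeros(50), np.ones(50)], dtype=np.uint8)
        ibd = np.array([np.zeros(50), np.ones(50)], dtype=np.int32)
        seen = set()
        for _ in range(50):
            g = meiosis(parent, ibd, spec, rng)
            assert g.alleles.min() == g.alleles.max()  # all-0 or all-1 row
            seen.add(int(g.alleles[0]))
        assert seen == {0, 1}  # both haplotypes transmitted at p=1/2

    def test_allele_and_ibd_consistency(self):
        """The gamete is a mosaic of the two parental rows: at every site the
        allele equals the row named by the IBD label."""
        spec = _diploid_spec()
        rng = np.random.default_rng(3)
        parent = rng.integers(0, 2, size=(2, 50)).astype(np.uint8)
        ibd = np.array([np.full(50, 8), np.full(50, 9)], dtype=np.int32)
        for _ in range(200):
            g = meiosis(parent, ibd, spec, rng)
            rows = g.ibd - 8
            assert set(np.unique(rows)) <= {0, 1}
            assert (g.alleles == parent[rows, np.arange(50)]).all()

    def test_csd_window_never_recombines(self, make_sim):
        """Over many gametes the transmitted csd word is always one of the
        parent's two words, never a recombinant."""
        sp, f = make_sim(n_csd_alleles=32)
        parent = f.individual_haplo(0)
        ibd = f.ibd_labels(0)
        cols = sp.spec.csd_cols()
        w0, w1 = tuple(parent[0, cols]), tuple(parent[1, cols])
        rng = np.random.default_rng(4)
        seen = set()
        for _ in range(10_000):
            g = meiosis(parent, ibd, sp.spec, rng)
            word = tuple(g.alleles[cols])
            assert word in (w0, w1)
            seen.add(word)
        assert seen == {w0, w1}

    def test_haploid_input_rejected(self):
        spec = _diploid_spec()
        with pytest.raises(hs.ConfigError):
            meiosis(np.zeros((1, 50)), np.zeros((1, 50)), spec, np.random.default_rng(0))


class TestDroneGamete:
    def test_clonal_copy(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        drone = hs.create_drones(vq, 1, sp=sp)[0]
        g1 = hs.drone_gamete(drone)
        g2 = hs.drone_gamete(drone)
        assert (g1.alleles == drone.haplo[0]).all()
        assert (g1.ibd == drone.ibd[0]).all()
        assert (g1.alleles == g2.alleles).all()

    def test_diploid_input_rejected(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        with pytest.raises(hs.ConfigError):
            hs.drone_gamete(vq)
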