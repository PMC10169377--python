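"""DCAs, mating stations, cross plans, and the mating operation."""

import numpy as np
import pytest

import hivesim as hs


@pytest.fixture
def colonies3(make_sim):
    """Three crossed colonies with disjoint-allele queens, plus leftovers."""
    sp, f = make_sim(seed=23)
    vqs = hs.create_virgin_queens(f, 10, sp=sp)
    cols = []
    for i in range(3):
        col = hs.create_colony(vqs[i], sp=sp)
        drones = hs.create_drones(vqs[3 + i], 40, sp=sp)
        hs.cross(col, drones=drones.sample(10, sp.rng, remove=True), sp=sp)
        cols.append(col)
    return sp, f, cols, vqs


class TestCreateDCA:
    def test_pooled_counts_and_pedigree(self, colonies3):
        sp, _, cols, _ = colonies3
        dca = hs.create_dca(cols, n_per_source=100, sp=sp)
        assert len(dca) == 300
        queen_ids = {c.queen.id for c in cols}
        assert all(d.mother_id in queen_ids for d in dca)

    def test_single_population_source(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        drones = hs.create_drones(vq, 25, sp=sp)
        dca = hs.create_dca(drones, sp=sp)
        assert dca.ids == drones.ids

    def test_empty_sources_rejected(self, make_sim):
        sp, _ = make_sim()
        with pytest.raises(hs.ConfigError):
            hs.create_dca([], sp=sp)


class TestMatingStation:
    def test_counts_and_two_step_pedigree(self, colonies3):
        sp, _, cols, _ = colonies3
        sire = cols[0]
        dca = hs.create_mating_station_dca(sire, n_dpq=10, n_drones_per_dpq=50, sp=sp)
        assert len(dca) == 500
        # every drone's mother's mother is the sire colony's queen
        for d in list(dca)[::37]:
            dpq_mother, _ = sp.pedigree[d.mother_id]
            assert dpq_mother == sire.queen.id

    def test_zero_dpq_rejected(self, colonies3):
        sp, _, cols, _ = colonies3
        with pytest.raises(hs.ConfigError):
            hs.create_mating_station_dca(cols[0], n_dpq=0, n_drones_per_dpq=10, sp=sp)

    def test_queenless_sire_rejected(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        col = hs.create_colony(vq, sp=sp)
        with pytest.raises(hs.StateError):
            hs.create_mating_station_dca(col, n_dpq=5, n_drones_per_dpq=10, sp=sp)


class TestPullDroneGroups:
    def test_disjoint_groups_removed_from_dca(self, colonies3):
        sp, _, cols, _ = colonies3
        dca = hs.create_dca(cols, n_per_source=334, sp=sp)
        n0 = len(dca)
        groups = hs.pull_drone_groups_from_dca(dca, 3, 15, sp=sp)
        assert [len(g) for g in groups] == [15, 15, 15]
        assert len(dca) == n0 - 45
        ids = [set(g.ids) for g in groups]
        assert ids[0].isdisjoint(ids[1]) and ids[0].isdisjoint(ids[2]) and ids[1].isdisjoint(ids[2])

    def test_sampler_group_sizes(self, colonies3):
        sp, _, cols, _ = colonies3
        dca = hs.create_dca(cols, n_per_source=1200, sp=sp)
        sampler = hs.make_count_sampler("truncPoisson", mean=15)
        groups = hs.pull_drone_groups_from_dca(dca, 60, sampler, sp=sp)
        sizes = np.array([len(g) for g in groups])
        assert sizes.min() >= 1
        se = np.sqrt(15 / 60)
        assert abs(sizes.mean() - 15) < 3 * se

    def test_polyandry_range_quantile(self, colonies3):
        """With the default polyandry sampler calibrated to the biological
        6-24 mating range, the bulk of group sizes falls inside it."""
        sp, _, cols, _ = colonies3
        sampler = hs.make_count_sampler("truncPoisson", mean=15)
        rng = np.random.default_rng(8)
        sizes = np.array([sampler(rng) for _ in range(500)])
        assert (np.mean((sizes >= 6) & (sizes <= 24))) > 0.9

    def test_exhausted_dca_rejected(self, colonies3):
        sp, _, cols, _ = colonies3
        dca = hs.create_dca(cols, n_per_source=10, sp=sp)
        with pytest.raises(hs.ConfigError):
            hs.pull_drone_groups_from_dca(dca, 3, 15, sp=sp)


class TestCrossPlan:
    def test_random_plan_disjoint(self, colonies3):
        sp, _, cols, vqs = colonies3
        dca = hs.create_dca(cols, n_per_source=40, sp=sp)
        plan = hs.create_random_cross_plan([vqs[6].id, vqs[7].id], dca, 15, sp=sp)
        all_ids = [d for ds in plan.values() for d in ds]
        assert len(all_ids) == 30 and len(set(all_ids)) == 30

    def test_plan_can_use_whole_dca(self, colonies3):
        sp, _, cols, vqs = colonies3
        dca = hs.create_dca(cols, n_per_source=10, sp=sp)
        plan = hs.create_random_cross_plan([vqs[6].id], dca, len(dca), sp=sp)
        assert sorted(plan[vqs[6].id]) == sorted(dca.ids)

    def test_insufficient_drones_rejected(self, colonies3):
        sp, _, cols, vqs = colonies3
        dca = hs.create_dca(cols, n_per_source=5, sp=sp)
        with pytest.raises(hs.ConfigError):
            hs.create_random_cross_plan([vqs[6].id, vqs[7].id], dca, 15, sp=sp)

    def test_csv_round_trip(self, colonies3, tmp_path):
        sp, _, cols, vqs = colonies3
        dca = hs.create_dca(cols, n_per_source=20, sp=sp)
        plan = hs.create_random_cross_plan([vqs[6].id], dca, 10, sp=sp)
        path = tmp_path / "plan.csv"
        plan.to_csv(path)
        plan2 = hs.CrossPlan.from_csv(path)
        assert plan2 == plan


class TestCross:
    def test_worked_example_semantics(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony(n_fathers=15)
        assert col.n_fathers == 15
        assert col.n_virgin_queens == 0
        assert col.queen.caste == "queen"
        assert all(not f.alive for f in col.queen.fathers)  # mated and died

    def test_double_cross_rejected(self, make_crossed_colony):
        sp, f, col, vqs = make_crossed_colony()
        drones = hs.create_drones(vqs[2], 20, sp=sp)
        with pytest.raises(hs.StateError):
            hs.cross(col, drones=drones, sp=sp)

    def test_mated_drone_reuse_rejected(self, make_sim):
        sp, f = make_sim()
        vqs = hs.create_virgin_queens(f, 3, sp=sp)
        drones = hs.create_drones(vqs[2], 10, sp=sp)
        hs.cross(vqs[0], drones=drones, sp=sp)
        with pytest.raises(hs.StateError):
            hs.cross(vqs[1], drones=drones, sp=sp)

    def test_empty_drone_group_rejected(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        with pytest.raises(hs.ConfigError):
            hs.cross(vq, drones=hs.Population(), sp=sp)

    def test_spermatheca_immutable_after_cross(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony(n_fathers=5)
        stored = list(col.queen.fathers.ids)
        hs.create_workers(col, 20, sp=sp)
        assert col.queen.fathers.ids == stored

    def test_batch_cross_with_plan_and_shared_dca(self, make_sim):
        sp, f = make_sim(seed=29)
        vqs = hs.create_virgin_queens(f, 8, sp=sp)
        apiary = hs.create_multi_colony(vqs[:3], sp=sp)
        dca = hs.create_dca([hs.create_drones(vq, 40, sp=sp) for vq in vqs[3:]], sp=sp)
        queen_ids = [c.virgin_queens[0].id for c in apiary]
        plan = hs.create_random_cross_plan(queen_ids, dca, 12, sp=sp)
        n0 = len(dca)
        apiary.cross(cross_plan=plan, dca=dca)
        assert all(c.is_queen_present() for c in apiary)
        assert all(c.n_fathers == 12 for c in apiary)
        assert len(dca) == n0 - 36  # mated drones removed from the pool

    def test_drone_single_use_across_trace(self, make_sim):
        """No drone id ever appears in two spermathecae."""
        sp, f = make_sim(seed=37)
        vqs = hs.create_virgin_queens(f, 8, sp=sp)
        dca = hs.create_dca([hs.create_drones(vq, 30, sp=sp) for vq in vqs[4:]], sp=sp)
        queens = []
        for vq in vqs[:4]:
            grp = dca.sample(10, sp.rng, remove=True)
            queens.append(hs.cross(vq, drones=grp, sp=sp))
        seen = set()
        for q in queens:
            ids = set(q.fathers.ids)
            assert ids.isdisjoint(seen)
            seen |= ids
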