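"""Colony container, caste access/mutation, and all colony events."""

import numpy as np
import pytest

import hivesim as hs


@pytest.fixture
def built_colony(make_crossed_colony):
    """Crossed colony built up to 20 workers / 4 drones (demo scale)."""
    sp, f, col, vqs = make_crossed_colony()
    col.build_up(n_workers=20, n_drones=4)
    return sp, f, col, vqs


class TestCreateColony:
    def test_from_virgin_queen(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        col = hs.create_colony(vq, sp=sp)
        assert col.queen is None
        assert col.location is None
        assert col.n_virgin_queens == 1
        assert col.n_workers == col.n_drones == col.n_fathers == 0
        assert not (col.swarmed or col.split or col.collapsed or col.productive)
        text = repr(col)
        assert "Location: NA" in text and "Queen: NA" in text

    def test_from_mated_queen(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony()
        col2 = hs.create_colony(col.queen, sp=sp)
        assert col2.queen is col.queen
        assert col2.n_fathers == 15

    def test_worker_rejected(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony()
        workers, _ = hs.create_workers(col, 1, sp=sp)
        with pytest.raises(hs.ConfigError):
            hs.create_colony(workers[0], sp=sp)


class TestCountAndAccess:
    def test_counts(self, built_colony):
        sp, _, col, _ = built_colony
        assert col.count_caste("worker") == 20
        assert col.count_caste("drone") == 4
        assert col.count_caste("father") == 15
        assert col.count_caste("virginQueen") == 0
        with pytest.raises(hs.ConfigError):
            col.count_caste("larva")

    def test_get_leaves_colony_unchanged(self, built_colony):
        sp, _, col, _ = built_colony
        a = col.get_caste_pop("worker")
        b = col.get_caste_pop("worker")
        assert a.ids == b.ids
        assert col.n_workers == 20

    def test_pull_removes(self, built_colony):
        sp, _, col, _ = built_colony
        pulled = col.pull_caste_pop("worker", 5)
        assert len(pulled) == 5
        assert col.n_workers == 15
        assert set(pulled.ids).isdisjoint(col.workers.ids)

    def test_pull_too_many_rejected(self, built_colony):
        sp, _, col, _ = built_colony
        with pytest.raises(hs.ConfigError):
            col.pull_caste_pop("virginQueen", 1)

    def test_add_remove_replace(self, built_colony):
        sp, _, col, _ = built_colony
        extra, _ = hs.create_workers(col, 10, sp=sp)
        col.add_caste_pop("worker", extra)
        assert col.n_workers == 30
        col.remove_caste_pop("drone")
        assert col.n_drones == 0
        old_ids = set(col.workers.ids)
        col.replace_caste_pop("worker", 8)
        assert col.n_workers == 8
        assert set(col.workers.ids).isdisjoint(old_ids)  # all fresh ids


class TestBuildUp:
    def test_topup_semantics_and_production(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony()
        col.build_up(n_workers=20, n_drones=4)
        assert (col.n_workers, col.n_drones) == (20, 4)
        assert col.productive
        ids_before = set(col.workers.ids)
        col.build_up(n_workers=20, n_drones=4)  # idempotent under top-up
        assert set(col.workers.ids) == ids_before

    def test_requires_mated_queen(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        col = hs.create_colony(vq, sp=sp)
        with pytest.raises(hs.StateError):
            col.build_up()


class TestSwarm:
    def test_partition_counts_and_flags(self, built_colony):
        sp, _, col, _ = built_colony
        before = set(col.workers.ids)
        queen_id = col.queen.id
        colony_id = col.id
        swarm_col, remnant = col.swarm(0.4)
        assert swarm_col.n_workers == 8  # round(0.4 * 20)
        assert remnant.n_workers == 12
        assert swarm_col.n_drones == 0 and remnant.n_drones == 4
        # conservation: disjoint union of worker ids equals the originals
        assert set(swarm_col.workers.ids) | set(remnant.workers.ids) == before
        assert set(swarm_col.workers.ids).isdisjoint(remnant.workers.ids)
        assert swarm_col.queen.id == queen_id
        assert swarm_col.id == colony_id and remnant.id != colony_id
        assert swarm_col.swarmed and remnant.swarmed
        assert not swarm_col.productive and not remnant.productive

    def test_remnant_virgin_queens_are_daughters(self, built_colony):
        sp, _, col, _ = built_colony
        queen_id = col.queen.id
        _, remnant = col.swarm(0.5)
        assert remnant.n_virgin_queens == 10  # SimParamBee default
        assert all(vq.mother_id == queen_id for vq in remnant.virgin_queens)

    def test_invalid_proportion(self, built_colony):
        sp, _, col, _ = built_colony
        with pytest.raises(hs.ConfigError):
            col.swarm(1.5)


class TestSplit:
    def test_partition_and_productivity(self, built_colony):
        sp, _, col, _ = built_colony
        queen_id, colony_id = col.queen.id, col.id
        before = set(col.workers.ids)
        split_col, remnant = hs.split(col, 0.3)
        assert split_col.n_workers == 6 and remnant.n_workers == 14
        assert set(split_col.workers.ids) | set(remnant.workers.ids) == before
        assert remnant.queen.id == queen_id
        assert remnant.id == colony_id  # identity follows the queen
        assert remnant.productive and not split_col.productive
        assert split_col.split and remnant.split
        assert split_col.n_virgin_queens > 0
        assert remnant.n_drones == 4


class TestSupersede:
    def test_queen_replaced_by_daughters(self, built_colony):
        sp, _, col, _ = built_colony
        queen_id = col.queen.id
        was_productive = col.productive
        col.supersede()
        assert col.queen is None
        assert col.n_virgin_queens > 0
        assert all(vq.mother_id == queen_id for vq in col.virgin_queens)
        assert col.productive == was_productive
        assert col.superseded

    def test_queenless_rejected(self, make_sim):
        sp, f = make_sim()
        vq = hs.create_virgin_queens(f, 1, sp=sp)[0]
        col = hs.create_colony(vq, sp=sp)
        with pytest.raises(hs.StateError):
            col.supersede()


class TestCollapse:
    def test_members_kept_but_frozen(self, built_colony):
        sp, _, col, _ = built_colony
        col.collapse()
        assert col.collapsed and not col.productive
        assert col.n_workers == 20 and col.n_drones == 4  # still countable
        with pytest.raises(hs.StateError):
            col.build_up()
        with pytest.raises(hs.StateError):
            col.collapse()  # double collapse


class TestDownsize:
    def test_default_and_explicit_proportion(self, built_colony):
        sp, _, col, _ = built_colony
        col.downsize(0.85)
        assert col.n_workers == 3  # 20 - round(0.85 * 20)
        assert col.n_drones == 0 and col.n_virgin_queens == 0
        assert not col.productive
        assert col.queen is not None


class TestCombine:
    def test_strong_absorbs_weak(self, make_crossed_colony):
        sp, f, strong, vqs = make_crossed_colony(seed=5)
        strong.build_up(n_workers=20, n_drones=4)
        weak = hs.create_colony(vqs[2], sp=sp)
        drones = hs.create_drones(vqs[3], 30, sp=sp)
        hs.cross(weak, drones=drones.sample(5, sp.rng, remove=True), sp=sp)
        weak.build_up(n_workers=10, n_drones=2)
        strong_queen = strong.queen.id
        combined = hs.combine(strong, weak)
        assert combined is strong
        assert combined.n_workers == 30 and combined.n_drones == 6
        assert combined.queen.id == strong_queen
        assert len(set(combined.workers.ids)) == 30  # no duplicated ids

    def test_collapsed_rejected(self, built_colony):
        sp, _, col, _ = built_colony
        other = hs.Colony(sp)
        other.collapse()
        with pytest.raises(hs.StateError):
            col.combine(other)


class TestReQueen:
    def test_mated_queen_installed(self, built_colony, make_crossed_colony):
        sp, _, col, _ = built_colony
        col.supersede()
        donor_sp, _, donor, _ = make_crossed_colony(seed=9)
        new_queen = donor.queen
        donor.queen = None
        col.re_queen(new_queen)
        assert col.queen is new_queen
        assert col.n_fathers == 15
        assert col.n_virgin_queens == 0  # cleared on mated installation

    def test_virgin_queen_leaves_colony_queenless(self, built_colony, make_sim):
        sp, _, col, _ = built_colony
        sp2, f2 = make_sim(seed=31)
        vq = hs.create_virgin_queens(f2, 1, sp=sp2)[0]
        col.re_queen(vq)
        assert col.queen is None
        assert col.n_virgin_queens == 1

    def test_worker_rejected(self, built_colony):
        sp, _, col, _ = built_colony
        with pytest.raises(hs.ConfigError):
            col.re_queen(col.workers[0])


class TestStatus:
    def test_presence_flags(self, make_crossed_colony):
        sp, _, col, _ = make_crossed_colony()
        assert col.is_queen_present()
        assert not col.is_virgin_queens_present()  # cleared at cross
        assert col.is_fathers_present()
        assert not col.is_productive()
        col.build_up(n_workers=10, n_drones=2)
        assert col.is_productive()
        assert col.is_workers_present() and col.is_drones_present()
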