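"""Parental selection: truncation, scoping, oracle, chimeric scoping.

Each greedy selector is checked against a literal, independent brute-force
re-execution of its rule on small instances.
"""

import numpy as np
import pytest

from breedsim.selection import (
    chimeric_scoping_select,
    f_score,
    oracle_parent_select,
    scoping_select,
    truncation_select,
)

from conftest import make_population, make_qtl_model


def pop_variance(col):
    col = np.asarray(col, dtype=float)
    return ((col - col.mean()) ** 2).mean()


def brute_force_scoping(dosages, ids, gebvs, SR, n_parents, n_scoping_couples=None):
    """Literal re-execution of the scoping rule: GEBV preselection, then
    sequential P1 (GEBV or F-score) / P2 (F-score) picks with p updated from
    the alleles present among selected parents."""
    n = len(ids)
    if n_scoping_couples is None:
        n_scoping_couples = n_parents // 2
    n_pre = int(np.ceil(SR * n))
    pre = sorted(range(n), key=lambda i: (-gebvs[i], ids[i]))[:n_pre]
    available = list(pre)
    selected = []
    p = np.ones(dosages.shape[1])

    def update_p():
        nonlocal p
        rows = dosages[selected]
        for j in range(dosages.shape[1]):
            if (rows[:, j] > -1).any() and (rows[:, j] < 1).any():
                p[j] = 0
        if not p.any():
            p = np.ones(dosages.shape[1])

    def pick_by_f():
        scored = []
        for i in available:
            rows = dosages[selected + [i]]
            F = sum(pop_variance(rows[:, j]) * p[j] for j in range(rows.shape[1]))
            scored.append((-F, ids[i], i))
        return min(scored)[2]

    couples = []
    for c in range(n_parents // 2):
        if c < n_scoping_couples:
            p1 = min(available, key=lambda i: (-gebvs[i], ids[i]))
        else:
            p1 = pick_by_f()
        selected.append(p1)
        available.remove(p1)
        update_p()
        p2 = pick_by_f()
        selected.append(p2)
        available.remove(p2)
        update_p()
        couples.append((str(ids[p1]), str(ids[p2])))
    return couples


def brute_force_oracle(presence, ids, n_parents):
    """Literal re-execution of the greedy favorable-allele coverage rule,
    counting only alleles that exist somewhere in the population."""
    n, L = presence.shape
    reachable = presence.any(axis=0)
    covered = np.zeros(L, dtype=bool)
    remaining = list(range(n))
    out = []
    for _ in range(n_parents):
        uncov = [k for k in range(L) if reachable[k] and not covered[k]]
        scored = []
        for i in remaining:
            if uncov:
                s = sum(presence[i, k] for k in uncov)
            else:
                s = presence[i].sum()
            scored.append((-s, ids[i], i))
        best = min(scored)[2]
        out.append(best)
        remaining.remove(best)
        covered |= presence[best]
    return out


class TestTruncation:
    def test_selects_top_block(self, rng):
        gebvs = np.arange(1.0, 201.0)
        ids = np.array([f"i{j:03d}" for j in range(200)], dtype=object)
        plan = truncation_select(gebvs, ids, 100, rng)
        assert sorted(plan.parents) == [f"i{j:03d}" for j in range(100, 200)]
        assert len(plan.couples) == 50

    def test_all_ties_resolve_by_id(self, rng):
        ids = np.array([f"i{j}" for j in range(6)], dtype=object)
        plan = truncation_select(np.zeros(6), ids, 4, rng)
        assert sorted(plan.parents) == ["i0", "i1", "i2", "i3"]

    def test_pairing_is_seed_deterministic(self):
        gebvs = np.arange(8.0)
        ids = np.array(list("abcdefgh"), dtype=object)
        p1 = truncation_select(gebvs, ids, 6, np.random.default_rng(5))
        p2 = truncation_select(gebvs, ids, 6, np.random.default_rng(5))
        assert p1.couples == p2.couples

    def test_odd_parent_count_rejected(self, rng):
        with pytest.raises(ValueError):
            truncation_select(np.arange(10.0), np.arange(10).astype(object), 5, rng)


class TestFScore:
    def test_identical_rows_score_zero(self):
        rows = np.array([[1, 1, -1], [1, 1, -1]])
        assert f_score(rows, np.ones(3)) == 0.0

    def test_opposite_homozygotes_score_two(self):
        rows = np.array([[1, 1], [-1, -1]])
        assert f_score(rows, np.ones(2)) == pytest.approx(2.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            f_score(np.array([[1, 1]]), np.ones(2))


class TestScoping:
    def test_identical_candidates_follow_gebv_order(self, rng):
        pop = make_population(np.tile([1, -1, 1], (6, 1)))
        gebvs = np.array([3.0, 6.0, 1.0, 5.0, 2.0, 4.0])
        plan = scoping_select(pop, gebvs, 1.0, 4, rng)
        # P1 of couple 1 = highest GEBV; all F ties resolve by id
        assert plan.couples[0][0] == "i01"
        assert plan.couples[1][0] == "i03"

    def test_complementary_line_chosen_over_elite_duplicate(self, rng):
        """With two identical elites and one complementary line, the F-score
        partner is the complementary line, as exhaustive search confirms."""
        dosages = np.array(
            [
                [1, 1, 1],   # elite P1
                [1, 1, 1],   # identical elite
                [-1, -1, -1],  # complementary
                [1, -1, 1],
            ]
        )
        pop = make_population(dosages)
        gebvs = np.array([4.0, 3.9, 0.5, 2.0])
        plan = scoping_select(pop, gebvs, 1.0, 2, rng)
        assert plan.couples[0] == ("i00", "i02")

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(15):
            rng = np.random.default_rng(300 + seed)
            n = int(rng.integers(6, 11))
            k = int(rng.integers(3, 7))
            dosages = rng.choice([-1, 1], size=(n, k))
            gebvs = rng.normal(size=n)
            ids = np.array([f"i{j:02d}" for j in range(n)], dtype=object)
            pop = make_population(dosages)
            plan = scoping_select(pop, gebvs, 1.0, 4, np.random.default_rng(0))
            expected = brute_force_scoping(dosages, ids, gebvs, 1.0, 4)
            assert plan.couples == expected

    def test_preselection_rate(self, rng):
        """SR = 0.3 on 1000 individuals preselects 300; every parent comes
        from that pool."""
        dosages = rng.choice([-1, 1], size=(1000, 10))
        pop = make_population(
            dosages, ids=np.array([f"i{j:04d}" for j in range(1000)], dtype=object)
        )
        gebvs = rng.normal(size=1000)
        plan = scoping_select(pop, gebvs, 0.3, 20, rng)
        top300 = set(
            str(pop.ids[i])
            for i in sorted(range(1000), key=lambda i: (-gebvs[i], pop.ids[i]))[:300]
        )
        assert set(plan.parents) <= top300

    def test_too_small_preselection_rejected(self, rng):
        pop = make_population(rng.choice([-1, 1], size=(10, 4)))
        with pytest.raises(ValueError):
            scoping_select(pop, np.arange(10.0), 0.2, 6, rng)


class TestOracleParentSelection:
    def test_first_parent_maximizes_total_favorable_count(self, rng):
        dosages = np.array([[1, 1, -1, -1], [1, 1, 1, -1], [1, 1, 1, 1], [-1, -1, -1, -1]])
        pop = make_population(dosages)
        model = make_qtl_model(4)
        plan = oracle_parent_select(pop, model, 2, rng)
        assert "i02" in plan.parents  # carries all 4 favorable alleles

    def test_rare_allele_carrier_selected_second(self, rng):
        """A low-value line uniquely carrying the favorable allele of QTL 4
        is picked second, exactly as the greedy rule replayed by hand."""
        dosages = np.array(
            [
                [1, 1, 1, -1],
                [1, 1, -1, -1],
                [1, -1, 1, -1],
                [-1, 1, -1, -1],
                [-1, -1, -1, 1],  # unique carrier of favorable QTL-4 allele
            ]
        )
        pop = make_population(dosages)
        model = make_qtl_model(4)
        plan = oracle_parent_select(pop, model, 4, rng)
        order = brute_force_oracle(dosages > -1, pop.ids, 4)
        assert plan.parents and set(plan.parents) == {str(pop.ids[i]) for i in order}
        assert str(pop.ids[order[1]]) == "i04"

    def test_everything_fixed_favorable_falls_back_to_id_order(self, rng):
        pop = make_population(np.ones((5, 3), dtype=int))
        model = make_qtl_model(3)
        plan = oracle_parent_select(pop, model, 4, rng)
        assert sorted(plan.parents) == ["i00", "i01", "i02", "i03"]

    def test_matches_brute_force_on_random_instances(self):
        """The selected sequence equals a literal re-execution of the greedy
        coverage rule on random toys (<= 8 individuals, <= 6 QTLs)."""
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            n = int(rng.integers(4, 9))
            L = int(rng.integers(2, 7))
            dosages = rng.choice([-1, 0, 1], size=(n, L))
            fav = rng.integers(0, 2, size=L).astype(np.int8)
            pop = make_population(dosages)
            model = make_qtl_model(L, favorable=fav)
            n_parents = 2 * int(rng.integers(1, n // 2 + 1))
            plan = oracle_parent_select(pop, model, n_parents, np.random.default_rng(0))
            signed = dosages * np.where(fav == 1, 1, -1)
            order = brute_force_oracle(signed > -1, pop.ids, n_parents)
            assert set(plan.parents) == {str(pop.ids[i]) for i in order}

    def test_coverage_of_reachable_favorable_alleles(self, rng):
        """Every favorable allele present in the population is carried by
        some selected parent once enough parents are taken."""
        for seed in range(10):
            r = np.random.default_rng(800 + seed)
            dosages = r.choice([-1, 0, 1], size=(8, 5))
            pop = make_population(dosages)
            model = make_qtl_model(5)
            plan = oracle_parent_select(pop, model, 8, r)
            idx = pop.index_of(plan.parents)
            present_pop = (dosages > -1).any(axis=0)
            present_parents = (dosages[idx] > -1).any(axis=0)
            assert np.array_equal(present_parents, present_pop)


class TestChimericScoping:
    def test_full_n_equals_plain_scoping(self, rng):
        dosages = np.random.default_rng(9).choice([-1, 1], size=(12, 5))
        pop = make_population(dosages)
        gebvs = np.random.default_rng(10).normal(size=12)
        a = scoping_select(pop, gebvs, 1.0, 6, np.random.default_rng(1))
        b = chimeric_scoping_select(pop, gebvs, 3, 1.0, 6, np.random.default_rng(1))
        assert a.couples == b.couples

    def test_n_zero_uses_no_gebv_parent(self, rng):
        dosages = np.random.default_rng(11).choice([-1, 1], size=(10, 4))
        pop = make_population(dosages)
        gebvs = np.random.default_rng(12).normal(size=10)
        plan = chimeric_scoping_select(pop, gebvs, 0, 1.0, 6, rng)
        assert all(tag == "f-score" for tag in plan.provenance.values())

    def test_later_couples_match_brute_force(self):
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            dosages = rng.choice([-1, 1], size=(8, 4))
            gebvs = rng.normal(size=8)
            ids = np.array([f"i{j:02d}" for j in range(8)], dtype=object)
            pop = make_population(dosages)
            plan = chimeric_scoping_select(
                pop, gebvs, 1, 1.0, 6, np.random.default_rng(0)
            )
            expected = brute_force_scoping(dosages, ids, gebvs, 1.0, 6, n_scoping_couples=1)
            assert plan.couples == expected
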