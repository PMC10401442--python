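"""Training-population updates: standard rules, PEV/CD criteria, oracle greedy."""

import numpy as np
import pytest

from breedsim.prediction import TrainingSet, _profile_reml, fit_rrblup, predict_gebv
from breedsim.tp_update import criterion_update, oracle_tp_update, standard_update

from conftest import make_population


def make_setup(rng, n_tp=8, n_pop=12, k=6, h2_noise=0.0):
    """A small TP plus a breeding population with true genetic values."""
    u = rng.normal(size=k)
    pop = make_population(rng.choice([-1, 1], size=(n_pop, k)))
    g = pop.dosages().astype(float) @ u
    Z_tp = rng.choice([-1, 1], size=(n_tp, k)).astype(float)
    y_tp = Z_tp @ u + rng.normal(0, h2_noise, n_tp)
    tp = TrainingSet(
        Z_tp, y_tp, np.zeros(n_tp, int),
        np.array([f"t{j:02d}" for j in range(n_tp)], dtype=object),
    )
    return tp, pop, g, u


def noiseless_phenotyper(g):
    return lambda idx: g[idx]


class TestStandardUpdate:
    def test_tails_takes_both_ends(self, rng):
        tp, pop, g, _ = make_setup(rng)
        gebvs = np.arange(float(pop.n_individuals))
        new_tp, report = standard_update(
            tp, pop, gebvs, "tails", 6, 0, rng, noiseless_phenotyper(g), cycle=1
        )
        added = set(report.added)
        ids = pop.ids
        assert {str(ids[i]) for i in (9, 10, 11)} <= added  # 3 highest
        assert {str(ids[i]) for i in (0, 1, 2)} <= added  # 3 lowest
        assert new_tp.n == tp.n + 6

    def test_top_takes_highest(self, rng):
        tp, pop, g, _ = make_setup(rng)
        gebvs = np.arange(float(pop.n_individuals))
        _, report = standard_update(
            tp, pop, gebvs, "top", 4, 0, rng, noiseless_phenotyper(g), cycle=1
        )
        assert set(report.added) == {str(pop.ids[i]) for i in (8, 9, 10, 11)}

    def test_noop_update_preserves_tp(self, rng):
        tp, pop, g, _ = make_setup(rng)
        new_tp, report = standard_update(
            tp, pop, np.zeros(pop.n_individuals), "top", 0, 0, rng,
            noiseless_phenotyper(g), cycle=1,
        )
        assert new_tp.n == tp.n
        assert report.added == [] and report.removed == []

    def test_oldest_dropped_first(self, rng):
        tp, pop, g, _ = make_setup(rng)
        tp.entry_cycle[:] = [0, 0, 1, 1, 2, 2, 3, 3]
        new_tp, report = standard_update(
            tp, pop, np.zeros(pop.n_individuals), "random", 2, 4, rng,
            noiseless_phenotyper(g), cycle=4,
        )
        assert set(report.removed) == {"t00", "t01", "t02", "t03"}
        assert new_tp.n == tp.n - 4 + 2

    def test_random_is_seed_reproducible(self, rng):
        tp, pop, g, _ = make_setup(rng)
        r1 = standard_update(
            tp, pop, np.zeros(12), "random", 3, 0, np.random.default_rng(4),
            noiseless_phenotyper(g), 1,
        )[1]
        r2 = standard_update(
            tp, pop, np.zeros(12), "random", 3, 0, np.random.default_rng(4),
            noiseless_phenotyper(g), 1,
        )[1]
        assert r1.added == r2.added

    def test_bookkeeping_identity(self, rng):
        tp, pop, g, _ = make_setup(rng)
        new_tp, report = standard_update(
            tp, pop, np.arange(12.0), "tails", 4, 2, rng, noiseless_phenotyper(g), 1
        )
        assert report.tp_size_after == tp.n - len(report.removed) + len(report.added)
        assert report.tp_size_after == new_tp.n

    def test_oversized_request_rejected(self, rng):
        tp, pop, g, _ = make_setup(rng)
        with pytest.raises(ValueError):
            standard_update(
                tp, pop, np.zeros(12), "top", 20, 0, rng, noiseless_phenotyper(g), 1
            )


class TestCriterionUpdate:
    def brute_force_single_pick(self, tp, pop, model, method):
        """Exhaustive 1-step search with densely inverted MME per candidate."""
        pop_Z = pop.dosages().astype(float)
        n_pop, k = pop_Z.shape
        best = None
        for i in range(n_pop):
            Z = np.vstack([tp.Z, pop_Z[i]])
            targets = [j for j in range(n_pop) if j != i]
            Zc = Z - Z.mean(axis=0)
            Cuu = np.linalg.inv(Zc.T @ Zc + model.lam * np.eye(k))
            contrasts = pop_Z[targets] - Z.mean(axis=0)
            pev = model.sigma_e2 * np.einsum("ij,jk,ik->i", contrasts, Cuu, contrasts)
            if method == "pevmean":
                score = -pev.mean()
            else:
                cc = (contrasts**2).sum(axis=1)
                score = np.mean(1 - pev / (model.sigma_u2 * cc))
            key = (-score, str(pop.ids[i]))
            if best is None or key < best[0]:
                best = (key, str(pop.ids[i]))
        return best[1]

    @pytest.mark.parametrize("method", ["pevmean", "cdmean"])
    def test_single_pick_matches_exhaustive_search(self, rng, method):
        tp, pop, g, _ = make_setup(rng, n_tp=6, n_pop=10, k=5, h2_noise=0.5)
        model = fit_rrblup(tp)
        _, report = criterion_update(
            tp, pop, method, 1, 0, model, noiseless_phenotyper(g), cycle=1
        )
        assert report.added == [self.brute_force_single_pick(tp, pop, model, method)]

    def test_duplicate_never_beats_informative_candidate(self):
        """A candidate duplicating a TP genotype is not preferred over one
        enlarging the genotype row space."""
        rng = np.random.default_rng(21)
        k = 4
        Z_tp = np.array([[1, 1, -1, 1], [1, -1, 1, 1], [-1, 1, 1, -1], [1, 1, 1, -1]], dtype=float)
        tp = TrainingSet(
            Z_tp, rng.normal(size=4) + Z_tp[:, 0], np.zeros(4, int),
            np.array(["t0", "t1", "t2", "t3"], dtype=object),
        )
        # population: an exact duplicate of t0, a novel complementary line,
        # and targets spread over genotype space
        dup, novel = Z_tp[0], np.array([-1, -1, -1, -1])
        pop_dos = np.vstack([dup, novel, rng.choice([-1, 1], size=(6, k))]).astype(int)
        pop = make_population(pop_dos)
        g = pop_dos.astype(float) @ np.ones(k)
        model = fit_rrblup(tp)
        _, report = criterion_update(
            tp, pop, "pevmean", 1, 0, model, noiseless_phenotyper(g), cycle=1
        )
        assert report.added != [str(pop.ids[0])]

    def test_empty_candidate_pool_is_noop(self, rng):
        tp, pop, g, _ = make_setup(rng)
        model = fit_rrblup(tp)
        new_tp, report = criterion_update(
            tp, pop, "cdmean", 0, 0, model, noiseless_phenotyper(g), cycle=1
        )
        assert new_tp.n == tp.n and report.added == []


class TestOracleUpdate:
    def test_zero_caps_leave_tp_unchanged(self, rng):
        tp, pop, g, _ = make_setup(rng)
        new_tp, report = oracle_tp_update(
            tp, pop, g, noiseless_phenotyper(g), cycle=1, max_add=0, max_remove=0
        )
        assert list(new_tp.ids) == list(tp.ids)
        assert report.added == [] and report.removed == []

    def test_first_addition_matches_exhaustive_search(self, rng):
        """The first accepted addition equals a brute-force sweep refitting
        the model on TP + candidate for every candidate."""
        tp, pop, g, _ = make_setup(rng, n_tp=6, n_pop=12, k=6, h2_noise=0.3)
        pop_Z = pop.dosages().astype(float)
        new_tp, report = oracle_tp_update(
            tp, pop, g, noiseless_phenotyper(g), cycle=1, max_add=1, max_remove=0
        )
        # independent sweep at the same fixed lambda
        lam = _profile_reml(tp.Z @ tp.Z.T, tp.y)[0]
        best = None
        for i in range(pop.n_individuals):
            aug = tp.extended(pop_Z[i], g[i], 1, [str(pop.ids[i])])
            model = fit_rrblup(aug, lam=lam)
            eval_idx = [j for j in range(pop.n_individuals) if j != i]
            pred = predict_gebv(model, pop_Z[eval_idx])
            r = np.corrcoef(pred, g[eval_idx])[0, 1]
            key = (-r, str(pop.ids[i]))
            if best is None or key < best[0]:
                best = (key, str(pop.ids[i]))
        if report.added:
            assert report.added == [best[1]]

    def test_noiseless_improvement_is_monotone(self, rng):
        """With exact phenotypes and an adversarial initial TP, every
        accepted step strictly raises the predictive performance."""
        tp, pop, g, u = make_setup(rng, n_tp=5, n_pop=30, k=8)
        # adversarial TP: phenotypes with the wrong sign everywhere
        tp = TrainingSet(tp.Z, -(tp.Z @ u), tp.entry_cycle, tp.ids)
        new_tp, report = oracle_tp_update(
            tp, pop, g, noiseless_phenotyper(g), cycle=1, max_add=10, max_remove=10
        )
        assert len(report.trace) >= 1
        assert np.all(np.diff(report.trace) > 0)
        assert new_tp.n == tp.n + len(report.added) - len(report.removed)

    def test_no_same_cycle_add_and_remove(self, rng):
        tp, pop, g, _ = make_setup(rng, n_tp=6, n_pop=20, k=6, h2_noise=0.4)
        _, report = oracle_tp_update(
            tp, pop, g, noiseless_phenotyper(g), cycle=1, max_add=8, max_remove=8
        )
        assert not (set(report.added) & set(report.removed))

    def test_tp_size_can_grow_or_shrink(self, rng):
        tp, pop, g, _ = make_setup(rng, n_tp=8, n_pop=25, k=6, h2_noise=0.5)
        new_tp, report = oracle_tp_update(
            tp, pop, g, noiseless_phenotyper(g), cycle=1, max_add=5, max_remove=5
        )
        assert report.tp_size_after == new_tp.n
        assert new_tp.n == tp.n + len(report.added) - len(report.removed)
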