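"""Training-population (TP) maintenance strategies.

Three families of update rules keep the prediction model's training set in
step with the advancing breeding population:

* ``standard_update`` — *top* (highest GEBVs), *tails* (both ends of the
  GEBV distribution) and *random* additions, after dropping the oldest TP
  entries;
* ``criterion_update`` — greedy forward selection of additions minimizing
  the mean prediction error variance (*PEVmean*) or maximizing the mean
  reliability (*CDmean*) of the remaining breeding population at fixed
  variance components;
* ``oracle_tp_update`` — a benchmark with access to true genetic values: it
  alternately adds the candidate and removes the member whose change most
  increases the Pearson correlation between GEBVs and true genetic values
  over the not-yet-recruited part of the breeding population, accepting only
  strict improvements, so the TP size can grow, shrink or stay put.

The oracle loop evaluates every candidate with an exact one-row update or
downdate of the kernel-system inverse at fixed lambda (re-estimated by REML
every few accepted changes), which keeps a full sweep over ~1000 candidates
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome import HaplotypePopulation
from .prediction import (
    RRBLUPModel,
    TrainingSet,
    _profile_reml,
    prediction_error_variance,
    reliability,
)

__all__ = [
    "TPUpdateReport",
    "standard_update",
    "criterion_update",
    "oracle_tp_update",
]

PhenotypeFn = Callable[[np.ndarray], np.ndarray]
"""Maps population indices to phenotypes, drawn as one phenotyping batch."""


@dataclass
class TPUpdateReport:
    """Bookkeeping of one TP update."""

    added: list[str]
    removed: list[str]
    tp_size_after: int
    trace: list[float] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _drop_oldest(tp: TrainingSet, n_drop: int) -> tuple[TrainingSet, list[str]]:
    """Remove the ``n_drop`` earliest-entry members (ties by id)."""
    if n_drop <= 0:
        return tp, []
    order = sorted(range(tp.n), key=lambda i: (tp.entry_cycle[i], tp.ids[i]))
    dropped = order[:n_drop]
    keep = np.setdiff1d(np.arange(tp.n), dropped)
    return tp.subset(keep), [str(tp.ids[i]) for i in dropped]


def _rank(gebvs: np.ndarray, ids: np.ndarray, ascending: bool = False) -> list[int]:
    sign = 1.0 if ascending else -1.0
    return sorted(range(len(ids)), key=lambda i: (sign * gebvs[i], ids[i]))


def standard_update(
    tp: TrainingSet,
    population: HaplotypePopulation,
    gebvs: np.ndarray,
    method: str,
    n_add: int,
    n_drop_oldest: int,
    rng: np.random.Generator,
    phenotype_fn: PhenotypeFn,
    cycle: int,
    marker_indices: np.ndarray | None = None,
) -> tuple[TrainingSet, TPUpdateReport]:
    """Drop the oldest TP members, then add ``n_add`` population members by
    the *top*, *tails* or *random* rule; additions are phenotyped as one
    batch and stamped with the current cycle."""
    if method not in ("top", "tails", "random"):
        raise ValueError(f"unknown standard update method {method!r}")
    if population.n_individuals < n_add:
        raise ValueError(
            f"population of {population.n_individuals} cannot supply {n_add} TP additions"
        )
    if method == "tails" and n_add % 2:
        raise ValueError("tails update needs an even n_add")
    tp, dropped = _drop_oldest(tp, n_drop_oldest)
    gebvs = np.asarray(gebvs, dtype=float)
    ids = population.ids
    if method == "top":
        chosen = _rank(gebvs, ids)[:n_add]
    elif method == "tails":
        top = _rank(gebvs, ids)[: n_add // 2]
        bottom = [i for i in _rank(gebvs, ids, ascending=True) if i not in set(top)]
        chosen = top + bottom[: n_add // 2]
    else:
        chosen = list(rng.choice(population.n_individuals, size=n_add, replace=False))
    chosen_idx = np.array(sorted(chosen, key=lambda i: ids[i]), dtype=np.int64)
    if n_add > 0:
        y_new = phenotype_fn(chosen_idx)
        new_tp = tp.extended(
            population.dosages(marker_indices)[chosen_idx],
            y_new,
            cycle,
            ids[chosen_idx],
        )
    else:
        new_tp = tp
    added = [str(i) for i in ids[chosen_idx]] if n_add else []
    return new_tp, TPUpdateReport(added, dropped, new_tp.n)


def criterion_update(
    tp: TrainingSet,
    population: HaplotypePopulation,
    method: str,
    n_add: int,
    n_drop_oldest: int,
    model: RRBLUPModel,
    phenotype_fn: PhenotypeFn,
    cycle: int,
    marker_indices: np.ndarray | None = None,
    contrast: str = "candidate_minus_mean",
) -> tuple[TrainingSet, TPUpdateReport]:
    """Greedy forward selection of additions by mean PEV or mean CD.

    After each accepted member the criterion is recomputed for the remaining
    breeding population at the fixed variance components of ``model``;
    *pevmean* minimizes the mean PEV, *cdmean* maximizes the mean
    reliability.
    """
    if method not in ("pevmean", "cdmean"):
        raise ValueError(f"unknown criterion update method {method!r}")
    tp, dropped = _drop_oldest(tp, n_drop_oldest)
    pop_Z = population.dosages(marker_indices).astype(np.float64)
    ids = population.ids
    n_pop = population.n_individuals
    if n_pop < n_add:
        raise ValueError(f"population of {n_pop} cannot supply {n_add} TP additions")
    chosen: list[int] = []
    trace: list[float] = []
    work = tp
    for _ in range(n_add):
        remaining = [i for i in range(n_pop) if i not in chosen]
        if not remaining:
            break
        best_i, best_score = None, None
        for i in remaining:
            targets = [j for j in remaining if j != i]
            if not targets:
                targets = [i]
            trial = work.extended(pop_Z[i], 0.0, cycle, [f"_trial_{i}"])
            trial_model = model  # fixed variance components
            if method == "pevmean":
                score = -float(
                    np.mean(
                        prediction_error_variance(
                            trial, trial_model, pop_Z[targets], contrast
                        )
                    )
                )
            else:
                score = float(
                    np.mean(reliability(trial, trial_model, pop_Z[targets], contrast))
                )
            key = (score, str(ids[i]))
            if best_score is None or score > best_score[0] or (
                score == best_score[0] and key[1] < best_score[1]
            ):
                best_i, best_score = i, key
        chosen.append(best_i)
        trace.append(best_score[0] if method == "cdmean" else -best_score[0])
        work = work.extended(pop_Z[best_i], 0.0, cycle, [f"_trial_{best_i}"])
    chosen_idx = np.array(sorted(chosen, key=lambda i: ids[i]), dtype=np.int64)
    if len(chosen_idx):
        y_new = phenotype_fn(chosen_idx)
        new_tp = tp.extended(pop_Z[chosen_idx], y_new, cycle, ids[chosen_idx])
    else:
        new_tp = tp
    report = TPUpdateReport(
        [str(i) for i in ids[chosen_idx]], dropped, new_tp.n, trace
    )
    return new_tp, report


# ---------------------------------------------------------------------------
# Oracle greedy add/remove
# ---------------------------------------------------------------------------

def _pearson_columns(G: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of G with g; -inf when degenerate."""
    g = g - g.mean()
    sg = np.sqrt((g * g).sum())
    Gc = G - G.mean(axis=0)
    sG = np.sqrt((Gc * Gc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Gc.T @ g) / (sG * sg)
    r[~np.isfinite(r)] = -np.inf
    if sg == 0.0:
        r[:] = -np.inf
    return r


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(_pearson_columns(a[:, None], b)[0])


def _loo_corr(G: np.ndarray, g: np.ndarray, drop_pos: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of G with g, leaving one (column-
    specific) observation out; -inf when degenerate."""
    e, c = G.shape
    m = e - 1
    if m < 3:
        return np.full(c, -np.inf)
    cols = np.arange(c)
    Gd = G[drop_pos, cols]
    gd = g[drop_pos]
    S1 = G.sum(axis=0) - Gd
    S2 = np.einsum("ij,ij->j", G, G) - Gd * Gd
    Sxy = G.T @ g - Gd * gd
    sg1 = g.sum() - gd
    sg2 = g @ g - gd * gd
    cov = Sxy - S1 * sg1 / m
    vx = S2 - S1 * S1 / m
    vy = sg2 - sg1 * sg1 / m
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy)
    r[~np.isfinite(r)] = -np.inf
    return r


class _OracleWorkspace:
    """Kernel-space evaluation of candidate TP additions and removals.

    The universe is the current TP stacked on the breeding population; all
    model refits at fixed lambda reduce to solves against sub-blocks of the
    universe kernel ``K = Z Z'``, with one-row bordered updates (additions)
    and Schur downdates (removals) of the inverse.
    """

    def __init__(self, K: np.ndarray, y: np.ndarray, lam: float):
        self.K = K
        self.y = y
        self.lam = lam

    def _system(self, tp_rows: np.ndarray):
        A = self.K[np.ix_(tp_rows, tp_rows)] + self.lam * np.eye(len(tp_rows))
        return np.linalg.inv(A)

    def gebv(self, tp_rows: np.ndarray, eval_rows: np.ndarray, Ainv=None) -> np.ndarray:
        if Ainv is None:
            Ainv = self._system(tp_rows)
        y = self.y[tp_rows]
        p = Ainv @ y
        q = Ainv @ np.ones(len(tp_rows))
        beta = p.sum() / q.sum()
        alpha = p - beta * q
        return self.K[np.ix_(eval_rows, tp_rows)] @ alpha

    def score(self, tp_rows: np.ndarray, eval_rows: np.ndarray, g: np.ndarray) -> float:
        if len(eval_rows) < 3:
            return -np.inf
        return _pearson(self.gebv(tp_rows, eval_rows), g)

    def score_additions(
        self,
        tp_rows: np.ndarray,
        candidates: np.ndarray,
        eval_rows: np.ndarray,
        g: np.ndarray,
        Ainv: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predictive performance after adding each candidate, vectorized.

        A candidate joins the TP on acceptance and thus leaves the
        evaluation set, so both its post-addition score and its comparison
        baseline are computed on the evaluation set without it.  Returns
        (scores, baselines), one pair per candidate.
        """
        c = len(candidates)
        if len(eval_rows) - 1 < 3:
            return np.full(c, -np.inf), np.full(c, -np.inf)
        K, lam, y = self.K, self.lam, self.y
        n = len(tp_rows)
        B = K[np.ix_(tp_rows, candidates)]  # n x c
        W = Ainv @ B
        s = K[candidates, candidates] + lam - np.einsum("ij,ij->j", B, W)
        s = np.where(s <= 1e-12, np.nan, s)
        y_tp, y_c = y[tp_rows], y[candidates]
        ones = np.ones(n)
        p0, q0 = Ainv @ y_tp, Ainv @ ones
        bp, bq = B.T @ p0, B.T @ q0
        zp = (y_c - bp) / s  # bordered bottom entries
        zq = (1.0 - bq) / s
        p_top = p0[:, None] - W * zp[None, :]
        q_top = q0[:, None] - W * zq[None, :]
        sum_p = p0.sum() - W.sum(axis=0) * zp + zp
        sum_q = q0.sum() - W.sum(axis=0) * zq + zq
        beta = sum_p / sum_q
        a_top = p_top - beta[None, :] * q_top
        a_bot = zp - beta * zq
        G = K[np.ix_(eval_rows, tp_rows)] @ a_top + K[np.ix_(eval_rows, candidates)] * a_bot[None, :]
        pos = {int(row): i for i, row in enumerate(eval_rows)}
        drop_pos = np.array([pos[int(cand)] for cand in candidates])
        scores = _loo_corr(G, g, drop_pos)
        scores[np.isnan(s)] = -np.inf
        g0 = self.gebv(tp_rows, eval_rows, Ainv=Ainv)
        baselines = _loo_corr(np.broadcast_to(g0[:, None], G.shape), g, drop_pos)
        return scores, baselines

    def score_removals(
        self,
        tp_rows: np.ndarray,
        removable_pos: Sequence[int],
        eval_rows: np.ndarray,
        g: np.ndarray,
        Ainv: np.ndarray,
    ) -> np.ndarray:
        """Predictive performance after removing each removable TP member."""
        out = np.full(len(removable_pos), -np.inf)
        if len(eval_rows) < 3 or len(tp_rows) <= 3:
            return out
        for t, j in enumerate(removable_pos):
            mask = np.ones(len(tp_rows), dtype=bool)
            mask[j] = False
            ajj = Ainv[j, j]
            col = Ainv[mask, j]
            A_sub = Ainv[np.ix_(mask, mask)] - np.outer(col, col) / ajj
            out[t] = _pearson(
                self.gebv(tp_rows[mask], eval_rows, Ainv=A_sub), g
            )
        return out


def oracle_tp_update(
    tp: TrainingSet,
    population: HaplotypePopulation,
    true_genetic_values: np.ndarray,
    phenotype_fn: PhenotypeFn,
    cycle: int,
    max_add: int = 50,
    max_remove: int = 50,
    marker_indices: np.ndarray | None = None,
    refit_every: int = 10,
    full_reml: bool = False,
    tol: float = 1e-10,
) -> tuple[TrainingSet, TPUpdateReport]:
    """Greedy add/remove TP optimization against true genetic values.

    Alternates one addition attempt and one removal attempt per iteration,
    each accepted only on strict improvement of the Pearson correlation
    between GEBVs and true genetic values over the evaluation set (the
    breeding population minus every individual accepted into the TP this
    cycle).  Members added this cycle are not removal candidates.  The whole
    population is phenotyped as one batch up front, so accepted candidates
    carry phenotypes; lambda is re-estimated by REML at the start and after
    every ``refit_every`` accepted changes (every evaluation if
    ``full_reml``).
    """
    pop_Z = population.dosages(marker_indices).astype(np.float64)
    n_tp0, n_pop = tp.n, population.n_individuals
    g = np.asarray(true_genetic_values, dtype=float)
    y_pop = phenotype_fn(np.arange(n_pop))
    Z_univ = np.vstack([tp.Z, pop_Z])
    y_univ = np.concatenate([tp.y, y_pop])
    K = Z_univ @ Z_univ.T
    ids_univ = np.concatenate([tp.ids, population.ids])

    def reml_lambda(tp_rows: np.ndarray) -> float:
        lam, _, _, _ = _profile_reml(K[np.ix_(tp_rows, tp_rows)], y_univ[tp_rows])
        return lam

    tp_rows = np.arange(n_tp0)
    accepted_this_cycle: set[int] = set()  # universe indices of this cycle's additions
    eval_mask = np.ones(n_pop, dtype=bool)  # over population universe rows
    removed_ids: list[str] = []
    trace: list[float] = []
    notes: list[str] = []
    lam = reml_lambda(tp_rows)
    ws = _OracleWorkspace(K, y_univ, lam)
    n_accepted_since_refit = 0
    n_added = n_removed = 0

    def eval_rows() -> np.ndarray:
        return n_tp0 + np.flatnonzero(eval_mask)

    def eval_g() -> np.ndarray:
        return g[eval_mask]

    baseline = ws.score(tp_rows, eval_rows(), eval_g())
    if not np.isfinite(baseline):
        notes.append("degenerate evaluation set at start; treated as -inf")

    while n_added < max_add or n_removed < max_remove:
        if full_reml:
            ws.lam = reml_lambda(tp_rows)
        changed = False

        if n_added < max_add:
            Ainv = ws._system(tp_rows)
            in_tp = set(tp_rows.tolist())
            candidates = np.array(
                [n_tp0 + i for i in range(n_pop) if (n_tp0 + i) not in in_tp],
                dtype=np.int64,
            )
            if len(candidates):
                scores, baselines = ws.score_additions(
                    tp_rows, candidates, eval_rows(), eval_g(), Ainv
                )
                order = sorted(
                    range(len(candidates)),
                    key=lambda t: (-scores[t], ids_univ[candidates[t]]),
                )
                best = order[0]
                if scores[best] > baselines[best] + tol:
                    chosen = int(candidates[best])
                    tp_rows = np.append(tp_rows, chosen)
                    accepted_this_cycle.add(chosen)
                    eval_mask[chosen - n_tp0] = False
                    n_added += 1
                    n_accepted_since_refit += 1
                    changed = True
                    baseline = ws.score(tp_rows, eval_rows(), eval_g())
                    trace.append(baseline)

        if n_removed < max_remove:
            if full_reml:
                ws.lam = reml_lambda(tp_rows)
            Ainv = ws._system(tp_rows)
            removable = [
                j for j in range(len(tp_rows)) if tp_rows[j] not in accepted_this_cycle
            ]
            if removable:
                scores = ws.score_removals(tp_rows, removable, eval_rows(), eval_g(), Ainv)
                order = sorted(
                    range(len(removable)),
                    key=lambda t: (-scores[t], ids_univ[tp_rows[removable[t]]]),
                )
                best = order[0]
                if scores[best] > baseline + tol:
                    j = removable[best]
                    removed_ids.append(str(ids_univ[tp_rows[j]]))
                    tp_rows = np.delete(tp_rows, j)
                    n_removed += 1
                    n_accepted_since_refit += 1
                    changed = True
                    baseline = ws.score(tp_rows, eval_rows(), eval_g())
                    trace.append(baseline)

        if not changed:
            break
        if n_accepted_since_refit >= refit_every:
            ws.lam = reml_lambda(tp_rows)
            n_accepted_since_refit = 0
            baseline = ws.score(tp_rows, eval_rows(), eval_g())

    # assemble the new TrainingSet from surviving universe rows
    keep_old = tp_rows[tp_rows < n_tp0]
    new_pop_rows = np.sort(tp_rows[tp_rows >= n_tp0]) - n_tp0
    new_tp = tp.subset(keep_old)
    if len(new_pop_rows):
        new_tp = new_tp.extended(
            pop_Z[new_pop_rows], y_pop[new_pop_rows], cycle, population.ids[new_pop_rows]
        )
    added_ids = [str(i) for i in population.ids[new_pop_rows]]
    report = TPUpdateReport(added_ids, removed_ids, new_tp.n, trace, notes)
    return new_tp, report
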