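"""Parental selection strategies and couple formation.

Four selectors are implemented.  *Truncation* takes the individuals with the
highest GEBVs and pairs them at random.  *Scoping* preselects a fraction
``SR`` of the population by GEBV and then builds couples sequentially,
choosing the partner that maximizes the F-score

    F = sum_i var(Z_{*,i}) * p_i

over markers, where ``Z`` holds the marker genotypes of the already-selected
parents (plus the candidate under evaluation) and ``p`` flags markers at
which both alleles are not yet present in the parental set; ``p`` is
restored to all-ones when it becomes all-zero.  *Oracle* parental selection
uses true QTL knowledge: it repeatedly picks the individual carrying the
most favorable QTL alleles, counting only QTLs whose favorable allele is
missing from the parents selected so far (all QTLs once everything is
covered).  *Chimeric scoping* fills the first ``N`` couples with scoping
mechanics and the remainder with pure F-score picks for both parents,
sharing the selected-set and ``p`` state across the whole crossing block.

Tie-breaking is everywhere by ascending individual id, so all selectors are
deterministic given the rng stream and invariant to input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import HaplotypePopulation, QTLModel

__all__ = [
    "CouplePlan",
    "ScopingState",
    "truncation_select",
    "f_score",
    "scoping_select",
    "oracle_parent_select",
    "chimeric_scoping_select",
]


@dataclass
class CouplePlan:
    """Ordered (P1, P2) pairs with per-parent provenance tags."""

    couples: list[tuple[str, str]]
    method: str
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parents = self.parents
        if len(set(parents)) != len(parents):
            raise ValueError("an individual may parent at most one couple")

    @property
    def parents(self) -> list[str]:
        return [p for c in self.couples for p in c]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "couple_index": np.arange(len(self.couples)),
                "P1": [c[0] for c in self.couples],
                "P2": [c[1] for c in self.couples],
                "method": self.method,
            }
        )


@dataclass
class ScopingState:
    """Mutable state of the sequential scoping loop (shared by chimeric)."""

    p: np.ndarray  # Boolean per marker: both alleles not yet in parental set
    selected: list[str]
    SR: float


def _rank_by_gebv(gebvs: np.ndarray, ids: np.ndarray) -> list[int]:
    """Indices sorted by descending GEBV, ties by ascending id."""
    return sorted(range(len(ids)), key=lambda i: (-gebvs[i], ids[i]))


def _pair_randomly(
    parents: list[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    order = rng.permutation(len(parents))
    return [(parents[order[i]], parents[order[i + 1]]) for i in range(0, len(parents), 2)]


def truncation_select(
    gebvs: np.ndarray,
    ids: np.ndarray,
    n_parents: int,
    rng: np.random.Generator,
) -> CouplePlan:
    """Select the ``n_parents`` highest-GEBV individuals, pair them randomly."""
    if n_parents % 2:
        raise ValueError("n_parents must be even (parents are paired)")
    if len(ids) < n_parents:
        raise ValueError(f"population of {len(ids)} cannot supply {n_parents} parents")
    gebvs = np.asarray(gebvs, dtype=float)
    ids = np.asarray(ids, dtype=object)
    chosen = [str(ids[i]) for i in _rank_by_gebv(gebvs, ids)[:n_parents]]
    plan = CouplePlan(_pair_randomly(chosen, rng), "truncation")
    plan.provenance = {p: "truncation" for p in chosen}
    return plan


def f_score(genotype_rows: np.ndarray, p: np.ndarray) -> float:
    """Marker-variance score of a set of genotype rows.

    Sum over markers of the population-denominator variance of the dosage
    column, counting only markers with ``p_i = 1``.
    """
    Z = np.atleast_2d(np.asarray(genotype_rows, dtype=float))
    if Z.shape[0] < 2:
        raise ValueError("F-score needs at least two genotype rows")
    return float(Z.var(axis=0) @ np.asarray(p, dtype=float))


class _ScopingLoop:
    """Incremental state for sequential F-score couple construction."""

    def __init__(self, dosages: np.ndarray, ids: np.ndarray, gebvs: np.ndarray):
        self.D = np.asarray(dosages, dtype=np.float64)
        self.ids = np.asarray(ids, dtype=object)
        self.gebvs = np.asarray(gebvs, dtype=float)
        k = self.D.shape[1]
        self.p = np.ones(k, dtype=bool)
        self.sum = np.zeros(k)
        self.sumsq = np.zeros(k)
        self.col_min = np.full(k, np.inf)
        self.col_max = np.full(k, -np.inf)
        self.selected: list[int] = []
        self.available: set[int] = set()

    def add_parent(self, i: int) -> None:
        row = self.D[i]
        self.selected.append(i)
        self.available.discard(i)
        self.sum += row
        self.sumsq += row * row
        np.minimum(self.col_min, row, out=self.col_min)
        np.maximum(self.col_max, row, out=self.col_max)
        # both alleles present at a marker once a carrier of each has joined
        self.p &= ~((self.col_min < 1) & (self.col_max > -1))
        if not self.p.any():
            self.p[:] = True

    def f_scores(self, candidates: np.ndarray) -> np.ndarray:
        """F-score of (selected set + candidate) for every candidate row."""
        n = len(self.selected) + 1
        C = self.D[candidates]
        mean = (self.sum + C) / n
        var = (self.sumsq + C * C) / n - mean * mean
        return var @ self.p.astype(float)

    def best_by_gebv(self) -> int:
        return min(self.available, key=lambda i: (-self.gebvs[i], self.ids[i]))

    def best_by_fscore(self) -> int:
        cand = np.fromiter(self.available, dtype=np.int64)
        scores = self.f_scores(cand)
        best = scores.max()
        tied = cand[scores >= best - 1e-12]
        return min(tied, key=lambda i: self.ids[i])


def _scoping_plan(
    dosages: np.ndarray,
    ids: np.ndarray,
    gebvs: np.ndarray,
    SR: float,
    n_parents: int,
    n_scoping_couples: int,
    rng: np.random.Generator,
    method: str,
) -> CouplePlan:
    if n_parents % 2:
        raise ValueError("n_parents must be even")
    n_pop = len(ids)
    n_pre = int(np.ceil(SR * n_pop))
    if n_pre < n_parents:
        raise ValueError(
            f"preselection of ceil({SR} * {n_pop}) = {n_pre} individuals "
            f"cannot supply {n_parents} parents"
        )
    loop = _ScopingLoop(dosages, ids, gebvs)
    preselected = _rank_by_gebv(loop.gebvs, loop.ids)[:n_pre]
    loop.available = set(preselected)
    couples: list[tuple[str, str]] = []
    provenance: dict[str, str] = {}
    for c in range(n_parents // 2):
        if c < n_scoping_couples:
            p1, tag1 = loop.best_by_gebv(), "gebv"
        else:
            p1, tag1 = loop.best_by_fscore(), "f-score"
        loop.add_parent(p1)
        p2 = loop.best_by_fscore()
        loop.add_parent(p2)
        id1, id2 = str(loop.ids[p1]), str(loop.ids[p2])
        couples.append((id1, id2))
        provenance[id1] = tag1
        provenance[id2] = "f-score"
    return CouplePlan(couples, method, provenance)


def scoping_select(
    population: HaplotypePopulation,
    gebvs: np.ndarray,
    SR: float,
    n_parents: int,
    rng: np.random.Generator,
    marker_indices: np.ndarray | None = None,
) -> CouplePlan:
    """Two-stage selection: GEBV preselection at rate ``SR``, then sequential
    couples with P1 by GEBV and P2 maximizing the F-score."""
    dosages = population.dosages(marker_indices)
    return _scoping_plan(
        dosages, population.ids, gebvs, SR, n_parents, n_parents // 2, rng, "scoping"
    )


def chimeric_scoping_select(
    population: HaplotypePopulation,
    gebvs: np.ndarray,
    N: int,
    SR: float,
    n_parents: int,
    rng: np.random.Generator,
    marker_indices: np.ndarray | None = None,
) -> CouplePlan:
    """First ``N`` couples by scoping mechanics, the remaining couples with
    both parents chosen by F-score, sharing state across the block."""
    if not 0 <= N <= n_parents // 2:
        raise ValueError("N must lie between 0 and the couple count")
    dosages = population.dosages(marker_indices)
    return _scoping_plan(
        dosages, population.ids, gebvs, SR, n_parents, N, rng, "chimeric_scoping"
    )


def oracle_parent_select(
    population: HaplotypePopulation,
    qtl_model: QTLModel,
    n_parents: int,
    rng: np.random.Generator,
) -> CouplePlan:
    """Greedy selection on true QTL content.

    Each unselected individual is scored by the number of QTLs at which it
    carries at least one favorable allele, restricted to QTLs whose favorable
    allele is absent from every parent selected so far; once every favorable
    allele is covered (or none remains reachable) the score runs over all
    QTLs.  The top scorer joins the parental set (ties by id); selected
    parents are paired uniformly at random.
    """
    if n_parents % 2:
        raise ValueError("n_parents must be even")
    n = population.n_individuals
    if n < n_parents:
        raise ValueError(f"population of {n} cannot supply {n_parents} parents")
    signed = qtl_model.signed_dosages(population)
    presence = signed > -1  # favorable allele present (het or favorable homozygote)
    ids = population.ids
    # a favorable allele absent from the whole population can never be
    # selected; treating it as uncoverable keeps the priority phase finite
    reachable = presence.any(axis=0)
    covered = np.zeros(qtl_model.n_qtl, dtype=bool)
    selected: list[int] = []
    remaining = set(range(n))
    for _ in range(n_parents):
        uncovered = reachable & ~covered
        if uncovered.any():
            scores = presence[:, uncovered].sum(axis=1)
        else:
            scores = presence.sum(axis=1)
        best = min(remaining, key=lambda i: (-scores[i], ids[i]))
        selected.append(best)
        remaining.discard(best)
        covered |= presence[best]
    chosen = [str(ids[i]) for i in selected]
    plan = CouplePlan(_pair_randomly(chosen, rng), "oracle")
    plan.provenance = {p: "oracle-priority" for p in chosen}
    return plan
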