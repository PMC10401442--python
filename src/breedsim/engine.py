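"""Orchestration of the recurrent genomic-selection breeding scheme.

One breeding cycle operates on the current breeding population ``P_t``:

1. update the training population (TP) using the previous model's GEBVs,
   phenotype the new entries, and refit the prediction model by REML;
2. predict GEBVs of ``P_t`` with the refitted model;
3. select and pair parents (truncation / scoping / chimeric scoping /
   oracle);
4. cross every couple into F1 offspring;
5. advance the F1 by single-seed descent to form ``P_{t+1}``;
6. record cycle metrics (genetic values, fixation, predictive performance,
   TP relationship and residual error) for ``P_t``.

Experiments replay this cycle for ``n_cycles`` and average over ``n_runs``
independent replicates.  Seeding is hierarchical: founders and the QTL model
derive from (master seed, run index) only, so different selection or TP
methods run on *paired* base material when launched from the same master
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import selection, tp_update
from .founders import FounderSet, generate_synthetic_founders, read_founders
from .genome import (
    HaplotypePopulation,
    QTLModel,
    build_qtl_model,
    cross_couples,
    fixed_genetic_value,
    max_reachable_value,
    population_genetic_values,
    single_seed_descent,
)
from .phenotype import PhenotypeModel, build_phenotype_model, simulate_phenotypes
from .prediction import RRBLUPModel, TrainingSet, fit_rrblup, predict_gebv
from .selection import CouplePlan

__all__ = [
    "ExperimentConfig",
    "BreedingState",
    "CycleMetrics",
    "initial_cross",
    "initialize_state",
    "run_cycle",
    "genetic_relationship",
    "run_experiment",
    "summarize",
]

SELECTION_METHODS = ("truncation", "scoping", "chimeric_scoping", "oracle", "phenotype", "true_value")
TP_METHODS = ("top", "tails", "random", "pevmean", "cdmean", "oracle", "none")


@dataclass
class ExperimentConfig:
    """Complete description of one simulation experiment."""

    # founder source: file paths take precedence over synthetic parameters
    founder_files: dict[str, str] | None = None
    synthetic: dict[str, Any] = field(default_factory=dict)
    # genetic architecture and scheme sizes
    L: int = 100
    n_parents: int = 100
    n_couples: int = 50
    offspring_per_couple: int = 20
    ssd_generations: int = 2
    n_cycles: int = 50
    n_runs: int = 100
    h2: float = 0.5
    n_env: int = 3
    # parental selection
    selection_method: str = "truncation"
    SR: float = 0.3
    chimeric_ramp: list[list[int]] = field(default_factory=lambda: [[1, 0]])
    # TP maintenance
    tp_method: str = "tails"
    tp_n_add: int = 150
    tp_n_drop_oldest: int = 150
    tp_initial: str = "full_base"  # or "random"
    tp_initial_size: int = 100
    tp_max_add: int = 50
    tp_max_remove: int = 50
    # variance freezing reference: first F3 population or the founders
    var_g_reference: str = "f3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents != 2 * self.n_couples:
            raise ValueError("n_parents must equal 2 * n_couples")
        for name in (
            "L",
            "n_parents",
            "n_couples",
            "offspring_per_couple",
            "ssd_generations",
            "n_cycles",
            "n_runs",
            "n_env",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.selection_method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection_method {self.selection_method!r}")
        if self.tp_method not in TP_METHODS:
            raise ValueError(f"unknown tp_method {self.tp_method!r}")
        if self.tp_initial not in ("full_base", "random"):
            raise ValueError("tp_initial must be 'full_base' or 'random'")
        if self.var_g_reference not in ("f3", "founders"):
            raise ValueError("var_g_reference must be 'f3' or 'founders'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def chimeric_N(self, cycle: int) -> int:
        """Scoping-couple count for the given cycle from the ramp schedule
        (list of [cycle, N] breakpoints; the last one at or before applies)."""
        n = 0
        for c, value in sorted(self.chimeric_ramp):
            if cycle >= c:
                n = value
        return int(n)


@dataclass
class CycleMetrics:
    """Per-cycle record of the breeding population and TP."""

    cycle: int
    top10_value: float
    mean_value: float
    max_reachable: float
    fixed_value: float
    predictive_performance: float
    tp_relationship: float
    residual_error: float
    tp_size: int
    n_added: int
    n_removed: int

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class BreedingState:
    """Everything that evolves over cycles within one simulation run."""

    population: HaplotypePopulation
    tp: TrainingSet
    qtl_model: QTLModel
    phen_model: PhenotypeModel
    model: RRBLUPModel
    base_marker_freqs: np.ndarray
    base_mean_relationship: float
    cycle: int = 1


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initial_cross(founders: FounderSet, n_couples: int) -> CouplePlan:
    """Pair the phenotypically best lines of the two founder groups.

    Each group is ranked by phenotype (descending, ties by id) and the
    rank-i line of the first group is coupled with the rank-i line of the
    second.
    """
    groups = founders.groups
    if len(groups) != 2:
        raise ValueError(f"founder set must contain exactly 2 groups, got {groups}")
    ranked: list[list[str]] = []
    for gname in groups:
        mask = founders.group == gname
        ids = founders.haplotypes.ids[mask]
        phen = founders.phenotypes[mask]
        if mask.sum() < n_couples:
            raise ValueError(
                f"group {gname!r} has {int(mask.sum())} lines, needs {n_couples}"
            )
        order = sorted(range(len(ids)), key=lambda i: (-phen[i], ids[i]))
        ranked.append([str(ids[i]) for i in order[:n_couples]])
    couples = list(zip(ranked[0], ranked[1]))
    plan = CouplePlan(couples, "initial_phenotypic")
    plan.provenance = {p: "phenotype" for c in couples for p in c}
    return plan


def _load_founders(config: ExperimentConfig, rng: np.random.Generator) -> FounderSet:
    if config.founder_files:
        return read_founders(
            config.founder_files["genotypes"],
            config.founder_files["map"],
            config.founder_files["phenotypes"],
        )
    return generate_synthetic_founders(h2=config.h2, seed=rng, **config.synthetic)


def initialize_state(
    founders: FounderSet,
    config: ExperimentConfig,
    qtl_rng: np.random.Generator,
    rng: np.random.Generator,
) -> BreedingState:
    """Build the QTL model, run the initial phenotype-ranked cross, freeze
    the phenotype variance components and fit the first prediction model."""
    gmap = founders.haplotypes.gmap
    qtl_model = build_qtl_model(gmap.n_loci, config.L, qtl_rng)

    plan = initial_cross(founders, config.n_couples)
    f1 = cross_couples(
        founders.haplotypes, plan.couples, config.offspring_per_couple, rng,
        birth_cycle=1, id_prefix="c1",
    )
    population = single_seed_descent(f1, config.ssd_generations, rng)

    if config.var_g_reference == "f3":
        g_ref = population_genetic_values(population, qtl_model)
    else:
        g_ref = population_genetic_values(founders.haplotypes, qtl_model)
    phen_model = build_phenotype_model(g_ref, config.h2, config.n_env)

    markers = qtl_model.marker_indices
    base_Z = founders.haplotypes.dosages(markers).astype(float)
    if config.tp_initial == "full_base":
        tp_index = np.arange(founders.n_individuals)
    else:
        tp_index = np.sort(
            rng.choice(founders.n_individuals, size=config.tp_initial_size, replace=False)
        )
    tp = TrainingSet(
        base_Z[tp_index],
        founders.phenotypes[tp_index],
        np.zeros(len(tp_index), dtype=int),
        founders.haplotypes.ids[tp_index],
    )
    model = fit_rrblup(tp)

    base_P = (base_Z.mean(axis=0) + 1.0) / 2.0  # frequency of allele 1
    base_mean = mean_self_relationship(base_Z, base_P)
    return BreedingState(population, tp, qtl_model, phen_model, model, base_P, base_mean)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def genetic_relationship(
    tp_genotypes: np.ndarray, pop_genotypes: np.ndarray, base_allele_freqs: np.ndarray
) -> float:
    """Mean VanRaden relationship between two sets of individuals.

    Columns of M are ``Z_i - 2 (P_i - 0.5)`` with ``P_i`` the alternative-
    allele frequency in the base population; the relationship matrix is
    ``M M' / (2 sum P_i (1 - P_i))`` and the cross-block mean between the
    two row sets is returned (unscaled — divide by the base-population mean
    to reproduce the reported, self-normalized quantity).
    """
    P = np.asarray(base_allele_freqs, dtype=float)
    denom = 2.0 * float(np.sum(P * (1.0 - P)))
    if denom == 0.0:
        raise ValueError("all base allele frequencies are 0 or 1; relationship undefined")
    center = 2.0 * (P - 0.5)
    M1 = np.atleast_2d(np.asarray(tp_genotypes, dtype=float)) - center
    M2 = np.atleast_2d(np.asarray(pop_genotypes, dtype=float)) - center
    return float((M1 @ M2.T).mean() / denom)


def mean_self_relationship(genotypes: np.ndarray, base_allele_freqs: np.ndarray) -> float:
    """Mean diagonal (self) VanRaden relationship of a set of individuals.

    Used as the base-population normalizer for the TP-population relationship
    metric: with frequencies estimated from the same set, the *off-diagonal*
    mean relationship is identically zero (the centered M columns sum to
    zero), so the average self-relationship — about ``1 + F``, 2 for fully
    inbred lines — is the only non-degenerate base reference.
    """
    P = np.asarray(base_allele_freqs, dtype=float)
    denom = 2.0 * float(np.sum(P * (1.0 - P)))
    if denom == 0.0:
        raise ValueError("all base allele frequencies are 0 or 1; relationship undefined")
    M = np.atleast_2d(np.asarray(genotypes, dtype=float)) - 2.0 * (P - 0.5)
    return float(np.einsum("ij,ij->i", M, M).mean() / denom)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# One cycle
# ---------------------------------------------------------------------------

def _update_tp(
    state: BreedingState,
    config: ExperimentConfig,
    g_true: np.ndarray,
    rng: np.random.Generator,
) -> tuple[TrainingSet, tp_update.TPUpdateReport]:
    pop = state.population
    markers = state.qtl_model.marker_indices

    def phenotype_fn(indices: np.ndarray) -> np.ndarray:
        return simulate_phenotypes(g_true[indices], state.phen_model, rng)

    if config.tp_method == "none":
        return state.tp, tp_update.TPUpdateReport([], [], state.tp.n)
    if config.tp_method in ("top", "tails", "random"):
        gebvs = predict_gebv(state.model, pop.dosages(markers))
        return tp_update.standard_update(
            state.tp, pop, gebvs, config.tp_method,
            config.tp_n_add, config.tp_n_drop_oldest, rng,
            phenotype_fn, state.cycle, markers,
        )
    if config.tp_method in ("pevmean", "cdmean"):
        return tp_update.criterion_update(
            state.tp, pop, config.tp_method,
            config.tp_n_add, config.tp_n_drop_oldest, state.model,
            phenotype_fn, state.cycle, markers,
        )
    return tp_update.oracle_tp_update(
        state.tp, pop, g_true, phenotype_fn, state.cycle,
        max_add=config.tp_max_add, max_remove=config.tp_max_remove,
        marker_indices=markers,
    )


def _select_parents(
    state: BreedingState,
    config: ExperimentConfig,
    gebvs: np.ndarray,
    g_true: np.ndarray,
    rng: np.random.Generator,
) -> CouplePlan:
    pop = state.population
    markers = state.qtl_model.marker_indices
    method = config.selection_method
    if method == "truncation":
        return selection.truncation_select(gebvs, pop.ids, config.n_parents, rng)
    if method == "scoping":
        return selection.scoping_select(
            pop, gebvs, config.SR, config.n_parents, rng, markers
        )
    if method == "chimeric_scoping":
        return selection.chimeric_scoping_select(
            pop, gebvs, config.chimeric_N(state.cycle), config.SR,
            config.n_parents, rng, markers,
        )
    if method == "oracle":
        return selection.oracle_parent_select(pop, state.qtl_model, config.n_parents, rng)
    if method == "true_value":
        return selection.truncation_select(g_true, pop.ids, config.n_parents, rng)
    # phenotype-based truncation: phenotype the whole population once
    y = simulate_phenotypes(g_true, state.phen_model, rng)
    return selection.truncation_select(y, pop.ids, config.n_parents, rng)


def run_cycle(
    state: BreedingState, config: ExperimentConfig, rng: np.random.Generator
) -> tuple[BreedingState, CycleMetrics]:
    """Advance the breeding program by one cycle and report its metrics."""
    pop = state.population
    model_q = state.qtl_model
    markers = model_q.marker_indices
    g_true = population_genetic_values(pop, model_q)

    # (1) TP update with the previous model's GEBVs, then refit
    new_tp, report = _update_tp(state, config, g_true, rng)
    model = fit_rrblup(new_tp) if config.tp_method != "none" else state.model

    # (2) GEBVs of the current breeding population
    gebvs = predict_gebv(model, pop.dosages(markers))

    # (3) parental selection, (4) crossing, (5) single-seed descent
    state_for_selection = dataclasses.replace(state, tp=new_tp, model=model)
    plan = _select_parents(state_for_selection, config, gebvs, g_true, rng)
    f1 = cross_couples(
        pop, plan.couples, config.offspring_per_couple, rng,
        birth_cycle=state.cycle + 1, id_prefix=f"c{state.cycle + 1}",
    )
    next_pop = single_seed_descent(f1, config.ssd_generations, rng)

    # (6) metrics on the population the cycle operated on
    denom = model_q.rescale_denominator
    g_scaled = g_true / denom
    top10 = float(np.mean(np.sort(g_scaled)[-10:]))
    added_mask = new_tp.entry_cycle == state.cycle
    if added_mask.any():
        added_idx = pop.index_of(new_tp.ids[added_mask])
        residual = float(np.mean(np.abs(g_true[added_idx] - new_tp.y[added_mask])))
    else:
        residual = float("nan")
    metrics = CycleMetrics(
        cycle=state.cycle,
        top10_value=top10,
        mean_value=float(g_scaled.mean()),
        max_reachable=max_reachable_value(pop, model_q, rescaled=True),
        fixed_value=fixed_genetic_value(pop, model_q, rescaled=True),
        predictive_performance=_pearson(gebvs, g_true),
        tp_relationship=genetic_relationship(
            new_tp.Z, pop.dosages(markers), state.base_marker_freqs
        )
        / state.base_mean_relationship,
        residual_error=residual,
        tp_size=new_tp.n,
        n_added=len(report.added),
        n_removed=len(report.removed),
    )
    new_state = BreedingState(
        next_pop, new_tp, model_q, state.phen_model, model,
        state.base_marker_freqs, state.base_mean_relationship, state.cycle + 1,
    )
    return new_state, metrics


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_single(
    config: ExperimentConfig, run_index: int = 0
) -> pd.DataFrame:
    """One replicate: returns a tidy per-cycle metrics table."""
    ss = np.random.SeedSequence([config.seed, run_index])
    s_founders, s_qtl, s_breed = ss.spawn(3)
    founders = _load_founders(config, np.random.default_rng(s_founders))
    state = initialize_state(
        founders, config, np.random.default_rng(s_qtl), np.random.default_rng(s_breed)
    )
    rng = np.random.default_rng(s_breed.spawn(1)[0])
    rows = []
    for _ in range(config.n_cycles):
        state, metrics = run_cycle(state, config, rng)
        row = metrics.to_dict()
        row["run"] = run_index
        row["method"] = f"{config.selection_method}+{config.tp_method}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """All replicates of one experiment; optionally persist raw and summary
    CSVs (``raw.csv``, ``summary.csv``) under ``out_dir``."""
    frames = [run_single(config, r) for r in range(config.n_runs)]
    raw = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out_dir / "raw.csv", index=False)
        summarize(raw).to_csv(out_dir / "summary.csv", index=False)
        config.to_yaml(out_dir / "config.yaml")
    return raw


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle mean and standard error over runs, in long form."""
    value_cols = [
        c for c in raw.columns if c not in ("run", "cycle", "method")
    ]
    long = raw.melt(
        id_vars=["run", "cycle", "method"], value_vars=value_cols,
        var_name="metric", value_name="value",
    )
    grouped = long.groupby(["method", "cycle", "metric"])["value"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"count": "n_runs"})
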