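"""Genomes, QTL architecture, and the generative mechanics of breeding.

This module owns the three in-memory containers the simulator is built on
(:class:`GeneticMap`, :class:`HaplotypePopulation`, :class:`QTLModel`) and the
operations that act on them: construction of the additive QTL model with a
geometric effect series, genetic-value computations (realised, fixed, and
maximum-reachable), and meiosis/crossing/single-seed descent.

Allele coding
-------------
Haplotype alleles are ``{0, 1}``.  The genotype *dosage* at a locus is
``h1 + h2 - 1`` and therefore lies in ``{-1, 0, +1}`` — homozygous for allele
0, heterozygous, homozygous for allele 1 — matching the conventional
``-1/0/+1`` marker coding of ridge-regression BLUP.  Fully inbred lines have
dosages in ``{-1, +1}`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "HaplotypePopulation",
    "QTLModel",
    "build_qtl_model",
    "genetic_value",
    "population_genetic_values",
    "max_reachable_value",
    "fixed_genetic_value",
    "make_gamete",
    "cross",
    "cross_couples",
    "single_seed_descent",
]


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci on a set of chromosomes with centimorgan positions.

    Parameters
    ----------
    chrom_names
        One identifier per chromosome, in order.
    chrom_offsets
        Index of the first locus of each chromosome in the global locus
        ordering, plus a trailing sentinel equal to the total locus count
        (length ``n_chromosomes + 1``).
    positions_cM
        Genetic position of every locus, concatenated chromosome by
        chromosome; strictly increasing within each chromosome.
    locus_ids
        Globally unique locus identifiers, same length as ``positions_cM``.
    """

    chrom_names: tuple[str, ...]
    chrom_offsets: np.ndarray
    positions_cM: np.ndarray
    locus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        offsets = np.asarray(self.chrom_offsets, dtype=np.int64)
        pos = np.asarray(self.positions_cM, dtype=np.float64)
        object.__setattr__(self, "chrom_offsets", offsets)
        object.__setattr__(self, "positions_cM", pos)
        if len(offsets) != len(self.chrom_names) + 1:
            raise ValueError("chrom_offsets must have one entry per chromosome plus a sentinel")
        if offsets[0] != 0 or offsets[-1] != len(pos):
            raise ValueError("chrom_offsets must start at 0 and end at the locus count")
        if len(self.locus_ids) != len(pos):
            raise ValueError(
                f"{len(self.locus_ids)} locus ids for {len(pos)} map positions"
            )
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus ids must be globally unique")
        for c, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
            if hi <= lo:
                raise ValueError(f"chromosome {self.chrom_names[c]} has no loci")
            if np.any(np.diff(pos[lo:hi]) <= 0):
                raise ValueError(
                    f"positions on chromosome {self.chrom_names[c]} must be strictly increasing"
                )

    @property
    def n_loci(self) -> int:
        return len(self.positions_cM)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self.chrom_offsets[c]), int(self.chrom_offsets[c + 1]))

    @classmethod
    def uniform(
        cls,
        n_loci: int,
        n_chromosomes: int,
        chrom_length_cM: float = 150.0,
        prefix: str = "M",
    ) -> "GeneticMap":
        """Evenly spaced loci distributed as equally as possible over
        ``n_chromosomes`` chromosomes of ``chrom_length_cM`` centimorgans."""
        if n_loci < n_chromosomes:
            raise ValueError("need at least one locus per chromosome")
        counts = np.full(n_chromosomes, n_loci // n_chromosomes, dtype=int)
        counts[: n_loci % n_chromosomes] += 1
        positions, offsets = [], [0]
        for m in counts:
            positions.append(np.linspace(0.0, chrom_length_cM, m))
            offsets.append(offsets[-1] + m)
        names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
        ids = tuple(f"{prefix}{i + 1}" for i in range(n_loci))
        return cls(names, np.array(offsets), np.concatenate(positions), ids)


# ---------------------------------------------------------------------------
# Haplotype population
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePopulation:
    """Phased biallelic haplotype pairs for a set of individuals.

    ``haplotypes`` has shape ``(n_individuals, 2, n_loci)`` with alleles in
    ``{0, 1}``.  ``birth_cycle`` records the breeding cycle each individual
    was created in (0 for founders).
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    ids: np.ndarray
    birth_cycle: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise ValueError(
                f"haplotype length {self.haplotypes.shape[2]} != "
                f"map locus count {self.gmap.n_loci}"
            )
        self.ids = np.asarray(self.ids, dtype=object)
        if len(self.ids) != self.haplotypes.shape[0]:
            raise ValueError("one id per individual required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        if self.birth_cycle is None:
            self.birth_cycle = np.zeros(len(self.ids), dtype=np.int64)
        else:
            self.birth_cycle = np.asarray(self.birth_cycle, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype dosages ``h1 + h2 - 1`` in ``{-1, 0, +1}``; optionally a
        column subset given by locus indices."""
        d = self.haplotypes.sum(axis=1, dtype=np.int8) - np.int8(1)
        return d if loci is None else d[:, loci]

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per locus over the 2n haplotypes."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1), dtype=np.float64)

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous loci."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)

    def subset(self, index: np.ndarray) -> "HaplotypePopulation":
        return HaplotypePopulation(
            self.haplotypes[index].copy(),
            self.gmap,
            self.ids[index].copy(),
            self.birth_cycle[np.asarray(index)].copy(),
        )

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# QTL model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLModel:
    """Additive QTL architecture with geometrically decaying effects.

    ``qtl_indices[k-1]`` is the locus index of the *k*-th QTL; its favorable
    homozygote contributes ``+a**k``, the heterozygote 0 and the unfavorable
    homozygote ``-a**k``, with ``a = (L - 1) / (L + 1)``.  Loci not chosen as
    QTLs are prediction markers.  ``rescale_denominator`` is the genetic value
    of the ideotype (all QTLs fixed favorable), used to rescale values to 1.
    """

    qtl_indices: np.ndarray
    favorable_allele: np.ndarray
    effects: np.ndarray
    marker_indices: np.ndarray
    a: float
    rescale_denominator: float

    def __post_init__(self) -> None:
        for name in ("qtl_indices", "marker_indices"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        object.__setattr__(self, "favorable_allele", np.asarray(self.favorable_allele, dtype=np.int8))
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=np.float64))
        if np.intersect1d(self.qtl_indices, self.marker_indices).size:
            raise ValueError("QTL and marker index sets must be disjoint")
        if np.any(self.effects <= 0) or np.any(np.diff(self.effects) >= 0):
            raise ValueError("effects must be strictly positive and strictly decreasing")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    def signed_dosages(self, population: HaplotypePopulation) -> np.ndarray:
        """Dosage of the *favorable* allele minus 1, per individual × QTL:
        +1 favorable homozygote, 0 heterozygote, -1 unfavorable homozygote."""
        d = population.dosages(self.qtl_indices)
        sign = np.where(self.favorable_allele == 1, 1, -1).astype(np.int8)
        return d * sign


def build_qtl_model(n_loci: int, L: int, seed: int | np.random.Generator) -> QTLModel:
    """Draw ``L`` QTLs uniformly without replacement from ``n_loci`` loci.

    The magnitude ranking (the power ``k`` in ``a**k``) is a uniform random
    permutation of the chosen loci, and the favorable allele at each QTL is
    assigned uniformly at random.  The remaining loci become markers.
    """
    if L >= n_loci:
        raise ValueError(f"L={L} must be smaller than the locus count {n_loci}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    qtl = rng.choice(n_loci, size=L, replace=False)
    qtl = rng.permutation(qtl)  # k-ordering independent of draw order
    favorable = rng.integers(0, 2, size=L).astype(np.int8)
    a = (L - 1) / (L + 1)
    effects = a ** np.arange(1, L + 1, dtype=np.float64)
    markers = np.setdiff1d(np.arange(n_loci), qtl)
    return QTLModel(qtl, favorable, effects, markers, a, float(effects.sum()))


def genetic_value(qtl_dosages: np.ndarray, model: QTLModel) -> np.ndarray:
    """Additive genetic value per individual from dosages at the QTL loci.

    Columns must be aligned with ``model.qtl_indices`` (k-order).  The value
    is ``sum_k s_k * a**k`` with ``s_k`` +1 for the favorable homozygote, 0
    for the heterozygote and -1 for the unfavorable homozygote; no dominance
    or epistasis.
    """
    d = np.atleast_2d(np.asarray(qtl_dosages))
    if d.shape[1] != model.n_qtl:
        raise ValueError(
            f"dosage matrix has {d.shape[1]} columns but the model has {model.n_qtl} QTLs"
        )
    sign = np.where(model.favorable_allele == 1, 1.0, -1.0)
    return (d * sign) @ model.effects


def population_genetic_values(
    population: HaplotypePopulation, model: QTLModel, rescaled: bool = False
) -> np.ndarray:
    """Genetic value of every individual; optionally rescaled to the ideotype."""
    g = genetic_value(population.dosages(model.qtl_indices), model)
    return g / model.rescale_denominator if rescaled else g


def _fixation_state(population: HaplotypePopulation, model: QTLModel) -> np.ndarray:
    """Per QTL: +1 fixed favorable, -1 fixed unfavorable, 0 segregating.

    Fixation is exact: a QTL is fixed iff a single allele is present across
    all haplotypes of the population.
    """
    s = model.signed_dosages(population)
    lo, hi = s.min(axis=0), s.max(axis=0)
    state = np.zeros(model.n_qtl, dtype=np.int8)
    state[(lo == 1) & (hi == 1)] = 1
    state[(lo == -1) & (hi == -1)] = -1
    return state


def max_reachable_value(
    population: HaplotypePopulation, model: QTLModel, rescaled: bool = True
) -> float:
    """Best genetic value still attainable given current fixation.

    Sum of the signed effects of fixed QTLs plus the favorable effect of every
    still-segregating QTL.  Rescaled, a population segregating (or fixed
    favorable) at every QTL scores exactly 1.
    """
    if population.n_individuals == 0:
        raise ValueError("population is empty")
    state = _fixation_state(population, model)
    contrib = np.where(state == -1, -model.effects, model.effects)
    value = float(contrib.sum())
    return value / model.rescale_denominator if rescaled else value


def fixed_genetic_value(
    population: HaplotypePopulation, model: QTLModel, rescaled: bool = True
) -> float:
    """Signed sum of effects of the QTLs fixed in the population."""
    if population.n_individuals == 0:
        raise ValueError("population is empty")
    state = _fixation_state(population, model)
    value = float((state * model.effects).sum())
    return value / model.rescale_denominator if rescaled else value


# ---------------------------------------------------------------------------
# Meiosis, crossing, single-seed descent
# ---------------------------------------------------------------------------

def make_gamete(
    hap_pair: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one meiosis: a recombinant haplotype from a haplotype pair.

    Per chromosome the crossover count is Poisson with mean equal to the map
    length in Morgans, crossover positions are uniform (no interference,
    i.e. Haldane's mapping), and the starting parental strand is chosen with
    probability 1/2.  Chromosomes assort independently.
    """
    gamete = np.empty(gmap.n_loci, dtype=np.int8)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        pos = gmap.positions_cM[sl]
        length_cM = pos[-1] - pos[0]
        n_x = rng.poisson(length_cM / 100.0)
        start = rng.integers(0, 2)
        if n_x == 0:
            gamete[sl] = hap_pair[start, sl]
            continue
        xpos = rng.uniform(pos[0], pos[-1], size=n_x)
        # strand at each locus flips once per crossover to its left
        source = (start + np.searchsorted(np.sort(xpos), pos, side="left")) % 2
        seg = hap_pair[:, sl]
        gamete[sl] = seg[source, np.arange(len(pos))]
    return gamete


def _offspring(
    parents: Sequence[tuple[np.ndarray, np.ndarray]],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty((len(parents), 2, gmap.n_loci), dtype=np.int8)
    for i, (hp1, hp2) in enumerate(parents):
        out[i, 0] = make_gamete(hp1, gmap, rng)
        out[i, 1] = make_gamete(hp2, gmap, rng)
    return out


def cross(
    p1: np.ndarray,
    p2: np.ndarray,
    gmap: GeneticMap,
    n_offspring: int,
    rng: np.random.Generator,
    ids: Sequence[str] | None = None,
    birth_cycle: int = 0,
) -> HaplotypePopulation:
    """Cross two individuals (haplotype pairs): each offspring receives one
    independent gamete from each parent."""
    haps = _offspring([(p1, p2)] * n_offspring, gmap, rng)
    if ids is None:
        ids = [f"x{i}" for i in range(n_offspring)]
    cycles = np.full(n_offspring, birth_cycle)
    return HaplotypePopulation(haps, gmap, np.asarray(ids, dtype=object), cycles)


def cross_couples(
    population: HaplotypePopulation,
    couples: Sequence[tuple[str, str]],
    n_offspring: int,
    rng: np.random.Generator,
    birth_cycle: int = 0,
    id_prefix: str = "F1",
) -> HaplotypePopulation:
    """Produce ``n_offspring`` F1 individuals from every (P1, P2) couple."""
    idx = {iid: i for i, iid in enumerate(population.ids)}
    pairs = []
    for p1, p2 in couples:
        hp = population.haplotypes
        pairs.extend([(hp[idx[p1]], hp[idx[p2]])] * n_offspring)
    haps = _offspring(pairs, population.gmap, rng)
    ids = np.array(
        [f"{id_prefix}_{c}_{o}" for c in range(len(couples)) for o in range(n_offspring)],
        dtype=object,
    )
    return HaplotypePopulation(haps, population.gmap, ids, np.full(len(ids), birth_cycle))


def single_seed_descent(
    population: HaplotypePopulation,
    generations: int,
    rng: np.random.Generator,
) -> HaplotypePopulation:
    """Advance every line by one selfed seed per generation.

    Each individual is replaced by a single offspring of a self-cross (two
    independent gametes from the same plant); population size and ids are
    preserved, heterozygosity halves per generation in expectation.
    """
    haps = population.haplotypes
    for _ in range(generations):
        haps = _offspring([(hp, hp) for hp in haps], population.gmap, rng)
    return replace(population, haplotypes=haps)
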