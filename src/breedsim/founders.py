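"""Founder populations: file readers and a synthetic generator.

The simulator starts from a base population of fully inbred lines split into
two subpopulations.  Real data enter through three TSV files (genotype matrix,
genetic map, phenotypes; VCF is accepted for genotypes), while
:func:`generate_synthetic_founders` creates populations with the same
statistical structure: two diverged groups of inbred lines, along-chromosome
linkage disequilibrium, a fraction of already-fixed loci, and phenotypes at a
target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import GeneticMap, HaplotypePopulation

__all__ = [
    "FounderSet",
    "FounderDataError",
    "read_founders",
    "read_genetic_map",
    "generate_synthetic_founders",
    "write_founders",
]


class FounderDataError(ValueError):
    """Raised when founder input files are structurally invalid."""


@dataclass
class FounderSet:
    """Base population: haplotypes plus one phenotype and group label each."""

    haplotypes: HaplotypePopulation
    phenotypes: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.float64)
        self.group = np.asarray(self.group, dtype=object)
        n = self.haplotypes.n_individuals
        if len(self.phenotypes) != n or len(self.group) != n:
            raise FounderDataError(
                "phenotype/group length must equal the number of individuals"
            )

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.n_individuals

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(str(g), None)
        return list(seen)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_genetic_map(map_path: str | Path) -> GeneticMap:
    """Read a TSV with columns ``locus_id``, ``chromosome``, ``position_cM``.

    Loci must be grouped by chromosome with strictly increasing positions;
    chromosome order follows first appearance.
    """
    df = pd.read_csv(map_path, sep="\t", dtype={"locus_id": str, "chromosome": str})
    required = {"locus_id", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise FounderDataError(
            f"{map_path}: map file needs columns {sorted(required)}, got {list(df.columns)}"
        )
    names: list[str] = []
    for c in df["chromosome"]:
        if c not in names:
            names.append(c)
    offsets = [0]
    positions: list[np.ndarray] = []
    ids: list[str] = []
    for c in names:
        sub = df[df["chromosome"] == c]
        positions.append(sub["position_cM"].to_numpy(dtype=float))
        ids.extend(sub["locus_id"])
        offsets.append(offsets[-1] + len(sub))
    try:
        return GeneticMap(tuple(names), np.array(offsets), np.concatenate(positions), tuple(ids))
    except ValueError as exc:
        raise FounderDataError(f"{map_path}: {exc}") from exc


def _dosages_to_haplotypes(dosages: np.ndarray) -> np.ndarray:
    """-1 -> (0,0); 0 -> (0,1) arbitrary phase; +1 -> (1,1)."""
    h = np.zeros((dosages.shape[0], 2, dosages.shape[1]), dtype=np.int8)
    h[:, 0, :] = dosages == 1
    h[:, 1, :] = dosages >= 0
    return h


def _read_genotype_tsv(path: str | Path, gmap: GeneticMap) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    file_loci = [str(c) for c in df.columns]
    if file_loci != list(gmap.locus_ids):
        if len(file_loci) != gmap.n_loci:
            raise FounderDataError(
                f"{path}: genotype file has {len(file_loci)} loci but the map has {gmap.n_loci}"
            )
        unknown = set(file_loci) - set(gmap.locus_ids)
        if unknown:
            raise FounderDataError(
                f"{path}: loci absent from the map: {sorted(unknown)[:5]}"
            )
        df = df[list(gmap.locus_ids)]  # reorder to map order
    try:
        values = np.asarray(df.to_numpy(), dtype=float)
    except ValueError as exc:
        raise FounderDataError(f"{path}: non-numeric genotype entry ({exc})") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FounderDataError(
            f"{path}: line {i + 2}: missing genotype at locus {df.columns[j]!r} "
            "(missing data are not supported)"
        )
    bad = ~np.isin(values, (-1.0, 0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FounderDataError(
            f"{path}: line {i + 2}: locus {df.columns[j]!r} has dosage "
            f"{values[i, j]!r}, expected -1/0/1 (biallelic coding)"
        )
    return [str(i) for i in df.index], values.astype(np.int8)


def _read_genotype_vcf(path: str | Path, gmap: GeneticMap) -> tuple[list[str], np.ndarray]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FounderDataError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FounderDataError(
                f"{path}: locus {variant.ID} at {variant.CHROM}:{variant.POS} is not biallelic"
            )
        gts = np.asarray(variant.genotype.array())[:, :2]
        if (gts < 0).any():
            raise FounderDataError(f"{path}: missing genotype at {variant.ID}")
        rows[str(variant.ID)] = gts.sum(axis=1).astype(np.int8) - np.int8(1)
    missing = [l for l in gmap.locus_ids if l not in rows]
    if missing:
        raise FounderDataError(f"{path}: map loci absent from VCF: {missing[:5]}")
    dosages = np.column_stack([rows[l] for l in gmap.locus_ids])
    return samples, dosages


def read_founders(
    genotype_path: str | Path,
    map_path: str | Path,
    phenotype_path: str | Path,
) -> FounderSet:
    """Assemble a :class:`FounderSet` from genotype, map and phenotype files.

    Genotypes are a TSV matrix (header row of locus ids; one row per
    individual with dosages in ``{-1, 0, 1}``) or a biallelic VCF.  Every
    genotyped individual must have a numeric phenotype and a group label.
    """
    gmap = read_genetic_map(map_path)
    if str(genotype_path).endswith((".vcf", ".vcf.gz")):
        ind_ids, dosages = _read_genotype_vcf(genotype_path, gmap)
    else:
        ind_ids, dosages = _read_genotype_tsv(genotype_path, gmap)

    ph = pd.read_csv(phenotype_path, sep="\t", dtype={"individual_id": str, "group": str})
    required = {"individual_id", "phenotype", "group"}
    if not required.issubset(ph.columns):
        raise FounderDataError(
            f"{phenotype_path}: phenotype file needs columns {sorted(required)}"
        )
    ph = ph.set_index("individual_id")
    if ph.index.has_duplicates:
        raise FounderDataError(f"{phenotype_path}: duplicated individual ids")
    missing = [i for i in ind_ids if i not in ph.index]
    if missing:
        raise FounderDataError(
            f"{phenotype_path}: no phenotype for genotyped individuals {missing[:5]}"
        )
    pheno = ph.loc[ind_ids, "phenotype"]
    if not np.issubdtype(pheno.dtype, np.number) or pheno.isna().any():
        bad = pheno.index[pd.to_numeric(pheno, errors="coerce").isna()][0]
        raise FounderDataError(
            f"{phenotype_path}: non-numeric phenotype for individual {bad!r}"
        )
    pop = HaplotypePopulation(
        _dosages_to_haplotypes(dosages), gmap, np.asarray(ind_ids, dtype=object)
    )
    return FounderSet(pop, pheno.to_numpy(dtype=float), ph.loc[ind_ids, "group"].to_numpy())


# ---------------------------------------------------------------------------
# Synthetic founders
# ---------------------------------------------------------------------------

def _ar1_haplotypes(
    n: int,
    gmap: GeneticMap,
    freqs: np.ndarray,
    ld_decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inbred haplotypes with AR(1) along-chromosome dependence.

    A latent Gaussian process with correlation ``ld_decay ** d`` between loci
    ``d`` cM apart is thresholded at the quantile of each locus's target
    allele frequency, so marginal frequencies are preserved while adjacent-
    locus correlation decays with map distance.
    """
    z = np.empty((n, gmap.n_loci))
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        pos = gmap.positions_cM[sl]
        z[:, sl.start] = rng.standard_normal(n)
        for j in range(1, len(pos)):
            r = ld_decay ** (pos[j] - pos[j - 1]) if ld_decay > 0 else 0.0
            z[:, sl.start + j] = r * z[:, sl.start + j - 1] + np.sqrt(
                1.0 - r * r
            ) * rng.standard_normal(n)
    thresholds = norm.ppf(np.clip(freqs, 0.0, 1.0))
    return (z < thresholds).astype(np.int8)


def generate_synthetic_founders(
    n_per_group: tuple[int, int] = (384, 380),
    n_loci: int = 1590,
    n_chromosomes: int = 7,
    ld_decay: float = 0.95,
    maf_floor: float = 0.05,
    fixed_fraction: float = 0.05,
    drift: float = 0.05,
    h2: float = 0.5,
    chrom_length_cM: float = 150.0,
    seed: int | np.random.Generator = 0,
) -> FounderSet:
    """Generate a two-group base population of fully inbred lines.

    Parameters
    ----------
    n_per_group
        Individuals in each of the two subpopulations.
    n_loci, n_chromosomes, chrom_length_cM
        Uniformly spaced biallelic loci over equally long chromosomes.
    ld_decay
        Per-centimorgan retention of the latent allele correlation between
        neighbouring loci (0 = independent loci, 1 = fully linked).
    maf_floor
        Lower bound of the minor-allele frequency for segregating loci.
    fixed_fraction
        Fraction of loci already fixed (frequency 0 or 1) in the union
        population, so that part of the genetic potential is out of reach
        from the start.
    drift
        Balding–Nichols divergence parameter between the two groups
        (0 = identical allele frequencies).
    h2
        Heritability of the provisional additive trait used to produce
        founder phenotypes.
    """
    if n_loci < n_chromosomes:
        raise ValueError("n_loci must be at least n_chromosomes")
    if not 0.0 <= ld_decay <= 1.0:
        raise ValueError("ld_decay must lie in [0, 1]")
    if not 0.0 < maf_floor < 0.5:
        raise ValueError("maf_floor must lie in (0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gmap = GeneticMap.uniform(n_loci, n_chromosomes, chrom_length_cM)

    base_freq = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_loci)
    fixed = rng.random(n_loci) < fixed_fraction
    base_freq[fixed] = rng.integers(0, 2, size=int(fixed.sum())).astype(float)

    haps, groups = [], []
    for label, n in zip(("A", "B"), n_per_group):
        if drift > 0:
            shape = (1.0 - drift) / drift
            gfreq = np.where(
                fixed,
                base_freq,
                rng.beta(
                    np.maximum(base_freq * shape, 1e-12),
                    np.maximum((1.0 - base_freq) * shape, 1e-12),
                ),
            )
        else:
            gfreq = base_freq
        h = _ar1_haplotypes(n, gmap, gfreq, ld_decay, rng)
        haps.append(np.repeat(h[:, None, :], 2, axis=1))  # inbred: identical pair
        groups.extend([label] * n)
    haplotypes = np.concatenate(haps, axis=0)
    ids = np.array(
        [f"{g}{i}" for g, n in zip(("A", "B"), n_per_group) for i in range(n)],
        dtype=object,
    )
    pop = HaplotypePopulation(haplotypes, gmap, ids)

    # provisional additive trait for founder phenotypes
    n_causal = min(100, max(2, n_loci // 4))
    causal = rng.choice(n_loci, size=n_causal, replace=False)
    effects = rng.standard_normal(n_causal)
    g = pop.dosages(causal) @ effects
    var_g = g.var()
    if var_g == 0:
        raise ValueError(
            "degenerate founder trait (no segregating causal loci); "
            "lower fixed_fraction or raise n_loci"
        )
    noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    phenotypes = g + rng.normal(0.0, noise_sd, size=pop.n_individuals)
    return FounderSet(pop, phenotypes, np.asarray(groups, dtype=object))


# ---------------------------------------------------------------------------
# Output (used by the CLI and for population snapshots)
# ---------------------------------------------------------------------------

def write_founders(founders: FounderSet, prefix: str | Path) -> dict[str, Path]:
    """Write genotype/map/phenotype TSVs readable by :func:`read_founders`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gmap = founders.haplotypes.gmap
    paths = {
        "genotypes": prefix.with_suffix(".genotypes.tsv"),
        "map": prefix.with_suffix(".map.tsv"),
        "phenotypes": prefix.with_suffix(".phenotypes.tsv"),
    }
    geno = pd.DataFrame(
        founders.haplotypes.dosages(),
        index=pd.Index(founders.haplotypes.ids, name="individual_id"),
        columns=list(gmap.locus_ids),
    )
    geno.to_csv(paths["genotypes"], sep="\t")
    chrom = np.repeat(
        np.asarray(gmap.chrom_names, dtype=object), np.diff(gmap.chrom_offsets)
    )
    pd.DataFrame(
        {"locus_id": list(gmap.locus_ids), "chromosome": chrom, "position_cM": gmap.positions_cM}
    ).to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame(
        {
            "individual_id": founders.haplotypes.ids,
            "phenotype": founders.phenotypes,
            "group": founders.group,
        }
    ).to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
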