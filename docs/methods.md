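# Methods

`breedsim` simulates a recurrent genomic-selection breeding program for a
self-pollinating crop and benchmarks practical selection strategies against
*oracle* strategies that are granted access to ground truth. This note
records the models, the calibration, the numerical choices, and the limits
of what the simulations can show.

## The breeding scheme

Each cycle operates on a breeding population of `n_couples ×
offspring_per_couple` lines (default 50 × 20 = 1000). In order:

1. **TP update.** The training population (TP) of the genomic prediction
   model is updated; newly recruited individuals are phenotyped as one batch
   and the ridge-regression BLUP (rrBLUP) model is refit by REML.
2. **Prediction.** GEBVs (`ĝ = Zû`) are computed for the whole breeding
   population with the refitted model.
3. **Parental selection.** 100 parents are selected and paired into 50
   couples by the configured method.
4. **Crossing.** Every couple produces 20 F1 offspring.
5. **Single-seed descent.** Two generations of selfing with one seed kept
   per line give 1000 F3 individuals — the next breeding population.
6. **Metrics** are recorded for the population the cycle operated on.

The first cycle is special: the 50 phenotypically best lines of each of the
two founder groups are paired rank-for-rank, and the initial TP is either
the complete base population (standard protocol) or a small random subset
(oracle-TP protocol). Standard updates use the *previous* cycle's model to
rank candidates, then refit — the update needs GEBVs before the refit can
happen; this ordering is stated here because it is easy to get subtly
wrong.

## Genetic architecture

`L` QTLs (default 100) are drawn uniformly without replacement from the
marker panel; the remaining loci are prediction markers and never causal.
Effects follow a geometric series: the k-th QTL contributes `+a^k` for the
favorable homozygote, `0` for the heterozygote and `-a^k` for the
unfavorable homozygote, with `a = (L-1)/(L+1)`. The magnitude ranking is a
uniform random permutation of the chosen loci and the favorable allele is
assigned by a fair coin per QTL, so favorable alleles can be rare — a
prerequisite for selection methods to differ. There is no dominance,
epistasis, mutation or de-novo variation: alleles only ever disappear.

Genetic values are rescaled by the ideotype value `Σ a^k`, so the *maximum
reachable genetic value* — signed effects of fixed QTLs plus favorable
effects of segregating QTLs — equals 1 while nothing unfavorable is fixed.
Fixation is assessed exactly (allele frequency 0 or 1) in the breeding
population only. The reachable maximum is non-increasing by construction;
the signed *fixed genetic value* is **not** monotone (fixing an unfavorable
allele lowers it), but the gap `max_reachable − fixed_value`, the
still-segregating favorable effect mass, is non-negative and shrinks.

## Meiosis

Recombination uses the Poisson count-location model with no interference
(Haldane's mapping): per chromosome, the crossover count is Poisson with
mean equal to the map length in Morgans, crossover positions are uniform,
and the starting strand is a fair coin. This is the standard neutral
assumption; crossover interference would shorten the tail of double
recombinants but is irrelevant at the 20+ cM marker spacings simulated
here. Validated against Haldane's closed-form recombinant fraction by Monte
Carlo (20,000 gametes, 3-SE band).

## Phenotypes

Phenotypes follow a three-environment model `y_ij = g_i + e_j + ε_ij`,
reported as the mean over environments. The environment effect `e_j ~
N(0, σE²)` is drawn once per environment per phenotyping batch and shared
by all individuals in the batch; residuals `ε_ij ~ N(0, σR²)` are
independent. The variance components are frozen before the first cycle:

    σE² = 8 · var(g)        σR² = 3 · (var(g)/h² − var(g))

with `var(g)` the genetic variance of the first F3 breeding population
(configurable to the founders instead) and `h² = 0.5`. With this scaling
the residual on the 3-environment mean has variance `var(g)(1/h² − 1)`, so
the realized heritability — environment means being estimable in a designed
trial, the shared `e_j` is excluded from the denominator — is `h²` exactly
in expectation. Environments are redrawn for every batch; a single frozen
draw would confound one environment realization with cycle effects.

## Prediction model

The rrBLUP model `y = 1β + Zu + ε`, `u ~ N(0, σu²I)`, `ε ~ N(0, σe²I)` is
fitted by REML, profiled to a one-dimensional bounded search over
`log λ ∈ [−10, 10]` (`λ = σe²/σu²`, tolerance 1e-8). Rotating the data into
the eigenbasis of the intercept-projected kernel `T K T'` (`K = ZZ'`, `T` a
Helmert contrast basis) makes each λ evaluation O(n), so a fit costs one
eigendecomposition. The profiled objective is unimodal in practice; the
analytic gradient at the optimum is checked in the tests. Boundary optima
are flagged, not errors — tiny or adversarial TPs legitimately push λ to a
bound, and downstream code only uses the resulting shrinkage.

All markers are kept, including monomorphic ones (their effects are shrunk
but well-defined since the ridge system is full-rank for λ > 0). GEBVs omit
the intercept; every consumer is rank-invariant to it.

Prediction error variances of candidate contrasts come from the
random-effect block of the inverted mixed-model-equations coefficient
matrix, `PEV(c) = σe² c'(Zc'Zc + λI)⁻¹c` with `Zc` the column-centered TP
genotypes, evaluated in observation space via the Woodbury identity and
verified against dense MME inversion in the tests. The default contrast
compares a candidate's GEBV to the TP mean (`c = z − z̄`); reliability is
`CD = 1 − PEV/(σu² c'c)`, defined as 1 for a null contrast.

## Parental selection

* **Truncation** — top `n_parents` GEBVs, random pairing.
* **Scoping** — preselect the top `⌈SR·n⌉` by GEBV (default SR = 0.3);
  build couples sequentially: P1 is the best remaining GEBV, P2 maximizes
  the F-score `F = Σᵢ var(Z*,ᵢ) pᵢ` over the selected parents plus the
  candidate (a candidate must be provisionally included for the score to
  react to it). After each parent joins, `pᵢ` is cleared at markers where
  both alleles are present among selected parents, and the all-ones reset
  applies when `p` empties. Couples alternate P1/P2 rather than selecting
  all P1s first: the selected set the F-score conditions on is a single
  growing set.
* **Chimeric scoping** — the first `N` couples per cycle use scoping
  mechanics, the rest choose *both* parents by F-score, sharing `p` and the
  selected set across the block. `N` follows a configurable
  `[cycle, N]` breakpoint ramp, since no canonical schedule exists.
* **Oracle parental selection** — greedy coverage of favorable QTL alleles:
  each candidate is scored by the number of QTLs where it carries at least
  one favorable allele (heterozygous counts as carrying), restricted to
  QTLs whose favorable allele is *reachable* — present somewhere in the
  population — but not yet carried by a selected parent; once every
  reachable favorable allele is covered, scoring runs over all QTLs.
  Restricting to reachable alleles matters: favorable alleles already lost
  to fixation can never be selected, and leaving them in the priority set
  permanently stalls the coverage phase, degrading all subsequent picks to
  tie-breaks (we observed exactly this failure mode before adding the
  reachability restriction).

Ties everywhere resolve by ascending individual id, making every selector
deterministic given its rng stream and invariant to input order. A parent
joins at most one couple.

## Training-population updates

Standard updates first drop the `n_drop_oldest` earliest-entry TP members
(default 150), then add `n_add` (default 150) by **top** GEBVs, **tails**
(75 highest + 75 lowest; the default protocol), or uniformly at **random**.
**PEVmean/CDmean** greedily add the candidate that minimizes the mean PEV
(maximizes mean CD) of the remaining population's contrasts, recomputed
after each accepted member at fixed variance components.

The **oracle TP update** alternates one addition and one removal attempt
per iteration, up to 50 each per cycle. A change is accepted only if it
*strictly* (tolerance 1e-10, preventing tie-cycling) increases the Pearson
correlation between GEBVs and true genetic values over the evaluation set —
the breeding population minus every individual accepted into the TP this
cycle. A candidate under evaluation is likewise excluded from its own
evaluation set, which keeps the accepted-step trace strictly increasing and
the comparison consistent before and after acceptance. Members added this
cycle are not removal candidates (no add/remove thrash). The whole
population is phenotyped as one batch up front so accepted candidates carry
phenotypes.

Cost control: λ is re-estimated by REML at loop start and after every 10
accepted changes; in between, every candidate is evaluated *exactly* at the
current λ through one-row bordered updates (additions) or Schur downdates
(removals) of the kernel-system inverse, so a full sweep over ~1000
candidates is a few matrix-vector products per candidate. A `full_reml`
flag restores per-evaluation REML for audits.

## Genetic relationship metric

The TP-to-population relationship uses the VanRaden matrix
`G = MM' / (2ΣPᵢ(1−Pᵢ))` with `M`'s columns `Zᵢ − 2(Pᵢ − 0.5)` and `Pᵢ` the
allele-1 frequency in the base population; the reported value is the mean
of the TP × population cross-block. Normalization: with frequencies
estimated from the base population itself, the mean off-diagonal (indeed
the full-matrix mean) base relationship is *identically zero* — the
centered columns of `M` sum to zero — so "scaled to the base-population
mean" is only well-defined against the mean **self**-relationship
(diagonal mean, ≈ 1 + F, 2 for fully inbred lines), which is what the
engine stores and divides by. The scaled metric starts near 0 and rises as
TP and population drift jointly away from base frequencies.

## Synthetic founders

The generator emulates the structure the simulator assumes about its real
founder panels: two subpopulations (defaults 384 and 380 fully inbred
lines), 1590 biallelic loci on 7 uniformly covered chromosomes of 150 cM
(map lengths are a modeling default, not an empirical claim), allele
frequencies uniform above a minor-allele floor of 0.05, around 5% of loci
already fixed in the union population (so the initial reachable maximum is
below 1), Balding–Nichols divergence between the groups (drift 0.05), and
along-chromosome LD from a latent Gaussian AR(1) process whose correlation
decays as `ld_decay^d` per d cM (default 0.95), thresholded to preserve
marginal frequencies. Founder phenotypes come from a provisional additive
trait (independent of the QTL model built later) at heritability 0.5.

What it does **not** emulate: U-shaped site-frequency spectra, realistic
haplotype-block structure from coalescent history, population-specific LD
decay, genotyping error or missingness. Passing tests therefore show that
the *methods* behave as designed under the stated structure, not that
effect sizes transfer to any particular crop panel.

## Scaled-down study conditions

The full design (1000 individuals × 50 cycles × 100 runs) is a
long-running computation; the package's acceptance suite runs a one-fifth
scale-down chosen to preserve the dynamical regime rather than just the
ratios: 200 individuals per cycle (10 couples × 20 offspring, 20 parents —
selection intensity preserved), founder groups of 80 + 80, and 636 loci
with L = 40 QTLs, keeping the full marker:QTL ratio. QTL count matters
beyond proportionality: with too few QTLs, lines carrying a favorable
allele at *every* QTL become common, the oracle's coverage score saturates
into ties, and small populations fix within 15 cycles, leaving correlations
undefined. At the chosen conditions populations still segregate over the
20-cycle horizon and reproduce the qualitative findings: oracle ≥ scoping ≥
truncation in final top-10 genetic value, an unchanged reachable maximum
under oracle selection, ≈ 30 cycles to approach the maximum, and oracle TP
updating far ahead of top updating in predictive performance. The TP
comparison is read as the mean predictive performance over cycles 1–8: at
toy scale a *successful* TP method drives the population to fixation before
cycle 15, where the Pearson correlation degenerates — the comparison window
ends where the metric stays defined for all arms.

## Known limitations

* Single trait, purely additive; no G×E beyond the shared environment
  effect; balanced three-environment design only.
* The external-package comparators of the original study design (a
  genetic-algorithm TP optimizer, an optimal-genomic-mating selector, and
  genebank-layer "deep scoping") are out of scope; the engine's
  method-dispatch seam is where such selectors would plug in.
* Populations are panmictic within the crossing block; no selfing
  avoidance is needed because parents are distinct by construction.
* The oracle TP update's greedy search is 1-step lookahead; it bounds what
  greedy phenotype/genotype-based TP construction can achieve, not the
  global optimum over TPs.
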