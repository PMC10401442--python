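"""Phenotype simulation under a frozen three-environment variance model.

An individual's phenotype is its genetic value plus an environment effect
shared by everyone phenotyped in the same batch and an individual-by-
environment residual, averaged over ``n_env`` environments:

    y_ij = g_i + e_j + eps_ij,      y_i = mean_j y_ij

with ``e_j ~ N(0, sigmaE2)`` and ``eps_ij ~ N(0, sigmaR2)``.  The variance
components are calibrated once against the genetic variance of the breeding
population before the first cycle (``var_g0``) and never change afterwards:

    sigmaE2 = 8 * var_g0
    sigmaR2 = n_env * (var_g0 / h2 - var_g0)

so that on the environment-averaged phenotype the residual variance is
``var_g0 * (1/h2 - 1)`` and the realised narrow-sense heritability (with the
shared environment effect excluded from the denominator, as in a trial where
environment means are estimable) equals ``h2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhenotypeModel", "build_phenotype_model", "simulate_phenotypes"]


@dataclass(frozen=True)
class PhenotypeModel:
    """Frozen variance components of the phenotyping process."""

    sigmaE2: float
    sigmaR2: float
    n_env: int
    h2: float
    var_g0: float


def build_phenotype_model(
    genetic_values: np.ndarray, h2: float = 0.5, n_env: int = 3
) -> PhenotypeModel:
    """Calibrate the variance components from the base genetic values.

    ``var_g0`` is the population-denominator variance of ``genetic_values``;
    it is computed once here and the returned model is immutable.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    g = np.asarray(genetic_values, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two genetic values to estimate var(g)")
    var_g0 = float(np.var(g))
    if var_g0 == 0.0:
        raise ValueError("degenerate genetic variance: all genetic values equal")
    sigmaE2 = 8.0 * var_g0
    sigmaR2 = n_env * (var_g0 / h2 - var_g0)
    return PhenotypeModel(sigmaE2, sigmaR2, n_env, h2, var_g0)


def simulate_phenotypes(
    genetic_values: np.ndarray,
    model: PhenotypeModel,
    rng: np.random.Generator,
    return_components: bool = False,
):
    """Phenotype one batch of individuals.

    One environment effect per environment is drawn for the whole batch;
    residuals are independent per individual and environment.  Returns the
    environment-averaged phenotypes (and, optionally, the per-individual
    averaged environment and residual components for diagnostics).
    """
    g = np.asarray(genetic_values, dtype=float)
    e = rng.normal(0.0, np.sqrt(model.sigmaE2), size=model.n_env)
    eps = rng.normal(0.0, np.sqrt(model.sigmaR2), size=(g.size, model.n_env))
    y = g + e.mean() + eps.mean(axis=1)
    if return_components:
        return y, np.full(g.size, e.mean()), eps.mean(axis=1)
    return y
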