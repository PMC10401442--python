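"""Ridge-regression BLUP: REML fitting, GEBVs, PEV and reliability.

The prediction model is the standard single-trait marker mixed model

    y = 1 * beta + Z u + eps,   u ~ N(0, sigma_u2 * I_k),  eps ~ N(0, sigma_e2 * I_n)

with ``Z`` the n x k marker dosage matrix of the training population (TP).
Both variance components are estimated by restricted maximum likelihood,
profiled down to a one-dimensional search over ``log(lambda)`` with
``lambda = sigma_e2 / sigma_u2``: after rotating the data into the
eigenbasis of the intercept-projected kernel ``Z Z'``, each candidate lambda
costs O(n) so the whole fit needs a single eigendecomposition.  Marker
effects follow from the observation-space solution,

    u_hat = Z' (Z Z' + lambda I)^(-1) (y - beta_hat),

which keeps every marker — including monomorphic ones, whose effects are
simply shrunk — and GEBVs are ``g_hat = Z u_hat`` (no intercept: GEBVs are
centered breeding values and all selection rules are rank-based).

Prediction error variances (PEV) and coefficients of determination (CD,
reliability) of candidate contrasts are computed from the mixed-model-
equations coefficient matrix, evaluated through the Woodbury identity so the
cost stays in observation space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, helmert
from scipy.optimize import minimize_scalar

__all__ = [
    "TrainingSet",
    "RRBLUPModel",
    "fit_rrblup",
    "predict_gebv",
    "prediction_error_variance",
    "reliability",
]

_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)
_XTOL = 1e-8


@dataclass
class TrainingSet:
    """Genotyped and phenotyped individuals used to fit the prediction model."""

    Z: np.ndarray
    y: np.ndarray
    entry_cycle: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.entry_cycle = np.asarray(self.entry_cycle, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        n = self.Z.shape[0]
        if not (len(self.y) == len(self.entry_cycle) == len(self.ids) == n):
            raise ValueError("rows of Z, y, entry_cycle and ids must align")
        if len(set(self.ids)) != n:
            raise ValueError("duplicated ids in training set")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]

    def subset(self, index: np.ndarray) -> "TrainingSet":
        index = np.asarray(index)
        return TrainingSet(
            self.Z[index], self.y[index], self.entry_cycle[index], self.ids[index]
        )

    def extended(
        self, Z: np.ndarray, y: np.ndarray, entry_cycle: int, ids: np.ndarray
    ) -> "TrainingSet":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return TrainingSet(
            np.vstack([self.Z, Z]),
            np.concatenate([self.y, np.atleast_1d(y)]),
            np.concatenate([self.entry_cycle, np.full(Z.shape[0], entry_cycle)]),
            np.concatenate([self.ids, np.asarray(ids, dtype=object)]),
        )


@dataclass(frozen=True)
class RRBLUPModel:
    """Fitted intercept, marker effects and REML variance components."""

    beta: float
    u_hat: np.ndarray
    sigma_u2: float
    sigma_e2: float
    converged: bool = True

    @property
    def lam(self) -> float:
        """Shrinkage ratio sigma_e2 / sigma_u2."""
        return self.sigma_e2 / self.sigma_u2

    def dump(self, path: str | Path) -> None:
        """Write the model as a plain-text key-value artifact."""
        with open(path, "w") as fh:
            fh.write(f"beta\t{float(self.beta)!r}\n")
            fh.write(f"sigma_u2\t{float(self.sigma_u2)!r}\n")
            fh.write(f"sigma_e2\t{float(self.sigma_e2)!r}\n")
            fh.write(f"converged\t{int(self.converged)}\n")
            fh.write("u_hat\t" + ",".join(repr(float(v)) for v in self.u_hat) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RRBLUPModel":
        fields: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, value = line.rstrip("\n").split("\t", 1)
                fields[key] = value
        return cls(
            beta=float(fields["beta"]),
            u_hat=np.array([float(v) for v in fields["u_hat"].split(",")]),
            sigma_u2=float(fields["sigma_u2"]),
            sigma_e2=float(fields["sigma_e2"]),
            converged=bool(int(fields["converged"])),
        )


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _restricted_spectrum(K: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the kernel projected off the intercept, and the squared
    rotated data, so the restricted likelihood is diagonal."""
    n = len(y)
    T = helmert(n, full=False)  # (n-1) x n, rows orthonormal and orthogonal to 1
    theta, U = eigh(T @ K @ T.T)
    eta = U.T @ (T @ y)
    return np.maximum(theta, 0.0), eta**2


def _neg_restricted_loglik(log_lam: float, theta: np.ndarray, eta2: np.ndarray) -> float:
    lam = np.exp(log_lam)
    d = theta + lam
    sigma_u2 = np.mean(eta2 / d)
    return 0.5 * (len(theta) * np.log(sigma_u2) + np.sum(np.log(d)))


def _profile_reml(K: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Return (lambda, sigma_u2, sigma_e2, converged) maximizing the REML."""
    theta, eta2 = _restricted_spectrum(K, y)
    res = minimize_scalar(
        _neg_restricted_loglik,
        bounds=_LOG_LAMBDA_BOUNDS,
        args=(theta, eta2),
        method="bounded",
        options={"xatol": _XTOL},
    )
    log_lam = float(res.x)
    lo, hi = _LOG_LAMBDA_BOUNDS
    at_boundary = log_lam < lo + 1e-3 or log_lam > hi - 1e-3
    lam = float(np.exp(log_lam))
    sigma_u2 = float(np.mean(eta2 / (theta + lam)))
    return lam, sigma_u2, lam * sigma_u2, bool(res.success) and not at_boundary


def _gls_intercept(K_lam_chol, y: np.ndarray) -> float:
    """Generalized-least-squares intercept at fixed variance ratio."""
    ones = np.ones_like(y)
    Vi1 = cho_solve(K_lam_chol, ones)
    return float((Vi1 @ y) / (Vi1 @ ones))


def fit_rrblup(tp: TrainingSet, lam: float | None = None) -> RRBLUPModel:
    """Fit the marker mixed model to a training set by REML.

    Parameters
    ----------
    tp
        Training set with aligned genotypes and phenotypes.
    lam
        If given, skip the REML search and solve at this fixed variance
        ratio (``sigma_u2`` is then still profiled from the data).
    """
    if tp.n < 3:
        raise ValueError("need at least 3 training individuals")
    if np.var(tp.y) == 0.0:
        raise ValueError("phenotypes have zero variance; REML is undefined")
    K = tp.Z @ tp.Z.T
    if lam is None:
        lam, sigma_u2, sigma_e2, converged = _profile_reml(K, tp.y)
    else:
        theta, eta2 = _restricted_spectrum(K, tp.y)
        sigma_u2 = float(np.mean(eta2 / (theta + lam)))
        sigma_e2 = lam * sigma_u2
        converged = True
    A = K + lam * np.eye(tp.n)
    chol = cho_factor(A, lower=True)
    beta = _gls_intercept(chol, tp.y)
    alpha = cho_solve(chol, tp.y - beta)
    u_hat = tp.Z.T @ alpha
    return RRBLUPModel(beta, u_hat, sigma_u2, sigma_e2, converged)


def predict_gebv(model: RRBLUPModel, genotypes: np.ndarray) -> np.ndarray:
    """Genomic estimated breeding values ``g_hat = Z u_hat`` (centered; no
    intercept, so rankings are unaffected)."""
    Z = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if Z.shape[1] != len(model.u_hat):
        raise ValueError(
            f"genotypes have {Z.shape[1]} markers, model has {len(model.u_hat)}"
        )
    return Z @ model.u_hat


# ---------------------------------------------------------------------------
# Prediction error variance and reliability
# ---------------------------------------------------------------------------

def _candidate_contrasts(
    tp_Z: np.ndarray, candidates: np.ndarray, contrast: str
) -> np.ndarray:
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    if contrast == "candidate_minus_mean":
        return C - tp_Z.mean(axis=0)
    if contrast == "candidate":
        return C
    raise ValueError(f"unknown contrast {contrast!r}")


def prediction_error_variance(
    tp: TrainingSet,
    model: RRBLUPModel,
    candidates: np.ndarray,
    contrast: str = "candidate_minus_mean",
) -> np.ndarray:
    """PEV of each candidate's GEBV contrast at the fitted components.

    For a marker-space contrast ``c`` the PEV is
    ``sigma_e2 * c' (Zc'Zc + lambda I_k)^(-1) c`` with ``Zc`` the
    column-centered TP genotypes — the random-effect block of the inverted
    mixed-model-equations coefficient matrix after absorbing the intercept.
    The default contrast compares the candidate's GEBV to the TP mean.
    Evaluated through the Woodbury identity in observation space.
    """
    lam = model.lam
    Zc = tp.Z - tp.Z.mean(axis=0)
    C = _candidate_contrasts(tp.Z, candidates, contrast)
    A = Zc @ Zc.T + lam * np.eye(tp.n)
    V = Zc @ C.T  # n x m
    S = np.linalg.solve(A, V)
    cc = np.einsum("ij,ij->i", C, C)
    pev = (model.sigma_e2 / lam) * (cc - np.einsum("ij,ij->j", V, S))
    return np.maximum(pev, 0.0)


def reliability(
    tp: TrainingSet,
    model: RRBLUPModel,
    candidates: np.ndarray,
    contrast: str = "candidate_minus_mean",
) -> np.ndarray:
    """Coefficient of determination ``CD = 1 - PEV / (sigma_u2 * c'c)``,
    bounded in [0, 1].  A null contrast (candidate equal to the TP mean) is
    predicted without error and scores 1."""
    pev = prediction_error_variance(tp, model, candidates, contrast)
    C = _candidate_contrasts(tp.Z, candidates, contrast)
    cc = np.einsum("ij,ij->i", C, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        cd = 1.0 - pev / (model.sigma_u2 * cc)
    cd[cc == 0.0] = 1.0
    return np.clip(cd, 0.0, 1.0)
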