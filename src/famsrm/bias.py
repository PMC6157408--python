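"""Analytic bias machinery for rank-deficient Bartlett scoring.

For a full-rank loading matrix the Bartlett score-coefficient matrix
satisfies ``FSC_B Lambda = I``, which is what makes Bartlett scores
conditionally unbiased as regression outcomes.  The SRM loading matrix has
rank 7 of 9, so the pseudo-inverse form yields instead

    FSC_B Lambda = P = (Lambda' Theta^-1 Lambda)^+ Lambda' Theta^-1 Lambda,

the orthogonal projector onto the row space of Lambda.  When the latent
effects are regressed on external predictors with true coefficient matrix
Gamma, the expected estimated coefficients are ``P Gamma`` rather than
Gamma: the family-effect row shrinks to 2/3 of its true value whenever the
actor and partner coefficient blocks each sum to zero columnwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MeasurementMatrices, SRMParameterSet, build_loading_matrix, model_implied_moments
from .scoring import RANK_RTOL

__all__ = [
    "ProjectorReport",
    "bartlett_projection_matrix",
    "predicted_bartlett_bias",
    "regression_identity_check",
]


@dataclass
class ProjectorReport:
    """The Bartlett projector and its structural diagnostics."""

    projector: np.ndarray = field(repr=False)
    rank: int = 0
    is_symmetric: bool = False
    is_idempotent: bool = False
    theta_used: np.ndarray = field(default=None, repr=False)

    def rounded(self, decimals: int = 3) -> np.ndarray:
        """Display form (internal computations are full precision)."""
        return np.round(self.projector, decimals)


def bartlett_projection_matrix(
    loading: np.ndarray | None = None, resid_cov: np.ndarray | None = None
) -> ProjectorReport:
    """Compute ``P = (L' Th^-1 L)^+ L' Th^-1 L`` with diagnostics.

    Defaults to the SRM loading matrix and the standard simulation
    residual covariance; P is invariant to the choice of any positive
    definite Theta for a fixed loading matrix.
    """
    lam = build_loading_matrix() if loading is None else np.asarray(loading, dtype=float)
    if resid_cov is None:
        resid_cov = model_implied_moments(SRMParameterSet.simulation_defaults()).resid_cov
    theta = np.asarray(resid_cov, dtype=float)
    eigmin = float(np.linalg.eigvalsh(theta)[0])
    if eigmin <= 0:
        raise ValueError(f"resid_cov must be positive definite (min eigenvalue {eigmin:.3e})")
    th_inv = np.linalg.inv(theta)
    m = lam.T @ th_inv @ lam
    proj = np.linalg.pinv(m, rcond=RANK_RTOL) @ m
    tol = 1e-10
    return ProjectorReport(
        projector=proj,
        rank=int(np.linalg.matrix_rank(proj, tol=tol * np.linalg.norm(proj, 2))),
        is_symmetric=bool(np.allclose(proj, proj.T, atol=tol)),
        is_idempotent=bool(np.allclose(proj @ proj, proj, atol=tol)),
        theta_used=theta,
    )


def _check_zero_sum(gamma: np.ndarray, atol: float = 1e-8) -> None:
    act_sum = gamma[1:5].sum(axis=0)
    par_sum = gamma[5:9].sum(axis=0)
    if np.any(np.abs(act_sum) > atol) or np.any(np.abs(par_sum) > atol):
        raise ValueError(
            "structural coefficient matrix must have zero-sum actor and partner "
            f"blocks per predictor (actor sums {act_sum}, partner sums {par_sum})"
        )


def predicted_bartlett_bias(
    gamma: np.ndarray, projector: np.ndarray | None = None
) -> np.ndarray:
    """Expected coefficient matrix ``P Gamma`` for pseudo-inverse Bartlett
    scores used as regression outcomes.

    ``gamma`` is 9xK in factor order (family, four actor, four partner
    rows) and must satisfy the zero-sum actor/partner constraints.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] != 9:
        raise ValueError("gamma must have 9 rows (factor order)")
    _check_zero_sum(gamma)
    P = bartlett_projection_matrix().projector if projector is None else projector
    return P @ gamma


def regression_identity_check(
    fit: MeasurementMatrices, loading_true: np.ndarray | None = None
) -> float:
    """Residual of the regression-score unbiasedness identity.

    Computes ``max | [ (FSC_R Sigma FSC_R')^+ FSC_R Lambda Psi - I ] Q |``
    where FSC_R comes from ``fit`` and Q projects onto the identified
    subspace range(Psi Lambda'), the span of covariance vectors the score
    system can produce.  A small residual certifies that regression scores
    used as predictors recover without bias any structural coefficient
    vector lying in that subspace (Q = I in the full-rank case, so the
    identity is then global).  ``loading_true`` lets the caller probe
    sensitivity: the covariance term uses the true loading matrix while
    FSC_R uses the fitted one, so a misspecified fit breaks the identity.
    """
    sigma = fit.sigma
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("Sigma is singular") from exc
    lam_true = fit.loading if loading_true is None else np.asarray(loading_true, float)
    fsc = fit.factor_cov @ fit.loading.T @ sigma_inv
    var_scores = fsc @ sigma @ fsc.T
    m = np.linalg.pinv(var_scores, rcond=RANK_RTOL) @ fsc @ lam_true @ fit.factor_cov
    u, s, _ = np.linalg.svd(fit.factor_cov @ lam_true.T)
    r = int((s > RANK_RTOL * s[0]).sum())
    q = u[:, :r] @ u[:, :r].T
    resid = (m - np.eye(m.shape[0])) @ q
    return float(np.max(np.abs(resid)))
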