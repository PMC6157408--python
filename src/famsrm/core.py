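"""Core structures of the four-member family social relations model (SRM).

A round-robin measurement X_ij (role i rates role j, no self-ratings)
decomposes as

    X_ij = Fam + Act_i + Par_j + Rel_ij + eps_ij,

with one indicator per dyad, so the relationship effect is absorbed in the
residual.  The measurement model is a confirmatory factor model with all
loadings fixed to one: 12 dyadic indicators load on 9 latent effects
(1 family, 4 actor, 4 partner).  The loading matrix has rank 7; its
two-dimensional null space (family vs. sum-of-actors and family vs.
sum-of-partners) is what makes Bartlett-type scoring rank-deficient.

This module defines the role/dyad conventions, the interpretable parameter
set (variances, reciprocities, constrained means), and the construction of
the model-implied moment matrices (Lambda, Psi, Theta, mu, Sigma).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "DYADS",
    "FACTORS",
    "UNORDERED_PAIRS",
    "RoleConventions",
    "SRMParameterSet",
    "MeasurementMatrices",
    "build_loading_matrix",
    "model_implied_moments",
    "variance_decomposition",
    "srm_means_from_observed",
]

#: Canonical role order: Mother, Father, Target adolescent, Sibling.
ROLES: tuple[str, ...] = ("M", "F", "T", "S")

#: The 12 ordered actor-partner pairs in actor-major order.
DYADS: tuple[str, ...] = tuple(a + p for a in ROLES for p in ROLES if a != p)

#: Latent effects: family, then actor effects, then partner effects.
FACTORS: tuple[str, ...] = (
    ("fam",) + tuple(f"act_{r}" for r in ROLES) + tuple(f"par_{r}" for r in ROLES)
)

#: The 6 unordered role pairs carrying dyadic reciprocity covariances.
UNORDERED_PAIRS: tuple[str, ...] = ("M/F", "M/T", "M/S", "F/T", "F/S", "T/S")


def _pair_key(a: str, b: str) -> str:
    i, j = sorted((a, b), key=ROLES.index)
    return f"{i}/{j}"


@dataclass(frozen=True)
class RoleConventions:
    """Fixed ordering of roles, dyads and latent factors.

    The default instance is the canonical convention used throughout the
    package; constructing a variant with missing/self/duplicated dyads or a
    malformed factor list raises ``ValueError``.
    """

    roles: tuple[str, ...] = ROLES
    dyads: tuple[str, ...] = DYADS
    factors: tuple[str, ...] = FACTORS

    def __post_init__(self) -> None:
        if len(self.roles) != 4 or len(set(self.roles)) != 4:
            raise ValueError("exactly four distinct roles required")
        if len(self.dyads) != 12 or len(set(self.dyads)) != 12:
            raise ValueError("exactly 12 distinct ordered dyads required")
        for d in self.dyads:
            if len(d) != 2 or d[0] == d[1] or not set(d) <= set(self.roles):
                raise ValueError(f"invalid dyad {d!r}")
        if len(self.factors) != 9:
            raise ValueError("factor list must have 9 entries (1 family + 4 actor + 4 partner)")

    @property
    def n_roles(self) -> int:
        return len(self.roles)

    def dyad_index(self, dyad: str) -> int:
        return self.dyads.index(dyad)


def _zero_roles() -> dict[str, float]:
    return {r: 0.0 for r in ROLES}


def _zero_dyads() -> dict[str, float]:
    return {d: 0.0 for d in DYADS}


@dataclass
class SRMParameterSet:
    """Interpretable SRM parameters.

    Covariance structure: the family variance, role-specific actor and
    partner variances, generalized reciprocities (same-role actor-partner
    covariances) and, per dyad, the relationship+error variance with dyadic
    reciprocities (covariance between eps_ij and eps_ji).

    Mean structure: family mean, actor means (sum zero), partner means
    (sum zero) and relationship means that are doubly centered (for each
    actor the sum over its three partners is zero, and likewise per
    partner), leaving 12 free mean parameters in total.
    """

    fam_var: float = 1.0
    act_var: dict[str, float] = field(default_factory=lambda: {r: 1.0 for r in ROLES})
    par_var: dict[str, float] = field(default_factory=lambda: {r: 1.0 for r in ROLES})
    gen_recip: dict[str, float] = field(default_factory=_zero_roles)
    resid_var: dict[str, float] = field(default_factory=lambda: {d: 1.0 for d in DYADS})
    dyad_recip: dict[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in UNORDERED_PAIRS}
    )
    mean_fam: float = 0.0
    mean_act: dict[str, float] = field(default_factory=_zero_roles)
    mean_par: dict[str, float] = field(default_factory=_zero_roles)
    mean_rel: dict[str, float] = field(default_factory=_zero_dyads)

    @classmethod
    def simulation_defaults(cls, recip_signs: dict[str, float] | None = None) -> "SRMParameterSet":
        """The study's standard data-generating variance components.

        Family variance 1, actor variances 1, partner variances 0.5,
        relationship(+error) variances 1.5, generalized reciprocities of
        magnitude 0.05 (positive for M and T, negative for F and S by
        default; override via ``recip_signs``), dyadic reciprocities 0.02.
        """
        signs = {"M": 1.0, "F": -1.0, "T": 1.0, "S": -1.0}
        if recip_signs is not None:
            signs.update(recip_signs)
        return cls(
            fam_var=1.0,
            act_var={r: 1.0 for r in ROLES},
            par_var={r: 0.5 for r in ROLES},
            gen_recip={r: 0.05 * signs[r] for r in ROLES},
            resid_var={d: 1.5 for d in DYADS},
            dyad_recip={p: 0.02 for p in UNORDERED_PAIRS},
        )

    # ------------------------------------------------------------------
    # validation

    def validate_for_generation(self) -> None:
        """Check non-negativity of variances and mean-structure constraints."""
        if self.fam_var < 0:
            raise ValueError("fam_var must be >= 0 for data generation")
        for name, dct in (("act_var", self.act_var), ("par_var", self.par_var)):
            for r, v in dct.items():
                if v < 0:
                    raise ValueError(f"{name}[{r}] must be >= 0 for data generation")
        for d, v in self.resid_var.items():
            if v < 0:
                raise ValueError(f"resid_var[{d}] must be >= 0 for data generation")
        self.validate_means()

    def validate_means(self, atol: float = 1e-8) -> None:
        if abs(sum(self.mean_act.values())) > atol:
            raise ValueError("actor means must sum to zero")
        if abs(sum(self.mean_par.values())) > atol:
            raise ValueError("partner means must sum to zero")
        for a in ROLES:
            s = sum(self.mean_rel[a + p] for p in ROLES if p != a)
            if abs(s) > atol:
                raise ValueError(f"relationship means for actor {a} must sum to zero")
        for p in ROLES:
            s = sum(self.mean_rel[a + p] for a in ROLES if a != p)
            if abs(s) > atol:
                raise ValueError(f"relationship means for partner {p} must sum to zero")

    # ------------------------------------------------------------------
    # conversions

    def mu(self) -> np.ndarray:
        """Model-implied 12-vector of dyadic means (actor-major dyad order)."""
        return np.array(
            [
                self.mean_fam + self.mean_act[d[0]] + self.mean_par[d[1]] + self.mean_rel[d]
                for d in DYADS
            ]
        )

    def covariance_vector(self) -> np.ndarray:
        """The 31 covariance-structure parameters in canonical order.

        Order: fam_var, act_var (M,F,T,S), par_var (M,F,T,S), gen_recip
        (M,F,T,S), resid_var (12 dyads), dyad_recip (6 pairs).
        """
        return np.array(
            [self.fam_var]
            + [self.act_var[r] for r in ROLES]
            + [self.par_var[r] for r in ROLES]
            + [self.gen_recip[r] for r in ROLES]
            + [self.resid_var[d] for d in DYADS]
            + [self.dyad_recip[p] for p in UNORDERED_PAIRS]
        )

    @classmethod
    def from_vectors(cls, cov: np.ndarray, mu: np.ndarray) -> "SRMParameterSet":
        """Inverse of (:meth:`covariance_vector`, :meth:`mu`)."""
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (31,):
            raise ValueError("covariance vector must have 31 entries")
        means = srm_means_from_observed(mu)
        return cls(
            fam_var=float(cov[0]),
            act_var={r: float(cov[1 + i]) for i, r in enumerate(ROLES)},
            par_var={r: float(cov[5 + i]) for i, r in enumerate(ROLES)},
            gen_recip={r: float(cov[9 + i]) for i, r in enumerate(ROLES)},
            resid_var={d: float(cov[13 + i]) for i, d in enumerate(DYADS)},
            dyad_recip={p: float(cov[25 + i]) for i, p in enumerate(UNORDERED_PAIRS)},
            mean_fam=means["mean_fam"],
            mean_act=means["mean_act"],
            mean_par=means["mean_par"],
            mean_rel=means["mean_rel"],
        )

    def replace(self, **kwargs) -> "SRMParameterSet":
        return dataclasses.replace(self, **kwargs)


COVARIANCE_PARAM_NAMES: tuple[str, ...] = (
    ("fam_var",)
    + tuple(f"act_var_{r}" for r in ROLES)
    + tuple(f"par_var_{r}" for r in ROLES)
    + tuple(f"gen_recip_{r}" for r in ROLES)
    + tuple(f"resid_var_{d}" for d in DYADS)
    + tuple(f"dyad_recip_{p}" for p in UNORDERED_PAIRS)
)


def build_loading_matrix(conventions: RoleConventions | None = None) -> np.ndarray:
    """The 12x9 SRM loading matrix with all paths fixed to one.

    Row for dyad (i, j) has ones exactly at the family column, the actor-i
    column and the partner-j column.  rank = 7.
    """
    conv = conventions or RoleConventions()
    lam = np.zeros((len(conv.dyads), len(conv.factors)))
    for k, d in enumerate(conv.dyads):
        a, p = d[0], d[1]
        lam[k, conv.factors.index("fam")] = 1.0
        lam[k, conv.factors.index(f"act_{a}")] = 1.0
        lam[k, conv.factors.index(f"par_{p}")] = 1.0
    return lam


@dataclass
class MeasurementMatrices:
    """Model-implied moment matrices of the SRM measurement model."""

    loading: np.ndarray       # 12x9 Lambda
    factor_cov: np.ndarray    # 9x9 Psi
    resid_cov: np.ndarray     # 12x12 Theta
    mean_vector: np.ndarray   # 12-vector mu

    @property
    def sigma(self) -> np.ndarray:
        """Sigma = Lambda Psi Lambda' + Theta."""
        return self.loading @ self.factor_cov @ self.loading.T + self.resid_cov

    def validate_patterns(self, atol: float = 0.0) -> None:
        """Reject nonzeros outside the SRM sparsity patterns of Psi / Theta."""
        psi_ok = np.zeros((9, 9), dtype=bool)
        np.fill_diagonal(psi_ok, True)
        for r in ROLES:
            i, j = FACTORS.index(f"act_{r}"), FACTORS.index(f"par_{r}")
            psi_ok[i, j] = psi_ok[j, i] = True
        if np.any(np.abs(self.factor_cov[~psi_ok]) > atol):
            raise ValueError("factor_cov violates the SRM pattern (diagonal + same-role actor-partner only)")
        th_ok = np.zeros((12, 12), dtype=bool)
        np.fill_diagonal(th_ok, True)
        for k, d in enumerate(DYADS):
            th_ok[k, DYADS.index(d[1] + d[0])] = True
        if np.any(np.abs(self.resid_cov[~th_ok]) > atol):
            raise ValueError("resid_cov violates the SRM pattern (diagonal + reciprocal-dyad only)")
        if not np.allclose(self.resid_cov, self.resid_cov.T):
            raise ValueError("resid_cov must be symmetric")


def model_implied_moments(params: SRMParameterSet) -> MeasurementMatrices:
    """Construct (Lambda, Psi, Theta, mu) from an SRM parameter set.

    Sigma is then Lambda Psi Lambda' + Theta, and mu_ij = mean_fam +
    mean_act_i + mean_par_j + mean_rel_ij.
    """
    lam = build_loading_matrix()
    psi = np.zeros((9, 9))
    psi[0, 0] = params.fam_var
    for i, r in enumerate(ROLES):
        psi[1 + i, 1 + i] = params.act_var[r]
        psi[5 + i, 5 + i] = params.par_var[r]
        psi[1 + i, 5 + i] = psi[5 + i, 1 + i] = params.gen_recip[r]
    theta = np.zeros((12, 12))
    for k, d in enumerate(DYADS):
        theta[k, k] = params.resid_var[d]
        rk = DYADS.index(d[1] + d[0])
        theta[k, rk] = theta[rk, k] = params.dyad_recip[_pair_key(d[0], d[1])]
    mm = MeasurementMatrices(loading=lam, factor_cov=psi, resid_cov=theta,
                             mean_vector=params.mu())
    mm.validate_patterns()
    return mm


def variance_decomposition(params: SRMParameterSet) -> pd.DataFrame:
    """Per-dyad shares of variance: family, actor, partner, relationship+error.

    Var(X_ij) = Var(Fam) + Var(Act_i) + Var(Par_j) + Var(Rel_ij + eps_ij);
    the four shares sum to one for every dyad.
    """
    rows = []
    for d in DYADS:
        parts = np.array(
            [
                params.fam_var,
                params.act_var[d[0]],
                params.par_var[d[1]],
                params.resid_var[d],
            ]
        )
        if np.any(parts < 0):
            raise ValueError(f"negative variance component for dyad {d}")
        total = parts.sum()
        rows.append([d, total, *(parts / total)])
    return pd.DataFrame(
        rows,
        columns=["dyad", "total_var", "family", "actor", "partner", "relationship"],
    ).set_index("dyad")


def srm_means_from_observed(mu: np.ndarray) -> dict:
    """Decompose a complete 12-vector of dyadic means into SRM mean components.

    The family mean is the average of the 12 entries; actor and partner
    components are the classical two-way weights for a round-robin table
    without self-ratings at family size n = 4,

        act_i = (9/8) rowmean_i + (3/8) colmean_i - (3/2) grand,
        par_j = (9/8) colmean_j + (3/8) rowmean_j - (3/2) grand,

    and the relationship components are the doubly-centered remainders.
    The decomposition is exact and unique under the zero-sum constraints,
    so it round-trips through :meth:`SRMParameterSet.mu`.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (12,) or np.any(~np.isfinite(mu)):
        raise ValueError("mu must be a complete (finite) 12-vector")
    table = {d: mu[k] for k, d in enumerate(DYADS)}
    grand = mu.mean()
    row = {a: np.mean([table[a + p] for p in ROLES if p != a]) for a in ROLES}
    col = {p: np.mean([table[a + p] for a in ROLES if a != p]) for p in ROLES}
    act = {r: 9.0 / 8.0 * row[r] + 3.0 / 8.0 * col[r] - 1.5 * grand for r in ROLES}
    par = {r: 9.0 / 8.0 * col[r] + 3.0 / 8.0 * row[r] - 1.5 * grand for r in ROLES}
    rel = {d: table[d] - grand - act[d[0]] - par[d[1]] for d in DYADS}
    return {"mean_fam": float(grand), "mean_act": act, "mean_par": par, "mean_rel": rel}
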