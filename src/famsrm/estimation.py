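"""Maximum-likelihood estimation of the family SRM.

Three model kinds share one structured multivariate-normal likelihood:

* the measurement model alone, fitted either on complete families
  (:func:`fit_srm_ml`) or casewise over missing-data patterns
  (:func:`fit_srm_fiml`);
* the joint SEM with role-specific outcomes regressed on (family, own
  actor, own partner) effects ("SRM as predictor");
* the joint MIMIC-style SEM with the nine SRM effects regressed on
  external predictors under zero-sum identification constraints
  ("SRM as outcome").

Families are grouped by missing-data pattern; each pattern contributes
through its sufficient statistics (a moment matrix of the observed
indicators, any fixed regressors, and a constant), so a likelihood or
gradient evaluation costs O(#patterns x dim^3) regardless of sample size.
Gradients are analytic throughout: the model-implied covariance is
Sigma = L Psi L' + Theta with L fixed (measurement) or linear in the free
structural coefficients (joint SEM), so every parameter's derivative is a
sparse contraction of the per-pattern gradient matrix.

Variances are optimized unconstrained, so improper (Heywood-type)
solutions can occur; they surface as a non-positive-definite fitted Sigma
and are flagged via ``converged=False`` rather than prevented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .core import (
    COVARIANCE_PARAM_NAMES,
    DYADS,
    FACTORS,
    ROLES,
    UNORDERED_PAIRS,
    MeasurementMatrices,
    SRMParameterSet,
    build_loading_matrix,
    model_implied_moments,
    srm_means_from_observed,
)
from .data import RoundRobinData

log = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "StructuralSpec",
    "fit_srm_ml",
    "fit_srm_fiml",
    "fit_joint_sem",
    "wald_tests",
]

GRAD_TOL = 1e-6          # optimizer projected-gradient tolerance
PD_EIG_TOL = 1e-10       # smallest eigenvalue for the fitted Sigma to count as PD
_PENALTY = 1e7           # soft barrier weight outside the PD region

MU_PARAM_NAMES = tuple(f"mu_{d}" for d in DYADS)

_LAMBDA = build_loading_matrix()


# ======================================================================
# pattern-grouped sufficient statistics


@dataclass
class _PatternStats:
    idx: tuple[int, ...]      # observed coordinates of the joint vector
    n: int
    W: np.ndarray             # sum of w w', w = (v_obs, z, 1)


def _collect_patterns(V: np.ndarray, Z: np.ndarray | None) -> tuple[list[_PatternStats], int]:
    """Group rows of V (NaN = missing) by pattern; Z columns are always observed.

    Returns the per-pattern statistics and the count of rows with no
    observed coordinate (they contribute nothing to the likelihood).
    """
    mask = ~np.isnan(V)
    n_empty = 0
    stats_list: list[_PatternStats] = []
    codes = np.packbits(mask, axis=1)
    _, inverse = np.unique(codes, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        idx = tuple(np.flatnonzero(mask[rows[0]]))
        if len(idx) == 0:
            n_empty += len(rows)
            continue
        X = V[np.ix_(rows, list(idx))]
        parts = [X]
        if Z is not None:
            parts.append(Z[rows])
        parts.append(np.ones((len(rows), 1)))
        w = np.hstack(parts)
        stats_list.append(_PatternStats(idx=idx, n=len(rows), W=w.T @ w))
    return stats_list, n_empty


class _StructuredMVN:
    """Negative log-likelihood and gradient for mu(theta), B(theta), Sigma(theta)."""

    def __init__(self, patterns: list[_PatternStats], dim: int, n_regressors: int):
        self.patterns = patterns
        self.dim = dim
        self.K = n_regressors
        self.n_total = sum(p.n for p in patterns)

    # subclasses implement: unpack(theta) -> (mu, B, Sigma); map_grads(...)

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        mu, B, Sigma = self.unpack(theta)
        d = self.dim
        # soft PD barrier on the full Sigma: principal submatrices inherit PD
        eigmin = float(np.linalg.eigvalsh(Sigma)[0])
        if eigmin <= 1e-12:
            vals, vecs = np.linalg.eigh(Sigma)
            v = vecs[:, 0]
            f = _PENALTY * (1.0 + (1e-12 - eigmin))
            g_sigma = -_PENALTY * np.outer(v, v)
            grad = self.map_grads(np.zeros(d),
                                  np.zeros((d, self.K)) if self.K else None,
                                  g_sigma, theta)
            return f, grad
        f = 0.0
        g_mu = np.zeros(d)
        g_B = np.zeros((d, self.K)) if self.K else None
        g_sigma = np.zeros((d, d))
        for p in self.patterns:
            sub = list(p.idx)
            dp = len(sub)
            Sp = Sigma[np.ix_(sub, sub)]
            c, low = cho_factor(Sp)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            # T = [I, -B_obs, -mu_obs] so that r = T w
            cols = dp + self.K + 1
            T = np.zeros((dp, cols))
            T[:, :dp] = np.eye(dp)
            if self.K:
                T[:, dp:dp + self.K] = -B[sub, :]
            T[:, -1] = -mu[sub]
            TW = T @ p.W
            R = TW @ T.T
            A_R = cho_solve((c, low), R)
            f += 0.5 * (p.n * (logdet + dp * np.log(2.0 * np.pi)) + np.trace(A_R))
            A = cho_solve((c, low), np.eye(dp))
            GS = 0.5 * (p.n * A - A @ R @ A)
            g_sigma[np.ix_(sub, sub)] += GS
            ATW = A @ TW
            if self.K:
                g_B[sub, :] += -ATW[:, dp:dp + self.K]
            g_mu[sub] += -ATW[:, -1]
        return f, self.map_grads(g_mu, g_B, g_sigma, theta)

    # ------------------------------------------------------------------
    def fit(self, theta0: np.ndarray, maxiter: int = 2000):
        res = optimize.minimize(
            self.value_and_grad, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                     "gtol": GRAD_TOL, "ftol": 1e-12},
        )
        return res

    def hessian(self, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        """Observed information: central differences of the analytic gradient."""
        p = len(theta)
        H = np.zeros((p, p))
        for k in range(p):
            h = rel_step * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            _, gp = self.value_and_grad(tp)
            _, gm = self.value_and_grad(tm)
            H[k] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


def _psi_theta_from_cov(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 31-vector -> (Psi 9x9, Theta 12x12)."""
    psi = np.zeros((9, 9))
    psi[0, 0] = cov[0]
    for i in range(4):
        psi[1 + i, 1 + i] = cov[1 + i]
        psi[5 + i, 5 + i] = cov[5 + i]
        psi[1 + i, 5 + i] = psi[5 + i, 1 + i] = cov[9 + i]
    theta = np.zeros((12, 12))
    for k, d in enumerate(DYADS):
        theta[k, k] = cov[13 + k]
    for q, pair in enumerate(UNORDERED_PAIRS):
        a, b = pair.split("/")
        i, j = DYADS.index(a + b), DYADS.index(b + a)
        theta[i, j] = theta[j, i] = cov[25 + q]
    return psi, theta


_RECIP_IDX = [(DYADS.index(p.split("/")[0] + p.split("/")[1]),
               DYADS.index(p.split("/")[1] + p.split("/")[0]))
              for p in UNORDERED_PAIRS]


def _cov_grad_from_psi_theta(g_psi: np.ndarray, g_theta: np.ndarray) -> np.ndarray:
    """Contract symmetric-matrix gradients to the canonical 31-vector."""
    g = np.zeros(31)
    g[0] = g_psi[0, 0]
    for i in range(4):
        g[1 + i] = g_psi[1 + i, 1 + i]
        g[5 + i] = g_psi[5 + i, 5 + i]
        g[9 + i] = g_psi[1 + i, 5 + i] + g_psi[5 + i, 1 + i]
    for k in range(12):
        g[13 + k] = g_theta[k, k]
    for q, (i, j) in enumerate(_RECIP_IDX):
        g[25 + q] = g_theta[i, j] + g_theta[j, i]
    return g


class _MeasurementMVN(_StructuredMVN):
    """theta = (31 covariance params, 12 mu)."""

    n_params = 43
    param_names = COVARIANCE_PARAM_NAMES + MU_PARAM_NAMES

    def unpack(self, theta):
        psi, th = _psi_theta_from_cov(theta[:31])
        sigma = _LAMBDA @ psi @ _LAMBDA.T + th
        return theta[31:43], None, sigma

    def map_grads(self, g_mu, g_B, g_sigma, theta):
        g_psi = _LAMBDA.T @ g_sigma @ _LAMBDA
        return np.concatenate([_cov_grad_from_psi_theta(g_psi, g_sigma), g_mu])


class _PredictorSEMMVN(_StructuredMVN):
    """Joint (x, y) model: theta = (31 cov, 12 mu_x, per-role [nu, b_fam,
    b_act, b_par, resid_var])."""

    n_params = 63
    param_names = (
        COVARIANCE_PARAM_NAMES
        + MU_PARAM_NAMES
        + tuple(
            f"{name}_{r}"
            for r in ROLES
            for name in ("y_intercept", "b_fam", "b_act", "b_par", "y_resid_var")
        )
    )

    def __init__(self, patterns, roles_present: list[str]):
        super().__init__(patterns, dim=12 + len(roles_present), n_regressors=0)
        self.roles_present = roles_present

    def _structural(self, theta):
        out = {}
        for q, r in enumerate(self.roles_present):
            nu, bf, ba, bp, sv = theta[43 + 5 * q: 48 + 5 * q]
            out[r] = (nu, bf, ba, bp, sv)
        return out

    def _L_and_theta(self, theta):
        psi, th = _psi_theta_from_cov(theta[:31])
        ny = len(self.roles_present)
        C = np.zeros((ny, 9))
        th_full = np.zeros((12 + ny, 12 + ny))
        th_full[:12, :12] = th
        nu = np.zeros(ny)
        for q, r in enumerate(self.roles_present):
            i = ROLES.index(r)
            nu_r, bf, ba, bp, sv = self._structural(theta)[r]
            C[q, 0] = bf
            C[q, 1 + i] = ba
            C[q, 5 + i] = bp
            th_full[12 + q, 12 + q] = sv
            nu[q] = nu_r
        L = np.vstack([_LAMBDA, C])
        return L, psi, th_full, nu

    def unpack(self, theta):
        L, psi, th_full, nu = self._L_and_theta(theta)
        mu = np.concatenate([theta[31:43], nu])
        return mu, None, L @ psi @ L.T + th_full

    def map_grads(self, g_mu, g_B, g_sigma, theta):
        L, psi, _, _ = self._L_and_theta(theta)
        g_psi = L.T @ g_sigma @ L
        g = np.zeros(self.n_params)
        g[:31] = _cov_grad_from_psi_theta(g_psi, g_sigma[:12, :12])
        g[31:43] = g_mu[:12]
        GLP = g_sigma @ L @ psi          # dF/dC_rk = 2 (G L Psi)[12+q, k]
        for q, r in enumerate(self.roles_present):
            i = ROLES.index(r)
            base = 43 + 5 * q
            g[base] = g_mu[12 + q]
            g[base + 1] = 2.0 * GLP[12 + q, 0]
            g[base + 2] = 2.0 * GLP[12 + q, 1 + i]
            g[base + 3] = 2.0 * GLP[12 + q, 5 + i]
            g[base + 4] = g_sigma[12 + q, 12 + q]
        return g


# free Gamma rows: family, act_M, act_F, act_T, par_M, par_F, par_T;
# act_S and par_S are minus the sum of their block's free rows.
_GAMMA_FREE_ROWS = (0, 1, 2, 3, 5, 6, 7)
_GAMMA_DERIVED = {4: (1, 2, 3), 8: (5, 6, 7)}


def _gamma_from_free(free: np.ndarray, K: int) -> np.ndarray:
    gamma = np.zeros((9, K))
    for q, row in enumerate(_GAMMA_FREE_ROWS):
        gamma[row] = free[q * K:(q + 1) * K]
    for row, parents in _GAMMA_DERIVED.items():
        gamma[row] = -gamma[list(parents)].sum(axis=0)
    return gamma


def _gamma_free_grad(g_gamma: np.ndarray, K: int) -> np.ndarray:
    g = np.zeros(len(_GAMMA_FREE_ROWS) * K)
    for q, row in enumerate(_GAMMA_FREE_ROWS):
        adj = g_gamma[row].copy()
        for drow, parents in _GAMMA_DERIVED.items():
            if row in parents:
                adj -= g_gamma[drow]
        g[q * K:(q + 1) * K] = adj
    return g


class _MimicMVN(_StructuredMVN):
    """x | z model: theta = (31 cov, 12 mu, 7*K free Gamma entries)."""

    def __init__(self, patterns, K: int):
        super().__init__(patterns, dim=12, n_regressors=K)
        self.n_params = 43 + 7 * K
        names = []
        row_labels = ["fam", "act_M", "act_F", "act_T", "par_M", "par_F", "par_T"]
        for lab in row_labels:
            for k in range(K):
                names.append(f"gamma_{lab}_z{k + 1}")
        self.param_names = COVARIANCE_PARAM_NAMES + MU_PARAM_NAMES + tuple(names)

    def unpack(self, theta):
        psi, th = _psi_theta_from_cov(theta[:31])
        gamma = _gamma_from_free(theta[43:], self.K)
        return theta[31:43], _LAMBDA @ gamma, _LAMBDA @ psi @ _LAMBDA.T + th

    def map_grads(self, g_mu, g_B, g_sigma, theta):
        g_psi = _LAMBDA.T @ g_sigma @ _LAMBDA
        g = np.zeros(self.n_params)
        g[:31] = _cov_grad_from_psi_theta(g_psi, g_sigma)
        g[31:43] = g_mu
        if g_B is not None:
            g[43:] = _gamma_free_grad(_LAMBDA.T @ g_B, self.K)
        return g


# ======================================================================
# fitted-model container


@dataclass
class FittedModel:
    """Result of an SRM (or joint SEM) maximum-likelihood fit."""

    params: SRMParameterSet
    theta: np.ndarray = field(repr=False)
    param_names: tuple[str, ...] = field(repr=False)
    vcov: np.ndarray = field(repr=False)
    loglik: float = np.nan
    converged: bool = False
    implied_pd: bool = False
    n_families: int = 0
    patterns: dict = field(default_factory=dict)
    model: str = "measurement"
    structural: dict | None = None
    gamma: np.ndarray | None = None
    optimizer_success: bool = False

    def measurement(self) -> MeasurementMatrices:
        """Model-implied (Lambda, Psi, Theta, mu) at the estimates."""
        psi, th = _psi_theta_from_cov(self.theta[:31])
        return MeasurementMatrices(
            loading=_LAMBDA, factor_cov=psi, resid_cov=th,
            mean_vector=self.theta[31:43].copy(),
        )

    def se(self) -> np.ndarray:
        d = np.diag(self.vcov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    def report(self) -> pd.DataFrame:
        se = self.se()
        est = self.theta
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        return pd.DataFrame(
            {"parameter": list(self.param_names), "estimate": est, "se": se,
             "z": z, "p": 2.0 * stats.norm.sf(np.abs(z))}
        )


@dataclass
class StructuralSpec:
    """Which structural regressions to attach to the measurement model.

    ``direction='srm_as_predictor'``: each present role-specific outcome
    y_r is regressed on (family, actor_r, partner_r) effects.

    ``direction='srm_as_outcome'``: all nine effects are regressed on the
    external predictors z_1..z_K, with per-column zero-sum constraints on
    the actor and partner coefficient blocks (three free rows per block,
    the fourth derived).
    """

    direction: str
    roles: tuple[str, ...] = ROLES
    n_predictors: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("srm_as_predictor", "srm_as_outcome"):
            raise ValueError(f"unknown direction {self.direction!r}")


# ======================================================================
# starting values


def _start_measurement(data: RoundRobinData) -> np.ndarray:
    """Moment-based starting values (ANOVA-score variances where possible)."""
    from .scoring import anova_scores

    V = data.values
    mu0 = np.nanmean(V, axis=0)
    mu0 = np.where(np.isfinite(mu0), mu0, 0.0)
    pooled = float(np.nanvar(V))
    if not np.isfinite(pooled) or pooled <= 0:
        pooled = 1.0
    cov = np.zeros(31)
    complete = data.complete_rows()
    if complete.sum() >= 10:
        sc = anova_scores(data).values[complete]
        floor = 0.02 * pooled
        cov[0] = max(np.var(sc[:, 0]), floor)
        for i in range(4):
            cov[1 + i] = max(np.var(sc[:, 1 + i]), floor)
            cov[5 + i] = max(np.var(sc[:, 5 + i]), floor)
            cov[9 + i] = np.cov(sc[:, 1 + i], sc[:, 5 + i])[0, 1]
        # residual per dyad: x - (fam + act_i + par_j) scores
        resid = V[complete] - sc @ _LAMBDA.T
        for k in range(12):
            cov[13 + k] = max(np.var(resid[:, k]), floor)
        for q, (i, j) in enumerate(_RECIP_IDX):
            cov[25 + q] = np.cov(resid[:, i], resid[:, j])[0, 1]
    else:
        cov[0] = 0.20 * pooled
        cov[1:5] = 0.25 * pooled
        cov[5:9] = 0.15 * pooled
        cov[13:25] = 0.40 * pooled
    return np.concatenate([cov, mu0])


# ======================================================================
# public fitting interface


def _finalize(model: _StructuredMVN, res, names, n_families, patterns_census,
              kind: str, compute_vcov: bool = True) -> FittedModel:
    theta = res.x
    _, _, sigma = model.unpack(theta)
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    implied_pd = eigmin > PD_EIG_TOL
    converged = bool(res.success) and implied_pd
    if not converged:
        log.warning("fit (%s) not converged: optimizer_success=%s, implied_pd=%s "
                    "(min eig %.3e)", kind, res.success, implied_pd, eigmin)
    vcov = np.full((len(theta), len(theta)), np.nan)
    if compute_vcov and converged:
        H = model.hessian(theta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        if np.any(np.diag(vcov) < -1e-8):
            log.warning("observed information not positive definite; some SEs undefined")
    params = SRMParameterSet.from_vectors(theta[:31], theta[31:43])
    return FittedModel(
        params=params, theta=theta, param_names=tuple(names), vcov=vcov,
        loglik=-float(res.fun), converged=converged, implied_pd=implied_pd,
        n_families=n_families, patterns=patterns_census, model=kind,
        optimizer_success=bool(res.success),
    )


def _pattern_census(patterns: list[_PatternStats], n_empty: int) -> dict:
    census = {"".join("1" if i in p.idx else "0" for i in range(12)): p.n
              for p in patterns}
    if n_empty:
        census["empty"] = n_empty
    return census


def fit_srm_ml(data: RoundRobinData, compute_vcov: bool = True) -> FittedModel:
    """Complete-data ML fit of the 43-parameter SRM measurement model.

    Incomplete families are excluded (with a logged count); at least two
    complete families are required.
    """
    complete = data.complete_rows()
    n_inc = int((~complete).sum())
    if n_inc:
        log.info("fit_srm_ml: excluding %d incomplete families", n_inc)
    if complete.sum() < 2:
        raise ValueError("fit_srm_ml requires at least 2 complete families")
    V = data.values[complete]
    patterns, n_empty = _collect_patterns(V, None)
    model = _MeasurementMVN(patterns, dim=12, n_regressors=0)
    theta0 = _start_measurement(data.subset(np.flatnonzero(complete)))
    res = model.fit(theta0)
    fit = _finalize(model, res, model.param_names, int(complete.sum()),
                    _pattern_census(patterns, n_empty), "measurement_ml",
                    compute_vcov)
    return fit


def fit_srm_fiml(data: RoundRobinData, compute_vcov: bool = True) -> FittedModel:
    """Casewise (full-information) ML fit over all missing-data patterns.

    Families with no observed indicator contribute zero to the likelihood.
    On complete data this coincides with :func:`fit_srm_ml`.
    """
    any_obs = data.mask.any(axis=1)
    if any_obs.sum() < 2:
        raise ValueError("fit_srm_fiml requires at least 2 families with data")
    patterns, n_empty = _collect_patterns(data.values, None)
    model = _MeasurementMVN(patterns, dim=12, n_regressors=0)
    theta0 = _start_measurement(data)
    res = model.fit(theta0)
    return _finalize(model, res, model.param_names, data.n_families,
                     _pattern_census(patterns, n_empty), "measurement_fiml",
                     compute_vcov)


def fit_joint_sem(
    data: RoundRobinData,
    spec: StructuralSpec,
    compute_vcov: bool = True,
    warm_start: FittedModel | None = None,
) -> FittedModel:
    """Joint SEM: measurement model plus structural regressions, FIML.

    For ``srm_as_predictor`` the role-specific outcomes enter the joint
    multivariate-normal vector; for ``srm_as_outcome`` the predictors are
    fixed regressors of the latent effects (a MIMIC-style model) with
    zero-sum actor/partner coefficient constraints enforced by deriving the
    fourth row of each block.  ``warm_start`` accepts a measurement-only
    fit whose estimates seed the joint optimization.
    """
    theta_meas = (warm_start.theta[:43] if warm_start is not None
                  else _start_measurement(data))
    if spec.direction == "srm_as_predictor":
        roles_present = [r for r in spec.roles if f"y_{r}" in data.table.columns]
        if not roles_present:
            raise ValueError("no outcome columns y_<role> present")
        Y = np.column_stack([data.outcome(r) for r in roles_present])
        V = np.hstack([data.values, Y])
        patterns, n_empty = _collect_patterns(V, None)
        model = _PredictorSEMMVN(patterns, roles_present)
        start_struct = []
        for r in roles_present:
            y = data.outcome(r)
            start_struct += [float(np.nanmean(y)), 0.0, 0.0, 0.0,
                             max(float(np.nanvar(y)), 1e-2)]
        theta0 = np.concatenate([theta_meas, start_struct])
        res = model.fit(theta0)
        fit = _finalize(model, res, model.param_names, data.n_families,
                        _pattern_census(patterns, n_empty), "joint_predictor",
                        compute_vcov)
        fit.structural = {
            r: {"intercept": res.x[43 + 5 * q], "b_fam": res.x[44 + 5 * q],
                "b_act": res.x[45 + 5 * q], "b_par": res.x[46 + 5 * q],
                "y_resid_var": res.x[47 + 5 * q]}
            for q, r in enumerate(roles_present)
        }
        return fit
    # --- srm_as_outcome (MIMIC)
    Z = data.predictors()
    K = Z.shape[1]
    if spec.n_predictors is not None and spec.n_predictors != K:
        raise ValueError(f"expected {spec.n_predictors} predictors, found {K}")
    if np.isnan(Z).any():
        raise ValueError("predictors z_* must be fully observed")
    patterns, n_empty = _collect_patterns(data.values, Z)
    model = _MimicMVN(patterns, K)
    gamma0 = np.zeros(7 * K)
    theta0 = np.concatenate([theta_meas, gamma0])
    res = model.fit(theta0)
    fit = _finalize(model, res, model.param_names, data.n_families,
                    _pattern_census(patterns, n_empty), "joint_mimic",
                    compute_vcov)
    fit.gamma = _gamma_from_free(res.x[43:], K)
    return fit


def gamma_full_vcov(fit: FittedModel) -> tuple[np.ndarray, np.ndarray]:
    """Estimates and covariance of all 9xK structural coefficients of a
    MIMIC fit, including the derived zero-sum rows (delta method)."""
    if fit.model != "joint_mimic" or fit.gamma is None:
        raise ValueError("gamma_full_vcov requires a joint MIMIC fit")
    K = fit.gamma.shape[1]
    n_free = 7 * K
    M = np.zeros((9 * K, n_free))
    for q, row in enumerate(_GAMMA_FREE_ROWS):
        for k in range(K):
            M[row * K + k, q * K + k] = 1.0
    for drow, parents in _GAMMA_DERIVED.items():
        for parent in parents:
            q = _GAMMA_FREE_ROWS.index(parent)
            for k in range(K):
                M[drow * K + k, q * K + k] = -1.0
    v_free = fit.vcov[43:, 43:]
    return fit.gamma.reshape(-1), M @ v_free @ M.T


def wald_tests(fit: FittedModel) -> pd.DataFrame:
    """Per-parameter Wald z-tests (SEs from the observed information)."""
    if not fit.converged:
        raise ValueError("Wald tests refused: fit did not converge")
    return fit.report()
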