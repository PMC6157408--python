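"""Synthetic round-robin data generation and the Monte-Carlo harness.

Two study conditions are emulated:

* **SRM as predictor** — role-specific outcomes ``y_i`` generated as
  linear functions of (family, actor_i, partner_i) effects plus noise;
* **SRM as outcome** — a MIMIC-style model where the nine effects are
  regressed on three i.i.d. standard-normal predictors ``z_1..z_3`` with
  per-column zero-sum constraints on the actor and partner coefficient
  blocks.

The default variance components in both conditions are: family variance
1, actor variances 1, partner variances 0.5, relationship(+error)
variances 1.5, generalized reciprocities +/-0.05, dyadic reciprocities
0.02.  Missingness mechanisms delete dyadic cells independently at a
fixed rate inside the stratum of families whose conditioning variable
(a dyadic measurement, an outcome, or a predictor) falls below its
empirical first quartile; they are MAR given the conditioning variable.

The harness runs generate -> delete -> fit/score/regress per method per
replicate and summarizes median bias z-scores, 95% coverage, MAD,
convergence and missing rates.  Randomness flows from a single master
seed through spawned per-replicate streams.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    DYADS,
    FACTORS,
    ROLES,
    SRMParameterSet,
    model_implied_moments,
)
from .data import RoundRobinData
from .estimation import (
    StructuralSpec,
    fit_joint_sem,
    fit_srm_fiml,
    fit_srm_ml,
    gamma_full_vcov,
)
from .fsr import FIML_SCORE_METHODS, fsr_outcome, fsr_predictor
from .scoring import compute_scores

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PREDICTOR_GAMMA",
    "DEFAULT_OUTCOME_GAMMA",
    "SimulationConfig",
    "SimulationSummary",
    "generate_predictor_condition",
    "generate_outcome_condition",
    "apply_missingness",
    "run_study",
    "summarize",
]

_Z95 = 1.959963984540054
#: asymptotic SE-of-the-median factor, sqrt(pi/2)
_MEDIAN_SE_FACTOR = 1.2533141373155003

#: Default structural coefficients for the predictor condition: per role,
#: (b_fam, b_act, b_par) on the outcome.  Role M is a fully null block so
#: that its three coefficients are exact nulls for every scoring method
#: (zero coefficients inside a role with nonzero effects are not clean
#: nulls for the biased score methods, whose estimands mix the role's
#: coefficients); the other roles carry nonzero mixes with one zero each.
#: Outcome residual variance 1.
DEFAULT_PREDICTOR_GAMMA: dict[str, dict[str, float]] = {
    "M": {"intercept": 0.0, "fam": 0.0, "act": 0.0, "par": 0.0, "resid_var": 1.0},
    "F": {"intercept": 0.0, "fam": 0.3, "act": 0.0, "par": 0.2, "resid_var": 1.0},
    "T": {"intercept": 0.0, "fam": 0.2, "act": 0.3, "par": 0.0, "resid_var": 1.0},
    "S": {"intercept": 0.0, "fam": 0.0, "act": 0.2, "par": 0.3, "resid_var": 1.0},
}


def _default_outcome_gamma() -> np.ndarray:
    """9x3 coefficient matrix: family row (0.021, -0.005, -0.094), zero-sum
    actor rows, zero partner rows (factor order fam, act M F T S, par M F T S)."""
    g = np.zeros((9, 3))
    g[0] = [0.021, -0.005, -0.094]
    g[1] = [0.10, 0.05, -0.02]    # act_M
    g[2] = [-0.05, 0.02, 0.06]    # act_F
    g[3] = [0.02, -0.04, -0.01]   # act_T
    g[4] = -(g[1] + g[2] + g[3])  # act_S
    return g


DEFAULT_OUTCOME_GAMMA: np.ndarray = _default_outcome_gamma()


# ======================================================================
# generators


def _draw_measurement(
    n: int, params: SRMParameterSet, rng: np.random.Generator,
    latent_shift: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent effects and indicators; returns (latent (n,9), x (n,12))."""
    mm = model_implied_moments(params)
    psi_c = np.linalg.cholesky(mm.factor_cov + 1e-12 * np.eye(9))
    th_c = np.linalg.cholesky(mm.resid_cov)
    eta = rng.standard_normal((n, 9)) @ psi_c.T
    if latent_shift is not None:
        eta = eta + latent_shift
    eps = rng.standard_normal((n, 12)) @ th_c.T
    x = mm.mean_vector + eta @ mm.loading.T + eps
    return eta, x


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_predictor_condition(
    n: int,
    params: SRMParameterSet | None = None,
    gamma: dict[str, dict[str, float]] | None = None,
    seed=None,
) -> RoundRobinData:
    """Generate families with role-specific outcomes driven by SRM effects.

    ``y_i = b0 + b_fam*Fam + b_act*Act_i + b_par*Par_i + N(0, resid_var)``.
    """
    params = params or SRMParameterSet.simulation_defaults()
    params.validate_for_generation()
    gamma = gamma or DEFAULT_PREDICTOR_GAMMA
    rng = _as_rng(seed)
    eta, x = _draw_measurement(n, params, rng)
    outcomes = {}
    for q, r in enumerate(ROLES):
        g = gamma[r]
        lin = (g["intercept"] + g["fam"] * eta[:, 0]
               + g["act"] * eta[:, 1 + q] + g["par"] * eta[:, 5 + q])
        outcomes[r] = lin + rng.normal(0.0, np.sqrt(g["resid_var"]), size=n)
    return RoundRobinData.from_arrays(x, outcomes=outcomes, latent=eta)


def generate_outcome_condition(
    n: int,
    params: SRMParameterSet | None = None,
    gamma: np.ndarray | None = None,
    seed=None,
) -> RoundRobinData:
    """Generate families from the MIMIC model: effects = Gamma z + disturbance.

    ``z_1..z_K`` are i.i.d. standard normal; the disturbance covariance is
    the SRM factor covariance.  Gamma must satisfy the per-column zero-sum
    constraints on its actor and partner blocks.
    """
    params = params or SRMParameterSet.simulation_defaults()
    params.validate_for_generation()
    gamma = DEFAULT_OUTCOME_GAMMA if gamma is None else np.asarray(gamma, dtype=float)
    from .bias import _check_zero_sum

    _check_zero_sum(gamma)
    K = gamma.shape[1]
    rng = _as_rng(seed)
    z = rng.standard_normal((n, K))
    eta, x = _draw_measurement(n, params, rng, latent_shift=z @ gamma.T)
    return RoundRobinData.from_arrays(x, predictors=z, latent=eta)


# ======================================================================
# missingness


_MECHANISMS = {
    ("predictor", "dyad_dependent"): [
        {"targets": ["TM", "TF"], "rate": 0.25, "cond": ("dyad", "TS")},
    ],
    ("predictor", "external_dependent"): [
        {"targets": ["TM", "TF", "TS"], "rate": 0.25, "cond": ("outcome", "T")},
    ],
    ("outcome", "dyad_dependent"): [
        {"targets": ["TM", "TF", "TS", "FM", "FT", "FS"], "rate": 0.40,
         "cond": ("dyad", "SM")},
    ],
    ("outcome", "external_dependent"): [
        {"targets": ["TM", "TF", "TS", "FM", "FT", "FS"], "rate": 0.40,
         "cond": ("predictor", "z_1")},
        {"targets": ["TM", "TF", "TS", "MF", "MT", "MS"], "rate": 0.40,
         "cond": ("predictor", "z_2")},
    ],
}


def apply_missingness(
    data: RoundRobinData,
    mechanism: str,
    seed=None,
    condition: str = "predictor",
) -> RoundRobinData:
    """Delete dyadic cells under one of the study's quartile mechanisms.

    ``mechanism`` is ``none``, ``dyad_dependent`` (conditioning on another
    dyadic measurement) or ``external_dependent`` (conditioning on the
    outcome ``y_T`` in the predictor condition, on ``z_1``/``z_2`` in the
    outcome condition).  Deletion is independent per eligible cell at the
    mechanism's rate within the stratum where the conditioning variable is
    below its empirical first quartile (linear-interpolation quantile).
    """
    if mechanism == "none":
        return data
    key = (condition, mechanism)
    if key not in _MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r} for condition {condition!r}")
    rng = _as_rng(seed)
    tab = data.table.copy()
    for rule in _MECHANISMS[key]:
        kind, name = rule["cond"]
        if kind == "dyad":
            cond_vals = tab[f"x_{name}"].to_numpy(dtype=float)
        elif kind == "outcome":
            cond_vals = data.outcome(name)
        else:
            cond_vals = tab[name].to_numpy(dtype=float)
        q1 = np.nanquantile(cond_vals, 0.25)
        eligible = cond_vals < q1
        for d in rule["targets"]:
            hit = eligible & (rng.random(len(tab)) < rule["rate"])
            tab.loc[hit, f"x_{d}"] = np.nan
    return RoundRobinData(tab, latent=data.latent)


# ======================================================================
# configuration


@dataclass
class SimulationConfig:
    """Settings of one Monte-Carlo study cell."""

    condition: str = "srm_as_predictor"
    n_families: int = 500
    reps: int = 1000
    seed: int = 0
    missing_mechanism: str = "none"
    methods: tuple[str, ...] = ("sem", "regression", "bartlett_pinv", "anova")
    predictor_gamma: dict = field(default_factory=lambda: DEFAULT_PREDICTOR_GAMMA)
    outcome_gamma: list | None = None
    params: SRMParameterSet = field(default_factory=SRMParameterSet.simulation_defaults)

    def __post_init__(self) -> None:
        if self.condition not in ("srm_as_predictor", "srm_as_outcome"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.missing_mechanism not in ("none", "dyad_dependent", "external_dependent"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")

    @property
    def outcome_gamma_matrix(self) -> np.ndarray:
        if self.outcome_gamma is None:
            return DEFAULT_OUTCOME_GAMMA
        return np.asarray(self.outcome_gamma, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "params" in raw:
            base = SRMParameterSet.simulation_defaults()
            over = raw["params"]
            raw["params"] = dataclasses.replace(base, **over)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d.pop("params", None)
        if self.outcome_gamma is not None:
            d["outcome_gamma"] = np.asarray(self.outcome_gamma).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimulationSummary:
    """Per method x coefficient summary of a Monte-Carlo study."""

    table: pd.DataFrame
    config: SimulationConfig = field(repr=False)
    quantile_method: str = "linear"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def text_report(self) -> str:
        cols = ["method", "coefficient", "truth", "median", "bias_z", "coverage",
                "mad", "convergence_rate", "mean_missing_rate"]
        return self.table[cols].to_string(index=False, float_format=lambda v: f"{v: .4f}")


# ======================================================================
# per-replicate estimation


def _truths_predictor(gamma: dict) -> dict[str, float]:
    truths = {}
    for r in ROLES:
        for term, key in (("fam", "fam"), (f"act_{r}", "act"), (f"par_{r}", "par")):
            truths[f"y_{r}:{term}"] = gamma[r][key]
    return truths


def _truths_outcome(gamma: np.ndarray) -> dict[str, float]:
    truths = {}
    for j, f in enumerate(FACTORS):
        for k in range(gamma.shape[1]):
            truths[f"{f}:z_{k + 1}"] = gamma[j, k]
    return truths


def _measurement_fit(method: str, data: RoundRobinData, cache: dict):
    """Fit (or reuse) the measurement model an FSR method needs."""
    if method == "anova":
        return None
    kind = "fiml" if method in FIML_SCORE_METHODS else "ml"
    if kind not in cache:
        fitter = fit_srm_fiml if kind == "fiml" else fit_srm_ml
        try:
            fit = fitter(data, compute_vcov=False)
        except (ValueError, np.linalg.LinAlgError) as exc:
            cache[kind] = exc
            raise RuntimeError(f"measurement model failed: {exc}") from exc
        cache[kind] = fit
    cached = cache[kind]
    if isinstance(cached, Exception):
        raise RuntimeError(f"measurement model failed: {cached}")
    if not cached.converged:
        raise RuntimeError("measurement model did not converge")
    return cached.measurement()


def _estimate_predictor(method: str, data: RoundRobinData, cache: dict) -> tuple[dict, dict]:
    """One method's coefficient estimates and naive SEs, predictor condition."""
    est, se = {}, {}
    if method == "sem":
        fit = fit_joint_sem(data, StructuralSpec("srm_as_predictor"))
        if not fit.converged:
            raise RuntimeError("SEM did not converge")
        ses = dict(zip(fit.param_names, fit.se()))
        for q, r in enumerate(ROLES):
            s = fit.structural[r]
            for term, key, pname in ((f"fam", "b_fam", f"b_fam_{r}"),
                                     (f"act_{r}", "b_act", f"b_act_{r}"),
                                     (f"par_{r}", "b_par", f"b_par_{r}")):
                est[f"y_{r}:{term}"] = s[key]
                se[f"y_{r}:{term}"] = ses[pname]
        return est, se
    scores = compute_scores(method, data, _measurement_fit(method, data, cache))
    for r in ROLES:
        res = fsr_predictor(scores, data, r)
        for _, row in res.coefficients.iterrows():
            if row["term"] == "intercept":
                continue
            est[f"y_{r}:{row['term']}"] = row["estimate"]
            se[f"y_{r}:{row['term']}"] = row["se_naive"]
    return est, se


def _estimate_outcome(method: str, data: RoundRobinData, cache: dict) -> tuple[dict, dict]:
    """One method's coefficient estimates and naive SEs, outcome condition."""
    est, se = {}, {}
    K = len(data.predictor_columns)
    if method == "sem":
        fit = fit_joint_sem(data, StructuralSpec("srm_as_outcome"))
        if not fit.converged:
            raise RuntimeError("SEM did not converge")
        g_vec, g_vcov = gamma_full_vcov(fit)
        g_se = np.sqrt(np.clip(np.diag(g_vcov), 0.0, None))
        for j, f in enumerate(FACTORS):
            for k in range(K):
                est[f"{f}:z_{k + 1}"] = g_vec[j * K + k]
                se[f"{f}:z_{k + 1}"] = g_se[j * K + k]
        return est, se
    scores = compute_scores(method, data, _measurement_fit(method, data, cache))
    res = fsr_outcome(scores, data)
    for _, row in res.coefficients.iterrows():
        if row["term"] == "intercept":
            continue
        est[f"{row['effect']}:{row['term']}"] = row["estimate"]
        se[f"{row['effect']}:{row['term']}"] = row["se_naive"]
    return est, se


# ======================================================================
# harness


def run_study(config: SimulationConfig) -> SimulationSummary:
    """Run the full Monte-Carlo study described by ``config``.

    Identical config + seed gives a bit-identical summary.  Per-replicate
    failures of any kind count as non-convergence for that method and are
    excluded from the summary statistics.
    """
    cond_short = "predictor" if config.condition == "srm_as_predictor" else "outcome"
    if config.condition == "srm_as_predictor":
        truths = _truths_predictor(config.predictor_gamma)
        estimate = _estimate_predictor
    else:
        truths = _truths_outcome(config.outcome_gamma_matrix)
        estimate = _estimate_outcome
    coef_names = list(truths)
    seeds = np.random.SeedSequence(config.seed).spawn(config.reps)
    records: dict[str, list] = {m: [] for m in config.methods}
    se_records: dict[str, list] = {m: [] for m in config.methods}
    missing_rates: dict[str, list] = {m: [] for m in config.methods}
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if config.condition == "srm_as_predictor":
            data = generate_predictor_condition(
                config.n_families, config.params, config.predictor_gamma, rng)
        else:
            data = generate_outcome_condition(
                config.n_families, config.params, config.outcome_gamma_matrix, rng)
        data = apply_missingness(data, config.missing_mechanism, rng, cond_short)
        miss_rate = data.missing_census()["incomplete_family_rate"]
        cache: dict = {}
        for m in config.methods:
            try:
                est, se = estimate(m, data, cache)
                records[m].append([est.get(c, np.nan) for c in coef_names])
                se_records[m].append([se.get(c, np.nan) for c in coef_names])
                missing_rates[m].append(miss_rate)
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                log.debug("rep %d method %s failed: %s", rep, m, exc)
                records[m].append(None)
                se_records[m].append(None)
                missing_rates[m].append(miss_rate)
    rows = []
    for m in config.methods:
        ok = [i for i, r in enumerate(records[m]) if r is not None]
        conv_rate = len(ok) / config.reps
        est_arr = np.array([records[m][i] for i in ok]) if ok else np.empty((0, len(coef_names)))
        se_arr = np.array([se_records[m][i] for i in ok]) if ok else np.empty((0, len(coef_names)))
        mm_rate = float(np.mean(missing_rates[m])) if missing_rates[m] else 0.0
        sub = summarize(est_arr, se_arr, np.array([truths[c] for c in coef_names]),
                        coef_names, min_reps=min(30, config.reps))
        sub.insert(0, "method", m)
        sub["convergence_rate"] = conv_rate
        sub["mean_missing_rate"] = mm_rate
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    return SimulationSummary(table=table, config=config)


def summarize(
    estimates: np.ndarray,
    ses: np.ndarray,
    truths: np.ndarray,
    coef_names: list[str] | None = None,
    min_reps: int = 30,
) -> pd.DataFrame:
    """Summary metrics over converged replicates.

    bias z = (median - truth) / (1.2533 sd / sqrt(R)); coverage is the
    share of replicates whose Wald 95% CI contains the truth; MAD is the
    median absolute deviation of estimates from the truth.  Cells with
    fewer than ``min_reps`` converged replicates are flagged, not
    summarized.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    truths = np.asarray(truths, dtype=float)
    p = truths.shape[0]
    names = coef_names or [f"coef_{j}" for j in range(p)]
    rows = []
    R = estimates.shape[0]
    for j in range(p):
        e = estimates[:, j] if R else np.array([])
        e = e[np.isfinite(e)]
        if len(e) < min_reps:
            rows.append({"coefficient": names[j], "truth": truths[j],
                         "n_converged": len(e), "flagged": True,
                         "median": np.nan, "mean": np.nan, "se_mean": np.nan,
                         "bias_z": np.nan, "coverage": np.nan, "mad": np.nan})
            continue
        med = float(np.median(e))
        sd = float(np.std(e, ddof=1))
        se_med = _MEDIAN_SE_FACTOR * sd / np.sqrt(len(e))
        bias_z = (med - truths[j]) / se_med if se_med > 0 else 0.0
        s = ses[:, j]
        fin = np.isfinite(estimates[:, j]) & np.isfinite(s)
        lo = estimates[fin, j] - _Z95 * s[fin]
        hi = estimates[fin, j] + _Z95 * s[fin]
        coverage = float(np.mean((lo <= truths[j]) & (truths[j] <= hi))) if fin.any() else np.nan
        rows.append({
            "coefficient": names[j], "truth": truths[j], "n_converged": len(e),
            "flagged": False, "median": med, "mean": float(np.mean(e)),
            "se_mean": sd / np.sqrt(len(e)), "bias_z": float(bias_z),
            "coverage": coverage, "mad": float(np.median(np.abs(e - truths[j]))),
        })
    return pd.DataFrame(rows)
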