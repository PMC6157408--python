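"""Two-step factor-score regression (FSR) pipelines.

Step 1 fits the SRM measurement model (ML on complete families, or
casewise FIML under missingness), step 2 computes factor scores, and step
3 regresses: either a role-specific outcome on that role's (family,
actor, partner) scores, or each of the nine effect scores on external
predictors.  Naive standard errors are the classical homoskedastic OLS
ones, which ignore that the scores are estimated; a family-level
nonparametric bootstrap (resampling families with replacement and
repeating all three steps) is available as the honest alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import FACTORS, ROLES
from .data import RoundRobinData
from .estimation import fit_srm_fiml, fit_srm_ml
from .scoring import FactorScoreSet, compute_scores

log = logging.getLogger(__name__)

__all__ = ["FSRResult", "fsr_predictor", "fsr_outcome", "bootstrap_se"]

_Z95 = 1.959963984540054

#: score methods whose step-1 fit uses casewise FIML
FIML_SCORE_METHODS = ("regression_fiml", "bartlett_fiml")


@dataclass
class FSRResult:
    """Coefficients of a factor-score regression with naive and optional
    bootstrap standard errors."""

    direction: str
    score_method: str
    coefficients: pd.DataFrame
    n_used: int
    n_dropped: int
    bootstrap_B: int | None = None
    bootstrap_seed: int | None = None
    n_bootstrap_failures: int = 0

    def ci(self, use: str = "naive") -> pd.DataFrame:
        """95% normal CIs, estimate +/- 1.96 SE, from the requested SE."""
        se = self.coefficients[f"se_{use}"]
        out = self.coefficients.copy()
        out["ci_lo"] = out["estimate"] - _Z95 * se
        out["ci_hi"] = out["estimate"] + _Z95 * se
        return out

    def to_csv(self, path) -> None:
        self.ci("bootstrap" if self.bootstrap_B else "naive").to_csv(path, index=False)


def _ols_rows(y: np.ndarray, X: np.ndarray, terms: list[str], label_col: str,
              label: str) -> list[dict]:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    rows = []
    for j, t in enumerate(["intercept"] + terms):
        rows.append({label_col: label, "term": t,
                     "estimate": model.params[j], "se_naive": model.bse[j]})
    return rows


def fsr_predictor(scores: FactorScoreSet, data: RoundRobinData, role: str) -> FSRResult:
    """Regress outcome y_role on the (family, actor_role, partner_role) scores."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    y = data.outcome(role)
    cols = ["fam", f"act_{role}", f"par_{role}"]
    X = scores.scores[cols].to_numpy(dtype=float)
    use = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n_used, n_dropped = int(use.sum()), int((~use).sum())
    if n_used < 5:
        raise ValueError(f"fewer than 5 usable families ({n_used})")
    if n_dropped:
        log.info("fsr_predictor(%s): dropped %d families with missing scores/outcome",
                 role, n_dropped)
    rows = _ols_rows(y[use], X[use], cols, "outcome", f"y_{role}")
    coef = pd.DataFrame(rows)
    coef["se_bootstrap"] = np.nan
    return FSRResult("srm_as_predictor", scores.method, coef, n_used, n_dropped)


def fsr_outcome(
    scores: FactorScoreSet, data: RoundRobinData, predictors: list[str] | None = None
) -> FSRResult:
    """Regress each of the nine effect scores on the external predictors."""
    cols = predictors or data.predictor_columns
    if not cols:
        raise ValueError("no predictor columns available")
    Z = data.table[cols].to_numpy(dtype=float)
    S = scores.values
    rows = []
    n_used = n_dropped = 0
    for j, f in enumerate(FACTORS):
        s = S[:, j]
        use = np.isfinite(s) & np.isfinite(Z).all(axis=1)
        n_used, n_dropped = int(use.sum()), int((~use).sum())
        if n_used < 5:
            raise ValueError(f"fewer than 5 usable families ({n_used}) for effect {f}")
        rows += _ols_rows(s[use], Z[use], cols, "effect", f)
    if n_dropped:
        log.info("fsr_outcome: dropped %d families with missing scores", n_dropped)
    coef = pd.DataFrame(rows)
    coef["se_bootstrap"] = np.nan
    return FSRResult("srm_as_outcome", scores.method, coef, n_used, n_dropped)


# ----------------------------------------------------------------------
# bootstrap


def _run_pipeline(data: RoundRobinData, score_method: str, direction: str,
                  role: str | None, predictors: list[str] | None,
                  add_means: bool = False) -> FSRResult:
    if score_method == "anova":
        fit_mm = None
    else:
        fitter = fit_srm_fiml if score_method in FIML_SCORE_METHODS else fit_srm_ml
        fit = fitter(data, compute_vcov=False)
        if not fit.converged:
            raise RuntimeError("measurement model did not converge")
        fit_mm = fit.measurement()
    scores = compute_scores(score_method, data, fit_mm, add_means=add_means)
    if direction == "srm_as_predictor":
        return fsr_predictor(scores, data, role)
    return fsr_outcome(scores, data, predictors)


def bootstrap_se(
    data: RoundRobinData,
    score_method: str,
    direction: str,
    role: str | None = None,
    predictors: list[str] | None = None,
    B: int = 500,
    seed: int | None = None,
) -> FSRResult:
    """Family-level bootstrap SEs for a full FSR pipeline.

    Resamples families with replacement; each resample re-estimates the
    measurement model, the scores and the regression.  Resamples whose
    measurement fit fails to converge are redrawn, with a cap of 3B total
    draws.  SEs are the standard deviations of the B coefficient draws.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    result = _run_pipeline(data, score_method, direction, role, predictors)
    rng = np.random.default_rng(seed)
    n = data.n_families
    draws = []
    attempts = failures = 0
    while len(draws) < B:
        if attempts >= 3 * B:
            raise RuntimeError(
                f"bootstrap exceeded {3 * B} attempts ({failures} non-converged resamples)"
            )
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            res_b = _run_pipeline(data.subset(idx), score_method, direction,
                                  role, predictors)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        draws.append(res_b.coefficients["estimate"].to_numpy())
    arr = np.vstack(draws)
    result.coefficients["se_bootstrap"] = arr.std(axis=0, ddof=1)
    result.bootstrap_B = B
    result.bootstrap_seed = seed
    result.n_bootstrap_failures = failures
    return result
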