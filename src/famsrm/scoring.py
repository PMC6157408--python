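"""Factor-score estimators for the family SRM.

Implements the two classical factor-score families and their
missing-data (casewise / full-information) extensions:

* regression (Thurstone-Thomson / empirical-Bayes) scores
  ``eta = Psi L' Sigma^-1 (x - mu)``, equivalently
  ``(Psi^-1 + L' Th^-1 L)^-1 L' Th^-1 (x - mu)``;
* Bartlett scores in three variants: residual-weighted
  ``(L' Th^-1 L)^-1 L' Th^-1``, GLS ``(L' Sig^-1 L)^-1 L' Sig^-1``
  (equivalent when the 9x9 system is invertible), and the Moore-Penrose
  pseudo-inverse form needed for the SRM, whose loading matrix has rank 7;
* casewise versions of both, obtained by restricting Lambda, Theta and mu
  to each family's observed indicators (valid under MAR);
* the classical weighted two-way ANOVA scores.

All model-based scores are reported as deviations from the factor means
(the score systems operate on ``x - mu``); pass ``add_means=True`` to add
the estimated SRM means back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DYADS, FACTORS, ROLES, MeasurementMatrices, srm_means_from_observed
from .data import RoundRobinData

log = logging.getLogger(__name__)

__all__ = [
    "RANK_RTOL",
    "FactorScoreSet",
    "regression_scores",
    "regression_fiml_scores",
    "bartlett_scores",
    "bartlett_fiml_scores",
    "anova_scores",
    "compute_scores",
]

#: Relative singular-value cutoff for pseudo-inverse rank decisions.  The
#: SRM rank deficit is structural (rank 7 of 9); a tight relative tolerance
#: keeps estimated-Theta noise from flipping the detected rank.
RANK_RTOL = 1e-10

COMPLETE_PATTERN = tuple(range(12))


@dataclass
class FactorScoreSet:
    """Per-family SRM effect scores plus the coefficient matrices used.

    ``scores`` is (n_families x 9), NaN rows marking families whose scores
    are undefined under the method (never silently dropped).  ``fsc`` maps
    each missing-data pattern (tuple of observed indicator indices) to its
    9 x n_observed score-coefficient matrix; complete-data methods carry a
    single entry for the complete pattern.
    """

    method: str
    scores: pd.DataFrame
    fsc: dict[tuple, np.ndarray] = field(repr=False)
    effective_rank: dict[tuple, int]
    family_id: pd.Series = field(default=None, repr=False)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def usable(self) -> np.ndarray:
        """Boolean index of families with a defined (non-missing) score."""
        return ~np.isnan(self.values).any(axis=1)

    def to_csv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "method", self.method)
        out.insert(0, "family_id", self.family_id.values
                   if self.family_id is not None else np.arange(1, len(out) + 1))
        out.to_csv(path, index=False, na_rep="")


def _score_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, columns=list(FACTORS))


def _mean_offsets(mm: MeasurementMatrices) -> np.ndarray:
    """Factor means implied by the estimated mean structure, factor order."""
    comp = srm_means_from_observed(mm.mean_vector)
    return np.array(
        [comp["mean_fam"]]
        + [comp["mean_act"][r] for r in ROLES]
        + [comp["mean_par"][r] for r in ROLES]
    )


def _chol_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    from scipy.linalg import cho_factor, cho_solve

    try:
        c = cho_factor(mat)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{name} is singular or not positive definite") from exc
    return cho_solve(c, np.eye(mat.shape[0]))


def _apply_fsc(
    data: RoundRobinData,
    mm: MeasurementMatrices,
    fsc_for_pattern,
    add_means: bool,
    allow_empty: bool,
    empty_is_zero: bool,
) -> tuple[np.ndarray, dict, dict]:
    """Group families by missing pattern and apply pattern-wise FSC matrices."""
    values = data.values
    mask = data.mask
    n = values.shape[0]
    out = np.full((n, 9), np.nan)
    fsc: dict[tuple, np.ndarray] = {}
    ranks: dict[tuple, int] = {}
    patt_codes = np.packbits(mask, axis=1)
    _, inverse = np.unique(patt_codes, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        idx = tuple(np.flatnonzero(mask[rows[0]]))
        if len(idx) == 0:
            if empty_is_zero:
                out[rows] = 0.0
                log.warning(
                    "%d famil(ies) with all indicators missing: scores set to the "
                    "factor mean (full shrinkage)", len(rows),
                )
            elif allow_empty:
                log.warning(
                    "%d famil(ies) with all indicators missing: scores undefined",
                    len(rows),
                )
            continue
        coef, rank = fsc_for_pattern(idx)
        if coef is None:
            continue
        fsc[idx] = coef
        ranks[idx] = rank
        centered = values[np.ix_(rows, idx)] - mm.mean_vector[list(idx)]
        out[rows] = centered @ coef.T
    if add_means:
        out = out + _mean_offsets(mm)
    return out, fsc, ranks


# ----------------------------------------------------------------------
# regression scores


def regression_scores(
    fit: MeasurementMatrices, data: RoundRobinData, add_means: bool = False
) -> FactorScoreSet:
    """Regression (Thurstone-Thomson) scores ``Psi L' Sigma^-1 (x - mu)``.

    Complete families only; incomplete families receive missing scores.
    """
    sigma_inv = _chol_inverse(fit.sigma, "Sigma")
    coef = fit.factor_cov @ fit.loading.T @ sigma_inv

    def fsc_for_pattern(idx):
        if idx != COMPLETE_PATTERN:
            return None, 0
        return coef, int(np.linalg.matrix_rank(coef))

    out, fsc, ranks = _apply_fsc(data, fit, fsc_for_pattern, add_means, True, False)
    n_missing = int(np.isnan(out).any(axis=1).sum())
    if n_missing:
        log.info("regression scores undefined for %d incomplete families", n_missing)
    return FactorScoreSet("regression", _score_frame(out), fsc, ranks,
                          data.table["family_id"])


def regression_fiml_scores(
    fit: MeasurementMatrices, data: RoundRobinData, add_means: bool = False
) -> FactorScoreSet:
    """Casewise (full-information) regression scores under missing data.

    Per missing-data pattern, Lambda, Theta and mu are restricted to the
    observed indicators and ``(Psi^-1 + L' Th^-1 L)^-1 L' Th^-1`` applied.
    With no missingness this reproduces :func:`regression_scores`; a family
    with no observed indicators shrinks fully to the factor mean (score 0).
    """
    psi_inv = _chol_inverse(fit.factor_cov, "Psi")

    def fsc_for_pattern(idx):
        sub = list(idx)
        lam = fit.loading[sub, :]
        th_inv = _chol_inverse(fit.resid_cov[np.ix_(sub, sub)], "Theta (observed block)")
        lt = lam.T @ th_inv
        m = psi_inv + lt @ lam
        coef = np.linalg.solve(m, lt)
        return coef, int(np.linalg.matrix_rank(m))

    out, fsc, ranks = _apply_fsc(data, fit, fsc_for_pattern, add_means, False, True)
    return FactorScoreSet("regression_fiml", _score_frame(out), fsc, ranks,
                          data.table["family_id"])


# ----------------------------------------------------------------------
# Bartlett scores


def _bartlett_system(lam: np.ndarray, weight_inv: np.ndarray) -> tuple[np.ndarray, int]:
    lt = lam.T @ weight_inv
    m = lt @ lam
    rank = int(np.linalg.matrix_rank(m, tol=RANK_RTOL * np.linalg.norm(m, 2)))
    return m, rank


def bartlett_scores(
    fit: MeasurementMatrices,
    data: RoundRobinData,
    variant: str = "pinv",
    add_means: bool = False,
) -> FactorScoreSet:
    """Bartlett scores on complete families.

    ``variant='residual'`` weights by ``Theta^-1``, ``'gls'`` by
    ``Sigma^-1`` (the two coincide when the 9x9 system is invertible), and
    ``'pinv'`` replaces the inverse with the Moore-Penrose pseudo-inverse,
    which is required for the SRM whose score system has rank 7 < 9.
    """
    if variant not in ("residual", "gls", "pinv"):
        raise ValueError(f"unknown Bartlett variant {variant!r}")
    weight_name = "Sigma" if variant == "gls" else "Theta"
    weight = fit.sigma if variant == "gls" else fit.resid_cov
    w_inv = _chol_inverse(weight, weight_name)
    m, rank = _bartlett_system(fit.loading, w_inv)
    if variant in ("residual", "gls") and rank < m.shape[0]:
        raise np.linalg.LinAlgError(
            f"Bartlett system Lambda' {weight_name}^-1 Lambda has rank {rank} < "
            f"{m.shape[0]}; the SRM loading matrix is rank-deficient -- use "
            "variant='pinv'"
        )
    if variant == "pinv":
        m_inv = np.linalg.pinv(m, rcond=RANK_RTOL)
    else:
        m_inv = np.linalg.inv(m)
    coef = m_inv @ fit.loading.T @ w_inv

    def fsc_for_pattern(idx):
        if idx != COMPLETE_PATTERN:
            return None, 0
        return coef, rank

    out, fsc, ranks = _apply_fsc(data, fit, fsc_for_pattern, add_means, True, False)
    method = "bartlett" if variant == "residual" else f"bartlett_{variant}"
    return FactorScoreSet(method, _score_frame(out), fsc, ranks, data.table["family_id"])


def bartlett_fiml_scores(
    fit: MeasurementMatrices, data: RoundRobinData, add_means: bool = False
) -> FactorScoreSet:
    """Casewise Bartlett scores under missing data (pseudo-inverse form).

    Per pattern: ``(L_o' Th_o^-1 L_o)^+ L_o' Th_o^-1 (x_o - mu_o)``.  The
    restricted system is also rank-deficient, hence the pseudo-inverse.
    A family with no observed indicator has no score (Bartlett scoring has
    no prior mean to shrink to): the row is left missing.
    """

    def fsc_for_pattern(idx):
        sub = list(idx)
        lam = fit.loading[sub, :]
        th_inv = _chol_inverse(fit.resid_cov[np.ix_(sub, sub)], "Theta (observed block)")
        m, rank = _bartlett_system(lam, th_inv)
        coef = np.linalg.pinv(m, rcond=RANK_RTOL) @ lam.T @ th_inv
        return coef, rank

    out, fsc, ranks = _apply_fsc(data, fit, fsc_for_pattern, add_means, True, False)
    return FactorScoreSet("bartlett_fiml", _score_frame(out), fsc, ranks,
                          data.table["family_id"])


# ----------------------------------------------------------------------
# ANOVA scores


#: Two-way round-robin weights at family size n = 4:
#: act_i = (9/8) rowmean_i + (3/8) colmean_i - (3/2) grand  (and dually).
ANOVA_W_OWN, ANOVA_W_CROSS, ANOVA_W_GRAND = 9.0 / 8.0, 3.0 / 8.0, 3.0 / 2.0


def anova_scores(data: RoundRobinData) -> FactorScoreSet:
    """Classical weighted ANOVA scores from each family's own 12 values.

    The family score is the grand mean of the family's round-robin table;
    actor/partner scores are the weighted row/column-mean contrasts.  Any
    missing dyad leaves all nine scores undefined for that family.
    """
    values = data.values
    n = values.shape[0]
    out = np.full((n, 9), np.nan)
    complete = data.mask.all(axis=1)
    for i in np.flatnonzero(complete):
        comp = srm_means_from_observed(values[i])
        out[i, 0] = comp["mean_fam"]
        for k, r in enumerate(ROLES):
            out[i, 1 + k] = comp["mean_act"][r]
            out[i, 5 + k] = comp["mean_par"][r]
    n_missing = int((~complete).sum())
    if n_missing:
        log.info("ANOVA scores undefined for %d incomplete families", n_missing)
    # the score map is linear in the raw table: expose it as an FSC on raw x
    fsc = np.zeros((9, 12))
    for k, d in enumerate(DYADS):
        a, p = d[0], d[1]
        fsc[0, k] = 1.0 / 12.0
        for j, r in enumerate(ROLES):
            row_w = (1.0 / 3.0) if a == r else 0.0
            col_w = (1.0 / 3.0) if p == r else 0.0
            fsc[1 + j, k] = ANOVA_W_OWN * row_w + ANOVA_W_CROSS * col_w - ANOVA_W_GRAND / 12.0
            fsc[5 + j, k] = ANOVA_W_OWN * col_w + ANOVA_W_CROSS * row_w - ANOVA_W_GRAND / 12.0
    return FactorScoreSet(
        "anova", _score_frame(out), {COMPLETE_PATTERN: fsc},
        {COMPLETE_PATTERN: int(np.linalg.matrix_rank(fsc))},
        data.table["family_id"],
    )


# ----------------------------------------------------------------------


def compute_scores(
    method: str,
    data: RoundRobinData,
    fit: MeasurementMatrices | None = None,
    add_means: bool = False,
) -> FactorScoreSet:
    """Dispatch on a method tag (regression, regression_fiml, bartlett,
    bartlett_gls, bartlett_pinv, bartlett_fiml, anova)."""
    if method == "anova":
        return anova_scores(data)
    if fit is None:
        raise ValueError(f"method {method!r} requires fitted measurement matrices")
    if method == "regression":
        return regression_scores(fit, data, add_means)
    if method == "regression_fiml":
        return regression_fiml_scores(fit, data, add_means)
    if method in ("bartlett", "bartlett_gls", "bartlett_pinv"):
        variant = {"bartlett": "residual", "bartlett_gls": "gls", "bartlett_pinv": "pinv"}[method]
        return bartlett_scores(fit, data, variant, add_means)
    if method == "bartlett_fiml":
        return bartlett_fiml_scores(fit, data, add_means)
    raise ValueError(f"unknown scoring method {method!r}")
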