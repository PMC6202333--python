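"""Recessive-model association testing and trait standardization.

Binary outcomes are tested with maximum-likelihood logistic regression and a
1-df likelihood-ratio test on the homozygosity indicator, adjusting for
covariates (sex, age, region in the synthetic cohorts).  When the data are
separated (all homozygotes are cases, or the fit diverges) the package falls
back to Firth's penalized logistic regression, flagged in the result's model
label.  Quantitative traits are rank-inverse-normal standardized (Blom
offsets, covariate-adjusted residuals) and tested with an ordinary
fixed-effect linear model; no mixed-model relatedness correction is applied,
which is an explicit simplification relative to population-scale biobank
practice (see the methods note for what this loses).

Genome-wide significance uses a weighted Bonferroni threshold per predicted
functional impact class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("cgdseek")

#: Weighted-Bonferroni genome-wide significance thresholds per impact class.
SIGNIFICANCE_THRESHOLDS: dict[str, float] = {
    "high": 2.5e-7,
    "moderate": 5.0e-8,
    "low": 4.5e-9,
    "dhs": 2.3e-9,
    "remaining": 7.5e-10,
}

#: Hard-call cutoff turning a dosage into a homozygosity indicator.
HOM_DOSAGE_CUTOFF = 1.5


class UntestableGenotypeError(ValueError):
    """No homozygotes (or no variation) to test."""


class DegenerateDistributionError(ValueError):
    """All trait values identical: standardization undefined."""


@dataclass(frozen=True)
class AssociationResult:
    """Effect estimate with 95% CI and likelihood-ratio p-value."""

    effect: float  # odds ratio (binary) or SD units (quantitative)
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int | None = None
    n_controls: int | None = None
    n: int | None = None
    model_label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("effect must lie within its CI")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def significance_threshold(impact: str) -> float:
    """Weighted-Bonferroni genome-wide threshold for an impact class."""
    try:
        return SIGNIFICANCE_THRESHOLDS[impact]
    except KeyError:
        raise ValueError(f"unknown impact class {impact!r}") from None


def hard_call_homozygotes(theta_hat: np.ndarray, cutoff: float = HOM_DOSAGE_CUTOFF) -> np.ndarray:
    """Homozygosity indicator from expected allele counts (1 iff dosage > cutoff)."""
    return (np.asarray(theta_hat, dtype=float) > cutoff).astype(int)


# ---------------------------------------------------------------------------
# Rank-based inverse normal transform
# ---------------------------------------------------------------------------


def inverse_normal_transform(
    values: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """Rank-based inverse normal standardization with Blom offsets.

    When covariates are supplied, values are first adjusted by ordinary
    least squares and the residuals are transformed.  Ranks use the Blom
    plotting position (rank - 3/8) / (n + 1/4), mapped through the standard
    normal quantile function; ties share their averaged rank.  Output has
    mean ~0 and SD ~1 and preserves the input rank order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.sum(~np.isnan(x)) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanstd(x) == 0.0:
        raise DegenerateDistributionError("all values identical")
    if covariates is not None:
        design = _design_matrix(covariates, len(x))
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta
    ranks = stats.rankdata(x, method="average")
    quantiles = (ranks - 0.375) / (len(x) + 0.25)
    return stats.norm.ppf(quantiles)


def _design_matrix(covariates, n: int) -> np.ndarray:
    """Intercept + numeric columns; categorical/object columns are dummied."""
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        parts = [np.ones((n, 1))]
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                parts.append(pd.get_dummies(s, drop_first=True).to_numpy(dtype=float))
            else:
                parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
        return np.hstack(parts)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return np.hstack([np.ones((n, 1)), arr])


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression (fallback on separation)
# ---------------------------------------------------------------------------


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Newton fit of logistic regression with Jeffreys-prior penalty.

    Returns (beta, penalized log-likelihood, covariance).  The penalty
    0.5 * log|X'WX| removes the first-order bias of the MLE and yields
    finite estimates under complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1.0 - pi)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Firth fit") from exc
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - pi + h * (0.5 - pi))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise RuntimeError("Firth fit did not converge")
    eta = np.clip(X @ beta, -30, 30)
    pi = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi)))
    w = pi * (1.0 - pi)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        raise RuntimeError("non-positive-definite information in Firth fit")
    pll = ll + 0.5 * logdet
    cov = np.linalg.inv(info)
    return beta, pll, cov


def _is_separated(geno: np.ndarray, y: np.ndarray) -> bool:
    """Quasi-complete separation on the genotype term: a genotype group whose
    outcome is constant while the other group is not entirely the same."""
    for g in (0, 1):
        mask = geno == g
        if mask.any() and (y[mask].min() == y[mask].max()):
            return True
    return False


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


def fit_recessive_binary(
    hom_indicator: np.ndarray,
    case_status: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> AssociationResult:
    """Recessive logistic association of a binary outcome.

    Fits logistic models with and without the homozygosity indicator; the
    p-value is the 1-df likelihood-ratio statistic, the odds ratio the
    exponentiated genotype coefficient, and the 95% CI Wald on the log-odds
    scale.  On separation or non-convergence the fit switches to Firth's
    penalized likelihood (penalized LRT), flagged via the model label.
    """
    geno = np.asarray(hom_indicator, dtype=float)
    y = np.asarray(case_status, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("case_status must be binary 0/1")
    if geno.sum() == 0:
        raise UntestableGenotypeError("no homozygotes to test")
    if (geno == 1).all():
        raise UntestableGenotypeError("genotype indicator is constant")
    Z = _design_matrix(covariates, len(y))
    X_full = np.hstack([geno.reshape(-1, 1), Z])
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)

    use_firth = _is_separated(geno.astype(int), y.astype(int))
    if not use_firth:
        try:
            with np.errstate(all="ignore"):
                full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
                reduced = sm.Logit(y, Z).fit(disp=0, maxiter=200)
            se = full.bse[0]
            if not full.mle_retvals["converged"] or not np.isfinite(se) or se > 50:
                use_firth = True
        except Exception:
            use_firth = True

    if use_firth:
        beta_f, pll_full, cov_f = _firth_logistic(X_full, y)
        _, pll_red, _ = _firth_logistic(Z, y)
        coef, se = beta_f[0], float(np.sqrt(cov_f[0, 0]))
        lrt = max(0.0, 2.0 * (pll_full - pll_red))
        label = "logistic_recessive_firth"
    else:
        coef, se = full.params[0], full.bse[0]
        lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
        label = "logistic_recessive"

    p = float(stats.chi2.sf(lrt, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        effect=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=p,
        n_cases=n_cases,
        n_controls=n_controls,
        model_label=label,
    )


def fit_quantitative(
    trait: np.ndarray,
    hom_indicator: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    reference_sd: float | None = None,
) -> AssociationResult:
    """Linear association of a standardized quantitative trait.

    Expects the trait already rank-inverse-normal standardized, so the
    genotype coefficient is in SD units; ``reference_sd`` (natural units per
    SD) is applied multiplicatively when supplied.  The p-value is the 1-df
    likelihood-ratio test between the models with and without the genotype
    term.
    """
    yv = np.asarray(trait, dtype=float)
    geno = np.asarray(hom_indicator, dtype=float)
    if np.std(yv) == 0.0:
        raise ValueError("constant trait")
    if geno.sum() == 0:
        raise UntestableGenotypeError("no homozygotes to test")
    Z = _design_matrix(covariates, len(yv))
    X_full = np.hstack([geno.reshape(-1, 1), Z])
    full = sm.OLS(yv, X_full).fit()
    reduced = sm.OLS(yv, Z).fit()
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(lrt, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    coef, se = full.params[0], full.bse[0]
    z = stats.norm.ppf(0.975)
    scale = reference_sd if reference_sd is not None else 1.0
    return AssociationResult(
        effect=float(coef * scale),
        ci_low=float((coef - z * se) * scale),
        ci_high=float((coef + z * se) * scale),
        p_value=p,
        n=len(yv),
        model_label="linear_quantitative" + ("_natural_units" if reference_sd else ""),
    )
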