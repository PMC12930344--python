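"""Statistical machinery for feature tables and cohort covariates.

Four analyses, mirroring a standard two-cohort acoustic-feature study:

* Bonferroni-corrected two-group comparisons (pooled or Welch t chosen
  by Levene's test), with pooled-SD Cohen's d;
* exploratory binary logistic regression over all features with Wald
  statistics, odds ratios, 95% CIs, Hosmer-Lemeshow calibration, and
  apparent accuracy at the 0.5 threshold;
* Pearson correlation with post-hoc power by the Fisher-z normal
  approximation;
* covariate-adjusted linear models (standardized betas, adjusted R²,
  variance inflation factors).

Model fits are delegated to statsmodels/scipy; the Hosmer-Lemeshow
statistic and the Fisher-z power calculation are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "LogisticFit",
    "PredictorEffect",
    "CorrelationResult",
    "AdjustedFit",
    "bonferroni_alpha",
    "compare_groups",
    "fit_logistic",
    "logistic_derived",
    "hosmer_lemeshow",
    "pearson_with_power",
    "fit_adjusted",
]

#: z quantile for 95% confidence intervals
Z95 = 1.959964


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test significance level for ``m`` tests at family level alpha."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return family_alpha / m


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    n1: int
    n2: int
    normality_p: tuple[float, float]  # KS p per group
    levene_p: float
    test: str  # "pooled t" | "Welch t"
    t: float
    p: float
    cohens_d: float
    adjusted_alpha: float
    significant: bool


def compare_groups(
    features: pd.DataFrame,
    labels: Sequence[str],
    family_alpha: float = 0.05,
    levene_alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Two-group comparison of every feature column.

    Per feature: Kolmogorov-Smirnov normality per group, Levene's test
    (center = mean) at ``levene_alpha`` to choose pooled vs Welch t,
    two-sided p, pooled-SD Cohen's d, and a significance flag at the
    Bonferroni-adjusted level ``family_alpha / n_features``.  Group 1 is
    the label first encountered; swapping groups negates t and d.
    """
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    alpha_adj = bonferroni_alpha(family_alpha, features.shape[1])
    results = []
    for name in features.columns:
        x = features.loc[labels == uniq[0], name].to_numpy(float)
        y = features.loc[labels == uniq[1], name].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 3 or y.size < 3:
            raise ValueError(f"feature {name!r}: each group needs n >= 3")
        ks = []
        for g in (x, y):
            sd = g.std(ddof=1)
            if sd == 0:
                ks.append(0.0)
            else:
                ks.append(float(sps.kstest(g, "norm", args=(g.mean(), sd)).pvalue))
        degenerate = x.std(ddof=1) == 0 or y.std(ddof=1) == 0
        if degenerate:
            lev_p, equal_var = 0.0, False  # small-variance guard: force Welch
        else:
            lev_p = float(sps.levene(x, y, center="mean").pvalue)
            equal_var = lev_p >= levene_alpha
        t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        sp = np.sqrt(
            ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
            / (x.size + y.size - 2)
        )
        d = 0.0 if sp == 0 else float((x.mean() - y.mean()) / sp)
        results.append(
            GroupComparisonResult(
                feature=str(name),
                mean1=float(x.mean()),
                sd1=float(x.std(ddof=1)),
                mean2=float(y.mean()),
                sd2=float(y.std(ddof=1)),
                n1=int(x.size),
                n2=int(y.size),
                normality_p=(ks[0], ks[1]),
                levene_p=lev_p,
                test="pooled t" if equal_var else "Welch t",
                t=float(t),
                p=float(p),
                cohens_d=d,
                adjusted_alpha=alpha_adj,
                significant=bool(p < alpha_adj),
            )
        )
    return results


@dataclass(frozen=True)
class PredictorEffect:
    """One predictor row of a logistic fit."""

    name: str
    coef: float
    se: float
    wald_chi2: float
    p: float
    odds_ratio: float
    ci95: tuple[float, float]


def logistic_derived(coef: float, se: float, z: float = Z95) -> PredictorEffect:
    """Derived columns (Wald chi2, OR, 95% CI) from a coefficient and SE.

    Pure arithmetic: OR = exp(coef), Wald = (coef/se)^2,
    CI = exp(coef -/+ z*se), p from the chi-square(1) tail.
    """
    wald = (coef / se) ** 2
    return PredictorEffect(
        name="",
        coef=coef,
        se=se,
        wald_chi2=wald,
        p=float(sps.chi2.sf(wald, 1)),
        odds_ratio=float(np.exp(coef)),
        ci95=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
    )


@dataclass(frozen=True)
class LogisticFit:
    predictors: list[PredictorEffect]
    intercept: float
    intercept_se: float
    hosmer_lemeshow: tuple[float, float, int]  # chi2, p, n_groups
    accuracy: float  # apparent accuracy at threshold 0.5
    n: int
    fitted_probabilities: np.ndarray = field(repr=False, default=None)


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    hl_groups: int = 10,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression.

    Newton/IRLS fit (gradient tolerance 1e-8); SEs from the observed
    information matrix.  Raises on perfect separation or a rank-deficient
    design.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, float)
    if set(np.unique(yv)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes, coded 0/1")
    if np.any(np.ptp(Xv, axis=0) == 0):
        raise ValueError("design contains a constant column")
    design = sm.add_constant(Xv, has_constant="raise")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    try:
        res = sm.Logit(yv, design).fit(method="newton", tol=1e-8, maxiter=200, disp=False)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if np.any(np.abs(res.params) > 50) or np.any(~np.isfinite(res.bse)):
        raise ValueError("diverging coefficients: perfect separation suspected")
    coefs, ses = res.params, res.bse
    predictors = []
    for i, name in enumerate(names, start=1):
        eff = logistic_derived(float(coefs[i]), float(ses[i]))
        predictors.append(
            PredictorEffect(
                name=name,
                coef=eff.coef,
                se=eff.se,
                wald_chi2=eff.wald_chi2,
                p=eff.p,
                odds_ratio=eff.odds_ratio,
                ci95=eff.ci95,
            )
        )
    probs = np.asarray(res.predict(design))
    try:
        chi2, p_hl = hosmer_lemeshow(probs, yv, n_groups=hl_groups)
    except ValueError:
        # saturated/coarse designs yield too few distinct risk groups
        chi2, p_hl = float("nan"), float("nan")
    accuracy = float(np.mean((probs >= 0.5) == (yv == 1)))
    return LogisticFit(
        predictors=predictors,
        intercept=float(coefs[0]),
        intercept_se=float(ses[0]),
        hosmer_lemeshow=(chi2, p_hl, hl_groups),
        accuracy=accuracy,
        n=int(yv.size),
        fitted_probabilities=probs,
    )


def hosmer_lemeshow(
    probabilities: np.ndarray,
    outcomes: np.ndarray,
    n_groups: int = 10,
) -> tuple[float, float]:
    """Decile-of-risk calibration test for fitted binary probabilities.

    Observations are grouped by fitted probability into ``n_groups``
    quantile bins (ties share a bin); the statistic is
    ``sum_k (O_k - E_k)^2 / (E_k (1 - E_k / n_k))`` with p-value from a
    chi-square with (groups used) - 2 degrees of freedom.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    if p.size != y.size:
        raise ValueError("probabilities and outcomes differ in length")
    if p.size < 2 * n_groups:
        raise ValueError(f"need n >= {2 * n_groups} observations for {n_groups} groups")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    edges = np.quantile(p, np.linspace(0, 1, n_groups + 1)[1:-1])
    bins = np.searchsorted(edges, p, side="right")
    chi2 = 0.0
    used = 0
    for k in np.unique(bins):
        mask = bins == k
        nk = int(mask.sum())
        ek = float(p[mask].sum())
        ok = float(y[mask].sum())
        denom = ek * (1.0 - ek / nk)
        if denom <= 0:
            raise ValueError(f"risk group {k} has expected count {ek}")
        chi2 += (ok - ek) ** 2 / denom
        used += 1
    df = used - 2
    if df < 1:
        raise ValueError("too few distinct risk groups for the chi-square reference")
    return float(chi2), float(sps.chi2.sf(chi2, df))


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    r: float
    p: float
    power: float  # post-hoc 1 - beta at the stated alpha and n
    n: int
    alpha: float


def pearson_with_power(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    feature: str = "",
) -> CorrelationResult:
    """Pearson r with two-sided p and post-hoc power (Fisher-z).

    Power treats the observed r as the population value: with
    ``z_r = atanh(r)`` and SE ``1/sqrt(n-3)``, the two-sided rejection
    probability is ``Phi(|z_r| sqrt(n-3) - z_a) + Phi(-|z_r| sqrt(n-3) - z_a)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    n = x.size
    za = sps.norm.ppf(1 - alpha / 2)
    lam = abs(np.arctanh(np.clip(r, -0.999999, 0.999999))) * np.sqrt(n - 3)
    power = float(sps.norm.cdf(lam - za) + sps.norm.cdf(-lam - za))
    return CorrelationResult(
        feature=feature, r=float(r), p=float(p), power=power, n=int(n), alpha=alpha
    )


@dataclass(frozen=True)
class AdjustedFit:
    outcome: str
    predictors: list[str]
    std_beta: dict[str, float]
    p: dict[str, float]
    vif: dict[str, float]
    adj_r2: float
    n: int


def fit_adjusted(
    data: pd.DataFrame,
    outcome: str,
    feature: str,
    covariates: Sequence[str] = ("age", "diabetes", "bmi", "sbp"),
    binary: Sequence[str] = ("diabetes",),
) -> AdjustedFit:
    """Covariate-adjusted OLS of ``outcome`` on one acoustic feature.

    Continuous variables (outcome included) are z-scored so betas are
    standardized; binary covariates stay 0/1.  Per-predictor VIFs come
    from auxiliary regressions; any VIF above 1e8 raises a collinearity
    error naming the predictor.
    """
    predictors = [feature, *covariates]
    df = data[[outcome, *predictors]].dropna().astype(float)
    if df.shape[0] <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    work = df.copy()
    for col in [outcome, *predictors]:
        if col in binary:
            continue
        sd = work[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        work[col] = (work[col] - work[col].mean()) / sd
    Xmat = work[predictors].to_numpy()
    vifs = {}
    for j, name in enumerate(predictors):
        others = np.delete(Xmat, j, axis=1)
        aux = sm.OLS(Xmat[:, j], sm.add_constant(others)).fit()
        r2j = min(aux.rsquared, 1.0)
        if r2j > 1 - 1e-8:
            raise ValueError(f"collinear design: predictor {name!r} has infinite VIF")
        vifs[name] = float(1.0 / (1.0 - r2j))
    res = sm.OLS(work[outcome].to_numpy(), sm.add_constant(Xmat)).fit()
    return AdjustedFit(
        outcome=outcome,
        predictors=predictors,
        std_beta={n: float(b) for n, b in zip(predictors, res.params[1:])},
        p={n: float(p) for n, p in zip(predictors, res.pvalues[1:])},
        vif=vifs,
        adj_r2=float(res.rsquared_adj),
        n=int(df.shape[0]),
    )
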