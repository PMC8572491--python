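"""The inference stack: linear association with partial R-squared,
quasi-Poisson burden regression, DerSimonian-Laird random-effects
meta-analysis, quasi-Bayesian mediation, and the targeted SNP analysis.

Conventions
-----------
* Continuous variables (float-typed or many-valued) are z-standardized
  before model fitting so coefficients are in SD units; dosages and other
  small-integer codes are left on their natural scale.
* Single-predictor associations are tested by the F-test of the full model
  against the covariate-only model; the partial R-squared is
  (SSE_reduced - SSE_full) / SSE_reduced.
* Quasi-Poisson point estimates equal the Poisson MLE; the dispersion
  (Pearson chi-squared / residual df) scales the standard errors only.
* Random-effects pooling uses the DerSimonian-Laird moment estimator with
  tau-squared truncated at zero (REML available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "QuasiPoissonFit",
    "MetaResult",
    "MediationResult",
    "linear_assoc",
    "multivariable_model",
    "quasipoisson_fit",
    "meta_random_effects",
    "mediate",
    "snp_meta_assoc",
]


# ---------------------------------------------------------------------------
# design-matrix helpers


def _is_continuous(s: pd.Series) -> bool:
    if s.dtype.kind == "f":
        return True
    return s.dtype.kind in "iu" and s.nunique() > 10


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError(f"column {s.name!r} is constant; cannot standardize")
    return (s - s.mean()) / sd


def _encode(df: pd.DataFrame, columns: Sequence[str], standardize: bool) -> pd.DataFrame:
    """Numeric design columns; object/categorical columns become dummy sets."""
    pieces = []
    for c in columns:
        s = df[c]
        if s.dtype.kind in "Ob" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            pieces.append(d)
        else:
            s = s.astype(float)
            if standardize and _is_continuous(df[c]):
                s = _zscore(s)
            pieces.append(s.to_frame(c))
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=df.index)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10 * max(1, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear terms include {bad}")


# ---------------------------------------------------------------------------
# linear association


@dataclass(frozen=True)
class AssocResult:
    term: str
    beta: float
    se: float
    statistic: float
    p: float
    partial_r2: float
    n: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    test: str = "F"


def linear_assoc(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = (),
    standardize: bool = True,
) -> AssocResult:
    """Association of one predictor with a continuous outcome, given covariates.

    OLS on complete cases; the predictor is tested by an F-test of the full
    model against the covariate-only model (a multi-level categorical
    predictor is tested jointly), and its partial R-squared is the fraction of
    covariate-adjusted residual variance it explains.  For single-column
    predictors the reported beta/SE are the OLS coefficient and its SE.
    """
    cols = [outcome, predictor, *covariates]
    data = df[cols].dropna()
    n = len(data)
    y = _zscore(data[outcome].astype(float)) if standardize else data[outcome].astype(float)
    X_cov = _encode(data, list(covariates), standardize)
    X_pred = _encode(data, [predictor], standardize)

    X_full = sm.add_constant(pd.concat([X_pred, X_cov], axis=1), has_constant="add")
    X_red = sm.add_constant(X_cov, has_constant="add")
    _check_rank(X_full.to_numpy(dtype=float), list(X_full.columns))

    full = sm.OLS(y.to_numpy(), X_full.to_numpy(dtype=float)).fit()
    red = sm.OLS(y.to_numpy(), X_red.to_numpy(dtype=float)).fit()

    sse_full, sse_red = full.ssr, red.ssr
    q = X_pred.shape[1]
    df_resid = n - X_full.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough complete cases for the requested model")
    fstat = ((sse_red - sse_full) / q) / (sse_full / df_resid)
    p = float(stats.f.sf(fstat, q, df_resid))
    partial_r2 = float((sse_red - sse_full) / sse_red) if sse_red > 0 else 1.0

    if q == 1:
        j = list(X_full.columns).index(X_pred.columns[0])
        beta, se = float(full.params[j]), float(full.bse[j])
        tcrit = stats.t.ppf(0.975, df_resid)
        ci = (beta - tcrit * se, beta + tcrit * se)
    else:
        beta, se, ci = np.nan, np.nan, (np.nan, np.nan)
    return AssocResult(
        term=predictor, beta=beta, se=se, statistic=float(fstat), p=p,
        partial_r2=partial_r2, n=n, ci_low=ci[0], ci_high=ci[1], test="F",
    )


def multivariable_model(
    df: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    standardize: bool = True,
) -> pd.DataFrame:
    """One joint OLS of all predictors; per-term t-tests with 95% CIs.

    Complete-case analysis; returns a forest-plot-ready table (one row per
    design column) with the number of complete cases in every row.
    """
    data = df[[outcome, *predictors]].dropna()
    n = len(data)
    y = _zscore(data[outcome].astype(float)) if standardize else data[outcome].astype(float)
    X = _encode(data, list(predictors), standardize)
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc.to_numpy(dtype=float), list(Xc.columns))
    fit = sm.OLS(y.to_numpy(), Xc.to_numpy(dtype=float)).fit()
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    rows = []
    for j, name in enumerate(Xc.columns):
        if name == "const":
            continue
        rows.append(
            {
                "term": name,
                "beta": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "t": float(fit.tvalues[j]),
                "p": float(fit.pvalues[j]),
                "ci_low": float(fit.params[j] - tcrit * fit.bse[j]),
                "ci_high": float(fit.params[j] + tcrit * fit.bse[j]),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quasi-Poisson


@dataclass
class QuasiPoissonFit:
    params: pd.Series            # coefficients on the log scale
    bse: pd.Series               # dispersion-scaled standard errors
    dispersion: float            # Pearson chi-squared / residual df
    pvalues: pd.Series           # Wald t-tests with scaled SEs
    percent_per_unit: pd.Series  # 100 * (exp(beta) - 1)
    n: int
    df_resid: int
    deviance: float
    ci_low: pd.Series = field(default=None)
    ci_high: pd.Series = field(default=None)

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return (
            float(self.params[term] - tcrit * self.bse[term]),
            float(self.params[term] + tcrit * self.bse[term]),
        )


def quasipoisson_fit(counts, design: pd.DataFrame, add_constant: bool = True) -> QuasiPoissonFit:
    """Quasi-Poisson regression of non-negative integer counts.

    Point estimates are the Poisson MLE via IRLS with log link; the free
    dispersion parameter phi (Pearson chi-squared over residual df) scales
    the SEs by sqrt(phi).  Per-term p-values are Wald t-tests on the scaled
    SEs, mirroring R's ``glm(..., family = quasipoisson)`` summary.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X = design.astype(float)
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson())
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {res.fit_history['iteration']} iterations; "
            f"deviance trace {res.fit_history.get('deviance')}"
        )
    df_resid = int(res.df_resid)
    phi = float(res.pearson_chi2 / df_resid)
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse * np.sqrt(phi), index=names)
    tvals = params / bse
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df_resid), index=names)
    tcrit = stats.t.ppf(0.975, df_resid)
    return QuasiPoissonFit(
        params=params,
        bse=bse,
        dispersion=phi,
        pvalues=pvals,
        percent_per_unit=100.0 * (np.exp(params) - 1.0),
        n=len(y),
        df_resid=df_resid,
        deviance=float(res.deviance),
        ci_low=params - tcrit * bse,
        ci_high=params + tcrit * bse,
    )


def quasipoisson_f_test(counts, design: pd.DataFrame, term: str) -> tuple[float, float]:
    """F-test on the scaled deviance for dropping one term.

    F = (deviance_reduced - deviance_full) / (q * phi_full), compared against
    F(q, n - p); the analysis-of-deviance analogue of the likelihood-ratio
    test under a free dispersion.
    """
    full = quasipoisson_fit(counts, design)
    red = quasipoisson_fit(counts, design.drop(columns=[term]))
    q = 1
    f = (red.deviance - full.deviance) / (q * full.dispersion)
    return float(f), float(stats.f.sf(f, q, full.df_resid))


# ---------------------------------------------------------------------------
# random-effects meta-analysis


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    tau2: float
    q_stat: float
    k: int
    ci_low: float
    ci_high: float
    study_betas: tuple = ()
    study_ses: tuple = ()
    method: str = "dl"


def _reml_tau2(b: np.ndarray, v: np.ndarray, tol: float = 1e-10, maxiter: int = 200) -> float:
    """Restricted maximum-likelihood tau-squared by fixed-point iteration."""
    tau2 = max(np.var(b, ddof=1) - v.mean(), 0.0)
    for _ in range(maxiter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * b) / np.sum(w)
        num = np.sum(w**2 * ((b - mu) ** 2 - v)) + np.sum(w**2) / np.sum(w) * tau2
        new = max(float(num / np.sum(w**2)), 0.0)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def meta_random_effects(
    betas: Sequence[float],
    ses: Sequence[float],
    method: str = "dl",
) -> MetaResult:
    """Random-effects inverse-variance pooling of per-study (beta, SE) pairs.

    DerSimonian-Laird moment estimator by default:
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with w = 1/SE^2;
    the pooled estimate uses weights 1 / (SE_i^2 + tau2).  A single study is
    returned unchanged with a warning.
    """
    b = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.shape != se.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-D and equally long")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(b)
    if k == 0:
        raise ValueError("no studies supplied")
    if k == 1:
        warnings.warn("single study: returning it unchanged (no pooling possible)", stacklevel=2)
        z = b[0] / se[0]
        return MetaResult(
            beta=float(b[0]), se=float(se[0]), z=float(z),
            p=float(2 * stats.norm.sf(abs(z))), tau2=0.0, q_stat=0.0, k=1,
            ci_low=float(b[0] - 1.959963984540054 * se[0]),
            ci_high=float(b[0] + 1.959963984540054 * se[0]),
            study_betas=tuple(b), study_ses=tuple(se), method=method,
        )
    v = se**2
    w = 1.0 / v
    mu_fe = np.sum(w * b) / np.sum(w)
    q_stat = float(np.sum(w * (b - mu_fe) ** 2))
    if method == "dl":
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q_stat - (k - 1)) / denom)
    elif method == "reml":
        tau2 = _reml_tau2(b, v)
    else:
        raise ValueError(f"unknown tau2 method {method!r}")
    ws = 1.0 / (v + tau2)
    beta = float(np.sum(ws * b) / np.sum(ws))
    se_p = float(np.sum(ws) ** -0.5)
    z = beta / se_p
    zc = 1.959963984540054
    return MetaResult(
        beta=beta, se=se_p, z=float(z), p=float(2 * stats.norm.sf(abs(z))),
        tau2=float(tau2), q_stat=q_stat, k=k,
        ci_low=beta - zc * se_p, ci_high=beta + zc * se_p,
        study_betas=tuple(b), study_ses=tuple(se), method=method,
    )


# ---------------------------------------------------------------------------
# quasi-Bayesian mediation


@dataclass(frozen=True)
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    proportion_ci: tuple[float, float]
    a: float
    b: float
    c_prime: float
    n_sim: int
    n: int
    unstable_proportion: bool = False


def mediate(
    df: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MediationResult:
    """Quasi-Bayesian causal mediation for linear mediator and outcome models.

    Fits mediator ~ treatment (+ covariates) and outcome ~ treatment +
    mediator (+ covariates) by OLS, draws ``n_sim`` parameter vectors from
    the joint asymptotic normal of each fit, and per draw forms
    ACME = a*b, ADE = c', total = ACME + ADE (exact in the linear case) and
    the proportion mediated ACME/total.  Point estimates are the draw means,
    intervals are 2.5/97.5 percentiles.  A total effect whose interval spans
    zero makes the proportion's ratio unstable; the proportion interval is
    then reported as (-inf, inf) and flagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = df[[treatment, mediator, outcome, *covariates]].dropna()
    n = len(data)
    Xc = _encode(data, list(covariates), standardize=False)

    Xm = sm.add_constant(
        pd.concat([data[[treatment]].astype(float), Xc], axis=1), has_constant="add"
    )
    m_fit = sm.OLS(data[mediator].astype(float).to_numpy(), Xm.to_numpy(dtype=float)).fit()
    Xy = sm.add_constant(
        pd.concat([data[[treatment, mediator]].astype(float), Xc], axis=1),
        has_constant="add",
    )
    y_fit = sm.OLS(data[outcome].astype(float).to_numpy(), Xy.to_numpy(dtype=float)).fit()

    ia = list(Xm.columns).index(treatment)
    ic = list(Xy.columns).index(treatment)
    ib = list(Xy.columns).index(mediator)

    m_draws = rng.multivariate_normal(m_fit.params, m_fit.cov_params(), size=n_sim)
    y_draws = rng.multivariate_normal(y_fit.params, y_fit.cov_params(), size=n_sim)
    a_s = m_draws[:, ia]
    b_s = y_draws[:, ib]
    c_s = y_draws[:, ic]
    acme_s = a_s * b_s
    total_s = acme_s + c_s
    prop_s = np.divide(acme_s, total_s, out=np.full(n_sim, np.nan), where=total_s != 0)

    def ci(x: np.ndarray) -> tuple[float, float]:
        return (float(np.nanpercentile(x, 2.5)), float(np.nanpercentile(x, 97.5)))

    total_ci = ci(total_s)
    unstable = total_ci[0] <= 0 <= total_ci[1]
    prop_ci = (-np.inf, np.inf) if unstable else ci(prop_s)
    return MediationResult(
        acme=float(acme_s.mean()), ade=float(c_s.mean()), total=float(total_s.mean()),
        proportion_mediated=float(np.nanmean(prop_s)),
        acme_ci=ci(acme_s), ade_ci=ci(c_s), total_ci=total_ci, proportion_ci=prop_ci,
        a=float(m_fit.params[ia]), b=float(y_fit.params[ib]), c_prime=float(y_fit.params[ic]),
        n_sim=n_sim, n=n, unstable_proportion=unstable,
    )


# ---------------------------------------------------------------------------
# targeted SNP association


def snp_meta_assoc(
    cohorts: Mapping[str, pd.DataFrame],
    dosage: str,
    outcome: str,
    covariates: Sequence[str] = (),
    n_tests: int = 81,
    method: str = "dl",
) -> tuple[MetaResult, float, pd.DataFrame]:
    """Per-region dosage association pooled across regions, Bonferroni-adjusted.

    Each region contributes an OLS coefficient for the (unstandardized) allele
    dosage with a z-standardized outcome; the per-region (beta, SE) pairs are
    pooled by random effects and the pooled p-value is multiplied by the size
    of the SNP panel (``n_tests``), capped at 1.
    """
    per_region = []
    for region, df in cohorts.items():
        r = linear_assoc(df, outcome, dosage, covariates, standardize=True)
        per_region.append({"region": region, "beta": r.beta, "se": r.se, "p": r.p, "n": r.n})
    table = pd.DataFrame(per_region)
    meta = meta_random_effects(table["beta"], table["se"], method=method)
    p_bf = min(1.0, meta.p * n_tests)
    return meta, p_bf, table
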