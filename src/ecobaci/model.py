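"""Negative-binomial many-GLM: per-taxon NB regressions on a shared design.

Each taxon's counts are modelled as ``Y_ij ~ NB(mu_j, Phi_j)`` with a log
link, ``log mu = X beta_j``, using the mean/size parameterization
``Var = mu + mu^2 / Phi`` (``Phi -> inf`` recovers Poisson).  Taxa are fitted
independently and combined through a summed log-likelihood; AIC counts every
regression coefficient plus one dispersion per taxon.  Treatment effects are
judged by AIC comparison of nested models, and term significance by
sequential analysis of deviance with p-values from resampling whole rows of
randomized-quantile (PIT) residuals, which preserves cross-taxon correlation.

This mirrors the model-based approach to multivariate abundance data used in
community ecology (the ``manyglm`` idiom), implemented here directly: IRLS
for the coefficients at fixed dispersion, alternated with a 1-D profile
maximum-likelihood update of the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy
from scipy.stats import nbinom

from .data import TaxonCountMatrix

__all__ = [
    "ModelSpec",
    "NBGlmFit",
    "MultiTaxonNB",
    "MultiTaxonNBResults",
    "ModelComparison",
    "fit_nb_glm",
    "nb_loglik",
    "compare_models_aic",
    "anova_deviance",
]

#: Reference levels come first; remaining levels get a dummy column each
#: (treatment-contrast coding).
_LEVEL_ORDER = {
    "period": ("before", "after"),
    "treatment": ("control", "treated"),
    "habitat": ("lawn", "forest"),
}

_THETA_MIN = 1e-3
_THETA_MAX = 1e8
_ETA_CLIP = 30.0
_AIC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of design factors for the log-linear mean model.

    The study's null model is ``('period', 'habitat', 'location')``; the
    alternative adds ``'treatment'``.  Factors are metadata columns of the
    count matrix; coding is treatment-contrast with a fixed reference level
    (``before``, ``control``, ``lawn``, else the lexicographically first).
    """

    terms: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in {self.terms}")

    @classmethod
    def null(cls) -> "ModelSpec":
        return cls(("period", "habitat", "location"))

    @classmethod
    def alternative(cls) -> "ModelSpec":
        return cls(("period", "habitat", "location", "treatment"))

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)

    def __str__(self) -> str:
        return "abundance ~ " + " + ".join(self.terms) if self.terms else "abundance ~ 1"


def _term_levels(values: pd.Series, term: str) -> list[str]:
    levels = sorted(values.astype(str).unique())
    preferred = _LEVEL_ORDER.get(term)
    if preferred:
        known = [l for l in preferred if l in levels]
        levels = known + [l for l in levels if l not in known]
    return levels


def build_design(meta: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept and reference-coded factor dummies."""
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.terms:
        if term not in meta.columns:
            raise ValueError(f"design factor {term!r} absent from metadata")
        values = meta[term].astype(str)
        levels = _term_levels(values, term)
        if len(levels) < 2:
            raise ValueError(
                f"factor {term!r} has a single level ({levels}); unidentifiable"
            )
        for level in levels[1:]:
            cols.append((values == level).to_numpy(dtype=float))
            names.append(f"{term}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for {spec} is rank deficient")
    return X, names


# -- single-taxon fit ------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB log-likelihood, mean/size form (Var = mu + mu^2/theta).

    Stable for arbitrarily large ``theta``: the gammaln difference
    ``lgamma(y + theta) - lgamma(theta)`` is catastrophically imprecise once
    theta exceeds ~1e10, so there it is replaced by its asymptotic expansion
    ``y log(theta) + y(y-1)/(2 theta) + O(y^3/theta^2)`` and the remaining
    terms are written with log1p; the Poisson limit is then exact.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if theta > 1e7:
        # sum_{k<y} log(1 + k/theta) via power sums, error O(y^5 / theta^4)
        s1 = y * (y - 1.0) / 2.0
        s2 = (y - 1.0) * y * (2.0 * y - 1.0) / 6.0
        s3 = s1**2
        inv = 1.0 / theta
        rising = y * np.log(theta) + inv * (s1 - inv * (s2 / 2.0 - inv * s3 / 3.0))
    else:
        rising = gammaln(y + theta) - gammaln(theta)
    return float(
        np.sum(
            rising
            - gammaln(y + 1.0)
            - theta * np.log1p(mu / theta)
            + xlogy(y, mu)
            - y * (np.log(theta) + np.log1p(mu / theta))
        )
    )


@dataclass
class NBGlmFit:
    """A single taxon's fitted NB regression."""

    coef: np.ndarray
    theta: float
    llf: float
    mu: np.ndarray
    converged: bool
    degenerate: bool = False
    n_iter: int = 0

    @property
    def n_params(self) -> int:
        # every coefficient plus the estimated dispersion
        return len(self.coef) + 1


def _irls(y, X, theta, beta, max_iter=40, tol=1e-10):
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        wx = X * w[:, None]
        a = X.T @ wx
        a.flat[:: a.shape[0] + 1] += 1e-12
        beta_new = np.linalg.solve(a, wx.T @ z)
        eta_new = np.clip(X @ beta_new, -_ETA_CLIP, _ETA_CLIP)
        done = np.max(np.abs(eta_new - eta)) < tol * (1.0 + np.max(np.abs(eta)))
        beta, eta = beta_new, eta_new
        if done:
            break
    return beta, np.exp(eta)


def _profile_theta(y, mu):
    """ML dispersion at fixed means, by Brent search on log(theta).

    For effectively Poisson data the profile is flat and increasing, so the
    interior optimum is compared against the bounds and the best taken (the
    supremum as theta -> inf is then attained at the cap, within ~1/theta).
    """
    lo, hi = np.log(_THETA_MIN), np.log(_THETA_MAX)
    res = minimize_scalar(
        lambda lt: -nb_loglik(y, mu, np.exp(lt)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best = min(
        [(res.fun, res.x)]
        + [(-nb_loglik(y, mu, np.exp(lt)), lt) for lt in (lo, hi)]
    )
    return float(np.exp(best[1]))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    theta: float | None = None,
    max_outer: int = 200,
    tol: float = 1e-8,
) -> NBGlmFit:
    """Maximum-likelihood NB regression with log link.

    Alternates IRLS updates of the coefficients at fixed dispersion with a
    bounded 1-D profile-likelihood update of ``theta``, until the relative
    log-likelihood change falls below ``tol``.  Pass ``theta`` to fix the
    dispersion (e.g. a huge value for a Poisson-limit fit).

    An all-zero response is degenerate: the mean is floored at 1e-8, the
    dispersion pinned at its upper bound, and the fit flagged; such taxa are
    kept in totals but excluded from likelihood-ratio statistics.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.any(y):
        coef = np.zeros(p)
        coef[0] = np.log(1e-8)
        mu = np.full(n, 1e-8)
        return NBGlmFit(coef, _THETA_MAX, nb_loglik(y, mu, _THETA_MAX), mu, True, True)

    fixed_theta = theta is not None
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    if not fixed_theta:
        m, v = y.mean(), y.var()
        theta = m**2 / (v - m) if v > m else 100.0
        theta = float(np.clip(theta, 0.05, 1e4))
    ll = -np.inf
    converged = False
    for it in range(1, max_outer + 1):
        beta, mu = _irls(y, X, theta, beta)
        if not fixed_theta:
            theta = _profile_theta(y, mu)
        ll_new = nb_loglik(y, mu, theta)
        if abs(ll_new - ll) <= tol * (abs(ll_new) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return NBGlmFit(beta, float(theta), ll, mu, converged, False, it)


def _fisher_cov(X, mu, theta):
    w = mu / (1.0 + mu / theta)
    a = X.T @ (X * w[:, None])
    a.flat[:: a.shape[0] + 1] += 1e-12
    return np.linalg.inv(a)


# -- multivariate model ----------------------------------------------------

class MultiTaxonNB:
    """Joint NB model for all taxa of a count matrix over one design.

    Statsmodels-style: construct from data, call :meth:`fit` for a
    :class:`MultiTaxonNBResults`.
    """

    def __init__(self, matrix: TaxonCountMatrix, spec: ModelSpec):
        self.matrix = matrix
        self.spec = spec
        self.exog, self.exog_names = build_design(matrix.meta, spec)

    @classmethod
    def from_terms(cls, matrix: TaxonCountMatrix, *terms: str) -> "MultiTaxonNB":
        return cls(matrix, ModelSpec(tuple(terms)))

    def fit(self, **kwargs) -> "MultiTaxonNBResults":
        fits = {
            taxon: fit_nb_glm(self.matrix.counts[taxon].to_numpy(), self.exog, **kwargs)
            for taxon in self.matrix.taxa
        }
        return MultiTaxonNBResults(self, fits)


@dataclass
class MultiTaxonNBResults:
    """Fitted many-GLM: per-taxon estimates plus pooled likelihood and AIC."""

    model: MultiTaxonNB
    fits: dict[str, NBGlmFit]

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def taxa(self) -> list[str]:
        return list(self.fits)

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients, taxa x design columns."""
        return pd.DataFrame(
            {t: f.coef for t, f in self.fits.items()},
            index=self.model.exog_names,
        ).T

    @property
    def dispersions(self) -> pd.Series:
        return pd.Series({t: f.theta for t, f in self.fits.items()}, name="dispersion")

    @property
    def llf_by_taxon(self) -> pd.Series:
        return pd.Series({t: f.llf for t, f in self.fits.items()}, name="llf")

    @property
    def llf(self) -> float:
        return float(sum(f.llf for f in self.fits.values()))

    @property
    def n_params(self) -> int:
        return int(sum(f.n_params for f in self.fits.values()))

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def df_resid(self) -> int:
        return self.model.exog.shape[0] - self.model.exog.shape[1]

    @property
    def fittedvalues(self) -> pd.DataFrame:
        return pd.DataFrame(
            {t: f.mu for t, f in self.fits.items()},
            index=self.model.matrix.meta["sample_id"].to_numpy(),
        )

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.fits.values())

    @property
    def degenerate_taxa(self) -> list[str]:
        return [t for t, f in self.fits.items() if f.degenerate]

    def bse(self) -> pd.DataFrame:
        """Per-taxon coefficient standard errors from the Fisher information."""
        rows = {}
        for t, f in self.fits.items():
            cov = _fisher_cov(self.model.exog, f.mu, f.theta)
            rows[t] = np.sqrt(np.diag(cov))
        return pd.DataFrame(rows, index=self.model.exog_names).T

    def compare(self, other: "MultiTaxonNBResults") -> "ModelComparison":
        return _compare_results(self, other)

    def anova(self, n_resamples: int = 999, seed: int | None = None,
              statistic: str = "LR") -> pd.DataFrame:
        return anova_deviance(
            self.model.matrix, self.spec, n_resamples=n_resamples,
            seed=seed, statistic=statistic,
        )

    def summary(self) -> str:
        lines = [
            "Multivariate negative-binomial GLM",
            f"  model:        {self.spec}",
            f"  observations: {self.model.exog.shape[0]}"
            f"    taxa: {len(self.fits)}    df resid: {self.df_resid}",
            f"  total log-likelihood: {self.llf:.2f}"
            f"    parameters: {self.n_params}    AIC: {self.aic:.1f}",
        ]
        if not self.converged:
            bad = [t for t, f in self.fits.items() if not f.converged]
            lines.append(f"  WARNING non-converged taxa (AIC approximate): {bad}")
        if self.degenerate_taxa:
            lines.append(f"  degenerate (all-zero) taxa: {self.degenerate_taxa}")
        lines.append("")
        tab = pd.DataFrame(
            {
                "dispersion": self.dispersions.round(3),
                "llf": self.llf_by_taxon.round(2),
                "mean_fit": self.fittedvalues.mean().round(2),
            }
        )
        lines.append(tab.to_string())
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """Nested-model AIC comparison (the study's treatment decision rule)."""

    spec_null: ModelSpec
    spec_alt: ModelSpec
    aic_null: float
    aic_alt: float
    lr: float
    p_value: float | None = None
    n_resamples: int | None = None

    @property
    def delta_aic(self) -> float:
        return self.aic_alt - self.aic_null

    @property
    def preferred(self) -> str:
        # ties (within numerical noise) go to the smaller model
        return "alternative" if self.delta_aic < -_AIC_TIE_TOL else "null"

    def as_table(self) -> pd.DataFrame:
        """Two-row layout: model, residual df, LR, P, AIC, delta AIC."""
        return pd.DataFrame(
            {
                "model": [str(self.spec_null), str(self.spec_alt)],
                "res_df": [np.nan, np.nan],
                "likelihood_ratio": [np.nan, self.lr],
                "p_value": [np.nan, self.p_value],
                "aic": [self.aic_null, self.aic_alt],
                "delta_aic": [0.0, self.delta_aic],
            }
        )


def _compare_results(
    null_res: MultiTaxonNBResults, alt_res: MultiTaxonNBResults
) -> ModelComparison:
    if not null_res.spec.is_nested_in(alt_res.spec):
        raise ValueError(
            f"{null_res.spec} is not nested in {alt_res.spec}"
        )
    keep = [t for t in null_res.taxa if not null_res.fits[t].degenerate]
    lr = 2.0 * sum(alt_res.fits[t].llf - null_res.fits[t].llf for t in keep)
    return ModelComparison(
        null_res.spec, alt_res.spec, null_res.aic, alt_res.aic, lr
    )


def compare_models_aic(
    matrix: TaxonCountMatrix,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    n_resamples: int | None = None,
    seed: int | None = None,
) -> ModelComparison:
    """Fit null and alternative on identical rows and compare by AIC.

    With ``n_resamples`` set, a resampling p-value for the added terms is
    computed by the same PIT-residual row-permutation scheme as
    :func:`anova_deviance`.
    """
    if not null_spec.is_nested_in(alt_spec):
        raise ValueError(f"{null_spec} is not nested in {alt_spec}")
    null_res = MultiTaxonNB(matrix, null_spec).fit()
    alt_res = MultiTaxonNB(matrix, alt_spec).fit()
    cmp = _compare_results(null_res, alt_res)
    if n_resamples is not None:
        lr_star = _resample_lr(
            matrix, null_res, alt_spec, n_resamples, np.random.default_rng(seed)
        )
        cmp.p_value = float((1 + np.sum(lr_star >= cmp.lr - 1e-9)) / (1 + n_resamples))
        cmp.n_resamples = n_resamples
    return cmp


# -- analysis of deviance with row resampling ------------------------------

def _pit_residuals(y: np.ndarray, mu: np.ndarray, theta: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomized quantile (Dunn-Smyth / PIT) residuals on the uniform scale."""
    p = theta / (theta + mu)
    hi = nbinom.cdf(y, theta, p)
    lo = np.where(y > 0, nbinom.cdf(y - 1, theta, p), 0.0)
    u = lo + rng.uniform(size=y.shape) * (hi - lo)
    return np.clip(u, 1e-10, 1.0 - 1e-10)


def _pit_counts(u: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mu)
    return nbinom.ppf(u, theta, p)


def _resample_lr(
    matrix: TaxonCountMatrix,
    small_res: MultiTaxonNBResults,
    big_spec: ModelSpec,
    n_resamples: int,
    rng: np.random.Generator,
    statistic: str = "LR",
) -> np.ndarray:
    """Null distribution of the added-terms statistic under the smaller model.

    Whole rows of the PIT-residual matrix are permuted together, preserving
    the cross-taxon correlation structure, then mapped back to counts through
    the smaller model's fitted distributions and both models refitted.
    """
    X_small = small_res.model.exog
    X_big, big_names = build_design(matrix.meta, big_spec)
    keep = [t for t in small_res.taxa if not small_res.fits[t].degenerate]
    n = X_small.shape[0]
    U = np.column_stack(
        [
            _pit_residuals(
                matrix.counts[t].to_numpy(), small_res.fits[t].mu,
                small_res.fits[t].theta, rng,
            )
            for t in keep
        ]
    )
    extra = [j for j, name in enumerate(big_names)
             if name not in small_res.model.exog_names]
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        perm = rng.permutation(n)
        stat = 0.0
        for k, t in enumerate(keep):
            f = small_res.fits[t]
            y_star = _pit_counts(U[perm, k], f.mu, f.theta)
            if not np.any(y_star):
                continue
            f_small = fit_nb_glm(y_star, X_small)
            f_big = fit_nb_glm(y_star, X_big)
            if statistic == "LR":
                stat += 2.0 * (f_big.llf - f_small.llf)
            else:
                stat += _wald_stat(f_big, X_big, extra)
        stats[b] = stat
    return stats


def _wald_stat(fit: NBGlmFit, X: np.ndarray, cols: list[int]) -> float:
    cov = _fisher_cov(X, fit.mu, fit.theta)
    b = fit.coef[cols]
    sub = cov[np.ix_(cols, cols)]
    return float(b @ np.linalg.solve(sub, b))


def anova_deviance(
    matrix: TaxonCountMatrix,
    spec: ModelSpec,
    n_resamples: int = 999,
    seed: int | None = None,
    statistic: str = "LR",
) -> pd.DataFrame:
    """Sequential (type-I) analysis of deviance with row-resampling p-values.

    Terms are added in the spec's order; for each, the statistic (summed over
    taxa) compares the model with and without it, and its p-value is
    ``(1 + #[resampled >= observed]) / (1 + n_resamples)`` under row
    permutation of PIT residuals from the smaller model.  ``statistic`` is
    ``"LR"`` (default) or ``"wald"``.
    """
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99 for usable p-value resolution")
    if statistic not in ("LR", "wald"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for i, term in enumerate(spec.terms):
        small = ModelSpec(spec.terms[:i])
        big = ModelSpec(spec.terms[: i + 1])
        small_res = MultiTaxonNB(matrix, small).fit()
        big_res = MultiTaxonNB(matrix, big).fit()
        keep = [t for t in small_res.taxa if not small_res.fits[t].degenerate]
        X_big, big_names = build_design(matrix.meta, big)
        extra = [j for j, name in enumerate(big_names)
                 if name not in small_res.model.exog_names]
        if statistic == "LR":
            obs = 2.0 * sum(big_res.fits[t].llf - small_res.fits[t].llf for t in keep)
        else:
            obs = sum(_wald_stat(big_res.fits[t], X_big, extra) for t in keep)
        null_dist = _resample_lr(matrix, small_res, big, n_resamples, rng, statistic)
        p = float((1 + np.sum(null_dist >= obs - 1e-9)) / (1 + n_resamples))
        rows.append(
            {
                "term": term,
                "df": len(extra),
                "statistic": statistic,
                "value": obs,
                "p_value": p,
                "n_resamples": n_resamples,
            }
        )
    return pd.DataFrame(rows)
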