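"""The NB many-GLM: likelihood, AIC bookkeeping, nesting, deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import nbinom

from ecobaci import (
    ModelSpec,
    MultiTaxonNB,
    TaxonCountMatrix,
    anova_deviance,
    compare_models_aic,
    fit_nb_glm,
)
from ecobaci.model import build_design, nb_loglik
from conftest import make_matrix


def _direct_optimum(y, X):
    """Independent oracle: direct Nelder-Mead over (beta, log theta)."""
    def nll(p):
        mu = np.exp(np.clip(X @ p[:-1], -30, 30))
        return -nb_loglik(y, mu, np.exp(p[-1]))

    best = None
    for b0 in (0.0, 1.0):
        for lt in (-1.0, 0.0, 2.0):
            x0 = np.r_[np.full(X.shape[1], b0), lt]
            r = minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000})
            if best is None or r.fun < best.fun:
                best = r
    return -best.fun, best.x


class TestSingleTaxonFit:
    def test_intercept_only_mean_is_mle(self):
        fit = fit_nb_glm(np.array([2.0, 2, 2, 2]), np.ones((4, 1)))
        assert fit.mu == pytest.approx(2.0)
        assert fit.coef[0] == pytest.approx(np.log(2.0))

    def test_loglik_matches_scipy_pmf(self):
        rng = np.random.default_rng(0)
        y = rng.negative_binomial(2.0, 0.3, 50).astype(float)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        fit = fit_nb_glm(y, X)
        p = fit.theta / (fit.theta + fit.mu)
        direct = nbinom.logpmf(y, fit.theta, p).sum()
        assert fit.llf == pytest.approx(direct, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_independent_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(10), rng.integers(0, 2, 10).astype(float)])
        mu = np.exp(0.5 + 0.8 * X[:, 1])
        y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu)).astype(float)
        fit = fit_nb_glm(y, X)
        oracle_llf, _ = _direct_optimum(y, X)
        assert fit.llf == pytest.approx(oracle_llf, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(42)
        n = 5000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        beta, theta = np.array([1.0, -0.7]), 1.3
        mu = np.exp(X @ beta)
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        fit = fit_nb_glm(y, X)
        # 3 standard errors from the Fisher information
        from ecobaci.model import _fisher_cov

        se = np.sqrt(np.diag(_fisher_cov(X, fit.mu, fit.theta)))
        assert np.all(np.abs(fit.coef - beta) < 3 * se)
        assert fit.theta == pytest.approx(theta, rel=0.15)

    def test_poisson_limit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = rng.poisson(np.exp(0.3 + 0.5 * X[:, 1])).astype(float)
        fit = fit_nb_glm(y, X, theta=1e6)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.coef == pytest.approx(pois.params, abs=1e-4)

    def test_all_zero_degenerate(self):
        fit = fit_nb_glm(np.zeros(8), np.ones((8, 1)))
        assert fit.degenerate and fit.converged
        assert fit.mu == pytest.approx(1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glm(np.array([1.0, -1.0]), np.ones((2, 1)))


@pytest.fixture(scope="module")
def toy_matrix():
    rng = np.random.default_rng(8)
    n = 48
    occ = np.tile(["pre", "post1"], n // 2)
    hab = np.repeat(["lawn", "forest"], n // 2)
    trt = np.tile(["control", "control", "treated", "treated"], n // 4)
    mu = 5 * np.exp(0.8 * (hab == "forest"))
    counts = {
        "acari": rng.negative_binomial(1.0, 1 / (1 + 40 * mu / 5)),
        "diptera": rng.negative_binomial(1.5, 1.5 / (1.5 + mu)),
        "araneae": rng.poisson(2.0, n),
    }
    return make_matrix(counts, occasion=occ, habitat=hab, treatment=trt)


class TestManyGLM:
    def test_single_taxon_reduces_to_univariate(self, toy_matrix):
        one = TaxonCountMatrix(
            toy_matrix.counts[["diptera"]], toy_matrix.meta
        )
        res = MultiTaxonNB(one, ModelSpec(("habitat",))).fit()
        X, _ = build_design(toy_matrix.meta, ModelSpec(("habitat",)))
        uni = fit_nb_glm(toy_matrix.counts["diptera"].to_numpy(), X)
        assert res.aic == pytest.approx(-2 * uni.llf + 2 * uni.n_params)

    def test_duplicated_taxon_doubles_totals(self, toy_matrix):
        spec = ModelSpec(("habitat",))
        base = MultiTaxonNB(toy_matrix, spec).fit()
        doubled_counts = toy_matrix.counts.copy()
        doubled_counts["diptera_copy"] = doubled_counts["diptera"]
        doubled = TaxonCountMatrix(doubled_counts, toy_matrix.meta)
        res = MultiTaxonNB(doubled, spec).fit()
        extra = base.fits["diptera"]
        assert res.llf == pytest.approx(base.llf + extra.llf)
        assert res.n_params == base.n_params + extra.n_params

    def test_aic_identity(self, toy_matrix):
        res = MultiTaxonNB(toy_matrix, ModelSpec(("period", "habitat"))).fit()
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params)

    def test_noise_factor_parameter_bookkeeping(self, toy_matrix):
        # adding a k-level factor adds (k-1) x n_taxa parameters
        base = MultiTaxonNB(toy_matrix, ModelSpec(("habitat",))).fit()
        more = MultiTaxonNB(toy_matrix, ModelSpec(("habitat", "treatment"))).fit()
        k = toy_matrix.meta["treatment"].nunique()
        assert more.n_params - base.n_params == (k - 1) * len(toy_matrix.taxa)

    def test_single_level_factor_named_in_error(self, toy_matrix):
        with pytest.raises(ValueError, match="location"):
            MultiTaxonNB(toy_matrix, ModelSpec(("habitat", "location")))

    def test_degenerate_taxon_flagged_and_retained(self, toy_matrix):
        counts = toy_matrix.counts.copy()
        counts["ghost"] = 0.0
        m = TaxonCountMatrix(counts, toy_matrix.meta)
        null = MultiTaxonNB(m, ModelSpec(("period",))).fit()
        alt = MultiTaxonNB(m, ModelSpec(("period", "habitat"))).fit()
        assert null.degenerate_taxa == ["ghost"]
        assert "ghost" in null.taxa  # retained in output
        cmp = null.compare(alt)
        no_ghost = compare_models_aic(
            TaxonCountMatrix(toy_matrix.counts, toy_matrix.meta),
            ModelSpec(("period",)), ModelSpec(("period", "habitat")),
        )
        assert cmp.lr == pytest.approx(no_ghost.lr)  # excluded from LR

    def test_summary_renders(self, toy_matrix):
        s = MultiTaxonNB(toy_matrix, ModelSpec(("habitat",))).fit().summary()
        assert "AIC" in s and "diptera" in s


class TestModelComparison:
    def test_identical_specs_tie_prefers_null(self, toy_matrix):
        spec = ModelSpec(("period", "habitat"))
        cmp = compare_models_aic(toy_matrix, spec, spec)
        assert cmp.delta_aic == pytest.approx(0.0)
        assert cmp.preferred == "null"

    def test_lr_nonnegative_for_nested(self, toy_matrix):
        cmp = compare_models_aic(
            toy_matrix, ModelSpec(("period",)), ModelSpec(("period", "habitat"))
        )
        assert cmp.lr >= -1e-6

    def test_non_nested_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="nested"):
            compare_models_aic(
                toy_matrix, ModelSpec(("period",)), ModelSpec(("habitat",))
            )

    def test_table_layout(self, toy_matrix):
        cmp = compare_models_aic(
            toy_matrix, ModelSpec(("period",)), ModelSpec(("period", "habitat"))
        )
        tab = cmp.as_table()
        assert list(tab["aic"]) == [cmp.aic_null, cmp.aic_alt]
        assert tab["delta_aic"].iloc[1] == pytest.approx(cmp.delta_aic)


class TestAnovaDeviance:
    def test_resolution_floor(self, toy_matrix):
        with pytest.raises(ValueError):
            anova_deviance(toy_matrix, ModelSpec(("habitat",)), n_resamples=50)

    def test_duplicated_rows_double_lr(self, toy_matrix):
        spec = ModelSpec(("habitat",))
        single = anova_deviance(toy_matrix, spec, n_resamples=99, seed=1)
        doubled = TaxonCountMatrix(
            pd.concat([toy_matrix.counts] * 2, ignore_index=True),
            pd.concat([toy_matrix.meta] * 2, ignore_index=True).assign(
                sample_id=lambda d: d["sample_id"] + np.where(
                    np.arange(len(d)) < len(toy_matrix.meta), "", "_dup"
                )
            ),
        )
        double = anova_deviance(doubled, spec, n_resamples=99, seed=1)
        assert double["value"].iloc[0] == pytest.approx(
            2 * single["value"].iloc[0], rel=1e-6
        )

    def test_real_effect_detected(self, toy_matrix):
        # habitat truly shifts two taxa; period does not
        dev = anova_deviance(
            toy_matrix, ModelSpec(("habitat", "period")), n_resamples=199, seed=2
        )
        assert dev.loc[dev["term"] == "habitat", "p_value"].iloc[0] <= 0.05
        assert dev.loc[dev["term"] == "period", "p_value"].iloc[0] > 0.05

    def test_wald_statistic_positive(self, toy_matrix):
        dev = anova_deviance(
            toy_matrix, ModelSpec(("habitat",)), n_resamples=99, seed=3,
            statistic="wald",
        )
        assert (dev["value"] > 0).all()

    def test_null_term_pvalues_roughly_uniform(self):
        """For a factor with no true effect the resampling p-value should be
        (discretely) uniform; check mean and spread over repeated draws."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(25):
            n = 30
            m = make_matrix(
                {"a": rng.poisson(4.0, n), "b": rng.negative_binomial(1.0, 0.25, n)},
                treatment=np.where(rng.random(n) < 0.5, "treated", "control"),
            )
            dev = anova_deviance(
                m, ModelSpec(("treatment",)), n_resamples=99,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(dev["p_value"].iloc[0])
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.2)
        assert min(pvals) < 0.4 and max(pvals) > 0.6
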