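"""The conditional block estimator: exactness, variances and invariances."""

import numpy as np
import pytest

from condgwas import oracle, simulate
from condgwas.conditional import (
    ConditionalExtras,
    approx_conditional,
    build_cross_products,
    conditional_multi,
    cov_beta1_gamma_m,
    solve_block,
    var_block_binary,
    var_block_continuous,
)
from condgwas.errors import CollinearityError, InputError
from condgwas.reconstruct import CrossProducts
from condgwas.relationship import (
    PhenotypeTable,
    TraitRelationship,
    estimate_gamma_m,
    pairwise_relationships,
)
from condgwas.simulate import SimConfig
from condgwas.summary_io import SummaryRecord

from conftest import exact_cross_products


def make_cc_data(seed=0, n=800, maf=0.25):
    rng = np.random.default_rng(seed)
    rep = simulate.gen_cc(n, maf, SimConfig(), rng)
    return rep.x.astype(float), rep.y1, rep.y2


def marginal_slope(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / (xc @ xc))


class TestSolveBlock:
    def test_orthogonal_covariate_returns_marginals(self):
        cp = CrossProducts(xtx=375.0, xty1=80.0, xty2=0.0, y1ty1=900.0, y2ty2=950.0, n=1000)
        beta, gamma = solve_block(cp, 0.231, 0.5)
        assert beta == pytest.approx(0.231)
        assert gamma == pytest.approx(0.5)

    def test_no_confounding(self):
        cp = CrossProducts(xtx=375.0, xty1=80.0, xty2=0.0, y1ty1=900.0, y2ty2=950.0, n=1000)
        assert solve_block(cp, 0.231, 0.0) == pytest.approx((0.231, 0.0))

    def test_singular_v_raises(self):
        cp = CrossProducts(
            xtx=100.0, xty1=0.0, xty2=100.0, y1ty1=900.0, y2ty2=100.0, n=1000
        )
        with pytest.raises(CollinearityError):
            solve_block(cp, 0.1, 0.1)


class TestExactness:
    """With exact cross-products the block algebra IS the adjusted OLS fit."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_point_estimates_and_se_match_ols(self, seed):
        x, y1, y2 = make_cc_data(seed)
        cp = exact_cross_products(x, y1, y2)
        gamma_m = marginal_slope(y2, y1)
        beta, gamma = solve_block(cp, marginal_slope(x, y1), gamma_m)
        xc, y1c, y2c = x - x.mean(), y1 - y1.mean(), y2 - y2.mean()
        fit = oracle.fit_ols(y1c, np.column_stack([xc, y2c]))
        assert beta == pytest.approx(fit.coef[0], abs=1e-10)
        assert gamma == pytest.approx(fit.coef[1], abs=1e-10)
        cov = var_block_continuous(cp, beta, gamma, len(x))
        assert np.sqrt(cov[0, 0]) == pytest.approx(fit.se[0], abs=1e-10)
        assert np.sqrt(cov[1, 1]) == pytest.approx(fit.se[1], abs=1e-10)

    def test_api_route_with_exact_cross_products(self):
        x, y1, y2 = make_cc_data(3)
        cp = exact_cross_products(x, y1, y2)
        rel = estimate_gamma_m(PhenotypeTable(y1, y2))
        out = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y1), 0.05, len(x))
        cov_rec = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y2), 0.05, len(x))
        res = approx_conditional(out, cov_rec, rel, cross_products=cp)
        xc, y1c, y2c = x - x.mean(), y1 - y1.mean(), y2 - y2.mean()
        fit = oracle.fit_ols(y1c, np.column_stack([xc, y2c]))
        assert res.beta_adj == pytest.approx(fit.coef[0], abs=1e-10)
        assert res.se_adj == pytest.approx(fit.se[0], abs=1e-10)


class TestVarBlockContinuous:
    def test_sample_size_scaling(self):
        x, y1, y2 = make_cc_data(4)
        cp = exact_cross_products(x, y1, y2)
        beta, gamma = solve_block(cp, marginal_slope(x, y1), marginal_slope(y2, y1))
        v1 = var_block_continuous(cp, beta, gamma, cp.n)
        cp2 = CrossProducts(
            xtx=2 * cp.xtx, xty1=2 * cp.xty1, xty2=2 * cp.xty2,
            y1ty1=2 * cp.y1ty1, y2ty2=2 * cp.y2ty2, n=2 * cp.n, y1ty2=2 * cp.y1ty2,
        )
        v2 = var_block_continuous(cp2, beta, gamma, 2 * cp.n)
        assert v2[0, 0] / v1[0, 0] == pytest.approx(0.5, rel=0.01)


class TestCovBeta1GammaM:
    def test_orthogonality_kills_covariance(self):
        cp = CrossProducts(
            xtx=375.0, xty1=50.0, xty2=0.0, y1ty1=900.0, y2ty2=950.0, n=1000, y1ty2=100.0
        )
        assert cov_beta1_gamma_m(cp, 0.01, 0.02, 1000) == 0.0

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_sign_follows_xty2(self, sign):
        cp = CrossProducts(
            xtx=375.0, xty1=50.0, xty2=sign * 60.0, y1ty1=900.0, y2ty2=950.0,
            n=1000, y1ty2=100.0,
        )
        assert np.sign(cov_beta1_gamma_m(cp, 0.01, 0.02, 1000)) == sign

    def test_matches_resampling_oracle(self):
        """Empirical covariance of the two marginal OLS slopes at fixed X, Y2."""
        rng = np.random.default_rng(7)
        n = 300
        x = rng.binomial(2, 0.3, n).astype(float)
        y2 = 0.5 * x + rng.normal(size=n)
        xc, y2c = x - x.mean(), y2 - y2.mean()
        b1s, gms = [], []
        for _ in range(8000):
            y1 = 0.2 * x + 0.4 * y2 + rng.normal(size=n)
            y1c = y1 - y1.mean()
            b1s.append((xc @ y1c) / (xc @ xc))
            gms.append((y2c @ y1c) / (y2c @ y2c))
        emp_cov = np.cov(b1s, gms)[0, 1]
        # one representative replicate supplies the cross-products
        y1 = 0.2 * x + 0.4 * y2 + rng.normal(size=n)
        cp = exact_cross_products(x, y1, y2)
        got = cov_beta1_gamma_m(cp, np.var(b1s, ddof=1), np.var(gms, ddof=1), n)
        assert got == pytest.approx(emp_cov, rel=0.15)


class TestVarBlockBinary:
    def test_orthogonal_zero_cov_is_diagonal(self):
        cp = CrossProducts(
            xtx=375.0, xty1=50.0, xty2=0.0, y1ty1=160.0, y2ty2=160.0, n=1000, y1ty2=10.0
        )
        out = var_block_binary(cp, 0.04, 0.09, 0.0)
        np.testing.assert_allclose(out, np.diag([0.04, 0.09]), atol=1e-12)

    def test_symmetric_nonnegative_diagonal(self):
        cp = CrossProducts(
            xtx=375.0, xty1=50.0, xty2=40.0, y1ty1=160.0, y2ty2=160.0, n=1000, y1ty2=30.0
        )
        out = var_block_binary(cp, 0.04, 0.09, 0.02)
        np.testing.assert_allclose(out, out.T, atol=1e-15)
        assert out[0, 0] >= 0 and out[1, 1] >= 0

    def test_non_psd_sigma_clipped_with_warning(self):
        cp = CrossProducts(
            xtx=375.0, xty1=50.0, xty2=40.0, y1ty1=160.0, y2ty2=160.0, n=1000, y1ty2=30.0
        )
        with pytest.warns(UserWarning, match="clipped"):
            var_block_binary(cp, 0.04, 0.09, 10.0)


class TestApproxConditional:
    def test_marginally_null_covariate_leaves_beta_unchanged(self):
        cp = CrossProducts(
            xtx=375.0, xty1=86.6, xty2=0.0, y1ty1=990.0, y2ty2=950.0, n=1000
        )
        out = SummaryRecord("v", "A", "G", 0.25, 0.231, 0.051, 1000)
        cov_rec = SummaryRecord("v", "A", "G", 0.25, 0.0, 0.051, 1000)
        rel = TraitRelationship(0.45, 0.001)
        res = approx_conditional(out, cov_rec, rel, cross_products=cp)
        assert res.beta_adj == pytest.approx(0.231)

    def test_allele_flip_antisymmetry(self):
        out = SummaryRecord("v", "A", "G", 0.25, 0.231, 0.051, 1000)
        cov_rec = SummaryRecord("v", "A", "G", 0.25, 0.31, 0.049, 1000)
        rel = TraitRelationship(0.45, 0.001)
        res = approx_conditional(out, cov_rec, rel)
        res_flip = approx_conditional(out.flipped(), cov_rec.flipped(), rel)
        assert res_flip.beta_adj == pytest.approx(-res.beta_adj, rel=1e-10)
        assert res_flip.se_adj == pytest.approx(res.se_adj, rel=1e-10)

    def test_covariate_rescaling_invariance(self):
        """Rescaling the covariate (with gamma_m rescaled consistently) leaves beta alone."""
        x, y1, y2 = make_cc_data(5)
        c = 3.7
        rel = estimate_gamma_m(PhenotypeTable(y1, y2))
        rel_c = estimate_gamma_m(PhenotypeTable(y1, c * y2))
        out = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y1), 0.05, len(x))
        cov1 = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y2), 0.05, len(x))
        cov2 = SummaryRecord(
            "v", "A", "G", x.mean() / 2, marginal_slope(x, c * y2), 0.05 * c, len(x)
        )
        r1 = approx_conditional(out, cov1, rel)
        r2 = approx_conditional(out, cov2, rel_c)
        assert r2.beta_adj == pytest.approx(r1.beta_adj, rel=1e-8)
        assert r2.se_adj == pytest.approx(r1.se_adj, rel=1e-8)

    def test_link_consistency_enforced(self):
        out = SummaryRecord(
            "v", "A", "G", 0.25, 0.2, 0.05, 1000,
            trait_type="binary", n_cases=200, n_controls=800,
        )
        cov_rec = SummaryRecord("v", "A", "G", 0.25, 0.3, 0.05, 1000)
        with pytest.raises(InputError, match="link"):
            approx_conditional(out, cov_rec, TraitRelationship(0.4, 0.01, link="identity"))

    def test_low_maf_binary_binary_flagged(self):
        out = SummaryRecord(
            "v", "A", "G", 0.005, 0.2, 0.3, 2000,
            trait_type="binary", n_cases=400, n_controls=1600,
        )
        cov_rec = SummaryRecord(
            "v", "A", "G", 0.005, 0.3, 0.3, 2000,
            trait_type="binary", n_cases=500, n_controls=1500,
        )
        rel = TraitRelationship(0.5, 0.01, link="logit")
        res = approx_conditional(
            out, cov_rec, rel, extras=ConditionalExtras(mean_y2_cases=0.4, mean_y2_controls=0.2)
        )
        assert "low_maf_binary_binary_bias" in res.method_flags

    def test_binary_outcome_requires_means_or_full_relationship(self):
        out = SummaryRecord(
            "v", "A", "G", 0.25, 0.2, 0.1, 1000,
            trait_type="binary", n_cases=200, n_controls=800,
        )
        cov_rec = SummaryRecord("v", "A", "G", 0.25, 0.3, 0.05, 1000)
        rel = TraitRelationship(0.5, 0.01, link="logit", source="literature")
        with pytest.raises(InputError, match="means"):
            approx_conditional(out, cov_rec, rel)

    def test_build_cross_products_reconstruction_accuracy(self):
        """Reconstructed V entries track the literal ones on simulated data."""
        x, y1, y2 = make_cc_data(6, n=2000)
        exact = exact_cross_products(x, y1, y2)
        rel = estimate_gamma_m(PhenotypeTable(y1, y2))
        n = len(x)
        xc = x - x.mean()
        se1 = oracle.fit_ols(y1, np.column_stack([np.ones(n), x])).se[1]
        se2 = oracle.fit_ols(y2, np.column_stack([np.ones(n), x])).se[1]
        out = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y1), se1, n)
        cov_rec = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y2), se2, n)
        cp, flags = build_cross_products(out, cov_rec, rel)
        assert "hwe_xtx" in flags
        assert cp.xtx == pytest.approx(xc @ xc, rel=0.05)
        assert cp.y1ty1 == pytest.approx(exact.y1ty1, rel=0.05)
        assert cp.y2ty2 == pytest.approx(exact.y2ty2, rel=0.05)
        assert cp.xty2 == pytest.approx(exact.xty2, rel=0.1)


class TestConditionalMulti:
    def _setup(self, seed=0, n=700):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.3, n).astype(float)
        y2 = 0.3 * x + rng.normal(size=n)
        y3 = 0.1 * x + 0.4 * y2 + rng.normal(size=n)
        y1 = 0.2 * x + 0.5 * y2 - 0.3 * y3 + rng.normal(size=n)
        return x, y1, y2, y3

    def _records(self, x, y1, y2s, ses=0.05):
        n = len(x)
        out = SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y1), ses, n)
        covs = [
            SummaryRecord("v", "A", "G", x.mean() / 2, marginal_slope(x, y), ses, n)
            for y in y2s
        ]
        return out, covs

    def test_matches_full_ols_with_exact_cross_products(self):
        x, y1, y2, y3 = self._setup()
        rel = pairwise_relationships(PhenotypeTable(y1, np.column_stack([y2, y3])))
        out, covs = self._records(x, y1, [y2, y3])
        xc = x - x.mean()
        y1c, y2c, y3c = y1 - y1.mean(), y2 - y2.mean(), y3 - y3.mean()
        res = conditional_multi(
            out, covs, rel,
            overrides=dict(
                xtx=xc @ xc, xty=[xc @ y2c, xc @ y3c], xty1=xc @ y1c, y1ty1=y1c @ y1c
            ),
        )
        fit = oracle.fit_ols(y1c, np.column_stack([xc, y2c, y3c]))
        assert res.beta_adj == pytest.approx(fit.coef[0], abs=1e-10)
        assert res.se_adj == pytest.approx(fit.se[0], abs=1e-10)

    def test_single_covariate_reduces_to_approx_conditional(self):
        x, y1, y2, _ = self._setup(1)
        relm = pairwise_relationships(PhenotypeTable(y1, y2))
        rel1 = estimate_gamma_m(PhenotypeTable(y1, y2))
        out, covs = self._records(x, y1, [y2])
        cp = exact_cross_products(x, y1, y2)
        res_multi = conditional_multi(
            out, covs, relm,
            overrides=dict(xtx=cp.xtx, xty=[cp.xty2], xty1=cp.xty1, y1ty1=cp.y1ty1),
        )
        res_single = approx_conditional(out, covs[0], rel1, cross_products=cp)
        assert res_multi.beta_adj == pytest.approx(res_single.beta_adj, abs=1e-10)
        assert res_multi.se_adj == pytest.approx(res_single.se_adj, abs=1e-10)

    def test_orthogonal_covariates_leave_beta_marginal(self, rng):
        n = 500
        x = rng.binomial(2, 0.3, n).astype(float)
        y2 = rng.normal(size=n)
        y3 = rng.normal(size=n)
        y1 = 0.2 * x + rng.normal(size=n)
        rel = pairwise_relationships(PhenotypeTable(y1, np.column_stack([y2, y3])))
        out, covs = self._records(x, y1, [y2, y3])
        res = conditional_multi(out, covs, rel, overrides=dict(xty=[0.0, 0.0]))
        assert res.beta_adj == pytest.approx(out.beta, rel=1e-8)

    def test_collinear_covariates_raise(self, rng):
        n = 400
        x = rng.binomial(2, 0.3, n).astype(float)
        y2 = rng.normal(size=n)
        y1 = 0.2 * x + rng.normal(size=n)
        with pytest.raises((CollinearityError, InputError)):
            rel = pairwise_relationships(
                PhenotypeTable(
                    y1, np.column_stack([y2, y2 * 0.3 + 1e-9 * rng.normal(size=n)])
                )
            )
            out, covs = self._records(x, y1, [y2, y2])
            conditional_multi(out, covs, rel)
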