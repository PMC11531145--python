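"""jSDM: probit fits, MC likelihood, lattice structure, attribution, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm, rankdata

from rootfungi.jsdm import (
    COMPARISON_PAIRS,
    MODEL_LATTICE,
    DesignMatrices,
    JointProbitModel,
    ModelSpec,
    fit_lattice,
    per_otu_llr,
    roc_auc,
    steel_dwass,
)
from rootfungi.community import CommunityDataError


def _designs(n, x=None, index=None):
    index = index or [f"s{i}" for i in range(n)]
    p = pd.DataFrame(index=index) if x is None else pd.DataFrame({"x": x}, index=index)
    empty = pd.DataFrame(index=index)
    return DesignMatrices(index, p, empty.copy(), empty.copy())


class TestProbitFit:
    def test_intercept_only_equals_probit_of_prevalence(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=200) < 0.25).astype(int)
        resp = pd.DataFrame({"o": y}, index=[f"s{i}" for i in range(200)])
        fit = JointProbitModel(resp, _designs(200), ModelSpec(), seed=0,
                               n_factors=0).fit(ridge=0.0)
        assert fit.b.iloc[0, 0] == pytest.approx(norm.ppf(y.mean()), abs=1e-6)

    def test_single_covariate_matches_irls_oracle(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < norm.cdf(-0.4 + 0.9 * x)).astype(int)
        resp = pd.DataFrame({"o": y}, index=[f"s{i}" for i in range(n)])
        fit = JointProbitModel(resp, _designs(n, x), ModelSpec(include_p=True),
                               n_factors=0, seed=0).fit(ridge=0.0)
        oracle = sm.Probit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.b.to_numpy().ravel(), oracle.params, atol=1e-4)

    def test_default_ridge_stays_within_oracle_tolerance(self):
        rng = np.random.default_rng(2)
        n = 250
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < norm.cdf(0.3 * x)).astype(int)
        resp = pd.DataFrame({"o": y}, index=[f"s{i}" for i in range(n)])
        fit = JointProbitModel(resp, _designs(n, x), ModelSpec(include_p=True),
                               n_factors=0, seed=0).fit()
        oracle = sm.Probit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.b.to_numpy().ravel(), oracle.params, atol=1e-4)

    def test_cov_requires_latent_factor(self):
        resp = pd.DataFrame({"o": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            JointProbitModel(resp, _designs(2, index=["a", "b"]),
                             ModelSpec(include_cov=True), n_factors=0)

    def test_loading_recovery_on_simulated_factors(self):
        rng = np.random.default_rng(3)
        n, s, r = 300, 40, 2
        lam = rng.normal(0, 0.9, size=(s, r))
        alpha = norm.ppf(rng.uniform(0.15, 0.5, s))
        u = rng.standard_normal((n, r))
        eta = alpha[None] + u @ lam.T
        y = (rng.uniform(size=eta.shape) < norm.cdf(eta)).astype(int)
        resp = pd.DataFrame(y, index=[f"s{i}" for i in range(n)],
                            columns=[f"o{j}" for j in range(s)])
        fit = JointProbitModel(resp, _designs(n), ModelSpec(include_cov=True),
                               n_factors=2, mc_samples=100, seed=5).fit()
        def latent_corr(l):
            c = l @ l.T + np.eye(s)
            d = np.sqrt(np.diag(c))
            return c / np.outer(d, d)
        iu = np.triu_indices(s, 1)
        mae = np.abs(latent_corr(lam)[iu] - latent_corr(fit.loadings.to_numpy())[iu]).mean()
        assert mae < 0.15

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        y = (rng.uniform(size=(60, 5)) < 0.3).astype(int)
        resp = pd.DataFrame(y, index=[f"s{i}" for i in range(60)],
                            columns=list("abcde"))
        fits = [
            JointProbitModel(resp, _designs(60), ModelSpec(include_cov=True),
                             n_factors=2, mc_samples=30, seed=9).fit(maxiter=50)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].b.to_numpy(), fits[1].b.to_numpy())
        assert np.array_equal(fits[0].loadings.to_numpy(), fits[1].loadings.to_numpy())


class TestLogLikelihood:
    def test_half_probabilities_closed_form(self):
        # b = 0 everywhere -> p = 0.5 -> LL = n*S*ln(0.5)
        n, s = 40, 3
        rng = np.random.default_rng(5)
        resp = pd.DataFrame(rng.integers(0, 2, size=(n, s)),
                            index=[f"s{i}" for i in range(n)], columns=list("abc"))
        model = JointProbitModel(resp, _designs(n), ModelSpec(), n_factors=0, seed=0)
        fit = model.fit(maxiter=0)
        fit.b.iloc[:, :] = 0.0
        fit._ll_cache.clear()
        total, per = fit.log_likelihood()
        assert total == pytest.approx(n * s * np.log(0.5))
        assert per.sum() == pytest.approx(total)

    def test_perfect_predictions_ll_near_zero(self):
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        resp = pd.DataFrame({"o": y}, index=[f"s{i}" for i in range(n)])
        model = JointProbitModel(resp, _designs(n, x=(y * 2 - 1).astype(float)),
                                 ModelSpec(include_p=True), n_factors=0, seed=0)
        fit = model.fit(maxiter=0)
        fit.b.iloc[:, 0] = [0.0, 20.0]  # huge slope: p ~= y
        fit._ll_cache.clear()
        total, _ = fit.log_likelihood()
        assert abs(total) < 1e-6

    def test_mc_estimate_matches_gauss_hermite_quadrature(self):
        rng = np.random.default_rng(6)
        n, s = 25, 4
        alpha = np.array([-0.5, 0.0, 0.4, -0.2])
        lam = np.array([0.8, -0.6, 0.5, 1.0])
        u = rng.standard_normal(n)
        y = (rng.uniform(size=(n, s)) < norm.cdf(alpha[None] + u[:, None] * lam[None])).astype(int)
        resp = pd.DataFrame(y, index=[f"s{i}" for i in range(n)], columns=list("abcd"))
        model = JointProbitModel(resp, _designs(n), ModelSpec(include_cov=True),
                                 n_factors=1, mc_samples=4000, seed=3)
        fit = model.fit(maxiter=0)
        fit.b.iloc[0, :] = alpha
        fit.loadings.iloc[:, 0] = lam
        fit._ll_cache.clear()
        total, per = fit.log_likelihood(mc_samples=4000, seed=11)
        nodes, weights = hermegauss(81)
        weights = weights / np.sqrt(2 * np.pi)
        ll_quad = 0.0
        for i in range(n):
            eta = alpha[None, :] + nodes[:, None] * lam[None, :]
            lp = np.where(y[i][None, :] == 1, norm.logcdf(eta), norm.logcdf(-eta)).sum(axis=1)
            ll_quad += np.log(np.sum(weights * np.exp(lp)))
        assert total == pytest.approx(ll_quad, rel=0.005)
        assert per.sum() == pytest.approx(total)


class TestLattice:
    def test_lattice_is_the_sixteen_models(self):
        names = [s.name for s in MODEL_LATTICE]
        assert len(names) == 16 and len(set(names)) == 16
        assert names[0] == "Full (P + S + Sp + Cov)"
        assert names[-1] == "Null"
        expected = {
            "Full (P + S + Sp + Cov)", "P + S + Sp", "P + S + Cov", "P + Sp + Cov",
            "S + Sp + Cov", "P + S", "P + Sp", "P + Cov", "S + Sp", "S + Cov",
            "Sp + Cov", "P", "S", "Sp", "Cov", "Null",
        }
        assert set(names) == expected

    def test_attribution_pairs_are_the_four_fixed_comparisons(self):
        assert COMPARISON_PAIRS == {
            "P": ("P + S + Sp", "S + Sp"),
            "S": ("P + S + Sp", "P + Sp"),
            "Sp": ("P + S + Sp", "P + S"),
            "Cov": ("Full (P + S + Sp + Cov)", "P + S + Sp"),
        }
        # no factor other than Cov is attributed against the full model
        for factor, (a, b) in COMPARISON_PAIRS.items():
            if factor != "Cov":
                assert "Full" not in a and "Full" not in b

    def test_null_model_ll_is_bernoulli_closed_form(self):
        rng = np.random.default_rng(7)
        n, s = 80, 4
        y = (rng.uniform(size=(n, s)) < 0.3).astype(int)
        resp = pd.DataFrame(y, index=[f"s{i}" for i in range(n)], columns=list("abcd"))
        fit = JointProbitModel(resp, _designs(n), ModelSpec(), n_factors=0,
                               seed=0).fit(ridge=0.0)
        total, _ = fit.log_likelihood()
        n1 = y.sum(axis=0)
        phat = np.clip(n1 / n, 1e-12, 1 - 1e-12)
        closed = np.sum(n1 * np.log(phat) + (n - n1) * np.log(1 - phat))
        assert total == pytest.approx(closed, abs=1e-4)


class TestPerOTULLR:
    def test_identical_fits_give_zero_and_sum_matches_total(self):
        rng = np.random.default_rng(8)
        y = (rng.uniform(size=(50, 3)) < 0.4).astype(int)
        resp = pd.DataFrame(y, index=[f"s{i}" for i in range(50)], columns=list("abc"))
        x = rng.standard_normal(50)
        fit_a = JointProbitModel(resp, _designs(50, x), ModelSpec(include_p=True),
                                 n_factors=0, seed=0).fit()
        fit_b = JointProbitModel(resp, _designs(50, x), ModelSpec(), n_factors=0,
                                 seed=0).fit()
        assert np.allclose(per_otu_llr(fit_a, fit_a), 0.0)
        llr = per_otu_llr(fit_a, fit_b)
        ta, _ = fit_a.log_likelihood(1000, 0)
        tb, _ = fit_b.log_likelihood(1000, 0)
        assert llr.sum() == pytest.approx(ta - tb)


class TestSteelDwass:
    def test_two_groups_match_wilcoxon_normal_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1, 30)
        out = steel_dwass(np.concatenate([a, b]),
                          np.array(["a"] * 25 + ["b"] * 30))
        # oracle: normal-approximation rank-sum p
        ranks = rankdata(np.concatenate([a, b]))
        ra = ranks[:25].sum()
        n = 55
        e = 25 * (n + 1) / 2
        v = 25 * 30 / (n * (n - 1)) * (np.sum(ranks**2) - n * (n + 1) ** 2 / 4)
        p_oracle = 2 * norm.sf(abs(ra - e) / np.sqrt(v))
        assert out["p"].iloc[0] == pytest.approx(p_oracle, abs=0.01)

    def test_identical_groups_p_near_one(self):
        vals = np.tile(np.arange(10.0), 2)
        out = steel_dwass(vals, np.array(["a"] * 10 + ["b"] * 10))
        assert out["p"].iloc[0] > 0.95

    def test_small_groups_excluded(self):
        vals = np.arange(24.0)
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 4)
        out = steel_dwass(vals, labels, min_group_size=5)
        assert set(out["group1"]) | set(out["group2"]) == {"a", "b"}
        with pytest.raises(CommunityDataError):
            steel_dwass(vals[:14], np.array(["a"] * 10 + ["c"] * 4))


class TestROCAUC:
    def test_perfect_and_constant_predictions(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(y.astype(float), y) == 1.0
        assert roc_auc(np.full(4, 0.3), y) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(10)
        scores = np.round(rng.normal(size=40), 1)  # rounding injects ties
        labels = rng.integers(0, 2, size=40).astype(bool)
        wins = ties = 0
        pos = scores[labels]
        neg = scores[~labels]
        for sp, sn in itertools.product(pos, neg):
            wins += sp > sn
            ties += sp == sn
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)


class TestPrepareInputs:
    def test_host_filter_boundary_and_soil_coverage(self, small_dataset):
        from rootfungi.jsdm import prepare_inputs

        ds = small_dataset
        counts = ds.metadata.roots["host_plant"].value_counts()
        thr = int(counts.iloc[1])  # second-most-frequent host count
        y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata,
                                    min_host_samples=thr)
        kept_hosts = set(
            ds.metadata.roots.set_index("sample_id")
            .loc[designs.sample_ids, "host_plant"]
        )
        assert kept_hosts == set(counts[counts >= thr].index)
        # a position without soil data loses its root samples
        soil_ids = ds.soil.sample_ids[1:]
        y2, d2 = prepare_inputs(ds.root, ds.soil.subset_samples(soil_ids),
                                ds.metadata, min_host_samples=5)
        dropped_pos = ds.metadata.soils.iloc[0]["position_id"]
        pos_of = ds.metadata.roots.set_index("sample_id")["position_id"]
        assert dropped_pos not in set(pos_of.loc[d2.sample_ids])

    def test_supplementary_mode_extra_covariate(self, small_dataset):
        """The relaxed 15-sample host filter with an appended continuous
        soil-chemistry covariate enters the design as a standardized column."""
        from rootfungi.jsdm import prepare_inputs

        ds = small_dataset
        rng = np.random.default_rng(0)
        ph = pd.DataFrame(
            {"soil_ph": rng.uniform(4.0, 6.5, len(ds.root.sample_ids))},
            index=ds.root.sample_ids,
        )
        y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata,
                                    min_host_samples=15, extra=ph)
        x = designs.matrix(ModelSpec(True, True, True, False))
        assert "soil_ph" in designs.column_names(ModelSpec(True, True, True, False))
        assert abs(designs.extra["soil_ph"].mean()) < 1e-10
        assert x.shape[0] == len(y)


class TestNullOptimism:
    def test_in_sample_auc_optimism_bounded_on_null_data(self):
        """On global-null data the pooled AUC of the full model should not
        exceed the prevalence-only baseline by much.

        Pooled-cell AUC mixes between-OTU prevalence differences into the
        score, so even an intercept-only model sits well above 0.5; the
        meaningful check is the optimism over that baseline."""
        from rootfungi.simulate import generate_dataset, null_preset
        from rootfungi.jsdm import prepare_inputs

        ds = generate_dataset(null_preset(), seed=0)
        y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata,
                                    min_host_samples=30)
        baseline = roc_auc(
            np.tile(y.to_numpy().mean(axis=0), (len(y), 1)).ravel(),
            y.to_numpy().ravel(),
        )
        fit = JointProbitModel(y, designs, ModelSpec(True, True, True, True),
                               n_factors=2, mc_samples=40, seed=11).fit(maxiter=120)
        assert fit.roc_auc() <= baseline + 0.12


class TestLatticeFitSmall:
    def test_nesting_monotonicity_and_structure(self, small_dataset):
        from rootfungi.jsdm import prepare_inputs

        ds = small_dataset
        y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata,
                                    min_host_samples=5)
        lat = fit_lattice(y, designs, n_factors=2, seed=0, mc_samples=30,
                          eval_mc_samples=300, maxiter=80)
        assert len(lat.results) == 16
        lls = {name: lat[name].log_likelihood(300, 0)[0] for name in lat.results}
        # every edge of the lattice that adds one factor cannot lose likelihood
        # beyond MC tolerance
        tol = 2.0 + 2e-3 * abs(lls["Null"])
        for spec in MODEL_LATTICE:
            flags = [spec.include_p, spec.include_s, spec.include_sp, spec.include_cov]
            for k in range(4):
                if not flags[k]:
                    bigger = list(flags)
                    bigger[k] = True
                    big = ModelSpec(*bigger)
                    assert lls[big.name] >= lls[spec.name] - tol, (big.name, spec.name)
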