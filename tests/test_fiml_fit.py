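import numpy as np
import pandas as pd
import pytest

from twinade import published
from twinade import synthetic_twins as st
from twinade.ade_model import ADEParameters, ModelSpec
from twinade.data import frame_to_records
from twinade.fiml_fit import (
    FitOptions,
    compare_models,
    fit,
    lrt_sex_moderation,
    pair_loglik,
    robust_se,
    total_loglik,
)
from conftest import make_uni_params, simulate_complete
from oracles import grouped_stats_fit, grouped_stats_loglik, oracle_pair_loglik


def _dataset(params, spec, n_mz, n_dz, seed, miss=(0.2, 0.2, 0.2)):
    design = st.SimulationDesign(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz,
        missingness=st.MissingnessSpec(*miss), seed=seed,
    )
    rng = np.random.default_rng(seed)
    data = st.simulate_pairs(params, spec, design, rng)
    return st.impose_missingness(data, spec, design, rng)


class TestPairLoglik:
    def test_univariate_complete_matches_bivariate_normal_formula(self):
        p = make_uni_params(0.5, 0.2, 0.3, beta=-0.2, intercept=0.1)
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 5, 5, seed=0)
        for rec in frame_to_records(data):
            rho = {"MZ": 0.7, "DZ": 0.5 * 0.5 + 0.25 * 0.2}[rec.zygosity]
            mu1 = 0.1 - 0.2 * rec.sex1
            mu2 = 0.1 - 0.2 * rec.sex2
            z1, z2 = rec.y1[0] - mu1, rec.y2[0] - mu2
            # bivariate normal density with unit variances, correlation rho
            expect = (
                -np.log(2 * np.pi)
                - 0.5 * np.log(1 - rho**2)
                - (z1**2 - 2 * rho * z1 * z2 + z2**2) / (2 * (1 - rho**2))
            )
            assert pair_loglik(p, rec, spec) == pytest.approx(expect, abs=1e-10)

    def test_one_twin_missing_marginalizes_to_single_twin_density(self, hyp_params):
        params, spec = hyp_params
        data = simulate_complete(params, spec, 3, 3, seed=1)
        m = spec.n_phenotypes
        for rec in frame_to_records(data, spec.phenotypes):
            rec.y2[:] = np.nan
            from twinade.ade_model import build_group_cov
            g = build_group_cov(params, rec.zygosity, rec.same_teacher, spec=spec)
            from scipy.stats import multivariate_normal
            mu = params.intercepts + params.beta_sex * rec.sex1
            expect = multivariate_normal(mean=mu, cov=g.within).logpdf(rec.y1)
            assert pair_loglik(params, rec, spec) == pytest.approx(expect, abs=1e-9)

    def test_arbitrary_patterns_match_scipy_oracle(self, hyp_params):
        params, spec = hyp_params
        data = _dataset(params, spec, 100, 100, seed=2, miss=(0.3, 0.3, 0.3))
        recs = [r for r in frame_to_records(data, spec.phenotypes) if r.n_observed]
        for rec in recs:
            assert pair_loglik(params, rec, spec) == pytest.approx(
                oracle_pair_loglik(params, rec, spec), abs=1e-10
            )

    def test_total_equals_sum_of_pairs(self, hyp_params):
        params, spec = hyp_params
        data = _dataset(params, spec, 50, 50, seed=3)
        recs = [r for r in frame_to_records(data, spec.phenotypes) if r.n_observed]
        total = sum(pair_loglik(params, r, spec) for r in recs)
        assert total_loglik(params, data, spec) == pytest.approx(total, rel=1e-12)

    def test_non_pd_submatrix_returns_minus_inf(self):
        p = ADEParameters(
            delta_a=np.zeros((1, 1)), delta_d=np.zeros((1, 1)),
            delta_e=np.zeros((1, 1)),
        )
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        from twinade.data import TwinPairRecord
        rec = TwinPairRecord(1, "MZ", 0, 0, False, [0.5], [0.2])
        assert pair_loglik(p, rec, spec) == -np.inf


class TestLoglikInvariances:
    def test_invariant_to_pair_order(self, hyp_params):
        params, spec = hyp_params
        data = _dataset(params, spec, 60, 60, seed=4)
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert total_loglik(params, data, spec) == pytest.approx(
            total_loglik(params, shuffled, spec), rel=1e-12
        )

    def test_invariant_to_twin_labels_within_mz(self, hyp_params):
        params, spec = hyp_params
        data = _dataset(params, spec, 60, 0, seed=5)
        swapped = data.copy()
        for p in spec.phenotypes:
            swapped[[f"{p}_1", f"{p}_2"]] = data[[f"{p}_2", f"{p}_1"]].to_numpy()
        swapped[["sex1", "sex2"]] = data[["sex2", "sex1"]].to_numpy()
        assert total_loglik(params, data, spec) == pytest.approx(
            total_loglik(params, swapped, spec), rel=1e-12
        )


class TestFit:
    def test_univariate_recovery(self):
        p = make_uni_params(0.5, 0.25, 0.25, beta=-0.2)
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 3000, 3000, seed=6)
        fr = fit(data, spec, FitOptions(n_starts=2, seed=0))
        assert fr.converged
        from twinade.derive import standardized_components
        comps = standardized_components(fr.estimates)
        assert comps["h2_broad"].iloc[0] == pytest.approx(0.75, abs=0.04)
        assert fr.estimates.beta_sex[0] == pytest.approx(-0.2, abs=0.05)

    def test_matches_grouped_sufficient_statistics_fit(self):
        # complete data: casewise FIML equals an independent fit through
        # per-group sufficient statistics (means + scatter matrices)
        params, spec = published.cholesky_parameters(("SWAN_HYP", "CPRS_HYP"))
        data = simulate_complete(params, spec, 400, 400, seed=7)
        fr = fit(data, spec, FitOptions(n_starts=2, seed=0))
        ll_oracle, x_oracle = grouped_stats_fit(data, spec, fr.x)
        assert fr.loglik == pytest.approx(ll_oracle, rel=1e-5)
        # and the likelihood functions themselves agree at the optimum
        assert grouped_stats_loglik(fr.estimates, data, spec) == pytest.approx(
            fr.loglik, rel=1e-10
        )

    def test_zero_additive_variance_estimated_near_zero(self):
        # generating a2 = 0: the estimate may sit at (not be fixed to) zero
        p = make_uni_params(0.0, 0.55, 0.45)
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 2000, 2000, seed=8)
        fr = fit(data, spec, FitOptions(n_starts=3, seed=0))
        from twinade.derive import standardized_components
        comps = standardized_components(fr.estimates)
        assert comps["a2"].iloc[0] <= 0.08
        assert comps["d2"].iloc[0] == pytest.approx(0.55, abs=0.08)

    def test_single_zygosity_warns_about_identification(self):
        p = make_uni_params()
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 200, 0, seed=9)
        with pytest.warns(UserWarning, match="single zygosity"):
            fit(data, spec, FitOptions(n_starts=1, seed=0))

    def test_profile_check_no_single_parameter_improvement(self):
        p = make_uni_params(0.4, 0.2, 0.4)
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 500, 500, seed=10)
        fr = fit(data, spec, FitOptions(n_starts=2, seed=0))
        from twinade.ade_model import unpack_parameters
        for i in range(len(fr.x)):
            for step in (-0.05, 0.05):
                x = fr.x.copy()
                x[i] += step
                ll = total_loglik(unpack_parameters(x, fr.spec), data, fr.spec)
                assert ll <= fr.loglik + 1e-8

    def test_deterministic_under_fixed_seed(self):
        p = make_uni_params()
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 200, 200, seed=11)
        a = fit(data, spec, FitOptions(n_starts=3, seed=5))
        b = fit(data, spec, FitOptions(n_starts=3, seed=5))
        np.testing.assert_array_equal(a.x, b.x)


@pytest.fixture(scope="module")
def normal_fit():
    p = make_uni_params(0.5, 0.2, 0.3, beta=-0.2)
    spec = ModelSpec(phenotypes=("P1",), rater=False)
    data = simulate_complete(p, spec, 2000, 2000, seed=12)
    fr = fit(data, spec, FitOptions(n_starts=2, seed=0))
    return fr, data


class TestRobustSE:

    def test_sandwich_close_to_observed_under_correct_model(self, normal_fit):
        fr, data = normal_fit
        se = robust_se(fr, data)
        ratio = se.sandwich / se.observed
        assert np.all(ratio > 0.85) and np.all(ratio < 1.15)

    def test_heavy_tails_inflate_sandwich(self):
        # t(5) unshared environment: sandwich SEs exceed naive on average
        rng = np.random.default_rng(13)
        n = 1500
        rows = []
        for zyg, r_a, r_d in (("MZ", 1.0, 1.0), ("DZ", 0.5, 0.25)):
            a = rng.standard_normal(n)
            a2_ = r_a * a + np.sqrt(1 - r_a**2) * rng.standard_normal(n)
            d = rng.standard_normal(n)
            d2_ = r_d * d + np.sqrt(1 - r_d**2) * rng.standard_normal(n)
            scale = np.sqrt(0.5 * 3 / 5)  # var of t5 is 5/3
            y1 = np.sqrt(0.3) * a + np.sqrt(0.2) * d + scale * rng.standard_t(5, n)
            y2 = np.sqrt(0.3) * a2_ + np.sqrt(0.2) * d2_ + scale * rng.standard_t(5, n)
            for i in range(n):
                rows.append((f"{zyg}{i}", zyg, 0, 0, False, y1[i], y2[i]))
        data = pd.DataFrame(
            rows, columns=["pair_id", "zygosity", "sex1", "sex2",
                           "same_teacher", "P1_1", "P1_2"]
        )
        spec = ModelSpec(phenotypes=("P1",), rater=False, sex_effect=False)
        fr = fit(data, spec, FitOptions(n_starts=2, seed=0))
        se = robust_se(fr, data)
        assert np.nanmean(se.sandwich / se.observed) > 1.0

    def test_parameter_count_matches_free_parameters(self, normal_fit):
        fr, data = normal_fit
        se = robust_se(fr, data)
        # a, d, e, intercept, beta_sex and nothing else (no SEs for
        # parameters the model does not estimate)
        assert len(se.observed) == 5 == fr.n_params

    def test_wrong_dataset_rejected(self, normal_fit):
        fr, data = normal_fit
        other = data.copy()
        other["P1_1"] += 1.0
        with pytest.raises(ValueError, match="does not match"):
            robust_se(fr, other)


class TestSexModeration:
    def test_nesting_equated_never_beats_free(self):
        p = make_uni_params(0.4, 0.2, 0.4)
        spec1 = ModelSpec(phenotypes=("P1",), rater=False)
        for seed in (14, 15):
            data = simulate_complete(p, spec1, 400, 400, seed=seed, prop_os_dz=0.0)
            res = lrt_sex_moderation(data, "P1", options=FitOptions(n_starts=1),
                                     component_tests=False)
            assert res.loglik_equated <= res.loglik_free + 1e-6
            assert res.df == 3

    def test_component_tests_have_one_df(self):
        p = make_uni_params(0.4, 0.2, 0.4)
        spec1 = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec1, 300, 300, seed=16, prop_os_dz=0.0)
        res = lrt_sex_moderation(data, "P1", options=FitOptions(n_starts=1))
        assert set(res.component_tests) == {"A", "D", "E"}
        for stat, df, pval in res.component_tests.values():
            assert df == 1 and stat >= 0 and 0 <= pval <= 1

    def test_power_against_dominance_difference(self):
        # girls' dominance variance much larger than boys': the 3-df test
        # should reject more often than not at n = 1500 pairs/sex
        rejections = 0
        n_rep = 12
        for r in range(n_rep):
            rng = np.random.default_rng(100 + r)
            frames = []
            for sex, d2 in ((0, 0.1), (1, 0.5)):
                a2, e2 = 0.5, 1.0 - 0.5 - d2
                p = make_uni_params(a2, d2, e2)
                spec1 = ModelSpec(phenotypes=("P1",), rater=False)
                design = st.SimulationDesign(
                    n_mz_pairs=750, n_dz_pairs=750, prop_female=float(sex),
                    prop_opposite_sex_dz=0.0,
                    missingness=st.MissingnessSpec(0, 0, 0), seed=int(rng.integers(2**31)),
                )
                frames.append(st.simulate_pairs(p, spec1, design))
            data = pd.concat(frames, ignore_index=True)
            data["pair_id"] = np.arange(len(data))
            res = lrt_sex_moderation(data, "P1", options=FitOptions(n_starts=1),
                                     component_tests=False)
            rejections += res.p_value < 0.01
        assert rejections / n_rep > 0.5

    def test_small_group_warns(self):
        p = make_uni_params()
        spec1 = ModelSpec(phenotypes=("P1",), rater=False)
        design = st.SimulationDesign(
            n_mz_pairs=60, n_dz_pairs=60, prop_female=0.05, prop_opposite_sex_dz=0.0,
            missingness=st.MissingnessSpec(0, 0, 0), seed=17,
        )
        data = st.simulate_pairs(p, spec1, design)
        with pytest.warns(UserWarning, match="unreliable"):
            lrt_sex_moderation(data, "P1", options=FitOptions(n_starts=1),
                               component_tests=False)


class TestCompareModels:
    def _fits(self, seed, d2_true, n=1500):
        p = make_uni_params(0.4, d2_true, 0.6 - d2_true)
        ade = ModelSpec(phenotypes=("P1",), rater=False)
        ae = ModelSpec(phenotypes=("P1",), components=("A", "E"), rater=False)
        data = simulate_complete(p, ade, n, n, seed=seed)
        return (
            fit(data, ade, FitOptions(n_starts=1, seed=0)),
            fit(data, ae, FitOptions(n_starts=1, seed=0)),
        )

    def test_identical_fits_give_zero_delta_p_one(self):
        fa, _ = self._fits(18, 0.3)
        cmp = compare_models(fa, fa)
        assert cmp.delta_loglik == 0.0
        assert cmp.p_value == 1.0

    def test_ae_rejected_when_dominance_present(self):
        rejections = 0
        for r in range(8):
            fa, fe = self._fits(200 + r, d2_true=0.3, n=1500)
            cmp = compare_models(fa, fe)
            rejections += cmp.p_value < 0.05
        assert rejections >= 6

    def test_bic_penalizes_useless_dominance_parameter(self):
        worse = 0
        n_rep = 12
        for r in range(n_rep):
            fa, fe = self._fits(300 + r, d2_true=0.0, n=800)
            if fa.bic > fe.bic:
                worse += 1
        assert worse >= n_rep - 1

    def test_different_datasets_rejected(self):
        fa, _ = self._fits(19, 0.2, n=100)
        fb, _ = self._fits(20, 0.2, n=100)
        with pytest.raises(ValueError, match="different datasets"):
            compare_models(fa, fb)
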