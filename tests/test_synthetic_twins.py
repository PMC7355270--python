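import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinade import published
from twinade import synthetic_twins as st
from twinade.ade_model import ADEParameters, ModelSpec, expected_twin_correlations
from twinade.transform import boxcox_transform
from conftest import make_uni_params, simulate_complete


def _cross_cov(data, phenos):
    y1 = data[[f"{p}_1" for p in phenos]].to_numpy(float)
    y2 = data[[f"{p}_2" for p in phenos]].to_numpy(float)
    y1 = y1 - y1.mean(axis=0)
    y2 = y2 - y2.mean(axis=0)
    c = (y1.T @ y2) / len(data)
    return 0.5 * (c + c.T)


class TestSimulatePairs:
    def test_pure_additive_mz_correlation_approaches_one(self):
        p = ADEParameters(
            delta_a=np.eye(1), delta_d=np.zeros((1, 1)), delta_e=1e-4 * np.eye(1)
        )
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 4000, 0, seed=0)
        r = np.corrcoef(data["P1_1"], data["P1_2"])[0, 1]
        assert r > 0.999

    def test_empirical_twin_correlations_match_closed_form(self):
        # published-magnitude univariate values: r_mz ~ a2+d2, r_dz ~ .5a2+.25d2
        p = make_uni_params(0.687, 0.226, 0.087)
        spec = ModelSpec(phenotypes=("SWAN_HYP",), rater=False)
        data = simulate_complete(p, spec, 20_000, 20_000, seed=1)
        r_mz_exp, r_dz_exp = expected_twin_correlations(p, 0)
        mz = data[data.zygosity == "MZ"]
        dz = data[data.zygosity == "DZ"]
        r_mz = np.corrcoef(mz["SWAN_HYP_1"], mz["SWAN_HYP_2"])[0, 1]
        r_dz = np.corrcoef(dz["SWAN_HYP_1"], dz["SWAN_HYP_2"])[0, 1]
        assert r_mz == pytest.approx(r_mz_exp, abs=0.01)
        assert r_dz == pytest.approx(r_dz_exp, abs=0.02)

    def test_same_teacher_adds_exactly_rater_covariance(self, hyp_params):
        params, spec = hyp_params
        design = st.SimulationDesign(
            n_mz_pairs=30_000,
            n_dz_pairs=0,
            prop_same_teacher=0.5,
            missingness=st.MissingnessSpec(0, 0, 0),
            seed=2,
        )
        data = st.simulate_pairs(params, spec, design, np.random.default_rng(2))
        shared = data[data.same_teacher]
        split = data[~data.same_teacher]
        diff = _cross_cov(shared, spec.phenotypes) - _cross_cov(split, spec.phenotypes)
        lam = params.rater_loadings
        expect = np.outer(lam, lam)
        # MC error on a covariance of unit-variance traits at n ~ 15k
        np.testing.assert_allclose(diff, expect, atol=4.5 / np.sqrt(len(shared)))

    def test_pooled_and_cross_twin_covariances_converge(self, hyp_params):
        params, spec = hyp_params
        data = simulate_complete(params, spec, 50_000, 50_000, seed=3)
        phenos = spec.phenotypes
        stacked = np.vstack(
            [
                data[[f"{p}_1" for p in phenos]].to_numpy(float),
                data[[f"{p}_2" for p in phenos]].to_numpy(float),
            ]
        )
        total = (
            params.sigma("A") + params.sigma("D") + params.sigma("E")
            + params.sigma_rater
        )
        emp = np.cov(stacked.T)
        # elementwise MC standard error of a covariance at n=200k draws of
        # ~unit-variance traits is < 0.007; allow 3 of them
        np.testing.assert_allclose(emp, total, atol=0.02)
        mz = data[data.zygosity == "MZ"]
        dz = data[data.zygosity == "DZ"]
        st_mz = mz["same_teacher"].mean()
        st_dz = dz["same_teacher"].mean()
        mz_expect = params.sigma("A") + params.sigma("D") + st_mz * params.sigma_rater
        dz_expect = (
            0.5 * params.sigma("A") + 0.25 * params.sigma("D")
            + st_dz * params.sigma_rater
        )
        np.testing.assert_allclose(_cross_cov(mz, phenos), mz_expect, atol=0.04)
        np.testing.assert_allclose(_cross_cov(dz, phenos), dz_expect, atol=0.04)

    def test_sex_enters_means_only(self):
        p = make_uni_params(0.5, 0.2, 0.3, beta=-0.4)
        spec = ModelSpec(phenotypes=("P1",), rater=False)
        data = simulate_complete(p, spec, 20_000, 20_000, seed=4)
        vals = np.concatenate([data["P1_1"], data["P1_2"]])
        sexes = np.concatenate([data["sex1"], data["sex2"]])
        assert vals[sexes == 1].mean() - vals[sexes == 0].mean() == pytest.approx(
            -0.4, abs=0.03
        )
        # variances equal across sex: the effect is mean-only
        assert vals[sexes == 1].var() == pytest.approx(vals[sexes == 0].var(), rel=0.05)

    def test_opposite_sex_pairs_only_in_dz(self):
        params, spec = published.cholesky_parameters(("SWAN_HYP",))
        data = simulate_complete(params, spec, 500, 500, seed=5)
        mz = data[data.zygosity == "MZ"]
        dz = data[data.zygosity == "DZ"]
        assert (mz.sex1 == mz.sex2).all()
        assert 0.3 < (dz.sex1 != dz.sex2).mean() < 0.65

    def test_dimension_mismatch_rejected(self):
        p = make_uni_params()
        spec = ModelSpec(phenotypes=("P1", "P2"))
        with pytest.raises(ValueError, match="phenotypes"):
            st.simulate_pairs(p, spec, st.SimulationDesign(10, 10))

    def test_same_seed_identical_datasets(self, hyp_params):
        params, spec = hyp_params
        design = st.SimulationDesign(n_mz_pairs=200, n_dz_pairs=200, seed=6)
        a = st.simulate_pairs(params, spec, design)
        b = st.simulate_pairs(params, spec, design)
        pd.testing.assert_frame_equal(a, b)


class TestRawScale:
    def test_relative_normal_identity(self):
        df = pd.DataFrame({"SWAN_HYP_1": [0.1, -0.5], "SWAN_HYP_2": [1.2, 0.0]})
        out, clamped = st.apply_raw_scale(
            df, [st.RawScaleSpec("SWAN_HYP", kind="relative-normal")]
        )
        pd.testing.assert_frame_equal(out, df)
        assert clamped == {}

    def test_censored_output_positively_skewed(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(10_000)
        df = pd.DataFrame({"CPRS_HYP_1": z, "CPRS_HYP_2": rng.standard_normal(10_000)})
        out, clamped = st.apply_raw_scale(
            df,
            [st.RawScaleSpec("CPRS_HYP", kind="absolute-censored",
                             inverse_lambda=-3.0, floor=0.0)],
        )
        v = out["CPRS_HYP_1"].to_numpy()
        assert stats.skew(v) > 0
        assert (v >= 0).all()
        assert clamped["CPRS_HYP"] > 0

    def test_roundtrip_through_forward_transform(self):
        # values inside the image map back exactly (no censoring active)
        lam = -2.0
        y = np.linspace(0.2, 6.0, 40)
        t = boxcox_transform(y, lam)
        df = pd.DataFrame({"X_1": t, "X_2": t})
        out, clamped = st.apply_raw_scale(
            df, [st.RawScaleSpec("X", kind="absolute-censored",
                                 inverse_lambda=lam, floor=0.0)]
        )
        np.testing.assert_allclose(
            boxcox_transform(out["X_1"].to_numpy(), lam), t, atol=1e-10
        )
        assert clamped["X"] == 0

    def test_reverse_coding(self):
        df = pd.DataFrame({"SWAN_HYP_1": [1.0, -2.0], "SWAN_HYP_2": [0.5, 0.0]})
        out, _ = st.apply_raw_scale(
            df, [st.RawScaleSpec("SWAN_HYP", reverse_coded=True)]
        )
        np.testing.assert_allclose(out["SWAN_HYP_1"], [-1.0, 2.0])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            st.RawScaleSpec("X", kind="absolute-censored", floor=np.inf)
        with pytest.raises(ValueError, match="nonzero"):
            st.RawScaleSpec("X", kind="absolute-censored", inverse_lambda=0.0)


class TestMissingness:
    def test_zero_probabilities_leave_data_unchanged(self, hyp_params):
        params, spec = hyp_params
        data = simulate_complete(params, spec, 100, 100, seed=8)
        design = st.SimulationDesign(
            n_mz_pairs=100, n_dz_pairs=100,
            missingness=st.MissingnessSpec(0.0, 0.0, 0.0), seed=8,
        )
        out = st.impose_missingness(data, spec, design)
        pd.testing.assert_frame_equal(out, data)

    def test_marginal_rate_within_binomial_interval(self):
        params, spec = published.cholesky_parameters(("CPRS_HYP",))
        data = simulate_complete(params, spec, 5000, 5000, seed=9)
        design = st.SimulationDesign(
            n_mz_pairs=5000, n_dz_pairs=5000,
            missingness=st.MissingnessSpec(mother_twin=0.5, swan_pair=0.0,
                                           teacher_twin=0.0),
            seed=9,
        )
        out = st.impose_missingness(data, spec, design)
        frac = out[["CPRS_HYP_1", "CPRS_HYP_2"]].isna().to_numpy().mean()
        assert 0.48 <= frac <= 0.52  # 99% binomial interval at n = 20,000 draws

    def test_swan_subproject_sparsity(self, hyp_params):
        # SWAN collected only in sub-projects: complete cases collapse
        params, spec = hyp_params
        data = simulate_complete(params, spec, 2000, 2000, seed=10)
        design = st.SimulationDesign(
            n_mz_pairs=2000, n_dz_pairs=2000,
            missingness=st.MissingnessSpec(mother_twin=0.0, swan_pair=0.8,
                                           teacher_twin=0.0),
            seed=10,
        )
        out = st.impose_missingness(data, spec, design)
        complete = out[[c for c in out.columns if c.endswith(("_1", "_2"))]].notna().all(axis=1)
        assert complete.sum() < 0.25 * len(out)
        assert complete.sum() > 0.15 * len(out)  # ~ pair retention 0.2

    def test_swan_missing_jointly_per_pair(self, hyp_params):
        params, spec = hyp_params
        data = simulate_complete(params, spec, 1000, 1000, seed=11)
        design = st.SimulationDesign(
            n_mz_pairs=1000, n_dz_pairs=1000,
            missingness=st.MissingnessSpec(0.0, 0.5, 0.0), seed=11,
        )
        out = st.impose_missingness(data, spec, design)
        m1 = out["SWAN_HYP_1"].isna()
        m2 = out["SWAN_HYP_2"].isna()
        assert (m1 == m2).all()

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            st.MissingnessSpec(mother_twin=1.2)

    def test_seeded_reproducibility(self, hyp_params):
        params, spec = hyp_params
        data = simulate_complete(params, spec, 300, 300, seed=12)
        design = st.SimulationDesign(n_mz_pairs=300, n_dz_pairs=300, seed=12)
        a = st.impose_missingness(data, spec, design)
        b = st.impose_missingness(data, spec, design)
        pd.testing.assert_frame_equal(a, b)
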