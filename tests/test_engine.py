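import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from cjskit.design import Panel, StudyDesign, simple_design
from cjskit.encounter import EncounterHistory, build_m_array
from cjskit.engine import (
    CJSData,
    CovariateTerm,
    ModelSpec,
    build_design,
    fit,
    marray_neg_log_likelihood,
    neg_log_likelihood,
    parse_spec,
    predict_survival,
)
from cjskit.simulate import default_covariate_table, simulate_cjs, simulate_histories, SimulationConfig


def nll_single_history(det, phi, p, design=None):
    design = design or simple_design(len(det))
    h = [EncounterHistory("x", "female", "panel-1",
                          np.asarray(det, dtype=np.int8))]
    data = CJSData.from_histories(h, design)
    dd = build_design(ModelSpec(), design, sexes=data.sexes)
    return neg_log_likelihood(np.array([logit(phi), logit(p)]), dd, data)


class TestLikelihoodValues:
    def test_seen_again_segment(self):
        # history 11 with phi=0.9, p=0.5: contribution phi*p = 0.45
        assert nll_single_history([1, 1], 0.9, 0.5) == \
            pytest.approx(-np.log(0.45), abs=1e-12)

    def test_never_seen_again_chi_recursion(self):
        # history 10: (1-phi) + phi*(1-p) = 0.55
        assert nll_single_history([1, 0], 0.9, 0.5) == \
            pytest.approx(-np.log(0.55), abs=1e-12)

    def test_certain_detection_reduces_to_survival_product(self):
        design = simple_design(3)
        h = [EncounterHistory("x", "female", "panel-1",
                              np.array([1, 1, 1], dtype=np.int8))]
        data = CJSData.from_histories(h, design)
        dd = build_design(ModelSpec(), design, sexes=data.sexes)
        v = neg_log_likelihood(np.array([logit(0.9), 40.0]), dd, data)
        assert v == pytest.approx(-2 * np.log(0.9), abs=1e-10)

    def test_non_finite_parameters_rejected(self):
        design = simple_design(3)
        h = [EncounterHistory("x", "female", "panel-1",
                              np.array([1, 1, 0], dtype=np.int8))]
        data = CJSData.from_histories(h, design)
        dd = build_design(ModelSpec(), design, sexes=data.sexes)
        with pytest.raises(ValueError, match="non-finite"):
            neg_log_likelihood(np.array([np.nan, 0.0]), dd, data)


class TestProbabilityConservation:
    @pytest.mark.parametrize("n_occ,first,seed", [
        (4, 0, 0), (5, 1, 1), (6, 0, 2), (6, 2, 3)])
    def test_enumeration_sums_to_one(self, n_occ, first, seed):
        """All possible post-release histories partition probability."""
        design = simple_design(n_occ)
        dd = build_design(parse_spec("t", "m*t"), design, sexes=("female",))
        rng = np.random.default_rng(seed)
        params = rng.normal(scale=1.0, size=dd.n_params)
        total = 0.0
        for tail in itertools.product([0, 1], repeat=n_occ - 1 - first):
            det = np.zeros(n_occ, dtype=np.int8)
            det[first] = 1
            det[first + 1:] = tail
            data = CJSData.from_histories(
                [EncounterHistory("x", "female", "panel-1", det)], design)
            total += np.exp(-neg_log_likelihood(params, dd, data))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_with_gap_mask(self):
        # two-panel design: capture impossible in the gap, probabilities
        # must still partition over the observable histories
        design = StudyDesign(
            occasions=tuple(range(2000, 2006)),
            gap_years=frozenset({2002}),
            panels=(Panel("panel-1", 2000, 2005),),
        )
        dd = build_design(parse_spec("t", "m+t"), design, sexes=("female",))
        rng = np.random.default_rng(7)
        params = rng.normal(size=dd.n_params)
        total = 0.0
        gap_idx = design.index(2002)
        for tail in itertools.product([0, 1], repeat=5):
            det = np.zeros(6, dtype=np.int8)
            det[0] = 1
            det[1:] = tail
            if det[gap_idx]:
                continue  # unobservable
            data = CJSData.from_histories(
                [EncounterHistory("x", "female", "panel-1", det)], design)
            total += np.exp(-neg_log_likelihood(params, dd, data))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestMArrayAgreement:
    def test_history_and_marray_likelihoods_agree(self):
        sim = simulate_cjs(400, 7, 0.8, 0.5, seed=13)
        design = sim.config.design
        data = CJSData.from_histories(sim.histories, design)
        dd = build_design(parse_spec("t", "t"), design, sexes=data.sexes)
        rng = np.random.default_rng(2)
        for _ in range(3):
            params = rng.normal(size=dd.n_params)
            phi, p = dd.tables(params)
            nll_h = neg_log_likelihood(params, dd, data)
            nll_m = marray_neg_log_likelihood(
                phi[:, 0], p[:, 0, 0], build_m_array(sim.histories, design))
            assert nll_h == pytest.approx(nll_m, abs=1e-8)


class TestDesignConstruction:
    def test_time_model_column_bookkeeping(self):
        design = simple_design(5)
        dd = build_design(parse_spec("t", "m+t"), design, sexes=("female",))
        assert dd.X_phi.shape == (4, 4)        # 4 intervals, 4 time columns
        # 4 occasions x 2 states rows; intercept + 3 time + 1 trap columns
        assert dd.X_p.shape == (8, 5)
        assert any("m2" in name for name in dd.p_names)

    def test_constant_model_is_intercept_only(self):
        design = simple_design(5)
        dd = build_design(ModelSpec(), design, sexes=("female",))
        assert dd.X_phi.shape[1] == 1 and dd.X_p.shape[1] == 1

    def test_covariate_slopes_add_columns(self):
        design = simple_design(6)
        covs = default_covariate_table(design, seed=0)
        spec = ModelSpec(phi_covariates=(
            CovariateTerm("LL_CC_br"), CovariateTerm("SOIyr"),
            CovariateTerm("SST_CC_2yr")))
        dd = build_design(spec, design, covariates=covs, sexes=("female",))
        assert dd.X_phi.shape[1] == 4  # intercept + 3 slopes

    def test_quadratic_includes_linear(self):
        design = simple_design(6)
        covs = default_covariate_table(design, seed=0)
        spec = ModelSpec(phi_covariates=(
            CovariateTerm("SOIyr", form="quadratic"),))
        dd = build_design(spec, design, covariates=covs, sexes=("female",))
        assert dd.X_phi.shape[1] == 3  # intercept + slope + square

    def test_unknown_covariate_rejected(self):
        design = simple_design(6)
        covs = default_covariate_table(design, seed=0)
        spec = ModelSpec(phi_covariates=(CovariateTerm("NOPE"),))
        with pytest.raises(KeyError, match="NOPE"):
            build_design(spec, design, covariates=covs, sexes=("female",))

    def test_split_slope_needs_periods(self):
        design = simple_design(6)
        covs = default_covariate_table(design, seed=0)
        spec = ModelSpec(phi_covariates=(CovariateTerm("SOIyr", split=True),))
        with pytest.raises(ValueError, match="period"):
            build_design(spec, design, covariates=covs, sexes=("female",))
        two_panel = StudyDesign.default()
        covs2 = default_covariate_table(two_panel, seed=0)
        dd = build_design(spec, two_panel, covariates=covs2,
                          sexes=("female",))
        assert dd.X_phi.shape[1] == 3  # intercept + one slope per period

    def test_gap_intervals_pool_to_one_level(self):
        design = StudyDesign.default()
        dd = build_design(parse_spec("t", "m+t"), design, sexes=("female",))
        # 28 informative intervals + 1 pooled gap level -> 29 phi columns
        assert dd.X_phi.shape[1] == 29
        assert (~dd.informative).sum() == 5

    def test_parse_spec_labels(self):
        assert parse_spec(".", "m+t").label == "phi(.) p(m+t)"
        assert parse_spec("sex*t", "m*sex*t").label == "phi(sex*t) p(m*sex*t)"
        s = parse_spec("LL^2+SOI:split", "t")
        assert s.phi_covariates[0].form == "quadratic"
        assert s.phi_covariates[1].split
        with pytest.raises(ValueError, match="unknown capture factor"):
            parse_spec(".", "m+x")


class TestFitting:
    def test_constant_model_parameter_recovery(self):
        sim = simulate_cjs(2000, 15, 0.9, 0.6, seed=21)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        res = fit(ModelSpec(), data, n_starts=1, seed=0)
        assert res.converged
        phi_hat = expit(res.estimates[0])
        p_hat = expit(res.estimates[1])
        assert abs(phi_hat - 0.9) < 2 * res.se[0] * phi_hat * (1 - phi_hat) + 0.02
        assert abs(p_hat - 0.6) < 0.05
        assert res.np_estimated == 2

    def test_saturated_model_matches_empirical_proportions(self):
        """On 3 occasions the time-dependent CJS is saturated: fitted
        cell probabilities equal the observed m-array proportions."""
        sim = simulate_cjs(800, 3, 0.85, 0.6, seed=5)
        design = sim.config.design
        data = CJSData.from_histories(sim.histories, design)
        res = fit(parse_spec("t", "t"), data, n_starts=3, seed=1)
        phi, p = res.dd.tables(res.estimates)
        ma = build_m_array(sim.histories, design)
        # row 0: released at occasion 0
        pr_01 = phi[0, 0] * p[1, 0, 0]
        pr_02 = phi[0, 0] * (1 - p[1, 0, 0]) * phi[1, 0] * p[2, 0, 0]
        np.testing.assert_allclose(
            [pr_01, pr_02],
            [ma.m[0, 1] / ma.releases[0], ma.m[0, 2] / ma.releases[0]],
            atol=2e-3)
        pr_12 = phi[1, 0] * p[2, 0, 0]
        assert pr_12 == pytest.approx(ma.m[1, 2] / ma.releases[1], abs=2e-3)

    def test_terminal_confounding_reduces_np(self):
        sim = simulate_cjs(600, 6, 0.85, 0.5, seed=2)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        res = fit(parse_spec("t", "t"), data, n_starts=1, seed=0)
        assert res.np_estimated == res.dd.n_params - 1

    def test_deviance_invariant_to_reparameterization(self):
        sim = simulate_cjs(400, 7, 0.85, 0.55, seed=9)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        devs = []
        for coding in ("Treatment", "Sum"):
            dd = build_design(parse_spec("t", "t"), sim.config.design,
                              sexes=data.sexes, coding=coding)
            r = fit(parse_spec("t", "t"), data, dd=dd, n_starts=1, seed=0,
                    compute_np=False)
            devs.append(r.deviance)
        assert devs[0] == pytest.approx(devs[1], abs=1e-6)

    def test_adding_covariate_never_increases_deviance(self):
        design = simple_design(10)
        covs = default_covariate_table(design, seed=3)
        cfg = SimulationConfig(design=design, n_individuals=600,
                               panel_split=(1.0,), transient_fraction=0.0,
                               trap_delta=0.0)
        sim = simulate_histories(cfg, covariates=covs, seed=17)
        data = CJSData.from_histories(sim.histories, design)
        base = fit(parse_spec(".", "t"), data, covariates=covs,
                   n_starts=1, seed=0, compute_np=False)
        extended = fit(parse_spec("SOIyr", "t"), data, covariates=covs,
                       n_starts=2, seed=0, compute_np=False)
        assert extended.deviance <= base.deviance + 1e-6

    def test_trap_effect_recovered(self):
        sim = simulate_cjs(1500, 12, 0.85, 0.5, delta=1.5, seed=30)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        res = fit(parse_spec(".", "m+t"), data, n_starts=1, seed=0)
        cf = res.coef_frame()
        m2 = cf.loc[[n for n in cf.index if "m2" in n][0]]
        # m2 offset estimates -delta
        assert abs(m2["coef"] + 1.5) < 3 * m2["se"] + 0.05


class TestPredictSurvival:
    def test_constant_model_gives_flat_series(self):
        sim = simulate_cjs(500, 8, 0.85, 0.5, seed=3)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        res = fit(ModelSpec(), data, n_starts=1, seed=0)
        series = predict_survival(res)
        assert series["phi"].nunique() == 1
        assert ((series["lo"] >= 0) & (series["hi"] <= 1)).all()
        assert series["phi"].iloc[0] == pytest.approx(
            expit(res.estimates[0]))

    def test_covariate_model_tracks_generating_series(self):
        design = simple_design(15)
        covs = default_covariate_table(design, seed=8)
        cfg = SimulationConfig(
            design=design, n_individuals=2500, panel_split=(1.0,),
            transient_fraction=0.0,
            survival_slopes=(("SOIyr", -0.5),))
        sim = simulate_histories(cfg, covariates=covs, seed=23)
        data = CJSData.from_histories(sim.histories, design)
        res = fit(parse_spec("SOIyr", "m+t"), data, covariates=covs,
                  n_starts=1, seed=0)
        series = predict_survival(res)
        pooled = series.groupby("year")["phi"].mean().to_numpy()
        rmse = np.sqrt(np.mean((pooled - sim.phi_true) ** 2))
        assert rmse < max(series["se"].mean(), 0.02) + 0.02

    def test_gap_intervals_flagged_inestimable(self):
        sim = simulate_histories(SimulationConfig(n_individuals=800), seed=6)
        data = CJSData.from_histories(sim.histories, sim.config.design)
        res = fit(parse_spec("t", "m+t"), data, n_starts=1, seed=0,
                  compute_np=False)
        series = predict_survival(res)
        gap_rows = series[series["year"].isin(range(1999, 2004))]
        assert not gap_rows["estimable"].any()
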