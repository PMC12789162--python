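"""DWLS engine: population oracles, parameter recovery, contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from auxmic import SimulationConfig, simulate_dataset
from auxmic.lcfa import (
    PAIRS,
    DwlsStats,
    LcfaError,
    LcfaModel,
    _implied_ab,
    _implied_c,
    build_model,
    fit_from_stats,
    fit_indices,
    fit_model,
    latent_mic,
    resolve_columns,
    sim_reliability_t1,
    trs_reliability,
)


class TestBuildModel:
    def test_model_a_structure(self):
        spec = build_model("A", "single_item")
        assert spec.treatments["sim_t1"] == "continuous"
        assert spec.treatments["aux_t1"] == "ordered"
        assert spec.parameterization == "delta" and not spec.invariant_sim

    def test_model_c_structure(self):
        spec = build_model("C", "sum_score")
        assert spec.treatments["sim_t1"] == "ordered"
        assert spec.treatments["aux_t1"] == "continuous"
        assert spec.parameterization == "theta" and spec.invariant_sim

    @pytest.mark.parametrize("model,aux", [("A", "sum_score"), ("B", "single_item"),
                                           ("C", "single_item"), ("D", "sum_score")])
    def test_contradictory_requests_rejected(self, model, aux):
        with pytest.raises(LcfaError):
            build_model(model, aux)


# a realistic model-C population parameter vector (lam=1 makes the SIM_T1
# reliability exactly 1/(1+1) = 0.5 by the closed-form variance ratio)
C_TRUTH = dict(lam=1.0, psi2=1.0, M2=0.8, V2=1.7, c12=1.0, g1=0.8, g2=0.62,
               lt1=-1.8, lt2=1.8, tau_t=1.44, cs=0.2, ca=0.15)
C_TAU = np.array([1.4 * (k - 6) for k in range(1, 11)])


def implied_stats_c(truth=C_TRUTH, tau=C_TAU, w=2000.0):
    p = np.concatenate([[truth[k] for k in ("lam", "psi2", "M2", "V2", "c12", "g1",
                                            "g2", "lt1", "lt2", "tau_t", "cs", "ca")], tau])
    idx = np.arange(len(tau))
    thr1, thr2, thrt, corr, _, _ = _implied_c(p, idx, idx, len(tau))
    bounds = np.arange(1, len(tau) + 1)
    return DwlsStats(
        corr=corr, corr_w=np.full(len(PAIRS), w),
        thr_s1=thr1, thr_s2=thr2, thr_trs=float(thrt),
        thr_s1_w=np.full(len(tau), w), thr_s2_w=np.full(len(tau), w),
        thr_trs_w=w, bounds_s1=bounds, bounds_s2=bounds, n_obs=2000,
    )


class TestPopulationOracle:
    def test_model_c_recovers_generating_parameters_exactly(self):
        """Fitting the model-implied statistics returns the parameter set."""
        stats = implied_stats_c()
        fit = fit_from_stats(stats, build_model("C", "sum_score"))
        assert fit.converged
        for name, true in C_TRUTH.items():
            assert fit.params[name] == pytest.approx(true, rel=0.02, abs=5e-3), name
        assert fit.params["tau_s"] == pytest.approx(C_TAU, rel=0.02, abs=5e-3)
        assert fit.mic_theta == pytest.approx(1.44 / 1.8, rel=0.005)
        assert fit.r2_sim_t1 == pytest.approx(0.5, abs=0.005)
        assert fit.discrepancy < 1e-6

    def test_model_ab_recovers_generating_parameters(self):
        truth = np.array([0.8, 0.873, 0.637, 0.75, 0.7, -0.9, 1.0, 0.1, 0.1])
        stats = DwlsStats(corr=_implied_ab(truth),
                          corr_w=np.full(len(PAIRS), 2000.0), n_obs=2000)
        for model, aux in (("A", "single_item"), ("B", "sum_score")):
            fit = fit_from_stats(stats, build_model(model, aux))
            assert fit.converged
            assert np.allclose(list(fit.params.values()), truth, atol=1e-3)
            expl = (truth[5] ** 2 * truth[0] + truth[6] ** 2 * truth[1]
                    + 2 * truth[5] * truth[6] * truth[2])
            assert fit.r2_trs == pytest.approx(expl, abs=1e-3)

    def test_saturated_fit_has_perfect_indices(self):
        stats = implied_stats_c()
        fit = fit_from_stats(stats, build_model("C", "sum_score"))
        assert fit.srmr == pytest.approx(0.0, abs=1e-5)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-4)
        assert fit.cfi == pytest.approx(1.0, abs=1e-6)


class TestGeneratorRecovery:
    """The generator's calibration is the oracle at population scale."""

    def test_latent_mic_recovered_within_two_percent(self, population_fit_c):
        _, est = population_fit_c
        assert latent_mic(est.lcfa_.result_) == pytest.approx(0.8, rel=0.02)

    def test_trs_reliability_recovered(self, population_fit_c):
        cfg, est = population_fit_c
        assert trs_reliability(est.lcfa_.result_) == pytest.approx(cfg.rel_trs, abs=0.03)

    def test_sim_reliability_recovered(self, population_fit_c):
        cfg, est = population_fit_c
        assert sim_reliability_t1(est.lcfa_.result_) == pytest.approx(
            cfg.rel_sim_t1, abs=0.04
        )

    def test_identification_fixes_t1_moments_and_frees_t2(self, population_fit_c):
        cfg, est = population_fit_c
        res = est.lcfa_.result_
        assert res.factor_mean_t1 == 0.0 and res.factor_var_t1 == 1.0
        # free T2 moments land near the generating values
        from auxmic.simulate import solve_mean_delta
        assert res.factor_mean_t2 == pytest.approx(solve_mean_delta(cfg), abs=0.05)
        true_v2 = 1 + cfg.sd_delta_theta**2 + 2 * cfg.cor_theta_t1_delta * cfg.sd_delta_theta
        assert res.factor_var_t2 == pytest.approx(true_v2, rel=0.06)

    def test_error_shrinks_with_sample_size(self):
        """Median recovery error of the latent MIC decreases in n."""
        sizes = (2000, 20_000, 100_000)
        med = {}
        for n in sizes:
            errs = []
            for seed in range(30, 38):
                obs = simulate_dataset(
                    SimulationConfig(n_subjects=n, seed=seed), include_latent=False
                ).observed_frame()
                fit = LcfaModel(model="C").fit(obs)
                if fit.converged_:
                    errs.append(abs(fit.mic_theta_ - 0.8))
            med[n] = float(np.median(errs))
        assert med[100_000] < med[2000]
        assert med[20_000] < med[2000]


class TestFitContracts:
    def test_repeated_fit_is_deterministic(self, observed_2000):
        f1 = LcfaModel(model="C").fit(observed_2000).result_
        f2 = LcfaModel(model="C").fit(observed_2000).result_
        assert f1.params["lam"] == f2.params["lam"]
        assert f1.mic_theta == f2.mic_theta
        assert f1.discrepancy == f2.discrepancy

    def test_constant_trs_flagged_not_raised(self, observed_2000):
        data = observed_2000.copy()
        data["trs_improved"] = 1
        fit = LcfaModel(model="C").fit(data).result_
        assert not fit.converged
        assert "trs" in fit.reason

    def test_too_few_rows_rejected_and_warned(self, observed_2000):
        spec = build_model("B", "sum_score")
        data = resolve_columns(observed_2000, "sum_score")
        with pytest.raises(LcfaError, match="at least 100"):
            fit_model(data.head(50), spec)
        with pytest.warns(UserWarning, match="unstable"):
            fit_model(data.head(150), spec)

    def test_accessors_require_convergence(self):
        from auxmic.lcfa import LcfaFit
        bad = LcfaFit(model_id="C", converged=False, reason="x")
        for fn in (fit_indices, trs_reliability, sim_reliability_t1, latent_mic):
            with pytest.raises(LcfaError, match="non-converged"):
                fn(bad)

    def test_latent_mic_requires_model_c(self, observed_2000):
        fit = LcfaModel(model="B").fit(observed_2000).result_
        assert fit.converged
        with pytest.raises(LcfaError, match="model C"):
            latent_mic(fit)

    def test_srmr_is_rms_of_residual_correlations(self, observed_2000):
        fit = LcfaModel(model="C").fit(observed_2000).result_
        manual = np.sqrt(np.mean((fit.sample_corr - fit.implied_corr) ** 2))
        assert fit.srmr == pytest.approx(manual, abs=1e-12)

    def test_fit_indices_look_like_good_fit_on_generated_data(self, population_fit_c):
        _, est = population_fit_c
        cfi, tli, rmsea, srmr = fit_indices(est.lcfa_.result_)
        assert cfi > 0.95 and srmr < 0.05 and rmsea < 0.06

    def test_aux_item_choice_changes_model_a(self, observed_2000):
        r1 = LcfaModel(model="A", aux_item=1).fit(observed_2000).r2_trs_
        r2 = LcfaModel(model="A", aux_item=5).fit(observed_2000).r2_trs_
        assert r1 != r2

    def test_missing_columns_reported(self, observed_2000):
        with pytest.raises(LcfaError, match="aux_sum_t1"):
            resolve_columns(observed_2000.drop(columns=["aux_sum_t1"]), "sum_score")
        with pytest.raises(LcfaError, match="trs"):
            resolve_columns(observed_2000.drop(columns=["trs_improved", "trs7"]),
                            "sum_score")

    def test_sklearn_interface(self, observed_2000):
        est = LcfaModel(model="B", max_iter=300)
        assert est.get_params()["model"] == "B"
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(model="C").fit(observed_2000)
        assert hasattr(est, "mic_theta_") and est.converged_
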