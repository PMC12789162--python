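"""Moment, calibration and degenerate-limit checks for the generator."""

import numpy as np
import pytest
from scipy import stats

from auxmic import SimulationConfig, simulate_dataset
from auxmic.simulate import (
    GenerationError,
    draw_latent_states,
    generate_sim_scores,
    generate_transition_ratings,
    round_half_away,
    solve_mean_delta,
)

N_BIG = 50_000


def mc_se(sd, n=N_BIG):
    return sd / np.sqrt(n)


def test_round_half_away_from_zero():
    x = np.array([0.5, 1.5, -0.5, -1.5, 2.49, -2.49, 6.5])
    assert round_half_away(x).tolist() == [1, 2, -1, -2, 2, -2, 7]


class TestLatentStates:
    def test_baseline_moments(self, central_panel):
        lat = central_panel.latent_frame()
        assert abs(lat.theta_t1.mean() - 0.0) < 4 * mc_se(1.0)
        assert abs(lat.theta_t1.std() - 1.0) < 0.02

    def test_shifted_mean_recovered(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=5, mean_theta_t1=-1.0)
        lat = draw_latent_states(cfg).latent_frame()
        assert abs(lat.theta_t1.mean() + 1.0) < 4 * mc_se(1.0)

    @pytest.mark.parametrize("rho", [0.0, -0.5])
    def test_baseline_change_correlation(self, rho):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=6, cor_theta_t1_delta=rho)
        lat = draw_latent_states(cfg).latent_frame()
        r = np.corrcoef(lat.theta_t1, lat.delta_theta)[0, 1]
        assert abs(r - rho) < 4 * mc_se(1.0)

    def test_change_sd(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=6, sd_delta_theta=1.15)
        lat = draw_latent_states(cfg).latent_frame()
        assert abs(lat.delta_theta.std() - 1.15) < 0.02

    @pytest.mark.parametrize("prop", [0.2, 0.5, 0.8])
    def test_improvement_proportion_calibrated(self, prop):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=8, prop_improved=prop)
        lat = draw_latent_states(cfg).latent_frame()
        frac = (lat.delta_theta > lat.individual_mic).mean()
        assert abs(frac - prop) < 4 * mc_se(np.sqrt(prop * (1 - prop)))

    def test_mean_delta_solver_matches_closed_form(self):
        # with normal individual MICs the calibration has a closed form
        for prop, sd in [(0.2, 0.85), (0.5, 1.15), (0.8, 1.15)]:
            cfg = SimulationConfig(prop_improved=prop, sd_delta_theta=sd)
            closed = 0.8 + stats.norm.ppf(prop) * np.hypot(sd, cfg.sd_individual_mic)
            assert solve_mean_delta(cfg) == pytest.approx(closed, abs=1e-8)

    def test_theta_b_strength_zero_collapses_to_theta_a(self):
        cfg = SimulationConfig(n_subjects=500, seed=9, strength_theta_b=0.0)
        lat = draw_latent_states(cfg).latent_frame()
        assert np.allclose(lat.theta_t1, lat.theta_a_t1)
        assert np.allclose(lat.theta_b_t1, 0.0)

    def test_component_sd_ratio(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=9, strength_theta_b=1.0)
        lat = draw_latent_states(cfg).latent_frame()
        ratio = lat.theta_b_t1.std() / lat.theta_a_t1.std()
        assert abs(ratio - 1.0) < 0.03
        assert abs(lat.theta_t1.std() - 1.0) < 0.02


class TestSimScores:
    def test_reliability_of_pre_discretization_score(self, central_panel):
        # squared correlation between the latent response and the construct
        # score, both taken from the generator's internals (eta and the
        # measurement error together make up the 1 - rel off-target share)
        cfg = central_panel.config
        lat = central_panel.latent_frame()
        r2 = np.corrcoef(lat.sim_star_t1, lat.theta_t1)[0, 1] ** 2
        assert r2 == pytest.approx(cfg.rel_sim_t1, abs=0.01)

    def test_t1_mean_and_sd_inside_printed_envelope(self, central_panel):
        obs = central_panel.observed_frame()
        assert 4.44 <= obs.sim_t1.mean() <= 6.58
        assert 1.11 <= obs.sim_t1.std() <= 1.51

    def test_scores_are_bounded_integers(self, central_panel):
        obs = central_panel.observed_frame()
        for col in ("sim_t1", "sim_t2"):
            assert obs[col].between(0, 10).all()
            assert np.issubdtype(obs[col].dtype, np.integer)

    def test_perfect_reliability_is_error_free(self):
        cfg = SimulationConfig(n_subjects=300, seed=10, rel_sim_t1=1.0)
        panel = draw_latent_states(cfg)
        s1a, s2a = generate_sim_scores(panel, rng=np.random.default_rng(1))
        s1b, s2b = generate_sim_scores(panel, rng=np.random.default_rng(99))
        assert np.array_equal(s1a, s1b) and np.array_equal(s2a, s2b)

    def test_invalid_reliability_rejected(self):
        cfg = SimulationConfig(n_subjects=300, seed=10)
        panel = draw_latent_states(cfg)
        with pytest.raises(GenerationError):
            generate_sim_scores(panel, rel_sim_t1=0.0)


class TestAuxItems:
    def test_alpha_inside_printed_envelope(self):
        for seed in (1, 2, 3):
            obs = simulate_dataset(
                SimulationConfig(n_subjects=2000, seed=seed)
            ).observed_frame()
            items = obs[[f"aux{j}_t1" for j in range(1, 9)]].to_numpy(float)
            alpha = 8 / 7 * (1 - items.var(axis=0, ddof=1).sum()
                             / items.sum(axis=1).var(ddof=1))
            assert 0.76 <= alpha <= 0.90

    def test_sum_equals_item_total(self, central_panel):
        obs = central_panel.observed_frame()
        items = obs[[f"aux{j}_t1" for j in range(1, 9)]].sum(axis=1)
        assert np.array_equal(items.to_numpy(), obs.aux_sum_t1.to_numpy())

    def test_xi_strength_zero_leaves_no_partial_association(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=11, strength_xi=0.0)
        panel = simulate_dataset(cfg)
        lat, obs = panel.latent_frame(), panel.observed_frame()
        # partial correlation of the AUX sum with xi given theta_a
        resid_aux = obs.aux_sum_t1 - np.polyval(
            np.polyfit(lat.theta_a_t1, obs.aux_sum_t1, 1), lat.theta_a_t1
        )
        r = np.corrcoef(resid_aux, lat.xi_t1)[0, 1]
        assert abs(r) < 4 * mc_se(1.0) + 0.005

    def test_xi_strength_raises_partial_association(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=11, strength_xi=0.5)
        panel = simulate_dataset(cfg)
        lat, obs = panel.latent_frame(), panel.observed_frame()
        resid_aux = obs.aux_sum_t1 - np.polyval(
            np.polyfit(lat.theta_a_t1, obs.aux_sum_t1, 1), lat.theta_a_t1
        )
        assert np.corrcoef(resid_aux, lat.xi_t1)[0, 1] > 0.2


class TestTransitionRatings:
    def test_psb_zero_weighted_change_is_plain_change(self, central_panel):
        lat = central_panel.latent_frame()
        assert np.allclose(lat.delta_theta_w, lat.delta_theta)

    def test_weighted_change_formula(self):
        cfg = SimulationConfig(n_subjects=5000, seed=12, psb=0.8)
        panel = simulate_dataset(cfg)
        lat = panel.latent_frame()
        expected = 0.2 * lat.delta_theta + 0.8 * (lat.theta_t2 - cfg.mean_theta_t1)
        assert np.allclose(lat.delta_theta_w, expected)

    def test_improvement_deterministic_given_perceived_change(self, central_panel):
        lat = central_panel.latent_frame()
        obs = central_panel.observed_frame()
        assert np.array_equal(
            obs.trs_improved.to_numpy(),
            (lat.perceived_change > lat.individual_mic).astype(int).to_numpy(),
        )

    def test_observed_proportion_near_target_when_noise_free(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=13, psb=0.0, rel_trs=0.999)
        obs = simulate_dataset(cfg).observed_frame()
        assert abs(obs.trs_improved.mean() - 0.5) < 4 * mc_se(0.5) + 0.01

    def test_full_psb_classification_ignores_change_given_t2(self):
        cfg = SimulationConfig(n_subjects=N_BIG, seed=14, psb=1.0, rel_trs=0.999,
                               sd_individual_mic=1e-6)
        panel = simulate_dataset(cfg)
        lat = panel.latent_frame()
        improved = panel.observed_frame().trs_improved.to_numpy()
        # within narrow theta_T2 strata the classification carries no
        # information about the actual change
        bins = np.digitize(lat.theta_t2, np.quantile(lat.theta_t2, np.linspace(0, 1, 41)[1:-1]))
        rs = []
        for b in np.unique(bins):
            m = bins == b
            if improved[m].std() > 0 and lat.delta_theta[m].std() > 0:
                rs.append(np.corrcoef(improved[m], lat.delta_theta[m])[0, 1])
        assert abs(np.mean(rs)) < 0.06

    def test_trs7_dichotomizes_back_to_binary(self, central_panel):
        obs = central_panel.observed_frame()
        assert np.array_equal((obs.trs7 >= 5).astype(int), obs.trs_improved)

    def test_biserial_with_change_score_in_printed_envelope(self, central_panel):
        obs = central_panel.observed_frame()
        d = obs.sim_t2 - obs.sim_t1
        pb = np.corrcoef(d, obs.trs_improved)[0, 1]
        p = obs.trs_improved.mean()
        biserial = pb * np.sqrt(p * (1 - p)) / stats.norm.pdf(stats.norm.ppf(p))
        assert 0.11 <= biserial <= 0.77


class TestCompose:
    def test_row_count_and_columns(self, observed_2000):
        assert len(observed_2000) == 2000
        expected = {"sim_t1", "sim_t2", "aux_sum_t1", "aux_sum_t2",
                    "trs_improved", "trs7"}
        assert expected <= set(observed_2000.columns)

    def test_seeded_determinism(self, central_config, observed_2000):
        again = simulate_dataset(central_config).observed_frame()
        assert again.equals(observed_2000)

    def test_different_seeds_differ(self, central_config, observed_2000):
        other = simulate_dataset(central_config.with_(seed=43)).observed_frame()
        assert not other.equals(observed_2000)
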