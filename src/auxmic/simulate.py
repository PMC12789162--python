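"""Generative model for two-wave SIM / AUX / transition-rating data.

The data-generating process uses four mutually independent latent traits:

* ``theta_a`` — the component of the construct of interest shared by the
  single-item measure (SIM) and the auxiliary PROM (AUX);
* ``theta_b`` — the component of the construct measured by the SIM but not
  by the AUX (its SD relative to theta_a is ``strength_theta_b``);
* ``xi``      — an AUX-only trait (its slope relative to theta_a's mean
  slope is ``strength_xi``);
* ``eta``     — a SIM-only nuisance trait.

The construct of interest is ``theta = theta_a + theta_b``, standardized to
unit variance at baseline, so the fixed true MIC of 0.8 is 0.8 baseline
latent SDs — and, because one unit of theta maps to one unit of SIM true
score, 0.8 SIM points as well.

Transition ratings arise from a *perceived change*: a weighted latent change
``delta_theta_w = (1-psb)*delta_theta + psb*(theta_T2 - mean(theta_T1))``
(present-state bias mixes in the follow-up state) plus rating noise, compared
against the subject's own individual MIC (normal around 0.8).  The noise
variance is calibrated so the binary anchor's model reliability equals
``rel_trs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import SimulationConfig

__all__ = [
    "SubjectPanel",
    "GenerationError",
    "draw_latent_states",
    "generate_sim_scores",
    "generate_aux_items",
    "generate_transition_ratings",
    "simulate_dataset",
    "round_half_away",
]


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realized (e.g. infeasible solve)."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (used everywhere)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class SubjectPanel:
    """Latent states and observed scores for one simulated sample."""

    config: SimulationConfig
    latent: pd.DataFrame
    observed: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.latent)

    def observed_frame(self) -> pd.DataFrame:
        if self.observed is None:
            raise GenerationError("observed scores not generated yet")
        return self.observed

    def latent_frame(self) -> pd.DataFrame:
        return self.latent


def _component_sds(cfg: SimulationConfig) -> tuple[float, float]:
    """SDs of theta_a and theta_b with total baseline variance 1."""
    r = cfg.strength_theta_b
    s_a = 1.0 / np.sqrt(1.0 + r * r)
    return s_a, r * s_a


def solve_mean_delta(cfg: SimulationConfig) -> float:
    """Mean latent change such that P(delta_theta > individual MIC) = prop_improved.

    delta_theta - MIC_i is normal with SD sqrt(sd_delta^2 + sd_mic^2); the
    mean is found by 1-D root finding (bracketing is guarded so that an
    infeasible request raises a GenerationError).
    """
    s = float(np.hypot(cfg.sd_delta_theta, cfg.sd_individual_mic))

    def f(mu: float) -> float:
        return stats.norm.sf(cfg.true_mic, loc=mu, scale=s) - cfg.prop_improved

    lo, hi = cfg.true_mic - 12.0 * s, cfg.true_mic + 12.0 * s
    if f(lo) > 0 or f(hi) < 0:
        raise GenerationError(
            f"cannot bracket mean(delta_theta) for prop_improved={cfg.prop_improved}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def draw_latent_states(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SubjectPanel:
    """Draw the latent part of a sample (thetas, xi, eta, individual MICs)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = cfg.n_subjects
    s_a, s_b = _component_sds(cfg)
    mu_delta = solve_mean_delta(cfg)

    # the severity shift applies to the whole construct: split it over the
    # two components in proportion to their variance shares
    a1 = cfg.mean_theta_t1 * s_a**2 + s_a * rng.standard_normal(n)
    b1 = cfg.mean_theta_t1 * s_b**2 + s_b * rng.standard_normal(n)

    # change components keep the theta_b/theta_a SD ratio; each correlates
    # with its own baseline component so corr(theta_T1, delta_theta) comes
    # out exactly cor_theta_t1_delta
    c = cfg.cor_theta_t1_delta
    sd_da = cfg.sd_delta_theta * s_a
    sd_db = cfg.sd_delta_theta * s_b
    resid = np.sqrt(1.0 - c * c)
    za = rng.standard_normal(n)
    zb = rng.standard_normal(n)
    a1_std = (a1 - cfg.mean_theta_t1 * s_a**2) / s_a
    b1_std = (b1 - cfg.mean_theta_t1 * s_b**2) / s_b if s_b > 0 else np.zeros(n)
    d_a = mu_delta * s_a**2 + c * sd_da * a1_std + resid * sd_da * za
    d_b = mu_delta * s_b**2 + c * sd_db * b1_std + resid * sd_db * zb

    a2, b2 = a1 + d_a, b1 + d_b

    def _two_wave(rho: float) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        return z1, z2

    xi1, xi2 = _two_wave(cfg.cor_xi)
    eta1, eta2 = _two_wave(cfg.cor_eta)

    mic_i = cfg.true_mic + cfg.sd_individual_mic * rng.standard_normal(n)

    theta1, theta2 = a1 + b1, a2 + b2
    latent = pd.DataFrame(
        {
            "theta_a_t1": a1,
            "theta_b_t1": b1,
            "theta_a_t2": a2,
            "theta_b_t2": b2,
            "theta_t1": theta1,
            "theta_t2": theta2,
            "delta_theta": theta2 - theta1,
            "xi_t1": xi1,
            "xi_t2": xi2,
            "eta_t1": eta1,
            "eta_t2": eta2,
            "individual_mic": mic_i,
        }
    )
    return SubjectPanel(config=cfg, latent=latent)


def generate_sim_scores(
    panel: SubjectPanel,
    rel_sim_t1: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed 0-10 SIM scores at both waves.

    The latent response is ``theta + c_eta*eta + e`` where the combined
    variance of the eta term and the measurement error e equals
    ``(1-rel)/rel`` (so the squared correlation of the latent response with
    theta at baseline is exactly ``rel_sim_t1``); eta takes a fixed share
    (``config.eta_share``) of that off-target variance.  Scores are shifted
    by 5.5, rounded half-away-from-zero, and clamped to 0..10.  The same
    error SD is used at both waves.
    """
    cfg = panel.config
    rel = cfg.rel_sim_t1 if rel_sim_t1 is None else rel_sim_t1
    if not 0.0 < rel <= 1.0:
        raise GenerationError("rel_sim_t1 must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    n = panel.n
    off_var = (1.0 - rel) / rel
    c_eta = np.sqrt(cfg.eta_share * off_var)
    sd_e = np.sqrt((1.0 - cfg.eta_share) * off_var)

    lat = panel.latent
    out = []
    for t in ("t1", "t2"):
        x = lat[f"theta_{t}"].to_numpy() + c_eta * lat[f"eta_{t}"].to_numpy()
        x = x + sd_e * rng.standard_normal(n)
        lat[f"sim_star_{t}"] = x  # pre-discretization latent response (oracle)
        score = np.clip(round_half_away(x + cfg.sim_offset), cfg.sim_min, cfg.sim_max)
        out.append(score.astype(int))
    return out[0], out[1]


def _aux_item_parameters(cfg: SimulationConfig, rng: np.random.Generator):
    """Item discriminations, xi slope, and graded thresholds for the AUX."""
    k = cfg.n_aux_items
    a = cfg.aux_mean_slope * rng.lognormal(
        mean=-0.5 * cfg.aux_slope_sigma**2, sigma=cfg.aux_slope_sigma, size=k
    )
    a_xi = cfg.strength_xi * float(np.mean(a))
    shifts = rng.uniform(-cfg.aux_shift_spread, cfg.aux_shift_spread, size=k)
    m = cfg.n_aux_categories - 1
    centers = (np.arange(m) - (m - 1) / 2.0) * cfg.aux_threshold_spacing
    b = cfg.aux_threshold_shift + shifts[:, None] + centers[None, :]
    return a, a_xi, b


def generate_aux_items(
    panel: SubjectPanel,
    strength_xi: float | None = None,
    rng: np.random.Generator | None = None,
):
    """AUX item responses (graded response mechanism) and sum scores per wave.

    Each item loads on theta_a with a lognormal discrimination and on xi with
    slope ``strength_xi * mean(discrimination)``; cumulative category
    probabilities are logistic with equally spaced, item-shifted thresholds.
    Returns ``(items_t1, items_t2, sum_t1, sum_t2)``.
    """
    cfg = panel.config
    if strength_xi is not None and strength_xi != cfg.strength_xi:
        cfg = cfg.with_(strength_xi=strength_xi)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    a, a_xi, b = _aux_item_parameters(cfg, rng)
    # discriminations act on the *standardized* shared component, so the
    # AUX's own measurement quality does not depend on how much of the SIM
    # construct (theta_b) it fails to cover
    s_a, _ = _component_sds(cfg)
    lat = panel.latent
    out = {}
    for t in ("t1", "t2"):
        lin = (
            a[None, :] * (lat[f"theta_a_{t}"].to_numpy()[:, None] / s_a)
            + a_xi * lat[f"xi_{t}"].to_numpy()[:, None]
        )
        # P(Y >= k) = expit(lin - b_k); one inverse-CDF uniform per item/person
        cum = 1.0 / (1.0 + np.exp(-(lin[:, :, None] - b[None, :, :])))
        u = rng.uniform(size=lin.shape)
        out[t] = (u[:, :, None] < cum).sum(axis=2).astype(int)
    return out["t1"], out["t2"], out["t1"].sum(axis=1), out["t2"].sum(axis=1)


def weighted_change_variance(cfg: SimulationConfig) -> float:
    """Population variance of the PSB-weighted latent change."""
    sd, c, p = cfg.sd_delta_theta, cfg.cor_theta_t1_delta, cfg.psb
    var_d = sd * sd
    var_t2 = 1.0 + var_d + 2.0 * c * sd
    cov = c * sd + var_d
    return (1 - p) ** 2 * var_d + p * p * var_t2 + 2 * p * (1 - p) * cov


# cosmetic 7-category mapping of perceived change relative to the own MIC;
# the boundary between categories 4 and 5 sits exactly at the individual MIC
# so the standard dichotomization (top two categories) reproduces trs_improved
_TRS7_OFFSETS = np.array([-1.8, -1.2, -0.6, -0.15, 0.0, 0.9])


def generate_transition_ratings(
    panel: SubjectPanel,
    psb: float | None = None,
    rel_trs: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary improved/not-improved anchor (plus a cosmetic 7-level version).

    The rating noise SD solves  Var(dtheta_w) / (Var(dtheta_w) + noise +
    Var(MIC_i)) = rel_trs,  so the binary item's latent-response R^2 on the
    two factors is rel_trs by construction.
    """
    cfg = panel.config
    updates = {}
    if psb is not None:
        updates["psb"] = psb
    if rel_trs is not None:
        updates["rel_trs"] = rel_trs
    if updates:
        cfg = cfg.with_(**updates)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    lat = panel.latent
    p = cfg.psb
    d_w = (1 - p) * lat["delta_theta"].to_numpy() + p * (
        lat["theta_t2"].to_numpy() - cfg.mean_theta_t1
    )
    var_w = weighted_change_variance(cfg)
    noise_var = max(
        var_w * (1.0 - cfg.rel_trs) / cfg.rel_trs - cfg.sd_individual_mic**2, 0.0
    )
    pc = d_w + np.sqrt(noise_var) * rng.standard_normal(panel.n)
    lat["delta_theta_w"] = d_w
    lat["perceived_change"] = pc
    mic_i = lat["individual_mic"].to_numpy()
    improved = (pc > mic_i).astype(int)
    bounds = mic_i[:, None] + _TRS7_OFFSETS[None, :]
    trs7 = (pc[:, None] > bounds).sum(axis=1).astype(int)
    return improved, trs7


def simulate_dataset(cfg: SimulationConfig, include_latent: bool = True) -> SubjectPanel:
    """Compose the four generators into a complete panel.

    A single master seed (``cfg.seed``) spawns independent substreams per
    generation stage, so the same config reproduces bit-identical data and
    changing e.g. the anchor stage does not perturb the SIM scores.
    """
    try:
        streams = [
            np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(4)
        ]
        panel = draw_latent_states(cfg, rng=streams[0])
        sim1, sim2 = generate_sim_scores(panel, rng=streams[1])
        it1, it2, sum1, sum2 = generate_aux_items(panel, rng=streams[2])
        improved, trs7 = generate_transition_ratings(panel, rng=streams[3])
    except GenerationError as err:
        raise GenerationError(f"{err} (config: {cfg})") from err

    cols = {"sim_t1": sim1, "sim_t2": sim2}
    for j in range(cfg.n_aux_items):
        cols[f"aux{j + 1}_t1"] = it1[:, j]
    for j in range(cfg.n_aux_items):
        cols[f"aux{j + 1}_t2"] = it2[:, j]
    cols["aux_sum_t1"] = sum1
    cols["aux_sum_t2"] = sum2
    cols["trs_improved"] = improved
    cols["trs7"] = trs7
    panel.observed = pd.DataFrame(cols)
    if not include_latent:
        panel.latent = panel.latent.iloc[0:0]
    return panel
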