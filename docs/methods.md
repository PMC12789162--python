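# Methods

This note documents the generative model behind `auxmic.simulate`, the
estimation machinery behind `auxmic.lcfa` and `auxmic.mic`, the numerical
choices that matter, and what the simulation study does and does not
establish about real data.

## 1. Generative model

Each simulated subject carries four mutually independent latent traits,
measured at baseline (T1) and follow-up (T2):

| trait | role | distribution |
|---|---|---|
| θ^A | construct component shared by SIM and AUX | normal, SD s_A |
| θ^B | construct component measured by the SIM only | normal, SD s_B |
| ξ   | AUX-only trait | standard normal, cross-wave corr `cor_xi` |
| η   | SIM-only nuisance trait | standard normal, cross-wave corr `cor_eta` |

The construct of interest is θ = θ^A + θ^B, standardized so Var(θ_T1) = 1;
the ratio s_B/s_A equals `strength_theta_b`, and the population severity
shift `mean_theta_t1` is divided over the two components in proportion to
their variance shares (a severity difference affects the whole construct,
not only the part the AUX can see).  The latent change Δθ has SD
`sd_delta_theta`, correlation `cor_theta_t1_delta` with θ_T1 (built
component-wise so the correlation is exact), and a mean solved by 1-D root
finding so that P(Δθ > MIC_i) = `prop_improved`, where the individual MICs
are normal with mean 0.8 (the fixed true MIC, in baseline latent SDs =
SIM score points) and SD 0.2.  With normal individual MICs the solve has a
closed form, which the unit tests use as the oracle; the root finder keeps
the generator valid for other MIC distributions.

**SIM scores.**  The latent response is x_t = θ_t + c·η_t + e_t with
Var(c·η + e) = (1 − rel)/rel, so the squared correlation of x with θ at
baseline equals `rel_sim_t1` exactly.  η takes a fixed share
(`eta_share` = 0.4) of that off-target variance; η is stable across waves
while e is not, so this split controls the SD of the change score (§2).
Scores are x + 5.5, rounded half away from zero, clamped to 0..10, with
the same error SD at both waves, so SIM measurement invariance holds
exactly in the population.

**AUX items.**  Eight graded items with five categories.  Item i has
discrimination a_i (lognormal, mean 1.6, σ = 0.25) on the *standardized*
shared component θ^A/s_A, and slope `strength_xi`·mean(a) on ξ; cumulative
category probabilities are logistic with equally spaced thresholds
(spacing 1.6, global shift +0.15, item-specific location shifts uniform on
±0.4).  Defining discriminations on the standardized component makes the
AUX's internal consistency independent of how much of the SIM construct it
fails to cover; Cronbach's alpha then stays in the 0.76–0.90 band across
the whole design.

**Transition ratings.**  The anchor responds to the weighted latent change

    Δθ_w = (1 − psb)·Δθ + psb·(θ_T2 − mean θ_T1),

so `psb` (present-state bias) is the share of the follow-up state mixed
into the judgment.  A perceived change adds normal rating noise whose
variance solves Var(Δθ_w) / (Var(Δθ_w) + σ²_noise + Var(MIC_i)) =
`rel_trs`; the subject reports "improved" iff perceived change exceeds
their own MIC.  Counting the individual-MIC heterogeneity inside the
unreliable part makes `rel_trs` exactly the model R² of the binary anchor,
which is what both MIC formulas consume.  A cosmetic 7-level version of
the anchor is emitted whose top-two-category dichotomization reproduces
the binary item.

**Randomness.**  One master seed per dataset spawns independent
substreams for the latent draw, SIM errors, AUX responses and anchor
noise, so the same configuration is bit-reproducible and editing one stage
does not perturb the others.

## 2. Calibration targets

The free constants above (η share, AUX slopes/thresholds, SIM offset) were
fixed once by matching the marginal behaviour of a realistic two-wave
pain-NRS study with a multi-item auxiliary PROM across the full design
grid: baseline SIM mean ≈ 5.5 (4.4–6.6 across conditions) and SD ≈ 1.3,
change-score SD ≈ 1.4, AUX sum mean ≈ 15 of 32 with SD ≈ 7 and alpha
0.76–0.90, SIM–AUX correlations ≈ 0.3–0.9, and biserial ΔSIM–anchor
correlations ≈ 0.1–0.8.  The η share of 0.4 is what sets the change-score
SD: η persists across waves, so a larger share lowers Var(ΔSIM) without
touching the cross-sectional SDs.  These targets were fixed before the
estimator-performance experiments and are not tuned afterwards.

## 3. Estimation

**Correlation structure.**  Ordinal–ordinal pairs use two-step ML
polychoric correlations (thresholds from the inverse-normal margins, ρ
maximizing the contingency-table likelihood; bivariate normal rectangle
probabilities via Owen's T).  Continuous–ordinal pairs use the two-step
polyserial (ρ maximizing the conditional likelihood of the ordinal
responses given the standardized continuous score).  The moment-based
shortcut r·sd(y)/Σφ(τ) serves only as a bracket center: under skewed
continuous indicators it can overstate the latent correlation by ~0.05,
which propagates into the anchor reliability and latent MIC, whereas the
likelihood-based two-step stays much closer to the linear-projection
target.  Continuous–continuous pairs are Pearson.  Unobserved extreme
categories simply contribute no thresholds; mid-scale empty categories
are not collapsed unless the caller does so.

**DWLS weights.**  Each statistic is weighted by the inverse of a cheap
asymptotic variance: the observed information of the pairwise profile
likelihood at the estimate (polychoric/polyserial), (1 − r²)²/(n − 1)
(Pearson), and the delta-method binomial variance (thresholds).  The
dependence of ρ̂ on the estimated thresholds is ignored; any positive
diagonal weights leave DWLS consistent, the weights only affect
efficiency.

**Models A/B** fit the 10 correlations with 9 free parameters (factor
variances/covariance, AUX and TRs loadings, two cross-wave residual
covariances; SIM loadings fixed at 1; everything on the unit-variance
latent-response scale, i.e. delta parameterization).  Their thresholds are
saturated and drop out of the discrepancy.  **Model C** additionally fits
the standardized thresholds of both SIMs (shared τ vector — measurement
invariance) and of the anchor, on the theta parameterization: residual
variances of SIM_T1 and the anchor fixed at 1, residual variance of
SIM_T2 free, M_T1 = 0, V_T1 = 1, M_T2 and V_T2 free.

**Identification of the mean structure.**  All ordinal intercepts are
fixed at 0.  With invariant thresholds, a free SIM_T2 intercept would
trade off one-for-one against (M_T2, τ_TRs) — the three shift along an
exact ridge and the anchor threshold, hence the latent MIC, would be
undefined.  Fixing the intercept is the standard longitudinal-invariance
convention, attributes the whole latent-response shift to the factor
mean, and matches the generative truth here.

**Optimization.**  The weighted least-squares discrepancy is minimized by
a bounded trust-region-reflective Gauss–Newton solver (`least_squares`,
2-point Jacobians, tolerances 1e-10, ≤ 500 outer iterations) from
deterministic data-driven starting values (thresholds from the margins,
loadings and factor moments back-solved from a few correlation entries).
A fit is *converged* only if the optimizer reports success **and** the
solution is admissible: positive variances, non-negative concentrated
residual variances, strictly increasing thresholds, implied correlations
in [−1, 1].  Inadmissible or failed fits are returned flagged, never
raised; correlation-stage failures (a constant indicator, an empty
category) are folded into the same flag.

**Fit indices** are the standard unscaled CFI/TLI/RMSEA computed from the
DWLS discrepancy against the zero-correlation baseline model, and SRMR as
the RMS residual correlation.  No mean-and-variance ("scaled")
corrections are applied; the indices are descriptive here, nothing in the
MIC pipeline consumes them.

**MIC estimators.**  MIC_PM comes from an unpenalized ML logistic fit of
improved status on ΔSIM, solved at the marginal log-odds (natural log);
separation and non-positive slopes are reported as errors.  MIC_APM
subtracts (0.8/Rel_TRs − 0.5)·SD(ΔSIM)·Cor·logodds(prop) with Cor the
Pearson correlation of ΔSIM with the 0/1 anchor.  MIC_LCFA multiplies the
model-C latent MIC τ_TRs/λ_TRs.T2 by the SIM true-score SD
√(var(SIM_T1)·R²(SIM_T1)), with var(SIM_T1) the *observed* score
variance.  Rounding ties are half away from zero everywhere, including
the continuous-SIM 12-point rescaling.

## 4. Monte-Carlo study

One dataset per condition, as in a fully crossed screening design; the
four estimators (APM with the reliability from A, B or C; LCFA with C)
are summarized by bias and RMSE against the true 0.8, with the bias MCSE
as SD/√K and the RMSE MCSE by leave-one-out jackknife.  Non-converged
fits are excluded per method (pairwise) and counted.  Desk-scale runs use
a balanced 1/25 stride subset of the 15,552-cell grid (a stride coprime
to 2 and 3 visits every parameter's levels near-uniformly) with n = 2000
per condition — about 620 conditions and 1,900 model fits, a couple of
minutes on one CPU; the driver parallelizes and accepts any subset
fraction.  The nonparametric bootstrap resamples rows, refits the chosen
model per replicate with the original dichotomization cutpoint, and takes
percentile 2.5/97.5 limits over converged replicates, reporting the
non-convergence count; model C also yields a present-state-bias proxy
1 + λ_TRs.T1/λ_TRs.T2, which is exact under the generative model.

## 5. What the simulation does and does not show

The generator produces exactly invariant SIM measurement, linear factor
structure, normal latents, complete data and an anchor that targets the
same construct as the SIM.  Passing tests therefore demonstrate that the
estimators recover a known MIC *under the model's own assumptions*, with
realistic marginals — not that they are robust to differential item
functioning, anchors targeting broader constructs than the SIM,
missingness, or response styles beyond the stable η trait.

Known quantitative limitations, visible in the package's own experiments:

* Treating the bounded AUX **sum score** as a linear-normal indicator
  (models B/C) is mildly misspecified when the AUX saturates; at
  ceiling-heavy conditions (high severity and 80% improved) this shifts
  the latent MIC by up to ±0.05 even at population scale, with signs that
  largely cancel across the design.  The single-item model A has no such
  distortion (the item is treated ordinally) but is noisier.
* MIC_LCFA inherits a small (~+2%) inflation because the observed score
  variance of a rounded scale exceeds its latent-response variance
  (Sheppard-type correction is deliberately not applied — the formula is
  used as defined).
* The APM route degrades sharply when present-state bias is high (≥ 0.8)
  and the improved proportion is far from one half (cell biases around
  ±0.3); the LCFA route is flat across those same cells.  This is a
  property of the method, reproduced, not a defect of the implementation.
* With only three indicators per factor the models are minimally
  identified; bootstrap replicates of small real datasets can show
  substantial non-convergence, which the bootstrap reports rather than
  hides.
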