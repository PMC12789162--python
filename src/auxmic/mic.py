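"""MIC estimators: predictive modeling, adjusted PM, and the latent-scale route.

Two estimation routes recover the mean individual minimal important change
(MIC) from a two-wave dataset with a dichotomized transition-rating anchor:

* **APM** — fit a logistic regression of improved status on the SIM change
  score; the predictive-modeling MIC is the change score at which the fitted
  log-odds equals the marginal log-odds of improvement, and the adjustment
  subtracts ``(0.8/Rel_TRs - 0.5) * SD(dSIM) * Cor * logodds(imp)`` to
  correct the proportion-improved bias (the 0.8 / 0.5 coefficients stem from
  prior simulation work; Rel_TRs is the anchor reliability from an LCFA).
* **LCFA** — take the latent MIC (tau_TRs / lambda_TRs.T2) from the
  invariance model (model C) and rescale it to SIM units through the SIM's
  true-score SD: ``MIC_LCFA = sqrt(var(SIM_T1) * Rel_SIM.T1) * MIC_theta``.

Continuous single-item scales are first mapped onto a 12-point ordinal scale
(multiply by T = 11.98/range, shift to [0.51, 12.49], round); the resulting
MIC is divided by T to return to the original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .lcfa import LcfaModel
from .simulate import round_half_away

__all__ = [
    "MicEstimates",
    "RescaleTransform",
    "MicError",
    "dichotomize_trs",
    "predictive_modeling_mic",
    "apm_adjustment",
    "lcfa_mic",
    "rescale_continuous",
    "backtransform_mic",
    "estimate_all",
    "MicEstimator",
]


class MicError(ValueError):
    """Raised when an MIC quantity is undefined for the given input."""


@dataclass
class MicEstimates:
    """MIC point estimates and their ingredients for one dataset."""

    converged: bool
    model_id: str
    mic_pm: float = float("nan")
    mic_apm: float = float("nan")
    mic_theta: float = float("nan")
    mic_lcfa: float = float("nan")
    rel_trs: float = float("nan")
    rel_sim_t1: float = float("nan")
    var_sim_t1: float = float("nan")
    sd_delta_sim: float = float("nan")
    cor_pb: float = float("nan")
    prop_improved: float = float("nan")
    b0: float = float("nan")
    b1: float = float("nan")
    reason: str = ""


@dataclass(frozen=True)
class RescaleTransform:
    """Affine map of a continuous scale onto the 1..12 ordinal analysis scale."""

    t_factor: float
    r_shift: float

    @property
    def back_factor(self) -> float:
        return 1.0 / self.t_factor


def logodds(p: float) -> float:
    """Natural-log odds; infinite at the boundaries."""
    if not 0.0 < p < 1.0:
        raise MicError(f"log-odds undefined for proportion {p}")
    return float(np.log(p / (1.0 - p)))


def dichotomize_trs(
    trs7: np.ndarray, cutpoint: int = 5, n_categories: int = 7
) -> tuple[np.ndarray, float]:
    """Binary improved indicator from an ordered transition-ratings item.

    ``cutpoint`` is the first category counted as improved (0-based codes);
    the default 5 on the canonical 7-level anchor keeps the top two
    categories ("much" and "very much" improved) as the improved group.  A
    one-sided result (everyone improved or nobody improved) is returned with
    a warning, since the anchor then carries no information for the MIC.
    """
    trs7 = np.asarray(trs7)
    if not 1 <= cutpoint <= n_categories - 1:
        raise MicError(
            f"cutpoint {cutpoint} outside the category range [1, {n_categories - 1}]"
        )
    if trs7.min() < 0 or trs7.max() > n_categories - 1:
        raise MicError(f"anchor codes outside 0..{n_categories - 1}")
    improved = (trs7 >= cutpoint).astype(int)
    prop = float(improved.mean())
    if prop in (0.0, 1.0):
        import warnings

        warnings.warn("single-class anchor: MIC_APM is undefined", stacklevel=2)
    return improved, prop


def predictive_modeling_mic(
    delta_sim: np.ndarray, improved: np.ndarray
) -> tuple[float, float, float]:
    """Predictive-modeling MIC and the logistic coefficients (b0, b1).

    The PM MIC is the change score equally likely in the improved and
    not-improved groups, i.e. where the fitted log-odds equals the marginal
    log-odds:  mic_pm = (logodds(prop) - b0) / b1.
    """
    delta_sim = np.asarray(delta_sim, dtype=float)
    improved = np.asarray(improved)
    classes = np.unique(improved)
    if len(classes) < 2:
        raise MicError("anchor has a single class; logistic fit impossible")
    X = sm.add_constant(delta_sim)
    try:
        res = sm.GLM(improved, X, family=sm.families.Binomial()).fit()
    except Exception as err:  # separation etc.
        raise MicError(f"logistic fit failed: {err}") from err
    b0, b1 = float(res.params[0]), float(res.params[1])
    if not np.isfinite(b0) or not np.isfinite(b1):
        raise MicError("logistic fit diverged (separation?)")
    if b1 <= 0:
        raise MicError("non-positive anchor slope: anchor uninformative about change")
    prop = float(np.mean(improved))
    return (logodds(prop) - b0) / b1, b0, b1


def apm_adjustment(
    mic_pm: float,
    rel_trs: float,
    sd_delta_sim: float,
    cor_pb: float,
    prop_improved: float,
) -> float:
    """Adjusted predictive-modeling MIC."""
    if not 0.0 < rel_trs <= 1.0:
        raise MicError("rel_trs must be in (0, 1]")
    if sd_delta_sim <= 0:
        raise MicError("sd_delta_sim must be positive")
    lo = logodds(prop_improved)
    return mic_pm - (0.8 / rel_trs - 0.5) * sd_delta_sim * cor_pb * lo


def lcfa_mic(var_sim_t1: float, rel_sim_t1: float, mic_theta: float) -> float:
    """MIC in SIM units from the latent MIC and the SIM true-score SD."""
    if var_sim_t1 <= 0:
        raise MicError("var_sim_t1 must be positive")
    if not 0.0 < rel_sim_t1 <= 1.0:
        raise MicError("rel_sim_t1 must be in (0, 1]")
    return float(np.sqrt(var_sim_t1 * rel_sim_t1) * mic_theta)


def rescale_continuous(
    values: np.ndarray, scale_min: float, scale_max: float
) -> tuple[np.ndarray, RescaleTransform]:
    """Map a continuous scale onto the 12-point ordinal analysis scale.

    Multiplies by T = 11.98/(range), shifts so the transformed scale runs
    from 0.51 to 12.49, and rounds (half away from zero) to integers 1..12.
    """
    values = np.asarray(values, dtype=float)
    if scale_max <= scale_min:
        raise MicError("scale_max must exceed scale_min")
    bad = np.flatnonzero((values < scale_min) | (values > scale_max))
    if bad.size:
        raise MicError(
            f"values outside declared range [{scale_min}, {scale_max}] "
            f"at rows {bad[:10].tolist()}"
        )
    t = 11.98 / (scale_max - scale_min)
    r = 0.51 - t * scale_min
    out = round_half_away(t * values + r).astype(int)
    return out, RescaleTransform(t_factor=t, r_shift=r)


def backtransform_mic(mic_on_transformed_scale: float, transform: RescaleTransform) -> float:
    """MIC back on the original continuous scale (change scores need no shift)."""
    return float(mic_on_transformed_scale * transform.back_factor)


class MicEstimator(BaseEstimator):
    """End-to-end MIC estimation on a two-wave dataset (sklearn interface).

    Fits the requested LCFA model for the anchor reliability (and, for model
    C, the latent MIC), the logistic anchor regression for the PM MIC, and
    combines them into the APM and (model C only) LCFA MIC estimates.

    Attributes after ``fit``: ``mic_pm_``, ``mic_apm_``, ``mic_theta_``,
    ``mic_lcfa_``, ``rel_trs_``, ``rel_sim_t1_``, ``sd_delta_sim_``,
    ``cor_pb_``, ``prop_improved_``, ``b0_``, ``b1_``, ``converged_``,
    ``lcfa_`` (the fitted :class:`~auxmic.lcfa.LcfaModel`), ``estimates_``.
    A non-convergent LCFA yields ``converged_ = False`` with NaN estimates,
    never an exception.
    """

    def __init__(self, model: str = "C", aux_item: int = 1, trs_cut: int | None = None):
        self.model = model
        self.aux_item = aux_item
        self.trs_cut = trs_cut

    def fit(self, X: pd.DataFrame, y=None) -> "MicEstimator":
        model_id = str(self.model).upper()
        if "trs_improved" in X.columns and self.trs_cut is None:
            improved = X["trs_improved"].to_numpy().astype(int)
            prop = float(improved.mean())
        elif "trs7" in X.columns or "trs" in X.columns:
            col = "trs7" if "trs7" in X.columns else "trs"
            improved, prop = dichotomize_trs(
                X[col].to_numpy(), 5 if self.trs_cut is None else self.trs_cut
            )
        else:
            raise MicError("no transition-ratings column (trs_improved / trs7 / trs)")

        data = X.copy()
        data["trs"] = improved

        delta_sim = (data["sim_t2"] - data["sim_t1"]).to_numpy(dtype=float)
        sd_delta = float(np.std(delta_sim, ddof=1))
        var_sim_t1 = float(np.var(data["sim_t1"].to_numpy(dtype=float), ddof=1))
        cor_pb = float(np.corrcoef(delta_sim, improved)[0, 1])

        lcfa = LcfaModel(model=model_id, aux_item=self.aux_item).fit(data)
        self.lcfa_ = lcfa

        est = MicEstimates(
            converged=lcfa.converged_,
            model_id=model_id,
            sd_delta_sim=sd_delta,
            var_sim_t1=var_sim_t1,
            cor_pb=cor_pb,
            prop_improved=prop,
            reason="" if lcfa.converged_ else lcfa.result_.reason,
        )
        if lcfa.converged_:
            est.rel_trs = float(lcfa.r2_trs_)
            try:
                est.mic_pm, est.b0, est.b1 = predictive_modeling_mic(delta_sim, improved)
                est.mic_apm = apm_adjustment(
                    est.mic_pm, est.rel_trs, sd_delta, cor_pb, prop
                )
            except MicError as err:
                est.converged = False
                est.reason = str(err)
            if model_id == "C" and est.converged:
                est.rel_sim_t1 = float(lcfa.r2_sim_t1_)
                est.mic_theta = float(lcfa.mic_theta_)
                est.mic_lcfa = lcfa_mic(var_sim_t1, est.rel_sim_t1, est.mic_theta)

        self.estimates_ = est
        self.converged_ = est.converged
        for name in ("mic_pm", "mic_apm", "mic_theta", "mic_lcfa", "rel_trs",
                     "rel_sim_t1", "sd_delta_sim", "cor_pb", "prop_improved",
                     "b0", "b1"):
            setattr(self, name + "_", getattr(est, name))
        return self


def estimate_all(
    dataset: pd.DataFrame, model_choice: str = "C", aux_mode: str | None = None,
    aux_item: int = 1, trs_cut: int | None = None,
) -> MicEstimates:
    """Run the full estimation pipeline and return the estimates record.

    ``aux_mode`` is implied by the model (A: single item; B/C: sum score) and
    only validated here.
    """
    model_id = str(model_choice).upper()
    expected = "single_item" if model_id == "A" else "sum_score"
    if aux_mode is not None and aux_mode != expected:
        raise MicError(f"model {model_id} requires aux_mode={expected!r}")
    return MicEstimator(model=model_id, aux_item=aux_item, trs_cut=trs_cut).fit(dataset).estimates_
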