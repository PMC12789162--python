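"""Auxiliary-enriched longitudinal CFA models for two-wave SIM data.

Three model variants of increasing strictness are fitted by diagonally
weighted least squares (DWLS) to the mixed polychoric/polyserial/Pearson
correlation structure (plus thresholds, for the invariance model):

* **Model A** — correlated two-factor model; indicators of each wave factor
  are the SIM (continuous, loading fixed to 1), a single AUX item (ordered),
  and the dichotomous transition-ratings (TRs) item, which loads on both
  factors.  Same indicators correlate over time.
* **Model B** — as A, but the AUX *sum score* (continuous) replaces the item.
* **Model C** — as B, but specified as a measurement-invariance model for
  the SIM: both SIMs are ordered with loadings and thresholds constrained
  equal over time; the baseline factor is standardized (M=0, V=1); residual
  variances of SIM_T1 and TRs are fixed to 1 (theta parameterization) while
  the residual mean/variance of SIM_T2 and the T2 factor moments are free.

All three recover the TRs reliability (its model R^2); model C additionally
recovers the latent MIC as tau_TRs / lambda_TRs.T2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .polycor import CorrelationError, CorrelationStructure, estimate_correlations

__all__ = [
    "LcfaModelSpec",
    "LcfaFit",
    "DwlsStats",
    "LcfaModel",
    "build_model",
    "build_stats",
    "fit_model",
    "fit_from_stats",
    "fit_indices",
    "trs_reliability",
    "latent_mic",
    "sim_reliability_t1",
    "resolve_columns",
]

VARIABLES = ("sim_t1", "sim_t2", "aux_t1", "aux_t2", "trs")
PAIRS = tuple(
    (VARIABLES[i], VARIABLES[j])
    for i in range(len(VARIABLES))
    for j in range(i + 1, len(VARIABLES))
)
ADMISSIBILITY_TOL = 1e-6


class LcfaError(ValueError):
    """Contract violation in model construction or result extraction."""


@dataclass(frozen=True)
class LcfaModelSpec:
    """Declarative structure of one of the three model variants."""

    model_id: str                       # "A" | "B" | "C"
    aux_mode: str                       # "single_item" | "sum_score"
    treatments: dict[str, str]          # indicator -> "ordered" | "continuous"
    parameterization: str               # "delta" (A, B) | "theta" (C)
    invariant_sim: bool                 # loadings/thresholds equal over waves


def build_model(model_id: str, aux_mode: str) -> LcfaModelSpec:
    """Model spec for A (single ordered AUX item), B or C (AUX sum score)."""
    model_id = str(model_id).upper()
    if model_id not in ("A", "B", "C"):
        raise LcfaError(f"unknown model {model_id!r}; expected A, B or C")
    if model_id == "A" and aux_mode != "single_item":
        raise LcfaError("model A requires a single AUX item (aux_mode='single_item')")
    if model_id in ("B", "C") and aux_mode != "sum_score":
        raise LcfaError(f"model {model_id} requires the AUX sum score (aux_mode='sum_score')")
    sim_treat = "ordered" if model_id == "C" else "continuous"
    aux_treat = "ordered" if model_id == "A" else "continuous"
    return LcfaModelSpec(
        model_id=model_id,
        aux_mode=aux_mode,
        treatments={
            "sim_t1": sim_treat,
            "sim_t2": sim_treat,
            "aux_t1": aux_treat,
            "aux_t2": aux_treat,
            "trs": "ordered",
        },
        parameterization="theta" if model_id == "C" else "delta",
        invariant_sim=model_id == "C",
    )


@dataclass
class DwlsStats:
    """Sample statistics and DWLS weights the discrepancy is computed from."""

    corr: np.ndarray                    # length-10 vector, PAIRS order
    corr_w: np.ndarray                  # DWLS weights (inverse asy. variances)
    thr_s1: np.ndarray = field(default_factory=lambda: np.empty(0))
    thr_s2: np.ndarray = field(default_factory=lambda: np.empty(0))
    thr_trs: float = 0.0
    thr_s1_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    thr_s2_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    thr_trs_w: float = 1.0
    bounds_s1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    bounds_s2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_obs: int = 0


@dataclass
class LcfaFit:
    """Estimated parameters and diagnostics of a fitted LCFA model."""

    model_id: str
    converged: bool
    reason: str = ""
    n_obs: int = 0
    params: dict = field(default_factory=dict)
    loadings: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    factor_mean_t1: float = 0.0
    factor_var_t1: float = 1.0
    factor_mean_t2: float = float("nan")
    factor_var_t2: float = float("nan")
    factor_cov: float = float("nan")
    residual_cov: dict = field(default_factory=dict)
    r2_trs: float = float("nan")
    r2_sim_t1: float = float("nan")
    mic_theta: float = float("nan")
    cfi: float = float("nan")
    tli: float = float("nan")
    rmsea: float = float("nan")
    srmr: float = float("nan")
    discrepancy: float = float("nan")
    df: int = 0
    implied_corr: np.ndarray | None = None
    sample_corr: np.ndarray | None = None


# ---------------------------------------------------------------------------
# model-implied statistics
# ---------------------------------------------------------------------------

def _implied_ab(p: np.ndarray) -> np.ndarray:
    """Implied correlations for models A/B (unit-variance, delta scale)."""
    V1, V2, c12, g1, g2, lt1, lt2, cs, ca = p
    return np.array(
        [
            c12 + cs,                    # sim_t1, sim_t2
            g1 * V1,                     # sim_t1, aux_t1
            g2 * c12,                    # sim_t1, aux_t2
            lt1 * V1 + lt2 * c12,        # sim_t1, trs
            g1 * c12,                    # sim_t2, aux_t1
            g2 * V2,                     # sim_t2, aux_t2
            lt1 * c12 + lt2 * V2,        # sim_t2, trs
            g1 * g2 * c12 + ca,          # aux_t1, aux_t2
            g1 * (lt1 * V1 + lt2 * c12),  # aux_t1, trs
            g2 * (lt1 * c12 + lt2 * V2),  # aux_t2, trs
        ]
    )


def _unpack_c(p: np.ndarray, n_tau: int) -> dict:
    names = ("lam", "psi2", "M2", "V2", "c12", "g1", "g2", "lt1", "lt2",
             "tau_t", "cs", "ca")
    d = dict(zip(names, p[: len(names)]))
    d["tau_s"] = p[len(names):]
    assert len(d["tau_s"]) == n_tau
    return d


def _implied_c(p: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, n_tau: int):
    """Implied thresholds (standardized) and correlations for model C."""
    d = _unpack_c(p, n_tau)
    lam, psi2, V2, c12 = d["lam"], d["psi2"], d["V2"], d["c12"]
    lt1, lt2 = d["lt1"], d["lt2"]
    v1 = lam * lam + 1.0
    v2 = lam * lam * V2 + psi2
    vt = lt1 * lt1 + lt2 * lt2 * V2 + 2.0 * lt1 * lt2 * c12 + 1.0
    v2 = max(v2, 1e-12)
    vt = max(vt, 1e-12)
    mu2 = lam * d["M2"]
    mut = lt2 * d["M2"]
    s1, s2, st = np.sqrt(v1), np.sqrt(v2), np.sqrt(vt)

    thr1 = d["tau_s"][idx1] / s1
    thr2 = (d["tau_s"][idx2] - mu2) / s2
    thrt = (d["tau_t"] - mut) / st

    g1, g2, cs, ca = d["g1"], d["g2"], d["cs"], d["ca"]
    corr = np.array(
        [
            (lam * lam * c12 + cs) / (s1 * s2),
            lam * g1 / s1,
            lam * g2 * c12 / s1,
            lam * (lt1 + lt2 * c12) / (s1 * st),
            lam * g1 * c12 / s2,
            lam * g2 * V2 / s2,
            lam * (lt1 * c12 + lt2 * V2) / (s2 * st),
            g1 * g2 * c12 + ca,
            g1 * (lt1 + lt2 * c12) / st,
            g2 * (lt1 * c12 + lt2 * V2) / st,
        ]
    )
    return thr1, thr2, thrt, corr, d, (v1, v2, vt)


# ---------------------------------------------------------------------------
# sample statistics
# ---------------------------------------------------------------------------

def build_stats(cs: CorrelationStructure, spec: LcfaModelSpec) -> DwlsStats:
    """Flatten a correlation structure into the DWLS statistic vector."""
    corr = np.array([cs.pair(a, b) for a, b in PAIRS])
    corr_w = np.array(
        [1.0 / max(float(cs.corr_var.loc[a, b]), 1e-12) for a, b in PAIRS]
    )
    stats = DwlsStats(corr=corr, corr_w=corr_w, n_obs=cs.n_obs)
    if spec.model_id == "C":
        for wave, name in (("s1", "sim_t1"), ("s2", "sim_t2")):
            vals = cs.categories[name]
            setattr(stats, f"thr_{wave}", np.asarray(cs.thresholds[name], dtype=float))
            setattr(stats, f"thr_{wave}_w", 1.0 / np.maximum(cs.threshold_var[name], 1e-12))
            # boundary id = upper category value of each inner boundary
            setattr(stats, f"bounds_{wave}", np.asarray(vals[1:], dtype=int))
        stats.thr_trs = float(cs.thresholds["trs"][0])
        stats.thr_trs_w = float(1.0 / max(cs.threshold_var["trs"][0], 1e-12))
    return stats


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _start_ab(r: np.ndarray) -> np.ndarray:
    V1 = V2 = 0.6
    c12 = float(np.clip(r[0], -0.95, 0.95)) * 0.8 * np.sqrt(V1 * V2)
    g1 = float(np.clip(r[1] / V1, -2, 2))
    g2 = float(np.clip(r[5] / V2, -2, 2))
    det = V1 * V2 - c12 * c12
    lt1 = (r[3] * V2 - r[6] * c12) / det if det > 1e-8 else 0.0
    lt2 = (r[6] * V1 - r[3] * c12) / det if det > 1e-8 else 0.5
    return np.array([V1, V2, c12, g1, g2,
                     float(np.clip(lt1, -3, 3)), float(np.clip(lt2, -3, 3)),
                     0.02, 0.02])


def _start_c(stats: DwlsStats, tau_ids: np.ndarray) -> np.ndarray:
    r = stats.corr
    lam = 1.0
    v1 = lam * lam + 1.0
    common = np.intersect1d(stats.bounds_s1, stats.bounds_s2)
    mu2, v2 = 0.0, 2.0
    if len(common) >= 2:
        t1 = stats.thr_s1[np.searchsorted(stats.bounds_s1, common)]
        t2 = stats.thr_s2[np.searchsorted(stats.bounds_s2, common)]
        spread1, spread2 = np.std(t1), np.std(t2)
        if spread2 > 1e-6:
            v2 = float(np.clip(v1 * (spread1 / spread2) ** 2, 0.2, 20.0))
        mu2 = float(np.mean(t1 * np.sqrt(v1) - t2 * np.sqrt(v2)))
    psi2 = max(v2 - lam * lam, 0.3)
    V2 = max((v2 - psi2) / lam**2, 0.2)
    M2 = mu2 / lam
    c12 = float(np.clip(r[0], -0.95, 0.95)) * np.sqrt(v1 * v2) / lam**2
    c12 = float(np.clip(c12, -0.95 * np.sqrt(V2), 0.95 * np.sqrt(V2)))
    g1 = float(np.clip(r[1] * np.sqrt(v1) / lam, -0.95, 0.95))
    g2 = float(np.clip(r[5] * np.sqrt(v2) / (lam * V2), -2, 2))
    vt = 2.0
    det = V2 - c12 * c12
    b1 = r[3] * np.sqrt(v1 * vt) / lam
    b2 = r[6] * np.sqrt(v2 * vt) / lam
    lt1 = (b1 * V2 - b2 * c12) / det if det > 1e-8 else 0.0
    lt2 = (b2 - b1 * c12) / det if det > 1e-8 else 0.7
    lt1, lt2 = float(np.clip(lt1, -3, 3)), float(np.clip(lt2, -3, 3))
    tau_t = stats.thr_trs * np.sqrt(vt) + lt2 * M2
    tau_s = np.empty(len(tau_ids))
    for i, b in enumerate(tau_ids):
        if b in stats.bounds_s1:
            j = int(np.searchsorted(stats.bounds_s1, b))
            tau_s[i] = stats.thr_s1[j] * np.sqrt(v1)
        else:
            j = int(np.searchsorted(stats.bounds_s2, b))
            tau_s[i] = stats.thr_s2[j] * np.sqrt(v2) + mu2
    head = np.array([lam, psi2, M2, V2, c12, g1, g2, lt1, lt2,
                     float(tau_t), 0.02, 0.02])
    return np.concatenate([head, np.sort(tau_s)])


def fit_from_stats(
    stats: DwlsStats,
    spec: LcfaModelSpec,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> LcfaFit:
    """Minimize the DWLS discrepancy for the given statistics and model."""
    if spec.model_id in ("A", "B"):
        return _fit_ab(stats, spec, start, max_iter, tol)
    return _fit_c(stats, spec, start, max_iter, tol)


def _solve(residuals, x0, lb, ub, max_iter, tol):
    """Weighted least-squares minimization (trust-region reflective, bounded)."""
    x0 = np.clip(np.asarray(x0, dtype=float), lb + 1e-12, ub - 1e-12)
    res = optimize.least_squares(
        residuals, x0, bounds=(lb, ub), method="trf",
        xtol=tol, ftol=tol, gtol=tol,
        max_nfev=max_iter * (len(x0) + 1),
    )
    res.discrepancy = float(np.sum(res.fun**2))
    return res


def _baseline_discrepancy(stats: DwlsStats) -> float:
    return float(np.sum(stats.corr_w * stats.corr**2))


def _finish_indices(fit: LcfaFit, stats: DwlsStats, n_stats: int, n_params: int) -> None:
    T = fit.discrepancy
    n = stats.n_obs
    df = max(n_stats - n_params, 0)
    fit.df = df
    Tb, dfb = _baseline_discrepancy(stats), len(PAIRS)
    d = max(T - df, 0.0)
    db = max(Tb - dfb, 0.0)
    fit.cfi = 1.0 - (d / db if db > 0 else (0.0 if d == 0 else 1.0))
    if df > 0 and dfb > 0 and Tb / dfb > 1.0:
        fit.tli = ((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0)
    else:
        fit.tli = float("nan")
    fit.rmsea = float(np.sqrt(d / (df * max(n - 1, 1)))) if df > 0 else 0.0
    resid = stats.corr - fit.implied_corr
    fit.srmr = float(np.sqrt(np.mean(resid**2)))


def _fit_ab(stats, spec, start, max_iter, tol) -> LcfaFit:
    w, r = stats.corr_w, stats.corr
    sqw = np.sqrt(w)

    def residuals(p: np.ndarray) -> np.ndarray:
        return sqw * (r - _implied_ab(p))

    x0 = _start_ab(r) if start is None else np.asarray(start, dtype=float)
    lb = np.array([1e-4, 1e-4, -50, -5, -5, -20, -20, -1, -1])
    ub = np.array([50.0, 50, 50, 5, 5, 20, 20, 1, 1])
    res = _solve(residuals, x0, lb, ub, max_iter, tol)
    V1, V2, c12, g1, g2, lt1, lt2, cs, ca = res.x
    explained_trs = lt1**2 * V1 + lt2**2 * V2 + 2 * lt1 * lt2 * c12
    fit = LcfaFit(
        model_id=spec.model_id,
        converged=bool(res.success),
        reason="" if res.success else f"optimizer: {res.message}",
        n_obs=stats.n_obs,
        params=dict(zip(("V1", "V2", "c12", "g1", "g2", "lt1", "lt2", "cs", "ca"), res.x)),
        loadings={"sim_t1": 1.0, "sim_t2": 1.0, "aux_t1": g1, "aux_t2": g2,
                  "trs_t1": lt1, "trs_t2": lt2},
        factor_mean_t1=0.0, factor_var_t1=V1,
        factor_mean_t2=0.0, factor_var_t2=V2, factor_cov=c12,
        residual_cov={"sim": cs, "aux": ca},
        r2_trs=explained_trs,
        r2_sim_t1=V1,
        discrepancy=res.discrepancy,
        implied_corr=_implied_ab(res.x),
        sample_corr=r.copy(),
    )
    # admissibility: residual variances on the unit-variance scale
    resid = {
        "sim_t1": 1 - V1, "sim_t2": 1 - V2,
        "aux_t1": 1 - g1**2 * V1, "aux_t2": 1 - g2**2 * V2,
        "trs": 1 - explained_trs,
    }
    bad = [k for k, v in resid.items() if v < -ADMISSIBILITY_TOL]
    if bad and fit.converged:
        fit.converged = False
        fit.reason = f"inadmissible solution (negative residual variance: {bad})"
    _finish_indices(fit, stats, n_stats=len(PAIRS), n_params=9)
    return fit


def _fit_c(stats, spec, start, max_iter, tol) -> LcfaFit:
    tau_ids = np.union1d(stats.bounds_s1, stats.bounds_s2).astype(int)
    n_tau = len(tau_ids)
    idx1 = np.searchsorted(tau_ids, stats.bounds_s1)
    idx2 = np.searchsorted(tau_ids, stats.bounds_s2)
    w = np.concatenate([stats.thr_s1_w, stats.thr_s2_w, [stats.thr_trs_w], stats.corr_w])
    s = np.concatenate([stats.thr_s1, stats.thr_s2, [stats.thr_trs], stats.corr])

    def implied(p: np.ndarray) -> np.ndarray:
        thr1, thr2, thrt, corr, _, _ = _implied_c(p, idx1, idx2, n_tau)
        return np.concatenate([thr1, thr2, [thrt], corr])

    sqw = np.sqrt(w)

    def residuals(p: np.ndarray) -> np.ndarray:
        return sqw * (s - implied(p))

    x0 = _start_c(stats, tau_ids) if start is None else np.asarray(start, dtype=float)
    lb = np.array([1e-3, 1e-4, -20, 1e-4, -50, -3, -5, -20, -20, -20, -5, -1]
                  + [-20.0] * n_tau)
    ub = np.array([20.0, 50, 20, 50, 50, 3, 5, 20, 20, 20, 5, 1]
                  + [20.0] * n_tau)
    res = _solve(residuals, x0, lb, ub, max_iter, tol)
    thr1, thr2, thrt, corr, d, (v1, v2, vt) = _implied_c(res.x, idx1, idx2, n_tau)
    lam, lt1, lt2 = d["lam"], d["lt1"], d["lt2"]
    fit = LcfaFit(
        model_id="C",
        converged=bool(res.success),
        reason="" if res.success else f"optimizer: {res.message}",
        n_obs=stats.n_obs,
        params={**{k: float(v) for k, v in d.items() if k != "tau_s"},
                "tau_s": np.asarray(d["tau_s"]), "tau_ids": tau_ids},
        loadings={"sim_t1": lam, "sim_t2": lam, "aux_t1": d["g1"], "aux_t2": d["g2"],
                  "trs_t1": lt1, "trs_t2": lt2},
        thresholds={"sim": dict(zip(tau_ids.tolist(), np.asarray(d["tau_s"]).tolist())),
                    "trs": float(d["tau_t"])},
        factor_mean_t1=0.0, factor_var_t1=1.0,
        factor_mean_t2=float(d["M2"]), factor_var_t2=float(d["V2"]),
        factor_cov=float(d["c12"]),
        residual_cov={"sim": float(d["cs"]), "aux": float(d["ca"])},
        r2_trs=(vt - 1.0) / vt,
        r2_sim_t1=lam * lam / v1,
        mic_theta=float(d["tau_t"] / lt2) if abs(lt2) > 1e-10 else float("nan"),
        discrepancy=res.discrepancy,
        implied_corr=corr,
        sample_corr=stats.corr.copy(),
    )
    problems = []
    if d["V2"] <= 0 or d["psi2"] <= 0:
        problems.append("non-positive variance")
    if 1 - d["g1"] ** 2 < -ADMISSIBILITY_TOL or 1 - d["g2"] ** 2 * d["V2"] < -ADMISSIBILITY_TOL:
        problems.append("negative AUX residual variance")
    tau_sorted = np.asarray(d["tau_s"])
    if np.any(np.diff(tau_sorted) <= 0):
        problems.append("non-increasing thresholds")
    if np.any(np.abs(corr) > 1 + ADMISSIBILITY_TOL):
        problems.append("implied correlation outside [-1, 1]")
    if abs(d["c12"]) > np.sqrt(d["V2"]) + ADMISSIBILITY_TOL:
        problems.append("factor correlation outside [-1, 1]")
    if problems and fit.converged:
        fit.converged = False
        fit.reason = "inadmissible solution: " + "; ".join(problems)
    n_stats = len(s)
    _finish_indices(fit, stats, n_stats=n_stats, n_params=12 + n_tau)
    return fit


def fit_model(data: pd.DataFrame, spec: LcfaModelSpec, **fit_kw) -> LcfaFit:
    """Estimate the correlation structure from data and fit the model.

    Estimation failures (constant indicators, empty categories) are returned
    as a non-converged :class:`LcfaFit`, never raised.
    """
    missing = [v for v in VARIABLES if v not in data.columns]
    if missing:
        raise LcfaError(f"missing indicator columns: {missing}")
    n = len(data)
    if n < 100:
        raise LcfaError(f"need at least 100 observations, got {n}")
    if n < 200:
        warnings.warn(f"only {n} observations; estimates may be unstable", stacklevel=2)
    try:
        cs = estimate_correlations(data[list(VARIABLES)], spec.treatments)
        stats = build_stats(cs, spec)
    except CorrelationError as err:
        return LcfaFit(model_id=spec.model_id, converged=False,
                       reason=f"correlation estimation failed: {err}", n_obs=n)
    return fit_from_stats(stats, spec, **fit_kw)


# ---------------------------------------------------------------------------
# extraction helpers (spec'd accessors)
# ---------------------------------------------------------------------------

def _require_converged(fit: LcfaFit, what: str) -> None:
    if not fit.converged:
        raise LcfaError(f"{what} requested on a non-converged fit ({fit.reason})")


def fit_indices(fit: LcfaFit) -> tuple[float, float, float, float]:
    """(cfi, tli, rmsea, srmr) of a converged fit."""
    _require_converged(fit, "fit indices")
    return fit.cfi, fit.tli, fit.rmsea, fit.srmr


def trs_reliability(fit: LcfaFit) -> float:
    """Model R^2 of the TRs item: factor-explained share of its latent response."""
    _require_converged(fit, "TRs reliability")
    return float(fit.r2_trs)


def sim_reliability_t1(fit: LcfaFit) -> float:
    """Model R^2 of SIM_T1 on the baseline factor."""
    _require_converged(fit, "SIM_T1 reliability")
    return float(fit.r2_sim_t1)


def latent_mic(fit: LcfaFit) -> float:
    """Latent MIC tau_TRs / lambda_TRs.T2 from a converged model-C fit."""
    _require_converged(fit, "latent MIC")
    if fit.model_id != "C":
        raise LcfaError("the latent MIC requires model C")
    if not np.isfinite(fit.mic_theta):
        raise LcfaError("latent MIC undefined: lambda_TRs.T2 is zero")
    return float(fit.mic_theta)


def resolve_columns(
    data: pd.DataFrame, aux_mode: str, aux_item: int = 1
) -> pd.DataFrame:
    """Map an observed-data table onto the five canonical indicator roles.

    Accepts either already-roled columns (sim_t1, sim_t2, aux_t1, aux_t2,
    trs) or the simulator/reader layout (aux_sum_*, aux<k>_*, trs_improved).
    """
    out = pd.DataFrame(index=data.index)
    for col in ("sim_t1", "sim_t2"):
        if col not in data.columns:
            raise LcfaError(f"missing column {col!r}")
        out[col] = data[col]
    for wave in ("t1", "t2"):
        role = f"aux_{wave}"
        if role in data.columns:
            out[role] = data[role]
        elif aux_mode == "sum_score":
            src = f"aux_sum_{wave}"
            if src not in data.columns:
                raise LcfaError(f"missing column {src!r}")
            out[role] = data[src]
        else:
            src = f"aux{aux_item}_{wave}"
            if src not in data.columns:
                raise LcfaError(f"missing column {src!r}")
            out[role] = data[src]
    if "trs" in data.columns:
        out["trs"] = data["trs"]
    elif "trs_improved" in data.columns:
        out["trs"] = data["trs_improved"]
    else:
        raise LcfaError("missing column 'trs' / 'trs_improved'")
    return out


class LcfaModel(BaseEstimator):
    """Longitudinal CFA estimator with a scikit-learn interface.

    Parameters
    ----------
    model : {"A", "B", "C"}
        Which model variant to fit (see module docstring).
    aux_item : int
        1-based index of the AUX item used when ``model="A"``.
    max_iter, tol : optimizer controls for the DWLS minimization.

    Attributes (after ``fit``)
    --------------------------
    converged_, loadings_, thresholds_, r2_trs_, r2_sim_t1_, mic_theta_
    (model C), factor_mean_t2_, factor_var_t2_, fit_indices_, result_.
    """

    def __init__(self, model: str = "C", aux_item: int = 1,
                 max_iter: int = 500, tol: float = 1e-10):
        self.model = model
        self.aux_item = aux_item
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None) -> "LcfaModel":
        aux_mode = "single_item" if str(self.model).upper() == "A" else "sum_score"
        spec = build_model(self.model, aux_mode)
        data = resolve_columns(X, aux_mode, self.aux_item)
        result = fit_model(data, spec, max_iter=self.max_iter, tol=self.tol)
        self.result_ = result
        self.spec_ = spec
        self.converged_ = result.converged
        self.loadings_ = result.loadings
        self.thresholds_ = result.thresholds
        self.r2_trs_ = result.r2_trs
        self.r2_sim_t1_ = result.r2_sim_t1
        self.mic_theta_ = result.mic_theta if result.model_id == "C" else float("nan")
        self.factor_mean_t2_ = result.factor_mean_t2
        self.factor_var_t2_ = result.factor_var_t2
        self.fit_indices_ = (result.cfi, result.tli, result.rmsea, result.srmr)
        self.n_features_in_ = 5
        return self
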