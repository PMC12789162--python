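"""Latent-correlation estimation for mixed ordinal/continuous indicators.

Pairwise estimates feed the diagonally weighted least squares (DWLS) model
fit: polychoric (ordinal-ordinal, two-step ML), polyserial
(continuous-ordinal, Olsson two-step), and Pearson (continuous-continuous)
correlations, together with inverse-normal thresholds and per-statistic
asymptotic variances that supply the DWLS weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CorrelationStructure",
    "CorrelationError",
    "bvn_cdf",
    "empirical_thresholds",
    "polychoric",
    "polyserial",
    "estimate_correlations",
]

CLAMP_EPS = 1e-6
_TAIL = 8.0  # |z| beyond which Phi is numerically 0/1


class CorrelationError(ValueError):
    """Raised when a correlation or threshold cannot be estimated."""


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T.

    Vectorized over ``h`` and ``k``; infinite bounds are supported.
    """
    h = np.clip(np.asarray(h, dtype=float), -_TAIL, _TAIL)
    k = np.clip(np.asarray(k, dtype=float), -_TAIL, _TAIL)
    h, k = np.broadcast_arrays(h, k)
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.maximum(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0)
    # nudge exact zeros so the Owen's-T arguments stay finite
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    d = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * d)
    a_k = (h - rho * k) / (k * d)
    delta = np.where(h * k > 0, 0.0, 0.5)
    out = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - delta
    )
    return np.clip(out, 0.0, 1.0)


def empirical_thresholds(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category values, inner thresholds, and threshold variances.

    Thresholds are the inverse-normal of the cumulative category proportions
    at the K-1 inner boundaries; their variances come from the delta method
    applied to the binomial cumulative proportions.
    """
    y = np.asarray(y)
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise CorrelationError("ordinal indicator has fewer than 2 observed categories")
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    tau = stats.norm.ppf(cum)
    dens = stats.norm.pdf(tau)
    var = cum * (1.0 - cum) / (n * dens**2)
    return values, tau, var


def _cell_loglik(table: np.ndarray, tau_r: np.ndarray, tau_c: np.ndarray, rho: float) -> float:
    a = np.concatenate(([-np.inf], tau_r, [np.inf]))
    b = np.concatenate(([-np.inf], tau_c, [np.inf]))
    grid = bvn_cdf(a[:, None], b[None, :], rho)
    probs = np.diff(np.diff(grid, axis=0), axis=1)
    probs = np.clip(probs, 1e-300, None)
    return float(np.sum(table * np.log(probs)))


def polychoric(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polychoric correlation and its asymptotic variance.

    Thresholds come from the univariate margins; rho maximizes the pairwise
    contingency-table likelihood.  The variance is the inverse observed
    information of that profile likelihood at the optimum.
    """
    xv, tau_x, _ = empirical_thresholds(x)
    yv, tau_y, _ = empirical_thresholds(y)
    xi = np.searchsorted(xv, x)
    yi = np.searchsorted(yv, y)
    table = np.zeros((len(xv), len(yv)))
    np.add.at(table, (xi, yi), 1.0)

    def nll(r: float) -> float:
        return -_cell_loglik(table, tau_x, tau_y, r)

    res = optimize.minimize_scalar(
        nll, bounds=(-1 + CLAMP_EPS, 1 - CLAMP_EPS), method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    var = _curvature_variance(nll, rho, len(x))
    return _clamped(rho), var


def polyserial(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step polyserial correlation of continuous ``x`` with ordinal ``y``.

    Thresholds come from the ordinal margins; rho maximizes the conditional
    likelihood of the ordinal responses given standardized ``x`` (Olsson's
    two-step).  The moment estimator r_xy * sd(y) / sum(phi(tau)) provides
    the bracket center.  The variance is the inverse observed information of
    the profile criterion at the optimum.
    """
    x = np.asarray(x, dtype=float)
    yv, tau, _ = empirical_thresholds(y)
    codes = np.searchsorted(yv, y).astype(float)
    sx = x.std(ddof=0)
    if sx == 0:
        raise CorrelationError("continuous indicator has zero variance")
    r = float(np.corrcoef(x, codes)[0, 1])
    rho0 = r * codes.std(ddof=0) / float(stats.norm.pdf(tau).sum())

    z = (x - x.mean()) / sx
    lo = np.concatenate(([-np.inf], tau))[np.searchsorted(yv, y)]
    hi = np.concatenate((tau, [np.inf]))[np.searchsorted(yv, y)]

    def nll(rh: float) -> float:
        rh = np.clip(rh, -1 + CLAMP_EPS, 1 - CLAMP_EPS)
        s = np.sqrt(1.0 - rh * rh)
        p = stats.norm.cdf((hi - rh * z) / s) - stats.norm.cdf((lo - rh * z) / s)
        return -float(np.sum(np.log(np.clip(p, 1e-300, None))))

    lo_b = max(-1 + CLAMP_EPS, min(rho0, 0) - 0.5)
    hi_b = min(1 - CLAMP_EPS, max(rho0, 0) + 0.5)
    res = optimize.minimize_scalar(
        nll, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-7}
    )
    rho = _clamped(float(res.x))
    var = _curvature_variance(nll, rho, len(x))
    return rho, var


def _curvature_variance(nll, rho: float, n: int, h: float = 1e-3) -> float:
    r = np.clip(rho, -1 + 2 * h, 1 - 2 * h)
    second = (nll(r + h) - 2.0 * nll(r) + nll(r - h)) / (h * h)
    if not np.isfinite(second) or second <= 0:
        return (1.0 - rho * rho) ** 2 / n
    return 1.0 / second


def _clamped(rho: float) -> float:
    # (near-)perfect association: pin to +/-(1 - eps) so downstream weights
    # and fits stay finite
    if abs(rho) >= 1.0 - 10 * CLAMP_EPS:
        warnings.warn("correlation clamped to +/-(1 - 1e-6)", stacklevel=3)
        return float(np.sign(rho) * (1.0 - CLAMP_EPS))
    return float(rho)


@dataclass
class CorrelationStructure:
    """Pairwise latent correlations, thresholds, and DWLS weight information."""

    variables: list[str]
    treatments: dict[str, str]                  # name -> "ordered" | "continuous"
    corr: pd.DataFrame
    corr_var: pd.DataFrame                      # asymptotic variances of corr entries
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    threshold_var: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, np.ndarray] = field(default_factory=dict)
    n_obs: int = 0

    def pair(self, a: str, b: str) -> float:
        return float(self.corr.loc[a, b])


def estimate_correlations(
    data: pd.DataFrame, treatments: dict[str, str]
) -> CorrelationStructure:
    """Estimate the full mixed correlation structure for the given columns.

    Ordinal-ordinal pairs use polychoric ML, ordinal-continuous polyserial,
    continuous-continuous Pearson.  Continuous columns are standardized
    internally (the model concentrates their scale out), so every entry is a
    correlation of (latent) standard-normal responses.
    """
    names = list(treatments)
    missing = [v for v in names if v not in data.columns]
    if missing:
        raise CorrelationError(f"columns not in data: {missing}")
    n = len(data)
    cols = {v: data[v].to_numpy() for v in names}

    thresholds, thr_var, cats = {}, {}, {}
    for v in names:
        if treatments[v] == "ordered":
            try:
                cats[v], thresholds[v], thr_var[v] = empirical_thresholds(cols[v])
            except CorrelationError as err:
                raise CorrelationError(f"indicator {v!r}: {err}") from err
        elif cols[v].std() == 0:
            raise CorrelationError(f"continuous indicator {v!r} has zero variance")

    k = len(names)
    R = np.eye(k)
    V = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            ta, tb = treatments[a], treatments[b]
            if ta == "ordered" and tb == "ordered":
                rho, var = polychoric(cols[a], cols[b])
            elif ta == "continuous" and tb == "continuous":
                rho = float(np.corrcoef(cols[a], cols[b])[0, 1])
                rho, var = _clamped(rho), (1.0 - rho * rho) ** 2 / max(n - 1, 1)
            elif ta == "continuous":
                rho, var = polyserial(cols[a], cols[b])
            else:
                rho, var = polyserial(cols[b], cols[a])
            R[i, j] = R[j, i] = rho
            V[i, j] = V[j, i] = var

    return CorrelationStructure(
        variables=names,
        treatments=dict(treatments),
        corr=pd.DataFrame(R, index=names, columns=names),
        corr_var=pd.DataFrame(V, index=names, columns=names),
        thresholds=thresholds,
        threshold_var=thr_var,
        categories=cats,
        n_obs=n,
    )
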