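"""Psychometric fitting, 2IFC observer simulation and reanalysis statistics.

The psychometric family is a cumulative Gaussian with a bounded lapse rate,
fitted by maximum likelihood in the 2IFC chose-test parameterization:

    P(choose test | level x) = lapse/2 + (1 - lapse) * Phi((x - pse)/sigma)

PSE is the 50% point; the j.n.d. is the level difference between the 50%
and 84% points (one SD of the underlying Gaussian); sensitivity is the
reciprocal of the j.n.d.

Also included: the default-prior (JZS) Bayes factor from a t statistic, a
log-space 3-SD outlier screen, the quadratic-sum cap applied to combined
reliabilities, a robust Pearson correlation with boxplot-rule bivariate
outlier rejection, and the CSF tissue correction for spectroscopy
concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

__all__ = [
    "PsychometricFit",
    "DegenerateFitError",
    "fit_psychometric",
    "simulate_2ifc",
    "bayes_factor_from_t",
    "cap_quadratic",
    "screen_outliers_log3sd",
    "robust_pearson",
    "tissue_correct",
]

_LAPSE_MAX = 0.1
_SIGMA_MIN = 1e-2
_SIGMA_MAX = 1e3


class DegenerateFitError(RuntimeError):
    """Raised when the psychometric fit pins a parameter at a bound on
    flat/uninformative data."""


@dataclass(frozen=True)
class PsychometricFit:
    pse: float                  # degrees
    jnd: float                  # degrees (1 SD of the underlying Gaussian)
    lapse: float
    negloglik: float
    n_trials: int
    at_lower_bound: bool = False   # step-function data: jnd at its floor

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.jnd

    def predict(self, levels: np.ndarray) -> np.ndarray:
        z = (np.asarray(levels, float) - self.pse) / self.jnd
        return self.lapse / 2.0 + (1.0 - self.lapse) * stats.norm.cdf(z)


def _nll(params, levels, n_chose, n_total):
    pse, sigma, lapse = params
    p = lapse / 2.0 + (1.0 - lapse) * stats.norm.cdf((levels - pse) / sigma)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(n_chose * np.log(p) + (n_total - n_chose) * np.log(1 - p))


def fit_psychometric(table: pd.DataFrame,
                     level_col: str = "test_level",
                     response_col: str = "response") -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit with lapse.

    ``table`` holds one row per trial with the test level (degrees) and the
    binary chose-test response. Requires >= 4 distinct levels and >= 10
    trials. Flat data (slope indistinguishable from zero: sigma at its
    ceiling) raise :class:`DegenerateFitError`; step-function data return a
    fit flagged ``at_lower_bound``.
    """
    levels_all = np.asarray(table[level_col], dtype=float)
    resp_all = np.asarray(table[response_col], dtype=float)
    if not np.all(np.isfinite(levels_all)):
        raise ValueError("test levels must be finite")
    if not np.all((resp_all == 0) | (resp_all == 1)):
        raise ValueError("responses must be binary")
    if np.unique(levels_all).size < 4:
        raise ValueError("need >= 4 distinct test levels")
    if levels_all.size < 10:
        raise ValueError("need >= 10 trials")
    grouped = (pd.DataFrame({"x": levels_all, "r": resp_all})
               .groupby("x")["r"].agg(["sum", "count"]).reset_index())
    x = grouped["x"].to_numpy()
    k = grouped["sum"].to_numpy()
    n = grouped["count"].to_numpy()
    span = x.max() - x.min()
    bounds = [(x.min() - span, x.max() + span),
              (_SIGMA_MIN, _SIGMA_MAX), (0.0, _LAPSE_MAX)]
    best = None
    for sigma0 in (span / 4, span / 10, span):
        res = optimize.minimize(
            _nll, x0=np.array([float(np.median(x)), sigma0, 0.02]),
            args=(x, k, n), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pse, sigma, lapse = best.x
    if sigma >= min(_SIGMA_MAX * 0.99, 5.0 * span):
        raise DegenerateFitError(
            "slope parameter (sigma) is unresolvably shallow (>= 5x the "
            "level span): responses do not depend on the stimulus level")
    return PsychometricFit(pse=float(pse), jnd=float(sigma),
                           lapse=float(lapse), negloglik=float(best.fun),
                           n_trials=int(levels_all.size),
                           at_lower_bound=bool(sigma <= _SIGMA_MIN * 1.01))


def simulate_2ifc(observer: Union[float, Callable[[float, float], float]],
                  reference: float, test_levels: Sequence[float],
                  n_per_level: int, seed: int,
                  condition_id: str = "condition") -> pd.DataFrame:
    """Simulate a two-interval forced-choice block (method of constant stimuli).

    ``observer`` is either a Gaussian internal SD (degrees) — the choice
    probability is then Phi((test - reference)/(sigma*sqrt(2))), the
    difference of two noisy interval estimates, so the sqrt(2) of the
    sensitivity conversion emerges from the task structure — or a callable
    p(test, reference) giving the chose-test probability directly.

    Returns a tidy trial table (condition_id, reference_level, test_level,
    response).
    """
    levels = np.asarray(test_levels, dtype=float)
    if not (levels.min() <= reference <= levels.max()):
        raise ValueError("test levels must bracket the reference")
    rng = np.random.default_rng(seed)
    rows = []
    for x in levels:
        if callable(observer):
            p = float(observer(x, reference))
        else:
            sigma = float(observer)
            if sigma <= 0:
                raise ValueError("observer SD must be positive")
            p = float(stats.norm.cdf((x - reference) / (sigma * np.sqrt(2.0))))
        resp = rng.random(n_per_level) < p
        for r in resp:
            rows.append({"condition_id": condition_id,
                         "reference_level": reference,
                         "test_level": x, "response": int(r)})
    return pd.DataFrame(rows)


def bayes_factor_from_t(t_value: float, n: int, r_scale: float = np.sqrt(2) / 2
                        ) -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a one-sample/paired t test.

    Computed by direct quadrature of the Zellner–Siow integrand with prior
    scale ``r_scale`` (default 0.707). Values > 1 favour the alternative.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    nu = n - 1
    t2 = float(t_value) ** 2

    def integrand(g):
        return ((1 + n * g * r_scale ** 2) ** -0.5
                * (1 + t2 / (nu * (1 + n * g * r_scale ** 2))) ** (-(nu + 1) / 2)
                * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)))

    marginal_alt, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    marginal_null = (1 + t2 / nu) ** (-(nu + 1) / 2)
    return float(marginal_alt / marginal_null)


def cap_quadratic(combined: np.ndarray, single_a: np.ndarray,
                  single_b: np.ndarray) -> np.ndarray:
    """Cap combined reliabilities at the quadratic sum of the singles."""
    combined = np.asarray(combined, dtype=float)
    single_a = np.asarray(single_a, dtype=float)
    single_b = np.asarray(single_b, dtype=float)
    if np.any(single_a < 0) or np.any(single_b < 0) or np.any(combined < 0):
        raise ValueError("reliabilities must be >= 0")
    return np.minimum(combined, np.hypot(single_a, single_b))


def screen_outliers_log3sd(values: Sequence[float]
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Remove values > 3 SD from the mean in log space.

    Returns (kept values in original order, removed indices). With n <= 2
    the SD is unstable and nothing is removed (a warning is issued).
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("values must be positive for the log transform")
    if v.size <= 2:
        warnings.warn("n <= 2: outlier screen skipped (SD unstable)")
        return v.copy(), np.array([], dtype=int)
    logv = np.log(v)
    z = (logv - logv.mean()) / logv.std(ddof=1)
    removed = np.flatnonzero(np.abs(z) > 3.0)
    kept = np.delete(v, removed)
    return kept, removed


def _boxplot_fences(x: np.ndarray) -> Tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def robust_pearson(x: Sequence[float], y: Sequence[float],
                   n_boot: int = 2000, seed: int = 0,
                   ci_level: float = 0.95):
    """Pearson correlation after boxplot-rule bivariate outlier rejection.

    A point is rejected when it falls outside the 1.5*IQR fences on either
    variable's projection. Returns a dict with n, r, the t-based p, a
    bootstrap percentile CI and the rejected indices (the figures' "empty
    circles").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    lo_x, hi_x = _boxplot_fences(x)
    lo_y, hi_y = _boxplot_fences(y)
    keep = (x >= lo_x) & (x <= hi_x) & (y >= lo_y) & (y <= hi_y)
    outliers = np.flatnonzero(~keep)
    xk, yk = x[keep], y[keep]
    if xk.size < 4:
        raise ValueError("fewer than 4 points remain after outlier rejection")
    if np.std(xk) == 0 or np.std(yk) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(xk, yk)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    idx = np.arange(xk.size)
    for b in range(n_boot):
        take = rng.choice(idx, size=idx.size, replace=True)
        if np.std(xk[take]) == 0 or np.std(yk[take]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.pearsonr(xk[take], yk[take])[0]
    alpha = (1 - ci_level) / 2
    ci = tuple(np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)]))
    return {"n": int(xk.size), "r": float(r), "p": float(p),
            "ci": (float(ci[0]), float(ci[1])),
            "outlier_indices": outliers}


def tissue_correct(C_meas: float, f_GM: float, f_WM: float) -> float:
    """CSF-corrected concentration: C / (f_GM + f_WM).

    The grey- plus white-matter fraction must lie in (0, 1]; the correction
    inflates the measured value in proportion to the CSF fraction.
    """
    total = f_GM + f_WM
    if not 0.0 < total <= 1.0:
        raise ValueError("f_GM + f_WM must lie in (0, 1]")
    return float(C_meas / total)
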