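"""Closed-form maximum-likelihood cue combination and a normalization comparator.

The MLE baseline is the standard reliability-weighted fusion scheme: the
combined estimate is a weighted average of the single-cue slants with weights
proportional to each cue's reliability (inverse variance), and the combined
SD is below either single cue's. These predictions are optimal for congruent
cues but never revert to the more reliable cue under conflict, which is the
failure mode the population model addresses.

``normalization_comparator`` is an illustrative, simplified
divisive-normalization model (congruent-only combination grid, activity
divided by summed population activity, decoded identically to the main
model). It is not a faithful reimplementation of any published normalization
model; it exists to show the qualitative failure to revert under conflict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import (
    ModelConfig,
    SlantStimulus,
    sample_poisson,
    unimodal_response,
)

__all__ = [
    "CuePrecision",
    "mle_sigma",
    "mle_weights",
    "mle_estimate",
    "sigma_to_sensitivity",
    "sensitivity_to_sigma",
    "normalization_comparator",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class CuePrecision:
    """Single-cue estimate SDs (degrees), reliabilities and slants for MLE."""

    sigma_delta: float
    sigma_chi: float
    S_delta: float
    S_chi: float

    def __post_init__(self) -> None:
        if self.sigma_delta <= 0 or self.sigma_chi <= 0:
            raise ValueError("sigmas must be positive")

    @property
    def r_delta(self) -> float:
        return 1.0 / self.sigma_delta ** 2

    @property
    def r_chi(self) -> float:
        return 1.0 / self.sigma_chi ** 2


def mle_sigma(sigma_delta: float, sigma_chi: float) -> float:
    """Combined estimate SD under optimal fusion: harmonic-style reduction.

    sigma_dx = sqrt(sd^2 sx^2 / (sd^2 + sx^2)); symmetric, never above the
    smaller input.
    """
    if sigma_delta <= 0 or sigma_chi <= 0:
        raise ValueError("sigmas must be positive")
    s2d, s2x = sigma_delta ** 2, sigma_chi ** 2
    return float(np.sqrt(s2d * s2x / (s2d + s2x)))


def mle_weights(r_delta: float, r_chi: float) -> Tuple[float, float]:
    """Reliability-proportional cue weights; sum to 1 exactly."""
    if r_delta < 0 or r_chi < 0:
        raise ValueError("reliabilities must be >= 0")
    total = r_delta + r_chi
    if total == 0:
        raise ValueError("at least one reliability must be positive")
    return r_delta / total, r_chi / total


def mle_estimate(S_delta: float, S_chi: float,
                 weights: Tuple[float, float]) -> float:
    """Weighted-average combined slant; weights must sum to 1."""
    w_d, w_x = weights
    if abs(w_d + w_x - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w_d + w_x}")
    return w_d * S_delta + w_x * S_chi


def sigma_to_sensitivity(sigma: float) -> float:
    """2IFC sensitivity from estimate SD: s = 1/(sigma * sqrt(2)).

    The sqrt(2) reflects the comparison of two independently noisy
    intervals in a forced-choice judgement.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (sigma * _SQRT2)


def sensitivity_to_sigma(sensitivity: float) -> float:
    """Inverse of :func:`sigma_to_sensitivity`."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    return 1.0 / (sensitivity * _SQRT2)


def normalization_comparator(stimulus: SlantStimulus, config: ModelConfig,
                             rng: Optional[np.random.Generator] = None,
                             noise_free: bool = False,
                             sigma_semi: float = 1.0):
    """Simplified divisive-normalization model: fused estimates, no reversion.

    Only congruent combination units exist (the grid diagonal); their summed
    activity is divided by the pooled population activity plus a
    semi-saturation constant, then decoded with the same centroid/peak rules
    as the population model.

    Returns (mean estimate rad, estimate SD rad, mean peak) over trials.
    """
    r_d = unimodal_response(stimulus.slant_delta, stimulus.A_delta, config, "disparity")
    r_x = unimodal_response(stimulus.slant_chi, stimulus.A_chi, config, "texture")
    if noise_free:
        fd, fx = r_d[None, :], r_x[None, :]
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        fd = sample_poisson(r_d, config.n_trials, rng).astype(float)
        fx = sample_poisson(r_x, config.n_trials, rng).astype(float)
    diag = np.sqrt(fd + fx)                       # congruent units only
    pooled = diag.sum(axis=-1, keepdims=True)
    R = diag / (sigma_semi + pooled)
    mass = R.sum(axis=-1)
    ok = mass > 0
    cen = (R[ok] * config.prefs).sum(axis=-1) / mass[ok]
    peak = R[ok].max(axis=-1)
    sd = float(cen.std()) if cen.size > 1 else np.nan
    return float(cen.mean()), sd, float(peak.mean())
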