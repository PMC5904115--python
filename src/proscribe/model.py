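"""Population-coding core: unimodal encoding, combination layer, suppressive readout.

The model estimates surface slant from two depth cues (binocular disparity and
texture).  Each cue is encoded by a bank of von Mises-tuned units; a 2-D layer
of *combination units* pools every (disparity-preference, texture-preference)
pair with a sublinear (square-root) summation; a 1-D output layer reads the
combination grid out along anti-diagonals with cosine weights whose negative
lobes implement *proscription* — suppression of unrealistic cue combinations.
The decoded peak position is the slant estimate and the peak height is the
reliability proxy.

Angles are radians internally; slant lives on [-pi/2, pi/2] and is mapped onto
one full cycle of the von Mises by a factor of 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ModelConfig",
    "SlantStimulus",
    "SlantEstimate",
    "ConditionSummary",
    "DegenerateEstimateError",
    "unimodal_response",
    "sample_poisson",
    "combine",
    "build_readout",
    "readout",
    "decode",
    "simulate_condition",
]

HALF_PI = np.pi / 2.0


class DegenerateEstimateError(ValueError):
    """Raised when a rectified output profile carries no peak (all zero)."""


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the proscriptive integration model.

    Parameters
    ----------
    n_units : int
        Number of unimodal preferences per cue; odd so that 0 rad is a
        preference. The combination layer has ``n_units**2`` units.
    k : float
        von Mises tuning concentration (unitless) on the doubled slant angle.
        The default 11.5 gives a tuning bandwidth (half-width at half-height)
        of ~10 degrees.
    c : float
        Tonic-inhibition offset subtracted from the cosine readout weights.
    beta : float
        Attenuation of the negative (suppressive) readout weights, in [0, 1].
        ``beta=1`` is full suppression; lower values weaken proscription.
    pos_scale, neg_scale : float
        Multiplicative factors on the positive / negative readout weights,
        in [0, 1]; used to emulate excitability perturbations (tDCS).
    n_trials : int
        Poisson repetitions per condition in stochastic simulations.
    rate_scale : float
        Mean spikes per interval at the tuning-curve peak for unit intensity.
    seed : int
        RNG seed for the Poisson stage.
    bimodal_ratio : float
        A secondary mode counts toward the bimodality flag when the output
        profile exceeds ``bimodal_ratio`` times the global peak in a second,
        disconnected region.
    edge_margin : int
        Decoded peaks within this many grid points of either end of the
        preference axis are flagged as edge-contaminated.
    """

    n_units: int = 37
    k: float = 11.5
    c: float = 0.05
    beta: float = 1.0
    pos_scale: float = 1.0
    neg_scale: float = 1.0
    n_trials: int = 100
    rate_scale: float = 30.0
    seed: int = 0
    bimodal_ratio: float = 0.7
    edge_margin: int = 2

    def __post_init__(self) -> None:
        if self.n_units < 3 or self.n_units % 2 == 0:
            raise ValueError("n_units must be odd and >= 3")
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name in ("beta", "pos_scale", "neg_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if not 0.0 < self.bimodal_ratio < 1.0:
            raise ValueError("bimodal_ratio must lie in (0, 1)")

    @property
    def prefs(self) -> np.ndarray:
        """Preferred slants: ``n_units`` evenly spaced values on [-pi/2, pi/2]."""
        return np.linspace(-HALF_PI, HALF_PI, self.n_units)

    @property
    def spacing(self) -> float:
        return np.pi / (self.n_units - 1)

    @property
    def offsets(self) -> np.ndarray:
        """Readout offsets j: integer multiples of the grid spacing, |j| <= pi/4."""
        m_max = int(np.floor((np.pi / 4.0) / self.spacing + 1e-12))
        return np.arange(-m_max, m_max + 1) * self.spacing

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SlantStimulus:
    """Cue slants (radians) and intensities for one condition.

    An intensity of 0 means the cue is absent.
    """

    slant_delta: float
    slant_chi: float
    A_delta: float
    A_chi: float

    def __post_init__(self) -> None:
        for name in ("slant_delta", "slant_chi"):
            s = getattr(self, name)
            if not -HALF_PI <= s <= HALF_PI:
                raise ValueError(f"{name}={s} outside [-pi/2, pi/2]")
        if self.A_delta < 0 or self.A_chi < 0:
            raise ValueError("cue intensities must be >= 0")

    @classmethod
    def from_degrees(cls, slant_delta_deg: float, slant_chi_deg: float,
                     A_delta: float, A_chi: float) -> "SlantStimulus":
        return cls(np.deg2rad(slant_delta_deg), np.deg2rad(slant_chi_deg),
                   A_delta, A_chi)


@dataclass(frozen=True)
class SlantEstimate:
    """Decoded output-layer profile for a single trial.

    ``slant_hat`` is the position of the profile peak; ``slant_centroid`` is
    the population-vector (centre-of-mass) estimate of the same rectified
    profile, which varies smoothly with the stimulus rather than in grid
    steps and is what condition summaries use for bias and trial-to-trial
    sensitivity.
    """

    F: np.ndarray               # rectified output profile, >= 0
    slant_hat: float            # peak position, radians
    slant_centroid: float       # centre of mass of the profile, radians
    peak_height: float          # max of the rectified profile
    bimodal: bool               # >= 2 disconnected supra-threshold modes
    edge_flag: bool             # peak within edge_margin of the axis ends


def unimodal_response(stimulus_slant: float, intensity: float,
                      config: ModelConfig, cue_label: str = "cue") -> np.ndarray:
    """Mean firing rates of one cue's unimodal bank for a single slant.

    von Mises tuning on the doubled angle (so [-pi/2, pi/2] spans one cycle),
    peak-normalized: the unit preferring the stimulus slant fires at
    ``intensity * rate_scale``. Rates scale exactly linearly with intensity.
    """
    if not -HALF_PI <= stimulus_slant <= HALF_PI:
        raise ValueError(
            f"{cue_label} slant {stimulus_slant} outside [-pi/2, pi/2]")
    if intensity < 0:
        raise ValueError(f"{cue_label} intensity must be >= 0")
    shape = np.exp(config.k * (np.cos(2.0 * (stimulus_slant - config.prefs)) - 1.0))
    return intensity * config.rate_scale * shape


def sample_poisson(rates: np.ndarray, n_trials: int,
                   rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n_trials`` independent Poisson spike-count vectors."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return rng.poisson(rates, size=(int(n_trials), rates.size))


def combine(f_delta: np.ndarray, f_chi: np.ndarray) -> np.ndarray:
    """Combination-unit activity E(i, j) = sqrt(f_delta(i) + f_chi(j)).

    Supports batched inputs of shape (..., n_units); the grid axes are the
    last two of the result (disparity preference first).
    """
    f_delta = np.asarray(f_delta, dtype=float)
    f_chi = np.asarray(f_chi, dtype=float)
    if np.any(f_delta < 0) or np.any(f_chi < 0):
        raise ValueError("unimodal inputs must be >= 0")
    if f_delta.shape[-1] != f_chi.shape[-1]:
        raise ValueError("input vectors must share n_units")
    return np.sqrt(f_delta[..., :, None] + f_chi[..., None, :])


def build_readout(config: ModelConfig) -> np.ndarray:
    """Cosine readout weights over offsets j: (cos(4 j) - c), scaled.

    The positive part is multiplied by ``pos_scale``; the negative part by
    ``neg_scale * beta`` (suppressive gain).
    """
    w = np.cos(4.0 * config.offsets) - config.c
    pos = np.clip(w, 0.0, None) * config.pos_scale
    neg = np.clip(w, None, 0.0) * config.neg_scale * config.beta
    return pos + neg


def readout(grid: np.ndarray, weights: np.ndarray,
            config: ModelConfig) -> np.ndarray:
    """Sum the combination grid along anti-diagonals with cosine weights.

    ``F_i = sum_j E(i - j, i + j) * w(j)``. Indices wrap circularly: the
    doubled-angle von Mises tuning identifies -pi/2 with +pi/2, so the
    preference axis is periodic (the endpoint unit is shared). Batched over
    leading axes.
    """
    grid = np.asarray(grid, dtype=float)
    n = config.n_units
    n_off = config.offsets.size
    if grid.shape[-2:] != (n, n):
        raise ValueError(f"grid must end in ({n}, {n}), got {grid.shape}")
    if weights.shape != (n_off,):
        raise ValueError(f"weights must have shape ({n_off},)")
    m_max = (n_off - 1) // 2
    # period is n - 1 grid steps (first and last preference coincide)
    period = n - 1
    i = np.arange(n)
    F = np.zeros(grid.shape[:-2] + (n,), dtype=float)
    for m_idx, m in enumerate(range(-m_max, m_max + 1)):
        F += weights[m_idx] * grid[..., (i - m) % period, (i + m) % period]
    return F


def _decode_batch(raw: np.ndarray, config: ModelConfig):
    """Vectorized decode of a (trials, n_units) batch of raw output profiles.

    Returns (slant_hat, centroid, peak_height, bimodal, edge, valid) arrays;
    trials with an all-zero rectified profile are marked invalid rather than
    raising.
    """
    F = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    if F.ndim == 1:
        F = F[None, :]
    peak = F.max(axis=-1)
    idx = F.argmax(axis=-1)
    prefs = config.prefs
    slant_hat = prefs[idx]
    valid = peak > 0
    mass = F.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = np.where(valid, (F * prefs).sum(axis=-1) / mass, np.nan)
    # bimodality: >= 2 disconnected runs of F >= bimodal_ratio * peak
    thresh = F >= (config.bimodal_ratio * peak[:, None])
    starts = thresh & ~np.concatenate(
        [np.zeros((F.shape[0], 1), bool), thresh[:, :-1]], axis=1)
    n_modes = starts.sum(axis=1)
    bimodal = valid & (n_modes >= 2)
    edge = valid & ((idx < config.edge_margin)
                    | (idx >= config.n_units - config.edge_margin))
    return slant_hat, centroid, peak, bimodal, edge, valid


def decode(raw_output: np.ndarray, config: ModelConfig) -> SlantEstimate:
    """Rectify a raw output profile and extract the slant estimate.

    Negative activity is thresholded to zero; the peak position is the slant
    estimate and the peak height the reliability proxy. Raises
    :class:`DegenerateEstimateError` when the rectified profile is all zero.
    """
    raw_output = np.asarray(raw_output, dtype=float)
    if raw_output.shape != (config.n_units,):
        raise ValueError("raw output must have length n_units")
    slant_hat, centroid, peak, bimodal, edge, valid = _decode_batch(
        raw_output, config)
    if not valid[0]:
        raise DegenerateEstimateError("rectified output is all zero: no peak")
    return SlantEstimate(F=np.clip(raw_output, 0.0, None),
                         slant_hat=float(slant_hat[0]),
                         slant_centroid=float(centroid[0]),
                         peak_height=float(peak[0]),
                         bimodal=bool(bimodal[0]),
                         edge_flag=bool(edge[0]))


@dataclass(frozen=True)
class ConditionSummary:
    """Trial-averaged decode of one stimulus condition with single-cue baselines.

    ``sensitivity_*`` is the inverse standard deviation of the decoded
    (centroid) estimate across Poisson trials, in 1/rad — the reciprocal of
    the estimator's dispersion, which is what 2IFC discrimination measures.
    ``peak_*`` is the mean rectified peak height, the secondary reliability
    proxy. Relative quantities are expressed against the more reliable
    single cue (reliability) and the disparity single cue (sensitivity).
    Bias is signed positive toward the less reliable cue, in radians.
    """

    sensitivity_combined: float
    sensitivity_single_delta: float
    sensitivity_single_chi: float
    peak_combined: float
    peak_single_delta: float
    peak_single_chi: float
    estimate_mean: float        # mean centroid estimate, radians
    slant_hat_mean: float       # mean peak-position estimate, radians
    bias: float
    rel_reliability: float
    rel_sensitivity: float
    weight_reliable: float
    reliable_cue: str           # "delta" or "chi"
    bimodal_frac: float
    edge_frac: float
    n_valid: int


def _variant_stats(stimulus: SlantStimulus, config: ModelConfig,
                   rng: Optional[np.random.Generator], noise_free: bool,
                   extra_delta: Optional[np.ndarray] = None,
                   extra_chi: Optional[np.ndarray] = None):
    """Decode statistics for one stimulus variant.

    Returns (mean centroid, centroid SD, mean slant_hat, mean peak,
    bimodal fraction, edge fraction, n_valid). ``extra_*`` rate vectors model
    latent residual cues added to a bank. An absent stimulus (all-zero rates)
    yields zeros/NaNs rather than an error.
    """
    r_d = unimodal_response(stimulus.slant_delta, stimulus.A_delta, config, "disparity")
    r_x = unimodal_response(stimulus.slant_chi, stimulus.A_chi, config, "texture")
    if extra_delta is not None:
        r_d = r_d + extra_delta
    if extra_chi is not None:
        r_x = r_x + extra_chi
    if not np.any(r_d) and not np.any(r_x):
        return np.nan, np.nan, np.nan, 0.0, 0.0, 0.0, 0
    weights = build_readout(config)
    if noise_free:
        fd, fx = r_d[None, :], r_x[None, :]
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        fd = sample_poisson(r_d, config.n_trials, rng).astype(float)
        fx = sample_poisson(r_x, config.n_trials, rng).astype(float)
    F = readout(combine(fd, fx), weights, config)
    slant_hat, centroid, peak, bimodal, edge, valid = _decode_batch(F, config)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateEstimateError(
            "all trials decoded to an empty (all-zero) profile")
    cen = centroid[valid]
    sd = float(cen.std()) if n_valid > 1 else np.nan
    return (float(cen.mean()), sd, float(slant_hat[valid].mean()),
            float(peak[valid].mean()), float(bimodal[valid].mean()),
            float(edge[valid].mean()), n_valid)


def _sensitivity(sd: float) -> float:
    """Inverse estimator dispersion (1/rad); 0 for an absent cue (NaN SD)."""
    if not np.isfinite(sd) or sd <= 0:
        return 0.0
    return 1.0 / sd


def simulate_condition(stimulus: SlantStimulus, config: ModelConfig,
                       rng: Optional[np.random.Generator] = None,
                       noise_free: bool = False,
                       latent_delta: Optional[np.ndarray] = None,
                       latent_chi: Optional[np.ndarray] = None) -> ConditionSummary:
    """Simulate one condition plus its single-cue baselines and summarize.

    Single-cue baselines are obtained by setting one cue intensity to zero.
    The more reliable cue is the single cue with the higher sensitivity
    (texture wins ties, matching the texture-more-reliable experimental
    design). ``latent_delta`` / ``latent_chi`` are optional rate vectors
    added to the respective bank in every variant that retains that bank's
    stimulus (used for latent-cue simulations). In ``noise_free`` mode
    sensitivities are undefined (single exact trial) and reported as NaN;
    bias/weight remain meaningful.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, sd_c, mu_hat, peak_c, bi, ed, n_valid = _variant_stats(
        stimulus, config, rng, noise_free, latent_delta, latent_chi)
    single_d = dataclasses.replace(stimulus, A_chi=0.0)
    single_x = dataclasses.replace(stimulus, A_delta=0.0)
    _, sd_d, _, peak_d, _, _, _ = _variant_stats(
        single_d, config, rng, noise_free, extra_delta=latent_delta)
    _, sd_x, _, peak_x, _, _, _ = _variant_stats(
        single_x, config, rng, noise_free, extra_chi=latent_chi)
    if noise_free:
        s_c = s_d = s_x = np.nan
        rel_rel = rel_sens = np.nan
        chi_reliable = peak_x >= peak_d
    else:
        s_c, s_d, s_x = _sensitivity(sd_c), _sensitivity(sd_d), _sensitivity(sd_x)
        chi_reliable = s_x >= s_d
        s_reliable = s_x if chi_reliable else s_d
        rel_rel = s_c / s_reliable if s_reliable > 0 else np.nan
        rel_sens = s_c / s_d if s_d > 0 else np.nan
    if chi_reliable:
        reliable, s_rel, s_unrel = "chi", stimulus.slant_chi, stimulus.slant_delta
    else:
        reliable, s_rel, s_unrel = "delta", stimulus.slant_delta, stimulus.slant_chi
    bias = (mu - s_rel) * (float(np.sign(s_unrel - s_rel)) or 1.0)
    if s_rel == s_unrel:
        weight = 1.0
    else:
        weight = float(np.clip(1.0 - abs(mu - s_rel) / abs(s_rel - s_unrel), 0.0, 1.0))
    return ConditionSummary(
        sensitivity_combined=s_c,
        sensitivity_single_delta=s_d,
        sensitivity_single_chi=s_x,
        peak_combined=peak_c,
        peak_single_delta=peak_d if np.isfinite(peak_d) else 0.0,
        peak_single_chi=peak_x if np.isfinite(peak_x) else 0.0,
        estimate_mean=mu,
        slant_hat_mean=mu_hat,
        bias=float(bias),
        rel_reliability=rel_rel,
        rel_sensitivity=rel_sens,
        weight_reliable=weight,
        reliable_cue=reliable,
        bimodal_frac=bi,
        edge_frac=ed,
        n_valid=n_valid,
    )
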