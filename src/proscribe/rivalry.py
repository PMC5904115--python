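"""Rivalry dynamics on the model's output layer.

When two conflicting cues are equally reliable the static readout is
bimodal and there is no principled winner. Adding mutual inhibition,
slow adaptation and noise to the output units turns the bimodal likelihood
into alternating dominance — perceptual rivalry:

    tau   dX_i/dt = F_i - (1 + A_i) X_i + W(0, sigma)
                    - gamma * sum_j S[X_j] K(theta_j, theta_i)
    tau_A dA_i/dt = -A_i + alpha S[X_i]

with S a Naka–Rushton sigmoid and K a half-wave-rectified cosine on the
doubled angle difference, K = [-cos(2(theta_j - theta_i))]_+ : inhibition is
maximal between maximally different slants and zero between similar ones.
The drive F is the rectified static readout, normalized to peak 1.
Integration is Euler–Maruyama.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model import (
    ModelConfig,
    SlantStimulus,
    build_readout,
    combine,
    readout,
    unimodal_response,
    _decode_batch,
)

__all__ = [
    "RivalryParams",
    "RivalryTrajectory",
    "drive_from_stimulus",
    "rivalry_step",
    "simulate_rivalry",
    "dominance_durations",
    "count_switches",
    "bistability_index",
    "bistability_conflict_sweep",
]


@dataclass(frozen=True)
class RivalryParams:
    """Dynamical parameters (times in units of the activity constant tau)."""

    tau: float = 1.0
    tau_A: float = 125.0
    gamma: float = 7.0           # mutual-inhibition strength
    alpha: float = 7.0           # adaptation strength
    sigma_noise: float = 0.005
    dt: float = 0.05
    T: float = 6250.0            # 50 * tau_A by default
    naka_n: float = 2.0
    naka_c50: float = 0.5        # as a fraction of the drive peak
    drive_gain: float = 8.0      # drive peak in activity units; sets the
                                 # drive : inhibition balance (gamma is fixed)
    threshold_ratio: float = 1.5  # dominance criterion
    min_episode: float = 1.0     # debounce, in units of tau
    record_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_A <= 0:
            raise ValueError("time constants must be positive")
        if self.dt >= self.tau / 10:
            raise ValueError("dt must be < tau/10 for a stable integration")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


@dataclass
class RivalryTrajectory:
    t: np.ndarray                # recorded time grid
    X: np.ndarray                # time x n_units output activity
    A: np.ndarray                # time x n_units adaptation
    prefs: np.ndarray            # radians
    percept_units: Sequence[np.ndarray]   # unit indices per percept (1 or 2 groups)
    percept_slants: np.ndarray   # slant (radians) per percept
    dominance: np.ndarray        # per-time labels: 0/1 percept index, -1 mixed
    params: RivalryParams


def _naka(x: np.ndarray, n: float, c50: float) -> np.ndarray:
    xp = np.clip(x, 0.0, None)
    return xp ** n / (xp ** n + c50 ** n)


def _inhibition_kernel(prefs: np.ndarray) -> np.ndarray:
    d = prefs[None, :] - prefs[:, None]
    return np.clip(-np.cos(2.0 * d), 0.0, None)


def drive_from_stimulus(stimulus: SlantStimulus, config: ModelConfig) -> np.ndarray:
    """Noise-free rectified readout, normalized to peak 1 (constant drive F)."""
    r_d = unimodal_response(stimulus.slant_delta, stimulus.A_delta, config, "disparity")
    r_x = unimodal_response(stimulus.slant_chi, stimulus.A_chi, config, "texture")
    F = readout(combine(r_d[None, :], r_x[None, :]), build_readout(config), config)[0]
    F = np.clip(F, 0.0, None)
    peak = F.max()
    if peak <= 0:
        raise ValueError("stimulus produces an empty drive profile")
    return F / peak


def rivalry_step(X: np.ndarray, A: np.ndarray, F: np.ndarray,
                 params: RivalryParams, rng: np.random.Generator,
                 K: Optional[np.ndarray] = None, prefs: Optional[np.ndarray] = None):
    """One Euler–Maruyama update of (X, A). Returns the new (X, A)."""
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(A))):
        n_bad = int(np.sum(~np.isfinite(X)) + np.sum(~np.isfinite(A)))
        raise FloatingPointError(
            f"non-finite state in {n_bad} entries; reduce dt or sigma_noise")
    if K is None:
        if prefs is None:
            raise ValueError("provide K or prefs")
        K = _inhibition_kernel(prefs)
    S = _naka(X, params.naka_n, params.naka_c50 * params.drive_gain)
    inh = params.gamma * (K @ S)
    drift = (F - (1.0 + A) * X - inh) / params.tau
    noise = params.sigma_noise * np.sqrt(params.dt / params.tau) * rng.standard_normal(X.shape)
    X_new = X + params.dt * drift + noise
    A_new = A + params.dt * (-A + params.alpha * S) / params.tau_A
    return X_new, A_new


def _percept_groups(F: np.ndarray, config: ModelConfig):
    """Split units into percept groups from the drive's modes.

    Uses the bimodality segmentation of the static decode: connected runs of
    F >= bimodal_ratio * peak. Returns (list of index arrays, mode slants).
    """
    peak = F.max()
    above = F >= config.bimodal_ratio * peak
    groups: List[np.ndarray] = []
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return [np.array([int(F.argmax())])], np.array([config.prefs[int(F.argmax())]])
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    slants = []
    for g in splits:
        groups.append(g)
        slants.append(config.prefs[g[np.argmax(F[g])]])
    if len(groups) > 2:           # keep the two tallest modes
        order = np.argsort([F[g].max() for g in groups])[::-1][:2]
        order = sorted(order)
        groups = [groups[i] for i in order]
        slants = [slants[i] for i in order]
    return groups, np.array(slants)


def simulate_rivalry(stimulus: SlantStimulus, config: ModelConfig,
                     params: RivalryParams) -> RivalryTrajectory:
    """Integrate the rivalry dynamics under a constant drive from ``stimulus``.

    Dominance at each recorded time: percept i dominates when its group's
    peak activity exceeds the other's by ``threshold_ratio``; otherwise the
    label is mixed (-1). With a unimodal drive there is a single percept and
    the label is constantly 0.
    """
    F = params.drive_gain * drive_from_stimulus(stimulus, config)
    prefs = config.prefs
    K = _inhibition_kernel(prefs)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x41A]))
    n_steps = int(round(params.T / params.dt))
    rec_idx = np.arange(0, n_steps + 1, params.record_every)
    X = np.zeros_like(F)
    A = np.zeros_like(F)
    Xs = np.empty((rec_idx.size, F.size))
    As = np.empty_like(Xs)
    ts = rec_idx * params.dt
    j = 0
    for step in range(n_steps + 1):
        if j < rec_idx.size and step == rec_idx[j]:
            Xs[j] = X
            As[j] = A
            j += 1
        X, A = rivalry_step(X, A, F, params, rng, K=K)
    groups, slants = _percept_groups(F, config)
    if len(groups) == 1:
        dominance = np.zeros(rec_idx.size, dtype=int)
    else:
        act = np.stack([Xs[:, g].max(axis=1) for g in groups], axis=1)
        act = np.clip(act, 1e-12, None)
        dominance = np.full(rec_idx.size, -1, dtype=int)
        dominance[act[:, 0] >= params.threshold_ratio * act[:, 1]] = 0
        dominance[act[:, 1] >= params.threshold_ratio * act[:, 0]] = 1
    return RivalryTrajectory(t=ts, X=Xs, A=As, prefs=prefs,
                             percept_units=groups, percept_slants=slants,
                             dominance=dominance, params=params)


def _episodes(traj: RivalryTrajectory):
    """Debounced dominance episodes as (percept, t_start, t_end)."""
    min_len = traj.params.min_episode * traj.params.tau
    eps = []
    cur, t0 = None, None
    for t, lab in zip(traj.t, traj.dominance):
        if lab == cur:
            continue
        if cur is not None and cur >= 0 and t - t0 >= min_len:
            eps.append((int(cur), float(t0), float(t)))
        cur, t0 = lab, t
    if cur is not None and cur >= 0 and traj.t[-1] - t0 >= min_len:
        eps.append((int(cur), float(t0), float(traj.t[-1])))
    return eps


def dominance_durations(traj: RivalryTrajectory) -> List[dict]:
    """Dominance episode durations, in units of tau_A.

    Returns a list of {"percept", "duration"} dicts; empty when one percept
    holds throughout (winner-take-all) or no episode passes the debounce.
    """
    eps = _episodes(traj)
    percepts = {p for p, _, _ in eps}
    if len(percepts) < 2:
        return []
    return [{"percept": p, "duration": (t1 - t0) / traj.params.tau_A}
            for p, t0, t1 in eps]


def count_switches(traj: RivalryTrajectory) -> int:
    """Number of transitions between the two percepts' dominance."""
    eps = _episodes(traj)
    seq = [p for p, _, _ in eps]
    return int(sum(1 for a, b in zip(seq, seq[1:]) if a != b))


def bistability_index(traj: RivalryTrajectory) -> float:
    """Difference (degrees) between the two cue-consistent estimates.

    Zero under fusion (unimodal drive, single percept); otherwise the
    angular separation of the two percepts' slants.
    """
    if len(traj.percept_slants) < 2:
        return 0.0
    return float(np.rad2deg(abs(traj.percept_slants[1] - traj.percept_slants[0])))


def bistability_conflict_sweep(conflicts_deg: Sequence[float],
                               config: ModelConfig,
                               A_delta: float = 1.0, A_chi: float = 1.0,
                               center_deg: float = 0.0) -> np.ndarray:
    """Static bistability index per conflict, from the drive's modality.

    For each conflict the two cue slants straddle ``center_deg``; the index
    is 0 when the rectified readout is unimodal (fusion) and the mode
    separation in degrees when it is bimodal.
    """
    out = []
    for conf in conflicts_deg:
        stim = SlantStimulus.from_degrees(center_deg - conf / 2.0,
                                          center_deg + conf / 2.0,
                                          A_delta, A_chi)
        F = drive_from_stimulus(stim, config)
        groups, slants = _percept_groups(F, config)
        out.append(0.0 if len(slants) < 2 else float(np.rad2deg(abs(slants[1] - slants[0]))))
    return np.asarray(out)
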