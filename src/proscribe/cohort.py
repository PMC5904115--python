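"""Synthetic observer cohorts for end-to-end pipeline recovery tests.

Each observer carries a latent suppressive-gain trait beta_true (the GABA
analogue); a noisy linear transform of it plays the role of a measured
neurochemical concentration. The observer's discrimination behaviour is
generated by running the population model at their beta, converting each
condition's model sensitivity to a behavioural internal SD, and simulating
2IFC trials through the standard observer model. Fitting the resulting
psychometric functions and correlating recovered sensitivity against the
measured trait exercises the whole analysis pipeline with a known ground
truth: the generative link runs through the incongruent condition only, so
recovery should show a trait–incongruent correlation and no comparable
trait–congruent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .model import ModelConfig, SlantStimulus
from .perturbation import _condition_stats, _default_conditions
from .psychophys import fit_psychometric, robust_pearson, simulate_2ifc

__all__ = ["Cohort", "generate_cohort", "export_cohort", "load_cohort",
           "analyze_cohort"]

# behavioural calibration: map model congruent sensitivity to a human-scale
# congruent sensitivity of 0.35 (1/deg), so internal SDs land in the range
# the constant-stimulus level grids can resolve
_TARGET_CONGRUENT_SENSITIVITY = 0.35

# constant-stimulus grids (degrees), per condition type
_LEVELS_COMBINED = np.array([-25.0, -17.8, -10.7, -3.6, 3.6, 10.7, 17.8, 25.0])
_LEVELS_SINGLE = np.array([-20.0, -14.3, -8.5, -2.8, 2.8, 8.5, 14.3, 20.0])


@dataclass
class Cohort:
    traits: pd.DataFrame          # observer_id, beta_true, gaba_like
    trials: pd.DataFrame          # per-trial 2IFC table with observer_id
    config: ModelConfig
    seed: int


def _behavioural_scale(config: ModelConfig, seed: int = 12345) -> float:
    """Factor mapping model sensitivity (1/rad) to behavioural 1/deg."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    _, s_cong, _ = _condition_stats(
        SlantStimulus.from_degrees(40.0, 40.0, 1.0, 1.0), config, rng)
    return _TARGET_CONGRUENT_SENSITIVITY / s_cong


def generate_cohort(n_observers: int = 18, trait_noise_sd: float = 0.05,
                    trials_per_condition: int = 400, seed: int = 0,
                    config: Optional[ModelConfig] = None) -> Cohort:
    """Generate a fully seeded synthetic cohort.

    beta_true ~ N(0.75, 0.1) clipped to [0, 1]; gaba_like = 1 + 2*beta_true
    + N(0, trait_noise_sd) (slope/intercept arbitrary — correlations are
    scale-free). Conditions are the standard sweep set (singles, congruent,
    incongruent). ``trials_per_condition`` is split evenly over the 8
    constant-stimulus levels.
    """
    if n_observers < 4:
        raise ValueError("need >= 4 observers")
    config = config or ModelConfig()
    scale = _behavioural_scale(config)
    master = np.random.SeedSequence([seed, 0xC0407])
    n_per_level = max(trials_per_condition // _LEVELS_COMBINED.size, 1)
    trait_rows, trial_frames = [], []
    for i, child in enumerate(master.spawn(n_observers)):
        rng = np.random.default_rng(child)
        beta = float(np.clip(rng.normal(0.75, 0.1), 0.0, 1.0))
        gaba = 1.0 + 2.0 * beta + rng.normal(0.0, trait_noise_sd)
        # the observer's *true* per-condition sensitivity is characterized
        # precisely (many Poisson repeats); sampling noise belongs to the
        # 2IFC stage, not to the observer's latent sensitivity
        cfg = config.replace(beta=beta, n_trials=max(config.n_trials, 500))
        trait_rows.append({"observer_id": f"obs{i:03d}", "beta_true": beta,
                           "gaba_like": gaba})
        for cond, stim in _default_conditions().items():
            _, s_model, _ = _condition_stats(stim, cfg, rng)
            sigma_int = 1.0 / (scale * s_model * np.sqrt(2.0))
            if cond == "incongruent":
                reference = 35.0          # midpoint of the 20/50 pair
                levels = reference + _LEVELS_COMBINED
            elif cond == "congruent":
                reference = 40.0
                levels = reference + _LEVELS_SINGLE
            else:
                reference = np.rad2deg(stim.slant_delta if stim.A_delta > 0
                                       else stim.slant_chi)
                levels = reference + _LEVELS_SINGLE
            block = simulate_2ifc(sigma_int, reference, levels, n_per_level,
                                  seed=int(rng.integers(2 ** 31)),
                                  condition_id=cond)
            block.insert(0, "observer_id", f"obs{i:03d}")
            trial_frames.append(block)
    return Cohort(traits=pd.DataFrame(trait_rows),
                  trials=pd.concat(trial_frames, ignore_index=True),
                  config=config, seed=seed)


def analyze_cohort(cohort: Cohort, seed: int = 0,
                   n_boot: int = 2000) -> Dict[str, dict]:
    """Fit psychometric functions per observer x condition and correlate the
    recovered sensitivities with the gaba-like trait (robust Pearson)."""
    fits = []
    for (obs, cond), block in cohort.trials.groupby(["observer_id", "condition_id"]):
        block = block.assign(test_level=block["test_level"] - block["reference_level"])
        fit = fit_psychometric(block)
        fits.append({"observer_id": obs, "condition_id": cond,
                     "pse": fit.pse, "jnd": fit.jnd,
                     "sensitivity": fit.sensitivity, "lapse": fit.lapse})
    sens = (pd.DataFrame(fits)
            .pivot(index="observer_id", columns="condition_id", values="sensitivity")
            .join(cohort.traits.set_index("observer_id")))
    out = {"fits": pd.DataFrame(fits)}
    for cond in ("incongruent", "congruent", "single_delta", "single_chi"):
        out[cond] = robust_pearson(sens["gaba_like"], sens[cond], seed=seed,
                                   n_boot=n_boot)
    return out


def export_cohort(cohort: Cohort, path) -> Dict[str, Path]:
    """Write traits and trial tables as CSV; round-trips losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traits_path = path / "traits.csv"
    trials_path = path / "trials.csv"
    cohort.traits.to_csv(traits_path, index=False)
    cohort.trials.to_csv(trials_path, index=False)
    return {"traits": traits_path, "trials": trials_path}


def load_cohort(path, config: Optional[ModelConfig] = None,
                seed: int = 0) -> Cohort:
    path = Path(path)
    return Cohort(traits=pd.read_csv(path / "traits.csv"),
                  trials=pd.read_csv(path / "trials.csv"),
                  config=config or ModelConfig(), seed=seed)
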