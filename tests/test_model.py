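"""Unit and property tests of the population-model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proscribe import (
    DegenerateEstimateError,
    ModelConfig,
    SlantStimulus,
    build_readout,
    combine,
    decode,
    readout,
    sample_poisson,
    simulate_condition,
    unimodal_response,
)

HALF_PI = np.pi / 2


# ---------------------------------------------------------------- config/types

def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_units=4)          # even
    with pytest.raises(ValueError):
        ModelConfig(n_units=1)
    with pytest.raises(ValueError):
        ModelConfig(beta=1.5)
    with pytest.raises(ValueError):
        ModelConfig(k=0)
    cfg = ModelConfig()
    assert cfg.prefs.size == cfg.n_units
    assert 0.0 in cfg.prefs             # odd n includes the frontoparallel unit
    # offsets span +-pi/4 in grid steps
    assert np.isclose(cfg.offsets.max(), np.pi / 4)


def test_stimulus_validation():
    with pytest.raises(ValueError):
        SlantStimulus(2.0, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        SlantStimulus(0.0, 0.0, -1.0, 1.0)
    s = SlantStimulus.from_degrees(20, 50, 1, 4)
    assert np.isclose(s.slant_delta, np.deg2rad(20))


# ---------------------------------------------------------------- unimodal

def test_unimodal_zero_intensity_gives_zero_rates(config):
    assert np.all(unimodal_response(0.3, 0.0, config) == 0.0)


def test_unimodal_peaks_at_nearest_preference_and_is_symmetric(config):
    theta = config.prefs[10]
    r = unimodal_response(theta, 1.0, config)
    assert r.argmax() == 10
    # symmetry about the preferred unit (circular in the doubled angle)
    for d in range(1, 5):
        assert np.isclose(r[10 - d], r[10 + d])


@given(st.floats(0.1, 8.0), st.floats(-1.2, 1.2))
@settings(max_examples=30, deadline=None)
def test_unimodal_linear_in_intensity(a, slant):
    cfg = ModelConfig()
    r1 = unimodal_response(slant, a, cfg)
    r2 = unimodal_response(slant, 2 * a, cfg)
    assert np.allclose(r2, 2 * r1, rtol=1e-12)


def test_unimodal_range_errors(config):
    with pytest.raises(ValueError):
        unimodal_response(2.0, 1.0, config)
    with pytest.raises(ValueError):
        unimodal_response(0.0, -0.5, config)


# ---------------------------------------------------------------- poisson

def test_poisson_zero_rate_gives_zero_counts(rng):
    counts = sample_poisson(np.zeros(5), 100, rng)
    assert counts.shape == (100, 5)
    assert np.all(counts == 0)


def test_poisson_moments_match_rate(rng):
    counts = sample_poisson(np.full(3, 10.0), 10000, rng)
    se = np.sqrt(10.0 / 10000)
    assert np.all(np.abs(counts.mean(axis=0) - 10.0) < 3 * se)
    ratio = counts.var(axis=0) / counts.mean(axis=0)
    assert np.all((ratio > 0.9) & (ratio < 1.1))


def test_poisson_deterministic_under_seed():
    a = sample_poisson(np.array([3.0, 7.0]), 50, 42)
    b = sample_poisson(np.array([3.0, 7.0]), 50, 42)
    assert np.array_equal(a, b)


def test_poisson_rejects_negative_rates(rng):
    with pytest.raises(ValueError):
        sample_poisson(np.array([-1.0]), 10, rng)


# ---------------------------------------------------------------- combination

def test_combine_is_sqrt_of_sum():
    E = combine(np.full(3, 4.0), np.full(3, 5.0))
    assert np.allclose(E, 3.0)
    assert np.all(combine(np.zeros(3), np.zeros(3)) == 0.0)


@given(st.lists(st.floats(0, 50), min_size=4, max_size=4),
       st.lists(st.floats(0, 50), min_size=4, max_size=4))
@settings(max_examples=30, deadline=None)
def test_combine_sublinear_sqrt2_scaling(fd, fx):
    fd, fx = np.array(fd), np.array(fx)
    assert np.allclose(combine(2 * fd, 2 * fx), np.sqrt(2) * combine(fd, fx))


def test_combine_rejects_negative():
    with pytest.raises(ValueError):
        combine(np.array([-1.0]), np.array([1.0]))


# ---------------------------------------------------------------- readout

def test_readout_weights_key_values():
    cfg = ModelConfig()
    w = build_readout(cfg)
    mid = w.size // 2
    assert np.isclose(w[mid], 1.0 - cfg.c)                # cos(0) - c = 0.95
    assert np.isclose(w[0], -1.0 - cfg.c)                 # cos(pi) - c = -1.05
    w_att = build_readout(cfg.replace(beta=0.5))
    assert np.isclose(w_att[0], 0.5 * (-1.0 - cfg.c))     # -0.525
    # with c=0 the weight vanishes where cos(4j) = 0 (j = pi/8)
    cfg0 = ModelConfig(c=0.0)
    j = cfg0.offsets
    idx = np.argmin(np.abs(j - np.pi / 8))
    if np.isclose(j[idx], np.pi / 8):
        assert abs(build_readout(cfg0)[idx]) < 1e-12


def test_readout_delta_grid_peaks_at_source(toy_config):
    cfg = toy_config.replace(c=0.0)
    grid = np.zeros((5, 5))
    grid[2, 2] = 1.0                                       # congruent cell at center
    F = readout(grid, build_readout(cfg), cfg)
    assert F.argmax() == 2


def _brute_force_readout(grid, cfg):
    """Direct transcription of the diagonal summation with circular indexing."""
    n = cfg.n_units
    per = n - 1
    w = build_readout(cfg)
    m_max = (w.size - 1) // 2
    F = np.zeros(n)
    for i in range(n):
        for m_idx, m in enumerate(range(-m_max, m_max + 1)):
            F[i] += w[m_idx] * grid[(i - m) % per, (i + m) % per]
    return F


def test_readout_matches_brute_force_oracle(toy_config, rng):
    grid = rng.random((5, 5)) * 10
    expected = _brute_force_readout(grid, toy_config)
    assert np.allclose(readout(grid, build_readout(toy_config), toy_config),
                       expected)


def test_readout_matches_brute_force_full_size(config, rng):
    grid = rng.random((config.n_units, config.n_units)) * 5
    expected = _brute_force_readout(grid, config)
    assert np.allclose(readout(grid, build_readout(config), config), expected)


def test_readout_shape_errors(config):
    with pytest.raises(ValueError):
        readout(np.zeros((4, 4)), build_readout(config), config)


def test_output_profile_mirror_symmetry(config):
    """Mirror-reflecting both cue slants about 0 mirrors the noise-free output."""
    w = build_readout(config)
    for s_d, s_x in [(np.deg2rad(10), np.deg2rad(35)),
                     (np.deg2rad(-5), np.deg2rad(20))]:
        f1 = readout(combine(unimodal_response(s_d, 1.0, config),
                             unimodal_response(s_x, 4.0, config)), w, config)
        f2 = readout(combine(unimodal_response(-s_d, 1.0, config),
                             unimodal_response(-s_x, 4.0, config)), w, config)
        # mirroring the stimulus reverses the output profile
        assert np.allclose(f1, f2[::-1], atol=1e-9)


# ---------------------------------------------------------------- decode

def test_decode_rectifies_and_finds_peak(config):
    raw = np.full(config.n_units, -1.0)
    raw[1] = 2.0
    est = decode(raw, config)
    assert np.all(est.F >= 0)
    assert est.peak_height == 2.0
    assert est.slant_hat == config.prefs[1]
    assert est.edge_flag        # index 1 is within the 2-point edge margin


def test_decode_all_negative_is_degenerate(config):
    with pytest.raises(DegenerateEstimateError):
        decode(np.full(config.n_units, -0.5), config)


def test_decode_bimodal_flag_for_equal_conflicting_cues(config):
    """Two equally reliable conflicting cues produce a bimodal output."""
    r_d = unimodal_response(np.deg2rad(-30), 1.0, config)
    r_x = unimodal_response(np.deg2rad(30), 1.0, config)
    F = readout(combine(r_d, r_x), build_readout(config), config)
    est = decode(F, config)
    assert est.bimodal
    # single cue: unimodal
    F1 = readout(combine(r_d, np.zeros_like(r_d)), build_readout(config), config)
    assert not decode(F1, config).bimodal


# ---------------------------------------------------------------- condition level

def test_congruent_condition_unbiased_and_fused(config):
    r = simulate_condition(SlantStimulus.from_degrees(40, 40, 1, 1), config,
                           rng=np.random.default_rng(5))
    assert abs(np.rad2deg(r.bias)) < 1.0
    assert r.weight_reliable == 1.0
    # peak-height reliability gain is the sqrt(2) fusion benefit
    assert np.isclose(r.peak_combined / r.peak_single_chi, np.sqrt(2), rtol=0.03)


def test_single_cue_ratio_tracks_sqrt_intensity(config):
    cfg = config.replace(n_trials=800)
    r = simulate_condition(SlantStimulus.from_degrees(0, 0, 1, 8), cfg,
                           rng=np.random.default_rng(6))
    ratio = r.sensitivity_single_chi / r.sensitivity_single_delta
    assert 2.2 < ratio < 3.5            # ~sqrt(8)


def test_robust_reversion_with_conflict(config):
    """At a fixed 1:2 reliability ratio the bias returns toward the reliable
    cue as conflict grows."""
    cfg = config.replace(n_trials=400)
    biases = {}
    for conf in (25, 50):
        stim = SlantStimulus.from_degrees(-conf / 2, conf / 2, 1, 4)
        r = simulate_condition(stim, cfg, rng=np.random.default_rng(conf))
        biases[conf] = abs(np.rad2deg(r.bias))
    assert biases[50] < biases[25]


def test_noise_free_mode_is_deterministic(config, incongruent_stimulus):
    a = simulate_condition(incongruent_stimulus, config, noise_free=True)
    b = simulate_condition(incongruent_stimulus, config, noise_free=True)
    assert a.estimate_mean == b.estimate_mean
    assert np.isnan(a.sensitivity_combined)   # no trial variance without noise
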