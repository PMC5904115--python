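"""Psychometric fitting, 2IFC simulation and reanalysis-statistics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proscribe import (
    DegenerateFitError,
    bayes_factor_from_t,
    cap_quadratic,
    fit_psychometric,
    robust_pearson,
    screen_outliers_log3sd,
    simulate_2ifc,
    tissue_correct,
)

LEVELS = np.array([-20.0, -14.3, -8.5, -2.8, 2.8, 8.5, 14.3, 20.0])


# ---------------------------------------------------------------- fitting

@pytest.mark.parametrize("pse,sd", [(40.0, 5.0), (35.0, 8.0), (42.0, 3.0)])
def test_psychometric_parameter_recovery(pse, sd):
    """A fit of data generated by the 2IFC simulator recovers the generating
    PSE and j.n.d. (sigma of the psychometric function = internal SD * sqrt2)."""
    sigma_int = sd / np.sqrt(2.0)        # so the fitted slope sigma equals sd
    table = simulate_2ifc(sigma_int, pse, pse + LEVELS, 250, seed=17)
    fit = fit_psychometric(table.assign(test_level=table["test_level"]))
    assert abs(fit.pse - pse) < 0.5
    assert abs(fit.jnd - sd) < max(0.5, 0.1 * sd)
    assert np.isclose(fit.sensitivity, 1.0 / fit.jnd)


def test_flat_data_raises_degenerate():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({"test_level": np.repeat(LEVELS, 40),
                          "response": rng.integers(0, 2, LEVELS.size * 40)})
    with pytest.raises(DegenerateFitError):
        fit_psychometric(table)


def test_step_function_data_flagged_at_lower_bound():
    table = pd.DataFrame({"test_level": np.repeat(LEVELS, 30)})
    table["response"] = (table["test_level"] > 0).astype(int)
    fit = fit_psychometric(table)
    assert fit.at_lower_bound


def test_fit_preconditions():
    small = pd.DataFrame({"test_level": [0, 1, 2, 3], "response": [0, 0, 1, 1]})
    with pytest.raises(ValueError):
        fit_psychometric(small)          # < 10 trials
    few_levels = pd.DataFrame({"test_level": [0, 0, 1, 1, 2] * 3,
                               "response": [0, 0, 1, 1, 1] * 3})
    with pytest.raises(ValueError):
        fit_psychometric(few_levels)     # < 4 distinct levels


# ---------------------------------------------------------------- 2IFC

def test_2ifc_chance_at_reference():
    table = simulate_2ifc(5.0, 40.0, 40.0 + LEVELS, 4000, seed=3)
    at_ref = table[np.isclose(table["test_level"], 37.2)]  # nearest level pair
    # exact chance only at test == reference; check the closest symmetric pair
    p_low = table[table["test_level"] == 40.0 - 2.8]["response"].mean()
    p_high = table[table["test_level"] == 40.0 + 2.8]["response"].mean()
    assert np.isclose(p_low + p_high, 1.0, atol=0.05)


def test_2ifc_sqrt2_conversion_emerges():
    """Fitting simulated data from a Gaussian observer with internal SD sigma
    yields sensitivity ~ 1/(sigma*sqrt(2)): the conversion constant comes out
    of the two-interval task structure."""
    sigma = 4.0
    table = simulate_2ifc(sigma, 0.0, LEVELS, 400, seed=5)
    fit = fit_psychometric(table)
    assert np.isclose(fit.sensitivity, 1.0 / (sigma * np.sqrt(2)), rtol=0.1)


def test_2ifc_deterministic_and_brackets():
    a = simulate_2ifc(5.0, 0.0, LEVELS, 10, seed=9)
    b = simulate_2ifc(5.0, 0.0, LEVELS, 10, seed=9)
    assert a.equals(b)
    with pytest.raises(ValueError):
        simulate_2ifc(5.0, 100.0, LEVELS, 10, seed=9)


# ---------------------------------------------------------------- Bayes factor

def test_bayes_factor_direction_and_monotonicity():
    assert bayes_factor_from_t(0.0, 20) < 1.0
    bfs = [bayes_factor_from_t(t, 20) for t in (0.5, 1.5, 3.0, 5.0)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
    with pytest.raises(ValueError):
        bayes_factor_from_t(1.0, 2)


def test_bayes_factor_matches_independent_implementation():
    """Cross-check the quadrature against pingouin's JZS implementation."""
    pingouin = pytest.importorskip("pingouin")
    for t, n in [(2.0, 12), (3.0, 20), (0.5, 50), (4.5, 9)]:
        ours = bayes_factor_from_t(t, n)
        theirs = float(pingouin.bayesfactor_ttest(t, n))
        assert np.isclose(ours, theirs, rtol=1e-3)


# ---------------------------------------------------------------- reanalysis

def test_cap_quadratic_examples():
    singles = np.array([1.0, 1.0, 1.0])
    combined = np.array([1.6, 1.2, np.sqrt(2)])
    capped = cap_quadratic(combined, singles, singles)
    assert np.isclose(capped[0], np.sqrt(2))
    assert capped[1] == 1.2
    assert np.isclose(capped[2], np.sqrt(2))
    # idempotent
    assert np.allclose(cap_quadratic(capped, singles, singles), capped)
    with pytest.raises(ValueError):
        cap_quadratic(np.array([-1.0]), np.array([1.0]), np.array([1.0]))


def test_screen_outliers_log3sd():
    same = np.full(10, 2.5)
    kept, removed = screen_outliers_log3sd(same)
    assert removed.size == 0
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.lognormal(0, 0.1, 29), [1e6]])
    kept, removed = screen_outliers_log3sd(vals)
    # direct z-score oracle in log space
    logv = np.log(vals)
    z = (logv - logv.mean()) / logv.std(ddof=1)
    assert set(removed) == set(np.flatnonzero(np.abs(z) > 3))
    assert 29 in removed
    # screening the kept values again removes nothing further
    kept2, removed2 = screen_outliers_log3sd(kept)
    assert removed2.size == 0
    with pytest.warns(UserWarning):
        screen_outliers_log3sd(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        screen_outliers_log3sd(np.array([1.0, -2.0, 3.0]))


def test_robust_pearson_collinear_and_outlier():
    x = np.linspace(0, 1, 12)
    res = robust_pearson(x, 2 * x + 1)
    assert np.isclose(res["r"], 1.0)
    assert res["outlier_indices"].size == 0
    # one gross off-line point gets rejected by the IQR rule
    y = 2 * x + 1
    y2 = y.copy()
    y2[5] = 50.0
    res2 = robust_pearson(x, y2, seed=1)
    assert 5 in res2["outlier_indices"]
    assert res2["r"] > 0.999
    assert res2["ci"][0] <= res2["r"] <= res2["ci"][1]
    with pytest.raises(ValueError):
        robust_pearson(np.ones(10), np.arange(10))


def test_tissue_correct():
    assert tissue_correct(1.0, 0.5, 0.5) == 1.0
    assert np.isclose(tissue_correct(1.0, 0.4, 0.4), 1.25)
    assert tissue_correct(2.0, 0.3, 0.3) >= 2.0
    with pytest.raises(ValueError):
        tissue_correct(1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        tissue_correct(1.0, 0.7, 0.7)


@given(st.floats(0.5, 20.0))
@settings(max_examples=20, deadline=None)
def test_sensitivity_is_reciprocal_jnd_property(sd):
    table = simulate_2ifc(sd / np.sqrt(2), 0.0, LEVELS * max(1.0, sd / 5), 60,
                          seed=7)
    try:
        fit = fit_psychometric(table)
    except DegenerateFitError:
        return
    assert np.isclose(fit.sensitivity * fit.jnd, 1.0, rtol=1e-12)
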