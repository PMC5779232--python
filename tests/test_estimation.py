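"""dIF curves, parameter/function/noise estimation, circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

import gammasync as gs
from gammasync._utils import TWO_PI
from gammasync.estimation import DEFAULT_BIN_WIDTH, _resolve_bins


def _curve_from_function(fn):
    """Noise-free DeltaIFCurve whose bin means follow fn(theta)."""
    edges = _resolve_bins(DEFAULT_BIN_WIDTH)
    centers = edges[:-1] + np.diff(edges) / 2
    vals = fn(centers)
    n = centers.size
    return gs.DeltaIFCurve(
        bin_centers=centers, mean_dif=vals, se=np.full(n, 1e-6),
        counts=np.full(n, 1000), n_total=1000 * n, fs=1000.0,
        flagged=np.zeros(n, dtype=bool))


def test_pooled_sample_count_is_trials_times_samples():
    # 33 trials x 1800 samples pool into 59,400 dIF observations
    rng = np.random.default_rng(0)
    p1 = rng.standard_normal((33, 1800)).cumsum(axis=1) * 0.01
    p2 = rng.standard_normal((33, 1800)).cumsum(axis=1) * 0.01
    curve = gs.delta_if_curve(p1, p2, fs=1000.0)
    assert curve.n_total == 59400
    assert curve.counts.sum() == 59400
    assert curve.n_bins == 25  # "0.25 rad nominal" -> 25 bins of 2*pi/25


def test_identical_phases_give_flat_zero_curve():
    rng = np.random.default_rng(1)
    ph = rng.uniform(-np.pi, np.pi, (5, 500)).cumsum(axis=1) * 0.01
    curve = gs.delta_if_curve(ph, ph, fs=1000.0)
    assert np.allclose(curve.mean_dif[curve.counts > 0], 0.0, atol=1e-9)


def test_binned_curve_matches_deterministic_term():
    """Simulated pair, detuning 4.8 Hz / coupling 1.8 Hz / noise 18 Hz:
    the binned curve reproduces 4.8 - 1.8*sin(theta) within 2 SE per bin."""
    pair = gs.simulate_oscillator_pair(36.4, 31.6, 1.8, sigma_each=18.0,
                                       n_trials=200, seed=42)
    curve = gs.delta_if_curve(pair.phi1, pair.phi2, 1000.0)
    expect = 4.8 - 1.8 * np.sin(curve.bin_centers)
    assert np.all(np.abs(curve.mean_dif - expect) <= 2.0 * curve.se)


def test_estimate_pair_params_on_exact_sinusoidal_curve():
    curve = _curve_from_function(lambda th: 4.8 - 1.8 * np.sin(th))
    est = gs.estimate_pair_params(curve, epsilon_estimator="sine")
    assert est.delta_omega_hat == pytest.approx(4.8, abs=1e-12)
    assert est.epsilon_hat == pytest.approx(1.8, abs=1e-12)
    # (max-min)/2 default on binned values: exact up to the bin grid
    est_r = gs.estimate_pair_params(curve)
    assert est_r.epsilon_hat == pytest.approx(1.8, rel=0.01)
    # worked-example check: the curve minimum is detuning - coupling
    assert est.delta_omega_hat - est.epsilon_hat == pytest.approx(3.0)


def test_flat_curve_estimates_zero():
    curve = _curve_from_function(lambda th: np.zeros_like(th))
    est = gs.estimate_pair_params(curve)
    assert est.delta_omega_hat == 0.0
    assert est.epsilon_hat == 0.0


def test_curve_minimum_equals_detuning_minus_coupling():
    curve = _curve_from_function(lambda th: 5.0 - 1.0 * np.sin(th))
    est = gs.estimate_pair_params(curve, epsilon_estimator="sine")
    assert est.delta_omega_hat - est.epsilon_hat == pytest.approx(4.0, abs=1e-9)


def test_estimate_pair_params_needs_enough_bins():
    curve = _curve_from_function(lambda th: 1.0 - np.sin(th))
    curve.flagged[:] = True
    curve.flagged[:5] = False
    with pytest.raises(ValueError):
        gs.estimate_pair_params(curve)


def test_low_confidence_diagnostic_when_many_bins_flagged():
    curve = _curve_from_function(lambda th: 1.0 - np.sin(th))
    curve.flagged[:10] = True
    est = gs.estimate_pair_params(curve)
    assert est.diagnostics["low_confidence"]


def test_interaction_function_identity_from_single_curve():
    # a + b*(-sin): normalization recovers -sin itself
    curve = _curve_from_function(lambda th: 4.5 + 1.3 * (-np.sin(th)))
    g = gs.estimate_interaction_function([curve])
    th = np.linspace(-np.pi, np.pi, 400, endpoint=False)
    r = np.corrcoef(g(th), -np.sin(th))[0, 1]
    assert r > 0.999


def test_interaction_function_pools_and_flips_negative_detuning():
    c_pos = _curve_from_function(lambda th: 5.0 - 1.5 * np.sin(th))
    c_neg = _curve_from_function(lambda th: -5.0 - 1.5 * np.sin(th))
    g = gs.estimate_interaction_function([c_pos, c_neg])
    th = np.linspace(-np.pi, np.pi, 400, endpoint=False)
    assert np.corrcoef(g(th), -np.sin(th))[0, 1] > 0.999


def test_interaction_function_respects_detuning_threshold():
    good = _curve_from_function(lambda th: 5.0 - 1.5 * np.sin(th))
    # a deformed low-detuning curve that would corrupt the pool
    bad = _curve_from_function(lambda th: 1.0 + 1.5 * np.sign(np.sin(th)))
    g_with = gs.estimate_interaction_function([good, bad])
    g_alone = gs.estimate_interaction_function([good])
    th = np.linspace(-np.pi, np.pi, 200, endpoint=False)
    assert np.allclose(g_with(th), g_alone(th))
    with pytest.raises(ValueError, match="impossible"):
        gs.estimate_interaction_function([bad])


def test_interaction_function_recovered_from_simulations():
    curves = []
    for k, dw in enumerate([5.0, 6.0, -5.0, -6.0]):
        pair = gs.simulate_oscillator_pair(34 + dw / 2, 34 - dw / 2, 1.5,
                                           sigma_each=18.0, n_trials=60,
                                           seed=100 + k)
        curves.append(gs.delta_if_curve(pair.phi1, pair.phi2, 1000.0))
    g = gs.estimate_interaction_function(curves)
    th = np.linspace(-np.pi, np.pi, 300, endpoint=False)
    assert np.corrcoef(g(th), -np.sin(th))[0, 1] >= 0.95


def test_sigma_recovery_from_simulated_pair():
    pair = gs.simulate_oscillator_pair(36.4, 31.6, 1.8, sigma_each=18.0,
                                       n_trials=100, seed=5)
    traces = [np.diff(pair.phi1, axis=-1) * 1000 / TWO_PI,
              np.diff(pair.phi2, axis=-1) * 1000 / TWO_PI]
    for method in ("diffusion", "sample"):
        assert gs.estimate_sigma(traces, 1000.0, method=method) == pytest.approx(18.0, abs=1.0)


def test_sigma_of_noiseless_tone_is_zero():
    t = np.arange(0, 1.8, 1e-3)
    if_trace = np.full((3, t.size), 34.0)
    assert gs.estimate_sigma([if_trace], 1000.0) == pytest.approx(0.0, abs=1e-9)
    assert gs.estimate_sigma([if_trace], 1000.0, method="sample") == pytest.approx(0.0, abs=1e-12)


def test_phase_diff_stats_degenerate_and_uniform():
    st_ = gs.phase_diff_stats(np.full(500, 1.3))
    assert st_.plv == pytest.approx(1.0)
    assert st_.mean_phase == pytest.approx(1.3)
    rng = np.random.default_rng(7)
    u = rng.uniform(-np.pi, np.pi, 10_000)
    assert gs.phase_diff_stats(u).plv <= 0.05


def test_phase_diff_stats_von_mises_bessel_ratio():
    rng = np.random.default_rng(8)
    x = rng.vonmises(0.4, 1.0, 100_000)
    st_ = gs.phase_diff_stats(x)
    assert st_.plv == pytest.approx(i1(1.0) / i0(1.0), abs=0.01)
    assert st_.mean_phase == pytest.approx(0.4, abs=0.02)


def test_phase_diff_stats_rejects_empty():
    with pytest.raises(ValueError):
        gs.phase_diff_stats([])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(offset=st.floats(-3.0, 3.0), seed=st.integers(0, 1000))
def test_plv_invariant_under_rotation(offset, seed):
    rng = np.random.default_rng(seed)
    x = rng.vonmises(0.0, 2.0, 2000)
    a = gs.phase_diff_stats(x)
    b = gs.phase_diff_stats(x + offset)
    assert b.plv == pytest.approx(a.plv, abs=1e-9)
    dphi = np.angle(np.exp(1j * (b.mean_phase - a.mean_phase - offset)))
    assert dphi == pytest.approx(0.0, abs=1e-9)


def test_pair_order_antisymmetry():
    """Swapping the pair negates detuning and mean phase; PLV and epsilon
    estimates are unchanged."""
    pair = gs.simulate_oscillator_pair(35.5, 32.5, 1.5, sigma_each=18.0,
                                       n_trials=40, seed=11)
    c_ab = gs.delta_if_curve(pair.phi1, pair.phi2, 1000.0)
    c_ba = gs.delta_if_curve(pair.phi2, pair.phi1, 1000.0)
    e_ab = gs.estimate_pair_params(c_ab, epsilon_estimator="sine")
    e_ba = gs.estimate_pair_params(c_ba, epsilon_estimator="sine")
    assert e_ba.delta_omega_hat == pytest.approx(-e_ab.delta_omega_hat, abs=1e-9)
    assert e_ba.epsilon_hat == pytest.approx(e_ab.epsilon_hat, abs=1e-9)
    w = gs.PhaseDiffTrajectorySet(pair.phi1 - pair.phi2, 1000.0).wrapped()
    s_ab = gs.phase_diff_stats(w.ravel())
    s_ba = gs.phase_diff_stats(-w.ravel())
    assert s_ba.plv == pytest.approx(s_ab.plv, abs=1e-12)
    assert s_ba.mean_phase == pytest.approx(-s_ab.mean_phase, abs=1e-9)


def test_shuffle_control_destroys_coupling():
    pair = gs.simulate_oscillator_pair(36.0, 32.0, 1.8, sigma_each=18.0,
                                       n_trials=30, seed=21)
    raw = gs.estimate_pair_params(
        gs.delta_if_curve(pair.phi1, pair.phi2, 1000.0),
        epsilon_estimator="sine").epsilon_hat
    res = gs.shuffle_epsilon_control(pair.phi1, pair.phi2, 1000.0,
                                     n_permutations=6, seed=0)
    assert raw > 1.2
    assert res["epsilon_mean"] < 0.45
    assert res["values"].shape == (6,)


def test_shuffle_control_validates_inputs():
    pair = gs.simulate_oscillator_pair(36.0, 32.0, 1.0, 18.0, n_trials=4, seed=0)
    with pytest.raises(ValueError):
        gs.shuffle_epsilon_control(pair.phi1, pair.phi2, 1000.0, n_permutations=0)
    with pytest.raises(ValueError):
        gs.shuffle_epsilon_control(pair.phi1[:1], pair.phi2[:1], 1000.0)


def test_amplitude_by_phase_independence_and_injection():
    rng = np.random.default_rng(3)
    th = rng.uniform(-np.pi, np.pi, 200_000)
    flat = gs.amplitude_by_phase(np.ones_like(th) + 0.01 * rng.standard_normal(th.size), th)
    assert flat["modulation_index"] < 0.05
    inj = gs.amplitude_by_phase(1.0 + 0.2 * np.cos(th), th)
    assert inj["modulation_index"] == pytest.approx(0.4, abs=0.02)
    assert inj["bin_centers"].size == 25  # same binning as the dIF curve
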