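"""Stationary solutions: normalization, regimes, oracles, tongue surface."""

import numpy as np
import pytest
from scipy.special import i0, i1

import gammasync as gs


def test_every_density_normalizes():
    for dw, eps, sig in [(0.0, 1.8, 18.0), (2.8, 1.8, 18.0), (5.0, 1.0, 18.0),
                         (4.8, 1.8, 5.0), (-3.0, 0.5, 30.0)]:
        d = gs.stationary_distribution(dw, eps, sigma=sig)
        dth = d.theta[1] - d.theta[0]
        assert d.density.sum() * dth == pytest.approx(1.0, abs=1e-6)
        assert np.all(d.density >= 0)


def test_zero_coupling_gives_uniform_density_and_zero_plv():
    d = gs.stationary_distribution(3.0, 0.0, sigma=18.0)
    assert np.allclose(d.density, 1 / (2 * np.pi), rtol=1e-9)
    st = gs.predict_stats(d)
    assert st["plv"] == pytest.approx(0.0, abs=1e-12)


def test_zero_detuning_density_symmetric_with_zero_mean_phase():
    d = gs.stationary_distribution(0.0, 1.8, sigma=18.0)
    p = d.density
    assert np.allclose(p[1:], p[1:][::-1], rtol=1e-8)  # symmetric about 0
    st = gs.predict_stats(d)
    assert st["mean_phase"] == pytest.approx(0.0, abs=1e-9)
    assert st["plv"] > 0.2


def test_predict_stats_bessel_ratio_for_von_mises_density():
    th = np.linspace(-np.pi, np.pi, 1024, endpoint=False)
    kappa = 2.0
    dens = np.exp(kappa * np.cos(th))
    dens /= dens.sum() * (th[1] - th[0])
    d = gs.StationaryDistribution(theta=th, density=dens)
    st = gs.predict_stats(d)
    assert st["plv"] == pytest.approx(i1(kappa) / i0(kappa), abs=1e-4)


def test_predict_stats_point_mass():
    d = gs.noise_free_distribution(1.0, 1.7)
    d.point_mass = 0.78  # a locked pair at 0.78 rad
    st = gs.predict_stats(d)
    assert st["plv"] == 1.0
    assert st["mean_phase"] == pytest.approx(0.78)


def test_predict_stats_rejects_unnormalized_density():
    th = np.linspace(-np.pi, np.pi, 256, endpoint=False)
    d = gs.StationaryDistribution(theta=th, density=np.ones_like(th))
    with pytest.raises(ValueError, match="normalized"):
        gs.predict_stats(d)


def test_noise_free_regimes():
    # locked: |detuning| <= epsilon -> point mass at the stable root, PLV 1
    d = gs.noise_free_distribution(1.0, 1.7)
    assert d.regime == "locked"
    st = gs.predict_stats(d)
    assert st["plv"] == 1.0
    assert st["mean_phase"] == pytest.approx(np.arcsin(1.0 / 1.7), abs=1e-9)
    # uncoupled: epsilon = 0 -> uniform, PLV 0
    d = gs.noise_free_distribution(3.0, 0.0)
    assert d.regime == "uncoupled"
    assert gs.predict_stats(d)["plv"] == pytest.approx(0.0, abs=1e-12)
    # degenerate: both zero
    d = gs.noise_free_distribution(0.0, 0.0)
    assert d.regime == "degenerate"


def test_noise_free_intermittent_density_peaks_where_drift_is_minimal():
    d = gs.noise_free_distribution(5.0, 1.0)
    assert d.regime == "intermittent"
    # drift 5 - sin is minimal at theta = pi/2 for G = -sin
    assert d.theta[np.argmax(d.density)] == pytest.approx(np.pi / 2, abs=0.01)
    st = gs.predict_stats(d)
    assert 0.0 < st["plv"] < 1.0


def test_noise_free_occupancy_matches_timed_simulation():
    d = gs.noise_free_distribution(5.0, 1.0)
    p = gs.PairParams(delta_omega=5.0, epsilon=1.0, sigma=0.0, duration=50.0,
                      n_trials=20, seed=1)
    edges, probs, _ = gs.occupancy_histogram(p, n_bins=50, burn_in=1.0)
    tv = 0.5 * np.abs(probs - d.bin_probabilities(edges)).sum()
    assert tv < 0.02


def test_noisy_density_matches_euler_maruyama_histogram():
    # single-setting oracle check (the full sweep runs in the acceptance suite)
    dw, eps, sig = 2.8, 1.8, 18.0
    p = gs.PairParams(delta_omega=dw, epsilon=eps, sigma=sig, duration=15.0,
                      n_trials=600, seed=2)
    edges, probs, _ = gs.occupancy_histogram(p, n_bins=50, burn_in=2.0)
    d = gs.stationary_distribution(dw, eps, sigma=sig)
    tv = 0.5 * np.abs(probs - d.bin_probabilities(edges)).sum()
    assert tv < 0.02


def test_quadrature_is_grid_converged():
    # second-order quadrature: refining the default grid 4x moves the
    # predicted statistics by well under the estimation noise floor
    a = gs.stationary_distribution(4.8, 1.8, sigma=18.0, n_grid=1024)
    b = gs.stationary_distribution(4.8, 1.8, sigma=18.0, n_grid=4096)
    pa = gs.predict_stats(a)
    pb = gs.predict_stats(b)
    assert pa["plv"] == pytest.approx(pb["plv"], abs=1e-5)
    assert pa["mean_phase"] == pytest.approx(pb["mean_phase"], abs=5e-5)


def test_small_sigma_converges_to_noise_free_plv():
    for dw, eps in [(1.0, 1.7), (5.0, 1.0)]:
        nf = gs.predict_stats(gs.noise_free_distribution(dw, eps))["plv"]
        noisy = gs.predict_stats(
            gs.stationary_distribution(dw, eps, sigma=0.35, n_grid=4096))["plv"]
        assert noisy == pytest.approx(nf, abs=0.05)


def test_sigma_zero_redirects_to_noise_free():
    with pytest.raises(ValueError, match="noise_free"):
        gs.stationary_distribution(1.0, 1.0, sigma=0.0)


def test_tongue_surface_monotonic_and_antisymmetric():
    dws = np.arange(-6.0, 6.1, 1.0)
    eps = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
    surf = gs.arnold_tongue_surface(dws, eps, sigma=18.0)
    # inside beats outside
    j0 = np.argmin(np.abs(dws))
    assert surf.plv[-1, j0] > surf.plv[0, np.argmax(np.abs(dws))]
    # PLV non-increasing in |detuning| at fixed epsilon
    pos = dws >= 0
    assert np.all(np.diff(surf.plv[:, pos], axis=1) <= 1e-9)
    # PLV non-decreasing in epsilon at fixed detuning
    assert np.all(np.diff(surf.plv, axis=0) >= -1e-9)
    # mean phase antisymmetric in detuning for odd G
    assert np.allclose(surf.mean_phase, -surf.mean_phase[:, ::-1], atol=1e-6)
    # higher-frequency oscillator leads: sign(phase) = sign(detuning)
    nz = dws != 0
    assert np.all(np.sign(surf.mean_phase[:, nz]) == np.sign(dws[nz]))
    assert np.allclose(surf.border_epsilon(), np.abs(dws))
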