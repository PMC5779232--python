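"""Synthetic-recording generator: maps, sessions, spiking, ground truth."""

import numpy as np
import pytest

import gammasync as gs


# ---------------------------------------------------------------- maps
def test_contrast_extremes_span_five_hz():
    d = gs.contrast_to_frequency(66.0) - gs.contrast_to_frequency(21.2)
    assert d == pytest.approx(5.0, abs=0.01)


def test_equal_contrasts_give_zero_frequency_difference():
    assert gs.contrast_to_frequency(40.0) - gs.contrast_to_frequency(40.0) == 0.0


def test_contrast_map_is_affine_and_monotone():
    c = np.array([20.0, 40.0, 60.0])
    f = gs.contrast_to_frequency(c)
    assert f[1] == pytest.approx((f[0] + f[2]) / 2)  # midpoint linearity
    assert np.all(np.diff(gs.contrast_to_frequency(np.linspace(0, 100, 50))) > 0)
    with pytest.raises(ValueError):
        gs.contrast_to_frequency(120.0)


def test_coupling_anchors_and_monotonicity():
    assert gs.coupling_from_distance(2.5) == pytest.approx(1.8, abs=1e-9)
    assert gs.coupling_from_distance(5.0) == pytest.approx(1.0, abs=1e-9)
    d = np.linspace(0, 8, 40)
    eps = gs.coupling_from_distance(d)
    assert np.all(np.diff(eps) < 0)
    assert gs.coupling_from_distance(0.0) == eps.max()
    with pytest.raises(ValueError):
        gs.coupling_from_distance(-1.0)


def test_default_condition_table_has_nine_conditions():
    conds = gs.default_condition_table()
    assert len(conds) == 9
    diffs = [c.contrasts[0] - c.contrasts[1] for c in conds]
    assert diffs[4] == 0.0  # middle condition: no contrast difference
    assert np.all(np.diff(diffs) < 0)


# ---------------------------------------------------------------- MUA
def test_mua_mean_count_matches_rate():
    rng_phase = np.zeros((20, 1800))
    trains = gs.generate_mua(rng_phase + np.pi / 2, 30.0, 0.0, seed=0)
    counts = np.array([len(t) for t in trains])
    expect = 30.0 * 1.8
    assert abs(counts.mean() - expect) < 3 * np.sqrt(expect / len(trains))


def test_mua_spike_phases_peak_at_zero_for_full_modulation():
    pair = gs.simulate_oscillator_pair(34.0, 34.0, 0.0, sigma_each=10.0,
                                       duration=10.0, n_trials=5, seed=1)
    trains = gs.generate_mua(pair.phi1, 40.0, 1.0, seed=2)
    phases = []
    for tr, times in enumerate(trains):
        idx = np.clip((np.asarray(times) * 1000).astype(int), 0, 9999)
        phases.append(gs._utils.wrap_phase(pair.phi1[tr, idx]))
    st = gs.phase_diff_stats(np.concatenate(phases))
    assert st.plv > 0.3
    assert st.mean_phase == pytest.approx(0.0, abs=0.1)


def test_mua_zero_depth_is_phase_uniform():
    pair = gs.simulate_oscillator_pair(34.0, 34.0, 0.0, sigma_each=10.0,
                                       duration=10.0, n_trials=5, seed=3)
    trains = gs.generate_mua(pair.phi1, 40.0, 0.0, seed=4)
    phases = []
    for tr, times in enumerate(trains):
        idx = np.clip((np.asarray(times) * 1000).astype(int), 0, 9999)
        phases.append(gs._utils.wrap_phase(pair.phi1[tr, idx]))
    assert gs.phase_diff_stats(np.concatenate(phases)).plv < 0.05


def test_mua_validates_inputs():
    with pytest.raises(ValueError):
        gs.generate_mua(np.zeros((1, 10)), -1.0, 0.5)
    with pytest.raises(ValueError):
        gs.generate_mua(np.zeros((1, 10)), 10.0, 1.5)


# ---------------------------------------------------------------- sessions
def test_session_is_deterministic_given_seed(small_session):
    cfg = gs.default_session_config(
        probes=[gs.ProbeGeometry(n_contacts=8, position_mm=0.0, n_superficial=6),
                gs.ProbeGeometry(n_contacts=8, position_mm=2.5, n_superficial=6)],
        n_trials=12)
    again = gs.generate_session(cfg, seed=101)
    assert np.array_equal(again.lfp, small_session.lfp)
    assert np.array_equal(again.ground_truth["phases"],
                          small_session.ground_truth["phases"])


def test_session_shapes_and_condition_bookkeeping(small_session):
    s = small_session
    assert s.lfp.shape == (2, 8, 9 * 12, 1800)
    assert s.trial_condition.shape == (108,)
    assert len(np.unique(s.trial_condition)) == 9
    assert s.ground_truth["omega"].shape == (2, 9)
    # detuning across probes follows the contrast table
    dw = s.ground_truth["omega"][0] - s.ground_truth["omega"][1]
    assert dw.max() == pytest.approx(5.0, abs=0.01)
    assert dw[4] == pytest.approx(0.0, abs=1e-9)


def test_clean_signal_limit_recovers_oscillation():
    """With mixing and noise off, the CSD stage returns a scaled oscillation
    whose instantaneous frequency matches the ground truth."""
    cfg = gs.default_session_config(
        probes=[gs.ProbeGeometry(n_contacts=8, position_mm=0.0, n_superficial=6),
                gs.ProbeGeometry(n_contacts=8, position_mm=2.5, n_superficial=6)],
        conditions=[gs.StimulusCondition(1, [36.5, 36.5])],
        n_trials=3, sigma=0.0, envelope_depth=0.0, mixing_width=0.0,
        local_noise_amp=0.0, common_noise_amp=0.0, white_noise_amp=0.0)
    sess = gs.generate_session(cfg, seed=5)
    rec = gs.compute_csd(sess.lfp[0, :8].astype(float), 150.0)
    chan = np.abs(rec.csd).max(axis=(1, 2)).argmax()
    x = rec.csd[chan, 0]
    # pure scaled cosine of the oscillator phase
    ph = sess.ground_truth["phases"][0, 0].astype(float)
    c = np.cos(ph)
    scale = float(np.dot(x, c) / np.dot(c, c))
    assert np.allclose(x, scale * c, atol=1e-4 * abs(scale))
    y = gs.extract_gamma_component(x, 1000.0)
    ag = gs.analytic_signal(y, 1000.0)
    f_true = gs.contrast_to_frequency(36.5)
    assert ag.inst_frequency[300:-300].mean() == pytest.approx(f_true, abs=0.5)


def test_volume_conduction_raises_lfp_but_not_csd_correlation():
    """At zero coupling the shared far field correlates raw LFPs across
    probes; the CSD suppresses it."""
    cfg = gs.default_session_config(
        probes=[gs.ProbeGeometry(n_contacts=8, position_mm=0.0, n_superficial=6),
                gs.ProbeGeometry(n_contacts=8, position_mm=2.5, n_superficial=6)],
        n_trials=4, coupling_scale=0.0)
    sess = gs.generate_session(cfg, seed=6)

    def mean_abs_corr(x, y):
        out = []
        for i in range(x.shape[0]):
            for j in range(y.shape[0]):
                out.append(abs(np.corrcoef(x[i].ravel(), y[j].ravel())[0, 1]))
        return np.mean(out)

    lfp_c = mean_abs_corr(sess.lfp[0, :8].astype(float), sess.lfp[1, :8].astype(float))
    csd0 = gs.compute_csd(sess.lfp[0, :8].astype(float), 150.0).csd
    csd1 = gs.compute_csd(sess.lfp[1, :8].astype(float), 150.0).csd
    csd_c = mean_abs_corr(csd0, csd1)
    assert lfp_c > csd_c + 0.1


def test_session_config_validation():
    with pytest.raises(ValueError):
        gs.SessionConfig(probes=[gs.ProbeGeometry()])  # < 2 probes
    with pytest.raises(ValueError):
        gs.SessionConfig(conditions=[gs.StimulusCondition(1, [30.0])])  # 1 contrast, 2 probes
    with pytest.raises(ValueError):
        gs.StimulusCondition(1, [30.0, 120.0])  # contrast out of range
    with pytest.raises(ValueError):
        gs.ProbeGeometry(n_contacts=2)
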