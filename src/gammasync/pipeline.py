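"""End-to-end orchestration: sessions and cohorts to records, predictions,
evaluation and Arnold-tongue reconstruction.

A *record* is one cross-probe contact (or oscillator) pair in one stimulus
condition.  Records are held in a pandas DataFrame with, per row, the
estimated detuning and interaction strength, the observed phase-locking
value (PLV) and mean phase, and — after prediction — the analytic PLV and
mean phase from the stationary solution.

Circularity guard: the interaction strength used for prediction is never
the pair's own raw estimate; pairs are binned by cortical distance
(default +-0.25 mm) and every pair in a bin is assigned the bin-average
epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import TWO_PI, wrap_phase
from .analytic import (ArnoldTongueSurface, noise_free_distribution,
                       predict_stats, stationary_distribution)
from .estimation import (DEFAULT_BIN_WIDTH, amplitude_by_phase, delta_if_curve,
                         estimate_interaction_function, estimate_pair_params,
                         estimate_sigma, phase_diff_stats)
from .interaction import InteractionFunction, make_interaction_function
from .oscillator import DEFAULT_NOISE, simulate_oscillator_pair
from .signals import (align_csd_polarity, analytic_signal, compute_csd,
                      extract_gamma_component, spike_density)
from .synthetic import SessionRecording, coupling_from_distance

__all__ = [
    "AnalysisConfig",
    "SessionAnalysis",
    "EvaluationReport",
    "derive_analytic_signals",
    "run_session_analysis",
    "run_cohort_analysis",
    "make_cohort",
    "assign_epsilon_by_distance",
    "population_binning",
    "reconstruct_arnold_tongue",
    "evaluate_predictions",
    "attach_ground_truth",
]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for session analysis."""

    band: Optional[tuple] = (25.0, 45.0)  # Hz; None -> spectral-peak band
    layers: str = "L2-4"  # analysis layer group ("L2-4" or "L5-6")
    signal: str = "csd"  # "csd", "spike-csd" or "spike-spike"
    channels_per_probe: Optional[int] = None  # cap on analyzed channels
    trim_start_s: float = 0.2  # stimulus-transient / filter-edge trim
    trim_end_s: float = 0.05
    bin_width: float = DEFAULT_BIN_WIDTH
    epsilon_estimator: str = "sine"
    detuning_threshold: float = 4.0  # |detuning| gate for G pooling
    dist_half_width: float = 0.25  # mm, epsilon-assignment bins
    sigma_method: str = "diffusion"
    sigma_lag_range: Optional[tuple] = None  # None -> per-context default
    predict_with_estimated_g: bool = True
    compute_amplitude_modulation: bool = False
    kernel_sigma_ms: float = 4.0  # spike-density kernel


@dataclass
class SessionAnalysis:
    """Output bundle of a session (or cohort) analysis."""

    records: pd.DataFrame
    g_hat: Optional[InteractionFunction]
    sigma_hat: float
    exclusions: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Prediction accuracy at the three reporting granularities."""

    raw_r2_plv: float
    raw_r2_phase: float
    pair_r2_plv: tuple  # (mean, se, n_pairs)
    pair_r2_phase: tuple
    pop_r2_plv: float
    pop_r2_phase: float
    n_records: int
    bin_spec: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# signal derivation
# ----------------------------------------------------------------------

def _probe_channel_signals(session: SessionRecording, pi: int,
                           config: AnalysisConfig):
    """Band-limited CSD (or spike-density) channels for one probe.

    Returns (signals, channel_ids) where signals has shape
    (n_channels, n_trials, n_time).
    """
    geom = session.geometry[pi]
    if config.signal == "csd":
        use_spikes = False
    elif config.signal == "spike-csd":
        use_spikes = pi == 0  # probe 0 contributes spike density, others CSD
    elif config.signal == "spike-spike":
        use_spikes = True
    else:
        raise ValueError(f"unknown signal type {config.signal!r}")

    labels = geom.depth_labels
    if use_spikes:
        contact_ids = [i for i in range(geom.n_contacts) if labels[i] == config.layers]
        n_time = session.lfp.shape[3]
        sig = np.empty((len(contact_ids), session.n_trials, n_time))
        for k, c in enumerate(contact_ids):
            for tr in range(session.n_trials):
                sig[k, tr] = spike_density(
                    session.spikes[pi][c][tr], session.fs, session.duration,
                    kernel_sigma=config.kernel_sigma_ms)
        return sig, np.asarray(contact_ids)

    lfp = session.lfp[pi, : geom.n_contacts].astype(float)
    rec = align_csd_polarity(compute_csd(lfp, geom.spacing, fs=session.fs,
                                         depth_labels=labels))
    chan_ids = [k for k, c in enumerate(rec.channel_contacts)
                if labels[c] == config.layers]
    return rec.csd[chan_ids], rec.channel_contacts[chan_ids]


def derive_analytic_signals(session: SessionRecording,
                            config: Optional[AnalysisConfig] = None) -> dict:
    """Per-probe instantaneous phase/frequency/amplitude arrays.

    Applies CSD (or spike-density conversion), zero-phase gamma band-pass
    and the Hilbert transform, then trims filter/stimulus-onset edges.
    """
    config = config or AnalysisConfig()
    out = {}
    i0 = int(round(config.trim_start_s * session.fs))
    i1 = session.lfp.shape[3] - int(round(config.trim_end_s * session.fs))
    for pi in range(session.n_probes):
        sig, chan = _probe_channel_signals(session, pi, config)
        band = config.band
        if band is None:
            from .signals import select_gamma_band
            band = select_gamma_band(sig, session.fs)
        nb = extract_gamma_component(sig, session.fs, band=band, axis=-1)
        ag = analytic_signal(nb, session.fs, axis=-1)
        phase = ag.phase[..., i0:i1]
        inst = ag.inst_frequency[..., i0:i1]
        amp = ag.amplitude[..., i0:i1]
        if config.channels_per_probe and len(chan) > config.channels_per_probe:
            # keep the channels with the strongest gamma (largest mean
            # band-limited power), as one would on recorded data
            power = (amp**2).mean(axis=(1, 2))
            keep = np.sort(np.argsort(power)[::-1][: config.channels_per_probe])
            phase, inst, amp, chan = phase[keep], inst[keep], amp[keep], chan[keep]
        out[pi] = {
            "phase": phase,
            "inst_frequency": inst,
            "amplitude": amp,
            "channels": np.asarray(chan),
            "band": band,
            "trim": (i0, i1),
        }
    return out


# ----------------------------------------------------------------------
# record construction
# ----------------------------------------------------------------------

def _pair_record(phase_a, phase_b, fs, config, amp_a=None, amp_b=None):
    """Curve, estimates and observed stats for one pair/condition."""
    curve = delta_if_curve(phase_a, phase_b, fs, bin_width=config.bin_width)
    est = estimate_pair_params(curve, epsilon_estimator=config.epsilon_estimator)
    theta = wrap_phase(np.asarray(phase_a) - np.asarray(phase_b))
    stats = phase_diff_stats(theta.ravel())
    rec = {
        "delta_omega_hat": est.delta_omega_hat,
        "epsilon_hat": est.epsilon_hat,
        "plv_obs": stats.plv,
        "mean_phase_obs": stats.mean_phase,
        "n_samples": curve.n_total,
        "frac_flagged": est.diagnostics["frac_flagged"],
    }
    if config.compute_amplitude_modulation and amp_a is not None:
        amp = 0.5 * (np.asarray(amp_a) + np.asarray(amp_b))
        rec["amp_mod_index"] = amplitude_by_phase(
            amp.ravel(), theta.ravel(), bin_width=config.bin_width)["modulation_index"]
    return curve, rec


def _predict_records(records: pd.DataFrame, g_hat, sigma_hat: float) -> pd.DataFrame:
    """Attach analytic PLV / mean-phase predictions to records."""
    records = records.copy()
    plv_pred = np.empty(len(records))
    ph_pred = np.empty(len(records))
    cache = {}
    for k, (_, row) in enumerate(records.iterrows()):
        key = (round(row["delta_omega_hat"], 4), round(row["epsilon_assigned"], 4))
        if key not in cache:
            if sigma_hat > 0:
                dist = stationary_distribution(
                    key[0], max(key[1], 0.0), g_hat, sigma_hat, n_grid=512)
            else:
                dist = noise_free_distribution(key[0], max(key[1], 0.0), g_hat)
            cache[key] = predict_stats(dist)
        st = cache[key]
        plv_pred[k] = st["plv"]
        ph_pred[k] = st["mean_phase"]
    records["plv_pred"] = plv_pred
    records["mean_phase_pred"] = ph_pred
    return records


def run_session_analysis(session: SessionRecording,
                         config: Optional[AnalysisConfig] = None,
                         derived: Optional[dict] = None) -> SessionAnalysis:
    """Full analysis of one session.

    For every cross-probe channel pair and condition: the binned dIF
    curve, detuning and interaction-strength estimates and the observed
    PLV / mean phase; then a session-level interaction function and phase
    noise; distance-binned epsilon assignment; and analytic predictions.

    Raises
    ------
    ValueError
        If the session holds fewer than two probes.
    """
    config = config or AnalysisConfig()
    if session.n_probes < 2:
        raise ValueError("session analysis needs at least 2 probes with derived signals")
    if derived is None:
        derived = derive_analytic_signals(session, config)

    positions = session.ground_truth.get(
        "positions_mm", np.array([g.position_mm for g in session.geometry]))
    cond_ids = np.unique(session.trial_condition)

    rows, curves = [], []
    for pa in range(session.n_probes):
        for pb in range(pa + 1, session.n_probes):
            dist = abs(positions[pa] - positions[pb])
            for ia, ca in enumerate(derived[pa]["channels"]):
                for ib, cb in enumerate(derived[pb]["channels"]):
                    for cid in cond_ids:
                        m = session.trial_condition == cid
                        curve, rec = _pair_record(
                            derived[pa]["phase"][ia, m], derived[pb]["phase"][ib, m],
                            session.fs, config,
                            amp_a=derived[pa]["amplitude"][ia, m],
                            amp_b=derived[pb]["amplitude"][ib, m])
                        rec.update({
                            "pair_id": f"p{pa}c{ca}-p{pb}c{cb}",
                            "probe_a": pa, "chan_a": int(ca),
                            "probe_b": pb, "chan_b": int(cb),
                            "distance_mm": dist, "condition_id": int(cid),
                            "signal_type": config.signal,
                            "layer_group": config.layers,
                        })
                        rows.append(rec)
                        curves.append(curve)
    records = pd.DataFrame(rows)

    # session-level interaction function and phase noise
    try:
        g_hat = estimate_interaction_function(
            curves, detuning_threshold=config.detuning_threshold,
            epsilon_estimator="sine")
    except ValueError:
        log.warning("no high-detuning curves: falling back to sinusoidal G")
        g_hat = InteractionFunction.sinusoid()
    if_traces = [derived[pi]["inst_frequency"][ia]
                 for pi in derived for ia in range(len(derived[pi]["channels"]))]
    # band-limited phases: fit the diffusion slope at lags beyond the
    # band-pass filter's memory, where variance growth is linear again
    lag_range = config.sigma_lag_range or (0.08, 0.3)
    sigma_hat = estimate_sigma(if_traces, session.fs, method=config.sigma_method,
                               lag_range_s=lag_range)

    records = assign_epsilon_by_distance(records, half_width=config.dist_half_width)
    g_used = g_hat if config.predict_with_estimated_g else InteractionFunction.sinusoid()
    records = _predict_records(records, g_used, sigma_hat)
    return SessionAnalysis(records=records, g_hat=g_hat, sigma_hat=sigma_hat)


# ----------------------------------------------------------------------
# oscillator-level cohorts
# ----------------------------------------------------------------------

def make_cohort(delta_omegas: Sequence[float], distances: Sequence[float],
                center_frequency: float = 34.0) -> pd.DataFrame:
    """Cohort specification: all (detuning, distance) combinations.

    The true interaction strength follows :func:`coupling_from_distance`.
    """
    rows = []
    for d in distances:
        eps = float(coupling_from_distance(d))
        for dw in delta_omegas:
            rows.append({
                "delta_omega_true": float(dw), "epsilon_true": eps,
                "distance_mm": float(d),
                "omega1": center_frequency + dw / 2.0,
                "omega2": center_frequency - dw / 2.0,
            })
    return pd.DataFrame(rows)


def run_cohort_analysis(
    cohort: pd.DataFrame,
    sigma: float = 18.0,
    n_trials: int = 100,
    duration: float = 1.8,
    fs: float = 1000.0,
    seed: Optional[int] = None,
    G: Optional[InteractionFunction] = None,
    config: Optional[AnalysisConfig] = None,
    burn_in_s: float = 0.2,
    sigma_traces: int = 4,
) -> SessionAnalysis:
    """Simulate and analyze a cohort of oscillator pairs.

    Each cohort row (true detuning, true epsilon, distance) is simulated
    as a mutually coupled noisy oscillator pair; estimation, epsilon
    assignment and analytic prediction then run exactly as for recorded
    sessions, but on the raw oscillator phases (no LFP rendering).
    """
    config = config or AnalysisConfig()
    G_true = InteractionFunction.sinusoid() if G is None else make_interaction_function(G)
    rng = np.random.SeedSequence(seed)
    child = [int(s) for s in rng.generate_state(len(cohort)) % (2**31)]
    i0 = int(round(burn_in_s * fs))

    rows, curves, if_traces = [], [], []
    for k, (_, spec) in enumerate(cohort.iterrows()):
        pair = simulate_oscillator_pair(
            spec["omega1"], spec["omega2"], spec["epsilon_true"],
            sigma_each=sigma, G=G_true, fs=fs, duration=duration,
            n_trials=n_trials, seed=child[k])
        p1, p2 = pair.phi1[:, i0:], pair.phi2[:, i0:]
        curve, rec = _pair_record(p1, p2, fs, config)
        rec.update({
            "pair_id": f"pair{k:03d}",
            "condition_id": k,
            "distance_mm": spec["distance_mm"],
            "delta_omega_true": spec["delta_omega_true"],
            "epsilon_true": spec["epsilon_true"],
            "signal_type": "oscillator",
            "layer_group": "n/a",
        })
        rows.append(rec)
        curves.append(curve)
        if len(if_traces) < 2 * sigma_traces:
            # forward-difference IF of the raw phases for sigma estimation
            if_traces.append(np.diff(p1, axis=-1) * fs / TWO_PI)
            if_traces.append(np.diff(p2, axis=-1) * fs / TWO_PI)
    records = pd.DataFrame(rows)

    try:
        g_hat = estimate_interaction_function(
            curves, detuning_threshold=config.detuning_threshold,
            epsilon_estimator="sine")
    except ValueError:
        log.warning("no high-detuning curves: falling back to sinusoidal G")
        g_hat = InteractionFunction.sinusoid()
    lag_range = config.sigma_lag_range or (0.005, 0.04)
    sigma_hat = estimate_sigma(if_traces, fs, method=config.sigma_method,
                               lag_range_s=lag_range)

    records = assign_epsilon_by_distance(records, half_width=config.dist_half_width)
    g_used = g_hat if config.predict_with_estimated_g else InteractionFunction.sinusoid()
    records = _predict_records(records, g_used, sigma_hat)
    return SessionAnalysis(records=records, g_hat=g_hat, sigma_hat=sigma_hat)


# ----------------------------------------------------------------------
# epsilon assignment, binning, evaluation
# ----------------------------------------------------------------------

def assign_epsilon_by_distance(records: pd.DataFrame,
                               half_width: float = 0.25) -> pd.DataFrame:
    """Distance-binned epsilon assignment (circularity guard).

    Pairs are binned by cortical distance (bin width 2*half_width, default
    +-0.25 mm); every pair in a bin receives the bin-average epsilon_hat.
    Pairs alone in their bin keep their own estimate and are flagged.
    """
    if "distance_mm" not in records:
        raise ValueError("records must carry a distance_mm column")
    records = records.copy()
    width = 2.0 * half_width
    bin_center = np.round(records["distance_mm"] / width) * width
    records["distance_bin"] = bin_center
    # one epsilon_hat per pair first, so heavily-sampled pairs don't dominate
    pair_eps = records.groupby(["distance_bin", "pair_id"])["epsilon_hat"].mean()
    bin_mean = pair_eps.groupby("distance_bin").mean()
    bin_npairs = pair_eps.groupby("distance_bin").size()
    records["epsilon_assigned"] = records["distance_bin"].map(bin_mean)
    singleton = records["distance_bin"].map(bin_npairs) == 1
    records.loc[singleton, "epsilon_assigned"] = records.loc[singleton, "epsilon_hat"]
    records["epsilon_singleton_bin"] = singleton
    n_single = int(records.loc[singleton, "pair_id"].nunique())
    if n_single:
        log.info("assign_epsilon_by_distance: %d singleton-bin pairs keep their own epsilon",
                 n_single)
    return records


def _circmean(x: np.ndarray) -> float:
    return float(np.angle(np.exp(1j * np.asarray(x)).mean()))


def population_binning(records: pd.DataFrame, d_delta_omega: float = 0.35,
                       d_distance: float = 0.3) -> pd.DataFrame:
    """Population means over (detuning, distance) cells.

    Cell half-widths default to +-0.35 Hz and +-0.3 mm.  Empty cells are
    dropped (their count is implicit in the returned table).
    """
    if records.empty:
        raise ValueError("records is empty")
    r = records.copy()
    r["dw_bin"] = np.round(r["delta_omega_hat"] / (2 * d_delta_omega)) * (2 * d_delta_omega)
    r["dist_bin"] = np.round(r["distance_mm"] / (2 * d_distance)) * (2 * d_distance)
    rows = []
    for (dwb, db), grp in r.groupby(["dw_bin", "dist_bin"]):
        row = {
            "dw_bin": dwb, "dist_bin": db, "n": len(grp),
            "plv_obs": grp["plv_obs"].mean(),
            "mean_phase_obs": _circmean(grp["mean_phase_obs"].to_numpy()),
        }
        if "plv_pred" in grp:
            row["plv_pred"] = grp["plv_pred"].mean()
            row["mean_phase_pred"] = _circmean(grp["mean_phase_pred"].to_numpy())
        if "epsilon_assigned" in grp:
            row["epsilon_assigned"] = grp["epsilon_assigned"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def reconstruct_arnold_tongue(records: pd.DataFrame,
                              delta_omega_edges=None,
                              epsilon_edges=None) -> ArnoldTongueSurface:
    """Empirical Arnold tongue: observed PLV / mean phase over
    (detuning, assigned epsilon) cells.

    Cells without records hold NaN; a degenerate epsilon span (single
    level) yields a 1-row surface with a warning.
    """
    if records.empty:
        raise ValueError("records is empty")
    dw = records["delta_omega_hat"].to_numpy()
    ep = records["epsilon_assigned"].to_numpy()
    if delta_omega_edges is None:
        lim = np.nanmax(np.abs(dw))
        delta_omega_edges = np.linspace(-lim, lim, 13)
    if epsilon_edges is None:
        if np.ptp(ep) < 1e-9:
            log.warning("single epsilon level: 1-D tongue slice")
            e0 = float(ep.mean())
            epsilon_edges = np.array([e0 - 0.5, e0 + 0.5])
        else:
            epsilon_edges = np.linspace(ep.min() - 1e-9, ep.max() + 1e-9, 7)
    delta_omega_edges = np.asarray(delta_omega_edges, dtype=float)
    epsilon_edges = np.asarray(epsilon_edges, dtype=float)
    ndw, nep = delta_omega_edges.size - 1, epsilon_edges.size - 1
    plv = np.full((nep, ndw), np.nan)
    phs = np.full((nep, ndw), np.nan)
    counts = np.zeros((nep, ndw), dtype=int)
    idw = np.digitize(dw, delta_omega_edges) - 1
    iep = np.digitize(ep, epsilon_edges) - 1
    ok = (idw >= 0) & (idw < ndw) & (iep >= 0) & (iep < nep)
    for i in range(nep):
        for j in range(ndw):
            m = ok & (iep == i) & (idw == j)
            if m.any():
                counts[i, j] = int(m.sum())
                plv[i, j] = records.loc[m, "plv_obs"].mean()
                phs[i, j] = _circmean(records.loc[m, "mean_phase_obs"].to_numpy())
    centers_dw = 0.5 * (delta_omega_edges[:-1] + delta_omega_edges[1:])
    centers_ep = 0.5 * (epsilon_edges[:-1] + epsilon_edges[1:])
    return ArnoldTongueSurface(delta_omega=centers_dw, epsilon=centers_ep,
                               plv=plv, mean_phase=phs, kind="empirical",
                               counts=counts)


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def _r2_circular(obs: np.ndarray, pred: np.ndarray) -> float:
    resid = wrap_phase(obs - pred)
    dev = wrap_phase(obs - _circmean(obs))
    ss_tot = float(np.sum(dev**2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def evaluate_predictions(records: pd.DataFrame,
                         d_delta_omega: float = 0.35,
                         d_distance: float = 0.3,
                         min_pair_conditions: int = 3) -> EvaluationReport:
    """Explained variance of the analytic predictions.

    PLV uses plain R^2 = 1 - SS_res/SS_tot; the mean phase uses wrapped
    residuals in (-pi, pi] against the wrapped deviation from the circular
    mean.  Reported at three granularities: all records pooled, per pair
    across conditions (mean +- SE), and over population (detuning x
    distance) bins.
    """
    needed = {"plv_obs", "plv_pred", "mean_phase_obs", "mean_phase_pred"}
    if not needed.issubset(records.columns):
        raise ValueError("records must carry observed and predicted values")
    n = len(records)
    if n < 3:
        return EvaluationReport(np.nan, np.nan, (np.nan, np.nan, 0),
                                (np.nan, np.nan, 0), np.nan, np.nan, n)
    raw_plv = _r2(records["plv_obs"].to_numpy(), records["plv_pred"].to_numpy())
    raw_phase = _r2_circular(records["mean_phase_obs"].to_numpy(),
                             records["mean_phase_pred"].to_numpy())

    pair_plv, pair_phase = [], []
    for _, grp in records.groupby("pair_id"):
        if len(grp) >= min_pair_conditions:
            pair_plv.append(_r2(grp["plv_obs"].to_numpy(), grp["plv_pred"].to_numpy()))
            pair_phase.append(_r2_circular(grp["mean_phase_obs"].to_numpy(),
                                           grp["mean_phase_pred"].to_numpy()))
    def _mse(vals):
        vals = np.asarray([v for v in vals if np.isfinite(v)])
        if vals.size == 0:
            return (np.nan, np.nan, 0)
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        return (float(vals.mean()), float(se), int(vals.size))

    pop = population_binning(records, d_delta_omega, d_distance)
    pop_plv = _r2(pop["plv_obs"].to_numpy(), pop["plv_pred"].to_numpy())
    pop_phase = _r2_circular(pop["mean_phase_obs"].to_numpy(),
                             pop["mean_phase_pred"].to_numpy())
    return EvaluationReport(
        raw_r2_plv=raw_plv, raw_r2_phase=raw_phase,
        pair_r2_plv=_mse(pair_plv), pair_r2_phase=_mse(pair_phase),
        pop_r2_plv=pop_plv, pop_r2_phase=pop_phase, n_records=n,
        bin_spec={"d_delta_omega": d_delta_omega, "d_distance": d_distance,
                  "n_population_bins": len(pop)},
    )


def attach_ground_truth(records: pd.DataFrame,
                        session: SessionRecording) -> pd.DataFrame:
    """Merge true detuning/epsilon from a synthetic session into records."""
    gt = session.ground_truth
    cond_ids = list(gt["condition_ids"])
    records = records.copy()
    dw_true = np.empty(len(records))
    ep_true = np.empty(len(records))
    for k, (_, row) in enumerate(records.iterrows()):
        ci = cond_ids.index(row["condition_id"])
        pa, pb = int(row["probe_a"]), int(row["probe_b"])
        dw_true[k] = gt["omega"][pa, ci] - gt["omega"][pb, ci]
        ep_true[k] = gt["epsilon"][pa, pb]
    records["delta_omega_true"] = dw_true
    records["epsilon_true"] = ep_true
    return records
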