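"""Estimation of coupled-oscillator quantities from instantaneous phases.

The deterministic part of the phase-difference equation is recovered from
data by binning the instantaneous frequency difference (dIF, Hz) as a
function of the wrapped phase difference theta: the time-averaged curve
dIF(theta) estimates delta_omega + epsilon*G(theta), because the
zero-mean phase noise averages out within bins.

Conditioning convention
-----------------------
Forward phase increments are binned at the *pre-increment* phase.  Binning
at the concurrent (or centred) phase estimates the probability current over
density, J/p(theta), instead of the drift: the occupancy gradient feeds
back into the conditional mean of trailing noise increments
(E[dtheta | theta] = v(theta) - D d(log p)/dtheta).  Ito conditioning on
the earlier sample removes that bias exactly for Markov phase trajectories.
The final sample of each trial keeps its trailing increment so the pooled
sample count equals trials x samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._utils import TWO_PI, wrap_phase
from .interaction import InteractionFunction

__all__ = [
    "DeltaIFCurve",
    "WCOEstimates",
    "PhaseDiffStats",
    "delta_if_curve",
    "modulation_amplitude",
    "estimate_pair_params",
    "estimate_interaction_function",
    "estimate_sigma",
    "phase_diff_stats",
    "shuffle_epsilon_control",
    "amplitude_by_phase",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = TWO_PI / 25  # "0.25 rad nominal": closest uniform partition


@dataclass
class DeltaIFCurve:
    """Binned mean instantaneous-frequency difference vs phase difference."""

    bin_centers: np.ndarray  # rad, over (-pi, pi]
    mean_dif: np.ndarray  # Hz
    se: np.ndarray  # Hz
    counts: np.ndarray
    n_total: int
    fs: float
    flagged: np.ndarray = None  # bins with < min_count samples
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def valid(self) -> np.ndarray:
        return ~self.flagged


@dataclass
class WCOEstimates:
    """Estimated weakly-coupled-oscillator quantities for one pair."""

    delta_omega_hat: float  # Hz
    epsilon_hat: float  # Hz
    sigma_hat: Optional[float] = None  # Hz
    G_hat: Optional[InteractionFunction] = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PhaseDiffStats:
    """Circular summary of pooled phase differences."""

    plv: float
    mean_phase: float  # rad, (-pi, pi]
    hist_centers: np.ndarray = None
    hist_density: np.ndarray = None
    n: int = 0


def _resolve_bins(bin_width: float) -> np.ndarray:
    """Bin edges over [-pi, pi) whose width is the closest divisor of 2*pi."""
    n_bins = int(round(TWO_PI / bin_width))
    if n_bins < 2:
        raise ValueError("bin_width too large")
    if abs(TWO_PI / n_bins - bin_width) > TWO_PI / n_bins:
        raise ValueError("bin_width must divide 2*pi to within one bin")
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def _phase_difference(phase1, phase2):
    """Unwrapped phase-difference trajectories from two phase arrays."""
    p1 = np.atleast_2d(np.asarray(phase1, dtype=float))
    p2 = np.atleast_2d(np.asarray(phase2, dtype=float))
    if p1.shape != p2.shape:
        raise ValueError("phase arrays must share shape (matched trials/samples)")
    d = p1 - p2
    return np.unwrap(wrap_phase(d), axis=-1)


def delta_if_curve(
    phase1,
    phase2,
    fs: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_count: int = 2,
) -> DeltaIFCurve:
    """Binned dIF(theta) curve from two per-trial phase arrays.

    Parameters
    ----------
    phase1, phase2 : ndarray, (n_trials, n_samples)
        Instantaneous phases (wrapped or unwrapped, rad) with matched trial
        structure.
    fs : float
        Sampling rate (Hz).
    bin_width : float
        Nominal phase-bin width (rad); snapped to the closest uniform
        partition of 2*pi (default 25 bins of 2*pi/25 ~ 0.2513 rad).
    min_count : int
        Bins with fewer samples are flagged (never silently interpolated).
    """
    theta = _phase_difference(phase1, phase2)
    n_tr, n_s = theta.shape
    if n_s < 2:
        raise ValueError("need at least 2 samples per trial")
    # forward increments binned at the pre-increment phase; the trailing
    # sample keeps its own trailing increment so counts = trials*samples
    dif = np.empty_like(theta)
    dif[:, :-1] = np.diff(theta, axis=-1)
    dif[:, -1] = dif[:, -2]
    dif *= fs / TWO_PI  # Hz
    at = wrap_phase(theta)

    edges = _resolve_bins(bin_width)
    n_bins = edges.size - 1
    width = TWO_PI / n_bins
    idx = np.clip(((at.ravel() + np.pi) / width).astype(int), 0, n_bins - 1)
    vals = dif.ravel()
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    sq = np.bincount(idx, weights=vals**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean**2
        se = np.sqrt(np.maximum(var, 0) / np.maximum(counts, 1))
    flagged = counts < min_count
    mean[counts == 0] = np.nan
    se[counts == 0] = np.nan
    if flagged.any():
        log.info("delta_if_curve: %d/%d bins flagged (< %d samples)",
                 int(flagged.sum()), n_bins, min_count)
    centers = edges[:-1] + width / 2
    return DeltaIFCurve(
        bin_centers=centers, mean_dif=mean, se=se, counts=counts,
        n_total=int(vals.size), fs=fs, flagged=flagged,
        meta={"bin_width": width, "n_trials": n_tr, "n_samples": n_s},
    )


def modulation_amplitude(curve: DeltaIFCurve, estimator: str = "range") -> float:
    """Modulation amplitude of a binned dIF curve (the epsilon estimate).

    ``"range"``: (max - min)/2 of the per-bin means (simple, upward-biased
    under bin noise).  ``"sine"``: amplitude of an unweighted least-squares
    sinusoid fit across valid bins (unbiased for sinusoidal interaction
    functions).
    """
    m = curve.valid & np.isfinite(curve.mean_dif)
    y = curve.mean_dif[m]
    th = curve.bin_centers[m]
    if y.size < 4:
        raise ValueError("too few valid bins for an amplitude estimate")
    if estimator == "range":
        return float((y.max() - y.min()) / 2.0)
    if estimator == "sine":
        X = np.column_stack([np.sin(th), np.cos(th), np.ones_like(th)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.hypot(coef[0], coef[1]))
    raise ValueError(f"unknown estimator {estimator!r}")


def estimate_pair_params(curve: DeltaIFCurve,
                         epsilon_estimator: str = "range") -> WCOEstimates:
    """Detuning and interaction strength from a binned dIF curve.

    delta_omega_hat is the unweighted mean of the per-bin means over the
    full phase range [-pi, pi] (equal weight per bin, undoing the occupancy
    bias that synchronization itself creates); epsilon_hat is the
    modulation amplitude (default (max-min)/2; ``"sine"`` selects the
    sinusoid-fit alternative).

    A low-confidence diagnostic is set when more than 25% of bins are
    flagged.
    """
    m = curve.valid & np.isfinite(curve.mean_dif)
    if m.sum() < 8:
        raise ValueError("curve must have at least 8 valid bins")
    dw = float(curve.mean_dif[m].mean())
    eps = modulation_amplitude(curve, estimator=epsilon_estimator)
    frac_flagged = float(curve.flagged.mean())
    diag = {
        "n_valid_bins": int(m.sum()),
        "frac_flagged": frac_flagged,
        "low_confidence": frac_flagged > 0.25,
        "epsilon_estimator": epsilon_estimator,
        "n_total": curve.n_total,
    }
    if diag["low_confidence"]:
        log.info("estimate_pair_params: low confidence (%.0f%% bins flagged)",
                 100 * frac_flagged)
    return WCOEstimates(delta_omega_hat=dw, epsilon_hat=eps, diagnostics=diag)


def estimate_interaction_function(
    curves: Sequence[DeltaIFCurve],
    detuning_threshold: float = 4.0,
    epsilon_estimator: str = "sine",
) -> InteractionFunction:
    """Pooled interaction-function estimate from dIF curves.

    Only curves with |delta_omega_hat| above ``detuning_threshold`` (default
    4 Hz) contribute: near zero detuning the occupancy concentrates and the
    recovered shape deforms.  Each passing curve is centred (detuning
    subtracted), sign-aligned (negative-detuning curves flipped so their
    modulations superpose), amplitude-normalized, averaged across curves,
    and re-normalized to zero mean and unit amplitude.

    Raises
    ------
    ValueError
        If no curve passes the detuning threshold.
    """
    shapes = []
    centers = None
    for c in curves:
        est = estimate_pair_params(c, epsilon_estimator=epsilon_estimator)
        if abs(est.delta_omega_hat) <= detuning_threshold:
            continue
        if est.epsilon_hat <= 0:
            continue
        if centers is None:
            centers = c.bin_centers
        elif not np.allclose(centers, c.bin_centers):
            raise ValueError("curves must share a common bin grid")
        s = (c.mean_dif - est.delta_omega_hat) / est.epsilon_hat
        if est.delta_omega_hat < 0:
            # reflect through the origin (equivalent to swapping the pair
            # order so detuning is positive): s(theta) -> -s(-theta)
            s = -s[::-1]
        shapes.append(s)
    if not shapes:
        raise ValueError(
            f"no curve exceeds |detuning| > {detuning_threshold} Hz: "
            "interaction-function estimation impossible")
    avg = np.nanmean(np.vstack(shapes), axis=0)
    ok = np.isfinite(avg)
    return InteractionFunction.from_table(centers[ok], avg[ok], normalize=True)


def estimate_sigma(
    if_traces,
    fs: float,
    method: str = "diffusion",
    lag_range_s: tuple = (0.005, 0.04),
) -> float:
    """Phase-noise SD (Hz) from per-contact instantaneous-frequency traces.

    Parameters
    ----------
    if_traces : sequence of ndarray
        One array per contact, shape (n_trials, n_samples), IF in Hz.
        Non-finite samples are excluded (count logged).
    method : {"diffusion", "sample"}
        ``"diffusion"`` (default) integrates the IF back to phase and fits
        the linear growth of the lagged phase-increment variance; the fit
        slope is invariant to smoothing/filtering of the trace, which only
        adds a constant offset, so the estimate is robust for band-limited
        signals.  The per-trial de-meaning bias (variance deflation by
        1 - lag/n) is corrected exactly.  ``"sample"`` is the plain SD of
        the de-meaned IF samples (valid for unfiltered traces with
        independent per-sample noise).

    Returns
    -------
    float
        Pooled sigma_hat = sqrt(mean of per-contact variances), matching
        the combined-noise convention eta ~ N(0, 2*sigma^2) when both
        oscillators carry SD sigma.
    """
    variances = []
    for x in if_traces:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        bad = ~np.isfinite(x)
        if bad.any():
            log.info("estimate_sigma: excluded %d non-finite samples", int(bad.sum()))
            x = np.where(bad, np.nanmean(x), x)
        x = x - x.mean(axis=-1, keepdims=True)  # per-trial detrend
        n = x.shape[-1]
        if method == "sample":
            variances.append(float(np.mean(x**2)))
            continue
        if method != "diffusion":
            raise ValueError(f"unknown method {method!r}")
        phi = np.cumsum(x, axis=-1) * TWO_PI / fs
        k_lo = max(1, int(round(lag_range_s[0] * fs)))
        k_hi = min(n - 2, int(round(lag_range_s[1] * fs)))
        lags = np.unique(np.linspace(k_lo, k_hi, 8).astype(int))
        v = []
        for k in lags:
            d = phi[:, k:] - phi[:, :-k]
            vk = float(np.mean(d**2) - np.mean(d) ** 2)
            v.append(vk / (1.0 - k / n))  # de-meaning correction
        A = np.column_stack([lags.astype(float), np.ones_like(lags, dtype=float)])
        slope, _ = np.linalg.lstsq(A, np.asarray(v), rcond=None)[0]
        s = fs * np.sqrt(max(slope, 0.0)) / TWO_PI
        variances.append(float(s**2))
    if not variances:
        raise ValueError("no IF traces given")
    return float(np.sqrt(np.mean(variances)))


def phase_diff_stats(phase_differences, n_bins: int = 60) -> PhaseDiffStats:
    """PLV, mean phase and circular histogram of pooled phase differences.

    plv = |mean of unit phasors|; mean phase its argument.
    """
    x = np.asarray(phase_differences, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty phase-difference input")
    if x.size < 100:
        warnings.warn("phase_diff_stats: fewer than 100 samples; estimates are noisy",
                      UserWarning, stacklevel=2)
    z = np.exp(1j * x).mean()
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(wrap_phase(x), bins=edges)
    density = counts / (x.size * (TWO_PI / n_bins))
    return PhaseDiffStats(
        plv=float(np.abs(z)), mean_phase=float(np.angle(z)),
        hist_centers=edges[:-1] + np.pi / n_bins, hist_density=density,
        n=int(x.size),
    )


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) without fixed points."""
    if n < 2:
        raise ValueError("derangement needs >= 2 elements")
    for _ in range(100):
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p
    return np.roll(np.arange(n), 1)  # cyclic shift fallback


def shuffle_epsilon_control(
    phase1,
    phase2,
    fs: float,
    n_permutations: int = 10,
    seed: Optional[int] = None,
    estimator: str = "sine",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict:
    """Residual interaction-strength estimate after trial shuffling.

    Trial pairings between the two phase arrays are permuted (derangement,
    so no trial meets itself), the binned dIF curve is recomputed across
    the shuffled pairs, and epsilon is re-estimated per permutation.  Any
    true coupling is destroyed by the shuffle; the residual epsilon_hat
    quantifies the noise floor of the amplitude estimator, which shrinks
    as 1/sqrt(trials x samples).

    Returns
    -------
    dict
        ``epsilon_mean``, ``epsilon_se``, ``values`` (per permutation).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    p1 = np.atleast_2d(np.asarray(phase1, dtype=float))
    p2 = np.atleast_2d(np.asarray(phase2, dtype=float))
    if p1.shape[0] < 2:
        raise ValueError("need at least 2 trials to shuffle")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_permutations):
        perm = _derangement(p1.shape[0], rng)
        curve = delta_if_curve(p1, p2[perm], fs, bin_width=bin_width)
        vals.append(modulation_amplitude(curve, estimator=estimator))
    vals = np.asarray(vals)
    return {
        "epsilon_mean": float(vals.mean()),
        "epsilon_se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
        "values": vals,
    }


def amplitude_by_phase(
    amplitude,
    phase_difference,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_count: int = 2,
) -> dict:
    """Mean gamma amplitude per phase-difference bin.

    Uses the same binning as :func:`delta_if_curve`.  Returns the binned
    curve and the modulation index (max - min)/mean.
    """
    a = np.asarray(amplitude, dtype=float).ravel()
    th = np.asarray(phase_difference, dtype=float).ravel()
    if a.shape != th.shape:
        raise ValueError("amplitude and phase arrays must share shape")
    edges = _resolve_bins(bin_width)
    n_bins = edges.size - 1
    width = TWO_PI / n_bins
    idx = np.clip(((wrap_phase(th) + np.pi) / width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=a, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    flagged = counts < min_count
    valid = ~flagged & np.isfinite(mean)
    mi = float((np.nanmax(mean[valid]) - np.nanmin(mean[valid])) / np.nanmean(mean[valid]))
    return {
        "bin_centers": edges[:-1] + width / 2,
        "mean_amplitude": mean,
        "counts": counts,
        "flagged": flagged,
        "modulation_index": mi,
    }
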