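"""Stochastic simulation of weakly coupled phase oscillators.

The central object is the phase-difference equation

    dtheta/dt = 2*pi * (delta_omega + epsilon * G(theta) + eta)

with detuning ``delta_omega`` (Hz), interaction strength ``epsilon`` (Hz),
interaction function ``G`` and white phase noise ``eta ~ N(0, 2*sigma**2)``
(Hz), following the convention 1 Hz = 2*pi rad/s.  The noise is drawn
i.i.d. per sample at the simulation rate, so a trajectory at ``fs`` Hz
advances per sample by

    theta[n+1] = theta[n] + 2*pi * (delta_omega + epsilon*G(theta[n]) + eta_n) / fs

(explicit Euler-Maruyama, no sub-stepping: the deterministic dynamics are
of order a few Hz, slow relative to the default 1 kHz rate).  The matching
continuous-time diffusion constant is provided by :class:`NoiseConvention`
so that the analytic stationary solutions in :mod:`gammasync.analytic` use
the identical convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._utils import TWO_PI, wrap_phase
from .interaction import InteractionFunction, make_interaction_function

__all__ = [
    "NoiseConvention",
    "DEFAULT_NOISE",
    "PairParams",
    "PhaseDiffTrajectorySet",
    "OscillatorPairTrajectories",
    "simulate_phase_difference",
    "simulate_oscillator_pair",
    "simulate_oscillator_network",
    "occupancy_histogram",
]


@dataclass(frozen=True)
class NoiseConvention:
    """Mapping between per-sample phase noise (Hz) and a diffusion constant.

    With i.i.d. per-sample noise of SD ``s`` Hz at rate ``fs_sim``, the
    phase performs a random walk with variance growth
    ``(2*pi*s)**2 / fs_sim`` rad^2 per second.  ``diffusion(sigma)``
    returns D (rad^2/s) such that the SDE ``dtheta = v dt + sqrt(2 D) dW``
    reproduces the discrete simulation of the *difference* equation, whose
    noise has variance ``2*sigma**2``:  D = (2*pi*sigma)**2 / fs_sim.
    """

    fs_sim: float = 1000.0
    name: str = "per-sample-hz-v1"

    def diffusion(self, sigma: float) -> float:
        """Diffusion constant D (rad^2/s) of the phase-difference process."""
        return (TWO_PI * sigma) ** 2 / self.fs_sim


DEFAULT_NOISE = NoiseConvention()


@dataclass
class PairParams:
    """Parameters of a simulated oscillator pair (difference equation).

    All frequencies are in Hz (1 Hz = 2*pi rad/s).
    """

    delta_omega: float
    epsilon: float
    sigma: float
    G: InteractionFunction = field(default_factory=InteractionFunction.sinusoid)
    fs: float = 1000.0
    duration: float = 1.8
    n_trials: int = 30
    seed: Optional[int] = None

    def __post_init__(self):
        self.G = make_interaction_function(self.G)
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class PhaseDiffTrajectorySet:
    """Per-trial unwrapped phase-difference trajectories theta(t) (rad)."""

    theta: np.ndarray  # (n_trials, n_samples), unwrapped rad
    fs: float

    @property
    def n_trials(self) -> int:
        return self.theta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.theta.shape[1]

    def wrapped(self) -> np.ndarray:
        """Phase differences wrapped to (-pi, pi]."""
        return wrap_phase(self.theta)


@dataclass
class OscillatorPairTrajectories:
    """Absolute-phase trajectories of two mutually coupled oscillators."""

    phi1: np.ndarray  # (n_trials, n_samples), unwrapped rad
    phi2: np.ndarray
    fs: float

    def difference(self) -> PhaseDiffTrajectorySet:
        return PhaseDiffTrajectorySet(theta=self.phi1 - self.phi2, fs=self.fs)


def _check_resolution(fs: float, delta_omega: float, epsilon: float) -> None:
    if fs < 20.0 * max(abs(delta_omega), epsilon):
        warnings.warn(
            f"fs={fs} Hz may be too low to resolve dynamics with "
            f"|delta_omega|={abs(delta_omega)} Hz, epsilon={epsilon} Hz "
            "(want fs >= 20*max of the two)",
            UserWarning,
            stacklevel=3,
        )


def simulate_phase_difference(
    params: PairParams,
    initial_phase: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> PhaseDiffTrajectorySet:
    """Integrate the stochastic phase-difference equation.

    Parameters
    ----------
    params : PairParams
    initial_phase : float, optional
        Common initial phase difference (rad).  Default: independent
        uniform draws on (-pi, pi] per trial.
    rng : numpy Generator, optional
        Overrides ``params.seed``.

    Returns
    -------
    PhaseDiffTrajectorySet
        Deterministic given ``params`` (including seed).
    """
    _check_resolution(params.fs, params.delta_omega, params.epsilon)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_samples
    theta = np.empty((params.n_trials, n), dtype=float)
    if initial_phase is None:
        th = rng.uniform(-np.pi, np.pi, params.n_trials)
    else:
        th = np.full(params.n_trials, float(initial_phase))
    noise_sd = np.sqrt(2.0) * params.sigma
    dt = 1.0 / params.fs
    G = params.G
    for k in range(n):
        theta[:, k] = th
        drift = params.delta_omega + params.epsilon * G(th)
        if noise_sd > 0:
            drift = drift + noise_sd * rng.standard_normal(params.n_trials)
        th = th + TWO_PI * drift * dt
    return PhaseDiffTrajectorySet(theta=theta, fs=params.fs)


def simulate_oscillator_network(
    omegas,
    eps_matrix,
    sigma_each: float,
    G: InteractionFunction = None,
    fs: float = 1000.0,
    duration: float = 1.8,
    n_trials: int = 30,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate N mutually coupled noisy phase oscillators.

    Each oscillator i obeys

        dphi_i/dt = 2*pi*(omega_i + sum_j (eps_ij/2) G(phi_i - phi_j) + eta_i)

    with eta_i ~ N(0, sigma_each**2) i.i.d. per sample.  With a symmetric
    coupling matrix and an odd G, any pairwise phase difference obeys the
    difference equation with detuning omega_i - omega_j, interaction
    strength eps_ij and combined noise variance 2*sigma_each**2.

    Returns
    -------
    ndarray, shape (n_osc, n_trials, n_samples)
        Unwrapped absolute phases (rad).
    """
    G = InteractionFunction.sinusoid() if G is None else make_interaction_function(G)
    omegas = np.asarray(omegas, dtype=float)
    eps = np.asarray(eps_matrix, dtype=float)
    n_osc = omegas.size
    if eps.shape != (n_osc, n_osc):
        raise ValueError("eps_matrix must be (n_osc, n_osc)")
    if sigma_each < 0:
        raise ValueError("sigma_each must be >= 0")
    _check_resolution(fs, float(np.abs(np.subtract.outer(omegas, omegas)).max()), float(eps.max(initial=0.0)))
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    phases = np.empty((n_osc, n_trials, n), dtype=float)
    ph = rng.uniform(-np.pi, np.pi, (n_osc, n_trials))
    dt = 1.0 / fs
    for k in range(n):
        phases[:, :, k] = ph
        drift = np.broadcast_to(omegas[:, None], ph.shape).copy()
        for i in range(n_osc):
            for j in range(n_osc):
                if i != j and eps[i, j] != 0:
                    drift[i] += 0.5 * eps[i, j] * G(ph[i] - ph[j])
        if sigma_each > 0:
            drift += sigma_each * rng.standard_normal(ph.shape)
        ph = ph + TWO_PI * drift * dt
    return phases


def simulate_oscillator_pair(
    omega1: float,
    omega2: float,
    epsilon: float,
    sigma_each: float,
    G: InteractionFunction = None,
    fs: float = 1000.0,
    duration: float = 1.8,
    n_trials: int = 30,
    seed: Optional[int] = None,
) -> OscillatorPairTrajectories:
    """Simulate two mutually coupled noisy oscillators (absolute phases).

    The phase difference phi1 - phi2 obeys the same law as
    :func:`simulate_phase_difference` with delta_omega = omega1 - omega2
    and combined noise variance 2*sigma_each**2 (for odd G).
    """
    eps = np.array([[0.0, epsilon], [epsilon, 0.0]])
    phases = simulate_oscillator_network(
        [omega1, omega2], eps, sigma_each, G=G, fs=fs, duration=duration,
        n_trials=n_trials, seed=seed,
    )
    return OscillatorPairTrajectories(phi1=phases[0], phi2=phases[1], fs=fs)


def occupancy_histogram(
    params: PairParams,
    n_bins: int = 50,
    burn_in: float = 2.0,
    chunk_s: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of the wrapped phase difference from a streamed simulation.

    Runs ``params.n_trials`` parallel chains for ``params.duration`` seconds
    each, discarding the first ``burn_in`` seconds, and accumulates the
    wrapped-phase histogram chunk by chunk (memory stays bounded for very
    long runs).

    Returns
    -------
    edges : ndarray, (n_bins+1,)
    probs : ndarray, (n_bins,)
        Bin probabilities (sum to 1).
    n : int
        Number of pooled samples.
    """
    if burn_in >= params.duration:
        raise ValueError("burn_in must be shorter than duration")
    rng = np.random.default_rng(params.seed)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    th = rng.uniform(-np.pi, np.pi, params.n_trials)
    noise_sd = np.sqrt(2.0) * params.sigma
    dt = 1.0 / params.fs
    G = params.G
    n_total = params.n_samples
    n_burn = int(round(burn_in * params.fs))
    chunk = max(1, int(round(chunk_s * params.fs)))
    done = 0
    n_kept = 0
    buf = np.empty((params.n_trials, chunk), dtype=float)
    while done < n_total:
        m = min(chunk, n_total - done)
        for k in range(m):
            buf[:, k] = th
            drift = params.delta_omega + params.epsilon * G(th)
            if noise_sd > 0:
                drift = drift + noise_sd * rng.standard_normal(params.n_trials)
            th = th + TWO_PI * drift * dt
        lo = max(0, n_burn - done)
        if lo < m:
            w = wrap_phase(buf[:, lo:m]).ravel()
            c, _ = np.histogram(w, bins=edges)
            counts += c
            n_kept += w.size
        done += m
    probs = counts / max(n_kept, 1)
    return edges, probs, n_kept
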