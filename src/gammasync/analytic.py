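"""Analytic stationary solutions of the noisy phase-difference equation.

For the phase-difference SDE

    dtheta = v(theta) dt + sqrt(2 D) dW,      v(theta) = 2*pi*(delta_omega + epsilon*G(theta))

on the circle, the stationary Fokker-Planck solution with constant
probability current is (Stratonovich/standard tilted-periodic-potential
result)

    p(theta)  proportional to  exp(-Phi(theta)) * integral_theta^{theta+2pi} exp(Phi(psi)) dpsi

with the tilted potential Phi(theta) = -(1/D) * integral_0^theta v(psi) dpsi.
The diffusion constant D is taken from the same :class:`NoiseConvention`
used by the discrete simulator, so analytic predictions and simulations are
mutually consistent by construction.

The noise-free limit has three regimes: full locking (|delta_omega| <=
epsilon: point mass at the stable zero of the drift, PLV = 1), uncoupled
(epsilon = 0: uniform, PLV = 0), and intermittent phase precession
(|delta_omega| > epsilon > 0: occupancy density proportional to
1/|drift|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from ._utils import TWO_PI
from .interaction import InteractionFunction, make_interaction_function
from .oscillator import DEFAULT_NOISE, NoiseConvention

__all__ = [
    "StationaryDistribution",
    "ArnoldTongueSurface",
    "stationary_distribution",
    "noise_free_distribution",
    "predict_stats",
    "arnold_tongue_surface",
]


@dataclass
class StationaryDistribution:
    """Stationary phase-difference distribution on [-pi, pi).

    ``density`` is None when the distribution is a point mass (noise-free
    locked regime); ``point_mass`` then carries the locked phase.
    """

    theta: np.ndarray
    density: Optional[np.ndarray]
    params: dict = field(default_factory=dict)
    regime: str = "noisy"
    point_mass: Optional[float] = None

    def bin_probabilities(self, edges: np.ndarray) -> np.ndarray:
        """Integrate the density over the given bin edges (rad)."""
        if self.density is None:
            p = np.zeros(len(edges) - 1)
            idx = np.searchsorted(edges, self.point_mass, side="right") - 1
            p[np.clip(idx, 0, len(p) - 1)] = 1.0
            return p
        # cumulative integral on the periodic grid
        dth = self.theta[1] - self.theta[0]
        cdf_grid = np.concatenate([[0.0], np.cumsum(self.density) * dth])
        grid = np.concatenate([self.theta, [self.theta[0] + TWO_PI]])
        cdf = np.interp(edges, grid, cdf_grid)
        return np.diff(cdf) / cdf_grid[-1]


@dataclass
class ArnoldTongueSurface:
    """PLV and mean phase over a (delta_omega, epsilon) grid.

    ``plv`` and ``mean_phase`` have shape (len(epsilon), len(delta_omega)).
    The noise-free synchronization border is epsilon = |delta_omega|.
    """

    delta_omega: np.ndarray
    epsilon: np.ndarray
    plv: np.ndarray
    mean_phase: np.ndarray
    kind: str = "analytic"
    sigma: Optional[float] = None
    counts: Optional[np.ndarray] = None

    def border_epsilon(self) -> np.ndarray:
        """epsilon = |delta_omega| border of the noise-free Arnold tongue."""
        return np.abs(self.delta_omega)

    def to_frame(self):
        """Long-format pandas DataFrame (one row per grid cell)."""
        import pandas as pd

        dw, ep = np.meshgrid(self.delta_omega, self.epsilon)
        data = {
            "delta_omega": dw.ravel(),
            "epsilon": ep.ravel(),
            "plv": self.plv.ravel(),
            "mean_phase": self.mean_phase.ravel(),
        }
        if self.counts is not None:
            data["count"] = self.counts.ravel()
        return pd.DataFrame(data)


def stationary_distribution(
    delta_omega: float,
    epsilon: float,
    G: InteractionFunction = None,
    sigma: float = 18.0,
    noise: NoiseConvention = DEFAULT_NOISE,
    n_grid: int = 1024,
) -> StationaryDistribution:
    """Stationary density of the noisy phase-difference equation.

    Evaluated by trapezoidal quadrature on a uniform ``n_grid``-point theta
    grid, with the wrap-around integral computed from cumulative sums on the
    periodically extended grid; exponentials are shifted into log-space for
    numerical stability at small sigma.

    Raises
    ------
    ValueError
        If ``sigma <= 0`` (use :func:`noise_free_distribution`).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0; use noise_free_distribution for sigma = 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    G = InteractionFunction.sinusoid() if G is None else make_interaction_function(G)
    D = noise.diffusion(sigma)

    n = int(n_grid)
    dth = TWO_PI / n
    # extended grid over [-pi, 3*pi]
    psi = -np.pi + dth * np.arange(2 * n + 1)
    v = TWO_PI * (delta_omega + epsilon * G(psi))  # rad/s
    # Phi(psi) = -(1/D) * cumulative integral of v (trapezoid)
    incr = 0.5 * (v[1:] + v[:-1]) * dth
    Phi = np.concatenate([[0.0], np.cumsum(-incr / D)])
    # wrap-around integral I(theta) = int_theta^{theta+2pi} exp(Phi),
    # integrating the piecewise-exponential interpolant of Phi exactly on
    # each segment and summing in log space: robust to the exponentially
    # tilted potential at small sigma, where exp(Phi) spans hundreds of
    # decades and develops boundary layers narrower than the grid.
    from scipy.special import logsumexp

    d = np.diff(Phi)  # 2n segment slopes (times dth)
    logf = np.empty_like(d)  # log[(exp(d)-1)/d], the segment shape factor
    small = np.abs(d) < 1e-8
    logf[small] = d[small] / 2.0
    pos = (~small) & (d > 0)
    neg = (~small) & (d < 0)
    logf[pos] = d[pos] + np.log1p(-np.exp(-d[pos])) - np.log(d[pos])
    logf[neg] = np.log1p(-np.exp(d[neg])) - np.log(-d[neg])
    logseg = Phi[:-1] + logf + np.log(dth)  # log integral over each segment
    windows = np.lib.stride_tricks.sliding_window_view(logseg, n)[:n]
    logI = logsumexp(windows, axis=1)
    logp = -Phi[:n] + logI
    logp -= logp.max()
    p = np.exp(logp)
    Z = p.sum() * dth  # uniform periodic grid: rectangle rule == trapezoid
    p /= Z
    theta = psi[:n]
    return StationaryDistribution(
        theta=theta,
        density=p,
        params={
            "delta_omega": delta_omega,
            "epsilon": epsilon,
            "sigma": sigma,
            "G": G.name,
            "noise_convention": noise.name,
            "fs_sim": noise.fs_sim,
        },
        regime="noisy",
    )


def noise_free_distribution(
    delta_omega: float,
    epsilon: float,
    G: InteractionFunction = None,
    n_grid: int = 1024,
) -> StationaryDistribution:
    """Noise-free stationary distribution and regime label.

    Regimes: ``"locked"`` (point mass, PLV = 1), ``"uncoupled"`` (uniform,
    PLV = 0), ``"intermittent"`` (occupancy density ~ 1/|drift|) and
    ``"degenerate"`` (epsilon = 0 and delta_omega = 0: any phase persists).
    """
    G = InteractionFunction.sinusoid() if G is None else make_interaction_function(G)
    if not (np.isfinite(delta_omega) and np.isfinite(epsilon)):
        raise ValueError("parameters must be finite")
    theta = np.linspace(-np.pi, np.pi, int(n_grid), endpoint=False)
    params = {"delta_omega": delta_omega, "epsilon": epsilon, "sigma": 0.0, "G": G.name}

    if epsilon == 0:
        if delta_omega == 0:
            # any initial phase persists: report uniform, flag degenerate
            dens = np.full(theta.size, 1.0 / TWO_PI)
            return StationaryDistribution(theta, dens, params, regime="degenerate")
        dens = np.full(theta.size, 1.0 / TWO_PI)
        return StationaryDistribution(theta, dens, params, regime="uncoupled")

    drift = delta_omega + epsilon * G(theta)

    # look for stable zeros of the drift
    ext = np.concatenate([drift, [drift[0]]])
    sign_change = np.nonzero(np.sign(ext[:-1]) * np.sign(ext[1:]) < 0)[0]
    roots = []
    f = lambda th: delta_omega + epsilon * G(th)
    dth = theta[1] - theta[0]
    for i in sign_change:
        a = theta[i]
        roots.append(brentq(f, a, a + dth, xtol=1e-12))
    # exact zeros on the grid
    for i in np.nonzero(ext[:-1] == 0)[0]:
        roots.append(theta[i])
    stable = [r for r in roots
              if epsilon * G.derivative(np.array([r]))[0] < 0]
    if stable:
        # locked regime: point mass at the stable root
        theta_star = float(stable[0])
        return StationaryDistribution(theta, None, params, regime="locked",
                                      point_mass=theta_star)
    if np.abs(drift).min() < 1e-12 * max(1.0, abs(delta_omega) + epsilon):
        # tangent (semi-stable) root at the tongue border
        theta_star = float(theta[np.abs(drift).argmin()])
        return StationaryDistribution(theta, None, params, regime="locked",
                                      point_mass=theta_star)

    # intermittent precession: occupancy ~ 1 / |drift|
    dens = 1.0 / np.abs(drift)
    dens /= dens.sum() * dth
    return StationaryDistribution(theta, dens, params, regime="intermittent")


def predict_stats(dist: StationaryDistribution) -> dict:
    """Predicted PLV and mean phase from a stationary distribution.

    plv = |integral exp(i*theta) p(theta) dtheta|, mean phase its argument.

    Raises
    ------
    ValueError
        If the density does not integrate to 1 (within 1e-6).
    """
    if dist.point_mass is not None:
        return {"plv": 1.0, "mean_phase": float(dist.point_mass)}
    dth = dist.theta[1] - dist.theta[0]
    total = dist.density.sum() * dth
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"density is not normalized (integral = {total:.8f})")
    z = np.sum(np.exp(1j * dist.theta) * dist.density) * dth
    return {"plv": float(np.abs(z)), "mean_phase": float(np.angle(z))}


def arnold_tongue_surface(
    delta_omega_grid,
    epsilon_grid,
    G: InteractionFunction = None,
    sigma: float = 18.0,
    noise: NoiseConvention = DEFAULT_NOISE,
    n_grid: int = 512,
) -> ArnoldTongueSurface:
    """Analytic PLV / mean-phase surface over a (delta_omega, epsilon) grid.

    For ``sigma = 0`` the noise-free solution is used per cell.
    """
    G = InteractionFunction.sinusoid() if G is None else make_interaction_function(G)
    dws = np.asarray(delta_omega_grid, dtype=float).ravel()
    eps = np.asarray(epsilon_grid, dtype=float).ravel()
    if not (np.all(np.isfinite(dws)) and np.all(np.isfinite(eps))):
        raise ValueError("grids must be finite")
    plv = np.empty((eps.size, dws.size))
    phs = np.empty_like(plv)
    for i, e in enumerate(eps):
        for j, dw in enumerate(dws):
            if sigma > 0:
                dist = stationary_distribution(dw, e, G, sigma, noise=noise, n_grid=n_grid)
            else:
                dist = noise_free_distribution(dw, e, G, n_grid=n_grid)
            st = predict_stats(dist)
            plv[i, j] = st["plv"]
            phs[i, j] = st["mean_phase"]
    return ArnoldTongueSurface(delta_omega=dws, epsilon=eps, plv=plv,
                               mean_phase=phs, kind="analytic", sigma=sigma)
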