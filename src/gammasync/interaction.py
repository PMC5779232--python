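"""Periodic interaction functions G(theta) for weakly coupled phase oscillators.

The interaction function describes how the instantaneous phase difference
between two mutually coupled oscillators accelerates or decelerates their
phase precession.  By convention it is periodic with period 2*pi, has zero
mean over one period and unit peak amplitude, so that the interaction
strength epsilon (in Hz) carries the full magnitude of the coupling.

The canonical instance is the Kuramoto sinusoid G(theta) = -sin(theta)
(attractive convention: for zero detuning the stable phase difference is 0).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from ._utils import TWO_PI, wrap_phase

__all__ = ["InteractionFunction", "make_interaction_function"]


class InteractionFunction:
    """Zero-mean, unit-amplitude periodic function of the phase difference.

    Parameters
    ----------
    fn : callable
        Vectorized function of phase (rad).  Must already be periodic;
        it is evaluated on wrapped phases.
    name : str
        Human-readable label.

    Notes
    -----
    Instances are callable: ``g(theta)`` evaluates the function at any
    (wrapped or unwrapped) phase.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], name: str = "custom"):
        self._fn = fn
        self.name = name

    def __call__(self, theta):
        theta = wrap_phase(theta)
        return self._fn(theta)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"InteractionFunction({self.name!r})"

    # ------------------------------------------------------------------
    @classmethod
    def sinusoid(cls) -> "InteractionFunction":
        """The Kuramoto sinusoid, G(theta) = -sin(theta)."""
        return cls(lambda th: -np.sin(th), name="sinusoid")

    @classmethod
    def from_table(cls, theta, values, normalize: bool = True) -> "InteractionFunction":
        """Build an interaction function from a tabulated curve.

        The table must cover a full period; it is wrapped to [-pi, pi),
        linearly interpolated (periodically), de-meaned and peak-normalized.

        Raises
        ------
        ValueError
            If the tabulation does not cover a full period or is constant
            (zero modulation after de-meaning).
        """
        theta = np.asarray(theta, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if theta.size != values.size:
            raise ValueError("theta and values must have the same length")
        if theta.size < 4:
            raise ValueError("need at least 4 tabulated points")
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(values))):
            raise ValueError("tabulated curve contains non-finite values")

        w = np.asarray(wrap_phase(theta), dtype=float)
        # fold pi onto -pi so the support is [-pi, pi)
        w = np.where(w == np.pi, -np.pi, w)
        order = np.argsort(w, kind="stable")
        w, v = w[order], values[order]
        # collapse duplicate phases
        uniq, inv = np.unique(w, return_index=True)
        w, v = w[inv], v[inv]
        gaps = np.diff(np.concatenate([w, [w[0] + TWO_PI]]))
        if gaps.max() > TWO_PI / 4:
            raise ValueError("tabulated curve does not cover a full period")

        # periodic extension for interpolation
        wx = np.concatenate([w, [w[0] + TWO_PI]])
        vx = np.concatenate([v, [v[0]]])

        def interp(th):
            return np.interp(np.mod(th - w[0], TWO_PI) + w[0], wx, vx)

        if normalize:
            dense = np.linspace(-np.pi, np.pi, 4096, endpoint=False)
            g = interp(dense)
            mean = g.mean()
            amp = np.abs(g - mean).max()
            if amp == 0:
                raise ValueError("tabulated curve has zero modulation")

            def fn(th, _m=mean, _a=amp):
                return (interp(th) - _m) / _a

        else:
            fn = interp
        return cls(fn, name="tabulated")

    # ------------------------------------------------------------------
    def grid(self, n: int = 1024):
        """Evaluate on a uniform grid over [-pi, pi).  Returns (theta, G)."""
        th = np.linspace(-np.pi, np.pi, n, endpoint=False)
        return th, self(th)

    def mean(self, n: int = 4096) -> float:
        """Mean over one period (should be ~0 for normalized functions)."""
        return float(self.grid(n)[1].mean())

    def amplitude(self, n: int = 4096) -> float:
        """Peak absolute value over one period."""
        return float(np.abs(self.grid(n)[1]).max())

    def derivative(self, theta, h: float = 1e-5):
        """Central-difference derivative dG/dtheta."""
        theta = np.asarray(theta, dtype=float)
        return (self(theta + h) - self(theta - h)) / (2 * h)


def make_interaction_function(spec) -> InteractionFunction:
    """Construct an :class:`InteractionFunction` from a name or a table.

    Parameters
    ----------
    spec : str, InteractionFunction or (theta, values) pair
        ``"sinusoid"`` returns the Kuramoto G(theta) = -sin(theta).
        A pair of arrays is treated as a tabulated curve over one period
        (normalized to zero mean, unit amplitude).
    """
    if isinstance(spec, InteractionFunction):
        return spec
    if isinstance(spec, str):
        if spec.lower() in ("sinusoid", "sine", "kuramoto"):
            return InteractionFunction.sinusoid()
        raise ValueError(f"unknown interaction function name: {spec!r}")
    if isinstance(spec, Sequence) and len(spec) == 2:
        return InteractionFunction.from_table(spec[0], spec[1])
    raise ValueError("spec must be a name, an InteractionFunction or a (theta, values) pair")
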