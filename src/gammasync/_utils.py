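"""Small shared helpers: phase wrapping, 1/f noise, seed spawning."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angles to (-pi, pi].

    Parameters
    ----------
    x : array_like
        Angles in radians.
    """
    x = np.asarray(x, dtype=float)
    w = (x + np.pi) % TWO_PI - np.pi
    # map the left edge onto the right one so the range is (-pi, pi]
    return np.where(w == -np.pi, np.pi, w)


def pink_noise(rng, shape, axis=-1):
    """Unit-variance noise with a 1/f power spectrum along `axis`.

    Generated by shaping the spectrum of white Gaussian noise with
    amplitude ~ f**-0.5 (DC excluded) and renormalizing each trace to
    zero mean, unit SD.
    """
    shape = tuple(shape)
    x = rng.standard_normal(shape)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    spec *= scale
    y = np.fft.irfft(spec, n=n, axis=-1)
    y -= y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    y /= sd
    return np.moveaxis(y, -1, axis)


def spawn_seeds(seed, n):
    """Derive `n` independent 31-bit integer seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
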