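"""Minimal plotting helpers for reports (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .analytic import ArnoldTongueSurface  # noqa: E402

__all__ = ["plot_arnold_tongue", "plot_prediction_scatter", "plot_delta_if_curve"]


def plot_arnold_tongue(surface: ArnoldTongueSurface, ax=None, what: str = "plv"):
    """Heatmap of a PLV (or mean-phase) surface with the eps=|detuning| border."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    z = surface.plv if what == "plv" else surface.mean_phase
    cmap = "viridis" if what == "plv" else "twilight"
    dw, ep = surface.delta_omega, surface.epsilon
    extent = [dw.min(), dw.max(), ep.min(), ep.max()]
    im = ax.imshow(z, origin="lower", aspect="auto", extent=extent, cmap=cmap)
    x = np.linspace(dw.min(), dw.max(), 200)
    ax.plot(x, np.abs(x), "k-", lw=1.2)
    ax.set_ylim(ep.min(), ep.max())
    ax.set_xlabel("detuning (Hz)")
    ax.set_ylabel("interaction strength (Hz)")
    ax.set_title(f"{surface.kind} {what}")
    plt.colorbar(im, ax=ax)
    return ax


def plot_prediction_scatter(records, ax=None, what: str = "plv"):
    """Observed vs predicted PLV (or mean phase) with the unity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    col = ("plv_obs", "plv_pred") if what == "plv" else ("mean_phase_obs", "mean_phase_pred")
    ax.plot(records[col[1]], records[col[0]], ".", ms=4, alpha=0.5)
    lo = min(records[col[1]].min(), records[col[0]].min())
    hi = max(records[col[1]].max(), records[col[0]].max())
    ax.plot([lo, hi], [lo, hi], "r-", lw=1)
    ax.set_xlabel(f"predicted {what}")
    ax.set_ylabel(f"observed {what}")
    return ax


def plot_delta_if_curve(curve, ax=None):
    """Binned dIF(theta) curve with +-SE shading."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    m = np.isfinite(curve.mean_dif)
    ax.fill_between(curve.bin_centers[m], (curve.mean_dif - curve.se)[m],
                    (curve.mean_dif + curve.se)[m], alpha=0.3)
    ax.plot(curve.bin_centers[m], curve.mean_dif[m], "-o", ms=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("phase difference (rad)")
    ax.set_ylabel("instantaneous frequency difference (Hz)")
    return ax
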