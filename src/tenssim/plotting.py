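"""Quick-look plots: field/membrane profiles and space-time response maps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_profiles", "plot_response_map"]


def plot_profiles(report: dict, ax=None):
    """Plot V_e and the membrane snapshots from a validation report."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    s = report["arc_length_mm"]
    ax[0].plot(s, report["v_e"] * 1e3, color="tab:blue")
    ax[0].set_ylabel("$V_{e,n}$ / mV")
    ax[1].plot(s, report["v_n_pulse_end"] * 1e3, label="end of pulse", color="tab:red")
    ax[1].plot(s, report["v_n_1ms"] * 1e3, label="1 ms after onset", color="tab:green")
    ax[1].set_xlabel("distance along nerve / mm")
    ax[1].set_ylabel("$V_n$ / mV")
    ax[1].legend(frameon=False)
    ax[0].set_title(report["scenario"])
    return ax


def plot_response_map(result, ax=None, vmax_mV: float | None = None):
    """Space-time image of the reduced membrane potential (mV)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    v = result.v * 1e3
    if vmax_mV is None:
        vmax_mV = float(np.abs(v).max()) or 1.0
    im = ax.pcolormesh(
        result.arc_length * 1e3, result.t * 1e3, v,
        cmap="RdBu_r", vmin=-vmax_mV, vmax=vmax_mV, shading="nearest",
    )
    ax.set_xlabel("distance along nerve / mm")
    ax.set_ylabel("time / ms")
    plt.colorbar(im, ax=ax, label="$V_n$ / mV")
    return ax
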