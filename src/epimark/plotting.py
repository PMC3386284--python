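"""Minimal plotting helpers (profile curves, saturation)."""

from __future__ import annotations

import numpy as np


def plot_profile_curves(offsets, curves: dict, ax=None, xlabel="offset from TSS (bp)"):
    """Plot one aggregate density curve per stratum; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = np.asarray(offsets, dtype=float)
    for name in sorted(curves):
        ax.plot(x, curves[name], label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("tag density (tags/bp)")
    ax.legend(frameon=False)
    return ax


def plot_saturation(curve: dict, ax=None):
    """Plot a read-subsampling saturation curve (fraction vs tags/bp on peaks)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    fr = sorted(curve)
    ax.plot(fr, [curve[f] for f in fr], marker="o")
    ax.set_xlabel("fraction of reads")
    ax.set_ylabel("tags/bp on peaks")
    return ax
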