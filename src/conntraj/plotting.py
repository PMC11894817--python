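"""Trajectory-band plotting."""

from __future__ import annotations

import numpy as np

from .posterior import TrajectoryWithBands


def plot_trajectory_bands(
    bands: TrajectoryWithBands,
    pair: tuple[int, int],
    ax=None,
    show_mean: bool = True,
):
    """Plot female/male mean-FC curves with 95% bands for one cluster pair.

    Male intervals are drawn dotted, female intervals dashed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    styles = {0: ("tab:red", "--", "female"), 1: ("tab:blue", ":", "male")}
    for sex, (color, ls, label) in styles.items():
        key = (pair[0], pair[1], sex)
        if show_mean:
            ax.plot(bands.ages, bands.mean[key], color=color, label=label)
        ax.plot(bands.ages, bands.lower[key], color=color, ls=ls, lw=1)
        ax.plot(bands.ages, bands.upper[key], color=color, ls=ls, lw=1)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("standardized FC")
    ax.set_title(f"cluster pair {pair}")
    ax.legend()
    return ax


def plot_similarity(psi: np.ndarray, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(psi, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.figure.colorbar(im, ax=ax, label="trajectory similarity")
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    return ax
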