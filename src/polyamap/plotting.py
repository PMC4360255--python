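"""Optional matplotlib rendering of composition profiles and motif traces.

Logos are drawn as stacked bars whose segment heights are the per-position
letter heights (frequency x information content); composition profiles as
per-base frequency traces over site coordinates, the site marked at +1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .composition import BASES, BaseFrequencyMatrix, seqlogo_heights
from .motifs import MotifPositionProfile

_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_composition(matrix: BaseFrequencyMatrix, ax=None, percent: bool = True):
    """Line plot of per-position base frequencies (one trace per base)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    scale = 100.0 if percent else 1.0
    x = np.arange(matrix.W)
    for base in BASES:
        label = "T/U" if base == "T" else base
        ax.plot(x, scale * matrix.base_freq(base), label=label, color=_COLORS[base], lw=1.2)
    _site_axis(ax, matrix.positions)
    ax.set_ylabel("base frequency (%)" if percent else "base frequency")
    ax.legend(loc="upper left", ncol=4, frameon=False)
    return ax


def plot_seqlogo_bars(
    matrix: BaseFrequencyMatrix, window: Optional[tuple[int, int]] = None, ax=None
):
    """Stacked-bar logo: per-position letters as colored segments whose
    total height is the information content in bits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    heights = seqlogo_heights(matrix)
    positions = matrix.positions
    if window is not None:
        keep = (positions >= window[0]) & (positions <= window[1])
        heights, positions = heights[:, keep], positions[keep]
    x = np.arange(len(positions))
    bottom = np.zeros(len(positions))
    for j, base in enumerate(BASES):
        order = np.argsort(heights, axis=0)  # small letters at the bottom
        seg = np.take_along_axis(heights, order, axis=0)[j]
        letters = np.array(list(BASES))[order[j]]
        for i in range(len(positions)):
            ax.bar(
                x[i], seg[i], bottom=bottom[i], width=0.9,
                color=_COLORS[letters[i]], edgecolor="none",
            )
        bottom += seg
    _site_axis(ax, positions)
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    return ax


def plot_motif_profile(profile: MotifPositionProfile, ax=None):
    """Per-position first-base frequency trace of one motif."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(profile.positions))
    ax.plot(x, profile.pct, lw=1.2, color="#444444")
    _site_axis(ax, profile.positions)
    ax.set_ylabel(f"% sites with {profile.motif.replace('T', 'U')}")
    return ax


def _site_axis(ax, positions) -> None:
    positions = np.asarray(positions)
    ticks = [p for p in (-100, -75, -50, -25, -1, 1, 25, 50, 75, 101) if p in positions]
    idx = [int(np.flatnonzero(positions == t)[0]) for t in ticks]
    ax.set_xticks(idx, [str(t) for t in ticks])
    if 1 in positions:
        ax.axvline(float(np.flatnonzero(positions == 1)[0]), color="0.7", ls="--", lw=0.8)
    ax.set_xlabel("position relative to poly(A) site")
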