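"""Simple plots: element-size histogram and conservation profile."""

from __future__ import annotations

import numpy as np

from .evolution import ConservationProfile


def plot_size_histogram(counts: np.ndarray, bin_width: int = 100, ax=None):
    """Bar plot of element counts per size bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    edges = np.arange(len(counts)) * bin_width
    ax.bar(edges, counts, width=bin_width * 0.9, align="edge", color="#4878a8")
    ax.set_xlabel("element size (bp)")
    ax.set_ylabel("count")
    return ax


def plot_conservation(profile: ConservationProfile, ax=None):
    """Line plot of per-window conservation scores."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.starts, profile.scores, lw=1.2, color="#a84848")
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("alignment position (nt)")
    ax.set_ylabel(f"mean similarity / {profile.window} nt")
    return ax
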