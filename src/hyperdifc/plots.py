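"""Figure helpers: significant-timepoint heatmap and dIFC trend curves."""

from __future__ import annotations

import numpy as np

from .groupstats import AnovaMap, cubic_trend


def plot_sig_heatmap(amap: AnovaMap, ax=None):
    """Heatmap of per-channel-pair counts of significant timepoints."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    counts = amap.sig_count
    im = ax.imshow(counts, cmap="Reds", aspect="auto")
    ax.set_xticks(range(len(amap.female_channels)),
                  amap.female_channels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(amap.male_channels)), amap.male_channels,
                  fontsize=6)
    ax.set_xlabel("female electrode")
    ax.set_ylabel("male electrode")
    ax.figure.colorbar(im, ax=ax, label="significant timepoints")
    return ax


def plot_difc_trend(tp: np.ndarray, series: dict[str, np.ndarray], ax=None,
                    n_dense: int = 200):
    """Cell-mean dIFC trajectories with cubic-interpolated trend lines.

    ``series`` maps a legend label (e.g. ``"lover / hand-on"``) to the mean
    r value at each timepoint in ``tp``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    tp = np.asarray(tp, dtype=float)
    dense = np.linspace(tp.min(), tp.max(), n_dense)
    for label, vals in series.items():
        spline = cubic_trend(tp, vals)
        line, = ax.plot(dense, spline(dense), label=label)
        ax.plot(tp, vals, "o", ms=3, color=line.get_color())
    ax.set_xlabel("timepoint")
    ax.set_ylabel("mean inter-brain r")
    ax.legend(fontsize=8)
    return ax
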