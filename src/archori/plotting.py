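"""Disparity-curve figures with replication-gene and prediction marks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .gene_roles import replication_genes  # noqa: E402
from .zcurve import COMPONENTS  # noqa: E402

_LABELS = {"at": "AT disparity (A−T)", "gc": "GC disparity (G−C)",
           "ry": "RY disparity (R−Y)", "mk": "MK disparity (M−K)"}


def plot_disparity_curves(profile, genome=None, predictions=None, path=None):
    """One panel per disparity curve; vertical red ticks mark replication
    genes, black arrows the predicted origin regions."""
    fig, axes = plt.subplots(len(COMPONENTS), 1, sharex=True,
                             figsize=(9, 2.1 * len(COMPONENTS)))
    for ax, comp in zip(axes, COMPONENTS):
        curve = profile.curve(comp) / (2.0 if comp in ("at", "gc") else 1.0)
        ax.plot(range(profile.n + 1), curve, lw=0.8, color="C0")
        ax.set_ylabel(_LABELS[comp], fontsize=8)
        if genome is not None:
            for g in replication_genes(genome):
                ax.axvline(g.start, color="red", lw=0.8, alpha=0.8)
        if predictions:
            ylim = ax.get_ylim()
            for p in predictions:
                mid = p.region.midpoint()
                ax.annotate("", xy=(mid, ylim[0]),
                            xytext=(mid, ylim[0] + 0.15 * (ylim[1] - ylim[0])),
                            arrowprops=dict(arrowstyle="->", color="black"))
    axes[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
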