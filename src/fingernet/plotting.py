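"""Score plots for discriminant models."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .design import StudyDesign  # noqa: E402

__all__ = ["score_plot"]

_PALETTE = [
    "#2ca02c", "#ffb347", "#ff7f0e", "#8b0000", "#1f77b4", "#9467bd", "#17becf",
]


def score_plot(results, design: StudyDesign, components=(0, 1), path=None, title=None):
    """Two-dimensional PLS-DA (or PCA) score plot with group coloring.

    ``results`` needs a ``scores`` array (samples x components).  Returns
    the matplotlib figure; saves to ``path`` when given.
    """
    T = results.scores
    a, b = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for j, g in enumerate(design.groups):
        mask = design.labels == g
        marker = "*" if g != design.control_group else "o"
        ax.scatter(
            T[mask, a], T[mask, b],
            label=f"{g} (N={mask.sum()})",
            color=_PALETTE[j % len(_PALETTE)],
            marker=marker, s=60, edgecolors="k", linewidths=0.3,
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"t[{a + 1}]")
    ax.set_ylabel(f"t[{b + 1}]")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
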