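"""Minimal morphospace scatter utility."""

from __future__ import annotations

import pandas as pd


def plot_scores(scores: pd.DataFrame, groups: pd.Series, x: str, y: str, path=None):
    """Scatter two ordination axes coloured by group; returns the Axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = pd.Series(groups).reindex(scores.index)
    for grp, sub in scores.groupby(groups):
        ax.scatter(sub[x], sub[y], label=str(grp), s=25, alpha=0.8)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
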