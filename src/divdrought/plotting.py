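"""Plotting helpers for the moving-window results (optional, needs matplotlib)."""

from __future__ import annotations

import pandas as pd

__all__ = ["scatter_density"]


def scatter_density(blocks: pd.DataFrame, covariate: str = "mean_ai", ax=None):
    """Hexbin scatter of block diversity-sensitivity correlations against a
    block-mean dryness covariate, with the zero line marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.hexbin(blocks[covariate], blocks["r"], gridsize=25, cmap="viridis", mincnt=1)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(covariate)
    ax.set_ylabel("diversity-sensitivity correlation r")
    return ax
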