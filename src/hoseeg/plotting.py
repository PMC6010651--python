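"""Contour plots of bispectrum magnitude and bicoherence on the bi-frequency plane."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .hos import BicoherenceEstimate, BispectrumEstimate


def plot_bifrequency_contour(
    estimate: BispectrumEstimate | BicoherenceEstimate,
    path: str | Path | None = None,
    levels: int = 12,
    title: str | None = None,
):
    """Contour plot of |B(f1, f2)| or bicoherence over the non-negative grid.

    Returns the matplotlib figure; saves it to ``path`` if given.
    """
    values = np.abs(estimate.values)
    f = estimate.grid.freq_axis
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    cs = ax.contour(f, f, values.T, levels=levels, cmap="viridis")
    ax.plot([0, f[-1] / 2], [0, f[-1] / 2], lw=0.5, color="grey")
    ax.set_xlabel("f1 (Hz)")
    ax.set_ylabel("f2 (Hz)")
    kind = "bicoherence" if isinstance(estimate, BicoherenceEstimate) else "|bispectrum|"
    ax.set_title(title or kind)
    fig.colorbar(cs, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
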