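"""Plotting helpers (orthogonal slice mosaics).

Matplotlib is imported lazily so headless batch use never needs a display;
callers writing files should rely on the Agg backend being selected when no
display is present.
"""

from __future__ import annotations

import numpy as np

from .volume import ImageVolume

__all__ = ["plot_slices", "plot_overlap"]


def plot_slices(
    vol: ImageVolume,
    n_slices: int = 6,
    axis: int = 2,
    cmap: str = "gray",
    title: str | None = None,
    out_path=None,
):
    """Evenly spaced slices along one axis; returns the figure."""
    import matplotlib

    if out_path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    idx = np.linspace(0, vol.shape[axis] - 1, n_slices + 2)[1:-1].astype(int)
    fig, axes = plt.subplots(1, n_slices, figsize=(2.2 * n_slices, 2.5))
    for ax, k in zip(np.atleast_1d(axes), idx):
        sl = np.take(vol.data, k, axis=axis)
        ax.imshow(np.asarray(sl, dtype=float).T, cmap=cmap, origin="lower")
        ax.set_title(f"slice {k}", fontsize=8)
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def plot_overlap(overlap: ImageVolume, out_path=None, n_slices: int = 6):
    """Lesion-frequency overlap map (fraction of subjects per voxel)."""
    return plot_slices(
        overlap,
        n_slices=n_slices,
        cmap="hot",
        title="WMH overlap (fraction of subjects)",
        out_path=out_path,
    )
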