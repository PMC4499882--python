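"""Rose plots and frequency-map rendering (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def rose_plot(
    angles_deg: np.ndarray,
    path: str | Path,
    n_bins: int = 24,
    axial: bool = False,
    reference_angle: float | None = None,
) -> None:
    """Polar histogram of angles; axial data is mirrored across the origin
    so each orientation appears at theta and theta + 180."""
    ang = np.asarray(angles_deg, float) % (180.0 if axial else 360.0)
    if axial:
        ang = np.concatenate([ang, ang + 180.0])
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(ang % 360.0, bins=edges)
    centers = np.radians(0.5 * (edges[:-1] + edges[1:]))
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.bar(centers, counts, width=np.radians(360.0 / n_bins),
           color="#4878a8", edgecolor="white", linewidth=0.5)
    if reference_angle is not None:
        ax.axvline(np.radians(reference_angle), color="red", lw=1.5)
        if axial:
            ax.axvline(np.radians(reference_angle + 180.0), color="red", lw=1.5)
    ax.set_yticklabels([])
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def frequency_map_png(frequency: np.ndarray, path: str | Path) -> None:
    """Colour-coded per-pixel occupancy frequency in [0, 1]."""
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(frequency, cmap="inferno", vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="occupancy frequency")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)
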