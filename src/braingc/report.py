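"""Reporting: formatted summary tables and degree topographic maps.

A topomap projects a per-channel scalar (here, node degree) onto standard
10-20 electrode positions, interpolated across the scalp disc — the usual
way channel-level network changes are displayed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

__all__ = ["montage_positions", "plot_topomap", "save_comparison_table"]


def montage_positions(labels: tuple[str, ...]) -> np.ndarray:
    """2-D scalp-plane coordinates for 10-20 labels (x right, y anterior)."""
    import mne

    montage = mne.channels.make_standard_montage("standard_1020")
    pos3d = montage.get_positions()["ch_pos"]
    lookup = {k.upper(): v for k, v in pos3d.items()}
    out = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        key = lab.upper()
        if key not in lookup:
            raise KeyError(f"channel '{lab}' not in the standard 10-20 montage")
        out[i] = lookup[key][:2]
    scale = np.abs(out).max()
    return out / (scale if scale > 0 else 1.0)


def plot_topomap(
    values: np.ndarray,
    labels: tuple[str, ...],
    path: str | Path,
    title: str = "",
    cmap: str = "viridis",
) -> Path:
    """Render a per-channel scalar map to an image file."""
    pos = montage_positions(labels)
    grid_x, grid_y = np.meshgrid(np.linspace(-1.1, 1.1, 120), np.linspace(-1.1, 1.1, 120))
    interp = griddata(pos, np.asarray(values, dtype=float), (grid_x, grid_y), method="cubic")
    outside = grid_x**2 + grid_y**2 > 1.1**2
    interp[outside] = np.nan

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(grid_x, grid_y, interp, shading="auto", cmap=cmap)
    ax.add_patch(plt.Circle((0, 0), 1.1, fill=False, lw=1.5))
    ax.plot([-0.1, 0, 0.1], [1.08, 1.2, 1.08], color="k", lw=1.5)  # nose
    ax.scatter(pos[:, 0], pos[:, 1], s=12, c="k", zorder=3)
    for (x, y), lab in zip(pos, labels):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(3, 3), fontsize=7)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.75)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_comparison_table(comparisons, path: str | Path) -> Path:
    """Write a list of StateComparison results as a delimited table."""
    import pandas as pd

    rows = [
        {
            "metric": c.metric_name,
            "state_a": c.state_pair[0],
            "state_b": c.state_pair[1],
            "n_subjects": c.n_subjects,
            "mean_a": c.mean_a,
            "mean_b": c.mean_b,
            "t": c.t_statistic,
            "p": c.p_value,
            "change_rate_pct": c.mean_change_rate,
        }
        for c in comparisons
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path
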