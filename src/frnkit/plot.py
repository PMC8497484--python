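"""Scalp-map rendering hooks (matplotlib, loaded lazily).

Cluster and encoder results can be visualized as per-timepoint scalp
topographies: electrodes are azimuthally projected to the plane and the
value at each electrode is interpolated onto a disc grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layout import ChannelLayout


def _project(layout: ChannelLayout) -> np.ndarray:
    """Azimuthal-equidistant projection of scalp electrodes to 2-D."""
    idx = layout.scalp_indices
    pos = layout.positions[idx]
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))  # polar angle from Cz
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def render_topomap(
    values: np.ndarray,
    layout: ChannelLayout,
    path: str | Path,
    title: str = "",
    cmap: str = "RdBu_r",
    vlim: float | None = None,
) -> Path:
    """Write a single scalp topography image.

    ``values`` has one entry per scalp channel (layout order).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    xy = _project(layout)
    values = np.asarray(values, float)
    if len(values) != len(xy):
        raise ValueError("need one value per scalp channel")
    r = np.abs(xy).max() * 1.05
    grid = np.linspace(-r, r, 120)
    gx, gy = np.meshgrid(grid, grid)
    gz = griddata(xy, values, (gx, gy), method="cubic")
    gz[np.hypot(gx, gy) > r] = np.nan
    vlim = vlim or max(1e-12, np.nanmax(np.abs(values)))

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(gx, gy, gz, cmap=cmap, vmin=-vlim, vmax=vlim,
                       shading="auto")
    ax.scatter(xy[:, 0], xy[:, 1], s=6, c="k")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_map_series(
    value_map: np.ndarray,
    times: np.ndarray,
    layout: ChannelLayout,
    outdir: str | Path,
    prefix: str = "topo",
    step: int = 1,
) -> list[Path]:
    """Write one topography per (stride of) timepoint for a scalp map."""
    outdir = Path(outdir)
    paths = []
    vlim = max(1e-12, float(np.nanmax(np.abs(value_map))))
    for j in range(0, value_map.shape[1], step):
        paths.append(
            render_topomap(
                value_map[:, j], layout,
                outdir / f"{prefix}_{int(round(times[j])):+05d}ms.png",
                title=f"{times[j]:.0f} ms", vlim=vlim,
            )
        )
    return paths
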