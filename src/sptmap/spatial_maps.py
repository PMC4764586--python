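"""Gridded local-diffusion heat maps and localization density maps.

The local-diffusion map evaluates an apparent diffusion coefficient on a
fine spatial grid (20 nm default): every lag-1 displacement is assigned
to each grid node within a capture radius (80 nm default) of the
displacement's *origin* point, and a node with at least
``min_displacements`` assigned displacements gets the value
mean(r²)/(4Δt).  Because the capture radius exceeds the grid spacing,
one displacement feeds several nodes — deliberate smoothing.  Nodes live
on the absolute grid (integer multiples of the spacing), so translating
all positions by one spacing translates the map by exactly one node.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from sptmap.diffusion import DisplacementSet, collect_displacements

__all__ = ["DiffusionMap", "DensityMap", "local_diffusion_map", "density_map"]


@dataclass
class DiffusionMap:
    """Sparse local apparent-D map: one row per defined grid node."""

    node_x: np.ndarray  # μm
    node_y: np.ndarray  # μm
    values: np.ndarray  # μm²/s
    counts: np.ndarray
    grid_spacing: float
    capture_radius: float
    min_displacements: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_x_um": self.node_x, "node_y_um": self.node_y,
             "D_um2_s": self.values, "n_displacements": self.counts}
        )

    def plot(self, path=None, vmax=None):
        """Scatter-render the defined nodes; undefined nodes stay blank."""
        fig, ax = plt.subplots(figsize=(6, 6))
        sc = ax.scatter(
            self.node_x, self.node_y, c=self.values, s=4, marker="s",
            cmap="inferno", vmin=0.0, vmax=vmax,
        )
        ax.invert_yaxis()
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax, label="local apparent D (μm²/s)")
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


@dataclass
class DensityMap:
    """2-D localization histogram (half-open bins)."""

    counts: np.ndarray  # [iy, ix]
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def local_diffusion_map(
    tracks_or_displacements: pd.DataFrame | DisplacementSet,
    frame_interval: float = 0.035,
    grid_spacing: float = 0.020,
    capture_radius: float = 0.080,
    min_displacements: int = 5,
) -> DiffusionMap:
    """Build the gridded local apparent-diffusion map.

    Accepts either a trajectory table (lag-1 displacements are collected
    internally) or a pre-collected :class:`DisplacementSet`.
    """
    if isinstance(tracks_or_displacements, DisplacementSet):
        d = tracks_or_displacements
    else:
        d = collect_displacements(
            tracks_or_displacements, 1, frame_interval=frame_interval
        )
    dt = d.lag
    if len(d) == 0:
        empty = np.array([])
        return DiffusionMap(
            empty, empty, empty, np.array([], dtype=np.int64),
            grid_spacing, capture_radius, min_displacements,
        )

    ox, oy, r2 = d.origin_x, d.origin_y, np.square(d.values)
    base_i = np.floor(ox / grid_spacing).astype(np.int64)
    base_j = np.floor(oy / grid_spacing).astype(np.int64)
    m = int(np.ceil(capture_radius / grid_spacing)) + 1

    node_i_parts, node_j_parts, r2_parts = [], [], []
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            ni = base_i + di
            nj = base_j + dj
            dist2 = (ni * grid_spacing - ox) ** 2 + (nj * grid_spacing - oy) ** 2
            sel = dist2 <= capture_radius**2
            if sel.any():
                node_i_parts.append(ni[sel])
                node_j_parts.append(nj[sel])
                r2_parts.append(r2[sel])

    ni = np.concatenate(node_i_parts)
    nj = np.concatenate(node_j_parts)
    rr = np.concatenate(r2_parts)
    agg = (
        pd.DataFrame({"i": ni, "j": nj, "r2": rr})
        .groupby(["i", "j"], sort=True)["r2"]
        .agg(["count", "mean"])
        .reset_index()
    )
    agg = agg[agg["count"] >= min_displacements]
    return DiffusionMap(
        node_x=agg["i"].to_numpy() * grid_spacing,
        node_y=agg["j"].to_numpy() * grid_spacing,
        values=agg["mean"].to_numpy() / (4.0 * dt),
        counts=agg["count"].to_numpy().astype(np.int64),
        grid_spacing=grid_spacing,
        capture_radius=capture_radius,
        min_displacements=min_displacements,
    )


def density_map(
    localizations: pd.DataFrame | np.ndarray,
    bin_size: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> DensityMap:
    """2-D histogram of localizations (not tracks) with half-open bins.

    ``localizations`` is a trajectory table (``x_um``/``y_um`` columns)
    or an (n, 2) array.  ``bounds`` = (x0, x1, y0, y1); by default the
    bin grid is extended past the data so every point — including one
    exactly on the outer edge — lands in exactly one bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if isinstance(localizations, pd.DataFrame):
        x = localizations.x_um.to_numpy()
        y = localizations.y_um.to_numpy()
    else:
        arr = np.asarray(localizations, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if bounds is None:
        if len(x) == 0:
            x0 = y0 = 0.0
            x1 = y1 = bin_size
        else:
            x0 = np.floor(x.min() / bin_size) * bin_size
            y0 = np.floor(y.min() / bin_size) * bin_size
            x1 = (np.floor(x.max() / bin_size) + 1) * bin_size
            y1 = (np.floor(y.max() / bin_size) + 1) * bin_size
    else:
        x0, x1, y0, y1 = bounds
    x_edges = np.arange(x0, x1 + bin_size / 2, bin_size)
    y_edges = np.arange(y0, y1 + bin_size / 2, bin_size)
    counts, _, _ = np.histogram2d(y, x, bins=[y_edges, x_edges])
    return DensityMap(
        counts=counts.astype(np.int64), x_edges=x_edges, y_edges=y_edges,
        bin_size=bin_size,
    )
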