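"""Two-dimensional free-energy landscape over (RMSD, Rg).

Frames are binned on the two reaction coordinates and the occupancy
histogram is Boltzmann-inverted,

    G_i = -k_B T ln(N_i / N_max),

so the modal bin sits at G = 0 and every other populated bin at a
positive free energy (kJ/mol, k_B = 0.0083145 kJ/mol/K, T = 300 K by
default).  Empty bins are assigned an artificial barrier energy (the
maximum finite G plus 2 k_B T) so the landscape is finite everywhere.
Basins are local minima of G on populated bins; each basin carries its
member frames and a representative frame closest to the bin centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, LandscapeError
from .geometry import ScalarSeries

__all__ = ["KB_KJ_PER_MOL_K", "LandscapeGrid", "Basin", "compute_fel",
           "extract_basins"]

KB_KJ_PER_MOL_K = 0.0083145


@dataclass
class LandscapeGrid:
    """2-D occupancy histogram with Gibbs energies."""

    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    counts: np.ndarray        # (n_rmsd_bins, n_rg_bins), ints
    G: np.ndarray             # kJ/mol, 0 at the modal bin
    temperature: float
    empty_bin_energy: float

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def bin_centers(self):
        return (
            0.5 * (self.rmsd_edges[:-1] + self.rmsd_edges[1:]),
            0.5 * (self.rg_edges[:-1] + self.rg_edges[1:]),
        )

    def to_long_format(self):
        """(rmsd_center, rg_center, count, G) rows for plotting/export."""
        import pandas as pd

        rc, gc = self.bin_centers()
        rows = []
        for i in range(len(rc)):
            for j in range(len(gc)):
                rows.append((rc[i], gc[j], int(self.counts[i, j]),
                             self.G[i, j]))
        return pd.DataFrame(
            rows, columns=["rmsd_bin_center", "rg_bin_center", "count", "G"]
        )


@dataclass
class Basin:
    """One local minimum of the landscape."""

    bin_index: tuple
    member_frames: np.ndarray
    representative_frame: int
    G: float


def compute_fel(
    rmsd: ScalarSeries,
    rg: ScalarSeries,
    n_bins=(50, 50),
    temperature: float = 300.0,
) -> LandscapeGrid:
    """Free-energy landscape from paired RMSD and Rg series."""
    x = np.asarray(rmsd.values, dtype=float)
    y = np.asarray(rg.values, dtype=float)
    if len(x) != len(y):
        raise ConfigError(
            f"series length mismatch: {len(x)} RMSD vs {len(y)} Rg frames"
        )
    if len(x) < 1:
        raise ConfigError("need at least one frame")
    nb = (int(n_bins[0]), int(n_bins[1]))
    if min(nb) < 2:
        raise ConfigError("need at least 2 bins per axis")
    counts, rmsd_edges, rg_edges = np.histogram2d(x, y, bins=nb)
    counts = counts.astype(int)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        G = -KB_KJ_PER_MOL_K * temperature * np.log(
            np.where(counts > 0, counts / n_max, np.nan)
        )
    finite_max = np.nanmax(G)
    barrier = finite_max + 2.0 * KB_KJ_PER_MOL_K * temperature
    G = np.where(counts > 0, G, barrier)
    return LandscapeGrid(rmsd_edges, rg_edges, counts, G, temperature, barrier)


def _bin_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value, upper edge of the last bin inclusive."""
    idx = np.digitize(values, edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx


def extract_basins(
    grid: LandscapeGrid,
    rmsd: ScalarSeries,
    rg: ScalarSeries,
    max_basins: int = 2,
) -> list[Basin]:
    """Local minima of G on populated bins, ranked by G then population.

    A populated bin is a basin minimum when no 4-connected populated
    neighbour has strictly lower G.  Member frames are the frames that
    fall in the minimum bin; the representative frame is the member
    closest to the bin centre in bin-width units.
    """
    if grid.counts.sum() == 0:
        raise LandscapeError("landscape has no populated bins")
    x = np.asarray(rmsd.values, dtype=float)
    y = np.asarray(rg.values, dtype=float)
    ix = _bin_of(x, grid.rmsd_edges)
    iy = _bin_of(y, grid.rg_edges)

    populated = np.argwhere(grid.counts > 0)
    minima = []
    for i, j in populated:
        g0 = grid.G[i, j]
        best = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (0 <= ni < grid.counts.shape[0]
                    and 0 <= nj < grid.counts.shape[1]
                    and grid.counts[ni, nj] > 0
                    and grid.G[ni, nj] < g0):
                best = False
                break
        if best:
            minima.append((g0, -int(grid.counts[i, j]), (int(i), int(j))))
    minima.sort()

    basins = []
    rc, gc = grid.bin_centers()
    wx = grid.rmsd_edges[1] - grid.rmsd_edges[0]
    wy = grid.rg_edges[1] - grid.rg_edges[0]
    for g0, _, (i, j) in minima[:max_basins]:
        members = np.flatnonzero((ix == i) & (iy == j))
        d = np.hypot((x[members] - rc[i]) / wx, (y[members] - gc[j]) / wy)
        rep = int(members[int(np.argmin(d))])
        basins.append(Basin((i, j), members, rep, float(g0)))
    return basins
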