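"""Orientation bitmaps and structural observers (defects, domains).

The simulated end-states are inspected the way the original bitmap analysis
was done: the box is divided into cells of roughly one lattice constant,
each cell is colored by the mean orientation of the dipoles it contains,
dopants are marked, and empty cells appear as voids.  Two scalar observers
quantify what the bitmaps show qualitatively: the number of void cells
(defects) and the fraction of aligned nearest-neighbor pairs (domains).
All observers are pure: they never mutate the state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ParseError
from .lattice import MembraneState

TWO_PI = 2.0 * math.pi


@dataclass
class OrientationRaster:
    """Grid summary of a state: occupancy, mean angle, and dopant flags."""

    occupancy: np.ndarray  # (gx, gy) int, dipole centers per cell
    mean_angle: np.ndarray  # (gx, gy) float in [0, 2pi), nan where empty
    dopant: np.ndarray  # (gx, gy) bool
    cell_size: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrientationRaster):
            return NotImplemented
        return (
            self.cell_size == other.cell_size
            and np.array_equal(self.occupancy, other.occupancy)
            and np.array_equal(self.mean_angle, other.mean_angle, equal_nan=True)
            and np.array_equal(self.dopant, other.dopant)
        )

    @property
    def n_empty_cells(self) -> int:
        return int((self.occupancy == 0).sum())


def rasterize(state: MembraneState, cell_size: float | None = None) -> OrientationRaster:
    """Bin dipoles into cells; per-cell circular-mean orientation."""
    cell = cell_size if cell_size is not None else state.params.spacing
    if cell <= 0:
        raise ConfigurationError(f"cell size must be positive, got {cell}")
    w, h = state.box
    gx, gy = max(1, int(round(w / cell))), max(1, int(round(h / cell)))
    occ = np.zeros((gx, gy), dtype=int)
    sin_sum = np.zeros((gx, gy))
    cos_sum = np.zeros((gx, gy))
    ix = np.clip((state.dip_pos[:, 0] / w * gx).astype(int), 0, gx - 1)
    iy = np.clip((state.dip_pos[:, 1] / h * gy).astype(int), 0, gy - 1)
    np.add.at(occ, (ix, iy), 1)
    np.add.at(sin_sum, (ix, iy), np.sin(state.dip_alpha))
    np.add.at(cos_sum, (ix, iy), np.cos(state.dip_alpha))
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(sin_sum, cos_sum) % TWO_PI
    ang[occ == 0] = np.nan
    dop = np.zeros((gx, gy), dtype=bool)
    if state.n_dopants:
        jx = np.clip((state.dop_pos[:, 0] / w * gx).astype(int), 0, gx - 1)
        jy = np.clip((state.dop_pos[:, 1] / h * gy).astype(int), 0, gy - 1)
        dop[jx, jy] = True
    return OrientationRaster(occupancy=occ, mean_angle=ang, dopant=dop, cell_size=cell)


def render_bitmap(
    state: MembraneState, path: str | None = None, cell_size: float | None = None
) -> OrientationRaster:
    """Rasterize the state and, if ``path`` is given, write a PNG bitmap.

    Orientation maps to hue on a cyclic colormap anchored so angle 0 (the +x
    axis) is red; empty cells render black, dopant cells carry a white dot.
    """
    raster = rasterize(state, cell_size)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        gx, gy = raster.occupancy.shape
        img = np.zeros((gy, gx, 3))
        hue = (raster.mean_angle.T % TWO_PI) / TWO_PI
        filled = raster.occupancy.T > 0
        cmap = plt.get_cmap("hsv")
        img[filled] = cmap(hue[filled])[:, :3]
        fig, ax = plt.subplots(figsize=(5, 5 * gy / max(gx, 1)))
        ax.imshow(img, origin="lower", interpolation="nearest")
        if raster.dopant.any():
            jy, jx = np.nonzero(raster.dopant.T)
            ax.scatter(jx, jy, s=18, c="white", edgecolors="black", linewidths=0.5)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return raster


def defect_metric(state: MembraneState, cell_size: float | None = None) -> int:
    """Number of raster cells containing no dipole center (void/defect count)."""
    return rasterize(state, cell_size).n_empty_cells


def domain_statistic(state: MembraneState, angle_threshold: float = math.pi / 2) -> float:
    """Fraction of nearest-neighbor dipole pairs aligned within ``angle_threshold``.

    Neighbors are pairs closer than 1.5 lattice constants; the orientation
    difference is circular (in [0, pi]).  For i.i.d. uniform orientations the
    expectation is ``angle_threshold / pi``; domain formation during
    equilibration raises the statistic above that baseline.
    """
    if not 0 < angle_threshold < math.pi:
        raise ConfigurationError(
            f"angle_threshold must lie in (0, pi), got {angle_threshold}"
        )
    tree = cKDTree(state.dip_pos)
    pairs = tree.query_pairs(1.5 * state.params.spacing, output_type="ndarray")
    if len(pairs) == 0:
        return float("nan")
    diff = np.abs(state.dip_alpha[pairs[:, 0]] - state.dip_alpha[pairs[:, 1]]) % TWO_PI
    circ = np.minimum(diff, TWO_PI - diff)
    return float(np.mean(circ < angle_threshold))


# ----------------------------------------------------------------------
# Diff-friendly plain-text raster dump
# ----------------------------------------------------------------------

_RASTER_MAGIC = "# membranemc raster v1"


def save_raster(raster: OrientationRaster, path: str) -> None:
    gx, gy = raster.occupancy.shape
    lines = [_RASTER_MAGIC, f"dims {gx} {gy}", f"cell_size {raster.cell_size!r}"]
    for i in range(gx):
        for j in range(gy):
            ang = raster.mean_angle[i, j]
            lines.append(
                f"{i} {j} {raster.occupancy[i, j]} "
                f"{'nan' if np.isnan(ang) else repr(float(ang))} "
                f"{int(raster.dopant[i, j])}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_raster(path: str) -> OrientationRaster:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0] != _RASTER_MAGIC:
        raise ParseError(f"{path!r}: missing raster header")
    try:
        _, gx, gy = lines[1].split()
        gx, gy = int(gx), int(gy)
        cell = float(lines[2].split()[1])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path!r}: malformed raster header: {exc}") from exc
    occ = np.zeros((gx, gy), dtype=int)
    ang = np.full((gx, gy), np.nan)
    dop = np.zeros((gx, gy), dtype=bool)
    for ln in lines[3:]:
        tok = ln.split()
        if len(tok) != 5:
            raise ParseError(f"malformed raster cell record: {ln!r}")
        i, j = int(tok[0]), int(tok[1])
        occ[i, j] = int(tok[2])
        ang[i, j] = float(tok[3])
        dop[i, j] = bool(int(tok[4]))
    return OrientationRaster(occupancy=occ, mean_angle=ang, dopant=dop, cell_size=cell)
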