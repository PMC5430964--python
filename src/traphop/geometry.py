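"""Slit-confined hexagonal micropost array geometry.

Cylindrical posts of radius ``R`` span a slit of height ``H`` and sit on a
triangular (hexagonal) lattice with surface-to-surface nearest gap ``d``, so
the center-to-center lattice constant is ``a = 2R + d``.  The periodic
in-plane supercell is built from the standard rectangular two-post cell of the
triangular lattice, ``a x a*sqrt(3)``, repeated ``n_cells_x x n_cells_y``
times; the slit plane is x-y and the wall-normal axis is z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or inconsistent cell counts."""


@dataclass(frozen=True)
class PostArrayGeometry:
    """Periodic hexagonal post array inside a slit.

    All lengths are in simulation units (sigma) unless the caller maps them
    with a :class:`~traphop.units.UnitMap`.
    """

    post_radius_R: float
    gap_d: float
    slit_height_H: float
    n_cells_x: int = 1
    n_cells_y: int = 1
    post_centers: np.ndarray = field(repr=False, default=None)
    box: np.ndarray = field(repr=False, default=None)

    @property
    def lattice_constant(self) -> float:
        """Center-to-center nearest-neighbour post spacing, 2R + d."""
        return 2.0 * self.post_radius_R + self.gap_d

    @property
    def cell_dimensions(self) -> np.ndarray:
        """Rectangular two-post unit cell, (a, a*sqrt(3))."""
        a = self.lattice_constant
        return np.array([a, a * math.sqrt(3.0)])

    def gap_over_rg(self, r_g: float) -> float:
        """Dimensionless gap d/Rg used to compare arrays across chain sizes."""
        return self.gap_d / r_g

    def to_dict(self) -> dict:
        """Plain key-value form for YAML serialization (no arrays)."""
        return {
            "post_radius_R": float(self.post_radius_R),
            "gap_d": float(self.gap_d),
            "slit_height_H": float(self.slit_height_H),
            "n_cells_x": int(self.n_cells_x),
            "n_cells_y": int(self.n_cells_y),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PostArrayGeometry":
        return build_hex_array(
            d["post_radius_R"],
            d["gap_d"],
            d["slit_height_H"],
            n_cells_x=d.get("n_cells_x", 1),
            n_cells_y=d.get("n_cells_y", 1),
        )


def build_hex_array(
    post_radius_R: float,
    gap_d: float,
    slit_height_H: float,
    n_cells_x: int = 1,
    n_cells_y: int = 1,
) -> PostArrayGeometry:
    """Construct a periodic hexagonal post array.

    Parameters
    ----------
    post_radius_R, gap_d, slit_height_H : float
        Post radius, surface-to-surface gap and slit height (sigma), all > 0.
    n_cells_x, n_cells_y : int
        Number of rectangular two-post cells tiled along x and y.

    Returns
    -------
    PostArrayGeometry
        With ``post_centers`` (M x 2) inside the periodic ``box`` whose
        dimensions are integer multiples of the rectangular cell, so
        minimum-image distances are consistent.
    """
    if not (post_radius_R > 0 and gap_d > 0 and slit_height_H > 0):
        raise InvalidGeometryError(
            f"all dimensions must be positive: R={post_radius_R}, "
            f"d={gap_d}, H={slit_height_H}"
        )
    if n_cells_x < 1 or n_cells_y < 1:
        raise InvalidGeometryError(
            f"n_cells must be >= 1 in each direction, got ({n_cells_x}, {n_cells_y})"
        )
    a = 2.0 * post_radius_R + gap_d
    cell = np.array([a, a * math.sqrt(3.0)])
    # two posts per rectangular cell: corner and body centre
    base = np.array([[0.0, 0.0], [0.5 * a, 0.5 * a * math.sqrt(3.0)]])
    centers = []
    for ix in range(n_cells_x):
        for iy in range(n_cells_y):
            centers.append(base + np.array([ix, iy]) * cell)
    post_centers = np.vstack(centers)
    box = cell * np.array([n_cells_x, n_cells_y])
    return PostArrayGeometry(
        post_radius_R=post_radius_R,
        gap_d=gap_d,
        slit_height_H=slit_height_H,
        n_cells_x=n_cells_x,
        n_cells_y=n_cells_y,
        post_centers=post_centers,
        box=box,
    )


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold in-plane displacement vectors into the nearest periodic image."""
    v = np.asarray(vectors, dtype=float)
    return v - box * np.round(v / box)


def nearest_post_distance(points: np.ndarray, geometry: PostArrayGeometry) -> np.ndarray:
    """In-plane distance from each point to the nearest post *axis* (min image)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts[:, None, :] - geometry.post_centers[None, :, :]
    d = minimum_image(d, geometry.box)
    dist = np.sqrt((d**2).sum(axis=2)).min(axis=1)
    return dist if pts.shape[0] > 1 else dist.reshape(())


def write_post_centers(geometry: PostArrayGeometry, path) -> None:
    """Export post centers as two-column delimited text (x, y in sigma)."""
    header = (
        "post centers (sigma)\n"
        f"R={geometry.post_radius_R} d={geometry.gap_d} H={geometry.slit_height_H} "
        f"box={geometry.box[0]}x{geometry.box[1]}\nx\ty"
    )
    np.savetxt(path, geometry.post_centers, delimiter="\t", header=header)
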