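"""Cell geometries, meshes and the imposed receptor-activation field.

The cell is a 2D domain: an ellipse with major axis 40 um (semi-axis
a = 20) and minor axis 1.8 um (semi-axis b = 0.9), the dimensions of a
migrating fibroblast.  The membrane is the 1D boundary curve of the domain;
membrane species diffuse along arclength on the closed loop, cytosolic
species diffuse in the 2D interior.  Asymmetric variants blunt one end by
raising the y-term of the ellipse equation to the 6th power on that half.

Activated receptors are imposed (not dynamically modelled) as a linear
profile along the long axis::

    r(x) = 130 * rfrac * (1 + rsteep * x / 40)

so that ``rfrac`` is the midpoint occupancy fraction (``rfrac = 1`` gives
130 molecules/um^2, about 1e5 receptors/cell) and ``rsteep`` is the
fractional front-to-back difference.  The same value applies on the top and
bottom arcs at equal x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellGeometry", "StimulusSpec", "build_cell_geometry",
           "receptor_field", "SHAPES", "R_CHARACTERISTIC"]

#: characteristic activated-receptor density at rfrac = 1 (molecules/um^2)
R_CHARACTERISTIC = 130.0

SEMI_MAJOR = 20.0   # um
SEMI_MINOR = 0.9    # um
CELL_LENGTH = 40.0  # um

SHAPES = ("symmetric", "back_blunted", "front_blunted")


def _y_exponent(shape: str, x: np.ndarray) -> np.ndarray:
    """Exponent of the y-term: 6 on the blunted half, 2 elsewhere."""
    q = np.full_like(np.asarray(x, dtype=float), 2.0)
    if shape == "back_blunted":
        q[np.asarray(x) < 0] = 6.0
    elif shape == "front_blunted":
        q[np.asarray(x) > 0] = 6.0
    return q


def _half_width(shape: str, x: np.ndarray) -> np.ndarray:
    """|y| extent of the boundary at position x along the major axis."""
    x = np.asarray(x, dtype=float)
    t = np.clip(1.0 - (x / SEMI_MAJOR) ** 2, 0.0, None)
    q = _y_exponent(shape, x)
    return SEMI_MINOR * t ** (1.0 / q)


def _inside(shape: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    q = _y_exponent(shape, x)
    return (np.asarray(x) / SEMI_MAJOR) ** 2 + \
        np.abs(np.asarray(y) / SEMI_MINOR) ** q <= 1.0


@dataclass
class StimulusSpec:
    """Imposed receptor-activation profile."""

    rfrac: float
    rsteep: float = 0.0
    direction: int = +1   # +1: increasing toward +x; -1: reversed

    def __post_init__(self) -> None:
        if self.rfrac < 0:
            raise ValueError("rfrac must be >= 0")
        if abs(self.rsteep) >= 2:
            raise ValueError("|rsteep| must be < 2 to keep r >= 0 over the cell")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    def reversed(self) -> "StimulusSpec":
        return StimulusSpec(self.rfrac, self.rsteep, -self.direction)


@dataclass
class CellGeometry:
    """2D interior voxel mesh plus 1D membrane (boundary) mesh."""

    shape: str
    h: float
    # interior voxels
    xc: np.ndarray            # voxel-centre x (um), length n_voxels
    yc: np.ndarray            # voxel-centre y (um)
    voxel_area: float         # h^2 (um^2), unit depth assumed
    laplacian: sp.csr_matrix  # no-flux FV Laplacian over interior voxels (1/um^2)
    # membrane nodes (ordered closed loop)
    xs: np.ndarray            # node x (um), length n_nodes
    ys: np.ndarray            # node y (um)
    ds: np.ndarray            # node-centred segment length (um)
    boundary_voxel: np.ndarray  # index of the membrane-adjacent voxel per node
    # derived measures
    area: float = field(init=False)
    perimeter: float = field(init=False)

    def __post_init__(self) -> None:
        self.area = self.voxel_area * len(self.xc)
        self.perimeter = float(self.ds.sum())

    @property
    def n_voxels(self) -> int:
        return len(self.xc)

    @property
    def n_nodes(self) -> int:
        return len(self.xs)

    def membrane_laplacian(self) -> sp.csr_matrix:
        """Conservative FV Laplacian along arclength on the closed loop (1/um^2)."""
        n = self.n_nodes
        # distance between consecutive node centres
        dx = np.diff(self.xs, append=self.xs[:1])
        dy = np.diff(self.ys, append=self.ys[:1])
        dist = np.hypot(dx, dy)          # dist[i] = |node i -> node i+1|
        rows, cols, vals = [], [], []
        for i in range(n):
            j = (i + 1) % n
            w = 1.0 / dist[i]
            # flux between i and j, divided by each segment length
            rows += [i, i, j, j]
            cols += [i, j, j, i]
            vals += [-w / self.ds[i], w / self.ds[i],
                     -w / self.ds[j], w / self.ds[j]]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def probe_indices(self) -> tuple[int, int]:
        """Membrane node indices nearest x = +20 and x = -20 (right, left)."""
        return int(np.argmax(self.xs)), int(np.argmin(self.xs))

    def surface_to_volume_profile(self, nbins: int = 40) -> pd.DataFrame:
        """Local boundary length per interior area, binned along x."""
        edges = np.linspace(-SEMI_MAJOR, SEMI_MAJOR, nbins + 1)
        blen, _ = np.histogram(self.xs, bins=edges, weights=self.ds)
        varea, _ = np.histogram(self.xc, bins=edges,
                                weights=np.full(self.n_voxels, self.voxel_area))
        with np.errstate(divide="ignore", invalid="ignore"):
            sv = np.where(varea > 0, blen / varea, np.nan)
        return pd.DataFrame({"x": 0.5 * (edges[:-1] + edges[1:]),
                             "boundary_length": blen, "area": varea,
                             "surface_to_volume": sv})

    def to_node_table(self) -> pd.DataFrame:
        return pd.DataFrame({"node": np.arange(self.n_nodes), "x": self.xs,
                             "y": self.ys, "ds": self.ds,
                             "boundary_voxel": self.boundary_voxel})

    def to_voxel_table(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel": np.arange(self.n_voxels),
                             "x": self.xc, "y": self.yc})


def _interior_mesh(shape: str, h: float):
    """Voxel centres inside the cell and the no-flux FV Laplacian."""
    nx = int(np.ceil(SEMI_MAJOR / h))
    ny = int(np.ceil(SEMI_MINOR / h))
    gx = (np.arange(-nx, nx) + 0.5) * h
    gy = (np.arange(-ny, ny) + 0.5) * h
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    mask = _inside(shape, X, Y)
    idx = -np.ones(mask.shape, dtype=int)
    idx[mask] = np.arange(mask.sum())
    xc, yc = X[mask], Y[mask]
    rows, cols, vals = [], [], []
    w = 1.0 / h ** 2
    for axis_shift in ((1, 0), (0, 1)):
        shifted = np.roll(idx, shift=-1, axis=0 if axis_shift[0] else 1)
        if axis_shift[0]:
            shifted[-1, :] = -1
        else:
            shifted[:, -1] = -1
        pair = mask & (shifted >= 0)
        a, b = idx[pair], shifted[pair]
        rows += [a, a, b, b]
        cols += [a, b, b, a]
        vals += [np.full(len(a), -w), np.full(len(a), w),
                 np.full(len(a), -w), np.full(len(a), w)]
    lap = sp.csr_matrix((np.concatenate(vals),
                         (np.concatenate(rows), np.concatenate(cols))),
                        shape=(len(xc), len(xc)))
    return xc, yc, lap


def _boundary_nodes(shape: str, n_nodes: int):
    """Equal-arclength resampling of the analytic boundary curve."""
    # dense parameterisation: top arc left->right, bottom arc right->left
    t = np.linspace(-SEMI_MAJOR, SEMI_MAJOR, 20001)
    top = np.column_stack([t, _half_width(shape, t)])
    bot = np.column_stack([t[::-1], -_half_width(shape, t[::-1])])
    pts = np.vstack([top, bot[1:-1]])
    seg = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n_nodes, endpoint=False)
    xi = np.interp(target, s[:-1], pts[:, 0])
    yi = np.interp(target, s[:-1], pts[:, 1])
    # node-centred segment lengths on the closed loop
    dxf = np.diff(xi, append=xi[:1]); dyf = np.diff(yi, append=yi[:1])
    fwd = np.hypot(dxf, dyf)
    ds = 0.5 * (fwd + np.roll(fwd, 1))
    return xi, yi, ds


def build_cell_geometry(shape: str = "symmetric", h: float = 0.1,
                        n_membrane: int | None = None) -> CellGeometry:
    """Build the interior and membrane meshes for a cell shape.

    Parameters
    ----------
    shape:
        ``symmetric``, ``back_blunted`` or ``front_blunted``.
    h:
        voxel side in um (default 0.1).  Must resolve the minor axis with at
        least 4 voxels.
    n_membrane:
        number of membrane nodes; defaults to one node per ``h`` of
        perimeter (at least 64).
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    if h <= 0 or h > 0.5:
        raise ValueError("h must be in (0, 0.5] um")
    if 2 * SEMI_MINOR / h < 4:
        raise ValueError(f"h = {h} too coarse: fewer than 4 voxels across the "
                         f"minor axis ({2 * SEMI_MINOR} um)")
    xc, yc, lap = _interior_mesh(shape, h)
    if n_membrane is None:
        # estimate perimeter from a dense polyline to size the membrane mesh
        xs0, ys0, ds0 = _boundary_nodes(shape, 2000)
        n_membrane = max(64, int(round(ds0.sum() / h)))
    xs, ys, ds = _boundary_nodes(shape, n_membrane)
    # map each membrane node to the nearest interior voxel
    bidx = np.empty(len(xs), dtype=int)
    for i, (x, y) in enumerate(zip(xs, ys)):
        bidx[i] = int(np.argmin((xc - x) ** 2 + (yc - y) ** 2))
    return CellGeometry(shape=shape, h=h, xc=xc, yc=yc, voxel_area=h * h,
                        laplacian=lap, xs=xs, ys=ys, ds=ds,
                        boundary_voxel=bidx)


def receptor_field(geometry: CellGeometry, spec: StimulusSpec) -> np.ndarray:
    """Activated-receptor density (molecules/um^2) at each membrane node."""
    s = spec.direction * spec.rsteep
    r = R_CHARACTERISTIC * spec.rfrac * (1.0 + s * geometry.xs / CELL_LENGTH)
    if np.any(r < -1e-12):
        raise ValueError("receptor field negative somewhere; reduce |rsteep|")
    return np.maximum(r, 0.0)
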