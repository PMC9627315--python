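"""Ultra-high-density electrode montage geometry.

The recording hardware modelled here is a patch of diamond-shaped 4x4
electrode grids (16 contacts each, 8.6 mm centre-to-centre pitch) attached
contiguously over the sensorimotor cortex of one hemisphere.  The scalp is
modelled as a parametric hemisphere; the planar grid lattice is mapped onto
it with an inverse Lambert azimuthal equal-area projection, which keeps
nearest-neighbour distances centred on the pitch (radial stretch and
tangential shrink cancel to first order in area).

Besides the full-density montage the module builds the two reduced-density
electrode subsets used for density comparisons: a sparse ~6-position set and
a denser ~11-position set covering the same patch, standing in for the
10-10 and extended 10-10 placement systems restricted to the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import InvalidParameterError

__all__ = [
    "Montage",
    "NeighborGraph",
    "build_uhd_montage",
    "edge_channels",
    "four_nearest_neighbors",
    "select_density_subset",
    "builtin_density_targets",
    "read_montage",
    "write_montage",
    "mirror_x",
]


@dataclass
class Montage:
    """Electrode labels, 3D positions (mm), grid membership and ROI mask."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) mm
    grid_id: np.ndarray  # (n,) int
    roi_mask: np.ndarray  # (n,) bool
    pitch: float  # mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.grid_id = np.asarray(self.grid_id, dtype=int)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidParameterError("channel labels must be unique")
        if self.positions.shape != (n, 3) or not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be a finite (n, 3) array")
        if self.grid_id.shape != (n,) or self.roi_mask.shape != (n,):
            raise InvalidParameterError("grid_id and roi_mask must have one entry per channel")
        if n >= 2 and pdist(self.positions).min() <= 0.0:
            raise InvalidParameterError("montage contains coincident electrodes")
        if not self.pitch > 0:
            raise InvalidParameterError("pitch must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "Montage":
        """Restrict the montage to the channels selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return Montage(
            labels=[l for l, m in zip(self.labels, mask) if m],
            positions=self.positions[mask],
            grid_id=self.grid_id[mask],
            roi_mask=self.roi_mask[mask],
            pitch=self.pitch,
        )


@dataclass
class NeighborGraph:
    """Unique unordered neighbouring-electrode pairs with their distances (mm)."""

    pairs: np.ndarray  # (m, 2) int, pairs[i, 0] < pairs[i, 1]
    distances: np.ndarray  # (m,) mm

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float)
        if len({tuple(p) for p in self.pairs}) != len(self.pairs):
            raise InvalidParameterError("neighbour pairs must be unique")
        if np.any(self.distances <= 0):
            raise InvalidParameterError("neighbour distances must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# construction


def _lattice(n_grids: int, pitch_mm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planar diamond lattice of 4x4 grids; returns (uv, grid, rowcol)."""
    g_cols = int(np.ceil(np.sqrt(n_grids)))
    g_rows = int(np.ceil(n_grids / g_cols))
    rows, cols, grids = [], [], []
    for g in range(n_grids):
        gr, gc = divmod(g, g_cols)
        for a in range(4):
            for b in range(4):
                rows.append(gr * 4 + a)
                cols.append(gc * 4 + b)
                grids.append(g)
    rows = np.asarray(rows, float)
    cols = np.asarray(cols, float)
    u = (cols - cols.mean()) * pitch_mm
    v = (rows - rows.mean()) * pitch_mm
    # rotate 45 degrees: the grids are diamond-shaped on the head
    c = np.sqrt(0.5)
    uv = np.column_stack([c * u - c * v, c * u + c * v])
    rowcol = np.column_stack([rows, cols]).astype(int)
    return uv, np.asarray(grids), rowcol


def _plane_to_sphere(uv: np.ndarray, radius_mm: float) -> np.ndarray:
    """Inverse Lambert azimuthal equal-area map, patch centred at the vertex."""
    rho = np.hypot(uv[:, 0], uv[:, 1])
    arg = np.clip(rho / (2.0 * radius_mm), 0.0, 1.0)
    theta = 2.0 * np.arcsin(arg)
    phi = np.arctan2(uv[:, 1], uv[:, 0])
    return radius_mm * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _roi_from_lattice(rowcol: np.ndarray, margin: int) -> np.ndarray:
    """Interior electrodes: erode the occupied-lattice map ``margin`` times."""
    if margin <= 0:
        return np.ones(len(rowcol), dtype=bool)
    h, w = rowcol.max(axis=0) + 1
    occ = np.zeros((h + 2, w + 2), dtype=bool)
    occ[rowcol[:, 0] + 1, rowcol[:, 1] + 1] = True
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = binary_erosion(occ, structure=cross, iterations=margin)
    return interior[rowcol[:, 0] + 1, rowcol[:, 1] + 1]


def build_uhd_montage(
    n_grids: int = 16,
    pitch_mm: float = 8.6,
    radius_mm: float = 90.0,
    roi_margin: int = 1,
) -> Montage:
    """Build the ultra-high-density montage on a hemispherical scalp.

    Parameters
    ----------
    n_grids
        Number of 16-electrode diamond grids (16 -> 256 channels).
    pitch_mm
        Centre-to-centre electrode spacing within a grid.
    radius_mm
        Radius of the parametric hemispherical scalp surface.
    roi_margin
        Number of outermost electrode rings excluded from the region of
        interest used for classification.
    """
    if not isinstance(n_grids, (int, np.integer)) or n_grids < 1:
        raise InvalidParameterError("n_grids must be a positive integer")
    if not pitch_mm > 0:
        raise InvalidParameterError("pitch_mm must be positive")
    if not radius_mm > 0:
        raise InvalidParameterError("radius_mm must be positive")

    uv, grids, rowcol = _lattice(n_grids, pitch_mm)
    # grid 0 is anchored at the vertex: relabel grids by centroid distance
    order = np.argsort([np.hypot(*uv[grids == g].mean(axis=0)) for g in range(n_grids)])
    relabel = np.empty(n_grids, dtype=int)
    relabel[order] = np.arange(n_grids)
    grids = relabel[grids]
    chan_order = np.lexsort((np.arange(len(grids)), grids))
    uv, grids, rowcol = uv[chan_order], grids[chan_order], rowcol[chan_order]

    positions = _plane_to_sphere(uv, radius_mm)
    roi = _roi_from_lattice(rowcol, roi_margin)
    within = np.concatenate([np.arange(np.sum(grids == g)) for g in range(n_grids)])
    labels = [f"G{g:02d}E{e:02d}" for g, e in zip(grids, within)]
    return Montage(labels=labels, positions=positions, grid_id=grids, roi_mask=roi, pitch=pitch_mm)


# ---------------------------------------------------------------------------
# projections and edges


class _Projection:
    """2D chart of the montage: tangent-plane Lambert equal-area for spherical
    layouts, PCA plane for flat ones.  Supports the inverse map for placing
    target positions back onto the scalp."""

    def __init__(self, positions: np.ndarray):
        self.origin = positions.mean(axis=0)
        norms = np.linalg.norm(positions, axis=1)
        self.spherical = norms.mean() > 0 and norms.std() < 1e-6 * max(norms.mean(), 1.0)
        if self.spherical:
            self.radius = norms.mean()
            c = self.origin / np.linalg.norm(self.origin)
            self.center = c
            ref = np.array([1.0, 0.0, 0.0])
            if abs(c @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = ref - (ref @ c) * c
            self.e1 = e1 / np.linalg.norm(e1)
            self.e2 = np.cross(c, self.e1)
        else:
            x = positions - self.origin
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            self.e1, self.e2 = vt[0], vt[1]

    def forward(self, positions: np.ndarray) -> np.ndarray:
        if self.spherical:
            p = positions / np.linalg.norm(positions, axis=1, keepdims=True)
            cosd = np.clip(p @ self.center, -1.0, 1.0)
            k = np.sqrt(2.0 / np.clip(1.0 + cosd, 1e-12, None))
            tang = p - cosd[:, None] * self.center
            return self.radius * k[:, None] * np.column_stack([tang @ self.e1, tang @ self.e2])
        x = positions - self.origin
        return np.column_stack([x @ self.e1, x @ self.e2])

    def inverse(self, uv: np.ndarray) -> np.ndarray:
        if self.spherical:
            rho = np.hypot(uv[:, 0], uv[:, 1])
            theta = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), 0.0, 1.0))
            with np.errstate(invalid="ignore"):
                direction = np.where(rho[:, None] > 0, uv / np.clip(rho[:, None], 1e-12, None), 0.0)
            t = direction[:, 0:1] * self.e1 + direction[:, 1:2] * self.e2
            p = np.cos(theta)[:, None] * self.center + np.sin(theta)[:, None] * t
            return self.radius * p
        return self.origin + uv[:, 0:1] * self.e1 + uv[:, 1:2] * self.e2


def _dist_to_hull_boundary(points2d: np.ndarray) -> np.ndarray:
    """Distance of each point to the boundary of the 2D convex hull."""
    hull = ConvexHull(points2d)
    verts = points2d[hull.vertices]
    d = np.full(len(points2d), np.inf)
    for i in range(len(verts)):
        a, b = verts[i], verts[(i + 1) % len(verts)]
        ab = b - a
        t = np.clip((points2d - a) @ ab / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.minimum(d, np.linalg.norm(points2d - proj, axis=1))
    return d


def edge_channels(montage: Montage) -> np.ndarray:
    """Boolean mask of electrodes on the outer boundary of the patch.

    An electrode is an edge electrode when it lies within half the minimum
    inter-electrode distance of the convex hull of the (projected) layout.
    """
    proj = _Projection(montage.positions)
    uv = proj.forward(montage.positions)
    min_d = pdist(uv).min()
    return _dist_to_hull_boundary(uv) < 0.5 * min_d


def four_nearest_neighbors(montage: Montage, n_neighbors: int = 4) -> NeighborGraph:
    """Neighbouring-electrode graph from the four nearest neighbours.

    Every interior (non-edge) electrode contributes its ``n_neighbors``
    nearest electrodes as pairs; edge electrodes only serve as neighbours.
    Duplicate unordered pairs are collapsed.
    """
    if montage.n_channels < n_neighbors + 1:
        raise InvalidParameterError(
            f"need at least {n_neighbors + 1} electrodes, got {montage.n_channels}"
        )
    d = squareform(pdist(montage.positions))
    interior = ~edge_channels(montage)
    pairs: dict[tuple[int, int], float] = {}
    for i in np.flatnonzero(interior):
        for j in np.argsort(d[i])[1 : n_neighbors + 1]:
            key = (min(i, int(j)), max(i, int(j)))
            pairs[key] = d[key[0], key[1]]
    if not pairs:
        return NeighborGraph(np.empty((0, 2), dtype=int), np.empty(0))
    keys = sorted(pairs)
    return NeighborGraph(np.array(keys), np.array([pairs[k] for k in keys]))


# ---------------------------------------------------------------------------
# density subsets


def select_density_subset(montage: Montage, target_positions: np.ndarray) -> np.ndarray:
    """Boolean mask of the uHD electrodes nearest to each target position.

    Mirrors how reduced-density montages are emulated from the full patch:
    for every standard-system position the single best-fitting uHD electrode
    is kept.  Two targets hitting the same electrode yield one selection.
    """
    targets = np.asarray(target_positions, dtype=float).reshape(-1, 3)
    if targets.size == 0:
        raise InvalidParameterError("target position list must not be empty")
    nearest = np.argmin(cdist(targets, montage.positions), axis=1)
    mask = np.zeros(montage.n_channels, dtype=bool)
    mask[nearest] = True
    return mask


def builtin_density_targets(montage: Montage, which: str) -> np.ndarray:
    """Built-in target sets covering the patch at reduced density.

    ``"sparse"`` is a ~6-position set and ``"dense"`` a ~11-position set,
    standing in for 10-10 and extended 10-10 coverage of the patch.  The
    sets are shipped as fractional patch coordinates and mapped into the
    montage's own frame, so they scale with pitch and scalp radius.
    """
    fname = {"sparse": "sparse_subset.tsv", "dense": "dense_subset.tsv"}.get(which)
    if fname is None:
        raise InvalidParameterError(f"unknown built-in target set {which!r}")
    text = resources.files("uhdfinger.data").joinpath(fname).read_text()
    fracs = np.array(
        [[float(x) for x in line.split("\t")] for line in text.strip().splitlines()[1:]]
    )
    proj = _Projection(montage.positions)
    uv = proj.forward(montage.positions)
    lo, hi = uv.min(axis=0), uv.max(axis=0)
    targets_uv = lo + fracs * (hi - lo)
    return proj.inverse(targets_uv)


# ---------------------------------------------------------------------------
# io and utilities


def write_montage(montage: Montage, path: str | Path) -> None:
    """Write a tab-separated montage file (label, x_mm, y_mm, z_mm, grid_id, roi)."""
    with open(path, "w") as fh:
        fh.write("label\tx_mm\ty_mm\tz_mm\tgrid_id\troi\n")
        for i, lab in enumerate(montage.labels):
            x, y, z = montage.positions[i]
            fh.write(
                f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{montage.grid_id[i]}\t{int(montage.roi_mask[i])}\n"
            )


def read_montage(path: str | Path, pitch: float | None = None) -> Montage:
    """Read a montage file written by :func:`write_montage`.

    When ``pitch`` is not given it is estimated as the minimum pairwise
    electrode distance.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise InvalidParameterError("montage file must start with a header line")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    arr = np.asarray(rows)
    if pitch is None:
        pitch = float(pdist(arr[:, :3]).min()) if len(arr) > 1 else 1.0
    return Montage(
        labels=labels,
        positions=arr[:, :3],
        grid_id=arr[:, 3].astype(int),
        roi_mask=arr[:, 4].astype(bool),
        pitch=pitch,
    )


def mirror_x(montage: Montage) -> Montage:
    """Mirror the montage on the sagittal plane (sign flip of x)."""
    positions = montage.positions.copy()
    positions[:, 0] *= -1.0
    return replace(montage, positions=positions)
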