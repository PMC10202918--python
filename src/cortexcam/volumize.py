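"""Render spherical source maps as standardized images and volumes.

The sphere is flattened with the equal-area Mollweide projection onto a
2:1 ellipse, sampled on a uniform ``grid_size x grid_size`` pixel grid
(default 120).  Scattered vertex values are linearly interpolated inside
the convex hull of the projected vertices, nearest-neighbor filled between
the hull and the ellipse boundary, and zero outside the ellipse.  Each
image is z-scored over its in-ellipse pixels.  A trial becomes a 3d volume
by averaging the current density within 16 contiguous 50 ms bins covering
0-800 ms and stacking the per-bin images depth-wise, or a single 2d image
by averaging within 200-350 ms.

Grid orientation: row 0 is the top of the map (y = +sqrt(2), the north
pole), column 0 the left edge (x = -2*sqrt(2)); longitude 0 (the anterior
midline) maps to the central column and the occipital pole to the left and
right edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, cKDTree

from .geometry import latlon
from .synthdata import SourceTrialSet, SurfaceGeometry

__all__ = [
    "MollweideMap",
    "InputVolume",
    "mollweide_xy",
    "make_mollweide_map",
    "grid_project",
    "standardize_image",
    "build_volume",
    "volumize_trialset",
    "region_pixel_mask",
    "BINS_3D_MS",
    "WINDOW_2D_MS",
]

_SQRT2 = np.sqrt(2.0)

#: 16 half-open 50 ms bins covering 0-800 ms (the 3d volume's depth axis)
BINS_3D_MS: tuple[tuple[float, float], ...] = tuple(
    (50.0 * i, 50.0 * (i + 1)) for i in range(16)
)
#: single averaging window for the 2d image
WINDOW_2D_MS: tuple[float, float] = (200.0, 350.0)


def mollweide_xy(lat_rad, lon_rad):
    """Mollweide planar coordinates for latitude/longitude in radians.

    Solves the auxiliary-angle equation ``2t + sin(2t) = pi*sin(lat)`` by
    Newton iteration to 1e-12 (poles handled analytically), then
    ``x = (2*sqrt(2)/pi) * lon * cos(t)``, ``y = sqrt(2) * sin(t)``.
    Accepts scalars or arrays; x spans [-2*sqrt(2), 2*sqrt(2)], y spans
    [-sqrt(2), sqrt(2)].
    """
    lat = np.asarray(lat_rad, dtype=float)
    lon = np.asarray(lon_rad, dtype=float)
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12) or np.any(np.abs(lon) > np.pi + 1e-12):
        raise ValueError("latitude must lie in [-pi/2, pi/2], longitude in [-pi, pi]")

    theta = np.array(lat, dtype=float, copy=True, ndmin=1)
    target = np.pi * np.sin(np.atleast_1d(lat))
    at_pole = np.abs(np.abs(np.atleast_1d(lat)) - np.pi / 2) < 1e-12
    theta[at_pole] = np.sign(theta[at_pole]) * np.pi / 2
    active = ~at_pole
    for _ in range(50):
        if not np.any(active):
            break
        t = theta[active]
        f = 2.0 * t + np.sin(2.0 * t) - target[active]
        theta[active] = t - f / (2.0 + 2.0 * np.cos(2.0 * t))
        still = np.zeros_like(active)
        still[active] = np.abs(f) > 1e-12
        active = still

    x = (2.0 * _SQRT2 / np.pi) * np.atleast_1d(lon) * np.cos(theta)
    y = _SQRT2 * np.sin(theta)
    if np.isscalar(lat_rad) and np.isscalar(lon_rad):
        return float(x[0]), float(y[0])
    return x.reshape(np.shape(lat_rad)), y.reshape(np.shape(lat_rad))


@dataclass(frozen=True)
class MollweideMap:
    """Precomputed projection + interpolation operator for one surface.

    ``interp`` maps per-vertex values to the in-ellipse pixels in one
    sparse matrix-vector product; it depends only on the geometry and is
    computed once per surface/grid-size pair.
    """

    vertex_xy: np.ndarray  # (n_vertices, 2) planar coordinates
    grid_size: int
    ellipse_mask: np.ndarray  # (grid, grid) bool, True inside the ellipse
    interp: sparse.csr_matrix  # (n_in_ellipse, n_vertices)
    pixel_main_vertex: np.ndarray  # (n_in_ellipse,) dominant source vertex

    @property
    def n_vertices(self) -> int:
        return self.interp.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all pixel centers, each (grid, grid)."""
        return _pixel_centers(self.grid_size)


def _pixel_centers(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    dx = 4.0 * _SQRT2 / grid_size
    dy = 2.0 * _SQRT2 / grid_size
    xs = -2.0 * _SQRT2 + (np.arange(grid_size) + 0.5) * dx
    ys = _SQRT2 - (np.arange(grid_size) + 0.5) * dy
    return np.meshgrid(xs, ys)


def make_mollweide_map(surface: SurfaceGeometry, grid_size: int = 120) -> MollweideMap:
    """Build the projection/interpolation operator for a surface."""
    lat, lon = latlon(surface.vertex_coords)
    vx, vy = mollweide_xy(lat, lon)
    vertex_xy = np.column_stack([vx, vy])
    # normalize to the unit disk so triangulation and distances are isotropic
    vnorm = np.column_stack([vx / (2.0 * _SQRT2), vy / _SQRT2])

    px, py = _pixel_centers(grid_size)
    inside = (px / (2.0 * _SQRT2)) ** 2 + (py / _SQRT2) ** 2 <= 1.0 + 1e-9
    pnorm = np.column_stack(
        [px[inside] / (2.0 * _SQRT2), py[inside] / _SQRT2]
    )

    n_pix = pnorm.shape[0]
    rows, cols, vals = [], [], []
    main_vertex = np.empty(n_pix, dtype=int)

    if surface.n_vertices >= 3:
        tri = Delaunay(vnorm)
        simplex = tri.find_simplex(pnorm)
    else:
        simplex = np.full(n_pix, -1)
    tree = cKDTree(vnorm)
    _, nearest = tree.query(pnorm)

    for i in range(n_pix):
        s = simplex[i]
        if s >= 0:
            verts = tri.simplices[s]
            T = tri.transform[s]
            bary2 = T[:2] @ (pnorm[i] - T[2])
            bary = np.append(bary2, 1.0 - bary2.sum())
            bary = np.clip(bary, 0.0, 1.0)
            bary = bary / bary.sum()
            rows.extend([i] * 3)
            cols.extend(verts.tolist())
            vals.extend(bary.tolist())
            main_vertex[i] = verts[np.argmax(bary)]
        else:  # between the convex hull and the ellipse boundary
            rows.append(i)
            cols.append(int(nearest[i]))
            vals.append(1.0)
            main_vertex[i] = int(nearest[i])

    interp = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_pix, surface.n_vertices)
    )
    return MollweideMap(
        vertex_xy=vertex_xy,
        grid_size=grid_size,
        ellipse_mask=inside,
        interp=interp,
        pixel_main_vertex=main_vertex,
    )


def grid_project(mmap: MollweideMap, vertex_values: np.ndarray) -> np.ndarray:
    """Interpolate per-vertex values onto the uniform grid (off-ellipse 0)."""
    vertex_values = np.asarray(vertex_values, dtype=float).ravel()
    if vertex_values.size != mmap.n_vertices:
        raise ValueError(
            f"got {vertex_values.size} values for {mmap.n_vertices} vertices"
        )
    img = np.zeros((mmap.grid_size, mmap.grid_size), dtype=float)
    img[mmap.ellipse_mask] = mmap.interp @ vertex_values
    return img


def standardize_image(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score an image over its in-ellipse pixels.

    A constant image maps to all zeros (the degenerate SD = 0 rule);
    off-ellipse pixels stay 0.  Idempotent.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    vals = image[mask]
    sd = vals.std(ddof=0)
    out = np.zeros_like(image)
    if sd > 0:
        out[mask] = (vals - vals.mean()) / sd
    return out


@dataclass
class InputVolume:
    """One standardized classifier input with provenance."""

    values: np.ndarray  # (grid, grid, n_windows)
    label: str  # "control" | "patient"
    subject_id: str
    trial_id: int
    window_def: tuple[tuple[float, float], ...]


def _bin_average(
    trial: np.ndarray, times_ms: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    lo, hi = window
    sel = (times_ms >= lo) & (times_ms < hi)
    if not sel.any():
        raise ValueError(f"epoch does not cover the window [{lo}, {hi}) ms")
    return trial[..., sel].mean(axis=-1)


def build_volume(
    trial: np.ndarray,
    times_ms: np.ndarray,
    mmap: MollweideMap,
    mode: str = "3d",
    label: str = "",
    subject_id: str = "",
    trial_id: int = 0,
) -> InputVolume:
    """Standardized image volume for one vertices x time trial.

    mode "3d": one frame per 50 ms bin over 0-800 ms (16 frames); mode
    "2d": a single 200-350 ms average frame.  Each frame is projected and
    z-scored independently; bins are half-open, so a sample at exactly
    800 ms is excluded.
    """
    if mode not in ("3d", "2d"):
        raise ValueError(f"mode must be '3d' or '2d', got {mode!r}")
    windows = BINS_3D_MS if mode == "3d" else (WINDOW_2D_MS,)
    if times_ms[0] > windows[0][0]:
        raise ValueError("trial epoch must start at or before 0 ms")
    frames = []
    for win in windows:
        img = grid_project(mmap, _bin_average(trial, times_ms, win))
        frames.append(standardize_image(img, mmap.ellipse_mask))
    values = np.stack(frames, axis=-1).astype(np.float32)
    return InputVolume(
        values=values,
        label=label,
        subject_id=subject_id,
        trial_id=trial_id,
        window_def=tuple(windows),
    )


def volumize_trialset(
    trials: SourceTrialSet, mmap: MollweideMap, mode: str = "3d"
) -> list[InputVolume]:
    """Build one InputVolume per trial of a subject's trial set."""
    times = trials.times_ms
    return [
        build_volume(
            trials.data[i],
            times,
            mmap,
            mode=mode,
            label=trials.group,
            subject_id=trials.subject_id,
            trial_id=i,
        )
        for i in range(trials.data.shape[0])
    ]


def region_pixel_mask(
    mmap: MollweideMap, surface: SurfaceGeometry, region_id: int
) -> np.ndarray:
    """(grid, grid) bool mask of the projected footprint of a region.

    A pixel belongs to the footprint when its dominant interpolation source
    vertex carries the region's label.
    """
    labels = surface.region_mask(region_id)
    mask = np.zeros((mmap.grid_size, mmap.grid_size), dtype=bool)
    mask[mmap.ellipse_mask] = labels[mmap.pixel_main_vertex]
    return mask
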