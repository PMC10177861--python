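"""Contour-aligned (s, t) coordinate system for closed rib contours.

A rib boundary is a closed, simple, piecewise-linear contour in image
coordinates.  The ST transform maps an image point to the pair ``(s, t)``
where ``t`` is arc length along the contour and ``s`` is the signed
perpendicular offset from the contour, positive toward the polygon interior.
Inside a rib the iso-intensity curves of the bone shadow run parallel to the
boundary, so in ST space they become straight lines along the ``t`` axis —
the property the rib-extraction stage exploits.

Conventions (fixed so tests can be bit-exact):

* pixel-center coordinates, 0-based, ``x`` = column index, ``y`` = row index;
* ``s > 0`` points inward;
* arc length ``t`` wraps modulo the contour length; each edge owns the
  half-open interval ``[t_i, t_{i+1})``;
* forward mapping selects, among edges whose offset segment contains the
  foot of the perpendicular, the one with smallest ``|s|`` (ties to the
  lowest edge index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as _Polygon

__all__ = [
    "Contour",
    "ContourError",
    "STPoint",
    "STImage",
    "forward_map",
    "forward_map_many",
    "inverse_map",
    "inverse_map_many",
    "mirror_position",
    "compute_centerline",
    "sample_to_st",
    "splat_to_image",
    "distance_to_contour",
]


class ContourError(ValueError):
    """Raised for geometrically invalid contours."""


@dataclass(frozen=True)
class STPoint:
    """A point in contour-aligned coordinates: inward offset ``s``, arc length ``t``."""

    s: float
    t: float


class Contour:
    """Closed simple piecewise-linear contour in pixel coordinates.

    Parameters
    ----------
    vertices : (N, 2) array-like
        Ordered ``(x, y)`` vertices.  The polygon is implicitly closed; a
        duplicated closing vertex is dropped.
    label : str, optional
        Rib label (e.g. ``"L3"``).
    """

    def __init__(self, vertices: Sequence, label: Optional[str] = None):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError("vertices must be an (N, 2) array of (x, y)")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ContourError("a contour needs at least 3 distinct vertices")
        edges = np.roll(v, -1, axis=0) - v
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        if np.any(lengths <= 0):
            raise ContourError("zero-length edge in contour")
        poly = _Polygon(v)
        if not poly.is_valid:
            lbl = f" '{label}'" if label else ""
            raise ContourError(f"contour{lbl} is not a simple polygon: {shapely.is_valid_reason(poly)}")

        self.label = label
        self.vertices = v
        self.edge_vectors = edges
        self.edge_lengths = lengths
        self.total_length = float(lengths.sum())
        # cumulative arc length at each vertex; cum[-1] == total_length
        self.cum_lengths = np.concatenate([[0.0], np.cumsum(lengths)])
        area2 = float(np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]))
        self.orientation = "ccw" if area2 > 0 else "cw"
        d = edges / lengths[:, None]
        self.edge_dirs = d
        # inward normal: interior is left of travel for ccw, right for cw
        if self.orientation == "ccw":
            self.inward_normals = np.stack([-d[:, 1], d[:, 0]], axis=1)
        else:
            self.inward_normals = np.stack([d[:, 1], -d[:, 0]], axis=1)
        self._polygon = poly
        self._prepared = False

    @property
    def n_edges(self) -> int:
        return len(self.vertices)

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-polygon test (boundary counts as inside)."""
        if not self._prepared:
            shapely.prepare(self._polygon)
            self._prepared = True
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = shapely.contains_xy(self._polygon, x, y)
        if np.ndim(inside) == 0:
            return bool(inside)
        return inside

    def area(self) -> float:
        return float(self._polygon.area)

    def __repr__(self):  # pragma: no cover
        return (f"Contour(label={self.label!r}, n={self.n_edges}, "
                f"length={self.total_length:.2f}, {self.orientation})")


@dataclass
class STImage:
    """Band of image intensities resampled into (s, t) coordinates.

    ``values[i, j]`` holds the intensity at ``s = s_min + i * ds``,
    ``t = j * dt`` (``s_min`` is 0 unless a lead-in margin outside the
    contour was requested).  ``valid`` marks cells whose inverse-mapped point
    lies inside the source image (and, when a rib mask was supplied, inside
    the band up to the centerline ``c(t)``).  ``centerline[j]`` is
    ``c(j * dt)`` in pixels, NaN on degenerate columns.
    """

    values: np.ndarray
    valid: np.ndarray
    ds: float
    dt: float
    s_max: float
    centerline: Optional[np.ndarray] = None
    contour: Optional[Contour] = field(default=None, repr=False)
    s_min: float = 0.0

    def __post_init__(self):
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")

    @property
    def s_coords(self) -> np.ndarray:
        return self.s_min + np.arange(self.values.shape[0]) * self.ds

    @property
    def t_coords(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.dt

    def copy_with(self, values=None, valid=None) -> "STImage":
        return STImage(
            values=self.values if values is None else values,
            valid=self.valid if valid is None else valid,
            ds=self.ds, dt=self.dt, s_max=self.s_max,
            centerline=self.centerline, contour=self.contour, s_min=self.s_min,
        )


# ---------------------------------------------------------------------------
# edge geometry helpers

def _edge_projections(contour: Contour, pts: np.ndarray):
    """Per point and edge: signed inward offset, along-edge parameter, in-segment flag.

    Returns ``(sgn, u, inseg)`` each of shape ``(M, E)``.
    """
    P = contour.vertices            # (E, 2)
    D = contour.edge_dirs           # (E, 2)
    N = contour.inward_normals      # (E, 2)
    L = contour.edge_lengths        # (E,)
    V = pts[:, None, :] - P[None, :, :]          # (M, E, 2)
    u = np.einsum("mei,ei->me", V, D)
    sgn = np.einsum("mei,ei->me", V, N)
    tol = 1e-9
    inseg = (u >= -tol) & (u <= L[None, :] + tol)
    return sgn, u, inseg


def distance_to_contour(contour: Contour, pts: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean distance from each point to the polygon boundary."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    sgn, u, inseg = _edge_projections(contour, pts)
    P = contour.vertices
    P_next = np.roll(P, -1, axis=0)
    d0 = np.hypot(pts[:, None, 0] - P[None, :, 0], pts[:, None, 1] - P[None, :, 1])
    d1 = np.hypot(pts[:, None, 0] - P_next[None, :, 0], pts[:, None, 1] - P_next[None, :, 1])
    d_end = np.minimum(d0, d1)
    d_edge = np.where(inseg, np.abs(sgn), d_end)
    return d_edge.min(axis=1)


def forward_map_many(contour: Contour, pts) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised forward ST map.  Returns ``(s, t)`` arrays for ``(M, 2)`` points.

    Points whose perpendicular foot misses every offset edge segment (corner
    fans) fall back to the nearest vertex: ``s`` = signed distance to it,
    ``t`` = its arc length.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    sgn, u, inseg = _edge_projections(contour, pts)
    cost = np.where(inseg, np.abs(sgn), np.inf)
    idx = np.argmin(cost, axis=1)
    rows = np.arange(len(pts))
    s = sgn[rows, idx]
    u_sel = np.clip(u[rows, idx], 0.0, None)
    # keep t inside the owning edge's half-open interval
    u_sel = np.minimum(u_sel, np.nextafter(contour.edge_lengths[idx], 0.0))
    t = contour.cum_lengths[idx] + u_sel

    nohit = ~np.isfinite(cost[rows, idx])
    if np.any(nohit):
        bad = pts[nohit]
        dv = np.hypot(bad[:, None, 0] - contour.vertices[None, :, 0],
                      bad[:, None, 1] - contour.vertices[None, :, 1])
        j = np.argmin(dv, axis=1)
        dist = dv[np.arange(len(bad)), j]
        inside = contour.contains(bad[:, 0], bad[:, 1])
        s[nohit] = np.where(inside, dist, -dist)
        t[nohit] = contour.cum_lengths[j]
    t %= contour.total_length
    return s, t


def forward_map(contour: Contour, point) -> STPoint:
    """Map one image point ``(x, y)`` to contour-aligned ``(s, t)``."""
    s, t = forward_map_many(contour, np.asarray(point, dtype=float)[None, :])
    return STPoint(float(s[0]), float(t[0]))


def inverse_map_many(contour: Contour, s, t) -> np.ndarray:
    """Vectorised inverse ST map: ``gamma(t) + s * n(t)`` -> ``(M, 2)`` points."""
    s = np.asarray(s, dtype=float).ravel()
    t = np.mod(np.asarray(t, dtype=float).ravel(), contour.total_length)
    idx = np.searchsorted(contour.cum_lengths, t, side="right") - 1
    idx = np.clip(idx, 0, contour.n_edges - 1)
    local = t - contour.cum_lengths[idx]
    return (contour.vertices[idx]
            + local[:, None] * contour.edge_dirs[idx]
            + s[:, None] * contour.inward_normals[idx])


def inverse_map(contour: Contour, p: STPoint) -> tuple[float, float]:
    """Map one ST point back to image coordinates ``(x, y)``."""
    xy = inverse_map_many(contour, [p.s], [p.t])[0]
    return float(xy[0]), float(xy[1])


def _circular_diff(a: float, b: float, period: float) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def mirror_position(contour: Contour, p: STPoint, atol: float = 0.5) -> Optional[STPoint]:
    """The same physical pixel expressed from the opposite side of the contour.

    Returns the ``(s_hat, t_hat)`` with smallest positive offset among the
    forward solutions distinct from ``p`` itself, or ``None`` when the pixel
    is reachable from only one side (e.g. lies outside the polygon).
    """
    xy = inverse_map_many(contour, [p.s], [p.t])
    if not contour.contains(xy[0, 0], xy[0, 1]):
        return None
    sgn, u, inseg = _edge_projections(contour, xy)
    sgn, u, inseg = sgn[0], u[0], inseg[0]
    cand = inseg & (sgn > 1e-9)
    if not np.any(cand):
        return None
    t_all = contour.cum_lengths[:-1] + np.clip(u, 0.0, contour.edge_lengths)
    best = None
    for e in np.nonzero(cand)[0]:
        s_e, t_e = float(sgn[e]), float(t_all[e] % contour.total_length)
        if abs(s_e - p.s) < atol and _circular_diff(t_e, p.t, contour.total_length) < atol:
            continue  # the point itself
        if best is None or s_e < best.s:
            best = STPoint(s_e, t_e)
    return best


def _mask_lookup(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Membership test of points in a boolean raster mask.

    Bilinear interpolation with a generous threshold, so sub-pixel points
    hugging the rasterised boundary of the filled polygon still count as
    inside; a point more than one pixel outside never does.
    """
    vals = ndimage.map_coordinates(mask.astype(float), [pts[:, 1], pts[:, 0]],
                                   order=1, mode="constant", cval=0.0)
    return vals > 0.25


def compute_centerline(contour: Contour, mask: np.ndarray, dt: float = 1.0,
                       s_step: float = 0.25, smooth_window: int = 5):
    """Centerline depth ``c(t)``: how far inward each contour column reaches.

    For each sampled ``t``, ``c(t)`` is the largest ``s`` whose inverse-mapped
    point (a) lies inside the filled rib mask and (b) is still nearest to its
    own side of the contour, i.e. its mirror solution has not become closer.
    The raw profile is smoothed with a short circular moving average along
    ``t`` to suppress rasterization jitter.

    Returns
    -------
    centerline : (T,) float array, NaN on degenerate (zero-thickness) columns.
    valid : (T,) bool array.
    """
    mask = np.asarray(mask, dtype=bool)
    T = int(np.ceil(contour.total_length / dt))
    if T < 1:
        raise ContourError("contour too short for the requested dt")
    t_vals = np.arange(T) * dt
    # upper bound on the inward reach from the mask extent
    s_cap = float(ndimage.distance_transform_edt(mask).max()) + 2.0 if mask.any() else 2.0
    K = max(int(np.ceil(s_cap / s_step)), 2)
    s_vals = (np.arange(K) + 1) * s_step
    # ownership slack: half a marching step plus room for the lateral drift of
    # columns rooted near polygon vertices (their march line is the edge
    # normal, not the exact radial direction)
    tol = 0.5 * s_step + 0.25

    c = np.zeros(T)
    chunk = max(1, int(2e5 / max(K, 1)))
    for j0 in range(0, T, chunk):
        tc = t_vals[j0:j0 + chunk]
        SS, TT = np.meshgrid(s_vals, tc, indexing="ij")   # (K, Tc)
        pts = inverse_map_many(contour, SS.ravel(), TT.ravel())
        inside = _mask_lookup(mask, pts)
        owned = distance_to_contour(contour, pts) >= SS.ravel() - tol
        ok = (inside & owned).reshape(K, len(tc))
        reach = np.cumprod(ok, axis=0).sum(axis=0)        # leading run of True
        c[j0:j0 + chunk] = reach * s_step

    valid = c > 0
    if smooth_window and smooth_window > 1 and valid.any():
        w = int(smooth_window)
        kernel = np.ones(w) / w
        cs = np.where(valid, c, 0.0)
        vs = valid.astype(float)
        num = ndimage.convolve1d(cs, kernel, mode="wrap")
        den = ndimage.convolve1d(vs, kernel, mode="wrap")
        sm = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        c = np.where(valid, sm, 0.0)
    c = np.where(valid, c, np.nan)
    return c, valid


def sample_to_st(image: np.ndarray, contour: Contour, ds: float = 1.0, dt: float = 1.0,
                 s_max: Optional[float] = None, mask: Optional[np.ndarray] = None,
                 s_min: float = 0.0, interp_order: int = 1) -> STImage:
    """Resample an image into the contour's (s, t) band.

    Interpolation is bilinear by default (``interp_order=1``); cubic spline
    sampling (``interp_order=3``) has markedly lower interpolation bias on
    smooth fields and is what the extraction pipeline uses.  ``valid[i, j]``
    is False where the inverse-mapped point leaves the image or, when
    ``mask`` is given, exceeds the centerline depth ``c(t)``.  ``s_min`` may
    be negative to include a lead-in margin outside the contour (used to
    anchor reintegration where the shadow vanishes).
    """
    if ds <= 0 or dt <= 0:
        raise ValueError("ds and dt must be positive")
    if s_min > 0:
        raise ValueError("s_min must be <= 0")
    image = np.asarray(image, dtype=float)
    centerline = None
    if mask is not None:
        centerline, cl_valid = compute_centerline(contour, mask, dt=dt)
    if s_max is None:
        if centerline is None:
            raise ValueError("s_max is required when no rib mask is given")
        finite = centerline[np.isfinite(centerline)]
        if finite.size == 0 or finite.max() <= 0:
            raise ContourError(f"empty band for contour {contour.label!r}")
        s_max = float(finite.max())
    if s_max <= 0:
        raise ValueError("s_max must be positive")

    Sn = int(np.ceil((s_max - s_min) / ds)) + 1
    Tn = int(np.ceil(contour.total_length / dt))
    s_grid = s_min + np.arange(Sn) * ds
    t_grid = np.arange(Tn) * dt
    SS, TT = np.meshgrid(s_grid, t_grid, indexing="ij")
    pts = inverse_map_many(contour, SS.ravel(), TT.ravel())
    H, W = image.shape
    x, y = pts[:, 0], pts[:, 1]
    in_img = (x >= 0) & (x <= W - 1) & (y >= 0) & (y <= H - 1)
    vals = ndimage.map_coordinates(image, [y, x], order=interp_order, mode="nearest")
    values = vals.reshape(Sn, Tn)
    valid = in_img.reshape(Sn, Tn)
    if centerline is not None:
        limit = np.where(np.isfinite(centerline), centerline, -1.0)
        valid &= s_grid[:, None] <= limit[None, :] + 1e-9
    return STImage(values=values, valid=valid, ds=ds, dt=dt, s_max=float(s_max),
                   centerline=centerline, contour=contour, s_min=float(s_min))


def splat_to_image(st: STImage, shape: tuple[int, int],
                   fill_mask: Optional[np.ndarray] = None,
                   cell_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Rasterise an ST band back to image space (inverse of :func:`sample_to_st`).

    Each valid ST cell deposits its value at its inverse-mapped position with
    bilinear weights; accumulated values are normalised by accumulated weight.
    Pixels of ``fill_mask`` left uncovered are filled from the nearest covered
    pixel.  ``cell_mask`` optionally restricts which ST cells are splatted.
    """
    if st.contour is None:
        raise ValueError("STImage lacks its contour; cannot rasterise")
    H, W = shape
    use = st.valid if cell_mask is None else (st.valid & cell_mask)
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    si, tj = np.nonzero(use)
    if len(si):
        pts = inverse_map_many(st.contour, st.s_min + si * st.ds, tj * st.dt)
        v = st.values[si, tj]
        x, y = pts[:, 0], pts[:, 1]
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx, fy = x - x0, y - y0
        for ddx, ddy, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                            (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
            xi, yi = x0 + ddx, y0 + ddy
            ok = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H) & (w > 0)
            np.add.at(acc, (yi[ok], xi[ok]), v[ok] * w[ok])
            np.add.at(wacc, (yi[ok], xi[ok]), w[ok])
    out = np.zeros((H, W))
    covered = wacc > 0
    out[covered] = acc[covered] / wacc[covered]
    if fill_mask is not None:
        holes = np.asarray(fill_mask, dtype=bool) & ~covered
        if holes.any() and covered.any():
            _, (iy, ix) = ndimage.distance_transform_edt(~covered, return_indices=True)
            out[holes] = out[iy[holes], ix[holes]]
    return out
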