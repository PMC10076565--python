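"""Contour and cross-section geometry for vessel-wall morphometry.

A plaque segmentation is a stack of cross-sections, each holding an ordered
lumen polygon nested inside an ordered outer-wall polygon, in millimetre
coordinates.  This module provides the geometric primitives every downstream
index is built from: polygon areas, effective circular diameters, wall
thickness extrema measured from the lumen boundary to the outer wall, wall
annulus rasterization onto an intensity grid, and perpendicular cross-section
resampling (multiplanar reformation) of a 3-D volume along a centerline.

Coordinate conventions
----------------------
* 2-D slices are indexed ``[row, col]`` with the voxel center of ``(r, c)``
  at millimetre position ``x = c * spacing``, ``y = r * spacing``.
* 3-D volumes are indexed ``[z, y, x]``; world coordinates are ``(x, y, z)``
  with the center of voxel ``(iz, iy, ix)`` at
  ``(ix * sx, iy * sy, iz * sz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.validation import explain_validity


class GeometryError(ValueError):
    """Base class for contour/section validation and geometry failures."""


class DegenerateContourError(GeometryError):
    """Fewer than three vertices or (numerically) zero enclosed area."""


class InvalidContourError(GeometryError):
    """Self-intersecting or otherwise non-simple polygon."""


class ContainmentError(GeometryError):
    """Lumen contour not strictly inside the outer-wall contour."""


class EmptyROIError(GeometryError):
    """Rasterization produced no voxels."""


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon (implicit closing edge), counter-clockwise.

    Orientation is normalized to counter-clockwise at construction;
    degenerate and self-intersecting inputs are rejected.
    """

    vertices: np.ndarray
    label: str = "lumen"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise DegenerateContourError("vertices must be an (n, 2) array")
        # drop an explicit closing vertex if present
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise DegenerateContourError(
                f"contour needs >= 3 vertices, got {len(v)}"
            )
        if not np.all(np.isfinite(v)):
            raise DegenerateContourError("contour has non-finite coordinates")
        if not Polygon(v).is_valid:
            reason = explain_validity(Polygon(v))
            if "Self-intersection" in reason or "Ring Self-intersection" in reason:
                raise InvalidContourError(f"contour is not simple: {reason}")
            raise DegenerateContourError(f"invalid contour: {reason}")
        area = _signed_area(v)
        if abs(area) < 1e-12:
            raise DegenerateContourError("contour encloses zero area")
        if area < 0:  # normalize to CCW
            v = v[::-1].copy()
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def transformed(
        self,
        rotation: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        scale: float = 1.0,
    ) -> "Contour":
        """Rigid rotation (radians, about the origin) + scale + translation."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ rot.T) + np.asarray(translation, float)
        return Contour(v, label=self.label)


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Absolute (orientation-independent) enclosed area in mm²."""
    if not isinstance(contour, Contour):
        contour = Contour(np.asarray(contour, dtype=float))
    return abs(_signed_area(contour.vertices))


def effective_diameter(area: float) -> float:
    """Diameter of the circle with the given area: ``2 * sqrt(area / pi)``."""
    if area < 0:
        raise GeometryError(f"area must be >= 0, got {area}")
    return 2.0 * float(np.sqrt(area / np.pi))


@dataclass(frozen=True)
class CrossSection:
    """One vessel cross-section: lumen nested inside the outer wall."""

    slice_index: int
    lumen: Contour
    outer_wall: Contour
    slice_spacing: float = 0.5

    def __post_init__(self) -> None:
        if self.slice_spacing <= 0:
            raise GeometryError("slice_spacing must be > 0")
        outer = self.outer_wall.polygon
        lx, ly = self.lumen.vertices[:, 0], self.lumen.vertices[:, 1]
        if not np.all(shapely.contains_xy(outer, lx, ly)):
            raise ContainmentError(
                f"slice {self.slice_index}: lumen not inside outer wall"
            )
        if polygon_area(self.lumen) >= polygon_area(self.outer_wall):
            raise ContainmentError(
                f"slice {self.slice_index}: lumen area >= outer-wall area"
            )

    @property
    def lumen_area(self) -> float:
        return polygon_area(self.lumen)

    @property
    def outer_area(self) -> float:
        return polygon_area(self.outer_wall)

    @property
    def wall_area(self) -> float:
        return self.outer_area - self.lumen_area


def wall_thickness_extrema(
    section: CrossSection, n_samples: int = 256
) -> tuple[float, float]:
    """Maximum and minimum wall thickness of a cross-section, in mm.

    The lumen boundary is resampled to ``n_samples`` points equally spaced
    by arc length; at each point the thickness is the shortest Euclidean
    distance to the outer-wall polygon boundary (edges included).  Returns
    ``(wall_max, wall_min)``.
    """
    if n_samples < 64:
        raise GeometryError("n_samples must be >= 64")
    ring = section.lumen.polygon.exterior
    distances = np.arange(n_samples) * (ring.length / n_samples)
    points = shapely.line_interpolate_point(ring, distances)
    thickness = shapely.distance(points, section.outer_wall.polygon.exterior)
    return float(thickness.max()), float(thickness.min())


def rasterize_wall_roi(
    section: CrossSection,
    grid_shape: tuple[int, int],
    spacing: float = 0.5,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Voxel indices of the wall annulus on a 2-D grid.

    Returns an ``(n, 2)`` integer array of ``(row, col)`` indices of voxels
    whose centers lie inside the outer wall and outside the lumen,
    lexicographically sorted (deterministic for a fixed grid).
    """
    ny, nx = grid_shape
    outer = section.outer_wall.polygon
    minx, miny, maxx, maxy = outer.bounds
    x_max = origin[0] + (nx - 1) * spacing
    y_max = origin[1] + (ny - 1) * spacing
    if minx < origin[0] - spacing / 2 or maxx > x_max + spacing / 2 \
            or miny < origin[1] - spacing / 2 or maxy > y_max + spacing / 2:
        raise GeometryError("contour extends beyond grid bounds")
    c0 = max(int(np.floor((minx - origin[0]) / spacing)), 0)
    c1 = min(int(np.ceil((maxx - origin[0]) / spacing)), nx - 1)
    r0 = max(int(np.floor((miny - origin[1]) / spacing)), 0)
    r1 = min(int(np.ceil((maxy - origin[1]) / spacing)), ny - 1)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    xs = origin[0] + cols.ravel() * spacing
    ys = origin[1] + rows.ravel() * spacing
    inside = shapely.contains_xy(outer, xs, ys) & ~shapely.contains_xy(
        section.lumen.polygon, xs, ys
    )
    if not inside.any():
        raise EmptyROIError("wall annulus covers no voxel centers")
    idx = np.column_stack([rows.ravel()[inside], cols.ravel()[inside]])
    order = np.lexsort((idx[:, 1], idx[:, 0]))
    return idx[order]


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D polyline (mm) with arc-length parameterization."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
            raise GeometryError("centerline needs >= 2 three-dimensional points")
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(steps == 0):
            raise GeometryError("consecutive centerline points must be distinct")
        p.setflags(write=False)
        object.__setattr__(self, "points", p)

    @property
    def arc_lengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def point_and_tangent(self, station: float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated point and unit tangent at an arc-length station."""
        s = self.arc_lengths
        if not 0.0 <= station <= s[-1]:
            raise GeometryError(
                f"station {station} outside centerline arc length [0, {s[-1]}]"
            )
        point = np.array([np.interp(station, s, self.points[:, k]) for k in range(3)])
        tangents = np.gradient(self.points, s, axis=0)
        tangent = np.array([np.interp(station, s, tangents[:, k]) for k in range(3)])
        return point, tangent / np.linalg.norm(tangent)


@dataclass(frozen=True)
class MPRSlice:
    """Result of a multiplanar reformation: the 2-D slice plus metadata."""

    data: np.ndarray
    spacing: float
    origin: np.ndarray          # plane center, world mm
    axis_u: np.ndarray          # in-plane unit vector along columns
    axis_v: np.ndarray          # in-plane unit vector along rows
    out_of_bounds: bool         # True if any sample fell outside the volume


def mpr_resample(
    volume: np.ndarray,
    centerline: Centerline,
    station: float,
    plane_size: float,
    spacing: float,
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
) -> MPRSlice:
    """Extract the plane normal to the centerline tangent at ``station``.

    Trilinear interpolation; samples outside the volume use nearest-neighbor
    fill and set the ``out_of_bounds`` flag.  ``voxel_spacing`` is
    ``(sz, sy, sx)`` matching the ``[z, y, x]`` volume layout.
    """
    if spacing <= 0 or plane_size <= 0:
        raise GeometryError("plane_size and spacing must be > 0")
    p0, t = centerline.point_and_tangent(station)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ t) * t
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    n = int(round(plane_size / spacing)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    world = (
        p0[None, None, :]
        + offsets[:, None, None] * v[None, None, :]
        + offsets[None, :, None] * u[None, None, :]
    )  # (rows, cols, xyz)
    sz, sy, sx = voxel_spacing
    coords = np.stack(
        [world[..., 2] / sz, world[..., 1] / sy, world[..., 0] / sx]
    )
    upper = np.array(volume.shape, dtype=float) - 1.0
    oob = bool(
        np.any(coords < -1e-9)
        or np.any(coords > upper[:, None, None] + 1e-9)
    )
    data = ndimage.map_coordinates(
        np.asarray(volume, dtype=float), coords, order=1, mode="nearest"
    )
    return MPRSlice(
        data=data, spacing=spacing, origin=p0, axis_u=u, axis_v=v,
        out_of_bounds=oob,
    )


@dataclass(frozen=True)
class LesionStack:
    """Per-plaque segmentation bundle linked to co-registered volumes.

    ``volumes`` maps weighting names (``t2``, ``t1_pre``, ``t1_post``) to
    ``[z, y, x]`` arrays on one shared grid; ``gray_matter_roi`` and
    ``muscle_roi`` are ``(n, 3)`` integer voxel-index arrays.
    """

    stenotic: CrossSection
    proximal_ref: CrossSection
    distal_ref: CrossSection
    whole_plaque: tuple[CrossSection, ...]
    volumes: Mapping[str, np.ndarray]
    gray_matter_roi: np.ndarray
    muscle_roi: np.ndarray
    voxel_spacing: float = 0.5
    plaque_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "whole_plaque", tuple(self.whole_plaque))
        if not self.whole_plaque:
            raise GeometryError("whole_plaque must be non-empty")
        indices = {s.slice_index for s in self.whole_plaque}
        if self.stenotic.slice_index not in indices:
            raise GeometryError(
                "whole_plaque does not contain the stenotic slice index"
            )
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise GeometryError("all volumes must share one grid")
        for name in ("gray_matter_roi", "muscle_roi"):
            roi = np.asarray(getattr(self, name), dtype=int)
            if roi.size == 0:
                raise GeometryError(f"{name} is empty")
            object.__setattr__(self, name, roi)
        shape = next(iter(shapes))
        wall = self.wall_mask()
        for name in ("gray_matter_roi", "muscle_roi"):
            roi = getattr(self, name)
            if np.any(roi < 0) or np.any(roi >= np.array(shape)[None, :]):
                raise GeometryError(f"{name} outside the volume grid")
            if wall[roi[:, 0], roi[:, 1], roi[:, 2]].any():
                raise GeometryError(f"{name} overlaps plaque wall voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def sections_by_index(self) -> dict[int, CrossSection]:
        return {s.slice_index: s for s in self.whole_plaque}

    def wall_mask(self) -> np.ndarray:
        """Boolean ``[z, y, x]`` mask of all whole-plaque wall voxels."""
        nz, ny, nx = self.grid_shape
        mask = np.zeros((nz, ny, nx), dtype=bool)
        for section in self.whole_plaque:
            idx = rasterize_wall_roi(section, (ny, nx), self.voxel_spacing)
            mask[section.slice_index, idx[:, 0], idx[:, 1]] = True
        return mask

    def roi_values(self, weighting: str, roi: np.ndarray) -> np.ndarray:
        vol = self.volumes[weighting]
        roi = np.asarray(roi, dtype=int)
        return vol[roi[:, 0], roi[:, 1], roi[:, 2]]

    def with_sections(
        self,
        stenotic: CrossSection,
        proximal_ref: CrossSection,
        distal_ref: CrossSection,
        whole_plaque: tuple[CrossSection, ...],
    ) -> "LesionStack":
        return replace(
            self,
            stenotic=stenotic,
            proximal_ref=proximal_ref,
            distal_ref=distal_ref,
            whole_plaque=whole_plaque,
        )
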