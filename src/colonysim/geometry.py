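"""Closed polygonal chains for the cell shape catalogue.

Every cell outline in the simulator is a closed 2D polygon with vertices in
micrometres.  The catalogue provides the four standard unicellular shapes --
straight rod (capsule), bent rod (arc-swept capsule), coccoid (circle) and
ellipsoid (ellipse) -- plus the exact polygon measures (area, pairwise
overlap) that the placement solver and the renderers rely on.

Conventions
-----------
* ``length`` is tip-to-tip including the hemispherical caps, matching how
  cell length is read off a micrograph.
* Polygons are stored counterclockwise; normalization happens on
  construction.
* The bent rod is parametrized by the total arc angle of its centerline
  (bounded, dimensionless), not by a curvature radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "InvalidShapeError",
    "PolygonChain",
    "ShapeParams",
    "make_rod",
    "make_bent_rod",
    "make_coccoid",
    "make_ellipsoid",
    "make_shape",
    "polygon_area",
    "polygon_centroid",
    "polygon_overlap_area",
    "place",
]

DEFAULT_N_VERTICES = 32

ShapeKind = Literal["rod", "bent_rod", "coccoid", "ellipsoid"]


class InvalidShapeError(ValueError):
    """Raised for degenerate shape dimensions or insufficient vertex counts."""


def _signed_area(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PolygonChain:
    """A simple closed polygon: ordered (x, y) vertices in µm.

    The last vertex connects implicitly back to the first.  On construction
    the loop is normalized to counterclockwise orientation and validated:
    at least 8 vertices, nonzero signed area, no self-intersection.
    """

    vertices: np.ndarray

    def __init__(self, vertices: Iterable) -> None:
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 8:
            raise InvalidShapeError(
                f"polygon chain needs >= 8 (x, y) vertices, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidShapeError("polygon chain has non-finite vertices")
        sa = _signed_area(arr)
        if sa == 0.0:
            raise InvalidShapeError("polygon chain has zero area")
        if sa < 0.0:
            arr = arr[::-1].copy()
        if not _ShapelyPolygon(arr).is_simple:
            raise InvalidShapeError("polygon chain is self-intersecting")
        arr.setflags(write=False)
        object.__setattr__(self, "vertices", arr)

    def __len__(self) -> int:
        return self.vertices.shape[0]


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one catalogue shape.

    length/width are tip-to-tip and across in µm; ``bend`` (bent_rod only)
    is the total arc angle of the centerline in radians.
    """

    kind: ShapeKind
    length: float
    width: float
    bend: float = 0.0
    n_vertices: int = DEFAULT_N_VERTICES

    def __post_init__(self) -> None:
        if self.kind not in ("rod", "bent_rod", "coccoid", "ellipsoid"):
            raise InvalidShapeError(f"unknown shape kind {self.kind!r}")
        if not (self.width > 0 and self.length > 0):
            raise InvalidShapeError("length and width must be positive")
        if self.kind in ("rod", "bent_rod") and self.length < self.width:
            raise InvalidShapeError("rod length must be >= width")
        if self.kind == "coccoid" and self.length != self.width:
            raise InvalidShapeError("coccoid requires length == width")
        if self.n_vertices < 8:
            raise InvalidShapeError("n_vertices must be >= 8")
        if self.kind == "bent_rod":
            if not abs(self.bend) < np.pi:
                raise InvalidShapeError("|bend| must be < pi")
            _check_bend_radius(self.length, self.width, self.bend)


def _check_bend_radius(length: float, width: float, bend: float) -> None:
    """A bent rod is only simple if the centerline's curvature radius
    exceeds the cap radius; otherwise the inner offset curve cusps."""
    if abs(bend) < 1e-12:
        return
    radius = (length - width) / abs(bend)
    if radius <= width / 2.0:
        raise InvalidShapeError(
            f"bend {bend:.3g} too sharp for length {length:.3g}, width {width:.3g}: "
            f"centerline radius {radius:.3g} µm must exceed the cap radius {width / 2:.3g} µm"
        )


def _as_vertices(chain: Union[PolygonChain, Iterable]) -> np.ndarray:
    if isinstance(chain, PolygonChain):
        return chain.vertices
    arr = np.asarray(chain, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidShapeError(f"expected (n, 2) vertex array, got shape {arr.shape}")
    return arr


def make_rod(length: float, width: float, n_vertices: int = DEFAULT_N_VERTICES) -> PolygonChain:
    """Straight rod: a capsule of tip-to-tip ``length`` and ``width``.

    A rectangle of length ``length - width`` capped by two semicircles of
    radius ``width / 2``; centroid at the origin, major axis along +x.
    """
    if not (length >= width > 0):
        raise InvalidShapeError("rod requires length >= width > 0")
    if n_vertices < 8:
        raise InvalidShapeError("n_vertices must be >= 8")
    r = width / 2.0
    half = (length - width) / 2.0
    if half == 0.0:  # degenerate capsule: a circle
        t = np.linspace(-np.pi / 2, 3 * np.pi / 2, n_vertices, endpoint=False)
        return PolygonChain(np.column_stack([r * np.cos(t), r * np.sin(t)]))
    n_cap = n_vertices // 2
    # right cap sweeps -90..+90 deg, left cap +90..270 deg; cap endpoints are
    # the rectangle corners, so the straight flanks are implicit edges
    t_right = np.linspace(-np.pi / 2, np.pi / 2, n_cap)
    t_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_vertices - n_cap)
    right = np.column_stack([half + r * np.cos(t_right), r * np.sin(t_right)])
    left = np.column_stack([-half + r * np.cos(t_left), r * np.sin(t_left)])
    return PolygonChain(np.vstack([right, left]))


def make_bent_rod(
    length: float, width: float, bend: float, n_vertices: int = DEFAULT_N_VERTICES
) -> PolygonChain:
    """Bent rod: a capsule whose centerline is a circular arc.

    The centerline has arc length ``length - width`` and subtends the total
    angle ``bend`` (radians).  ``bend = 0`` reduces exactly to
    :func:`make_rod`.  The polygon is re-centred so its centroid is at the
    origin with the chord of the centerline along +x.
    """
    if not (length >= width > 0):
        raise InvalidShapeError("bent rod requires length >= width > 0")
    if n_vertices < 8:
        raise InvalidShapeError("n_vertices must be >= 8")
    if not abs(bend) < np.pi:
        raise InvalidShapeError("|bend| must be < pi")
    if abs(bend) < 1e-12:
        return make_rod(length, width, n_vertices)
    _check_bend_radius(length, width, bend)

    r = width / 2.0
    arc_len = length - width
    # signed curvature radius: centerline is an arc of radius |R| whose
    # midpoint sits at the origin with tangent along +x
    R = arc_len / bend if arc_len > 0 else 0.0

    n_cap = max(4, n_vertices // 4)
    n_side = max(4, (n_vertices - 2 * n_cap) // 2 + 1)

    def centerline(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Point and tangent angle at arc-length fraction s in [0, 1]."""
        theta = bend * (s - 0.5)
        if arc_len == 0:
            return np.zeros((len(s), 2)), theta
        return np.column_stack([R * np.sin(theta), R * (1.0 - np.cos(theta))]), theta

    s_side = np.linspace(0.0, 1.0, n_side)
    pts, theta = centerline(s_side)
    normals = np.column_stack([-np.sin(theta), np.cos(theta)])

    left = pts + r * normals  # offset band walking s: 0 -> 1
    right = pts - r * normals

    # tip cap at s=1: semicircle swinging from -normal through +tangent to +normal
    tcap1 = theta[-1] + np.linspace(-np.pi / 2, np.pi / 2, n_cap)[1:-1]
    cap1 = pts[-1] + r * np.column_stack([np.cos(tcap1), np.sin(tcap1)])
    # base cap at s=0: from +normal through -tangent back to -normal
    tcap0 = theta[0] + np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap)[1:-1]
    cap0 = pts[0] + r * np.column_stack([np.cos(tcap0), np.sin(tcap0)])

    verts = np.vstack([right, cap1, left[::-1], cap0])
    chain = PolygonChain(verts)
    c = polygon_centroid(chain)
    return PolygonChain(chain.vertices - c)


def make_coccoid(width: float, n_vertices: int = DEFAULT_N_VERTICES) -> PolygonChain:
    """Coccoid (circular) cell of diameter ``width``."""
    return make_ellipsoid(width, width, n_vertices)


def make_ellipsoid(
    major: float, minor: float, n_vertices: int = DEFAULT_N_VERTICES
) -> PolygonChain:
    """Ellipse contour with semi-axes ``major / 2`` and ``minor / 2``.

    ``major == minor`` yields the coccoid.
    """
    if not (major >= minor > 0):
        raise InvalidShapeError("ellipsoid requires major >= minor > 0")
    if n_vertices < 8:
        raise InvalidShapeError("n_vertices must be >= 8")
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([0.5 * major * np.cos(t), 0.5 * minor * np.sin(t)])
    return PolygonChain(verts)


def make_shape(params: ShapeParams) -> PolygonChain:
    """Instantiate a catalogue shape, centred at the origin."""
    if params.kind == "rod":
        return make_rod(params.length, params.width, params.n_vertices)
    if params.kind == "bent_rod":
        return make_bent_rod(params.length, params.width, params.bend, params.n_vertices)
    if params.kind == "coccoid":
        return make_coccoid(params.width, params.n_vertices)
    return make_ellipsoid(params.length, params.width, params.n_vertices)


def polygon_area(chain: Union[PolygonChain, Iterable]) -> float:
    """Unsigned shoelace area in µm²; independent of vertex orientation."""
    return abs(_signed_area(_as_vertices(chain)))


def polygon_centroid(chain: Union[PolygonChain, Iterable]) -> np.ndarray:
    """Area centroid (µm) of the closed polygon."""
    v = _as_vertices(chain)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_overlap_area(
    a: Union[PolygonChain, Iterable], b: Union[PolygonChain, Iterable]
) -> float:
    """Area (µm²) of the intersection of two closed polygonal regions."""
    pa = _ShapelyPolygon(_as_vertices(a))
    pb = _ShapelyPolygon(_as_vertices(b))
    if not pa.intersects(pb):
        return 0.0
    return float(shapely.intersection(pa, pb).area)


def place(
    chain: Union[PolygonChain, Iterable], position: tuple[float, float], angle: float
) -> PolygonChain:
    """Rigidly place a shape: rotate by ``angle`` about the origin, then translate."""
    v = _as_vertices(chain)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return PolygonChain(v @ rot.T + np.asarray(position, dtype=float))
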