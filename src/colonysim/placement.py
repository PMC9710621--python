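"""Overlap resolution: keep the growing colony a feasible 2D monolayer packing.

After every growth/division pass the cell polygons may interpenetrate.
This module resolves them with an iterative rigid-body separation solver
working on capsule spines: every catalogue shape is approximated by a
centerline polyline with a contact radius (a rod is exactly a capsule, a
coccoid a point, a bent rod a short arc polyline), so the penetration depth
of a cell pair is ``r_i + r_j - distance(spine_i, spine_j)`` -- a cheap,
fully vectorized computation.  Each relaxation pass pushes penetrating
pairs apart along the true contact normal and applies a torque about each
cell centre, which lets rods slide past one another and produces the
nematic ordering seen in real rod-shaped microcolonies.

Convergence, however, is judged on the exact cell polygons: after each
relaxation round the solver intersects all candidate polygon pairs
(STR-tree broad phase, exact polygon intersection) and stops only when
every pairwise overlap area is at most ``overlap_tolerance`` times the
smaller cell's area.  If a round ever increases the global overlap area it
is reverted and retried with smaller steps, so the logged per-iteration
totals are non-increasing; a radial colony expansion serves as a fallback
for uniformly compressed packings.

Cells are rigid throughout: lengths, widths and bends never change here,
only positions and angles.  The solver is deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.strtree import STRtree

from .agents import CellAgent
from .geometry import ShapeParams, make_shape

__all__ = ["PlacementConfig", "InvalidStateError", "resolve_overlaps", "colony_bounding_box"]

logger = logging.getLogger(__name__)


class InvalidStateError(ValueError):
    """Raised when agents carry non-finite poses."""


@dataclass(frozen=True)
class PlacementConfig:
    """Solver parameters.

    overlap_tolerance is a fraction of the smaller cell's area (default 1%,
    sub-pixel at 0.09 µm/pixel).  damping scales each separation step;
    torque_gain scales the angular response.  boundary, if set, is a
    rectangular arena (min_x, min_y, max_x, max_y) in µm that cells are
    pushed back into.
    """

    max_iterations: int = 50
    overlap_tolerance: float = 0.01
    damping: float = 0.7
    torque_gain: float = 0.15
    inner_passes: int = 60
    boundary: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.overlap_tolerance < 0:
            raise ValueError("overlap_tolerance must be >= 0")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")


# --------------------------------------------------------------------------
# exact polygon oracle (convergence check)


def _world_polygons(base_verts, positions, angles):
    """Shapely polygons for every agent at the given trial poses (vectorized).

    All cells sharing one vertex count are created in a single C call.
    """
    n = len(base_verts)
    cos, sin = np.cos(angles), np.sin(angles)
    counts = np.array([len(b) for b in base_verts])
    out = np.empty(n, dtype=object)
    for m in np.unique(counts):
        idx = np.flatnonzero(counts == m)
        stack = np.stack([base_verts[k] for k in idx])  # (n_m, m, 2)
        c, s = cos[idx], sin[idx]
        x = stack[..., 0] * c[:, None] - stack[..., 1] * s[:, None]
        y = stack[..., 0] * s[:, None] + stack[..., 1] * c[:, None]
        world = np.stack([x, y], axis=-1) + positions[idx][:, None, :]
        out[idx] = shapely.polygons(world)
    return out


def _pair_overlaps(polys):
    """All intersecting index pairs (i < j) and their intersection geometries."""
    if len(polys) < 2:
        return np.empty((0, 2), dtype=int), np.empty(0, dtype=object)
    tree = STRtree(polys)
    left, right = tree.query(polys, predicate="intersects")
    keep = left < right
    pairs = np.column_stack([left[keep], right[keep]])
    polys = np.asarray(polys, dtype=object)
    inters = shapely.intersection(polys[pairs[:, 0]], polys[pairs[:, 1]])
    return pairs, inters


def _total_overlap(polys) -> float:
    _, inters = _pair_overlaps(polys)
    return float(np.sum(shapely.area(inters))) if len(inters) else 0.0


# --------------------------------------------------------------------------
# capsule-spine contact model


def _body_spine(shape: ShapeParams) -> np.ndarray:
    """Centerline polyline of a shape in its body frame."""
    if shape.kind == "coccoid":
        return np.zeros((2, 2))
    half = max((shape.length - shape.width) / 2.0, 0.0)
    if shape.kind in ("rod", "ellipsoid") or abs(shape.bend) < 1e-12:
        return np.array([[-half, 0.0], [half, 0.0]])
    # bent rod: sample the centerline arc finely enough that the chordal
    # error stays far below the contact-depth tolerance
    arc_len = shape.length - shape.width
    R = arc_len / shape.bend
    n_pts = max(5, int(np.ceil(abs(shape.bend) / 0.15)) + 1)
    theta = shape.bend * (np.linspace(0.0, 1.0, n_pts) - 0.5)
    return np.column_stack([R * np.sin(theta), R * (1.0 - np.cos(theta))])


def _segment_closest_points(p1, p2, q1, q2):
    """Vectorized closest points between segment batches [p1,p2] and [q1,q2].

    Returns (ca, cb, dist): closest point on each segment and the distance.
    Clamped-parameter formulation; degenerate (zero-length) segments are
    handled by the clamping.
    """
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-14, np.clip((b * f - c * e) / np.where(denom > 1e-14, denom, 1.0), 0, 1), 0.0)
    t_nom = b * s + f
    t = np.clip(np.where(e > 1e-14, t_nom / np.where(e > 1e-14, e, 1.0), 0.0), 0, 1)
    # recompute s for the clamped t
    s = np.clip(np.where(a > 1e-14, (b * t - c) / np.where(a > 1e-14, a, 1.0), 0.0), 0, 1)
    ca = p1 + s[:, None] * d1
    cb = q1 + t[:, None] * d2
    dist = np.linalg.norm(ca - cb, axis=1)
    return ca, cb, dist


def _fallback_direction(i, j):
    """Deterministic unit vectors for coincident contact points."""
    h = (i * 73856093) ^ (j * 19349663)
    ang = (h % 6283185) / 1e6
    return np.column_stack([np.cos(ang), np.sin(ang)])


class _SpineModel:
    """Precomputed per-cell spine data and the vectorized contact sweep."""

    def __init__(self, agents: list[CellAgent]):
        self.n = len(agents)
        self.radii = np.array([a.shape.width / 2.0 for a in agents])
        self.bound = np.array([a.shape.length / 2.0 for a in agents])
        self.gyr2 = np.array(
            [(a.shape.length ** 2 + a.shape.width ** 2) / 12.0 for a in agents]
        )
        spines = [_body_spine(a.shape) for a in agents]
        self.k = np.array([len(s) for s in spines])
        self.max_k = int(self.k.max()) if self.n else 2
        # pad all spines to max_k by repeating the last point
        pad = np.zeros((self.n, self.max_k, 2))
        for idx, s in enumerate(spines):
            pad[idx, : len(s)] = s
            pad[idx, len(s):] = s[-1]
        self.body = pad

    def world_spines(self, positions, angles):
        c, s = np.cos(angles), np.sin(angles)
        x = self.body[..., 0] * c[:, None] - self.body[..., 1] * s[:, None]
        y = self.body[..., 0] * s[:, None] + self.body[..., 1] * c[:, None]
        return np.stack([x, y], axis=-1) + positions[:, None, :]

    def candidate_pairs(self, positions):
        """Bounding-circle broad phase on the current cell centres."""
        if self.n < 2:
            return np.empty((0, 2), dtype=int)
        tree = cKDTree(positions)
        pairs = tree.query_pairs(r=2.0 * self.bound.max() + 1e-9, output_type="ndarray")
        if len(pairs) == 0:
            return pairs
        keep = (
            np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
            <= self.bound[pairs[:, 0]] + self.bound[pairs[:, 1]]
        )
        return pairs[keep]

    def contacts(self, spines, pairs):
        """Penetration depth, contact normal and contact point per pair.

        The normal points from cell j towards cell i (push direction of i).
        """
        i, j = pairs[:, 0], pairs[:, 1]
        nseg = self.max_k - 1
        best_dist = np.full(len(pairs), np.inf)
        best_ca = np.zeros((len(pairs), 2))
        best_cb = np.zeros((len(pairs), 2))
        for si in range(nseg):
            for sj in range(nseg):
                # skip padded segments (zero length repeats are harmless but wasteful)
                mask = (si < np.maximum(self.k[i] - 1, 1)) & (sj < np.maximum(self.k[j] - 1, 1))
                if not mask.any():
                    continue
                ca, cb, dist = _segment_closest_points(
                    spines[i, si], spines[i, si + 1], spines[j, sj], spines[j, sj + 1]
                )
                better = mask & (dist < best_dist)
                best_dist = np.where(better, dist, best_dist)
                best_ca[better] = ca[better]
                best_cb[better] = cb[better]
        depth = self.radii[i] + self.radii[j] - best_dist
        normal = best_ca - best_cb
        norms = np.linalg.norm(normal, axis=1)
        degenerate = norms < 1e-9
        if degenerate.any():
            normal[degenerate] = _fallback_direction(i[degenerate], j[degenerate])
            norms = np.where(degenerate, 1.0, norms)
        normal /= norms[:, None]
        contact = 0.5 * (best_ca + best_cb)
        return depth, normal, contact


def resolve_overlaps(
    agents: list[CellAgent],
    config: PlacementConfig,
    history: list[float] | None = None,
) -> list[CellAgent]:
    """Separate overlapping cells; returns agents with updated poses only.

    If ``history`` is given, the total pairwise polygon overlap area (µm²)
    at each outer iteration is appended to it -- a non-increasing sequence.
    Deterministic for identical inputs.
    """
    if not agents:
        return []
    positions = np.array([a.position for a in agents], dtype=float)
    angles = np.array([a.angle for a in agents], dtype=float)
    if not (np.all(np.isfinite(positions)) and np.all(np.isfinite(angles))):
        raise InvalidStateError("agents carry non-finite positions or angles")

    base_verts = [make_shape(a.shape).vertices for a in agents]
    areas = np.array([abs(_poly_area(v)) for v in base_verts])
    model = _SpineModel(agents)
    # depth tolerance: a contact no deeper than this cannot produce more
    # than ~overlap_tolerance of the smaller cell's area; tightened further
    # whenever the polygon oracle disagrees
    d_tol = 0.35 * config.overlap_tolerance * float(model.radii.min() * 2.0)
    damping = config.damping

    converged = False
    for _ in range(config.max_iterations):
        polys = _world_polygons(base_verts, positions, angles)
        pairs, inters = _pair_overlaps(polys)
        overlaps = shapely.area(inters) if len(inters) else np.empty(0)
        total = float(overlaps.sum())
        if history is not None:
            history.append(total)

        limits = (
            config.overlap_tolerance * np.minimum(areas[pairs[:, 0]], areas[pairs[:, 1]])
            if len(pairs)
            else np.empty(0)
        )
        if not len(pairs) or np.all(overlaps <= limits):
            converged = True
            break

        accepted = False
        for _retry in range(3):
            trial_pos, trial_ang, settled = _relax(
                model, positions, angles, config, damping, d_tol
            )
            if config.boundary is not None:
                trial_pos = _clamp_to_boundary(base_verts, trial_pos, trial_ang, config.boundary)
            trial_total = _total_overlap(_world_polygons(base_verts, trial_pos, trial_ang))
            if trial_total <= total:
                if trial_total == total and settled:
                    # spine model is content but the polygon oracle is not:
                    # demand deeper separation next round
                    d_tol *= 0.5
                positions, angles = trial_pos, trial_ang
                accepted = True
                break
            damping *= 0.5
        if not accepted:
            # uniformly compressed packing: expand radially about the centroid
            centre = positions.mean(axis=0)
            for eps in (0.04, 0.02, 0.01, 0.005):
                trial_pos = centre + (1.0 + eps) * (positions - centre)
                if config.boundary is not None:
                    trial_pos = _clamp_to_boundary(base_verts, trial_pos, angles, config.boundary)
                if _total_overlap(_world_polygons(base_verts, trial_pos, angles)) < total:
                    positions = trial_pos
                    accepted = True
                    break
        if not accepted:
            logger.warning("placement stalled at total overlap %.3g µm²", total)
            break

    if not converged and history is not None and len(history) and history[-1] > 0:
        logger.warning(
            "placement hit max_iterations=%d with residual overlap %.3g µm²",
            config.max_iterations,
            history[-1],
        )

    return [
        dataclasses.replace(a, position=(float(p[0]), float(p[1])), angle=float(ang))
        for a, p, ang in zip(agents, positions, angles)
    ]


def _relax(model, positions, angles, config, damping, d_tol):
    """Inner spine relaxation: Jacobi passes pushing penetrating pairs apart.

    Returns the relaxed poses and whether all depths fell below d_tol.
    """
    positions = positions.copy()
    angles = angles.copy()
    pairs = model.candidate_pairs(positions)
    settled = True
    if len(pairs) == 0:
        return positions, angles, settled
    i, j = pairs[:, 0], pairs[:, 1]
    for _ in range(config.inner_passes):
        spines = model.world_spines(positions, angles)
        depth, normal, contact = model.contacts(spines, pairs)
        active = depth > d_tol
        if not active.any():
            settled = True
            break
        settled = False
        push = 0.5 * damping * depth[active, None] * normal[active]
        ia, ja = i[active], j[active]
        moves = np.zeros_like(positions)
        np.add.at(moves, ia, push)
        np.add.at(moves, ja, -push)
        spins = np.zeros_like(angles)
        lever_i = contact[active] - positions[ia]
        lever_j = contact[active] - positions[ja]
        tau_i = lever_i[:, 0] * push[:, 1] - lever_i[:, 1] * push[:, 0]
        tau_j = -(lever_j[:, 0] * push[:, 1] - lever_j[:, 1] * push[:, 0])
        np.add.at(spins, ia, config.torque_gain * tau_i / model.gyr2[ia])
        np.add.at(spins, ja, config.torque_gain * tau_j / model.gyr2[ja])
        positions += moves
        angles += spins
    return positions, angles, settled


def _poly_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _clamp_to_boundary(base_verts, positions, angles, boundary):
    """Shift cells whose outline spills outside the rectangular arena back in."""
    min_x, min_y, max_x, max_y = boundary
    out = positions.copy()
    for k, (base, pos, ang) in enumerate(zip(base_verts, positions, angles)):
        c, s = np.cos(ang), np.sin(ang)
        verts = base @ np.array([[c, -s], [s, c]]).T + pos
        lo = verts.min(axis=0)
        hi = verts.max(axis=0)
        shift = np.zeros(2)
        if lo[0] < min_x:
            shift[0] = min_x - lo[0]
        elif hi[0] > max_x:
            shift[0] = max_x - hi[0]
        if lo[1] < min_y:
            shift[1] = min_y - lo[1]
        elif hi[1] > max_y:
            shift[1] = max_y - hi[1]
        out[k] = pos + shift
    return out


def colony_bounding_box(agents: list[CellAgent]) -> tuple[float, float, float, float]:
    """Tight axis-aligned bounding box (µm) over all cell outline vertices."""
    if not agents:
        raise ValueError("colony_bounding_box requires at least one agent")
    all_verts = np.vstack([a.polygon().vertices for a in agents])
    lo = all_verts.min(axis=0)
    hi = all_verts.max(axis=0)
    return (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))
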