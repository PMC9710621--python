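"""Ground-truth emitters.

The simulator's value for training data generation lies here: every
rendered frame can be accompanied by pixel-accurate annotations in the
formats segmentation/detection/tracking tools consume --

* YOLO detection boxes (one normalized-box text line per cell),
* COCO instance segmentation JSON (polygon segmentation, single "cell"
  category),
* 16-bit label masks (one integer label per cell),
* TrackMate-style XML lineage tracks (spots + edges),
* watertight STL meshes of individual cells for CFD input,

plus a batch generator that renders a whole annotated dataset of
independent colonies spanning a configurable cell-count range.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import shapely
import tifffile
import trimesh
from imageio.v3 import imwrite
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon as _draw_polygon

from .agents import CellAgent, HomeostasisModel
from .engine import SimulationConfig, World, init_world, step
from .geometry import ShapeParams, polygon_area
from .placement import PlacementConfig
from .render import RenderConfig, frame_origin, render_phase_contrast, world_to_pixel

__all__ = [
    "CellAnnotation",
    "FrameAnnotation",
    "DatasetSpec",
    "annotate",
    "write_yolo",
    "write_coco",
    "read_coco",
    "write_masks",
    "write_trackmate",
    "export_mesh",
    "generate_ground_truth_dataset",
]


@dataclass(frozen=True)
class CellAnnotation:
    """One cell's per-frame ground truth, in pixel coordinates."""

    cell_id: int
    parent_id: int | None
    polygon: np.ndarray  # (n, 2) float (x, y) px, clipped to the image
    bbox: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max) px


@dataclass(frozen=True)
class FrameAnnotation:
    """All cell annotations of one frame."""

    frame_index: int
    image_size: tuple[int, int]  # (height, width) px
    cells: list[CellAnnotation]


@dataclass(frozen=True)
class DatasetSpec:
    """Batch dataset parameters: n independent colonies, one frame each.

    Per-image target cell counts are drawn log-uniformly over
    ``cell_count_range``; when the range starts at 0 the log-uniform draw
    naturally produces occasional empty frames.
    """

    n_images: int = 128
    image_size: int = 512  # square frames, px
    calibration: float = 0.09  # µm / pixel
    cell_count_range: tuple[int, int] = (0, 512)
    seed: int = 0
    emitters: tuple[str, ...] = ("yolo", "coco", "masks")
    dt: float = 0.1  # h, simulation step used while growing each colony
    max_steps: int = 3000

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.cell_count_range
        if not (hi >= lo >= 0):
            raise ValueError("cell_count_range must satisfy max >= min >= 0")
        unknown = set(self.emitters) - {"yolo", "coco", "masks"}
        if unknown:
            raise ValueError(f"unknown dataset emitters: {sorted(unknown)}")


def annotate(world: World, config: RenderConfig, frame_index: int = 0) -> FrameAnnotation:
    """Project every cell polygon into pixel coordinates and clip to the image.

    Uses the same camera transform as the renderer, so annotations align
    with rendered frames to sub-pixel accuracy.  Cells wholly outside the
    field of view are omitted.
    """
    h, w = config.image_size
    origin = frame_origin(world, config)
    frame_rect = shapely.box(0.0, 0.0, float(w), float(h))
    cells: list[CellAnnotation] = []
    for agent in world.agents:
        px = world_to_pixel(agent.polygon().vertices, origin, config.calibration)
        poly = _ShapelyPolygon(px)
        clipped = shapely.intersection(poly, frame_rect)
        if clipped.is_empty or clipped.area == 0.0:
            continue
        if clipped.geom_type == "MultiPolygon":  # keep the largest fragment
            clipped = max(clipped.geoms, key=lambda g: g.area)
        verts = np.asarray(clipped.exterior.coords[:-1], dtype=float)
        x_min, y_min, x_max, y_max = clipped.bounds
        cells.append(
            CellAnnotation(
                cell_id=agent.id,
                parent_id=agent.parent_id,
                polygon=verts,
                bbox=(float(x_min), float(y_min), float(x_max), float(y_max)),
            )
        )
    return FrameAnnotation(frame_index=frame_index, image_size=(h, w), cells=cells)


def write_yolo(annotation: FrameAnnotation, path: str | Path) -> None:
    """YOLO detection labels: one line ``0 cx cy w h`` per cell, normalized to [0, 1]."""
    h, w = annotation.image_size
    lines = []
    for cell in annotation.cells:
        x0, y0, x1, y1 = cell.bbox
        cx = (x0 + x1) / 2.0 / w
        cy = (y0 + y1) / 2.0 / h
        bw = (x1 - x0) / w
        bh = (y1 - y0) / h
        lines.append(f"0 {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_coco(
    annotations: list[FrameAnnotation],
    image_paths: list[str],
    path: str | Path,
) -> None:
    """COCO instance-segmentation JSON with polygon segmentations.

    One image record per frame, one annotation per cell with
    ``segmentation`` as a flat [x1, y1, x2, y2, ...] polygon, ``bbox`` as
    [x, y, w, h], shoelace ``area``, and the single category "cell".
    """
    images = []
    annos = []
    next_anno_id = 1
    for frame, img_path in zip(annotations, image_paths):
        h, w = frame.image_size
        image_id = frame.frame_index + 1
        images.append({"id": image_id, "file_name": str(img_path), "width": w, "height": h})
        for cell in frame.cells:
            x0, y0, x1, y1 = cell.bbox
            seg = [round(float(v), 4) for v in cell.polygon.ravel()]
            annos.append(
                {
                    "id": next_anno_id,
                    "image_id": image_id,
                    "category_id": 1,
                    "segmentation": [seg],
                    "bbox": [
                        round(x0, 4),
                        round(y0, 4),
                        round(x1 - x0, 4),
                        round(y1 - y0, 4),
                    ],
                    "area": round(polygon_area(cell.polygon), 4),
                    "iscrowd": 0,
                }
            )
            next_anno_id += 1
    doc = {
        "images": images,
        "annotations": annos,
        "categories": [{"id": 1, "name": "cell"}],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> dict:
    """Parse a COCO JSON file back into a dictionary."""
    return json.loads(Path(path).read_text())


def write_masks(annotation: FrameAnnotation, path: str | Path) -> np.ndarray:
    """16-bit instance label mask: background 0, cells labelled 1..n.

    Labels are assigned in ascending cell id; residual overlap pixels go to
    the smaller-id cell (painted last, so it wins).  Returns the mask array
    as written.
    """
    h, w = annotation.image_size
    n = len(annotation.cells)
    if n >= 65536:
        raise ValueError(f"too many cells for a 16-bit mask: {n}")
    mask = np.zeros((h, w), dtype=np.uint16)
    ordered = sorted(annotation.cells, key=lambda c: c.cell_id)
    labels = {cell.cell_id: i + 1 for i, cell in enumerate(ordered)}
    # paint larger ids first so smaller-id cells overwrite contested pixels
    for cell in sorted(annotation.cells, key=lambda c: -c.cell_id):
        rr, cc = _draw_polygon(
            cell.polygon[:, 1] - 0.5, cell.polygon[:, 0] - 0.5, shape=(h, w)
        )
        mask[rr, cc] = labels[cell.cell_id]
    tifffile.imwrite(str(path), mask)
    return mask


def write_trackmate(
    trajectory: list[tuple[World, FrameAnnotation]], path: str | Path
) -> None:
    """TrackMate-style XML: one spot per cell per frame, lineage edges.

    Spots carry position in µm and an equivalent-area radius.  Edges link
    each cell's spots in consecutive emitted frames, and a mother's last
    spot to each daughter's first spot.  Tracks are the connected
    components of the edge graph (one per founder lineage).
    """
    spot_ids: dict[tuple[int, int], int] = {}  # (frame, cell_id) -> spot id
    spots_by_frame: dict[int, list[dict]] = {}
    frames_of_cell: dict[int, list[int]] = {}
    parent_of: dict[int, int | None] = {}
    next_spot = 0
    for world, frame in trajectory:
        fi = frame.frame_index
        spots_by_frame.setdefault(fi, [])
        for agent in world.agents:
            radius = math.sqrt(polygon_area(agent.polygon()) / math.pi)
            spot_ids[(fi, agent.id)] = next_spot
            spots_by_frame[fi].append(
                {
                    "ID": next_spot,
                    "name": f"cell_{agent.id}_f{fi}",
                    "FRAME": fi,
                    "POSITION_X": agent.position[0],
                    "POSITION_Y": agent.position[1],
                    "POSITION_Z": 0.0,
                    "POSITION_T": world.time,
                    "RADIUS": radius,
                    "QUALITY": 1.0,
                }
            )
            frames_of_cell.setdefault(agent.id, []).append(fi)
            parent_of[agent.id] = agent.parent_id
            next_spot += 1

    edges: list[tuple[int, int]] = []
    for cell_id, frames in frames_of_cell.items():
        frames = sorted(frames)
        for fa, fb in zip(frames[:-1], frames[1:]):
            edges.append((spot_ids[(fa, cell_id)], spot_ids[(fb, cell_id)]))
        parent = parent_of[cell_id]
        if parent is not None and parent in frames_of_cell:
            mother_last = max(frames_of_cell[parent])
            edges.append((spot_ids[(mother_last, parent)], spot_ids[(frames[0], cell_id)]))

    # connected components over spots -> tracks
    parent_uf = list(range(next_spot))

    def find(a: int) -> int:
        while parent_uf[a] != a:
            parent_uf[a] = parent_uf[parent_uf[a]]
            a = parent_uf[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_uf[ra] = rb

    tracks: dict[int, list[tuple[int, int]]] = {}
    for a, b in edges:
        tracks.setdefault(find(a), []).append((a, b))

    root = ET.Element("TrackMate", version="7.0.0")
    model = ET.SubElement(root, "Model", spatialunits="µm", timeunits="h")
    all_spots = ET.SubElement(model, "AllSpots", nspots=str(next_spot))
    for fi in sorted(spots_by_frame):
        frame_el = ET.SubElement(all_spots, "SpotsInFrame", frame=str(fi))
        for spot in spots_by_frame[fi]:
            ET.SubElement(
                frame_el,
                "Spot",
                {k: (v if isinstance(v, str) else f"{v}") for k, v in spot.items()},
            )
    all_tracks = ET.SubElement(model, "AllTracks")
    filtered = ET.SubElement(model, "FilteredTracks")
    for track_id, (_root_spot, track_edges) in enumerate(sorted(tracks.items())):
        track_el = ET.SubElement(
            all_tracks,
            "Track",
            TRACK_ID=str(track_id),
            name=f"Track_{track_id}",
            NUMBER_SPOTS=str(len({s for e in track_edges for s in e})),
            NUMBER_EDGES=str(len(track_edges)),
        )
        for a, b in track_edges:
            ET.SubElement(
                track_el, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b)
            )
        ET.SubElement(filtered, "TrackID", TRACK_ID=str(track_id))
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


# --------------------------------------------------------------------------
# 3D meshes for CFD


def _revolved_mesh(ring_x: np.ndarray, ring_r: np.ndarray, n_res: int) -> trimesh.Trimesh:
    """Surface of revolution about the x axis with pole fans at both ends.

    ``ring_x``/``ring_r`` are axial station / radius profiles; the first and
    last stations must have radius 0 (the poles).
    """
    theta = np.linspace(0.0, 2 * np.pi, n_res, endpoint=False)
    verts = [np.array([ring_x[0], 0.0, 0.0])]
    for x, r in zip(ring_x[1:-1], ring_r[1:-1]):
        verts.extend(np.column_stack([np.full(n_res, x), r * np.cos(theta), r * np.sin(theta)]))
    verts.append(np.array([ring_x[-1], 0.0, 0.0]))
    verts = np.vstack(verts)

    faces = []
    n_rings = len(ring_x) - 2
    first = 1  # index of the first ring vertex
    # fan at the start pole (outward normals point -x, wind accordingly)
    for k in range(n_res):
        faces.append([0, first + k, first + (k + 1) % n_res])
    for ring in range(n_rings - 1):
        a = first + ring * n_res
        b = a + n_res
        for k in range(n_res):
            k2 = (k + 1) % n_res
            faces.append([a + k, b + k, a + k2])
            faces.append([a + k2, b + k, b + k2])
    last_pole = len(verts) - 1
    base = first + (n_rings - 1) * n_res
    for k in range(n_res):
        faces.append([last_pole, base + (k + 1) % n_res, base + k])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    return mesh


def _capsule_profile(length: float, width: float, n_res: int) -> tuple[np.ndarray, np.ndarray]:
    r = width / 2.0
    half = (length - width) / 2.0
    n_cap = max(4, n_res // 2)
    phi = np.linspace(0.0, np.pi / 2.0, n_cap + 1)
    left_x = -half - r * np.cos(phi)
    left_r = r * np.sin(phi)
    if half > 0:
        n_mid = max(2, n_res // 4)
        mid_x = np.linspace(-half, half, n_mid + 2)[1:-1]
        mid_r = np.full_like(mid_x, r)
    else:
        mid_x = np.empty(0)
        mid_r = np.empty(0)
    right_x = half + r * np.cos(phi[::-1])
    right_r = r * np.sin(phi[::-1])
    xs = np.concatenate([left_x, mid_x, right_x])
    rs = np.concatenate([left_r, mid_r, right_r])
    return xs, rs


def cell_mesh(shape: ShapeParams, n_res: int = 64) -> trimesh.Trimesh:
    """Watertight 3D mesh of one cell, centred at its volume centroid.

    rod -> capsule (cylinder with hemispherical caps); coccoid -> sphere;
    ellipsoid -> revolved ellipse; bent_rod -> a capsule bent so its axis
    follows the centerline arc.  ``n_res`` is the angular resolution.
    """
    if shape.kind in ("rod", "bent_rod"):
        xs, rs = _capsule_profile(shape.length, shape.width, n_res)
        mesh = _revolved_mesh(xs, rs, n_res)
        if shape.kind == "bent_rod" and abs(shape.bend) > 1e-12:
            arc_len = shape.length - shape.width
            R = arc_len / shape.bend
            v = mesh.vertices.copy()
            alpha = v[:, 0] / R
            radial = R - v[:, 1]
            v[:, 0] = radial * np.sin(alpha)
            v[:, 1] = R - radial * np.cos(alpha)
            mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
            mesh.fix_normals()
    elif shape.kind == "coccoid":
        r = shape.width / 2.0
        phi = np.linspace(0.0, np.pi, n_res + 1)
        mesh = _revolved_mesh(-r * np.cos(phi), r * np.sin(phi), n_res)
    elif shape.kind == "ellipsoid":
        a = shape.length / 2.0
        b = shape.width / 2.0
        phi = np.linspace(0.0, np.pi, n_res + 1)
        mesh = _revolved_mesh(-a * np.cos(phi), b * np.sin(phi), n_res)
    else:  # pragma: no cover - guarded by ShapeParams
        raise ValueError(f"unknown shape kind {shape.kind!r}")
    mesh.apply_translation(-mesh.center_mass)
    return mesh


def export_mesh(agent: CellAgent, path: str | Path, n_res: int = 64) -> trimesh.Trimesh:
    """Export one cell as a watertight binary STL (for CFD meshing).

    The mesh is posed at the agent's world position/angle (z = 0 plane).
    Returns the mesh.
    """
    mesh = cell_mesh(agent.shape, n_res=n_res)
    transform = np.eye(4)
    c, s = np.cos(agent.angle), np.sin(agent.angle)
    transform[:2, :2] = [[c, -s], [s, c]]
    transform[0, 3] = agent.position[0]
    transform[1, 3] = agent.position[1]
    mesh.apply_transform(transform)
    mesh.export(str(path), file_type="stl")
    return mesh


# --------------------------------------------------------------------------
# batch dataset generation


def _target_counts(spec: DatasetSpec) -> list[int]:
    """Per-image target cell counts, log-uniform over the configured range."""
    lo, hi = spec.cell_count_range
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    log_lo = math.log(max(lo, 0.5))
    log_hi = math.log(hi + 1.0) if hi >= 1 else math.log(1.0)
    draws = np.exp(rng.uniform(log_lo, log_hi, size=spec.n_images))
    return [int(np.clip(math.floor(x), lo, hi)) for x in draws]


def _grow_to_count(
    target: int, seed: int, model: HomeostasisModel, spec: DatasetSpec
) -> tuple[World | None, str | None]:
    """Simulate one colony until it reaches ``target`` cells."""
    config = SimulationConfig(
        seed=seed,
        dt=spec.dt,
        duration=float("inf"),  # unused; stepping is explicit
        model=model,
        placement=PlacementConfig(),
    )
    world = init_world(config)
    if target <= 1:
        return (World(time=0.0, agents=[], next_id=0, seed=seed) if target == 0 else world), None
    hi = spec.cell_count_range[1]
    for _ in range(spec.max_steps):
        prev = world
        world = step(world, config)
        if world.count() >= target:
            if world.count() > hi:
                # the coarse step overshot the admissible range: re-advance
                # from the previous state with a finer step
                fine = dataclasses.replace(config, dt=spec.dt / 20.0)
                world = prev
                for _ in range(40):
                    world = step(world, fine)
                    if world.count() >= target:
                        break
                if world.count() > hi:
                    return None, (
                        f"count {world.count()} overshot range maximum {hi} "
                        f"(synchronous divisions)"
                    )
            return world, None
    return None, f"target count {target} not reached within {spec.max_steps} steps"


def generate_ground_truth_dataset(
    spec: DatasetSpec,
    model: HomeostasisModel,
    render: RenderConfig,
    output_dir: str | Path,
) -> dict:
    """Generate ``n_images`` annotated frames from independent colonies.

    Each image gets its own colony simulation (seeded from ``spec.seed`` +
    image index), snapshotted once its cell count reaches a per-image
    target drawn to span ``cell_count_range``.  Writes rendered frames,
    the requested annotation formats (YOLO per-image text files, one COCO
    JSON, 16-bit TIFF label masks) and a JSON manifest with per-image seed
    and cell count.  Fully deterministic for a fixed spec.  Returns the
    manifest.
    """
    out = Path(output_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    if "yolo" in spec.emitters:
        (out / "yolo").mkdir(exist_ok=True)
    if "masks" in spec.emitters:
        (out / "masks").mkdir(exist_ok=True)

    render_cfg = dataclasses.replace(
        render,
        image_size=(spec.image_size, spec.image_size),
        calibration=spec.calibration,
    )
    targets = _target_counts(spec)
    manifest: dict = {
        "n_images": spec.n_images,
        "image_size": spec.image_size,
        "calibration_um_per_px": spec.calibration,
        "cell_count_range": list(spec.cell_count_range),
        "seed": spec.seed,
        "colonies": "independent (one simulation per image)",
        "images": [],
    }
    frame_annotations: list[FrameAnnotation] = []
    image_files: list[str] = []
    for i in range(spec.n_images):
        img_seed = spec.seed + i
        world, error = _grow_to_count(targets[i], img_seed, model, spec)
        record = {"index": i, "seed": img_seed, "target_count": targets[i]}
        if error is not None:
            record["error"] = error
            manifest["images"].append(record)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i, 7]))
        frame = render_phase_contrast(world, render_cfg, rng)
        name = f"frame_{i:06d}.png" if render_cfg.output_depth == 8 else f"frame_{i:06d}.tif"
        img_path = out / "images" / name
        if render_cfg.output_depth == 8:
            imwrite(img_path, frame)
        else:
            tifffile.imwrite(str(img_path), frame)
        annotation = annotate(world, render_cfg, frame_index=i)
        record["cell_count"] = len(annotation.cells)
        manifest["images"].append(record)
        frame_annotations.append(annotation)
        image_files.append(f"images/{name}")
        if "yolo" in spec.emitters:
            write_yolo(annotation, out / "yolo" / f"frame_{i:06d}.txt")
        if "masks" in spec.emitters:
            write_masks(annotation, out / "masks" / f"frame_{i:06d}.tif")
    if "coco" in spec.emitters:
        write_coco(frame_annotations, image_files, out / "coco.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
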