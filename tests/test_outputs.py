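"""Annotation emitters: YOLO, COCO, masks, TrackMate XML, STL meshes, dataset."""

import json
from xml.etree import ElementTree as ET

import numpy as np
import pytest

from colonysim.agents import HomeostasisModel
from colonysim.engine import World
from colonysim.geometry import ShapeParams, polygon_area
from colonysim.outputs import (
    DatasetSpec,
    annotate,
    cell_mesh,
    export_mesh,
    generate_ground_truth_dataset,
    read_coco,
    write_coco,
    write_masks,
    write_trackmate,
    write_yolo,
)
from colonysim.render import RenderConfig
from conftest import make_agent


def world_of(agents):
    return World(time=0.0, agents=agents, next_id=len(agents), seed=0)


class TestAnnotate:
    def test_empty_world(self, render_config):
        annotation = annotate(world_of([]), render_config)
        assert annotation.cells == []

    def test_centred_cell_box_is_centred(self, render_config):
        annotation = annotate(world_of([make_agent()]), render_config)
        (cell,) = annotation.cells
        h, w = render_config.image_size
        cx = (cell.bbox[0] + cell.bbox[2]) / 2
        cy = (cell.bbox[1] + cell.bbox[3]) / 2
        assert abs(cx - w / 2) <= 1.0 and abs(cy - h / 2) <= 1.0

    def test_pixel_area_matches_micron_area(self, render_config):
        agent = make_agent(length=3.0, width=1.0)
        annotation = annotate(world_of([agent]), render_config)
        px_area = polygon_area(annotation.cells[0].polygon)
        um_area = polygon_area(agent.polygon()) / render_config.calibration**2
        assert 0.98 <= px_area / um_area <= 1.02

    def test_boxes_tightly_contain_polygons(self, render_config, small_colony):
        annotation = annotate(small_colony[-1], render_config)
        assert annotation.cells
        for cell in annotation.cells:
            x0, y0, x1, y1 = cell.bbox
            assert np.all(cell.polygon[:, 0] >= x0 - 1e-9)
            assert np.all(cell.polygon[:, 0] <= x1 + 1e-9)
            assert np.all(cell.polygon[:, 1] >= y0 - 1e-9)
            assert np.all(cell.polygon[:, 1] <= y1 + 1e-9)
            # shrinking any side by 2 px excludes at least one vertex
            assert (
                (cell.polygon[:, 0] < x0 + 2).any()
                and (cell.polygon[:, 0] > x1 - 2).any()
                and (cell.polygon[:, 1] < y0 + 2).any()
                and (cell.polygon[:, 1] > y1 - 2).any()
            )


class TestYolo:
    def test_empty_frame_writes_empty_file(self, render_config, tmp_path):
        path = tmp_path / "f.txt"
        write_yolo(annotate(world_of([]), render_config), path)
        assert path.read_text() == ""

    def test_centred_cell_normalized_box(self, render_config, tmp_path):
        # a rod spanning about half the 256 px * 0.09 field horizontally
        agent = make_agent(length=256 * 0.09 / 2, width=1.0)
        path = tmp_path / "f.txt"
        write_yolo(annotate(world_of([agent]), render_config), path)
        cls, cx, cy, w, h = path.read_text().split()
        assert cls == "0"
        assert float(cx) == pytest.approx(0.5, abs=1 / 256)
        assert float(w) == pytest.approx(0.5, abs=1 / 256)

    def test_all_values_normalized(self, render_config, small_colony, tmp_path):
        path = tmp_path / "f.txt"
        write_yolo(annotate(small_colony[-1], render_config), path)
        for line in path.read_text().splitlines():
            values = [float(v) for v in line.split()[1:]]
            assert all(0.0 <= v <= 1.0 for v in values)


class TestCoco:
    def test_round_trip_is_lossless(self, render_config, small_colony, tmp_path):
        annotation = annotate(small_colony[-1], render_config)
        path = tmp_path / "coco.json"
        write_coco([annotation], ["img.png"], path)
        doc = read_coco(path)
        assert len(doc["annotations"]) == len(annotation.cells)
        for cell, anno in zip(annotation.cells, doc["annotations"]):
            flat = np.asarray(anno["segmentation"][0]).reshape(-1, 2)
            assert np.allclose(flat, np.round(cell.polygon, 4))
        assert doc == read_coco(path)  # parse is stable

    def test_area_matches_polygon(self, render_config, small_colony, tmp_path):
        annotation = annotate(small_colony[-1], render_config)
        path = tmp_path / "coco.json"
        write_coco([annotation], ["img.png"], path)
        for cell, anno in zip(annotation.cells, read_coco(path)["annotations"]):
            assert anno["area"] == pytest.approx(polygon_area(cell.polygon), rel=0.02)

    def test_category_and_ids(self, render_config, small_colony, tmp_path):
        annotation = annotate(small_colony[-1], render_config)
        path = tmp_path / "coco.json"
        write_coco([annotation], ["img.png"], path)
        doc = read_coco(path)
        assert doc["categories"] == [{"id": 1, "name": "cell"}]
        ids = [a["id"] for a in doc["annotations"]]
        assert len(set(ids)) == len(ids)


class TestMasks:
    def test_empty_frame_all_zero(self, render_config, tmp_path):
        mask = write_masks(annotate(world_of([]), render_config), tmp_path / "m.tif")
        assert mask.dtype == np.uint16
        assert not mask.any()

    def test_labels_are_one_to_n(self, render_config, small_colony, tmp_path):
        annotation = annotate(small_colony[-1], render_config)
        mask = write_masks(annotation, tmp_path / "m.tif")
        labels = set(np.unique(mask)) - {0}
        assert labels == set(range(1, len(annotation.cells) + 1))

    def test_mask_area_consistent_with_coco(self, render_config, small_colony, tmp_path):
        annotation = annotate(small_colony[-1], render_config)
        mask = write_masks(annotation, tmp_path / "m.tif")
        write_coco([annotation], ["img.png"], tmp_path / "c.json")
        doc = read_coco(tmp_path / "c.json")
        labels = {
            cell.cell_id: i + 1
            for i, cell in enumerate(sorted(annotation.cells, key=lambda c: c.cell_id))
        }
        for cell, anno in zip(annotation.cells, doc["annotations"]):
            px = int((mask == labels[cell.cell_id]).sum())
            # rasterized pixel count vs shoelace area of the same polygon
            assert px == pytest.approx(anno["area"], rel=0.07, abs=6)


class TestTrackmate:
    def trajectory(self, render_config, colony):
        emitted = colony[::5]
        return [(w, annotate(w, render_config, frame_index=k)) for k, w in enumerate(emitted)]

    def test_spot_count_equals_total_cells(self, render_config, small_colony, tmp_path):
        pairs = self.trajectory(render_config, small_colony)
        path = tmp_path / "t.xml"
        write_trackmate(pairs, path)
        root = ET.parse(path).getroot()
        spots = root.findall(".//Spot")
        assert len(spots) == sum(w.count() for w, _ in pairs)

    def test_single_cell_track(self, render_config, tmp_path):
        agent = make_agent()
        pairs = [
            (World(time=0.1 * k, agents=[agent], next_id=1, seed=0),
             annotate(World(time=0.1 * k, agents=[agent], next_id=1, seed=0),
                      render_config, frame_index=k))
            for k in range(5)
        ]
        path = tmp_path / "t.xml"
        write_trackmate(pairs, path)
        root = ET.parse(path).getroot()
        assert len(root.findall(".//Spot")) == 5
        assert len(root.findall(".//Edge")) == 4

    def test_division_creates_out_degree_two(self, render_config, small_colony, tmp_path):
        pairs = self.trajectory(render_config, small_colony)
        path = tmp_path / "t.xml"
        write_trackmate(pairs, path)
        root = ET.parse(path).getroot()
        out_degree: dict[str, int] = {}
        for edge in root.findall(".//Edge"):
            src = edge.get("SPOT_SOURCE_ID")
            out_degree[src] = out_degree.get(src, 0) + 1
        assert max(out_degree.values()) == 2  # at least one division emitted

    def test_edges_reconstruct_lineage_forest(self, render_config, small_colony, tmp_path):
        pairs = self.trajectory(render_config, small_colony)
        path = tmp_path / "t.xml"
        write_trackmate(pairs, path)
        root = ET.parse(path).getroot()
        # map spot id -> (frame, position) and rebuild parent links
        spot_info = {
            s.get("ID"): (int(s.get("FRAME")), s.get("name"))
            for s in root.findall(".//Spot")
        }
        for edge in root.findall(".//Edge"):
            f_src = spot_info[edge.get("SPOT_SOURCE_ID")][0]
            f_tgt = spot_info[edge.get("SPOT_TARGET_ID")][0]
            assert f_src < f_tgt


class TestMeshes:
    def test_sphere_volume(self):
        mesh = cell_mesh(ShapeParams("coccoid", 1.0, 1.0), n_res=64)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(np.pi / 6, rel=0.01)

    def test_capsule_volume(self):
        mesh = cell_mesh(ShapeParams("rod", 2.0, 1.0), n_res=64)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(np.pi * 0.25 + np.pi / 6, rel=0.01)

    def test_ellipsoid_volume(self):
        mesh = cell_mesh(ShapeParams("ellipsoid", 3.0, 1.0), n_res=64)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 1.5 * 0.5 * 0.5, rel=0.01)

    def test_bent_rod_watertight(self):
        mesh = cell_mesh(ShapeParams("bent_rod", 3.0, 1.0, bend=0.8), n_res=32)
        assert mesh.is_watertight

    def test_volume_converges_with_resolution(self):
        exact = np.pi / 6
        errors = [
            abs(cell_mesh(ShapeParams("coccoid", 1.0, 1.0), n_res=n).volume - exact)
            for n in (8, 16, 32)
        ]
        assert errors[0] > errors[1] > errors[2]

    def test_export_stl_binary(self, tmp_path):
        import trimesh

        path = tmp_path / "cell.stl"
        export_mesh(make_agent(position=(1.0, 2.0)), path)
        loaded = trimesh.load(str(path))
        assert loaded.is_watertight
        assert loaded.center_mass[:2] == pytest.approx([1.0, 2.0], abs=0.01)


class TestDataset:
    model = HomeostasisModel(kind="sizer", trigger_mean=3.0, trigger_cv=0.12, rate_cv=0.1)

    def test_single_image_dataset(self, tmp_path):
        spec = DatasetSpec(n_images=1, image_size=128, cell_count_range=(1, 8), seed=2)
        manifest = generate_ground_truth_dataset(spec, self.model, RenderConfig(), tmp_path)
        assert len(manifest["images"]) == 1
        assert (tmp_path / "images" / "frame_000000.png").exists()
        assert (tmp_path / "yolo" / "frame_000000.txt").exists()
        doc = read_coco(tmp_path / "coco.json")
        assert len(doc["images"]) == 1

    def test_cross_emitter_consistency(self, tmp_path):
        """YOLO line count == COCO annotation count == mask label count,
        frame by frame."""
        spec = DatasetSpec(n_images=3, image_size=256, cell_count_range=(2, 30), seed=4)
        generate_ground_truth_dataset(spec, self.model, RenderConfig(), tmp_path)
        import tifffile

        doc = read_coco(tmp_path / "coco.json")
        for i in range(3):
            yolo_lines = (tmp_path / "yolo" / f"frame_{i:06d}.txt").read_text().splitlines()
            coco_annos = [a for a in doc["annotations"] if a["image_id"] == i + 1]
            mask = tifffile.imread(tmp_path / "masks" / f"frame_{i:06d}.tif")
            n_labels = len(set(np.unique(mask)) - {0})
            assert len(yolo_lines) == len(coco_annos) == n_labels

    def test_manifest_counts_within_range(self, tmp_path):
        spec = DatasetSpec(n_images=4, image_size=128, cell_count_range=(0, 16), seed=8)
        manifest = generate_ground_truth_dataset(spec, self.model, RenderConfig(), tmp_path)
        for record in manifest["images"]:
            assert 0 <= record["cell_count"] <= 16
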