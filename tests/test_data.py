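"""Preprocessing pipeline: letterbox, mosaic, tiling, anchors, annotation I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikedet.data import (AnchorSet, LabeledImage, best_possible_recall,
                           fit_anchors, letterbox, mosaic, read_voc_xml,
                           read_yolo_txt, tile_image, unletterbox_boxes,
                           write_voc_xml, write_yolo_txt)
from spikedet.model import DEFAULT_ANCHORS


def make_item(rng, h=96, w=128, n_boxes=3, seed_id="img"):
    img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
    x1 = rng.uniform(0, w - 20, n_boxes)
    y1 = rng.uniform(0, h - 20, n_boxes)
    bw = rng.uniform(5, 19, n_boxes)
    bh = rng.uniform(5, 19, n_boxes)
    boxes = np.column_stack([x1, y1, np.minimum(x1 + bw, w),
                             np.minimum(y1 + bh, h)])
    return LabeledImage(img, boxes, np.zeros(n_boxes, dtype=int), seed_id)


class TestLetterbox:
    @pytest.mark.parametrize("w,h,exp_scale,exp_wh", [
        (1024, 1024, 0.625, (640, 640)),
        (960, 720, 2 / 3, (640, 480)),
        (1000, 700, 0.64, (640, 448)),
    ])
    def test_reference_shapes_have_zero_padding(self, w, h, exp_scale, exp_wh):
        img = np.zeros((h, w, 3), dtype=np.uint8)
        out, scale, pad = letterbox(img)
        assert scale == pytest.approx(exp_scale)
        assert out.shape[:2] == (exp_wh[1], exp_wh[0])
        assert pad == (0, 0, 0, 0)

    @given(st.integers(10, 2000), st.integers(10, 2000))
    @settings(max_examples=300, deadline=None)
    def test_padding_minimal_and_stride_aligned(self, w, h):
        img = np.zeros((h, w, 3), dtype=np.uint8)
        out, scale, pad = letterbox(img, target=640, stride=32)
        ph, pw = out.shape[:2]
        nw, nh = round(w * scale), round(h * scale)
        assert pw % 32 == 0 and ph % 32 == 0
        assert pw - nw < 32 and ph - nh < 32      # minimal padding
        assert pad[0] + pad[2] == pw - nw
        assert pad[1] + pad[3] == ph - nh
        assert abs(pad[0] - pad[2]) <= 1 and abs(pad[1] - pad[3]) <= 1

    def test_roundtrip_coordinate_mapping_is_exact(self, rng):
        img = rng.integers(0, 255, (700, 1000, 3), dtype=np.uint8)
        _, scale, pad = letterbox(img)
        boxes = rng.uniform(0, 600, (10, 4))
        fwd = boxes * scale
        fwd[:, 0::2] += pad[0]
        fwd[:, 1::2] += pad[1]
        back = unletterbox_boxes(fwd, scale, pad)
        assert np.allclose(back, boxes, atol=1e-9)

    def test_square_mode_pads_to_target(self):
        out, _, _ = letterbox(np.zeros((300, 500, 3), dtype=np.uint8),
                              target=640, square=True)
        assert out.shape[:2] == (640, 640)


class TestMosaic:
    def test_requires_exactly_four_images(self, rng):
        with pytest.raises(ValueError):
            mosaic([make_item(rng)] * 3, canvas=160, rng_seed=0)

    def test_empty_inputs_give_empty_boxes(self, rng):
        items = [LabeledImage(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8),
                              np.zeros((0, 4)), np.zeros(0, dtype=int))
                 for _ in range(4)]
        out = mosaic(items, canvas=160, rng_seed=5)
        assert len(out.boxes) == 0
        assert out.image.shape == (160, 160, 3)

    def test_deterministic_and_contained(self, rng):
        items = [make_item(rng, seed_id=str(i)) for i in range(4)]
        a = mosaic(items, canvas=160, rng_seed=42)
        b = mosaic(items, canvas=160, rng_seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.boxes, b.boxes)
        c = mosaic(items, canvas=160, rng_seed=43)
        assert not np.array_equal(a.image, c.image)
        if len(a.boxes):
            assert (a.boxes[:, 0::2] >= 0).all() and (a.boxes[:, 0::2] <= 160).all()
            assert (a.boxes[:, 1::2] >= 0).all() and (a.boxes[:, 1::2] <= 160).all()

    def test_full_frame_boxes_survive_from_all_quadrants(self, rng):
        items = []
        for i in range(4):
            img = rng.integers(0, 255, (80, 80, 3), dtype=np.uint8)
            items.append(LabeledImage(img, np.array([[0, 0, 80, 80.0]]), [0],
                                      str(i)))
        out = mosaic(items, canvas=160, rng_seed=9, min_visibility=0.0)
        assert len(out.boxes) == 4

    def test_box_count_never_exceeds_input_total(self, rng):
        for seed in range(30):
            items = [make_item(rng, n_boxes=4, seed_id=str(i)) for i in range(4)]
            out = mosaic(items, canvas=160, rng_seed=seed)
            assert len(out.boxes) <= 16


class TestTiling:
    def test_reference_grid_with_border_snap(self, rng):
        item = make_item(rng, h=720, w=960, n_boxes=0)
        tiles = tile_image(item, tile=640, stride=320)
        origins = {t.source_id.split("@")[1] for t in tiles}
        assert origins == {"0,0", "320,0", "0,80", "320,80"}
        assert all(t.image.shape == (640, 640, 3) for t in tiles)

    def test_identity_tile(self, rng):
        item = make_item(rng, h=640, w=640)
        tiles = tile_image(item)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].image, item.image)
        assert np.allclose(tiles[0].boxes, item.boxes)

    def test_box_inside_single_tile_appears_once(self, rng):
        # bottom-right corner region covered only by the border-snapped tile
        img = rng.integers(0, 255, (720, 960, 3), dtype=np.uint8)
        item = LabeledImage(img, np.array([[700, 660, 760, 710.0]]), [0], "t")
        tiles = tile_image(item, tile=640, stride=320)
        hits = [t for t in tiles if len(t.boxes)]
        assert len(hits) == 1
        assert hits[0].source_id.endswith("@320,80")

    def test_union_of_tiles_covers_image(self, rng):
        item = make_item(rng, h=700, w=900, n_boxes=0)
        tiles = tile_image(item, tile=640, stride=320)
        cover = np.zeros((700, 900), dtype=bool)
        for t in tiles:
            x0, y0 = map(int, t.source_id.split("@")[1].split(","))
            cover[y0:y0 + 640, x0:x0 + 640] = True
        assert cover.all()


class TestAnchors:
    def test_bpr_examples(self):
        assert best_possible_recall([(10, 10)], [(50, 50)]) == 0.0
        assert best_possible_recall([(10, 10)], [(20, 20)]) == 1.0
        sizes = [(12, 30), (50, 44), (100, 90)]
        assert best_possible_recall(sizes, sizes) == 1.0

    def test_bpr_monotone_in_threshold_and_anchor_inclusion(self, rng):
        wh = rng.uniform(5, 200, (100, 2))
        anchors = rng.uniform(5, 200, (5, 2))
        b1 = best_possible_recall(wh, anchors, ratio_thresh=2.0)
        b2 = best_possible_recall(wh, anchors, ratio_thresh=4.0)
        assert b2 >= b1
        more = np.vstack([anchors, rng.uniform(5, 200, (4, 2))])
        assert best_possible_recall(wh, more) >= best_possible_recall(wh, anchors)

    def test_fit_recovers_planted_clusters(self, rng):
        centers = np.array([[10, 14], [25, 18], [18, 40], [45, 30], [60, 70],
                            [90, 55], [120, 130], [200, 160], [320, 300.0]])
        boxes = np.vstack([c + rng.normal(0, 0.5, (40, 2)) for c in centers])
        fitted = fit_anchors(boxes, k=9, rng_seed=0)
        ordered = centers[np.argsort(centers.prod(axis=1))]
        assert np.abs(fitted.wh - ordered).max() / ordered.max() < 0.05
        for c, f in zip(ordered, fitted.wh):
            assert np.abs(f - c).max() / c.max() < 0.05

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore:Number of distinct clusters")
    def test_identical_boxes_collapse_to_one_size(self):
        boxes = np.tile([40.0, 60.0], (30, 1))
        fitted = fit_anchors(boxes, k=9, rng_seed=1)
        assert np.allclose(fitted.wh, [40, 60], atol=1e-6)

    def test_fitted_bpr_never_below_default(self, rng):
        flat = np.asarray(DEFAULT_ANCHORS, dtype=float).reshape(-1, 2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            wh = np.exp(r.normal(3.0, 1.2, (80, 2)))  # wide log-normal sizes
            fitted = fit_anchors(wh, k=9, rng_seed=seed, default=flat)
            assert best_possible_recall(wh, fitted) >= \
                best_possible_recall(wh, flat) - 1e-12

    def test_too_few_boxes_rejected(self):
        with pytest.raises(ValueError):
            fit_anchors(np.ones((5, 2)), k=9)
        with pytest.raises(ValueError):
            best_possible_recall(np.zeros((0, 2)), [(1, 1)])


class TestAnnotationIO:
    def test_voc_roundtrip(self, tmp_path, rng):
        item = make_item(rng, n_boxes=2, seed_id="fixture")
        write_voc_xml(tmp_path / "a.xml", item)
        back = read_voc_xml(tmp_path / "a.xml", image=item.image)
        assert np.allclose(back.boxes, item.boxes, atol=1e-5)
        assert back.source_id == "fixture"

    def test_yolo_roundtrip(self, tmp_path, rng):
        item = make_item(rng, n_boxes=2)
        write_yolo_txt(tmp_path / "a.txt", item)
        back = read_yolo_txt(tmp_path / "a.txt", item.image)
        assert np.allclose(back.boxes, item.boxes, atol=1e-3)

    def test_voc_yolo_convention_bridge(self, tmp_path):
        """VOC (1,1,640,640) on 640px == YOLO (0.5, 0.5, 1, 1)."""
        img = np.zeros((640, 640, 3), dtype=np.uint8)
        item = LabeledImage(img, np.array([[0, 0, 640, 640.0]]), [0], "full")
        write_voc_xml(tmp_path / "b.xml", item)
        text = (tmp_path / "b.xml").read_text()
        assert "<xmin>1</xmin>" in text and "<xmax>640</xmax>" in text
        write_yolo_txt(tmp_path / "b.txt", item)
        assert (tmp_path / "b.txt").read_text().split() == \
            ["0", "0.500000", "0.500000", "1.000000", "1.000000"]

    def test_empty_annotation_files(self, tmp_path):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        item = LabeledImage(img, np.zeros((0, 4)), np.zeros(0, dtype=int))
        write_yolo_txt(tmp_path / "e.txt", item)
        assert len(read_yolo_txt(tmp_path / "e.txt", img).boxes) == 0
        write_voc_xml(tmp_path / "e.xml", item)
        assert len(read_voc_xml(tmp_path / "e.xml", image=img).boxes) == 0

    def test_malformed_files_raise_with_location(self, tmp_path):
        (tmp_path / "bad.txt").write_text("0 0.5 0.5 0.1\n")
        with pytest.raises(ValueError, match="bad.txt:1"):
            read_yolo_txt(tmp_path / "bad.txt", np.zeros((8, 8, 3), np.uint8))
        (tmp_path / "bad.xml").write_text("<annotation><size>")
        with pytest.raises(ValueError, match="malformed"):
            read_voc_xml(tmp_path / "bad.xml")
        (tmp_path / "nosize.xml").write_text("<annotation></annotation>")
        with pytest.raises(ValueError, match="size"):
            read_voc_xml(tmp_path / "nosize.xml")

    def test_boxes_outside_image_rejected(self):
        with pytest.raises(ValueError):
            LabeledImage(np.zeros((10, 10, 3), np.uint8),
                         np.array([[0, 0, 12, 5.0]]), [0])
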