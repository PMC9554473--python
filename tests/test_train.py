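"""Training pipeline: anchor gate, determinism, counting and evaluation."""

import numpy as np
import pytest

from spikedet.data import LabeledImage
from spikedet.metrics import CountSeries, mae, rmse
from spikedet.model import Model, ModelConfig, load_checkpoint, save_checkpoint
from spikedet.synth import SceneSpec, generate_scene
from spikedet.train import (TrainConfig, check_anchors, count, evaluate,
                            train)


@pytest.fixture(scope="module")
def tiny_scenes():
    return [generate_scene(SceneSpec(canvas=(96, 96), n_spikes=3,
                                     length_range=(18, 30),
                                     width_range=(7, 11),
                                     overlap_target=0.0, rng_seed=s))
            for s in range(4)]


def tiny_cfg(**kw):
    base = dict(epochs=1, batch_size=2, imgsz=96, mosaic_prob=0.0, seed=0,
                warmup_epochs=0)
    base.update(kw)
    return TrainConfig(**base)


class TestAnchorGate:
    def test_well_covered_boxes_keep_anchors(self, tiny_scenes):
        logs = []
        anchors, bpr, refit = check_anchors(tiny_scenes, imgsz=640,
                                            log=logs.append)
        assert not refit
        assert bpr >= 0.98
        assert any("anchors kept" in m for m in logs)

    def test_uncovered_boxes_trigger_refit(self, rng):
        # boxes far outside the default prior range at the eval resolution
        img = np.zeros((640, 640, 3), dtype=np.uint8)
        boxes = np.column_stack([np.full(20, 10.0), np.full(20, 10.0),
                                 np.full(20, 14.0), np.full(20, 610.0)])
        boxes += rng.uniform(0, 3, boxes.shape)
        items = [LabeledImage(img, boxes, np.zeros(20, dtype=int), "x")]
        logs = []
        anchors, bpr, refit = check_anchors(items, imgsz=640, log=logs.append)
        assert refit
        assert any("anchors refit" in m for m in logs)
        assert bpr >= 0.98  # the refit priors cover these boxes


class TestTraining:
    def test_zero_lr_leaves_model_unchanged(self, tiny_scenes):
        cfg = tiny_cfg(lr0=0.0)
        model, _ = train(tiny_scenes, cfg, log=lambda m: None)
        fresh = Model(model.cfg)
        for (n1, p1), (n2, p2) in zip(model.named_parameters(),
                                      fresh.named_parameters()):
            assert n1 == n2
            assert np.array_equal(p1.data, p2.data)

    def test_same_seed_reproduces_epoch_losses(self, tiny_scenes):
        h1 = train(tiny_scenes, tiny_cfg(), log=lambda m: None)[1]
        h2 = train(tiny_scenes, tiny_cfg(), log=lambda m: None)[1]
        assert h1[0]["loss"] == h2[0]["loss"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], tiny_cfg())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(imgsz=100)

    def test_checkpoints_and_log_written(self, tiny_scenes, tmp_path):
        train(tiny_scenes, tiny_cfg(), out_dir=tmp_path, log=lambda m: None)
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "train_log.jsonl").read_text().strip()

    def test_checkpoint_roundtrip_reproduces_metrics(self, tiny_scenes,
                                                     tmp_path):
        model, _ = train(tiny_scenes, tiny_cfg(), log=lambda m: None)
        save_checkpoint(tmp_path / "m.npz", model)
        s1 = count(tiny_scenes, model=model, conf=0.1)
        s2 = count(tiny_scenes, checkpoint=tmp_path / "m.npz", conf=0.1)
        assert s1 == s2


class TestCountingPath:
    def _echo_stub(self, items):
        return {it.source_id: (it.boxes.copy(),
                               np.linspace(0.99, 0.9, len(it.boxes)))
                for it in items}

    def test_ground_truth_echo_is_perfect(self, tiny_scenes):
        summary = count(tiny_scenes, detections=self._echo_stub(tiny_scenes))
        assert summary["rmse"] == 0.0 and summary["mae"] == 0.0
        assert summary["mean_accuracy_pct"] == 100.0
        assert summary["map50"] == pytest.approx(1.0)
        assert summary["recall"] == pytest.approx(1.0)

    def test_off_by_one_stub_counting_errors(self):
        items = [generate_scene(SceneSpec(canvas=(320, 320), n_spikes=10,
                                          length_range=(30, 50),
                                          width_range=(10, 16),
                                          overlap_target=0.0, rng_seed=s))
                 for s in range(3)]
        dets = {}
        for it in items:
            extra = np.array([[5.0, 5.0, 25.0, 25.0]])
            boxes = np.vstack([it.boxes, extra])
            dets[it.source_id] = (boxes, np.linspace(0.99, 0.5, len(boxes)))
        summary = count(items, detections=dets)
        assert summary["mae"] == pytest.approx(1.0)
        assert summary["mean_error_pct"] == pytest.approx(10.0)

    def test_report_files_written(self, tiny_scenes, tmp_path):
        count(tiny_scenes, detections=self._echo_stub(tiny_scenes),
              out_dir=tmp_path)
        assert (tmp_path / "per_image.csv").exists()
        assert (tmp_path / "summary.json").exists()


class TestEvaluate:
    def test_id_mismatch_lists_offenders(self):
        with pytest.raises(ValueError, match="b"):
            evaluate({"a": (np.zeros((0, 4)), np.zeros(0))},
                     {"a": np.zeros((0, 4)), "b": np.array([[0, 0, 1, 1.0]])})

    def test_empty_detections_zero_scores(self):
        gts = {"a": np.array([[0, 0, 10, 10.0]])}
        out = evaluate({"a": (np.zeros((0, 4)), np.zeros(0))}, gts)
        assert out["recall"] == 0.0 and out["map50"] == 0.0

    def test_metrics_invariant_to_image_order(self, rng):
        def rand_img(seed):
            r = np.random.default_rng(seed)
            xy = r.uniform(0, 80, (4, 2))
            gt = np.column_stack([xy, xy + r.uniform(5, 20, (4, 2))])
            dxy = r.uniform(0, 80, (5, 2))
            det = (np.column_stack([dxy, dxy + r.uniform(5, 20, (5, 2))]),
                   r.random(5))
            return gt, det
        gts, dets = {}, {}
        for i in range(4):
            gts[str(i)], dets[str(i)] = rand_img(i)
        fwd = evaluate(dets, gts)
        rev = evaluate(dict(reversed(dets.items())),
                       dict(reversed(gts.items())))
        assert fwd == rev
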