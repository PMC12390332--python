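"""Training harness: target assignment, loss behavior, an overfit smoke
on one phantom, and end-to-end decode/filter plumbing."""

import numpy as np
import pytest

from fbstrnet import nn
from fbstrnet.model import ArchitectureConfig, FBStrNet
from fbstrnet.model.assign import build_targets
from fbstrnet.model.decode import decode_predictions
from fbstrnet.model.loss import DetectionLoss
from fbstrnet.train import TrainConfig, YoloDataset, evaluate_model, predict, train


def tiny_arch(**kw):
    base = dict(width_multiple=0.25, input_size=64, head_hidden_channels=16)
    base.update(kw)
    return ArchitectureConfig(**base)


class TestAssignment:
    def test_every_target_assigned_somewhere(self, rng):
        cfg = tiny_arch()
        anchors = [cfg.scaled_anchors()[i] / s for i, s in enumerate((8, 16, 32))]
        targets = np.array([[0, 1, 0.5, 0.5, 0.3, 0.3], [0, 2, 0.25, 0.75, 0.1, 0.08]])
        out = build_targets(targets, [(8, 8), (4, 4), (2, 2)], anchors, 5.0)
        assert sum(lt.n for lt in out) > 0
        for lt, (h, w) in zip(out, [(8, 8), (4, 4), (2, 2)]):
            assert np.all((lt.gi >= 0) & (lt.gi < w))
            assert np.all((lt.gj >= 0) & (lt.gj < h))
            # cell offsets live in the lateral-expansion window
            assert np.all(lt.tbox[:, :2] > -0.5 - 1e-9)
            assert np.all(lt.tbox[:, :2] < 1.5 + 1e-9)

    def test_no_targets_is_fine(self):
        cfg = tiny_arch()
        anchors = [cfg.scaled_anchors()[i] / s for i, s in enumerate((8, 16, 32))]
        out = build_targets(np.zeros((0, 6)), [(8, 8), (4, 4), (2, 2)], anchors, 5.0)
        assert all(lt.n == 0 for lt in out)

    def test_anchor_threshold_gates_extreme_shapes(self):
        cfg = tiny_arch()
        anchors = [cfg.scaled_anchors()[i] / s for i, s in enumerate((8, 16, 32))]
        # pathologically thin target: ratio to every anchor exceeds the gate
        sliver = np.array([[0, 0, 0.5, 0.5, 0.9, 0.0004]])
        out = build_targets(sliver, [(8, 8), (4, 4), (2, 2)], anchors, 5.0)
        assert sum(lt.n for lt in out) == 0


class TestLoss:
    def _preds(self, model, rng, n=2, size=64):
        x = nn.Tensor(rng.normal(size=(n, 3, size, size)).astype(np.float32))
        return model(x)

    def test_loss_finite_and_backpropagates(self, rng):
        cfg = tiny_arch()
        model = FBStrNet(cfg)
        preds = self._preds(model, rng)
        targets = np.array([[0, 0, 0.5, 0.5, 0.4, 0.3], [1, 5, 0.3, 0.6, 0.2, 0.2]])
        loss, comps = DetectionLoss(cfg)(preds, targets)
        assert np.isfinite(loss.data)
        assert comps["box"] > 0 and comps["obj"] > 0 and comps["cls"] > 0
        loss.backward()
        grads = [p.grad for p in model.parameters() if p.grad is not None]
        assert len(grads) > 0
        assert all(np.all(np.isfinite(g)) for g in grads)

    def test_siou_and_ciou_losses_differ_but_params_match(self, rng):
        nn.seed_init(0)
        m1 = FBStrNet(tiny_arch(loss_name="SIoU"))
        nn.seed_init(0)
        m2 = FBStrNet(tiny_arch(loss_name="CIoU"))
        assert m1.num_parameters() == m2.num_parameters()
        preds1 = self._preds(m1, np.random.default_rng(0))
        preds2 = self._preds(m2, np.random.default_rng(0))
        targets = np.array([[0, 0, 0.4, 0.5, 0.3, 0.3]])
        l1, _ = DetectionLoss(m1.cfg)(preds1, targets)
        l2, _ = DetectionLoss(m2.cfg)(preds2, targets)
        assert float(l1.data) != pytest.approx(float(l2.data), abs=1e-9)

    def test_no_objects_only_objectness_term(self, rng):
        cfg = tiny_arch()
        model = FBStrNet(cfg)
        preds = self._preds(model, rng, n=1)
        loss, comps = DetectionLoss(cfg)(preds, np.zeros((0, 6)))
        assert comps["box"] == 0.0 and comps["cls"] == 0.0 and comps["obj"] > 0


class TestDecode:
    def test_decode_shapes_and_bounds(self, rng):
        cfg = tiny_arch()
        model = FBStrNet(cfg)
        model.eval()
        x = nn.Tensor(rng.normal(size=(2, 3, 64, 64)).astype(np.float32))
        raw = [o.data for o in model(x)]
        per_image = decode_predictions(raw, cfg, conf_threshold=0.0, apply_nms=False)
        assert len(per_image) == 2
        for dets in per_image:
            for d in dets[:50]:
                assert 0 <= d.x1 <= d.x2 <= 64
                assert 0 <= d.y1 <= d.y2 <= 64
                assert 0 <= d.conf <= 1

    def test_confidence_one_gate_empties_output(self, rng):
        cfg = tiny_arch()
        model = FBStrNet(cfg)
        model.eval()
        raw = [o.data for o in model(nn.Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))]
        assert decode_predictions(raw, cfg, conf_threshold=1.0) == [[]]


@pytest.fixture(scope="module")
def overfit_run(tmp_path_factory):
    """Train ~200 steps on a single phantom (shared by the smoke tests)."""
    from fbstrnet.phantom import PhantomSpec, generate_phantom, write_yolo_labels
    from PIL import Image
    import yaml

    root = tmp_path_factory.mktemp("overfit")
    sample = generate_phantom(PhantomSpec(plane="TLVAP", image_size=64, seed=4))
    for split in ("train", "val"):
        (root / f"images/{split}").mkdir(parents=True)
        (root / f"labels/{split}").mkdir(parents=True)
        Image.fromarray(sample.image).save(root / f"images/{split}/p.png")
        write_yolo_labels(root / f"labels/{split}/p.txt", sample.labels, 64)
    from fbstrnet.postfilter import CLASS_NAMES

    manifest = {
        "path": str(root), "names": list(CLASS_NAMES),
        "train": ["images/train/p.png"], "val": ["images/val/p.png"],
        "planes": {"p": "TLVAP"}, "image_size": 64,
    }
    with open(root / "data.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)

    arch = tiny_arch()
    cfg = TrainConfig(learning_rate=0.05, weight_decay=0.0, epochs=200,
                      image_size=64, batch_size=1, seed=3, ema=False)
    model, history = train(arch, cfg, root / "data.yaml", root / "run", log_every=0)
    return model, history, root


class TestOverfitSmoke:
    def test_loss_decreases_on_smoothed_window(self, overfit_run):
        _, history, _ = overfit_run
        totals = np.array([h["total"] for h in history])
        k = 20
        smoothed = np.convolve(totals, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < 0.5 * smoothed[0]
        assert totals[-1] < totals[0]

    def test_predictions_exist_after_overfit(self, overfit_run):
        model, _, root = overfit_run
        ds = YoloDataset(root / "data.yaml", "val", 64)
        dets = predict(model, np.stack([ds.items[0][1]]), conf_threshold=0.1)[0]
        assert len(dets) > 0

    def test_filtered_output_is_subset_and_plane_consistent(self, overfit_run):
        from fbstrnet.postfilter import P_OBJS, filter_detections

        model, _, root = overfit_run
        ds = YoloDataset(root / "data.yaml", "val", 64)
        dets = predict(model, np.stack([ds.items[0][1]]), conf_threshold=0.01)[0]
        filtered = filter_detections(dets, "TLVAP")
        assert len(filtered) <= 4
        assert all(d in dets for d in filtered)
        assert all(d.class_name in P_OBJS["TLVAP"] for d in filtered)


class TestDeterminism:
    def test_two_runs_identical_losses(self, tiny_dataset):
        arch = tiny_arch(input_size=128)
        cfg = TrainConfig(learning_rate=0.01, epochs=2, image_size=128,
                          batch_size=4, seed=7)
        import tempfile

        with tempfile.TemporaryDirectory() as d1, tempfile.TemporaryDirectory() as d2:
            _, h1 = train(arch, cfg, tiny_dataset, d1, log_every=0)
            _, h2 = train(arch, cfg, tiny_dataset, d2, log_every=0)
        assert [h["total"] for h in h1] == [h["total"] for h in h2]


class TestConfigErrors:
    def test_mismatched_sizes_rejected_before_training(self, tiny_dataset):
        with pytest.raises(ValueError, match="input_size"):
            train(tiny_arch(input_size=64),
                  TrainConfig(epochs=1, image_size=128), tiny_dataset, "unused")

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
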