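"""Negative-mining workflow: guards, strict harvesting, retraining, transfer."""
import numpy as np
import pytest

from scintidet import detector as det
from scintidet.detector import BackendConfig, Detection, DetectorModel
from scintidet.errors import ModelStateError, TrainingError, ValidationError
from scintidet.fusion import FusedImage
from scintidet.mining import (
    MinedNegatives,
    MiningConfig,
    fold_equivocal_to_normal,
    harvest_negatives,
    pretrain_positive_only,
    retrain_two_class,
    transfer_finetune,
)
from scintidet.scan_io import Box, Category


class StubBackend:
    """Backend that returns pre-scripted detections, for workflow tests."""

    name = "stub"

    def predict(self, model, image, confidence_floor):
        dets = model.state.get("script", {}).get(image.source_id, [])
        return [d for d in dets if d.confidence > confidence_floor]


det.register_backend(StubBackend())


def _stub_model(script, n_categories=1):
    return DetectorModel(
        backend="stub", n_categories=n_categories,
        state={"script": script}, seed=0, config_digest="stub",
    )


def _blank(source_id, boxes=()):
    z = np.zeros((64, 64), np.uint8)
    return FusedImage(red=z, green=z, third=z, boxes=list(boxes), source_id=source_id)


def _det(conf, x=10.0):
    box = Box(category=Category.METASTASIS, x_min=x, y_min=10, x_max=x + 12, y_max=22,
              confidence=conf)
    return Detection(box=box, confidence=conf)


class TestPretrain:
    def test_contract_one_category(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:10] if pos]
        model = pretrain_positive_only(positives, MiningConfig(seed=1))
        assert model.n_categories == 1

    def test_metastasis_free_image_rejected(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:10] if pos]
        negative = next(img for img, pos in easy_corpus if not pos)
        with pytest.raises(ValidationError, match="no metastasis box"):
            pretrain_positive_only(positives + [negative], MiningConfig())

    def test_seeded_rerun_identical(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:10] if pos]
        m1 = pretrain_positive_only(positives, MiningConfig(seed=5))
        m2 = pretrain_positive_only(positives, MiningConfig(seed=5))
        np.testing.assert_array_equal(
            m1.state["classifier"].coef_, m2.state["classifier"].coef_
        )


class TestHarvest:
    def test_never_firing_model_mines_nothing(self):
        model = _stub_model({})
        mined = harvest_negatives(model, [_blank("n1"), _blank("n2")], MiningConfig())
        assert len(mined) == 0

    def test_counts_and_relabeling_from_scripted_model(self):
        script = {
            "n1": [_det(0.9, 10), _det(0.9, 40)],
            "n2": [_det(0.9, 10)],
            "n3": [_det(0.9, 10), _det(0.9, 30), _det(0.9, 50)],
        }
        model = _stub_model(script)
        normals = [_blank(k) for k in ("n1", "n2", "n3")]
        mined = harvest_negatives(model, normals, MiningConfig())
        assert len(mined) == 6
        assert all(b.category == Category.NORMAL_HOTSPOT for _i, b, _c in mined.entries)
        assert len(mined.boxes_for("n3")) == 3

    def test_confidence_exactly_at_threshold_is_excluded(self):
        script = {"n1": [_det(0.1, 10), _det(0.100001, 40), _det(0.5, 70)]}
        mined = harvest_negatives(_stub_model(script), [_blank("n1")], MiningConfig())
        assert len(mined) == 2
        assert all(c > 0.1 for _i, _b, c in mined.entries)

    def test_two_category_model_rejected(self):
        with pytest.raises(ModelStateError):
            harvest_negatives(_stub_model({}, n_categories=2), [_blank("n")], MiningConfig())

    def test_image_with_metastasis_truth_rejected(self):
        met = Box(category=Category.METASTASIS, x_min=5, y_min=5, x_max=15, y_max=15)
        with pytest.raises(ValidationError, match="mining normal"):
            harvest_negatives(_stub_model({}), [_blank("p", boxes=[met])], MiningConfig())

    def test_store_round_trips(self, tmp_path):
        script = {"n1": [_det(0.4, 10)]}
        mined = harvest_negatives(_stub_model(script), [_blank("n1")], MiningConfig())
        mined.save(tmp_path)
        back = MinedNegatives.load(tmp_path)
        assert back.entries == mined.entries
        assert back.harvest_confidence == 0.1


class TestRetrainAndTransfer:
    def test_empty_mined_set_raises_with_advice(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:6] if pos]
        empty = MinedNegatives(entries=[], model_digest="x", harvest_confidence=0.1)
        with pytest.raises(TrainingError, match="harvest"):
            retrain_two_class(positives, [], empty, MiningConfig())

    def test_retrained_model_has_two_categories(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:10] if pos]
        normals = [img for img, pos in easy_corpus[:10] if not pos]
        pre = pretrain_positive_only(positives, MiningConfig(seed=2))
        mined = harvest_negatives(pre, normals, MiningConfig(seed=2))
        assert len(mined) > 0
        model = retrain_two_class(positives, normals, mined, MiningConfig(seed=2))
        assert model.n_categories == 2

    def test_mined_boxes_classified_normal_after_retraining(self, easy_corpus):
        """On an easy corpus the retrained model should call most mined
        false positives non-metastasis (that is the point of mining)."""
        positives = [img for img, pos in easy_corpus if pos][:12]
        normals = [img for img, pos in easy_corpus if not pos][:12]
        cfg = MiningConfig(seed=3)
        pre = pretrain_positive_only(positives, cfg)
        mined = harvest_negatives(pre, normals, cfg)
        assert len(mined) > 0
        model = retrain_two_class(positives, normals, mined, cfg)
        by_image = {img.source_id: img for img in normals}
        agree = total = 0
        for iid, box, _conf in mined.entries:
            img = by_image[iid]
            cands = [box]
            X = det.featurize_many(img, cands, context=cands)
            dets = det.predict_from_features(model, cands, X, confidence_floor=0.0)
            if dets:
                total += 1
                agree += dets[0].category == Category.NORMAL_HOTSPOT
        assert total > 0 and agree / total >= 0.7

    def test_transfer_requires_two_categories(self, easy_corpus):
        positives = [img for img, pos in easy_corpus[:6] if pos]
        pre = pretrain_positive_only(positives, MiningConfig(seed=1))
        with pytest.raises(ModelStateError):
            transfer_finetune(pre, positives, MiningConfig())

    def test_empty_target_returns_pretrained_with_warning(self, trained_two_class):
        with pytest.warns(UserWarning, match="empty target"):
            out = transfer_finetune(trained_two_class, [], MiningConfig())
        assert out is trained_two_class

    def test_finetuned_model_differs_on_nonempty_target(self, easy_corpus, trained_two_class):
        target = [img for img, _pos in easy_corpus[20:30]]
        out = transfer_finetune(trained_two_class, target, MiningConfig(seed=4))
        assert not np.array_equal(
            out.state["classifier"].coef_, trained_two_class.state["classifier"].coef_
        )

    def test_equivocal_folded_to_normal(self):
        eq = Box(category=Category.EQUIVOCAL, x_min=1, y_min=1, x_max=9, y_max=9)
        img = _blank("e", boxes=[eq])
        folded = fold_equivocal_to_normal(img)
        assert folded.boxes[0].category == Category.NORMAL_HOTSPOT
        assert img.boxes[0].category == Category.EQUIVOCAL  # original untouched
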