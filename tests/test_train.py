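"""Semi-supervised training loop: step accounting, loss additivity,
reproducibility and the consistency-pull property."""

import logging

import numpy as np
import pytest

from atsvit.augment import AugmentationSet, identity
from atsvit.losses import pseudo_label_loss
from atsvit.model import ViTATS
from atsvit.train import TrainConfig, one_hot, train


@pytest.fixture
def smoke_setup(tiny_model, rng):
    images = [rng.random((64, 64)) for _ in range(8)]
    labels = rng.integers(0, 2, 8)
    unlabeled = [rng.random((64, 64)) for _ in range(4)]
    return tiny_model, images, labels, unlabeled


def smoke_config(**kw):
    base = dict(learning_rate=1e-3, batch_size=4, epochs=1, input_size=64,
                ats_tokens=(16, 8), seed=0)
    base.update(kw)
    return TrainConfig(**base)


def test_defaults_echo_reference_training_setting():
    cfg = TrainConfig()
    assert cfg.learning_rate == 2e-5
    assert cfg.eps == 1e-8
    assert cfg.batch_size == 64
    assert cfg.epochs == 300
    assert cfg.input_size == 256
    assert cfg.ats_tokens == (256, 128, 64, 32, 16, 8)
    assert cfg.loss_weights == (1.0, 1.0, 1.0)


def test_one_epoch_batch_four_gives_two_steps(smoke_setup):
    model, images, labels, unlabeled = smoke_setup
    result = train(model, images, labels, unlabeled, smoke_config())
    assert len(result.step_bundles) == 2
    assert len(result.log) == 1


def test_loss_additivity_at_every_step(smoke_setup):
    model, images, labels, unlabeled = smoke_setup
    result = train(model, images, labels, unlabeled, smoke_config(epochs=2))
    assert result.step_bundles  # at least one consistency step ran
    for b in result.step_bundles:
        assert b.total == pytest.approx(b.ce + b.mse + b.em, abs=1e-6)
        assert b.ce >= 0 and b.mse >= 0 and b.em >= 0


def test_same_seed_gives_identical_trajectories(tiny_config, rng):
    images = [rng.random((64, 64)) for _ in range(8)]
    labels = rng.integers(0, 2, 8)
    unlabeled = [rng.random((64, 64)) for _ in range(4)]
    runs = []
    for _ in range(2):
        model = ViTATS(tiny_config)
        res = train(model, images, labels, unlabeled, smoke_config(epochs=2))
        runs.append([(b.ce, b.mse, b.em) for b in res.step_bundles])
    assert runs[0] == runs[1]


def test_branches_share_the_same_parameter_objects(smoke_setup):
    model, images, labels, unlabeled = smoke_setup
    ids_before = [id(p) for p in model.parameters()]
    data_before = model.state_dict()
    train(model, images, labels, unlabeled, smoke_config())
    assert [id(p) for p in model.parameters()] == ids_before
    # and the shared parameters actually moved
    assert any(not np.array_equal(data_before[k], v.data)
               for k, v in model.params.items())


def test_empty_unlabeled_set_degrades_to_supervised(smoke_setup, caplog):
    model, images, labels, _ = smoke_setup
    with caplog.at_level(logging.WARNING, logger="atsvit.train"):
        result = train(model, images, labels, [], smoke_config())
    assert "supervised-only" in caplog.text
    assert all(b.mse == 0.0 and b.em == 0.0 for b in result.step_bundles)


def test_identity_augmentation_gives_zero_consistency_loss(smoke_setup):
    model, images, labels, unlabeled = smoke_setup
    aug = AugmentationSet(transforms=[identity], seed=0)
    result = train(model, images, labels, unlabeled, smoke_config(),
                   augmentations=aug)
    for b in result.step_bundles:
        assert b.mse == pytest.approx(0.0, abs=1e-12)
        assert b.em == pytest.approx(0.0, abs=1e-12)


def test_consistency_loss_shrinks_with_augmentation_strength(tiny_model, rng):
    """The pseudo-label pull vanishes as the perturbation approaches
    identity (deterministic contrast family, fixed untrained model)."""
    img = rng.random((64, 64))
    losses = []
    for s in (0.4, 0.3, 0.2, 0.1, 0.0):
        z = np.clip(img.mean() + (1 + s) * (img - img.mean()), 0, 1)
        p_x = tiny_model.predict_proba([img])
        from atsvit.autodiff import Tensor
        p_z = Tensor(tiny_model.predict_proba([z]))
        losses.append(pseudo_label_loss(p_x, p_z).item())
    assert losses[-1] == pytest.approx(0.0, abs=1e-12)
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_checkpoint_selection_tracks_best_validation_f1(smoke_setup, rng):
    model, images, labels, unlabeled = smoke_setup
    val_images = [rng.random((64, 64)) for _ in range(4)]
    val_labels = rng.integers(0, 2, 4)
    result = train(model, images, labels, unlabeled, smoke_config(epochs=3),
                   val_images=val_images, val_labels=val_labels)
    f1s = [r.val.f1 for r in result.log]
    assert result.best_val_f1 == pytest.approx(max(f1s))
    assert result.best_epoch == int(np.argmax(f1s))


def test_one_hot_encoding():
    out = one_hot(np.array([0, 2, 1]), 3)
    np.testing.assert_array_equal(out, np.eye(3)[[0, 2, 1]])


def test_training_log_lines_are_json_records(smoke_setup, tmp_path):
    import json
    model, images, labels, unlabeled = smoke_setup
    path = tmp_path / "log.jsonl"
    train(model, images, labels, unlabeled, smoke_config(), log_path=path)
    lines = path.read_text().strip().splitlines()
    rec = json.loads(lines[0])
    assert {"epoch", "L_CE", "L_MSE", "L_EM", "L"} <= set(rec)
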