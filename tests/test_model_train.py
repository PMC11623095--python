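"""Full network assembly and the training loop."""

import numpy as np
import pytest

from msrunet import (
    ConfigurationError,
    MSRUNet,
    StagePlan,
    TrainConfig,
    augment_pair,
    poly_lr,
)
from msrunet.phantoms import Dataset, PhantomSpec, generate_phantom
from msrunet.train import train, validate_dsc


@pytest.fixture(scope="module")
def small_model():
    return MSRUNet(StagePlan.small(), num_classes=4, img_size=64, seed=0)


def test_forward_shape_64(small_model, rng):
    logits = small_model.forward(rng.normal(size=(2, 64, 64)))
    assert logits.shape == (2, 64, 64, 4)


def test_encoder_grid_ledger(small_model):
    assert small_model.stage_hws == [(16, 16), (8, 8), (4, 4), (2, 2)]


def test_indivisible_input_rejected():
    with pytest.raises(ConfigurationError, match="divisible by 32"):
        MSRUNet(StagePlan.small(), num_classes=2, img_size=100)


def test_wrong_runtime_size_rejected(small_model, rng):
    with pytest.raises(ConfigurationError, match="built for"):
        small_model.forward(rng.normal(size=(1, 32, 32)))


def test_forward_deterministic(small_model, rng):
    x = rng.normal(size=(1, 64, 64))
    a = small_model.forward(x).data
    b = small_model.forward(x).data
    assert np.array_equal(a, b)


def test_every_parameter_gets_gradient_in_one_step(rng):
    model = MSRUNet(StagePlan.small(), num_classes=3, img_size=64, seed=1)
    logits = model.forward(rng.normal(size=(2, 64, 64)))
    (logits * logits).sum().backward()
    missing = [n for n, p in model.named_parameters() if p.grad is None]
    assert missing == []
    zero = [n for n, p in model.named_parameters() if np.abs(p.grad).sum() == 0]
    assert zero == []


def test_parameter_count_independent_of_dilation_preset():
    counts = {
        preset: MSRUNet(
            StagePlan.small(), num_classes=4, img_size=64, preset=preset, seed=0
        ).num_parameters()
        for preset in ("default", "low", "high")
    }
    assert len(set(counts.values())) == 1  # keys come from sampling, not weights


def test_predict_returns_label_mask(small_model, rng):
    mask = small_model.predict(rng.normal(size=(64, 64)))
    assert mask.shape == (64, 64)
    assert mask.dtype.kind in "iu"
    assert set(np.unique(mask)) <= {0, 1, 2, 3}


# ------------------------------------------------------------------ poly LR
def test_poly_lr_endpoints_and_midpoint():
    assert poly_lr(0, 1000, base=0.05) == pytest.approx(0.05)
    assert poly_lr(1000, 1000, base=0.05) == 0.0
    assert poly_lr(500, 1000, base=0.05, power=1.0) == pytest.approx(0.025)


def test_poly_lr_monotone_non_increasing():
    etas = [poly_lr(t, 1000) for t in range(1001)]
    assert all(a >= b for a, b in zip(etas, etas[1:]))


def test_poly_lr_clamps_beyond_schedule_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        assert poly_lr(1001, 1000) == 0.0


# -------------------------------------------------------------- augmentation
def test_augmentation_preserves_class_counts_without_resampling(rng):
    image, mask = generate_phantom(PhantomSpec(seed=2))
    before = np.bincount(mask.ravel(), minlength=4)
    for _ in range(10):
        _, m2 = augment_pair(image, mask, rng, small_rotation=False)
        assert np.array_equal(np.bincount(m2.ravel(), minlength=4), before)


def test_augmentation_applies_same_transform_to_both(rng):
    image, mask = generate_phantom(PhantomSpec(seed=2, noise_std=0.0))
    spec = PhantomSpec(seed=2, noise_std=0.0)
    im2, m2 = augment_pair(image, mask, rng, small_rotation=False)
    # piecewise-constant image: the mask must still predict the intensity
    assert np.allclose(spec.means[m2], im2)


# ------------------------------------------------------------ training loop
def _tiny_dataset(n=6, seed=0):
    cases = [generate_phantom(PhantomSpec(seed=seed + i)) for i in range(n)]
    return Dataset(train=cases[:-2], val=cases[-2:])


def test_short_training_reduces_loss():
    ds = _tiny_dataset()
    model = MSRUNet(StagePlan.small(), num_classes=4, img_size=64, seed=3)
    cfg = TrainConfig(input_side=64, max_iters=30, batch_size=4, seed=3,
                      val_interval=30, small_rotation=False)
    res = train(model, ds, cfg)
    assert res.final_loss < res.initial_loss


def test_training_reproducible_given_seed():
    losses = []
    for _ in range(2):
        ds = _tiny_dataset()
        model = MSRUNet(StagePlan.small(), num_classes=4, img_size=64, seed=4)
        cfg = TrainConfig(input_side=64, max_iters=8, batch_size=2, seed=4,
                          val_interval=8, small_rotation=False)
        res = train(model, ds, cfg)
        losses.append([h["loss"] for h in res.history])
    assert losses[0] == losses[1]


def test_dice_only_mode_ignores_lambda():
    ds = _tiny_dataset()
    results = []
    for lam in (0.0, 1.0):
        model = MSRUNet(StagePlan.small(), num_classes=4, img_size=64, seed=5)
        cfg = TrainConfig(input_side=64, max_iters=3, batch_size=2, seed=5,
                          loss_mode="dice", lam=lam, val_interval=3,
                          small_rotation=False, augment=False)
        results.append([h["loss"] for h in train(model, ds, cfg).history])
    assert results[0] == results[1]


def test_empty_dataset_raises():
    model = MSRUNet(StagePlan.small(), num_classes=4, img_size=64, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(model, Dataset(train=[], val=[]), TrainConfig(input_side=64))


def test_validate_dsc_perfect_on_ground_truth_predictor():
    class Oracle:
        num_classes = 4

        def predict(self, images):
            return np.broadcast_to(self._mask, images.shape)

    cases = [generate_phantom(PhantomSpec(seed=9))]
    oracle = Oracle()
    oracle._mask = cases[0][1]
    assert validate_dsc(oracle, cases, 4) == pytest.approx(100.0)
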