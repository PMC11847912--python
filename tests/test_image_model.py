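"""Image preprocessing, augmentation, CNN training and Grad-CAM."""

import numpy as np
import pytest
from PIL import Image

from woundtriage.evaluation import auc
from woundtriage.image import (
    DEFAULT_AUGMENTATION,
    WoundCnnClassifier,
    augment,
    cam,
    preprocess_images,
)

_IDENTITY_SPEC = {
    "max_translation": 0.0,
    "max_rotation_deg": 0.0,
    "scale_range": (1.0, 1.0),
    "flip": False,
}


def _toy_image_dataset(n=60, size=32, seed=0):
    """Class 1 images carry a bright red patch; class 0 are plain noise."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.3, 0.5, size=(n, size, size, 3))
    y = (rng.random(n) < 0.5).astype(int)
    patch = size // 4
    for i in np.flatnonzero(y):
        r, c = rng.integers(0, size - patch, size=2)
        X[i, r : r + patch, c : c + patch, 0] += 0.45
    return np.clip(X, 0, 1), y


# -- preprocessing ----------------------------------------------------------

def test_resize_to_standard_square(tmp_path):
    arr = (np.random.default_rng(0).random((512, 512, 3)) * 255).astype(np.uint8)
    path = tmp_path / "img.png"
    Image.fromarray(arr).save(path)
    batch = preprocess_images([path], target_size=256)
    assert batch.pixels.shape == (1, 256, 256, 3)
    assert batch.pixels.min() >= 0 and batch.pixels.max() <= 1


def test_already_sized_image_passes_through(tmp_path):
    arr = (np.random.default_rng(1).random((256, 256, 3)) * 255).astype(np.uint8)
    path = tmp_path / "img.png"
    Image.fromarray(arr).save(path)
    batch = preprocess_images([path], target_size=256)
    assert np.allclose(batch.pixels[0], arr / 255.0, atol=1e-9)


def test_batch_shape(tmp_path):
    rng = np.random.default_rng(2)
    paths = []
    for i in range(10):
        arr = (rng.random((100, 140, 3)) * 255).astype(np.uint8)
        p = tmp_path / f"im{i}.jpg"
        Image.fromarray(arr).save(p)
        paths.append(p)
    batch = preprocess_images(paths, target_size=64)
    assert batch.pixels.shape == (10, 64, 64, 3)


def test_grayscale_replicated_with_warning(tmp_path):
    arr = (np.random.default_rng(3).random((80, 80)) * 255).astype(np.uint8)
    path = tmp_path / "grey.png"
    Image.fromarray(arr, mode="L").save(path)
    with pytest.warns(UserWarning, match="grayscale"):
        batch = preprocess_images([path], target_size=64)
    px = batch.pixels[0]
    assert np.array_equal(px[..., 0], px[..., 1])


def test_unreadable_file_names_the_file(tmp_path):
    bad = tmp_path / "broken.png"
    bad.write_bytes(b"not a png at all")
    with pytest.raises(OSError, match="broken.png"):
        preprocess_images([bad])


# -- augmentation -----------------------------------------------------------

def test_identity_augmentation_is_identity(rng):
    X = np.random.default_rng(0).random((3, 32, 32, 3))
    out = augment(X, rng, _IDENTITY_SPEC)
    assert np.allclose(out, X, atol=1e-12)


def test_double_flip_restores_image():
    X = np.random.default_rng(1).random((16, 16, 3))
    assert np.array_equal(np.flip(np.flip(X, axis=1), axis=1), X)


def test_augmentation_preserves_interior_intensity(rng):
    X = np.full((4, 64, 64, 3), 0.5)
    out = augment(X, rng)
    interior = out[:, 16:48, 16:48, :]
    assert np.allclose(interior.mean(), 0.5, atol=0.02)


def test_augmented_batch_differs_but_same_shape(rng):
    X = np.random.default_rng(2).random((5, 32, 32, 3))
    out = augment(X, rng)
    assert out.shape == X.shape
    assert not np.allclose(out, X)


# -- CNN --------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_cnn():
    X, y = _toy_image_dataset()
    model = WoundCnnClassifier(
        channels=(8, 16), epochs=12, augmentation=False, random_state=0
    ).fit(X, y)
    return model, X, y


def test_cnn_learns_red_patch_signal(trained_cnn):
    model, X, y = trained_cnn
    Xte, yte = _toy_image_dataset(n=40, seed=99)
    assert auc(model.predict_proba(Xte)[:, 1], yte, ci=False) > 0.8


def test_cnn_null_signal_near_chance():
    """Under label permutation the held-out AUC stays within chance bounds."""
    rng = np.random.default_rng(0)
    X, y = _toy_image_dataset(n=120, seed=5)
    model = WoundCnnClassifier(
        channels=(8, 16), epochs=4, augmentation=False, random_state=0
    ).fit(X, rng.permutation(y))
    Xte, yte = _toy_image_dataset(n=80, seed=123)
    # evaluate against labels independent of the image content (the null)
    value = auc(model.predict_proba(Xte)[:, 1], rng.permutation(yte), ci=False)
    assert 0.3 < value < 0.7


def test_cnn_seed_determinism():
    X, y = _toy_image_dataset(n=24, size=16, seed=7)
    kw = dict(channels=(4, 8), epochs=2, augmentation=False, random_state=3)
    p1 = WoundCnnClassifier(**kw).fit(X, y).predict_proba(X)
    p2 = WoundCnnClassifier(**kw).fit(X, y).predict_proba(X)
    assert np.array_equal(p1, p2)


def test_cnn_prediction_is_augmentation_free(trained_cnn):
    model, X, _ = trained_cnn
    assert np.array_equal(model.predict_proba(X[:4]), model.predict_proba(X[:4]))


def test_cnn_single_class_refused():
    X, _ = _toy_image_dataset(n=10, size=16)
    with pytest.raises(ValueError, match="single class"):
        WoundCnnClassifier(channels=(4,)).fit(X, np.zeros(10))


def test_cnn_rejects_bad_shapes():
    with pytest.raises(ValueError, match="must be"):
        WoundCnnClassifier().fit(np.zeros((4, 10)), [0, 1, 0, 1])
    with pytest.raises(ValueError, match="divisible"):
        WoundCnnClassifier(channels=(4, 8, 16, 32)).fit(
            np.zeros((4, 24, 24, 3)), [0, 1, 0, 1]
        )


def test_cnn_early_stopping_trace(trained_cnn):
    model, _, _ = trained_cnn
    meta = model.training_meta_
    best = meta["best_trace"]
    assert all(a >= b for a, b in zip(best, best[1:]))
    assert meta["best_loss"] == best[-1]


def test_cnn_save_load_round_trip(tmp_path, trained_cnn):
    model, X, _ = trained_cnn
    path = model.save(tmp_path / "cnn.npz")
    back = WoundCnnClassifier.load(path)
    assert np.allclose(model.predict_proba(X[:6]), back.predict_proba(X[:6]))


def test_pretrained_checkpoint_fine_tune(tmp_path, trained_cnn):
    """A saved checkpoint can seed fine-tuning with frozen early blocks."""
    model, X, y = trained_cnn
    path = model.save(tmp_path / "ckpt.npz")
    tuned = WoundCnnClassifier(
        channels=(8, 16), epochs=1, augmentation=False,
        pretrained_weights=str(path), unfreeze_from_block=2, random_state=1,
    ).fit(X, y)
    # frozen first conv block keeps the checkpoint weights exactly
    assert np.array_equal(tuned._net.layers[0].W, model._net.layers[0].W)


# -- Grad-CAM ---------------------------------------------------------------

def test_cam_constant_image_near_uniform(trained_cnn):
    model, _, _ = trained_cnn
    heat = cam(model, np.full((32, 32, 3), 0.5))
    assert heat.weights.shape == (32, 32)
    # uniform away from the zero-padding border band
    assert heat.weights[8:-8, 8:-8].std() < 0.05


def test_cam_normalization_contract(trained_cnn):
    model, X, _ = trained_cnn
    heat = cam(model, X[0])
    assert heat.weights.min() >= 0.0 and heat.weights.max() <= 1.0
    assert heat.weights.max() == pytest.approx(1.0) or heat.weights.max() == 0.0
    assert heat.overlay.shape == (32, 32, 3)


def test_cam_refuses_model_without_conv():
    X = np.random.default_rng(0).random((12, 16, 16, 3))
    y = np.tile([0, 1], 6)
    model = WoundCnnClassifier(channels=(), epochs=1, augmentation=False).fit(X, y)
    with pytest.raises(ValueError, match="convolutional"):
        model.class_activation_map(X[0])
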