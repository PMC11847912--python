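"""Procedural renderer for synthetic surgical-wound photographs.

Each image is a uniform skin-tone background carrying a dark curvilinear
incision, an erythema halo (red shift around the incision, scaled by
``erythema_intensity``), and optional yellow purulent spots. The renderer
is a stand-in for real wound photographs — synthetic by construction and
labelled as such — but its generative law ties the visual features
monotonically to infection status, which is what the image classifier and
its class-activation maps are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# skin base colours (RGB in [0,1]) interpolated by the skin-tone parameter
_DARK = np.array([0.38, 0.24, 0.18])
_LIGHT = np.array([0.90, 0.69, 0.57])
_PUS = np.array([0.93, 0.88, 0.42])


@dataclass
class SyntheticImage:
    """A rendered wound image plus its generative ground truth."""

    pixels: np.ndarray  # (size, size, 3) float in [0, 1]
    wound_mask: np.ndarray  # (size, size) bool, incision + periwound region
    truth: dict  # erythema_intensity, pus_count, skin_tone


def _incision_distance(size: int, rng: np.random.Generator) -> np.ndarray:
    """Distance (pixels) from each pixel to a random quadratic Bezier incision."""
    c = size / 2.0
    spread = size * 0.28
    p0 = np.array([c + rng.uniform(-spread, spread), c - spread * rng.uniform(0.7, 1.1)])
    p2 = np.array([c + rng.uniform(-spread, spread), c + spread * rng.uniform(0.7, 1.1)])
    p1 = (p0 + p2) / 2 + rng.uniform(-spread, spread, size=2)
    t = np.linspace(0.0, 1.0, 4 * size)[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    ij = np.clip(np.round(curve).astype(int), 0, size - 1)
    on_curve = np.zeros((size, size), dtype=bool)
    on_curve[ij[:, 1], ij[:, 0]] = True
    return ndimage.distance_transform_edt(~on_curve)


def render_wound_image(
    erythema_intensity: float,
    pus_count: int,
    skin_tone: float,
    rng: np.random.Generator,
    image_size: int = 256,
) -> SyntheticImage:
    """Render one synthetic wound photograph.

    Parameters
    ----------
    erythema_intensity:
        In [0, 1]; scales the red halo around the incision.
    pus_count:
        Number of purulent (yellow) spots placed along the incision.
    skin_tone:
        In [0, 1]; linearly interpolates the background between a dark and
        a light skin base colour.
    rng:
        Drives incision geometry, spot placement and pixel noise; a fixed
        generator state reproduces the image exactly.
    image_size:
        Side length in pixels; must be >= 64 so the downstream CNN's
        pooling pyramid is meaningful.
    """
    if image_size < 64:
        raise ValueError("image_size must be >= 64")
    if not 0.0 <= erythema_intensity <= 1.0:
        raise ValueError("erythema_intensity must be in [0, 1]")
    if pus_count < 0:
        raise ValueError("pus_count must be >= 0")
    size = int(image_size)

    base = _DARK + float(np.clip(skin_tone, 0, 1)) * (_LIGHT - _DARK)
    img = np.broadcast_to(base, (size, size, 3)).copy()
    img += rng.normal(0.0, 0.015, size=img.shape)

    dist = _incision_distance(size, rng)
    peri = size * 0.085
    wound_mask = dist < peri

    # erythema: red-shifted halo with Gaussian falloff from the incision
    halo = np.exp(-((dist / (size * 0.11)) ** 2))
    shift = erythema_intensity * halo
    img[..., 0] += 0.30 * shift
    img[..., 1] -= 0.10 * shift
    img[..., 2] -= 0.12 * shift

    # purulent spots on the incision line
    if pus_count > 0:
        line = np.argwhere(dist < 1.5)
        picks = line[rng.integers(0, len(line), size=int(pus_count))]
        yy, xx = np.mgrid[0:size, 0:size]
        r_spot = max(2.0, size / 55.0)
        for py, px in picks:
            blob = np.exp(-(((yy - py) ** 2 + (xx - px) ** 2) / (2 * r_spot**2)))
            img += blob[..., None] * (_PUS - img) * 0.9

    # incision itself: narrow dark line, feathered
    w_line = max(1.0, size / 170.0)
    darkening = 0.65 * np.exp(-((dist / w_line) ** 2))
    img *= 1.0 - darkening[..., None]

    np.clip(img, 0.0, 1.0, out=img)
    frac = wound_mask.mean()
    assert 0.01 <= frac <= 0.40, f"wound mask covers {frac:.1%} of pixels"
    return SyntheticImage(
        pixels=img,
        wound_mask=wound_mask,
        truth={
            "erythema_intensity": float(erythema_intensity),
            "pus_count": int(pus_count),
            "skin_tone": float(skin_tone),
        },
    )
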