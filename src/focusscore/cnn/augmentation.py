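"""Training-time data augmentation for focus images.

Label-preserving random geometric transforms, applied after the resize to
network input size: rotation uniform on [-90, 90] degrees, translation
uniform on [-44, 44] pixels per axis (at the reference 224-px input; scaled
proportionally for other sizes), shear uniform on [-15, 15] degrees, and
horizontal / vertical flips each with probability 0.5.  Out-of-frame areas
are filled with the per-image border-median colour, so transformed images
keep a plausible monolayer background instead of black corners.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, warp

from ..synthgen import FocusImage

__all__ = ["augment", "AugmentParams", "draw_params", "apply_params"]

REFERENCE_INPUT = 224


class AugmentParams:
    """One concrete draw of the augmentation transform."""

    __slots__ = ("rotation_deg", "translation", "shear_deg", "hflip", "vflip")

    def __init__(self, rotation_deg=0.0, translation=(0.0, 0.0), shear_deg=0.0,
                 hflip=False, vflip=False):
        self.rotation_deg = rotation_deg
        self.translation = translation
        self.shear_deg = shear_deg
        self.hflip = hflip
        self.vflip = vflip


def draw_params(config, rng: np.random.Generator, input_hw: tuple[int, int]) -> AugmentParams:
    """Draw transform parameters from the configured uniform ranges."""
    scale = min(input_hw) / REFERENCE_INPUT
    t = config.translate * scale
    return AugmentParams(
        rotation_deg=float(rng.uniform(-config.rotation, config.rotation)),
        translation=(float(rng.uniform(-t, t)), float(rng.uniform(-t, t))),
        shear_deg=float(rng.uniform(-config.shear, config.shear)),
        hflip=bool(rng.uniform() < config.flip_p),
        vflip=bool(rng.uniform() < config.flip_p),
    )


def _border_median(img: np.ndarray) -> np.ndarray:
    edges = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]], axis=0)
    return np.median(edges, axis=0)


def apply_params(img: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply one parameter draw to a float HxWx3 image in [0, 1]."""
    out = img
    if params.rotation_deg or params.shear_deg or any(params.translation):
        h, w = img.shape[:2]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        center = AffineTransform(translation=(-cx, -cy))
        core = AffineTransform(rotation=np.deg2rad(params.rotation_deg),
                               shear=np.deg2rad(params.shear_deg))
        back = AffineTransform(translation=(cx + params.translation[0],
                                            cy + params.translation[1]))
        tform = center + core + back
        fill = _border_median(img)
        out = np.stack([
            warp(img[:, :, c], tform.inverse, mode="constant", cval=float(fill[c]),
                 order=1, preserve_range=True)
            for c in range(img.shape[2])
        ], axis=2)
    if params.hflip:
        out = out[:, ::-1]
    if params.vflip:
        out = out[::-1]
    return np.ascontiguousarray(out)


def augment(image: FocusImage | np.ndarray, config, rng: np.random.Generator):
    """Randomly transform one image; deterministic given the rng state.

    Accepts a uint8 :class:`FocusImage` or a float array in [0, 1]; returns
    the same kind, same shape.
    """
    params = draw_params(config, rng, _hw(image))
    if isinstance(image, FocusImage):
        f = image.pixels.astype(np.float64) / 255.0
        out = apply_params(f, params)
        px = (np.clip(out, 0, 1) * 255).round().astype(np.uint8)
        return FocusImage(pixels=px, label=image.label, chemical=image.chemical,
                          source=image.source, id=image.id)
    return apply_params(np.asarray(image, dtype=np.float64), params)


def _hw(image) -> tuple[int, int]:
    px = image.pixels if isinstance(image, FocusImage) else np.asarray(image)
    return px.shape[0], px.shape[1]
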