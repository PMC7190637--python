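"""Core image preparation, half-splitting, patch sampling and augmentation.

Conventions: 0-based, half-open pixel coordinates in (row, col) order.
A prepared core is 1600x1600 px at 0.5 um/px; its left half is columns
[0, W/2) and its right half is columns [W/2, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .synthgen import StyleParams, render_style

__all__ = [
    "CoreImage",
    "StylePair",
    "PatchSample",
    "AugmentConfig",
    "prepare_core",
    "split_halves",
    "sample_patch",
    "augment_patch",
    "restyle",
    "to_grayscale",
]

TARGET_MPP = 0.5
TARGET_SIZE = 1600
PATCH = 224

_LUMA = np.array([0.2126, 0.7152, 0.0722], dtype=np.float32)


@dataclass
class CoreImage:
    """A TMA core raster with identity and scale metadata."""

    core_index: int
    patient_id: int
    style_id: str
    pixels: np.ndarray  # (H,W,3) uint8
    microns_per_pixel: float
    prepared: bool = False
    pad_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")


@dataclass
class StylePair:
    """Same-morphology core rendered in two styles (a core and its restyled twin)."""

    image_1: CoreImage
    image_2: CoreImage

    def __post_init__(self):
        if self.image_1.core_index != self.image_2.core_index:
            raise ValueError("style pair must share a core_index")


@dataclass
class PatchSample:
    pixels: np.ndarray            # (224,224,3) uint8
    core_index: int = 0
    half: str = "left"            # {left, right}
    origin: tuple[int, int] = (0, 0)  # (row, col) of the top-left pixel


@dataclass
class AugmentConfig:
    """Augmentation knobs applied in order: rotation/flips, photometric
    jitter, optional grayscale conversion."""

    rotate: bool = True
    flip: bool = True
    brightness: float = 0.1   # multiplicative jitter in [1-b, 1+b]
    contrast: float = 0.08    # additive jitter in [-c, c] (on the [0,1] scale)
    grayscale_input: bool = True


def _modal_border_color(raster: np.ndarray) -> np.ndarray:
    """Most common color on the 1-px border; used as padding background."""
    border = np.concatenate([raster[0], raster[-1], raster[:, 0], raster[:, -1]])
    colors, counts = np.unique(border.reshape(-1, raster.shape[-1]), axis=0,
                               return_counts=True)
    return colors[counts.argmax()]


def prepare_core(raw: np.ndarray, mpp_in: float, core_index: int = 0,
                 patient_id: int = 0, style_id: str = "", pad: bool = True) -> CoreImage:
    """Rescale to 0.5 um/px (bilinear) and center-crop/pad to 1600x1600.

    Padding (when the rescaled raster is short of 1600 px in a dimension)
    uses the modal border color and is recorded in ``pad_info``.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[-1] != 3:
        raise ValueError("raw must be an (H,W,3) RGB raster")
    if mpp_in <= 0:
        raise ValueError("mpp_in must be positive")

    scale = mpp_in / TARGET_MPP
    out_shape = (round(raw.shape[0] * scale), round(raw.shape[1] * scale))
    if out_shape != raw.shape[:2]:
        img = resize(raw.astype(np.float32), out_shape, order=1,
                     anti_aliasing=scale < 1, preserve_range=True)
        img = np.clip(img, 0, 255).round().astype(np.uint8)
    else:
        img = raw.copy()

    pad_info: dict = {}
    h, w = img.shape[:2]
    if (h < TARGET_SIZE or w < TARGET_SIZE) and not pad:
        raise ValueError(f"raster {h}x{w} smaller than {TARGET_SIZE} and padding disabled")
    if h < TARGET_SIZE or w < TARGET_SIZE:
        color = _modal_border_color(img)
        py = max(0, TARGET_SIZE - h)
        px = max(0, TARGET_SIZE - w)
        pads = ((py // 2, py - py // 2), (px // 2, px - px // 2), (0, 0))
        img = np.stack([
            np.pad(img[..., c], pads[:2], constant_values=color[c]) for c in range(3)
        ], axis=-1)
        pad_info = {"rows": pads[0], "cols": pads[1], "color": color.tolist()}
        h, w = img.shape[:2]
    r0 = (h - TARGET_SIZE) // 2
    c0 = (w - TARGET_SIZE) // 2
    img = img[r0 : r0 + TARGET_SIZE, c0 : c0 + TARGET_SIZE]
    return CoreImage(core_index, patient_id, style_id, img, TARGET_MPP,
                     prepared=True, pad_info=pad_info)


def split_halves(core: CoreImage) -> tuple[np.ndarray, np.ndarray]:
    """Left = columns [0, W/2), right = [W/2, W); half-open, 0-based."""
    if not core.prepared:
        raise RuntimeError("core must be prepared before splitting")
    w = core.pixels.shape[1]
    mid = w // 2
    return core.pixels[:, :mid], core.pixels[:, mid:]


def sample_patch(half: np.ndarray, rng: np.random.Generator,
                 core_index: int = 0, side: str = "left") -> PatchSample:
    """Uniformly sample a 224x224 patch fully inside the half."""
    h, w = half.shape[:2]
    if h < PATCH or w < PATCH:
        raise ValueError(f"half {h}x{w} smaller than patch size {PATCH}")
    r = int(rng.integers(0, h - PATCH + 1))
    c = int(rng.integers(0, w - PATCH + 1))
    return PatchSample(half[r : r + PATCH, c : c + PATCH], core_index, side, (r, c))


def to_grayscale(patch: np.ndarray) -> np.ndarray:
    """Luminance replicated to 3 identical channels (same dtype semantics)."""
    lum = patch.astype(np.float32) @ _LUMA
    return np.repeat(lum[..., None], 3, axis=-1)


def augment_patch(patch: PatchSample | np.ndarray, rng: np.random.Generator,
                  config: AugmentConfig | None = None,
                  rotation_k: int | None = None) -> np.ndarray:
    """Augment a patch; returns float32 (224,224,3) in [0,1].

    Order: right-angle rotation (k quarter turns, optionally forced via
    ``rotation_k``) and flips; multiplicative brightness in [1-b, 1+b] and
    additive contrast shift in [-c, c]; optional grayscale conversion
    (3 identical channels); clip to [0,1].
    """
    config = config or AugmentConfig()
    px = patch.pixels if isinstance(patch, PatchSample) else patch
    x = px.astype(np.float32) / 255.0
    if rotation_k is None:
        rotation_k = int(rng.integers(0, 4)) if config.rotate else 0
    x = np.rot90(x, k=rotation_k)
    if config.flip and rng.integers(0, 2):
        x = x[:, ::-1]
    if config.brightness:
        x = x * rng.uniform(1 - config.brightness, 1 + config.brightness)
    if config.contrast:
        x = x + rng.uniform(-config.contrast, config.contrast)
    if config.grayscale_input:
        lum = x @ _LUMA
        x = np.repeat(lum[..., None], 3, axis=-1)
    return np.ascontiguousarray(np.clip(x, 0.0, 1.0))


def restyle(image: np.ndarray, from_style: StyleParams, to_style: StyleParams,
            morphology: np.ndarray | None = None,
            restyled_files: dict | None = None, core_index: int | None = None) -> np.ndarray:
    """Re-render an image in another site style, preserving morphology.

    Three modes, in order of precedence:

    * file-backed: if ``restyled_files`` maps ``core_index`` to a stored
      twin (e.g. output of an external neural style-transfer model), return
      it unchanged;
    * known morphology: re-render the (nuclear, cytoplasm) channels with the
      target style directly;
    * blind: invert the parametric stain model of ``from_style`` (undo
      brightness/gamma, solve the two-stain log-linear system per pixel by
      least squares) and re-render with ``to_style``.
    """
    if from_style.style_id == to_style.style_id:
        return image
    if restyled_files is not None:
        if core_index not in restyled_files:
            raise KeyError(f"no restyled twin stored for core {core_index}")
        return restyled_files[core_index]
    if morphology is not None:
        return render_style(morphology, to_style)

    rgb = np.clip(image.astype(np.float64) / 255.0 - from_style.brightness, 1e-6, 1.0)
    rgb = np.power(rgb, 1.0 / from_style.gamma)
    bg = np.clip(np.array(from_style.background_rgb, np.float64) / 255.0, 1e-3, 1)
    h_col = np.clip(np.array(from_style.hematoxylin_rgb, np.float64) / 255.0, 1e-3, 1)
    e_col = np.clip(np.array(from_style.eosin_rgb, np.float64) / 255.0, 1e-3, 1)
    # log(rgb/bg) = n*log(H) + c*log(E): 3 equations, 2 unknowns per pixel
    basis = np.stack([np.log(h_col), np.log(e_col)], axis=1)  # (3,2)
    target = np.log(rgb / bg).reshape(-1, 3).T                # (3,P)
    coef, *_ = np.linalg.lstsq(basis, target, rcond=None)     # (2,P)
    n_ch, c_ch = np.clip(coef, 0.0, 1.0).reshape(2, *image.shape[:2])
    return render_style(np.stack([n_ch, c_ch]).astype(np.float32), to_style)
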