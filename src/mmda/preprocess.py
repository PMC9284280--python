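"""Fundus photograph normalization: resize, crop to the retinal disc,
and Gaussian-difference contrast enhancement.

The enhancement computes, per channel,

    out = clip(lambda_ * (G_sigma * I) + omega * I + delta, 0, 255)

with reflective boundary handling for the Gaussian blur. The default
weights (lambda_=4, omega=-4, delta=128) boost local contrast around a
mid-grey baseline so lesions stand out against the retinal background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError, InvalidParameterError

#: summed-channel intensity above which a pixel counts as retina, not border
DEFAULT_CROP_THRESHOLD = 21.0  # 7 units per channel
#: sigma as a fraction of the estimated disc radius
SIGMA_RADIUS_FRACTION = 1.0 / 30.0


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidInputError("empty image")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise InvalidInputError("intensities outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class EnhancementParams:
    lambda_: float = 4.0
    omega: float = -4.0
    delta: float = 128.0
    sigma: float | None = None  # None -> derived from disc radius

    def __post_init__(self):
        if self.sigma is not None and self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class CropResult:
    image: FundusImage
    center: tuple[float, float]  # (row, col)
    radius: float


def resize_long_side(img: FundusImage, max_side: int) -> FundusImage:
    """Shrink so the longer side equals ``max_side``; never enlarges."""
    if max_side < 1:
        raise InvalidParameterError(f"max_side must be >= 1, got {max_side}")
    h, w = img.height, img.width
    long = max(h, w)
    if long <= max_side:
        return img
    scale = max_side / long
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    pil = Image.fromarray(img.pixels).resize((new_w, new_h), Image.BILINEAR)
    return FundusImage(np.asarray(pil), img.source_path)


def crop_to_disc(img: FundusImage, threshold: float = DEFAULT_CROP_THRESHOLD) -> CropResult:
    """Crop to the bounding box of above-threshold pixels.

    The disc center is the centroid of the above-threshold mask and the
    radius half the larger box side. A fully dark image is returned
    unchanged with the image center and half the larger side as radius.
    """
    mask = img.pixels.sum(axis=2, dtype=np.int64) > threshold
    if not mask.any():
        h, w = img.height, img.width
        return CropResult(img, ((h - 1) / 2.0, (w - 1) / 2.0), max(h, w) / 2.0)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    rr, cc = np.nonzero(mask)
    center = (float(rr.mean()), float(cc.mean()))
    radius = max(r1 - r0, c1 - c0) / 2.0
    cropped = FundusImage(img.pixels[r0:r1, c0:c1], img.source_path)
    return CropResult(cropped, center, radius)


def enhance(img: FundusImage, params: EnhancementParams, radius: float | None = None) -> FundusImage:
    """Apply the blur-difference enhancement; output clipped to 8-bit."""
    sigma = params.sigma
    if sigma is None:
        base = radius if radius is not None else min(img.height, img.width)
        sigma = max(base * SIGMA_RADIUS_FRACTION, 0.5)
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    x = img.pixels.astype(np.float64)
    blurred = np.empty_like(x)
    for ch in range(3):
        blurred[:, :, ch] = gaussian_filter(x[:, :, ch], sigma=sigma, mode="reflect")
    out = params.lambda_ * blurred + params.omega * x + params.delta
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return FundusImage(out, img.source_path)


def preprocess_image(
    img: FundusImage,
    max_side: int = 1024,
    params: EnhancementParams | None = None,
    crop_threshold: float = DEFAULT_CROP_THRESHOLD,
) -> FundusImage:
    """Full pipeline: resize -> crop -> enhance."""
    params = params or EnhancementParams()
    resized = resize_long_side(img, max_side)
    crop = crop_to_disc(resized, crop_threshold)
    return enhance(crop.image, params, radius=crop.radius)


def load_image(path: str | Path) -> FundusImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return FundusImage(arr, str(path))


def save_image(img: FundusImage, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.pixels).save(path)


def preprocess_manifest(
    manifest_path: str | Path,
    out_dir: str | Path,
    max_side: int = 1024,
    params: EnhancementParams | None = None,
    crop_threshold: float = DEFAULT_CROP_THRESHOLD,
) -> Path:
    """Batch-preprocess every image in a manifest; writes PNGs and a new manifest."""
    from .data import read_image_manifest, write_image_manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = read_image_manifest(manifest_path)
    base = Path(manifest_path).parent
    rows = []
    for _, row in df.iterrows():
        src = Path(row["path"])
        if not src.is_absolute():
            src = base / src
        img = load_image(src)
        out = preprocess_image(img, max_side=max_side, params=params, crop_threshold=crop_threshold)
        dest = out_dir / (src.stem + ".png")
        save_image(out, dest)
        rows.append({"path": dest.name, "grade": row.get("grade", ""), "domain": row["domain"]})
    out_manifest = out_dir / "manifest.csv"
    write_image_manifest(rows, out_manifest)
    return out_manifest
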