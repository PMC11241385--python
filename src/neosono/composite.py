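"""Two-ROI composite construction for the CNN classifier.

The two cropped regions (parenchyma, plexus) are each standardised to
100 x 100 pixels, stacked along the row axis into a 200 x 100 raw
composite, and the composite is then resized to the network input
(100 x 100 x 3 by default). Parenchyma occupies the top half, plexus the
bottom; the order is fixed so trained models are comparable.

Resizing is bilinear with anti-aliasing off, which keeps the operation
bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .density import RegionSpec, UltrasoundImage, crop_region

__all__ = ["CompositeSample", "concat_pair", "resize_image", "make_sample"]

#: Side length of each standardised ROI patch before stacking.
PATCH_SIDE = 100
#: Default network input (height, width).
INPUT_SIZE = (100, 100)


@dataclass
class CompositeSample:
    """A standardised two-ROI composite with provenance.

    ``pixels`` is uint8 ``(H, W, 3)`` at the network input size.
    """

    pixels: np.ndarray
    label: str | None = None
    source: str | None = None
    roi_parenchyma: RegionSpec | None = None
    roi_plexus: RegionSpec | None = None


def concat_pair(
    patch_a: UltrasoundImage, patch_b: UltrasoundImage, axis: str = "rows"
) -> UltrasoundImage:
    """Stack two patches into one composite (no resampling).

    ``axis="rows"`` puts ``patch_a`` on top of ``patch_b``; ``"cols"``
    places them left/right. The non-concatenated dimension must agree.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    ax = 0 if axis == "rows" else 1
    other = 1 - ax
    if patch_a.pixels.shape[other] != patch_b.pixels.shape[other]:
        raise ValueError(
            f"patch shapes {patch_a.pixels.shape} and {patch_b.pixels.shape} "
            f"disagree on the non-concatenated dimension"
        )
    if patch_a.colorspace != patch_b.colorspace:
        raise ValueError("patches must share a colorspace")
    out = np.concatenate([patch_a.pixels, patch_b.pixels], axis=ax)
    return UltrasoundImage(out, colorspace=patch_a.colorspace)


def resize_image(img: UltrasoundImage, P: int, Q: int) -> UltrasoundImage:
    """Bilinear resize to ``P`` rows by ``Q`` columns (anti-aliasing off).

    Resizing to the input's own size returns the image unchanged.
    """
    if P < 1 or Q < 1:
        raise ValueError("target dimensions must be positive")
    px = img.pixels
    if px.shape[:2] == (P, Q):
        return UltrasoundImage(px.copy(), colorspace=img.colorspace,
                               source_path=img.source_path)
    out = _sk_resize(
        px.astype(np.float64),
        (P, Q, px.shape[2]),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    if img.colorspace == "rgb":
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return UltrasoundImage(out, colorspace=img.colorspace,
                           source_path=img.source_path)


def make_sample(
    img: UltrasoundImage,
    roi_parenchyma: RegionSpec,
    roi_plexus: RegionSpec,
    label: str | None = None,
    input_size: tuple[int, int] = INPUT_SIZE,
) -> CompositeSample:
    """Build the standardised composite fed to the classifier.

    Crops both ROIs, resizes each to 100 x 100, stacks parenchyma over
    plexus (200 x 100 raw composite), then resizes to ``input_size``.
    Deterministic: identical inputs give bit-identical pixels.
    """
    a = resize_image(crop_region(img, roi_parenchyma), PATCH_SIDE, PATCH_SIDE)
    b = resize_image(crop_region(img, roi_plexus), PATCH_SIDE, PATCH_SIDE)
    raw = concat_pair(a, b, axis="rows")
    std = resize_image(raw, input_size[0], input_size[1])
    return CompositeSample(
        pixels=std.pixels,
        label=label,
        source=img.source_path,
        roi_parenchyma=roi_parenchyma,
        roi_plexus=roi_plexus,
    )


def compose_patches(
    patch_parenchyma: UltrasoundImage,
    patch_plexus: UltrasoundImage,
    label: str | None = None,
    input_size: tuple[int, int] = INPUT_SIZE,
) -> CompositeSample:
    """Composite from two already-cropped patches (phantom pathway)."""
    a = resize_image(patch_parenchyma, PATCH_SIDE, PATCH_SIDE)
    b = resize_image(patch_plexus, PATCH_SIDE, PATCH_SIDE)
    raw = concat_pair(a, b, axis="rows")
    std = resize_image(raw, input_size[0], input_size[1])
    return CompositeSample(pixels=std.pixels, label=label)
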