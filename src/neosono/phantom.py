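"""Synthetic neurosonogram phantoms with class-controlled echogenicity gaps.

Clinical cranial ultrasound is not redistributable, so every stage of the
pipeline is exercised on speckle phantoms instead. Each sample is a pair
of achromatic textured patches: the "plexus" patch has a fixed high mean
lightness, and the "parenchyma" patch is offset darker so that the
lightness gap — and hence the delta-E score, since a* = b* = 0 on gray
patches — lands in the generating class's band:

* Normal:    delta-E target 50 (well above the 40 cut),
* Moderate:  delta-E target 25 (mid-band),
* Intensive: delta-E target 5  (below the 10 cut),

each jittered per sample (default sd 2 delta-E units, keeping the bands
more than two sd away from the cuts). Texture is multiplicative
gamma-distributed speckle (mean 1) smoothed with a Gaussian kernel — a
first-order mimic of ultrasound speckle granularity; no anatomy, probe
geometry or attenuation is modelled, because the grading method consumes
only the regional mean lightness.

Generation is fully reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .composite import compose_patches
from .datasets import LabeledDataset
from .density import (
    CLASS_NAMES,
    ThresholdSet,
    UltrasoundImage,
    channel_means,
    delta_e_cie76,
    rgb_to_lab,
)

__all__ = ["PhantomConfig", "generate_pair", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults emulate the three clinical grade bands."""

    patch_size: tuple[int, int] = (100, 100)
    plexus_lightness: float = 75.0
    delta_e_targets: tuple[tuple[str, float], ...] = (
        ("Normal", 50.0),
        ("Moderate", 25.0),
        ("Intensive", 5.0),
    )
    jitter_sd: float = 2.0
    speckle_shape: float = 60.0  # gamma shape; larger -> weaker speckle
    blur_sigma: float = 1.5
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)

    def target_for(self, cls: str) -> float:
        for name, t in self.delta_e_targets:
            if name == cls:
                return t
        raise ValueError(f"unknown class {cls!r}")

    def __post_init__(self) -> None:
        targets = dict(self.delta_e_targets)
        missing = set(CLASS_NAMES) - set(targets)
        if missing:
            raise ValueError(f"missing delta-E targets for {sorted(missing)}")
        t_i, t_n = self.thresholds.t_intensive, self.thresholds.t_normal
        margin = 2.0 * self.jitter_sd
        ordered = targets["Intensive"] < targets["Moderate"] < targets["Normal"]
        inside = (
            targets["Intensive"] + margin < t_i
            and t_i <= targets["Moderate"] - margin
            and targets["Moderate"] + margin <= t_n
            and t_n < targets["Normal"] - margin
        )
        if not (ordered and inside):
            raise ValueError(
                "class delta-E bands overlap the thresholds beyond tolerance: "
                f"targets {targets}, thresholds ({t_i}, {t_n}), "
                f"jitter sd {self.jitter_sd}"
            )
        if self.speckle_shape <= 0 or self.blur_sigma < 0:
            raise ValueError("speckle_shape must be > 0 and blur_sigma >= 0")


# CIE Lab lightness <-> linear luminance (D65, Yn = 1), and sRGB transfer.
_DELTA = 6.0 / 29.0


def _lightness_to_luminance(L: float) -> float:
    fy = (L + 16.0) / 116.0
    if fy > _DELTA:
        return fy**3
    return 3.0 * _DELTA**2 * (fy - 4.0 / 29.0)


def _srgb_encode(y: np.ndarray) -> np.ndarray:
    y = np.clip(y, 0.0, 1.0)
    return np.where(
        y <= 0.0031308, 12.92 * y, 1.055 * np.power(y, 1.0 / 2.4) - 0.055
    )


def _textured_patch(
    target_lightness: float, cfg: PhantomConfig, rng: np.random.Generator
) -> UltrasoundImage:
    """A gray speckle patch whose mean lightness tracks the target."""
    h, w = cfg.patch_size
    k = cfg.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
    if cfg.blur_sigma > 0:
        speckle = gaussian_filter(speckle, sigma=cfg.blur_sigma, mode="reflect")
    speckle /= speckle.mean()
    luminance = _lightness_to_luminance(target_lightness) * speckle
    gray = np.clip(np.rint(255.0 * _srgb_encode(luminance)), 0, 255).astype(np.uint8)
    return UltrasoundImage(gray[:, :, None], colorspace="rgb")


def realized_delta_e(
    parenchyma: UltrasoundImage, plexus: UltrasoundImage
) -> float:
    """Delta-E between two whole patches via the scoring pipeline."""
    s1 = channel_means(rgb_to_lab(parenchyma))
    s2 = channel_means(rgb_to_lab(plexus))
    return delta_e_cie76(s1, s2)


def generate_pair(
    cls: str, cfg: PhantomConfig = PhantomConfig(), seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> tuple[UltrasoundImage, UltrasoundImage, float, str]:
    """One (parenchyma, plexus) patch pair with the class's delta-E gap.

    Returns the two patches, the realized delta-E (recomputed from the
    generated pixels by the scoring pipeline), and the generating label.
    Bit-reproducible for a fixed seed.
    """
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown class {cls!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    target = cfg.target_for(cls) + rng.normal(0.0, cfg.jitter_sd)
    target = max(target, 0.5)
    plexus = _textured_patch(cfg.plexus_lightness, cfg, rng)
    parenchyma = _textured_patch(cfg.plexus_lightness - target, cfg, rng)
    return parenchyma, plexus, realized_delta_e(parenchyma, plexus), cls


def generate_dataset(
    n_per_class: int,
    cfg: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    input_size: tuple[int, int] = (100, 100),
) -> LabeledDataset:
    """A balanced labelled dataset of standardised composites.

    Composites are built by the same pathway as clinical samples (ROI
    patches -> 100 x 100 each -> stacked -> network input size). The
    manifest records, per sample, the generating label, the realized
    delta-E, and the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, rows = [], [], []
    for i in range(n_per_class):
        for cls in CLASS_NAMES:
            par, plex, de, _ = generate_pair(cls, cfg, rng=rng)
            sample = compose_patches(par, plex, label=cls, input_size=input_size)
            sid = f"{cls.lower()}_{i:04d}"
            images.append(sample.pixels)
            labels.append(cls)
            rows.append(
                {"sample_id": sid, "label": cls, "delta_e": de, "seed": seed}
            )
    import pandas as pd

    return LabeledDataset(
        X=np.stack(images),
        y=np.asarray(labels, dtype=object),
        manifest=pd.DataFrame(rows),
    )
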