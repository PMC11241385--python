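"""Echogenicity-difference scoring between two ultrasound regions of interest.

The score is the CIE76 colour difference (Euclidean distance in CIE L*a*b*)
between the channel means of two user-defined regions: the choroid plexus,
which serves as the internal brightness reference, and the periventricular
brain parenchyma. On grayscale ultrasound the chromatic channels vanish, so
the score effectively measures the lightness gap between the two tissues.

Fixed clinical thresholds partition the score into three grades:

* ``delta_e < 10``        -> ``Intensive`` (parenchyma nearly as echogenic
  as the plexus: marked white-matter hyperechogenicity),
* ``10 <= delta_e <= 40`` -> ``Moderate``,
* ``delta_e > 40``        -> ``Normal`` (clearly hypoechoic parenchyma).

Both boundary values belong to the Moderate grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2lab
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CLASS_NAMES",
    "UltrasoundImage",
    "RegionSpec",
    "LabSummary",
    "ThresholdSet",
    "DensityAssessment",
    "rgb_to_lab",
    "crop_region",
    "channel_means",
    "delta_e_cie76",
    "categorize",
    "assess_pair",
    "ThresholdDensityClassifier",
]

#: Canonical grade order used throughout the package (report row order).
CLASS_NAMES = ("Normal", "Moderate", "Intensive")


@dataclass
class UltrasoundImage:
    """A 2-D raster with its colour-space tag.

    ``pixels`` is ``(H, W, 3)``; RGB images are 8-bit unsigned, Lab images
    are float with L in [0, 100]. Single-channel input is promoted to three
    identical channels (ultrasound is achromatic, the replication preserves
    the Lab machinery unchanged).
    """

    pixels: np.ndarray
    colorspace: str = "rgb"
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(
                f"expected HxW, HxWx1 or HxWx3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.colorspace not in ("rgb", "lab"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")
        if self.colorspace == "rgb":
            if px.dtype != np.uint8:
                raise TypeError(
                    f"RGB input must be 8-bit per channel (uint8), got {px.dtype}"
                )
            if px.shape[2] == 1:
                px = np.repeat(px, 3, axis=2)
        else:
            px = np.asarray(px, dtype=np.float64)
            if px.shape[2] == 1:
                raise ValueError("Lab images must have three channels")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionSpec:
    """Half-open pixel region ``[row_start, row_end) x [col_start, col_end)``."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError(f"need 0 <= row_start < row_end, got {self}")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"need 0 <= col_start < col_end, got {self}")

    @classmethod
    def from_one_based_inclusive(
        cls, row1: int, row2: int, col1: int, col2: int
    ) -> "RegionSpec":
        """Translate 1-based inclusive (MATLAB-style) bounds to this convention."""
        return cls(row1 - 1, row2, col1 - 1, col2)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


@dataclass(frozen=True)
class LabSummary:
    """Channel means of a Lab region: (L_mean, a_mean, b_mean, n_pixels)."""

    L_mean: float
    a_mean: float
    b_mean: float
    n_pixels: int

    def as_triple(self) -> np.ndarray:
        return np.array([self.L_mean, self.a_mean, self.b_mean], dtype=float)


@dataclass(frozen=True)
class ThresholdSet:
    """Clinical delta-E cut points: Intensive below 10, Normal above 40."""

    t_intensive: float = 10.0
    t_normal: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.t_intensive < self.t_normal):
            raise ValueError(
                f"need 0 < t_intensive < t_normal, got "
                f"({self.t_intensive}, {self.t_normal})"
            )


@dataclass(frozen=True)
class DensityAssessment:
    delta_e: float
    category: str
    summaries: tuple[LabSummary, LabSummary]
    thresholds: ThresholdSet

    def to_record(self) -> dict:
        s1, s2 = self.summaries
        return {
            "delta_e": self.delta_e,
            "category": self.category,
            "parenchyma_L": s1.L_mean,
            "parenchyma_a": s1.a_mean,
            "parenchyma_b": s1.b_mean,
            "plexus_L": s2.L_mean,
            "plexus_a": s2.a_mean,
            "plexus_b": s2.b_mean,
            "t_intensive": self.thresholds.t_intensive,
            "t_normal": self.thresholds.t_normal,
        }


def rgb_to_lab(img: UltrasoundImage) -> UltrasoundImage:
    """Convert an 8-bit RGB image to CIE L*a*b* (sRGB primaries, D65 white).

    L lands in [0, 100]; for achromatic input a* and b* are ~0.
    """
    if img.colorspace != "rgb":
        raise ValueError("rgb_to_lab expects an RGB image")
    lab = rgb2lab(img.pixels)
    return UltrasoundImage(lab, colorspace="lab", source_path=img.source_path)


def crop_region(img: UltrasoundImage, region: RegionSpec) -> UltrasoundImage:
    """Extract a rectangular region; pixel values are copied unchanged."""
    if region.row_end > img.height or region.col_end > img.width:
        raise ValueError(
            f"region {region} exceeds image bounds {img.height}x{img.width}"
        )
    sub = img.pixels[
        region.row_start : region.row_end, region.col_start : region.col_end
    ].copy()
    return UltrasoundImage(sub, colorspace=img.colorspace, source_path=img.source_path)


def channel_means(lab_img: UltrasoundImage) -> LabSummary:
    """Per-channel arithmetic means of a Lab region."""
    if lab_img.colorspace != "lab":
        raise ValueError("channel_means expects a Lab image")
    px = lab_img.pixels
    n = px.shape[0] * px.shape[1]
    if n < 1:
        raise ValueError("empty raster")
    m = px.reshape(n, 3).mean(axis=0)
    return LabSummary(float(m[0]), float(m[1]), float(m[2]), n)


def delta_e_cie76(s1: LabSummary, s2: LabSummary) -> float:
    """CIE76 colour difference: Euclidean distance between two Lab triples."""
    t1, t2 = s1.as_triple(), s2.as_triple()
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ValueError("non-finite Lab summary")
    return float(np.sqrt(np.sum((t1 - t2) ** 2)))


def categorize(delta_e: float, thresholds: ThresholdSet = ThresholdSet()) -> str:
    """Map a delta-E score to its grade; both cut points fall in Moderate."""
    if delta_e < 0:
        raise ValueError("delta_e must be nonnegative")
    if delta_e < thresholds.t_intensive:
        return "Intensive"
    if delta_e <= thresholds.t_normal:
        return "Moderate"
    return "Normal"


def assess_pair(
    img: UltrasoundImage,
    roi_parenchyma: RegionSpec,
    roi_plexus: RegionSpec,
    thresholds: ThresholdSet = ThresholdSet(),
) -> DensityAssessment:
    """Full scoring pipeline on one image: convert, crop, summarize, score.

    Composes ``rgb_to_lab`` -> ``crop_region`` (both ROIs) ->
    ``channel_means`` -> ``delta_e_cie76`` -> ``categorize`` and records the
    intermediate summaries.
    """
    lab = rgb_to_lab(img) if img.colorspace == "rgb" else img
    s_par = channel_means(crop_region(lab, roi_parenchyma))
    s_plex = channel_means(crop_region(lab, roi_plexus))
    de = delta_e_cie76(s_par, s_plex)
    return DensityAssessment(
        delta_e=de,
        category=categorize(de, thresholds),
        summaries=(s_par, s_plex),
        thresholds=thresholds,
    )


class ThresholdDensityClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based grader mapping delta-E scores to Normal/Moderate/Intensive.

    A scikit-learn-compatible classifier over one feature (the delta-E
    score). ``fit`` only validates the thresholds and records the class
    labels; prediction applies the fixed clinical rule, so the estimator
    composes with sklearn model selection and metrics without learning
    anything from the data.

    Parameters
    ----------
    t_intensive : float, default=10.0
        Scores strictly below this bound are graded Intensive.
    t_normal : float, default=40.0
        Scores strictly above this bound are graded Normal; the closed
        interval between the bounds is Moderate.
    """

    def __init__(self, t_intensive: float = 10.0, t_normal: float = 40.0):
        self.t_intensive = t_intensive
        self.t_normal = t_normal

    def fit(self, X, y=None):
        self.thresholds_ = ThresholdSet(self.t_intensive, self.t_normal)
        self.classes_ = np.asarray(CLASS_NAMES, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        de = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(
            [categorize(v, self.thresholds_) for v in de], dtype=object
        )


def batch_assess(
    images: Sequence[UltrasoundImage],
    roi_parenchyma: RegionSpec,
    roi_plexus: RegionSpec,
    thresholds: ThresholdSet = ThresholdSet(),
) -> list[DensityAssessment]:
    """Score a sequence of images with shared ROI coordinates."""
    return [assess_pair(im, roi_parenchyma, roi_plexus, thresholds) for im in images]
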