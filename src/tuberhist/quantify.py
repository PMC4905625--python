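"""Semi-automated IHC quantification on slide images.

Implements the measurement battery used to characterise cortical tuber
tissue: tissue segmentation by background luminance, DAB-positive pixel
masking in the blue channel, positive-area fractions, size-gated connected
component counting (cell densities per mm^2), optical density of the
positive area, the composite overall myelin content (OMC = area% x mean OD)
and field-based giant-cell densities.

All pixel intensities are 8-bit (0-255); slide resolution defaults to
0.64 um/pixel throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage import measure, morphology

from .errors import (
    InvalidInputError,
    MissingChannelError,
    UndefinedValueWarning,
)

#: Default scan resolution in micrometres per pixel.
DEFAULT_RESOLUTION_UM_PER_PX = 0.64

#: Luminance at or above which a pixel is considered slide background.
BACKGROUND_CUTOFF = 240

#: Tissue components smaller than this many pixels are discarded as debris.
MIN_TISSUE_COMPONENT_PX = 64

#: Reference intensity for optical density; +1 offset avoids log(0).
OD_REFERENCE = 256.0


def _as_rgb(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3 or img.size == 0:
        raise InvalidInputError(
            f"expected a non-empty HxWx3 image, got shape {getattr(img, 'shape', None)}"
        )
    return img[..., :3]


def _luminance(image: np.ndarray) -> np.ndarray:
    """Per-pixel luminance as the float mean of the three channels."""
    return _as_rgb(image).astype(np.float64).mean(axis=-1)


def pixel_area_mm2(resolution_um_per_px: float) -> float:
    """Area of one pixel in mm^2 at the given scan resolution."""
    return resolution_um_per_px**2 * 1e-6


@dataclass(frozen=True)
class MarkerConfig:
    """Detection parameters for one IHC marker.

    ``mode`` selects the measurement: ``count`` (size-gated object density),
    ``area`` (positive-area percentage) or ``od`` (area percentage plus
    optical density, used for myelin).
    """

    name: str
    blue_threshold: int
    min_area_px: int = 1
    max_area_px: Optional[int] = None  # None = unbounded
    mode: str = "count"

    def __post_init__(self):
        if not 0 <= self.blue_threshold <= 255:
            raise InvalidInputError(
                f"{self.name}: blue_threshold {self.blue_threshold} outside 0-255"
            )
        if self.min_area_px < 1:
            raise InvalidInputError(f"{self.name}: min_area_px must be >= 1")
        if self.max_area_px is not None and self.max_area_px < self.min_area_px:
            raise InvalidInputError(
                f"{self.name}: max_area_px {self.max_area_px} < min_area_px "
                f"{self.min_area_px}"
            )
        if self.mode not in ("count", "area", "od"):
            raise InvalidInputError(f"{self.name}: unknown mode {self.mode!r}")


def default_panel(autopsy: bool = False) -> list[MarkerConfig]:
    """The standard marker panel with its published detection parameters.

    Counted markers use the per-stain blue-channel brightness thresholds
    (NeuN 120; CD3, SMI32, Olig2 100; CD34 150) and pixel-area gates
    (NeuN 120-2500, CD3 20-155, Olig2 20-155 surgical / 5-120 autopsy,
    CD34 100-unlimited, SMI32 750-5000). Giant cells (vimentin) share the
    large-cell gate of SMI32. Area/OD markers carry a permissive threshold;
    brown-vs-blue discrimination does the heavy lifting for them.
    """
    olig2_gate = (5, 120) if autopsy else (20, 155)
    return [
        MarkerConfig("NeuN", 120, 120, 2500, "count"),
        MarkerConfig("CD3", 100, 20, 155, "count"),
        MarkerConfig("Olig2", 100, olig2_gate[0], olig2_gate[1], "count"),
        MarkerConfig("CD34", 150, 100, None, "count"),
        MarkerConfig("SMI32", 100, 750, 5000, "count"),
        MarkerConfig("vimentin", 100, 750, 5000, "count"),
        MarkerConfig("pS6", 220, mode="area"),
        MarkerConfig("GFAP", 220, mode="area"),
        MarkerConfig("Cr3/43", 220, mode="area"),
        MarkerConfig("MBP", 220, mode="od"),
    ]


#: Maps marker names to QuantResult field names for count/area modes.
MARKER_FIELDS = {
    "NeuN": "neun_density",
    "CD3": "cd3_density",
    "Olig2": "olig2_density",
    "CD34": "cd34_density",
    "SMI32": "smi32_density",
    "vimentin": "vimentin_density",
    "pS6": "ps6_pct",
    "GFAP": "gfap_pct",
    "Cr3/43": "cr343_pct",
    "MBP": "mbp_pct",
}


@dataclass
class TissueMask:
    """Binary tissue mask with its physical area."""

    mask: np.ndarray
    tissue_area_mm2: float
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX


@dataclass
class FieldCountConfig:
    """Manual counting protocol: ``n_fields`` fields of ``field_area_mm2``."""

    n_fields: int = 10
    field_area_mm2: float = 1.081

    def __post_init__(self):
        if self.n_fields < 1 or self.field_area_mm2 <= 0:
            raise InvalidInputError("n_fields >= 1 and field_area_mm2 > 0 required")


@dataclass
class QuantResult:
    """Full measurement vector for one sample.

    ``omc`` is derived, always exactly ``mbp_pct * mbp_mean_od``.
    """

    ps6_pct: float = 0.0
    gfap_pct: float = 0.0
    cr343_pct: float = 0.0
    mbp_pct: float = 0.0
    mbp_mean_od: float = 0.0
    mbp_integrated_od: float = 0.0
    neun_density: float = 0.0
    cd3_density: float = 0.0
    olig2_density: float = 0.0
    cd34_density: float = 0.0
    smi32_density: float = 0.0
    vimentin_density: float = 0.0
    calcification_present: bool = False
    omc: float = field(init=False, default=0.0)

    def __post_init__(self):
        for name in ("ps6_pct", "gfap_pct", "cr343_pct", "mbp_pct"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise InvalidInputError(f"{name}={v} outside [0, 100]")
        for name in (
            "neun_density",
            "cd3_density",
            "olig2_density",
            "cd34_density",
            "smi32_density",
            "vimentin_density",
            "mbp_mean_od",
            "mbp_integrated_od",
        ):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise InvalidInputError(f"{name}={v} must be non-negative")
        self.omc = self.mbp_pct * self.mbp_mean_od

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def segment_tissue(
    image,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    background_cutoff: float = BACKGROUND_CUTOFF,
    min_component_px: int = MIN_TISSUE_COMPONENT_PX,
) -> TissueMask:
    """Segment tissue from slide background by luminance.

    A pixel belongs to tissue when its luminance (channel mean) is below
    ``background_cutoff``; the raw mask is morphologically closed and
    components below ``min_component_px`` are dropped as debris. The
    physical area is ``|mask| * resolution^2 * 1e-6`` mm^2.
    """
    if resolution_um_per_px <= 0:
        raise InvalidInputError("resolution must be positive")
    lum = _luminance(image)
    mask = lum < background_cutoff
    mask = morphology.closing(mask, footprint=np.ones((3, 3), bool))
    mask = morphology.remove_small_objects(mask, max_size=min_component_px - 1)
    area = float(mask.sum()) * pixel_area_mm2(resolution_um_per_px)
    if not mask.any():
        warnings.warn("no tissue detected in image", UndefinedValueWarning)
    return TissueMask(mask=mask, tissue_area_mm2=area,
                      resolution_um_per_px=resolution_um_per_px)


def positive_pixel_mask(image, blue_threshold: int, tissue: TissueMask) -> np.ndarray:
    """DAB-positive pixels: dark in blue, browner than blue, inside tissue.

    DAB chromogen absorbs strongly in the blue channel, so positivity is
    blue <= threshold; requiring red > blue rejects the hematoxylin
    counterstain, whose pixels are blue-dominant. Monotone in the
    threshold: raising it never removes a positive pixel.
    """
    if not 0 <= blue_threshold <= 255:
        raise InvalidInputError(f"blue_threshold {blue_threshold} outside 0-255")
    img = _as_rgb(image)
    red = img[..., 0].astype(np.int16)
    blue = img[..., 2].astype(np.int16)
    return tissue.mask & (blue <= blue_threshold) & (red > blue)


def area_fraction(positive: np.ndarray, tissue: TissueMask) -> float:
    """Positive area as a percentage of tissue area.

    Returns NaN with an :class:`UndefinedValueWarning` when there is no
    tissue (the fraction is undefined, not zero).
    """
    n_tissue = int(tissue.mask.sum())
    if n_tissue == 0:
        warnings.warn("area fraction undefined: zero tissue area",
                      UndefinedValueWarning)
        return float("nan")
    if np.any(positive & ~tissue.mask):
        raise InvalidInputError("positive mask extends outside tissue")
    return 100.0 * float(np.count_nonzero(positive)) / n_tissue


def count_objects(
    image,
    cfg: MarkerConfig,
    tissue: TissueMask,
    resolution_um_per_px: Optional[float] = None,
) -> tuple[int, float]:
    """Size-gated connected-component count and density per mm^2.

    Components of the positive-pixel mask are labelled with 8-connectivity;
    only components whose pixel area lies within the marker's gate are
    counted. Density is count / tissue area.
    """
    if cfg.mode != "count":
        raise InvalidInputError(f"marker {cfg.name} is not a counted marker")
    if resolution_um_per_px is None:
        resolution_um_per_px = tissue.resolution_um_per_px
    mask = positive_pixel_mask(image, cfg.blue_threshold, tissue)
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    hi = np.inf if cfg.max_area_px is None else cfg.max_area_px
    count = int(np.count_nonzero((areas >= cfg.min_area_px) & (areas <= hi)))
    if tissue.tissue_area_mm2 == 0:
        warnings.warn("density undefined: zero tissue area", UndefinedValueWarning)
        return count, float("nan")
    return count, count / tissue.tissue_area_mm2


def optical_density(image, positive: np.ndarray) -> tuple[float, float]:
    """Mean and integrated optical density over the positive pixels.

    Per-pixel OD is ``-log10((L + 1) / 256)`` with ``L`` the luminance.
    For an empty mask the mean is undefined (NaN + warning) and the
    integrated OD is 0.
    """
    lum = _luminance(image)
    od = -np.log10((lum + 1.0) / OD_REFERENCE)
    vals = od[np.asarray(positive, bool)]
    if vals.size == 0:
        warnings.warn("mean OD undefined: empty positive mask",
                      UndefinedValueWarning)
        return float("nan"), 0.0
    return float(vals.mean()), float(vals.sum())


def overall_myelin_content(area_pct: float, mean_od: float) -> float:
    """OMC: the product of stain frequency (area %) and intensity (mean OD)."""
    if area_pct < 0 or area_pct > 100 or mean_od < 0:
        raise InvalidInputError(
            f"area_pct must be in [0,100] and mean_od >= 0, got "
            f"({area_pct}, {mean_od})"
        )
    return area_pct * mean_od


def field_density(field_counts: Sequence[int], cfg: FieldCountConfig = None) -> float:
    """Cell density per mm^2 from manual counts over representative fields."""
    cfg = cfg or FieldCountConfig()
    if len(field_counts) != cfg.n_fields:
        raise InvalidInputError(
            f"expected {cfg.n_fields} field counts, got {len(field_counts)}"
        )
    return float(sum(field_counts)) / (cfg.n_fields * cfg.field_area_mm2)


def quantify_sample(
    images: Mapping[str, np.ndarray],
    panel: Sequence[MarkerConfig],
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    calcification_flag: bool = False,
) -> QuantResult:
    """Quantify one sample across its marker panel.

    Each marker is measured on its own stained image with the panel's
    parameters (kept identical across samples in a batch). Calcification is
    an eye-scored input (from H&E review), not an image measurement.
    """
    values: dict = {}
    for cfg in panel:
        if cfg.name not in images:
            raise MissingChannelError(cfg.name)
        field_name = MARKER_FIELDS.get(cfg.name)
        if field_name is None:
            raise InvalidInputError(f"unknown marker {cfg.name!r}")
        image = images[cfg.name]
        tissue = segment_tissue(image, resolution_um_per_px)
        if cfg.mode == "count":
            _, density = count_objects(image, cfg, tissue)
            values[field_name] = density
        else:
            pos = positive_pixel_mask(image, cfg.blue_threshold, tissue)
            pct = area_fraction(pos, tissue)
            values[field_name] = pct
            if cfg.mode == "od":
                if np.count_nonzero(pos) == 0:
                    mean_od, int_od = 0.0, 0.0
                else:
                    mean_od, int_od = optical_density(image, pos)
                values["mbp_mean_od"] = mean_od
                values["mbp_integrated_od"] = int_od
    return QuantResult(calcification_present=bool(calcification_flag), **values)
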