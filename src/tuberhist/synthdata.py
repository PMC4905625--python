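"""Synthetic slide phantoms and cohort feature tables with known truth.

Two generators make the whole pipeline testable without any slide archive:

* :func:`render_slide_phantom` draws a color slide phantom emulating DAB
  immunohistochemistry — brown chromogen objects and/or diffuse positive
  stain, blue hematoxylin nuclei and dense basophilic calcifications on a
  pale background — and records exact ground truth (tissue mask, per-marker
  positive masks, object counts, area fractions, mean optical densities).

* :func:`sample_cohort` draws per-sample marker feature tables for the five
  study groups (tuber types A/B/C, perituberal cortex, autopsy control)
  from median/range parameterizations, with the group-defining constraints
  enforced sample-by-sample.

Both are deterministic given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecError, PlacementInfeasibleError
from .quantify import DEFAULT_RESOLUTION_UM_PER_PX, QuantResult, _luminance

# ---------------------------------------------------------------------------
# slide phantoms
# ---------------------------------------------------------------------------

#: Pale, slightly basophilic tissue base color (blue >= red, luminance < 240).
TISSUE_BASE = (218, 221, 229)

#: Hematoxylin nucleus color: blue-dominant, never DAB-positive.
NUCLEUS_COLOR = (95, 85, 150)

#: Calcification color: dense basophilic blue-purple.
CALCIFICATION_COLOR = (70, 60, 130)

#: Red/green offsets above the blue value used to paint brown DAB pixels.
DAB_RED_OFFSET = 90
DAB_GREEN_OFFSET = 40


@dataclass(frozen=True)
class ObjectSpec:
    """One marker's discrete positive objects to place in a phantom."""

    marker: str
    n_objects: int
    area_px_range: Tuple[int, int]
    chromogen_darkness: int = 60  # blue-channel value of DAB pixels


@dataclass
class PhantomSpec:
    width_px: int = 256
    height_px: int = 256
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    tissue_fraction: float = 0.9
    objects: Sequence[ObjectSpec] = field(default_factory=tuple)
    diffuse_marker: str = "MBP"
    diffuse_positive_fraction: float = 0.0
    diffuse_mean_od: float = 0.0
    n_calcifications: int = 0
    background_level: int = 250
    nucleus_density_per_mm2: float = 150.0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidSpecError("phantom dimensions must be positive")
        if self.resolution_um_per_px <= 0:
            raise InvalidSpecError("resolution must be positive")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise InvalidSpecError("tissue_fraction must be in (0, 1]")
        if not 0.0 <= self.diffuse_positive_fraction <= 1.0:
            raise InvalidSpecError("diffuse_positive_fraction must be in [0, 1]")
        if self.diffuse_mean_od < 0:
            raise InvalidSpecError("diffuse_mean_od must be non-negative")
        if self.n_calcifications < 0:
            raise InvalidSpecError("n_calcifications must be >= 0")
        if not 0 <= self.background_level <= 255:
            raise InvalidSpecError("background_level outside 0-255")
        for o in self.objects:
            lo, hi = o.area_px_range
            if lo < 1 or hi < lo:
                raise InvalidSpecError(
                    f"{o.marker}: object areas must satisfy 1 <= lo <= hi"
                )
            if o.n_objects < 0:
                raise InvalidSpecError(f"{o.marker}: n_objects must be >= 0")
            if not 0 <= o.chromogen_darkness <= 255:
                raise InvalidSpecError(f"{o.marker}: darkness outside 0-255")


@dataclass
class SlidePhantom:
    """Rendered phantom plus exact ground truth."""

    image: np.ndarray  # H x W x 3, uint8
    truth_tissue_mask: np.ndarray  # H x W bool
    truth_positive_mask: Dict[str, np.ndarray]
    truth_object_count: Dict[str, int]
    truth_area_fraction: Dict[str, float]  # percent of tissue
    truth_mean_od: Dict[str, float]
    truth_calcification_count: int
    resolution_um_per_px: float


def _grow_blob(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target_area: int,
    max_tries: int = 50,
) -> Optional[np.ndarray]:
    """Grow a random 4-connected blob of exactly ``target_area`` pixels
    inside ``allowed``. Returns an (area, 2) coordinate array or None."""
    H, W = allowed.shape
    coords = np.argwhere(allowed)
    if coords.shape[0] < target_area:
        return None
    for _ in range(max_tries):
        start = coords[rng.integers(coords.shape[0])]
        chosen = {(int(start[0]), int(start[1]))}
        frontier = [tuple(start)]
        while frontier and len(chosen) < target_area:
            i = rng.integers(len(frontier))
            r, c = frontier[i]
            neighbors = [
                (r + dr, c + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < H and 0 <= c + dc < W
                and allowed[r + dr, c + dc]
                and (r + dr, c + dc) not in chosen
            ]
            if not neighbors:
                frontier[i] = frontier[-1]
                frontier.pop()
                continue
            nxt = neighbors[rng.integers(len(neighbors))]
            chosen.add(nxt)
            frontier.append(nxt)
        if len(chosen) == target_area:
            return np.array(sorted(chosen), dtype=int)
    return None


def _dilate3x3(mask: np.ndarray) -> np.ndarray:
    """8-neighborhood dilation; keeps placed blobs 8-disconnected."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    out[:-1, 1:] |= mask[1:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    return out


def render_slide_phantom(spec: PhantomSpec, seed: int) -> SlidePhantom:
    """Render a phantom; identical (spec, seed) gives bitwise-identical output.

    Discrete objects are placed by rejection sampling with a one-pixel
    guard band so no two blobs touch (even diagonally) — connected-component
    counting on the truth masks is therefore an exact oracle. Raises
    :class:`PlacementInfeasibleError` if the requested positive area cannot
    fit in the tissue.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    H, W = spec.height_px, spec.width_px

    # tissue: centered rectangle covering ~tissue_fraction of the image
    th = min(H, max(1, round(H * np.sqrt(spec.tissue_fraction))))
    tw = min(W, max(1, round(W * np.sqrt(spec.tissue_fraction))))
    r0, c0 = (H - th) // 2, (W - tw) // 2
    tissue = np.zeros((H, W), dtype=bool)
    tissue[r0 : r0 + th, c0 : c0 + tw] = True
    n_tissue = int(tissue.sum())

    # lower bound on requested pixels: certainly infeasible if it exceeds tissue
    requested = sum(
        o.n_objects * o.area_px_range[0] for o in spec.objects
    ) + spec.n_calcifications * 60
    if requested > n_tissue:
        raise PlacementInfeasibleError(
            f"requested up to {requested} object pixels but tissue has {n_tissue}"
        )

    placed = np.zeros((H, W), dtype=bool)  # all discrete blobs incl. calc
    marker_masks: Dict[str, np.ndarray] = {}
    marker_counts: Dict[str, int] = {}
    marker_darkness: Dict[str, int] = {}
    blob_pixels: list[tuple[np.ndarray, tuple[int, int, int]]] = []

    def place(area: int, color: tuple[int, int, int]) -> np.ndarray:
        allowed = tissue & ~_dilate3x3(placed)
        blob = _grow_blob(rng, allowed, area)
        if blob is None:
            raise PlacementInfeasibleError(
                f"could not place a {area}-px object in remaining tissue"
            )
        placed[blob[:, 0], blob[:, 1]] = True
        blob_pixels.append((blob, color))
        return blob

    for o in spec.objects:
        mask = marker_masks.setdefault(o.marker, np.zeros((H, W), dtype=bool))
        marker_darkness[o.marker] = o.chromogen_darkness
        lo, hi = o.area_px_range
        for _ in range(o.n_objects):
            area = int(rng.integers(lo, hi + 1))
            b = o.chromogen_darkness
            color = (
                min(255, b + DAB_RED_OFFSET),
                min(255, b + DAB_GREEN_OFFSET),
                b,
            )
            blob = place(area, color)
            mask[blob[:, 0], blob[:, 1]] = True
        marker_counts[o.marker] = marker_counts.get(o.marker, 0) + o.n_objects

    calc_count = 0
    for _ in range(spec.n_calcifications):
        area = int(rng.integers(60, 401))
        place(area, CALCIFICATION_COLOR)
        calc_count += 1

    # diffuse positive stain (e.g. myelin): random tissue pixels at the
    # luminance matching the requested mean OD
    diffuse_mask = np.zeros((H, W), dtype=bool)
    if spec.diffuse_positive_fraction > 0:
        target = int(round(spec.diffuse_positive_fraction * n_tissue))
        free = np.argwhere(tissue & ~placed)
        if free.shape[0] < target:
            raise PlacementInfeasibleError(
                "diffuse positive fraction exceeds unoccupied tissue"
            )
        sel = rng.choice(free.shape[0], size=target, replace=False)
        pix = free[sel]
        diffuse_mask[pix[:, 0], pix[:, 1]] = True
        m = marker_masks.setdefault(spec.diffuse_marker,
                                    np.zeros((H, W), dtype=bool))
        m |= diffuse_mask
        marker_counts.setdefault(spec.diffuse_marker, 0)

    # ---- painting ---------------------------------------------------------
    img = np.full((H, W, 3), spec.background_level, dtype=np.int16)
    noise = rng.integers(-4, 5, size=(H, W), dtype=np.int16)
    for ch, base in enumerate(TISSUE_BASE):
        chan = img[..., ch]
        chan[tissue] = base + noise[tissue]

    # hematoxylin nuclei (painted before stains; later layers overwrite)
    px_mm2 = (spec.resolution_um_per_px**2) * 1e-6
    n_nuclei = int(round(spec.nucleus_density_per_mm2 * n_tissue * px_mm2))
    if n_nuclei > 0:
        tissue_coords = np.argwhere(tissue)
        centers = tissue_coords[rng.integers(tissue_coords.shape[0],
                                             size=n_nuclei)]
        for r, c in centers:
            rr = slice(max(0, r - 1), min(H, r + 2))
            cc = slice(max(0, c - 1), min(W, c + 2))
            blk = tissue[rr, cc]
            for ch, v in enumerate(NUCLEUS_COLOR):
                img[rr, cc, ch][blk] = v + noise[rr, cc][blk]

    if diffuse_mask.any():
        lum = int(np.clip(round(256.0 * 10 ** (-spec.diffuse_mean_od) - 1.0),
                          26, 229))
        dn = noise[diffuse_mask]
        img[..., 0][diffuse_mask] = lum + 25 + dn
        img[..., 1][diffuse_mask] = lum + dn
        img[..., 2][diffuse_mask] = lum - 25 + dn

    for blob, color in blob_pixels:
        bn = noise[blob[:, 0], blob[:, 1]]
        for ch, v in enumerate(color):
            img[blob[:, 0], blob[:, 1], ch] = np.clip(v + bn, 0, 255)

    image = np.clip(img, 0, 255).astype(np.uint8)

    # ---- exact truth ------------------------------------------------------
    fractions, mean_ods = {}, {}
    lum_img = _luminance(image)
    od_img = -np.log10((lum_img + 1.0) / 256.0)
    for marker, mask in marker_masks.items():
        fractions[marker] = 100.0 * float(mask.sum()) / n_tissue
        mean_ods[marker] = float(od_img[mask].mean()) if mask.any() else 0.0

    return SlidePhantom(
        image=image,
        truth_tissue_mask=tissue,
        truth_positive_mask=marker_masks,
        truth_object_count=marker_counts,
        truth_area_fraction=fractions,
        truth_mean_od=mean_ods,
        truth_calcification_count=calc_count,
        resolution_um_per_px=spec.resolution_um_per_px,
    )


def write_phantom(phantom: SlidePhantom, path) -> Path:
    """Write a phantom image (PNG or TIFF by extension) plus a JSON sidecar
    of its scalar ground truth."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, phantom.image)
    else:
        from PIL import Image

        Image.fromarray(phantom.image).save(path)
    sidecar = {
        "resolution_um_per_px": phantom.resolution_um_per_px,
        "tissue_px": int(phantom.truth_tissue_mask.sum()),
        "object_count": phantom.truth_object_count,
        "area_fraction_pct": phantom.truth_area_fraction,
        "mean_od": phantom.truth_mean_od,
        "calcification_count": phantom.truth_calcification_count,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return path


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

GROUPS = ("A", "B", "C", "perituberal", "control")

#: (median, low, high) per feature per group. Marker rows follow the study's
#: published per-group medians and ranges; SMI32/vimentin rows (not tabulated
#: there) are set a priori to respect the classifier cutoffs (type A at or
#: below 10 and 3 per mm^2, type B above) with the clear between-pattern
#: separation that near-perfect inter-rater agreement implies.
DEFAULT_FEATURE_PARAMS: Dict[str, Dict[str, Tuple[float, float, float]]] = {
    "ps6_pct": {
        "A": (1.73, 0.84, 4.09), "B": (1.53, 0.63, 6.64),
        "C": (4.14, 0.88, 6.82), "perituberal": (0.70, 0.44, 3.64),
        "control": (0.18, 0.03, 0.67),
    },
    "neun_density": {
        "A": (261.20, 106.56, 296.26), "B": (139.18, 32.03, 258.29),
        "C": (175.88, 55.70, 277.31), "perituberal": (256.63, 126.69, 459.07),
        "control": (351.39, 275.69, 540.46),
    },
    "gfap_pct": {
        "A": (16.87, 1.01, 44.41), "B": (18.34, 8.16, 34.06),
        "C": (13.87, 7.09, 34.02), "perituberal": (5.89, 2.15, 12.78),
        "control": (5.61, 2.25, 9.34),
    },
    "cd3_density": {
        "A": (7.70, 4.23, 19.32), "B": (13.81, 7.38, 35.85),
        "C": (22.64, 7.29, 34.20), "perituberal": (9.08, 1.91, 13.55),
        "control": (5.54, 0.56, 29.76),
    },
    "cr343_pct": {
        "A": (3.10, 0.21, 7.63), "B": (2.16, 0.25, 33.24),
        "C": (5.14, 0.26, 11.66), "perituberal": (0.95, 0.11, 2.50),
        "control": (0.51, 0.07, 1.70),
    },
    "cd34_density": {
        "A": (73.85, 36.65, 169.35), "B": (73.90, 40.06, 190.45),
        "C": (114.48, 77.57, 154.12), "perituberal": (66.93, 28.49, 114.06),
        "control": (130.41, 36.77, 239.79),
    },
    "omc": {
        "A": (389.95, 161.97, 3185.74), "B": (196.23, 0.24, 8110.52),
        "C": (273.46, 0.01, 3168.69), "perituberal": (2711.58, 909.27, 6869.83),
        "control": (2801.68, 188.05, 5815.44),
    },
    "olig2_density": {
        "A": (159.22, 9.51, 405.16), "B": (103.03, 20.51, 390.42),
        "C": (133.31, 66.73, 832.46), "perituberal": (184.98, 109.86, 334.99),
        "control": (208.17, 88.01, 522.37),
    },
    "smi32_density": {
        "A": (0.8, 0.1, 2.5), "B": (6.0, 3.3, 15.0), "C": (18.0, 6.0, 45.0),
        "perituberal": (0.0, 0.0, 0.0), "control": (0.0, 0.0, 0.0),
    },
    "vimentin_density": {
        "A": (3.0, 0.5, 9.0), "B": (18.0, 11.0, 40.0), "C": (60.0, 25.0, 140.0),
        "perituberal": (0.0, 0.0, 0.0), "control": (0.0, 0.0, 0.0),
    },
}

#: Left-skewed features generated on the log scale.
DEFAULT_SKEWED_FEATURES = frozenset(
    {"ps6_pct", "smi32_density", "vimentin_density"}
)

#: Calcification is definitional for type C and absent elsewhere.
DEFAULT_CALCIFICATION_PROB = {
    "A": 0.0, "B": 0.0, "C": 1.0, "perituberal": 0.0, "control": 0.0,
}

#: Age at surgery in years: (median, low, high) per group.
DEFAULT_AGE_PARAMS = {
    "A": (10.0, 3.0, 47.0), "B": (7.0, 0.83, 22.0), "C": (3.0, 1.0, 6.0),
    "perituberal": (7.0, 1.0, 22.0), "control": (10.0, 1.0, 47.0),
}

DEFAULT_FCD_LIKE_PROB = {
    "A": 0.2, "B": 0.6, "C": 0.7, "perituberal": 0.0, "control": 0.0,
}


@dataclass
class CohortSpec:
    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {
            "A": 7, "B": 13, "C": 8, "perituberal": 7, "control": 10
        }
    )
    feature_params: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {
            f: dict(g) for f, g in DEFAULT_FEATURE_PARAMS.items()
        }
    )
    skewed_features: frozenset = DEFAULT_SKEWED_FEATURES
    calcification_prob: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALCIFICATION_PROB)
    )
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise InvalidSpecError(f"unknown group {g!r}")
            if n < 0:
                raise InvalidSpecError(f"n_per_group[{g!r}] must be >= 0")
        for feat, groups in self.feature_params.items():
            for g, (med, lo, hi) in groups.items():
                if not lo <= med <= hi:
                    raise InvalidSpecError(
                        f"{feat}/{g}: require low <= median <= high, "
                        f"got ({med}, {lo}, {hi})"
                    )
        for g, p in self.calcification_prob.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError(f"calcification_prob[{g!r}] outside [0,1]")


@dataclass
class SampleRecord:
    sample_id: str
    true_group: str
    features: QuantResult
    age_at_surgery_y: float
    epilepsy_duration_y: float
    aed_count: int
    fcd_like: bool
    engel: int


def _sigma_from_range(lo: float, hi: float) -> float:
    """Log-scale sigma so the central 95% of mass spans roughly [lo, hi]."""
    if lo <= 0:
        lo = hi / 1e3 if hi > 0 else 1.0
    return float(np.log(hi / lo) / (2 * 1.959963984540054)) if hi > lo else 0.0


def _draw_feature(
    rng: np.random.Generator,
    params: Tuple[float, float, float],
    skewed: bool,
) -> float:
    """One draw: log-normal with the configured median if skewed, else a
    symmetric normal clipped to [low, high]."""
    med, lo, hi = params
    if med == 0.0 and hi == 0.0:
        return 0.0
    if skewed:
        sigma = _sigma_from_range(lo, hi)
        return float(med * np.exp(sigma * rng.standard_normal()))
    sd = (hi - lo) / (2 * 1.959963984540054) if hi > lo else 0.0
    return float(np.clip(med + sd * rng.standard_normal(), lo, hi))


def sample_cohort(spec: Optional[CohortSpec] = None) -> list[SampleRecord]:
    """Draw a synthetic cohort; deterministic under ``spec.seed``.

    Group-defining constraints are enforced per draw: type A keeps
    vimentin <= 10 and SMI32 <= 3 per mm^2, type B exceeds at least one,
    type C additionally carries calcification, and perituberal/control
    samples have no giant cells or dysmorphic neurons at all.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    fp = spec.feature_params
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            values = {
                feat: _draw_feature(rng, groups[group],
                                    feat in spec.skewed_features)
                for feat, groups in fp.items()
                if group in groups
            }
            # enforce the classifier-consistency constraints
            if group == "A":
                for _ in range(10_000):
                    if (values["vimentin_density"] <= 10.0
                            and values["smi32_density"] <= 3.0):
                        break
                    values["vimentin_density"] = _draw_feature(
                        rng, fp["vimentin_density"][group], True)
                    values["smi32_density"] = _draw_feature(
                        rng, fp["smi32_density"][group], True)
                else:  # pragma: no cover - parameters make this unreachable
                    raise InvalidSpecError(
                        "group A parameters incompatible with its cutoffs")
            elif group == "B":
                for _ in range(10_000):
                    if (values["vimentin_density"] > 10.0
                            or values["smi32_density"] > 3.0):
                        break
                    values["vimentin_density"] = _draw_feature(
                        rng, fp["vimentin_density"][group], True)
                    values["smi32_density"] = _draw_feature(
                        rng, fp["smi32_density"][group], True)
                else:  # pragma: no cover
                    raise InvalidSpecError(
                        "group B parameters incompatible with its cutoffs")
            elif group in ("perituberal", "control"):
                values["vimentin_density"] = 0.0
                values["smi32_density"] = 0.0

            calcified = bool(rng.random() < spec.calcification_prob.get(group, 0.0))
            omc = values.pop("omc", 0.0)
            mbp_pct = float(np.clip(55.0 + 15.0 * rng.standard_normal(),
                                    20.0, 90.0))
            mbp_mean_od = omc / mbp_pct
            # nominal positive pixel count: pct/100 of a 1e6-px tissue field
            mbp_integrated = mbp_mean_od * mbp_pct * 1e4
            q = QuantResult(
                mbp_pct=mbp_pct,
                mbp_mean_od=mbp_mean_od,
                mbp_integrated_od=mbp_integrated,
                calcification_present=calcified,
                **values,
            )
            age = _draw_feature(rng, DEFAULT_AGE_PARAMS[group], skewed=True)
            duration = float(rng.uniform(0.3, 0.9)) * age
            aed = int(rng.integers(1, 3 if group == "A" else 6))
            fcd = bool(rng.random() < DEFAULT_FCD_LIKE_PROB[group])
            engel = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.2, 0.15, 0.1]))
            records.append(
                SampleRecord(
                    sample_id=f"{group}-{i:03d}",
                    true_group=group,
                    features=q,
                    age_at_surgery_y=age,
                    epilepsy_duration_y=duration,
                    aed_count=aed,
                    fcd_like=fcd,
                    engel=engel,
                )
            )
    return records


def cohort_to_dataframe(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Flatten SampleRecords into one row per sample."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "true_group": r.true_group}
        row.update(r.features.to_dict())
        row.update(
            age_at_surgery_y=r.age_at_surgery_y,
            epilepsy_duration_y=r.epilepsy_duration_y,
            aed_count=r.aed_count,
            fcd_like=r.fcd_like,
            engel=r.engel,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[SampleRecord], path) -> Path:
    path = Path(path)
    cohort_to_dataframe(records).to_csv(path, index=False)
    return path


def cohort_spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a YAML mapping; omitted keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "n_per_group" in raw:
        kwargs["n_per_group"] = {str(k): int(v)
                                 for k, v in raw["n_per_group"].items()}
    if "feature_params" in raw:
        kwargs["feature_params"] = {
            f: {g: tuple(v) for g, v in groups.items()}
            for f, groups in raw["feature_params"].items()
        }
    if "skewed_features" in raw:
        kwargs["skewed_features"] = frozenset(raw["skewed_features"])
    if "calcification_prob" in raw:
        kwargs["calcification_prob"] = {
            str(k): float(v) for k, v in raw["calcification_prob"].items()
        }
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return CohortSpec(**kwargs)
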