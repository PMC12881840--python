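"""Patch quota allocation, coordinate sampling and tile preprocessing.

Coordinates are 0-based with the origin at the top-left; a patch occupies the
half-open square ``[x, x+size) x [y, y+size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from shapely.geometry import box
from shapely.ops import unary_union

from .cohort import PatientRecord, RegionAnnotation

logger = logging.getLogger(__name__)

OUTPUT_SIZE_PX = 224
PATCHES_PER_PATIENT = 100

#: per-channel normalization constants for RGB input in [0, 1]
CHANNEL_MEAN = (0.485, 0.456, 0.406)
CHANNEL_STD = (0.229, 0.224, 0.225)

#: rejection-sampling attempt budget, per requested patch
ATTEMPTS_PER_PATCH = 1000


@dataclass(frozen=True)
class TileSpec:
    """Patch geometry: 4096 px squares for 80x-scanned slides, 2048 for 20x."""

    patch_size_px: int = 4096
    output_size_px: int = OUTPUT_SIZE_PX
    patches_per_patient: int = PATCHES_PER_PATIENT

    def __post_init__(self) -> None:
        if self.patch_size_px < self.output_size_px:
            raise ValueError("patch_size_px must be >= output_size_px")
        if self.patches_per_patient < 1:
            raise ValueError("patches_per_patient must be >= 1")


@dataclass(frozen=True)
class PreprocessSpec:
    channel_mean: tuple[float, float, float] = CHANNEL_MEAN
    channel_std: tuple[float, float, float] = CHANNEL_STD

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.channel_std):
            raise ValueError("channel_std must be strictly positive")


def _largest_remainder(total: int, keys: list[str]) -> dict[str, int]:
    # Even split with at most +-1 spread; the `total % n` extra units go to the
    # lexicographically first keys.
    n = len(keys)
    base, rem = divmod(total, n)
    ordered = sorted(keys)
    return {k: base + (1 if idx < rem else 0) for idx, k in enumerate(ordered)}


def allocate_quota(patient: PatientRecord, total: int) -> dict[str, int]:
    """Distribute ``total`` patches evenly over specimens, then over slides.

    Returns a slide_id → count map whose values sum to ``total``; specimen
    subtotals differ by at most one, as do slide counts within a specimen.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    spec_quota = _largest_remainder(total, [s.specimen_id for s in patient.specimens])
    out: dict[str, int] = {}
    for spec in patient.specimens:
        out.update(_largest_remainder(spec_quota[spec.specimen_id], list(spec.slides)))
    return out


@dataclass
class PatchSample:
    """Sampled top-left coordinates plus a shortfall flag."""

    coords: list[tuple[int, int]] = field(default_factory=list)
    requested: int = 0

    @property
    def shortfall(self) -> bool:
        return len(self.coords) < self.requested


def sample_patches(
    annotation: RegionAnnotation,
    count: int,
    spec: TileSpec,
    seed: int,
) -> PatchSample:
    """Rejection-sample patch top-left corners from the tumor regions.

    Candidate corners are drawn uniformly over the tumor bounding box; a
    candidate is kept when its square lies fully inside the tumor union and
    has zero-area overlap with every artifact polygon.  Overlapping patches
    are permitted.  If fewer than ``count`` placements are found within the
    attempt budget the shortfall is flagged, not raised.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if not annotation.tumor_polygons:
        raise ValueError(f"slide {annotation.slide_id!r} has no tumor polygons")
    result = PatchSample(requested=count)
    if count == 0:
        return result

    size = spec.patch_size_px
    tumor = unary_union(annotation.tumor_polygons)
    artifact = unary_union(annotation.artifact_polygons) if annotation.artifact_polygons else None
    minx, miny, maxx, maxy = tumor.bounds
    x_lo, y_lo = int(np.ceil(minx)), int(np.ceil(miny))
    x_hi, y_hi = int(np.floor(maxx)) - size, int(np.floor(maxy)) - size
    if x_hi < x_lo or y_hi < y_lo:
        logger.warning(
            "slide %s: no %d px square fits in the tumor bounding box",
            annotation.slide_id, size,
        )
        return result

    rng = np.random.default_rng(seed)
    budget = ATTEMPTS_PER_PATCH * count
    for _ in range(budget):
        x = int(rng.integers(x_lo, x_hi + 1))
        y = int(rng.integers(y_lo, y_hi + 1))
        square = box(x, y, x + size, y + size)
        if not square.covered_by(tumor):
            continue
        if artifact is not None and square.intersection(artifact).area > 0:
            continue
        result.coords.append((x, y))
        if len(result.coords) == count:
            return result
    logger.warning(
        "slide %s: sampled %d/%d patches within the attempt budget",
        annotation.slide_id, len(result.coords), count,
    )
    return result


def preprocess_patch(
    tile: np.ndarray,
    spec: PreprocessSpec = PreprocessSpec(),
    out_size: int = OUTPUT_SIZE_PX,
    expected_size: int | None = None,
) -> np.ndarray:
    """Area-average a square uint8 RGB tile to ``out_size`` and standardize.

    Output value per channel c is ``(pixel/255 - mean_c) / std_c``.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected HxWx3 tile, got shape {tile.shape}")
    h, w = tile.shape[:2]
    if h != w:
        raise ValueError(f"tile must be square, got {h}x{w}")
    if expected_size is not None and h != expected_size:
        raise ValueError(f"tile is {h} px, expected {expected_size}")
    img = Image.fromarray(tile.astype(np.uint8), mode="RGB")
    small = np.asarray(img.resize((out_size, out_size), Image.Resampling.BOX), dtype=np.float64)
    mean = np.asarray(spec.channel_mean, dtype=np.float64)
    std = np.asarray(spec.channel_std, dtype=np.float64)
    return (small / 255.0 - mean) / std
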