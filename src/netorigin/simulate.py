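"""Synthetic cohorts with the latent structure the pipeline assumes.

Two separable class clusters sit at ``-delta/2`` / ``+delta/2`` on the first
embedding axis, each patient carrying a Gaussian random effect on that axis
and isotropic patch noise around it.  Other-origin patients are drawn from a
configurable mixture concentrated near the decision boundary.  A companion
generator emits textured PNG tiles plus GeoJSON annotations so the tiling
and toy-extractor path can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import box

from . import tiling
from .cohort import (
    OTHER,
    PANCREAS,
    RESECTION,
    SMALL_INTESTINE,
    Manifest,
    PatientRecord,
    RegionAnnotation,
    SpecimenRecord,
    make_embedding_frame,
    write_annotations,
    write_manifest,
)
from .embedding import TOY_STATS_DIM


@dataclass(frozen=True)
class SimulationConfig:
    n_pancreas: int = 20
    n_si: int = 20
    n_other: int = 8
    patches_per_patient: int = 100
    dim: int = TOY_STATS_DIM
    delta: float = 5.0
    sigma_patch: float = 1.0
    sigma_patient: float = 0.5
    #: (center offset on the separation axis, patient-effect spread, weight)
    other_mix: tuple[tuple[float, float, float], ...] = (
        (-0.3, 0.25, 0.5),
        (0.3, 0.25, 0.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.sigma_patch <= 0 or self.sigma_patient <= 0:
            raise ValueError("spreads must be > 0")
        if self.patches_per_patient < 1:
            raise ValueError("patches_per_patient must be >= 1")
        if self.n_other and abs(sum(w for _, _, w in self.other_mix) - 1.0) > 1e-9:
            raise ValueError("other_mix weights must sum to 1")
        if any(s <= 0 for _, s, _ in self.other_mix):
            raise ValueError("other_mix spreads must be > 0")


def _patients(prefix: str, n: int, origin: str) -> list[PatientRecord]:
    return [
        PatientRecord(
            f"{prefix}{j:03d}",
            origin,
            [SpecimenRecord(f"{prefix}{j:03d}-s1", RESECTION, [f"{prefix}{j:03d}-sl1"])],
        )
        for j in range(1, n + 1)
    ]


def simulate_cohort(cfg: SimulationConfig) -> tuple[Manifest, pd.DataFrame]:
    """Generate a manifest plus an embedding table, reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    patients = (
        _patients("pan", cfg.n_pancreas, PANCREAS)
        + _patients("si", cfg.n_si, SMALL_INTESTINE)
        + _patients("oth", cfg.n_other, OTHER)
    )
    manifest = Manifest(patients)

    weights = np.array([w for _, _, w in cfg.other_mix]) if cfg.other_mix else None
    frames = []
    for patient in patients:
        if patient.origin == PANCREAS:
            effect = rng.normal(-cfg.delta / 2.0, cfg.sigma_patient)
        elif patient.origin == SMALL_INTESTINE:
            effect = rng.normal(cfg.delta / 2.0, cfg.sigma_patient)
        else:
            comp = int(rng.choice(len(cfg.other_mix), p=weights))
            offset, spread, _ = cfg.other_mix[comp]
            effect = rng.normal(offset, spread)
        vecs = rng.normal(0.0, cfg.sigma_patch, size=(cfg.patches_per_patient, cfg.dim))
        vecs[:, 0] += effect
        spec = patient.specimens[0]
        prov = pd.DataFrame(
            {
                "patient_id": patient.patient_id,
                "specimen_id": spec.specimen_id,
                "slide_id": spec.slides[0],
                "x": np.arange(cfg.patches_per_patient) * 4096,
                "y": 0,
                "size_px": 4096,
            }
        )
        frames.append(make_embedding_frame(prov, vecs))
    embeddings = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return manifest, embeddings


# ---------------------------------------------------------------------------
# Textured tiles
# ---------------------------------------------------------------------------

#: mean RGB intensity per origin for the textured-tile generator
DEFAULT_PALETTE = {
    PANCREAS: (150, 90, 140),
    SMALL_INTESTINE: (190, 140, 170),
    OTHER: (170, 115, 155),
}


@dataclass
class TileSimulation:
    manifest: Manifest
    annotations: dict[str, RegionAnnotation]
    coords: pd.DataFrame
    tile_paths: list[Path] = field(default_factory=list)


def simulate_tiles(
    cfg: SimulationConfig,
    out_dir: str | Path,
    tile_spec: tiling.TileSpec = tiling.TileSpec(patch_size_px=256, patches_per_patient=5),
    palette: dict[str, tuple[int, int, int]] = DEFAULT_PALETTE,
    texture_std: float = 12.0,
    artifact_half: bool = False,
) -> TileSimulation:
    """Write PNG tiles, GeoJSON annotations and a manifest for a tiny cohort.

    Each slide is a conceptual canvas of 4x4 patch sizes whose tumor polygon
    covers everything; with ``artifact_half`` the left half is additionally
    marked as artifact, forcing the sampler into the right half.  Tile pixels
    are Gaussian noise around the origin's palette color.
    """
    out_dir = Path(out_dir)
    (out_dir / "tiles").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    patients = (
        _patients("pan", cfg.n_pancreas, PANCREAS)
        + _patients("si", cfg.n_si, SMALL_INTESTINE)
        + _patients("oth", cfg.n_other, OTHER)
    )
    manifest = Manifest(patients) if patients else Manifest([])
    canvas = 4 * tile_spec.patch_size_px

    annotations: dict[str, RegionAnnotation] = {}
    rows = []
    tile_paths: list[Path] = []
    for patient in patients:
        for spec in patient.specimens:
            quota = tiling.allocate_quota(patient, tile_spec.patches_per_patient)
            for slide in spec.slides:
                tumor = [box(0, 0, canvas, canvas)]
                artifacts = [box(0, 0, canvas / 2, canvas)] if artifact_half else []
                ann = RegionAnnotation(slide, tumor, artifacts)
                annotations[slide] = ann
                write_annotations(ann, out_dir / "annotations" / f"{slide}.geojson")
                sample = tiling.sample_patches(
                    ann, quota[slide], tile_spec, seed=int(rng.integers(2**31))
                )
                color = np.asarray(palette[patient.origin], dtype=float)
                for x, y in sample.coords:
                    pixels = rng.normal(
                        color, texture_std, size=(tile_spec.patch_size_px, tile_spec.patch_size_px, 3)
                    )
                    tile = np.clip(pixels, 0, 255).astype(np.uint8)
                    name = f"{patient.patient_id}__{spec.specimen_id}__{slide}__{x}_{y}.png"
                    path = out_dir / "tiles" / name
                    Image.fromarray(tile, mode="RGB").save(path)
                    tile_paths.append(path)
                    rows.append(
                        (patient.patient_id, spec.specimen_id, slide, x, y, tile_spec.patch_size_px)
                    )
    coords = pd.DataFrame(
        rows, columns=["patient_id", "specimen_id", "slide_id", "x", "y", "size_px"]
    )
    if patients:
        write_manifest(manifest, out_dir / "manifest.csv")
    coords.to_csv(out_dir / "coords.csv", index=False)
    return TileSimulation(manifest, annotations, coords, tile_paths)
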