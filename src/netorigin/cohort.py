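"""Cohort data model and file I/O.

The cohort is a patient → specimen → slide → patch hierarchy.  Manifests are
flat CSV files (one row per slide), region annotations are GeoJSON feature
collections, and patch embeddings live in a single wide table with provenance
columns followed by ``f0..f{d-1}`` feature columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

logger = logging.getLogger(__name__)

PANCREAS = "pancreas"
SMALL_INTESTINE = "small_intestine"
OTHER = "other"
ORIGINS = (PANCREAS, SMALL_INTESTINE, OTHER)
BINARY_ORIGINS = (PANCREAS, SMALL_INTESTINE)

RESECTION = "resection"
BIOPSY = "biopsy"
SPECIMEN_KINDS = (RESECTION, BIOPSY)

MANIFEST_COLUMNS = ["patient_id", "specimen_id", "slide_id", "origin", "specimen_kind"]
PROVENANCE_COLUMNS = ["patient_id", "specimen_id", "slide_id", "x", "y", "size_px"]


class CohortError(ValueError):
    """Raised for malformed manifests, annotations or embedding tables."""


@dataclass
class SpecimenRecord:
    specimen_id: str
    kind: str
    slides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in SPECIMEN_KINDS:
            raise CohortError(
                f"unknown specimen kind {self.kind!r}; allowed: {SPECIMEN_KINDS}"
            )
        if not self.slides:
            raise CohortError(f"specimen {self.specimen_id!r} has no slides")


@dataclass
class PatientRecord:
    patient_id: str
    origin: str
    specimens: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise CohortError(
                f"unknown origin {self.origin!r} for patient {self.patient_id!r}; "
                f"allowed: {ORIGINS}"
            )
        if not self.specimens:
            raise CohortError(f"patient {self.patient_id!r} has no specimens")
        slide_ids = self.slide_ids
        if len(slide_ids) != len(set(slide_ids)):
            raise CohortError(f"duplicate slide id within patient {self.patient_id!r}")

    @property
    def slide_ids(self) -> list[str]:
        return [s for spec in self.specimens for s in spec.slides]


class Manifest:
    """Validated collection of :class:`PatientRecord`."""

    def __init__(self, patients: Iterable[PatientRecord]):
        self.patients = list(patients)
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise CohortError("duplicate patient ids in manifest")
        all_slides = [s for p in self.patients for s in p.slide_ids]
        if len(all_slides) != len(set(all_slides)):
            raise CohortError("duplicate slide ids across manifest")
        self._by_id = {p.patient_id: p for p in self.patients}

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        try:
            return self._by_id[patient_id]
        except KeyError:
            raise CohortError(f"patient {patient_id!r} not in manifest") from None

    def origin_of(self, patient_id: str) -> str:
        return self.patient(patient_id).origin

    def patient_ids(self, origins: Sequence[str] | None = None) -> list[str]:
        if origins is None:
            return sorted(self._by_id)
        return sorted(p.patient_id for p in self.patients if p.origin in origins)

    def origin_counts(self) -> dict[str, int]:
        counts = {o: 0 for o in ORIGINS}
        for p in self.patients:
            counts[p.origin] += 1
        return counts

    def subset(self, patient_ids: Iterable[str]) -> "Manifest":
        wanted = set(patient_ids)
        return Manifest([p for p in self.patients if p.patient_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for spec in p.specimens:
                for slide in spec.slides:
                    rows.append((p.patient_id, spec.specimen_id, slide, p.origin, spec.kind))
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Manifest":
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"manifest missing columns: {missing}")
        seen_slides: set[str] = set()
        patients: dict[str, dict] = {}
        for idx, row in df.iterrows():
            slide = str(row["slide_id"])
            if slide in seen_slides:
                raise CohortError(f"duplicate slide id {slide!r} (row {idx})")
            seen_slides.add(slide)
            origin = str(row["origin"])
            if origin not in ORIGINS:
                raise CohortError(
                    f"row {idx}: unknown origin {origin!r}; allowed: {ORIGINS}"
                )
            pid = str(row["patient_id"])
            entry = patients.setdefault(pid, {"origin": origin, "specimens": {}})
            if entry["origin"] != origin:
                raise CohortError(f"patient {pid!r} has conflicting origins")
            sid = str(row["specimen_id"])
            spec = entry["specimens"].setdefault(sid, {"kind": str(row["specimen_kind"]), "slides": []})
            if spec["kind"] != str(row["specimen_kind"]):
                raise CohortError(f"specimen {sid!r} has conflicting kinds")
            spec["slides"].append(slide)
        records = [
            PatientRecord(
                pid,
                entry["origin"],
                [
                    SpecimenRecord(sid, spec["kind"], spec["slides"])
                    for sid, spec in entry["specimens"].items()
                ],
            )
            for pid, entry in patients.items()
        ]
        return cls(records)


def read_manifest(path: str | Path) -> Manifest:
    """Read a slide-per-row CSV manifest into a validated :class:`Manifest`."""
    df = pd.read_csv(path, dtype=str)
    return Manifest.from_frame(df)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Region annotations (GeoJSON)
# ---------------------------------------------------------------------------

TUMOR_CLASS = "Tumor"
ARTIFACT_CLASS = "Artifact"


@dataclass
class RegionAnnotation:
    slide_id: str
    tumor_polygons: list[Polygon] = field(default_factory=list)
    artifact_polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        for poly in list(self.tumor_polygons) + list(self.artifact_polygons):
            _validate_polygon(poly)


def _validate_polygon(poly: Polygon) -> None:
    if not isinstance(poly, Polygon):
        raise CohortError(f"expected Polygon, got {type(poly).__name__}")
    if not poly.is_valid:
        raise CohortError("polygon is not simple/valid")
    coords = np.asarray(poly.exterior.coords)
    if not np.all(np.isfinite(coords)):
        raise CohortError("polygon has non-finite coordinates")
    if np.any(coords < 0):
        raise CohortError("polygon has negative coordinates")


def _classification_name(feature: dict) -> str | None:
    props = feature.get("properties") or {}
    cls = props.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return None


def read_annotations(path: str | Path, slide_id: str | None = None) -> RegionAnnotation:
    """Parse a GeoJSON FeatureCollection into tumor/artifact polygon lists.

    Features are partitioned by their ``classification.name`` property
    (``Tumor`` / ``Artifact``); features without a classification are skipped
    with a logged warning, and classified non-polygon geometries are an error.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise CohortError(f"{path}: expected a GeoJSON FeatureCollection")
    if slide_id is None:
        slide_id = path.stem
    tumors: list[Polygon] = []
    artifacts: list[Polygon] = []
    for feature in doc.get("features", []):
        name = _classification_name(feature)
        if name not in (TUMOR_CLASS, ARTIFACT_CLASS):
            logger.warning("%s: skipping feature with classification %r", path, name)
            continue
        geom = shape(feature["geometry"])
        if geom.geom_type == "Polygon":
            polys = [geom]
        elif geom.geom_type == "MultiPolygon":
            polys = list(geom.geoms)
        else:
            raise CohortError(
                f"{path}: classified feature has non-polygon geometry {geom.geom_type}"
            )
        (tumors if name == TUMOR_CLASS else artifacts).extend(polys)
    return RegionAnnotation(slide_id, tumors, artifacts)


def write_annotations(annotation: RegionAnnotation, path: str | Path) -> None:
    def _feature(poly: Polygon, name: str) -> dict:
        return {
            "type": "Feature",
            "geometry": poly.__geo_interface__,
            "properties": {"classification": {"name": name}},
        }

    features = [_feature(p, TUMOR_CLASS) for p in annotation.tumor_polygons]
    features += [_feature(p, ARTIFACT_CLASS) for p in annotation.artifact_polygons]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Embedding tables
# ---------------------------------------------------------------------------


def feature_columns(dim: int) -> list[str]:
    return [f"f{i}" for i in range(dim)]


def make_embedding_frame(provenance: pd.DataFrame, vectors: np.ndarray | Sequence) -> pd.DataFrame:
    """Assemble an embedding table from provenance rows and feature vectors."""
    if len(provenance) != len(vectors):
        raise CohortError("provenance and vectors disagree in length")
    if isinstance(vectors, np.ndarray):
        mat = vectors
    else:
        dims = {len(v) for v in vectors}
        if len(dims) > 1:
            raise CohortError(f"mixed embedding dimensions: {sorted(dims)}")
        mat = np.asarray(list(vectors), dtype=float)
    if mat.ndim != 2:
        raise CohortError("vectors must form a 2-D matrix")
    missing = [c for c in PROVENANCE_COLUMNS if c not in provenance.columns]
    if missing:
        raise CohortError(f"provenance missing columns: {missing}")
    out = provenance[PROVENANCE_COLUMNS].reset_index(drop=True).copy()
    feats = pd.DataFrame(mat, columns=feature_columns(mat.shape[1]))
    return pd.concat([out, feats], axis=1)


def embedding_dim(df: pd.DataFrame) -> int:
    cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    expected = feature_columns(len(cols))
    if sorted(cols, key=lambda c: int(c[1:])) != expected:
        raise CohortError("feature columns are not contiguous f0..f{d-1}")
    return len(cols)


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[feature_columns(embedding_dim(df))].to_numpy(dtype=float)


def write_embeddings(df: pd.DataFrame, path: str | Path) -> None:
    embedding_dim(df)  # validates homogeneity / contiguity
    df.to_csv(path, index=False, float_format="%.17g")


def read_embeddings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "specimen_id": str, "slide_id": str},
    )
    missing = [c for c in PROVENANCE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"embedding table missing columns: {missing}")
    embedding_dim(df)
    return df
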