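import numpy as np
import pandas as pd
import pytest

from netorigin.cohort import (
    PANCREAS,
    SMALL_INTESTINE,
    Manifest,
    PatientRecord,
    SpecimenRecord,
    make_embedding_frame,
)


def single_slide_patient(pid: str, origin: str) -> PatientRecord:
    return PatientRecord(
        pid, origin, [SpecimenRecord(f"{pid}-s1", "resection", [f"{pid}-sl1"])]
    )


def embeddings_for(patients, vectors_fn, patches=20):
    """Build an embedding table from per-patient vector generators."""
    frames = []
    for patient in patients:
        spec = patient.specimens[0]
        vecs = vectors_fn(patient)
        prov = pd.DataFrame(
            {
                "patient_id": patient.patient_id,
                "specimen_id": spec.specimen_id,
                "slide_id": spec.slides[0],
                "x": np.arange(len(vecs)),
                "y": 0,
                "size_px": 224,
            }
        )
        frames.append(make_embedding_frame(prov, vecs))
    return pd.concat(frames, ignore_index=True)


def mirror_cohort(n_per_class=6, patches=20, dim=2, sep=10.0, seed=0, flip=False):
    """Separable toy cohort whose SI patches are the exact mirror of pancreas.

    The mirror symmetry makes the linear-SVM solution antisymmetric, so the
    decision boundary passes through the origin up to solver tolerance.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=(n_per_class * patches, dim))
    base[:, 0] += sep / 2
    patients, chunks = [], {}
    for prefix, sign in (("p", -1.0), ("s", 1.0)):
        origin = PANCREAS if prefix == "p" else SMALL_INTESTINE
        if flip:
            origin = SMALL_INTESTINE if prefix == "p" else PANCREAS
        for j in range(n_per_class):
            pid = f"{prefix}{j}"
            patients.append(single_slide_patient(pid, origin))
            chunks[pid] = sign * base[j * patches : (j + 1) * patches]
    manifest = Manifest(patients)
    embeddings = embeddings_for(patients, lambda p: chunks[p.patient_id], patches)
    return manifest, embeddings


@pytest.fixture
def separable_toy():
    return mirror_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
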