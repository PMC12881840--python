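import numpy as np
import pandas as pd
import pytest

from conftest import single_slide_patient
from netorigin.cohort import OTHER, PANCREAS, SMALL_INTESTINE, Manifest
from netorigin.evaluation import (
    ConfusionMatrix3,
    binary_accuracy,
    class_metrics,
    external_evaluate,
    loo_evaluate,
    loo_scores,
    split_binary,
)
from netorigin.simulate import SimulationConfig, simulate_cohort

# confusion matrices as printed for the internal cohort at confidence 0.875
# and 1.0 and the external cohort at confidence 0.875 (rows: pancreas, SI,
# other; columns: pancreas, SI, uncertain)
INTERNAL_0875 = ConfusionMatrix3.from_rows([17, 5, 18], [2, 47, 2], [3, 0, 5])
INTERNAL_10 = ConfusionMatrix3.from_rows([7, 5, 28], [0, 47, 4], [1, 0, 7])
EXTERNAL_0875 = ConfusionMatrix3.from_rows([3, 0, 6], [1, 10, 3], [0, 0, 3])


class TestClassMetrics:
    def test_internal_confidence_one_si(self):
        m = class_metrics(INTERNAL_10, SMALL_INTESTINE)
        assert m["sensitivity"] == pytest.approx(47 / 51)
        assert m["ppv"] == pytest.approx(47 / 52)
        assert m["specificity"] == pytest.approx(43 / 48)

    def test_external_si(self):
        m = class_metrics(EXTERNAL_0875, SMALL_INTESTINE)
        assert m["sensitivity"] == pytest.approx(10 / 14)
        assert m["specificity"] == pytest.approx(1.0)
        assert m["ppv"] == pytest.approx(1.0)

    def test_internal_0875_pancreas(self):
        m = class_metrics(INTERNAL_0875, PANCREAS)
        assert m["sensitivity"] == pytest.approx(17 / 40)
        assert m["specificity"] == pytest.approx(54 / 59)
        assert m["ppv"] == pytest.approx(17 / 22)

    def test_identity_matrix(self):
        m3 = ConfusionMatrix3.from_rows([10, 0, 0], [0, 10, 0], [0, 0, 10])
        for k in (PANCREAS, SMALL_INTESTINE):
            metrics = class_metrics(m3, k)
            assert all(v == pytest.approx(1.0) for v in metrics.values())

    def test_undefined_metrics_are_none(self):
        # nothing predicted pancreas -> PPV undefined; no pancreas row -> sensitivity undefined
        m3 = ConfusionMatrix3.from_rows([0, 0, 0], [0, 5, 0], [0, 0, 3])
        metrics = class_metrics(m3, PANCREAS)
        assert metrics["sensitivity"] is None
        assert metrics["ppv"] is None
        assert metrics["specificity"] == pytest.approx(1.0)

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(INTERNAL_10, OTHER)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix3(np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            ConfusionMatrix3.from_rows([-1, 0, 0], [0, 0, 0], [0, 0, 0])


class TestSplit:
    def test_disjoint_and_stratified(self):
        patients = [single_slide_patient(f"pa{j}", PANCREAS) for j in range(10)]
        patients += [single_slide_patient(f"si{j}", SMALL_INTESTINE) for j in range(10)]
        manifest = Manifest(patients)
        ids = manifest.patient_ids()
        train, cal = split_binary(manifest, ids, seed=0)
        assert not set(train) & set(cal)
        assert sorted(train + cal) == sorted(ids)
        assert sum(p.startswith("pa") for p in train) == 6
        assert sum(p.startswith("si") for p in train) == 6

    def test_seed_changes_split(self):
        patients = [single_slide_patient(f"pa{j}", PANCREAS) for j in range(10)]
        patients += [single_slide_patient(f"si{j}", SMALL_INTESTINE) for j in range(10)]
        manifest = Manifest(patients)
        ids = manifest.patient_ids()
        assert split_binary(manifest, ids, seed=0) != split_binary(manifest, ids, seed=1)
        assert split_binary(manifest, ids, seed=0) == split_binary(manifest, ids, seed=0)

    def test_singleton_class_goes_to_training(self):
        patients = [
            single_slide_patient("pa0", PANCREAS),
            single_slide_patient("si0", SMALL_INTESTINE),
            single_slide_patient("si1", SMALL_INTESTINE),
        ]
        manifest = Manifest(patients)
        train, cal = split_binary(manifest, manifest.patient_ids(), seed=0)
        assert "pa0" in train

    def test_empty_class_rejected(self):
        patients = [
            single_slide_patient("si0", SMALL_INTESTINE),
            single_slide_patient("si1", SMALL_INTESTINE),
        ]
        manifest = Manifest(patients)
        with pytest.raises(ValueError, match=">= 1"):
            split_binary(manifest, manifest.patient_ids(), seed=0)


def small_cohort(seed=0, n_other=4, delta=6.0):
    cfg = SimulationConfig(
        n_pancreas=6, n_si=6, n_other=n_other, dim=6,
        patches_per_patient=30, delta=delta, seed=seed,
    )
    return simulate_cohort(cfg)


class TestLoo:
    def test_micro_cohort_smoke(self):
        cfg = SimulationConfig(
            n_pancreas=2, n_si=2, n_other=1, dim=4, patches_per_patient=10, seed=0
        )
        manifest, embeddings = simulate_cohort(cfg)
        result = loo_evaluate(embeddings, manifest, confidence=1.0, seed=0)
        assert len(result.predictions) == 5
        assert result.matrix.total == 5

    def test_confidence_zero_no_uncertain(self):
        manifest, embeddings = small_cohort()
        result = loo_evaluate(embeddings, manifest, confidence=0.0, seed=0)
        assert result.matrix.col_total("uncertain") == 0

    def test_confidence_one_others_abstain(self):
        manifest, embeddings = small_cohort()
        result = loo_evaluate(embeddings, manifest, confidence=1.0, seed=0)
        assert result.matrix.counts[2, 2] == 4
        # binary classes stay essentially correctly labeled
        assert result.matrix.counts[0, 0] + result.matrix.counts[1, 1] >= 11

    def test_row_sums_match_composition(self):
        manifest, embeddings = small_cohort()
        result = loo_evaluate(embeddings, manifest, confidence=0.5, seed=0)
        counts = manifest.origin_counts()
        assert result.matrix.row_total(PANCREAS) == counts[PANCREAS]
        assert result.matrix.row_total(SMALL_INTESTINE) == counts[SMALL_INTESTINE]
        assert result.matrix.row_total(OTHER) == counts[OTHER]

    def test_deterministic(self):
        manifest, embeddings = small_cohort()
        a = loo_evaluate(embeddings, manifest, confidence=0.5, seed=3)
        b = loo_evaluate(embeddings, manifest, confidence=0.5, seed=3)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.matrix == b.matrix

    def test_patient_honesty_bookkeeping(self):
        manifest, embeddings = small_cohort(n_other=1)
        folds = loo_scores(embeddings, manifest, seed=0)
        assert [f.patient_id for f in folds] == manifest.patient_ids()


class TestExternal:
    def test_row_conservation(self):
        train_manifest, train_embeddings = small_cohort(seed=0)
        cfg = SimulationConfig(
            n_pancreas=3, n_si=3, n_other=2, dim=6,
            patches_per_patient=30, delta=6.0, sigma_patch=1.3, seed=99,
        )
        test_manifest, test_embeddings = simulate_cohort(cfg)
        # disjoint patient ids
        test_frame = test_manifest.to_frame()
        for col in ("patient_id", "specimen_id", "slide_id"):
            test_frame[col] = "x-" + test_frame[col]
        test_manifest = Manifest.from_frame(test_frame)
        test_embeddings = test_embeddings.assign(
            patient_id="x-" + test_embeddings["patient_id"],
            specimen_id="x-" + test_embeddings["specimen_id"],
            slide_id="x-" + test_embeddings["slide_id"],
        )
        result = external_evaluate(
            train_embeddings, train_manifest, test_embeddings, test_manifest,
            confidence=0.875, seed=0,
        )
        counts = test_manifest.origin_counts()
        for origin in (PANCREAS, SMALL_INTESTINE, OTHER):
            assert result.matrix.row_total(origin) == counts[origin]

    def test_separable_confidence_zero_diagonal(self):
        train_manifest, train_embeddings = small_cohort(seed=1)
        test_manifest, test_embeddings = small_cohort(seed=2, n_other=0)
        frame = test_manifest.to_frame()
        for col in ("patient_id", "specimen_id", "slide_id"):
            frame[col] = "t-" + frame[col]
        test_manifest = Manifest.from_frame(frame)
        test_embeddings = test_embeddings.assign(
            patient_id="t-" + test_embeddings["patient_id"],
            specimen_id="t-" + test_embeddings["specimen_id"],
            slide_id="t-" + test_embeddings["slide_id"],
        )
        result = external_evaluate(
            train_embeddings, train_manifest, test_embeddings, test_manifest,
            confidence=0.0, seed=1,
        )
        assert result.matrix.col_total("uncertain") == 0
        assert result.matrix.counts[0, 0] == 6 and result.matrix.counts[1, 1] == 6

    def test_empty_test_cohort(self):
        train_manifest, train_embeddings = small_cohort(seed=0)
        empty_manifest = Manifest([])
        empty_embeddings = train_embeddings.iloc[0:0]
        result = external_evaluate(
            train_embeddings, train_manifest, empty_embeddings, empty_manifest,
            confidence=0.875, seed=0,
        )
        assert result.matrix.total == 0
        assert len(result.predictions) == 0

    def test_overlapping_cohorts_rejected(self):
        manifest, embeddings = small_cohort(seed=0)
        with pytest.raises(ValueError, match="share"):
            external_evaluate(embeddings, manifest, embeddings, manifest)


class TestBinaryAccuracy:
    def test_all_correct(self):
        manifest, embeddings = small_cohort(n_other=0)
        folds = loo_scores(embeddings, manifest, seed=0)
        assert binary_accuracy(folds, "patient") == 1.0

    def test_half_correct(self):
        manifest, embeddings = small_cohort(n_other=0)
        folds = loo_scores(embeddings, manifest, seed=0)[:2]
        folds[0].patch_scores = -folds[0].patch_scores  # force one wrong vote
        assert binary_accuracy(folds, "patient") == 0.5

    def test_aggregation_gain(self):
        # moderate separation: patch errors exist, the vote absorbs them
        cfg = SimulationConfig(
            n_pancreas=8, n_si=8, n_other=0, dim=6,
            patches_per_patient=50, delta=2.0, sigma_patient=0.2, seed=5,
        )
        manifest, embeddings = simulate_cohort(cfg)
        folds = loo_scores(embeddings, manifest, seed=5)
        patch = binary_accuracy(folds, "patch")
        patient = binary_accuracy(folds, "patient")
        assert patch < 1.0
        assert patient >= patch

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            binary_accuracy([], level="slide")
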