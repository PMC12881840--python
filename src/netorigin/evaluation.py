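"""Leave-one-out and external evaluation of the two-step pipeline.

Protocol: the binary-origin (pancreas / small-intestine) patients are split
60/40; the 60% train the patch classifier, the 40% plus every other-origin
patient calibrate the abstention thresholds.  Internal performance uses
leave-one-out over all patients with a fresh split, model and calibration
per fold; external performance uses one fixed split of the full training
cohort.  Metric conventions: abstentions count against sensitivity and as
correct rejections for specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abstention import (
    CalibrationSet,
    ThresholdPair,
    UNCERTAIN,
    classify_with_abstention,
    determine_thresholds,
)
from .classify import ClassifierConfig, FittedScorer, majority_vote, train
from .cohort import (
    BINARY_ORIGINS,
    OTHER,
    PANCREAS,
    SMALL_INTESTINE,
    Manifest,
    embedding_dim,
    feature_matrix,
)

logger = logging.getLogger(__name__)

ROW_LABELS = (PANCREAS, SMALL_INTESTINE, OTHER)
COL_LABELS = (PANCREAS, SMALL_INTESTINE, UNCERTAIN)

#: threshold placement used when classifying held-out patients; midpoint
#: padding leaves margin between the calibration sums and the thresholds so
#: that unseen other-origin patients slightly more extreme than every
#: calibration one still abstain (calibration counts are unaffected)
DEFAULT_PADDING = "midpoint"


@dataclass(frozen=True)
class SplitProtocol:
    train_fraction: float = 0.60
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_binary(
    manifest: Manifest,
    patient_ids: list[str],
    seed: int,
    protocol: SplitProtocol = SplitProtocol(),
) -> tuple[list[str], list[str]]:
    """Split binary-origin patients into (train, calibration) id lists.

    Stratified by origin; both parts keep at least one patient per class.
    """
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    cal_ids: list[str] = []
    groups = [patient_ids] if not protocol.stratified else [
        [p for p in patient_ids if manifest.origin_of(p) == origin]
        for origin in BINARY_ORIGINS
    ]
    for group in groups:
        group = sorted(group)
        if len(group) == 0:
            raise ValueError("each binary class needs >= 1 patient to split")
        if len(group) == 1:
            # a singleton class must train the classifier; its calibration
            # side is simply empty for this fold
            train_ids += group
            continue
        perm = rng.permutation(len(group))
        n_train = int(round(protocol.train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train_ids += [group[j] for j in perm[:n_train]]
        cal_ids += [group[j] for j in perm[n_train:]]
    return sorted(train_ids), sorted(cal_ids)


class ConfusionMatrix3:
    """3x3 counts: rows = true origin, columns = predicted origin."""

    def __init__(self, counts=None):
        self.counts = np.zeros((3, 3), dtype=int) if counts is None else np.asarray(counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @classmethod
    def from_rows(cls, pancreas, small_intestine, other) -> "ConfusionMatrix3":
        return cls(np.array([pancreas, small_intestine, other]))

    def add(self, true_origin: str, predicted: str) -> None:
        self.counts[ROW_LABELS.index(true_origin), COL_LABELS.index(predicted)] += 1

    def row_total(self, label: str) -> int:
        return int(self.counts[ROW_LABELS.index(label)].sum())

    def col_total(self, label: str) -> int:
        return int(self.counts[:, COL_LABELS.index(label)].sum())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "rows": list(ROW_LABELS),
            "columns": list(COL_LABELS),
            "counts": self.counts.tolist(),
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, ConfusionMatrix3) and np.array_equal(self.counts, other.counts)

    def __repr__(self) -> str:
        return f"ConfusionMatrix3({self.counts.tolist()})"


def class_metrics(m: ConfusionMatrix3, k: str) -> dict[str, float | None]:
    """Sensitivity / specificity / PPV / NPV for class ``k``.

    Abstentions ("uncertain") count against sensitivity and as correct
    rejections for specificity.  A metric with a zero denominator is
    reported as ``None`` (undefined), never silently 0 or 1.
    """
    if k not in BINARY_ORIGINS:
        raise ValueError(f"k must be one of {BINARY_ORIGINS}")
    r = ROW_LABELS.index(k)
    c = COL_LABELS.index(k)
    counts = m.counts

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    row_total = counts[r].sum()
    col_total = counts[:, c].sum()
    non_k_rows = [j for j in range(3) if j != r]
    non_k_total = sum(counts[j].sum() for j in non_k_rows)
    false_pos = sum(counts[j, c] for j in non_k_rows)

    sensitivity = ratio(counts[r, c], row_total)
    specificity = None if non_k_total == 0 else 1.0 - false_pos / non_k_total
    ppv = ratio(counts[r, c], col_total)
    npv = ratio(
        sum(counts[j].sum() - counts[j, c] for j in non_k_rows),
        m.total - col_total,
    )
    return {"sensitivity": sensitivity, "specificity": specificity, "ppv": ppv, "npv": npv}


# ---------------------------------------------------------------------------
# Fold machinery
# ---------------------------------------------------------------------------


@dataclass
class FoldScore:
    """Held-out patient's scores plus the calibration set of its fold."""

    patient_id: str
    true_origin: str
    patch_scores: np.ndarray
    cal: CalibrationSet

    @property
    def sum_signed(self) -> float:
        return float(np.sum(self.patch_scores))

    @property
    def majority_label(self) -> str:
        return majority_vote(self.patch_scores)


def _patient_sums(scorer: FittedScorer, by_patient: dict[str, pd.DataFrame], pids) -> np.ndarray:
    return np.array(
        [float(scorer.signed_score(feature_matrix(by_patient[p])).sum()) for p in pids]
    )


def _group_by_patient(embeddings: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {str(pid): grp for pid, grp in embeddings.groupby(embeddings["patient_id"].astype(str))}


def _rounded_i(confidence: float, o: int) -> int:
    if not 0 <= confidence <= 1:
        raise ValueError("confidence must be in [0, 1]")
    if o == 0:
        if confidence > 0:
            logger.warning(
                "no other-origin calibration patients in this fold; "
                "i = round(%.3g * 0) = 0, falling back to binary classification",
                confidence,
            )
        return 0
    return int(np.floor(confidence * o + 0.5))


def loo_scores(
    embeddings: pd.DataFrame,
    manifest: Manifest,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    protocol: SplitProtocol = SplitProtocol(),
) -> list[FoldScore]:
    """Leave-one-out folds: per held-out patient, retrain and recalibrate.

    Fold ``j`` uses seed ``seed + j`` for its 60/40 split of the remaining
    binary patients; the remaining other-origin patients always calibrate.
    """
    by_patient = _group_by_patient(embeddings)
    pids = manifest.patient_ids()
    missing = [p for p in pids if p not in by_patient]
    if missing:
        raise ValueError(f"patients without embeddings: {missing}")
    folds = []
    for fold_idx, held in enumerate(pids):
        rest = [p for p in pids if p != held]
        rest_binary = [p for p in rest if manifest.origin_of(p) in BINARY_ORIGINS]
        rest_other = [p for p in rest if manifest.origin_of(p) == OTHER]
        train_ids, cal_ids = split_binary(manifest, rest_binary, seed + fold_idx, protocol)
        train_df = embeddings[embeddings["patient_id"].astype(str).isin(train_ids)]
        scorer = train(train_df, manifest, config, seed=seed + fold_idx)
        assert held not in scorer.train_patient_ids  # patient honesty
        cal = CalibrationSet(
            _patient_sums(scorer, by_patient, [p for p in cal_ids if manifest.origin_of(p) == PANCREAS]),
            _patient_sums(scorer, by_patient, [p for p in cal_ids if manifest.origin_of(p) == SMALL_INTESTINE]),
            _patient_sums(scorer, by_patient, rest_other),
        )
        patch_scores = scorer.signed_score(feature_matrix(by_patient[held]))
        folds.append(FoldScore(held, manifest.origin_of(held), patch_scores, cal))
    return folds


@dataclass
class EvaluationResult:
    predictions: pd.DataFrame
    matrix: ConfusionMatrix3
    thresholds: list[ThresholdPair] = field(default_factory=list)


def classify_folds(
    folds: list[FoldScore],
    confidence: float,
    contain_zero: bool = True,
    padding: str = DEFAULT_PADDING,
) -> EvaluationResult:
    """Apply the abstention rule to every fold at one confidence level."""
    rows = []
    matrix = ConfusionMatrix3()
    thresholds = []
    for fold in folds:
        i = _rounded_i(confidence, fold.cal.o)
        thr = determine_thresholds(fold.cal, i, contain_zero=contain_zero, padding=padding)
        predicted = classify_with_abstention(fold.sum_signed, thr)
        matrix.add(fold.true_origin, predicted)
        thresholds.append(thr)
        rows.append((fold.patient_id, fold.true_origin, fold.sum_signed, predicted))
    predictions = pd.DataFrame(rows, columns=["patient_id", "true_origin", "sum_signed", "predicted"])
    return EvaluationResult(predictions, matrix, thresholds)


def loo_evaluate(
    embeddings: pd.DataFrame,
    manifest: Manifest,
    config: ClassifierConfig = ClassifierConfig(),
    confidence: float = 0.875,
    seed: int = 0,
    protocol: SplitProtocol = SplitProtocol(),
    contain_zero: bool = True,
    padding: str = DEFAULT_PADDING,
) -> EvaluationResult:
    folds = loo_scores(embeddings, manifest, config, seed, protocol)
    return classify_folds(folds, confidence, contain_zero, padding)


def external_evaluate(
    train_embeddings: pd.DataFrame,
    train_manifest: Manifest,
    test_embeddings: pd.DataFrame,
    test_manifest: Manifest,
    config: ClassifierConfig = ClassifierConfig(),
    confidence: float = 0.875,
    seed: int = 0,
    protocol: SplitProtocol = SplitProtocol(),
    contain_zero: bool = True,
    padding: str = DEFAULT_PADDING,
) -> EvaluationResult:
    """Train and calibrate once on the full training cohort, test externally."""
    overlap = set(train_manifest.patient_ids()) & set(test_manifest.patient_ids())
    if overlap:
        raise ValueError(f"train and test cohorts share patients: {sorted(overlap)}")
    if len(test_embeddings) and embedding_dim(test_embeddings) != embedding_dim(train_embeddings):
        raise ValueError("train and test embedding dimensions differ")

    binary_ids = train_manifest.patient_ids(BINARY_ORIGINS)
    other_ids = train_manifest.patient_ids([OTHER])
    train_ids, cal_ids = split_binary(train_manifest, binary_ids, seed, protocol)
    by_patient = _group_by_patient(train_embeddings)
    train_df = train_embeddings[train_embeddings["patient_id"].astype(str).isin(train_ids)]
    scorer = train(train_df, train_manifest, config, seed=seed)
    cal = CalibrationSet(
        _patient_sums(scorer, by_patient, [p for p in cal_ids if train_manifest.origin_of(p) == PANCREAS]),
        _patient_sums(scorer, by_patient, [p for p in cal_ids if train_manifest.origin_of(p) == SMALL_INTESTINE]),
        _patient_sums(scorer, by_patient, other_ids),
    )
    i = _rounded_i(confidence, cal.o)
    thr = determine_thresholds(cal, i, contain_zero=contain_zero, padding=padding)

    test_by_patient = _group_by_patient(test_embeddings)
    rows = []
    matrix = ConfusionMatrix3()
    for pid in test_manifest.patient_ids():
        if pid not in test_by_patient:
            raise ValueError(f"test patient {pid!r} has no embeddings")
        s = float(scorer.signed_score(feature_matrix(test_by_patient[pid])).sum())
        predicted = classify_with_abstention(s, thr)
        matrix.add(test_manifest.origin_of(pid), predicted)
        rows.append((pid, test_manifest.origin_of(pid), s, predicted))
    predictions = pd.DataFrame(rows, columns=["patient_id", "true_origin", "sum_signed", "predicted"])
    return EvaluationResult(predictions, matrix, [thr])


def binary_accuracy(folds: list[FoldScore], level: str = "patient") -> float:
    """Pooled fraction correct on binary-origin patients at patch or patient level."""
    if level not in ("patch", "patient"):
        raise ValueError("level must be 'patch' or 'patient'")
    binary = [f for f in folds if f.true_origin in BINARY_ORIGINS]
    if not binary:
        raise ValueError("no binary-origin patients among folds")
    if level == "patient":
        correct = sum(f.majority_label == f.true_origin for f in binary)
        return correct / len(binary)
    n_correct = 0
    n_total = 0
    for f in binary:
        want_positive = f.true_origin == SMALL_INTESTINE
        n_correct += int(np.sum(f.patch_scores > 0) if want_positive else np.sum(f.patch_scores <= 0))
        n_total += f.patch_scores.size
    return n_correct / n_total
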