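"""Binary patch-level classifier (pancreas vs. small intestine).

The classifier is trained on patch embeddings with each patch carrying its
patient's origin label.  Its signed decision value — positive for small
intestine, negative for pancreas — is the building block of both the
majority-vote patient prediction and the downstream abstention layer.  No
hyperparameter search is performed; model defaults are fixed in
:class:`ClassifierConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .cohort import (
    BINARY_ORIGINS,
    PANCREAS,
    SMALL_INTESTINE,
    Manifest,
    feature_matrix,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("svm_rbf", "svm_linear", "logreg")


@dataclass(frozen=True)
class ClassifierConfig:
    model_kind: str = "svm_rbf"
    c: float = 1.0
    svm_degree: int = 3
    svm_gamma: str = "auto"  # 1/d
    logreg_penalty: str = "l2"
    logreg_max_iter: int = 100
    positive_class: str = SMALL_INTESTINE

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.positive_class not in BINARY_ORIGINS:
            raise ValueError(f"positive_class must be one of {BINARY_ORIGINS}")


def _build_model(config: ClassifierConfig, seed: int):
    if config.model_kind == "svm_rbf":
        return SVC(kernel="rbf", C=config.c, gamma=config.svm_gamma,
                   degree=config.svm_degree, random_state=seed)
    if config.model_kind == "svm_linear":
        return SVC(kernel="linear", C=config.c, random_state=seed)
    kwargs = {}
    if config.logreg_penalty != "l2":  # l2 is the default; passing it is deprecated
        kwargs["penalty"] = config.logreg_penalty
    return LogisticRegression(C=config.c, max_iter=config.logreg_max_iter, **kwargs)


@dataclass
class FittedScorer:
    """Fitted patch scorer exposing a signed decision value per embedding."""

    model: object
    config: ClassifierConfig
    dim: int
    train_patient_ids: frozenset = field(default_factory=frozenset)

    def signed_score(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        if vectors.shape[1] != self.dim:
            raise ValueError(
                f"embedding dim {vectors.shape[1]} does not match training dim {self.dim}"
            )
        return np.asarray(self.model.decision_function(vectors), dtype=float)


def train(
    embeddings: pd.DataFrame,
    manifest: Manifest,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> FittedScorer:
    """Fit the patch classifier on embeddings of pancreas/SI patients only."""
    pids = embeddings["patient_id"].astype(str)
    origins = pids.map(manifest.origin_of)
    bad = sorted(set(pids[~origins.isin(BINARY_ORIGINS)]))
    if bad:
        raise ValueError(f"training embeddings include non-binary patients: {bad}")
    y = (origins == config.positive_class).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class; need both origins")
    X = feature_matrix(embeddings)
    model = _build_model(config, seed)
    model.fit(X, y)
    return FittedScorer(model, config, X.shape[1], frozenset(pids.unique()))


def score_patches(scorer: FittedScorer, embeddings: pd.DataFrame) -> pd.DataFrame:
    """Score each patch; sign > 0 means small intestine, <= 0 pancreas."""
    scores = scorer.signed_score(feature_matrix(embeddings))
    out = embeddings[["patient_id", "specimen_id", "slide_id", "x", "y", "size_px"]].copy()
    out["signed_score"] = scores
    out["predicted_label"] = np.where(scores > 0, SMALL_INTESTINE, PANCREAS)
    return out


def majority_vote(scores) -> str:
    """Patient-level label from patch scores.

    The class with strictly more patch votes wins; a tie falls back to the
    sign of the summed scores, and a summed score of exactly zero resolves to
    pancreas (logged).
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("majority_vote needs at least one patch score")
    votes_si = int(np.sum(s > 0))
    votes_pa = int(np.sum(s < 0))
    if votes_si != votes_pa:
        return SMALL_INTESTINE if votes_si > votes_pa else PANCREAS
    total = float(s.sum())
    if total > 0:
        return SMALL_INTESTINE
    if total == 0:
        logger.info("majority_vote: exact tie with zero summed score; returning pancreas")
    return PANCREAS
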