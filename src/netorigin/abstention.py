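"""Confidence-calibrated abstention on summed signed patch scores.

Each patient is reduced to the sum of their patches' signed decision values.
Given calibration sums for pancreas / small-intestine patients and for ``o``
patients of other origin, a pair of thresholds is chosen for each
``i in 0..o`` such that exactly ``i`` of the other-origin sums fall inside
the closed interval while the number of in-class (pancreas + SI) sums inside
is minimized.  The ratio ``c = i/o`` acts as a confidence parameter: the
fraction of other-origin calibration patients the thresholds capture as
"uncertain".  A patient whose sum falls inside the interval is labeled
uncertain; below the lower threshold pancreas; above the upper one small
intestine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PANCREAS, SMALL_INTESTINE

UNCERTAIN = "uncertain"

#: how thresholds are placed relative to the included other-origin sums:
#: "none"     — exactly at the extreme included sums (tightest interval);
#: "midpoint" — pushed halfway toward the nearest excluded calibration sum on
#:              each side, which never changes any calibration count but
#:              leaves margin for unseen patients.
PADDINGS = ("none", "midpoint")


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    sum_signed: float
    n_patches: int

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if not np.isfinite(self.sum_signed):
            raise ValueError("sum_signed must be finite")


def patient_sum(scores, patient_id: str = "") -> PatientScore:
    """Sum a patient's signed patch scores into a :class:`PatientScore`."""
    if isinstance(scores, pd.DataFrame):
        scores = scores["signed_score"]
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("patient_sum needs at least one patch score")
    return PatientScore(patient_id, float(s.sum()), int(s.size))


@dataclass(frozen=True)
class ThresholdPair:
    lower: float
    upper: float
    i: int
    o: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")
        if not 0 <= self.i <= self.o:
            raise ValueError("need 0 <= i <= o")

    @property
    def confidence(self) -> float:
        return self.i / self.o if self.o else 0.0

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "i": self.i,
            "o": self.o,
            "confidence": self.confidence,
        }


@dataclass
class CalibrationSet:
    pancreas_sums: np.ndarray
    si_sums: np.ndarray
    other_sums: np.ndarray

    def __post_init__(self) -> None:
        self.pancreas_sums = np.asarray(self.pancreas_sums, dtype=float)
        self.si_sums = np.asarray(self.si_sums, dtype=float)
        self.other_sums = np.asarray(self.other_sums, dtype=float)
        for arr in (self.pancreas_sums, self.si_sums, self.other_sums):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("calibration sums must be finite")

    @property
    def in_class_sums(self) -> np.ndarray:
        return np.concatenate([self.pancreas_sums, self.si_sums])

    @property
    def o(self) -> int:
        return int(self.other_sums.size)


def _count_in(values: np.ndarray, lo: float, hi: float) -> int:
    return int(np.sum((values >= lo) & (values <= hi)))


def determine_thresholds(
    cal: CalibrationSet,
    i: int,
    contain_zero: bool = True,
    padding: str = "none",
) -> ThresholdPair:
    """Pick the threshold pair capturing exactly ``i`` other-origin sums.

    Because any interval's captured other-origin sums are contiguous in
    sorted order, candidates are the ``o - i + 1`` contiguous windows of
    ``i`` sorted other sums.  With ``contain_zero`` (default) a window's
    interval is anchored to the decision boundary — it is extended to include
    0 and discarded if the extension would capture extra other sums.  Among
    admissible candidates the winner minimizes, in order: in-class sums
    inside, the largest absolute endpoint, interval width, distance of the
    midpoint from 0.  The second criterion keeps equally good intervals
    nested as ``i`` grows (it favors the ``i`` other sums closest to the
    boundary), so the uncertain region only expands with the confidence
    parameter.

    ``i = 0`` degenerates to ``lower = upper = 0`` so that confidence 0
    reproduces the plain binary classifier on every patient with a nonzero
    sum.
    """
    if padding not in PADDINGS:
        raise ValueError(f"padding must be one of {PADDINGS}")
    o = cal.o
    if i > o:
        raise ValueError(f"i={i} exceeds the number of other-origin sums o={o}")
    if i < 0:
        raise ValueError("i must be >= 0")
    if i == 0:
        return ThresholdPair(0.0, 0.0, 0, o)

    others = np.sort(cal.other_sums)
    in_class = cal.in_class_sums
    best = None
    best_key = None
    for k in range(o - i + 1):
        lo, hi = float(others[k]), float(others[k + i - 1])
        if contain_zero:
            lo, hi = min(lo, 0.0), max(hi, 0.0)
            if _count_in(others, lo, hi) != i:
                continue
        key = (_count_in(in_class, lo, hi), max(abs(lo), abs(hi)), hi - lo, abs((lo + hi) / 2.0))
        if best_key is None or key < best_key:
            best, best_key = (lo, hi), key
    if best is None:
        raise ValueError(
            f"no admissible interval captures exactly i={i} other-origin sums "
            "under the contain-zero constraint"
        )
    lo, hi = best
    if padding == "midpoint":
        lo, hi = _pad_midpoint(lo, hi, np.concatenate([others, in_class]))
    return ThresholdPair(lo, hi, i, o)


def _pad_midpoint(lo: float, hi: float, pool: np.ndarray) -> tuple[float, float]:
    below = pool[pool < lo]
    above = pool[pool > hi]
    if below.size:
        lo = (lo + float(below.max())) / 2.0
    if above.size:
        hi = (hi + float(above.min())) / 2.0
    return lo, hi


def classify_with_abstention(score: PatientScore | float, thr: ThresholdPair) -> str:
    """Three-way label from a patient's summed score and a threshold pair."""
    s = score.sum_signed if isinstance(score, PatientScore) else float(score)
    if thr.lower <= s <= thr.upper:
        return UNCERTAIN
    return PANCREAS if s < thr.lower else SMALL_INTESTINE


def sweep_confidence(
    cal: CalibrationSet,
    contain_zero: bool = True,
    padding: str = "none",
) -> list[ThresholdPair]:
    """Threshold pairs for every ``i = 0..o`` (confidences 0, 1/o, ..., 1)."""
    return [
        determine_thresholds(cal, i, contain_zero=contain_zero, padding=padding)
        for i in range(cal.o + 1)
    ]
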