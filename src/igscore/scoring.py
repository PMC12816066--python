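"""Semi-quantitative grading and the 0–15 immunologic gingival (IG) score.

Each of the five markers is graded 0–3 (no / mild / moderate / severe
infiltrate) in the area of interest with the most intense staining; the
final per-marker grade is the one at least two of three observers agree on
(three-way disagreement triggers re-examination); the IG total is the sum
of the five grades and is thresholded to classify a patient.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MARKERS, CohortConfig, GradeThresholds

HEALTHY_LIKE = "healthy-like"
PERIODONTITIS_LIKE = "periodontitis-like"


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class AOIResult:
    """Axis-aligned window of maximal positive-cell density."""

    row: int
    col: int
    window_px: int
    count: int
    local_density: float  # cells/mm²


@dataclass
class IGScore:
    patient_id: str
    grades: dict[str, int]
    reexamined: set[str] = field(default_factory=set)
    classification: str | None = None

    def __post_init__(self) -> None:
        for marker, g in self.grades.items():
            if not 0 <= int(g) <= 3:
                raise ValueError(f"grade for {marker} outside 0..3")
        if not self.reexamined <= set(self.grades):
            raise ValueError("reexamined markers must belong to the panel")

    @property
    def total(self) -> int:
        return total_ig(list(self.grades.values()))


def select_aoi(
    points: np.ndarray | Sequence[tuple[float, float]],
    shape: tuple[int, int],
    window_um: float,
    pixel_size_um: float,
    tissue_mask: np.ndarray | None = None,
) -> AOIResult:
    """Find the window (square, ``window_um`` per side) with the highest
    positive-cell density.

    ``points`` are (row, col) pixel centroids.  All fully-inside window
    positions are scanned exactly via an integral image of the binned
    counts; ties break toward the smallest (row, col).
    """
    h, w = shape
    win = int(round(window_um / pixel_size_um))
    if win <= 0 or win > h or win > w:
        raise ValueError("window must be positive and smaller than the tissue extent")
    if tissue_mask is not None and not np.asarray(tissue_mask, bool).any():
        raise DegenerateGeometryError("no tissue")
    counts = np.zeros((h, w), dtype=np.int64)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts):
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        np.add.at(counts, (rr, cc), 1)
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = counts.cumsum(0).cumsum(1)
    sums = (
        integral[win:, win:]
        - integral[:-win, win:]
        - integral[win:, :-win]
        + integral[:-win, :-win]
    )
    best_flat = int(np.argmax(sums))  # first occurrence = smallest (row, col)
    r0, c0 = divmod(best_flat, sums.shape[1])
    count = int(sums[r0, c0])
    area_mm2 = (win * pixel_size_um) ** 2 / 1e6
    return AOIResult(row=r0, col=c0, window_px=win, count=count, local_density=count / area_mm2)


def grade_from_density(local_density: float, cutpoints: Sequence[float]) -> int:
    """Map a positive-cell density to a 0–3 grade using left-closed cut-point
    intervals: density < c1 → 0, [c1, c2) → 1, [c2, c3) → 2, ≥ c3 → 3."""
    if local_density < 0:
        raise ValueError("density must be nonnegative")
    c1, c2, c3 = cutpoints
    if not 0 < c1 < c2 < c3:
        raise ValueError("cutpoints must be increasing and positive")
    return int(np.searchsorted([c1, c2, c3], local_density, side="right"))


def consensus(observer_grades: Sequence[int]) -> tuple[int, bool]:
    """Consensus of exactly three observer grades.

    If at least two agree, that grade wins and no re-examination is needed.
    If all three differ, the slide is flagged for re-examination and the
    median stands in for the human re-read (logged via the flag).
    """
    grades = [int(g) for g in observer_grades]
    if len(grades) != 3:
        raise ValueError("consensus requires exactly three observer grades")
    if any(not 0 <= g <= 3 for g in grades):
        raise ValueError("grades must lie in 0..3")
    for g in set(grades):
        if grades.count(g) >= 2:
            return g, False
    return int(np.median(grades)), True


def total_ig(grades: Sequence[int]) -> int:
    """IG total: arithmetic sum of the five per-marker grades (0–15)."""
    if len(grades) != 5:
        raise ValueError("the IG panel has exactly five markers")
    if any(not 0 <= int(g) <= 3 for g in grades):
        raise ValueError("grades must lie in 0..3")
    return int(sum(int(g) for g in grades))


def classify_patient(total: int, cutoff: int) -> str:
    """Label a patient from the IG total: score ≥ cut-off is disease-positive
    (the boundary counts as positive, limiting false negatives)."""
    if not 0 <= cutoff <= 15:
        raise ValueError("cutoff must lie in 0..15")
    return PERIODONTITIS_LIKE if total >= cutoff else HEALTHY_LIKE


# ---------------------------------------------------------------------------
# cohort-level scoring paths
# ---------------------------------------------------------------------------

def score_from_observer_grades(
    patient_id: str, observer_grades: Mapping[str, Sequence[int]]
) -> IGScore:
    """Consensus-score one patient from per-marker observer grade triplets."""
    grades: dict[str, int] = {}
    reexamined: set[str] = set()
    for marker, triplet in observer_grades.items():
        g, flag = consensus(triplet)
        grades[marker] = g
        if flag:
            reexamined.add(marker)
    return IGScore(patient_id=patient_id, grades=grades, reexamined=reexamined)


def score_cohort_observers(
    cohort, config: CohortConfig, rng: np.random.Generator
) -> list[IGScore]:
    """Simulate three blinded observers per marker-section and apply the
    consensus rule across a whole cohort."""
    from .synthetic import simulate_observers

    scores = []
    for patient in cohort:
        triplets = {
            m: simulate_observers(patient.true_grade[m], 3, config.observer_noise, rng)
            for m in config.markers
        }
        scores.append(score_from_observer_grades(patient.patient_id, triplets))
    return scores


def score_from_quantifications(
    quants: Sequence, thresholds: GradeThresholds
) -> list[IGScore]:
    """Grade patients from quantitative measurements (density → grade)."""
    per_patient: dict[str, dict[str, int]] = {}
    for q in quants:
        per_patient.setdefault(q.patient_id, {})[q.marker] = grade_from_density(
            q.density_positive, thresholds[q.marker]
        )
    return [IGScore(patient_id=pid, grades=g) for pid, g in per_patient.items()]


def scores_to_frame(scores: Sequence[IGScore], markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"patient_id": s.patient_id}
        for m in markers:
            row[f"grade_{m}"] = s.grades[m]
        row["reexamined"] = ";".join(sorted(s.reexamined))
        row["ig_total"] = s.total
        if s.classification is not None:
            row["classification"] = s.classification
        rows.append(row)
    return pd.DataFrame(rows)
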