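"""Mark classification (TP / FP / suppressed) and the descriptive
detection metrics: point sensitivity, event sensitivity and scene
specificity.

Scoring rules
-------------
* A mark hits a hazard area iff its Euclidean distance from the centre
  is at most the radius (boundary inclusive).
* If a mark lies inside several overlapping areas it is assigned to the
  area whose centre is nearest (ties broken by lowest hazard_point_id).
* Among all marks assigned to one hazard point, the highest-rated one is
  the TP (ties broken by earliest entry order); the rest are
  *suppressed* and excluded from every downstream count and curve.
* Every other mark — outside all areas, or on a scene without hazard
  points — is an FP.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, UndefinedQuantityError
from .ground_truth import Mark, ObserverResponse, SceneSet, validate

__all__ = [
    "MarkLabel",
    "ScoredMark",
    "ScoringResult",
    "classify_marks",
    "sensitivity_points",
    "sensitivity_events",
    "specificity",
    "scored_marks_to_frame",
    "save_scored_marks",
]


class MarkLabel(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class ScoredMark:
    """One mark with its classification.

    ``matched_hazard_point_id`` is set iff the mark fell inside a hazard
    area (label TP or suppressed).
    """

    mark: Mark
    label: MarkLabel
    matched_hazard_point_id: str | None

    def __post_init__(self) -> None:
        inside = self.label in (MarkLabel.TP, MarkLabel.SUPPRESSED)
        if inside != (self.matched_hazard_point_id is not None):
            raise ContractError(
                "matched_hazard_point_id must be set iff label is "
                "TP/suppressed"
            )


@dataclass(frozen=True)
class ScoringResult:
    """Classification of one observer/session against a scene set."""

    observer_id: str
    session_label: str
    scored_marks: tuple[ScoredMark, ...]

    @property
    def tp_count(self) -> int:
        return len(self.detected_hazard_point_ids)

    @property
    def fp_count(self) -> int:
        return sum(1 for s in self.scored_marks if s.label is MarkLabel.FP)

    @property
    def detected_hazard_point_ids(self) -> frozenset[str]:
        return frozenset(
            s.matched_hazard_point_id
            for s in self.scored_marks
            if s.label is MarkLabel.TP and s.matched_hazard_point_id
        )

    @property
    def marked_scene_ids(self) -> frozenset[str]:
        return frozenset(s.mark.scene_id for s in self.scored_marks)

    def marks_with_label(self, label: MarkLabel) -> tuple[ScoredMark, ...]:
        return tuple(s for s in self.scored_marks if s.label is label)


def classify_marks(
    scene_set: SceneSet,
    response: ObserverResponse,
    *,
    prevalidated: bool = False,
) -> ScoringResult:
    """Label every mark of a response as TP, FP or suppressed.

    The response must validate cleanly against ``scene_set``; set
    ``prevalidated`` to skip the internal check when validation has
    already been performed.
    """
    if not prevalidated:
        report = validate(scene_set, [response])
        if not report.ok:
            raise ContractError(
                "response fails validation: " + "; ".join(report.hard_errors)
            )

    scenes = scene_set.scenes_by_id
    # mark index -> hazard point id it falls inside (nearest-centre rule)
    assignment: dict[int, str] = {}
    per_point: dict[str, list[int]] = {}
    for idx, mark in enumerate(response.marks):
        scene = scenes[mark.scene_id]
        best: tuple[float, str] | None = None
        for area in scene.hazard_areas:
            dist = math.hypot(mark.x - area.center_x, mark.y - area.center_y)
            if dist <= area.radius:
                key = (dist, area.hazard_point_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            assignment[idx] = best[1]
            per_point.setdefault(best[1], []).append(idx)

    # highest rating wins the TP; earliest entry order breaks ties
    tp_indices: set[int] = set()
    for indices in per_point.values():
        winner = max(indices, key=lambda i: (response.marks[i].rating, -i))
        tp_indices.add(winner)

    scored: list[ScoredMark] = []
    for idx, mark in enumerate(response.marks):
        if idx in assignment:
            label = MarkLabel.TP if idx in tp_indices else MarkLabel.SUPPRESSED
            scored.append(ScoredMark(mark, label, assignment[idx]))
        else:
            scored.append(ScoredMark(mark, MarkLabel.FP, None))
    return ScoringResult(
        observer_id=response.observer_id,
        session_label=response.session_label,
        scored_marks=tuple(scored),
    )


def sensitivity_points(result: ScoringResult, scene_set: SceneSet) -> float:
    """Fraction of all hazard points the observer marked (TP)."""
    n_points = scene_set.n_hazard_points
    if n_points == 0:
        raise UndefinedQuantityError(
            "point sensitivity undefined: scene set has no hazard points"
        )
    return len(result.detected_hazard_point_ids) / n_points


def sensitivity_events(result: ScoringResult, scene_set: SceneSet) -> float:
    """Fraction of events detected, where an event counts as detected as
    soon as any one of its hazard points is marked.

    Hazard points without an event are excluded from numerator and
    denominator.
    """
    events = scene_set.events
    if not events:
        raise UndefinedQuantityError(
            "event sensitivity undefined: scene set has no events"
        )
    detected = result.detected_hazard_point_ids
    hit = sum(
        1 for points in events.values() if any(p in detected for p in points)
    )
    return hit / len(events)


def specificity(result: ScoringResult, scene_set: SceneSet) -> float:
    """Fraction of hazard-free scenes left entirely unmarked.

    A hazard-free scene is identified "correctly" iff the observer placed
    zero marks on it; any mark on such a scene (necessarily an FP) makes
    it incorrect.
    """
    normal = scene_set.normal_scene_ids
    if not normal:
        raise UndefinedQuantityError(
            "specificity undefined: scene set has no hazard-free scenes"
        )
    marked = result.marked_scene_ids
    correct = sum(1 for sid in normal if sid not in marked)
    return correct / len(normal)


# ---------------------------------------------------------------------
# Scored-mark CSV export
# ---------------------------------------------------------------------

SCORED_COLUMNS = [
    "observer_id",
    "session_label",
    "scene_id",
    "x",
    "y",
    "rating",
    "label",
    "matched_hazard_point_id",
]


def scored_marks_to_frame(results: Iterable[ScoringResult]) -> pd.DataFrame:
    rows = [
        (
            r.observer_id,
            r.session_label,
            s.mark.scene_id,
            s.mark.x,
            s.mark.y,
            s.mark.rating,
            s.label.value,
            s.matched_hazard_point_id or "",
        )
        for r in results
        for s in r.scored_marks
    ]
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def save_scored_marks(
    results: Sequence[ScoringResult], path: str | Path
) -> None:
    scored_marks_to_frame(results).to_csv(path, index=False)
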