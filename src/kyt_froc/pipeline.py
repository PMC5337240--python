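"""End-to-end convenience layer: validate, score and reduce a whole
study to per-observer metrics and group-average curves."""
from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .afroc import AFROCCurve, average_curves, observer_curve, observer_fom
from .errors import UndefinedQuantityError, ValidationError
from .ground_truth import ObserverResponse, SceneSet, validate
from .scoring import (
    ScoringResult,
    classify_marks,
    sensitivity_events,
    sensitivity_points,
    specificity,
)

__all__ = ["score_study", "group_average_curves", "METRIC_COLUMNS"]

METRIC_COLUMNS = [
    "observer_id",
    "group_label",
    "session_label",
    "fom",
    "sensitivity_points",
    "sensitivity_events",
    "specificity",
]


def score_study(
    scene_set: SceneSet,
    responses: Sequence[ObserverResponse],
    variant: str = "normal_only",
) -> tuple[list[ScoringResult], pd.DataFrame]:
    """Validate and score every response; return the scoring results and
    a per-observer metrics table (fractions, unrounded).

    Metrics whose denominator the scene set lacks (e.g. event
    sensitivity without events) are reported as NaN.
    """
    report = validate(scene_set, responses)
    if not report.ok:
        raise ValidationError(
            "responses fail validation:\n" + "\n".join(report.hard_errors)
        )
    results: list[ScoringResult] = []
    rows: list[dict] = []
    for resp in responses:
        result = classify_marks(scene_set, resp, prevalidated=True)
        results.append(result)
        row: dict = {
            "observer_id": resp.observer_id,
            "group_label": resp.group_label,
            "session_label": resp.session_label,
            "fom": observer_fom(result, scene_set, variant),
        }
        for name, fn in (
            ("sensitivity_points", sensitivity_points),
            ("sensitivity_events", sensitivity_events),
            ("specificity", specificity),
        ):
            try:
                row[name] = fn(result, scene_set)
            except UndefinedQuantityError:
                row[name] = math.nan
        rows.append(row)
    return results, pd.DataFrame(rows, columns=METRIC_COLUMNS)


def group_average_curves(
    scene_set: SceneSet,
    responses: Sequence[ObserverResponse],
    results: Sequence[ScoringResult],
    variant: str = "normal_only",
    grid_size: int = 100,
) -> dict[str, AFROCCurve]:
    """Average AFROC curve per (group_label, session_label)."""
    by_group: dict[str, list[AFROCCurve]] = {}
    for resp, result in zip(responses, results):
        label = resp.group_label
        if resp.session_label:
            label = f"{resp.group_label}/{resp.session_label}"
        by_group.setdefault(label, []).append(
            observer_curve(result, scene_set, variant)
        )
    return {
        label: average_curves(curves, grid_size)
        for label, curves in by_group.items()
    }
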