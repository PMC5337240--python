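"""Reference per-observer results shipped with the package.

The before/after training comparison that motivated this package's
group-summary and paired-test machinery was published only as a table of
per-observer figures: six radiography students (S1-S6) each read the
same 53-scene hazard-prediction set twice, five months apart, with
patient-safety training in between. The table below carries their
figures of merit, point sensitivities (% of 42 hazard points) and scene
specificities (% of 27 hazard-free scenes) per session, and is used by
the examples, the acceptance script and the tests to exercise the
group-arithmetic and paired-test layers on real numbers.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["rt_student_results"]

_RT_STUDENT_ROWS = [
    # observer, fom_before, fom_after, sens_before, sens_after, spec_before, spec_after
    ("S1", 0.713, 0.799, 45.2, 54.8, 100.0, 100.0),
    ("S2", 0.729, 0.788, 57.1, 66.7, 81.5, 88.9),
    ("S3", 0.743, 0.764, 57.1, 78.6, 85.2, 66.7),
    ("S4", 0.707, 0.751, 47.6, 59.5, 85.2, 88.9),
    ("S5", 0.746, 0.756, 57.1, 61.9, 81.5, 88.9),
    ("S6", 0.751, 0.683, 66.7, 61.9, 88.9, 51.9),
]


def rt_student_results() -> pd.DataFrame:
    """Published per-observer results of the six-student before/after
    hazard-prediction study.

    Returns a DataFrame with columns ``observer_id``, ``fom_before``,
    ``fom_after``, ``sensitivity_before``, ``sensitivity_after``,
    ``specificity_before``, ``specificity_after`` (sensitivity and
    specificity in percent).
    """
    return pd.DataFrame(
        _RT_STUDENT_ROWS,
        columns=[
            "observer_id",
            "fom_before",
            "fom_after",
            "sensitivity_before",
            "sensitivity_after",
            "specificity_before",
            "specificity_after",
        ],
    )
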