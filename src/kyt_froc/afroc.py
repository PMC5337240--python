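"""AFROC curves and the Wilcoxon-type figure of merit (FOM).

A scored free-response study reduces, per observer, to *rating data*:

* for every hazard point, the rating of its TP mark (absent if the
  point went undetected), and
* for every FP-contributing scene, the highest FP rating placed on it
  (absent if the scene received no FP).

The figure of merit is the two-sample Wilcoxon statistic on these two
collections,

    theta = (1 / (N_L * N_S)) * sum_{l, s} psi(r_l, m_s)

with ``psi = 1`` if ``r_l > m_s``, ``0.5`` if ``r_l = m_s`` (both
finite) and ``0`` otherwise. Undetected hazard points and unmarked
scenes enter with rating ``-inf``; the (undetected, unmarked) pair
scores 0, so an observer who marks nothing scores ``theta = 0`` while a
perfect observer (every point detected, no FPs) scores ``theta = 1``.
``theta`` equals the trapezoidal area under the empirical AFROC curve
(LLF vs. FPF, extended to (1, 1)) whenever every hazard point and every
FP-contributing scene has a finite rating; with absent ratings the
Wilcoxon sum is the definition of record and the (1, 1)-extended
polyline is reported for display only.

Two FOM variants are provided: ``normal_only`` (FP maxima taken from
hazard-free scenes only — the default, matching the standard free-
response figure of merit) and ``all_scenes`` (FPs on hazardous scenes
count too).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedQuantityError
from .ground_truth import SceneSet
from .scoring import MarkLabel, ScoringResult

__all__ = [
    "RatingData",
    "AFROCPoint",
    "AFROCCurve",
    "extract_rating_data",
    "compute_fom",
    "afroc_curve",
    "average_curves",
    "observer_fom",
    "observer_curve",
    "curve_to_frame",
    "FOM_VARIANTS",
]

FOM_VARIANTS = ("normal_only", "all_scenes")


@dataclass(frozen=True)
class RatingData:
    """Sufficient statistic of one scored response for the FOM.

    ``lesion_ratings`` maps hazard_point_id -> TP rating (absent key =
    undetected point). ``normal_fp_max`` maps scene_id -> highest FP
    rating (absent key = no FP on that scene); which scenes may appear
    depends on ``variant``.
    """

    lesion_ratings: Mapping[str, float]
    normal_fp_max: Mapping[str, float]
    variant: str = "normal_only"

    def __post_init__(self) -> None:
        if self.variant not in FOM_VARIANTS:
            raise ContractError(
                f"unknown FOM variant {self.variant!r}; "
                f"expected one of {FOM_VARIANTS}"
            )
        for name, mapping in (
            ("lesion_ratings", self.lesion_ratings),
            ("normal_fp_max", self.normal_fp_max),
        ):
            for key, r in mapping.items():
                if not (0.0 < r <= 1.0):
                    raise ContractError(
                        f"{name}[{key!r}] = {r} outside (0, 1]"
                    )


def extract_rating_data(
    scoring_result: ScoringResult,
    scene_set: SceneSet,
    variant: str = "normal_only",
) -> RatingData:
    """Reduce a scoring result to its per-point / per-scene ratings.

    Suppressed marks never contribute. For ``normal_only`` FPs on
    hazardous scenes are discarded; for ``all_scenes`` every scene may
    contribute its FP maximum.
    """
    if variant not in FOM_VARIANTS:
        raise ContractError(f"unknown FOM variant {variant!r}")
    known_points = scene_set.hazard_areas_by_id
    scenes = scene_set.scenes_by_id
    lesion: dict[str, float] = {}
    for s in scoring_result.marks_with_label(MarkLabel.TP):
        pid = s.matched_hazard_point_id
        if pid not in known_points:
            raise ContractError(
                f"scoring result references hazard point {pid!r} absent "
                "from the scene set"
            )
        lesion[pid] = s.mark.rating
    fp_max: dict[str, float] = {}
    for s in scoring_result.marks_with_label(MarkLabel.FP):
        sid = s.mark.scene_id
        if sid not in scenes:
            raise ContractError(
                f"scoring result references scene {sid!r} absent from the "
                "scene set"
            )
        if variant == "normal_only" and scenes[sid].has_hazard:
            continue
        fp_max[sid] = max(fp_max.get(sid, 0.0), s.mark.rating)
    return RatingData(lesion, fp_max, variant)


def _rating_arrays(
    rating_data: RatingData, n_lesions: int, n_fp_scenes: int
) -> tuple[np.ndarray, np.ndarray]:
    if n_lesions < 1 or n_fp_scenes < 1:
        raise UndefinedQuantityError(
            "FOM undefined for zero hazard points or zero FP-eligible scenes"
        )
    if len(rating_data.lesion_ratings) > n_lesions:
        raise ContractError(
            f"{len(rating_data.lesion_ratings)} lesion ratings exceed "
            f"n_lesions = {n_lesions}"
        )
    if len(rating_data.normal_fp_max) > n_fp_scenes:
        raise ContractError(
            f"{len(rating_data.normal_fp_max)} scene FP maxima exceed "
            f"n_fp_scenes = {n_fp_scenes}"
        )
    r = np.full(n_lesions, -np.inf)
    r[: len(rating_data.lesion_ratings)] = sorted(
        rating_data.lesion_ratings.values()
    )
    m = np.full(n_fp_scenes, -np.inf)
    m[: len(rating_data.normal_fp_max)] = sorted(
        rating_data.normal_fp_max.values()
    )
    return r, m


def compute_fom(
    rating_data: RatingData, n_lesions: int, n_fp_scenes: int
) -> float:
    """Wilcoxon figure of merit over all (hazard point, scene) pairs.

    ``n_lesions`` / ``n_fp_scenes`` are the *totals* in the study
    (detected or not, marked or not); absent entries in ``rating_data``
    enter as ``-inf``.
    """
    r, m = _rating_arrays(rating_data, n_lesions, n_fp_scenes)
    rr = r[:, None]
    mm = m[None, :]
    wins = (rr > mm).astype(float)
    ties = 0.5 * (
        (rr == mm) & np.isfinite(rr) & np.isfinite(mm)
    ).astype(float)
    return float((wins + ties).mean())


@dataclass(frozen=True)
class AFROCPoint:
    """One vertex of an AFROC polyline.

    ``threshold`` is NaN for the synthetic (0,0) / (1,1) end points and
    for vertices of an averaged curve.
    """

    threshold: float
    fpf: float
    llf: float


@dataclass(frozen=True)
class AFROCCurve:
    """Empirical AFROC operating points plus the authoritative area.

    ``area`` is the Wilcoxon statistic (for observer curves) or the
    trapezoidal area of the averaged polyline (for group-average
    curves); the polyline itself — prepended with (0,0) and extended to
    (1,1) — is a display object.
    """

    points: tuple[AFROCPoint, ...]
    area: float

    @property
    def fpf(self) -> np.ndarray:
        return np.array([p.fpf for p in self.points])

    @property
    def llf(self) -> np.ndarray:
        return np.array([p.llf for p in self.points])

    def trapezoid_area(self) -> float:
        """Trapezoidal integral of the display polyline; equals ``area``
        when every rating is finite (no undetected points / unmarked
        scenes)."""
        return float(np.trapezoid(self.llf, self.fpf))


def afroc_curve(
    rating_data: RatingData, n_lesions: int, n_fp_scenes: int
) -> AFROCCurve:
    """Empirical AFROC curve: one operating point per distinct rating.

    Thresholds sweep the distinct finite ratings in descending order;
    at threshold t, FPF is the fraction of FP-eligible scenes whose max
    FP rating is >= t and LLF the fraction of hazard points whose TP
    rating is >= t.
    """
    r, m = _rating_arrays(rating_data, n_lesions, n_fp_scenes)
    thresholds = sorted(
        {v for v in np.concatenate([r, m]) if math.isfinite(v)}, reverse=True
    )
    points = [AFROCPoint(math.nan, 0.0, 0.0)]
    for t in thresholds:
        points.append(
            AFROCPoint(
                threshold=t,
                fpf=float((m >= t).mean()),
                llf=float((r >= t).mean()),
            )
        )
    points.append(AFROCPoint(math.nan, 1.0, 1.0))
    area = compute_fom(rating_data, n_lesions, n_fp_scenes)
    return AFROCCurve(tuple(points), area)


def _interpolate(curve: AFROCCurve, grid: np.ndarray) -> np.ndarray:
    """Sample the display polyline at the grid FPF values.

    Vertical jumps (duplicate FPF vertices) take their upper LLF value;
    between jumps the polyline is linear. Segments are processed left to
    right so a later segment's left endpoint (the top of a jump) wins at
    shared grid points.
    """
    xs = [p.fpf for p in curve.points]
    ys = [p.llf for p in curve.points]
    out = np.zeros_like(grid, dtype=float)
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if x1 < x0:
            raise ContractError("AFROC polyline has decreasing FPF")
        if x1 == x0:
            continue
        mask = (grid >= x0) & (grid <= x1)
        out[mask] = y0 + (grid[mask] - x0) * (y1 - y0) / (x1 - x0)
    # a terminal vertical jump ends the curve at (xs[-1], ys[-1])
    out[grid >= xs[-1]] = ys[-1]
    return out


def average_curves(
    curves: Sequence[AFROCCurve], grid_size: int = 100
) -> AFROCCurve:
    """Vertical (reader-averaging) mean of AFROC polylines.

    Each display polyline is sampled at ``grid_size + 1`` evenly spaced
    FPF values on [0, 1] by linear interpolation and the LLF values are
    averaged. The returned curve's ``area`` is the trapezoidal area of
    the averaged polyline — distinct from (and not a substitute for) the
    arithmetic mean of the member FOMs.
    """
    if not curves:
        raise ContractError("average_curves requires at least one curve")
    if grid_size < 1:
        raise ContractError("grid_size must be >= 1")
    grid = np.linspace(0.0, 1.0, grid_size + 1)
    stacked = np.vstack([_interpolate(c, grid) for c in curves])
    mean = stacked.mean(axis=0)
    points = tuple(
        AFROCPoint(math.nan, float(x), float(y)) for x, y in zip(grid, mean)
    )
    return AFROCCurve(points, float(np.trapezoid(mean, grid)))


# ---------------------------------------------------------------------
# Convenience wrappers
# ---------------------------------------------------------------------

def _denominators(
    scene_set: SceneSet, variant: str
) -> tuple[int, int]:
    n_fp = (
        scene_set.n_normal_scenes
        if variant == "normal_only"
        else scene_set.n_scenes
    )
    return scene_set.n_hazard_points, n_fp


def observer_fom(
    scoring_result: ScoringResult,
    scene_set: SceneSet,
    variant: str = "normal_only",
) -> float:
    """FOM of one scored response, using the scene set's denominators."""
    data = extract_rating_data(scoring_result, scene_set, variant)
    return compute_fom(data, *_denominators(scene_set, variant))


def observer_curve(
    scoring_result: ScoringResult,
    scene_set: SceneSet,
    variant: str = "normal_only",
) -> AFROCCurve:
    """AFROC curve of one scored response."""
    data = extract_rating_data(scoring_result, scene_set, variant)
    return afroc_curve(data, *_denominators(scene_set, variant))


def curve_to_frame(curve: AFROCCurve) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.threshold, p.fpf, p.llf) for p in curve.points],
        columns=["threshold", "fpf", "llf"],
    )


def save_curve(curve: AFROCCurve, path: str | Path) -> None:
    curve_to_frame(curve).to_csv(path, index=False)
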