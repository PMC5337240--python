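"""Synthetic scene sets and simulated observers.

Raw mark-rating data from hazard-prediction observer studies is rarely
released, so this module provides (a) a scene-set generator that
reproduces the structural composition of the emulated study — 53 scenes
(26 with hazard points, 27 without), 42 hazard points grouped into 30
events plus 6 event-less "attention lapse" points, 1-3 points per
hazardous scene — with randomized circle geometry, and (b) a simple
stochastic observer: each hazard point is detected independently with
probability ``p_detect`` (mark placed uniformly inside its circle), and
each scene receives a Poisson number of false-positive marks placed
uniformly outside all hazard circles. Ratings are beta-distributed,
affinely mapped into a configurable subinterval of (0, 1] and floored
at 0.01 (the recording scale's lower end).

All operations draw from a single ``numpy`` generator seeded explicitly
and iterate scenes/points in sorted-id order, so outputs are
reproducible bit-for-bit across platforms.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .afroc import observer_fom
from .errors import ContractError, GenerationError
from .ground_truth import (
    EventClass,
    HazardArea,
    Mark,
    ObserverResponse,
    RegionLabel,
    Scene,
    SceneSet,
)
from .scoring import classify_marks

__all__ = [
    "ObserverModel",
    "SceneSetConfig",
    "OracleFOM",
    "generate_scene_set",
    "simulate_response",
    "oracle_fom",
]

_PLACEMENT_RETRIES = 1000

# Event composition of the emulated 26-hazard-scene study: class -> list
# of per-event hazard-point counts (30 events, 36 points), plus 6
# event-less attention-lapse points.
_STUDY_EVENT_SIZES: dict[EventClass, tuple[int, ...]] = {
    EventClass.TUMBLING: (2, 2, 2, 2, 1, 1, 1, 1, 1, 1),
    EventClass.FALLING: (1, 1, 1, 1, 1),
    EventClass.PATIENT_INJURY: (2, 2, 1, 1, 1),
    EventClass.FINGER_CAUGHT: (1, 1, 1, 1),
    EventClass.TUBE_REMOVAL: (1, 1, 1, 1),
    EventClass.DEVICE_DAMAGE: (1, 1),
}
_STUDY_N_LAPSE_POINTS = 6

# Examination-region mix over all 53 scenes.
_STUDY_REGION_MIX: dict[RegionLabel, int] = {
    RegionLabel.HEAD: 4,
    RegionLabel.CHEST: 9,
    RegionLabel.ABDOMEN: 11,
    RegionLabel.PELVIS: 3,
    RegionLabel.UPPER_EXTREMITY: 9,
    RegionLabel.LOWER_EXTREMITY: 11,
    RegionLabel.PATIENT_MOVEMENT: 6,
}


@dataclass(frozen=True)
class SceneSetConfig:
    """Parameters of the scene-set generator.

    With ``study_emulation`` (the default construction via
    :meth:`study`) the exact event/point composition above is laid out
    deterministically and only geometry and region assignment vary with
    the seed. Otherwise each hazard point forms its own single-point
    event with a class drawn uniformly from the non-lapse classes, and
    per-scene point counts are drawn from ``points_per_scene``.
    """

    n_hazard_scenes: int = 26
    n_normal_scenes: int = 27
    points_per_scene: tuple[int, int] = (1, 3)
    width: float = 1200.0
    height: float = 900.0
    radius_range: tuple[float, float] = (40.0, 90.0)
    seed: int = 0
    study_emulation: bool = False

    def __post_init__(self) -> None:
        if self.n_hazard_scenes < 0 or self.n_normal_scenes < 0:
            raise ContractError("scene counts must be non-negative")
        lo, hi = self.points_per_scene
        if not (1 <= lo <= hi):
            raise ContractError("points_per_scene range must be >= 1 and ordered")
        rlo, rhi = self.radius_range
        if not (0 < rlo <= rhi):
            raise ContractError("radius_range must be positive and ordered")
        if 2 * rhi >= min(self.width, self.height):
            raise ContractError("radius_range too large for image dimensions")

    @classmethod
    def study(cls, seed: int = 0, **overrides) -> "SceneSetConfig":
        """The emulated-study preset: 26/27 scenes, 42 points, 30 events."""
        return cls(seed=seed, study_emulation=True, **overrides)


@dataclass(frozen=True)
class ObserverModel:
    """A stochastic free-response observer.

    Parameters
    ----------
    p_detect:
        Probability that a hazard point receives a mark; either one
        global value or a mapping per :class:`EventClass`.
    tp_rating, fp_rating:
        Beta shape parameters (a, b) for TP and FP confidence ratings.
    tp_rating_bounds, fp_rating_bounds:
        Subinterval of (0, 1] the beta draw is mapped into; disjoint
        bounds give perfectly separated ratings. All ratings are floored
        at 0.01.
    fp_rate:
        Mean number of FP marks per scene (Poisson).
    """

    p_detect: float | Mapping[EventClass, float] = 0.55
    tp_rating: tuple[float, float] = (6.0, 2.0)
    tp_rating_bounds: tuple[float, float] = (0.01, 1.0)
    fp_rate: float = 0.14
    fp_rating: tuple[float, float] = (2.0, 5.0)
    fp_rating_bounds: tuple[float, float] = (0.01, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            [self.p_detect]
            if isinstance(self.p_detect, (int, float))
            else list(self.p_detect.values())
        )
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ContractError(f"p_detect {p} outside [0, 1]")
        if self.fp_rate < 0:
            raise ContractError("fp_rate must be >= 0")
        for name, (a, b) in (
            ("tp_rating", self.tp_rating),
            ("fp_rating", self.fp_rating),
        ):
            if a <= 0 or b <= 0:
                raise ContractError(f"{name} beta parameters must be positive")
        for name, (lo, hi) in (
            ("tp_rating_bounds", self.tp_rating_bounds),
            ("fp_rating_bounds", self.fp_rating_bounds),
        ):
            if not (0.0 < lo < hi <= 1.0):
                raise ContractError(
                    f"{name} must satisfy 0 < lo < hi <= 1"
                )

    def detect_probability(self, event_class: EventClass) -> float:
        if isinstance(self.p_detect, (int, float)):
            return float(self.p_detect)
        try:
            return float(self.p_detect[event_class])
        except KeyError:
            raise ContractError(
                f"p_detect mapping lacks event class {event_class.value!r}"
            ) from None


@dataclass(frozen=True)
class OracleFOM:
    """Monte-Carlo estimate of an observer model's expected FOM."""

    mean: float
    std_error: float
    std_dev: float
    n_replicates: int


# ---------------------------------------------------------------------
# Scene-set generation
# ---------------------------------------------------------------------

def _place_circles(
    rng: np.random.Generator,
    n: int,
    config: SceneSetConfig,
) -> list[tuple[float, float, float]]:
    """Rejection-sample ``n`` non-overlapping circles fully inside the
    image bounds."""
    placed: list[tuple[float, float, float]] = []
    rlo, rhi = config.radius_range
    for _ in range(n):
        for _attempt in range(_PLACEMENT_RETRIES):
            r = float(rng.uniform(rlo, rhi))
            cx = float(rng.uniform(r, config.width - r))
            cy = float(rng.uniform(r, config.height - r))
            if all(
                math.hypot(cx - px, cy - py) > r + pr
                for px, py, pr in placed
            ):
                placed.append((cx, cy, r))
                break
        else:
            raise GenerationError(
                f"could not place {n} non-overlapping circles of radius "
                f"{config.radius_range} in a {config.width}x{config.height} "
                "image; enlarge the image or shrink the radii"
            )
    return placed


def _study_scene_items(
    rng: np.random.Generator,
) -> list[list[tuple[str | None, EventClass, int]]]:
    """Deterministic packing of the study's events onto 26 scenes.

    Items are (event_id, event_class, n_points). The six two-point
    events each share a scene with one single-point item (3 points);
    four scenes take two single-point items; sixteen take one. Which
    single-point item lands where is shuffled by the seed.
    """
    two_point: list[tuple[str | None, EventClass, int]] = []
    singles: list[tuple[str | None, EventClass, int]] = []
    eid = 0
    for cls, sizes in _STUDY_EVENT_SIZES.items():
        for size in sizes:
            eid += 1
            item = (f"E{eid:02d}", cls, size)
            (two_point if size == 2 else singles).append(item)
    singles.extend(
        (None, EventClass.ATTENTION_LAPSE, 1)
        for _ in range(_STUDY_N_LAPSE_POINTS)
    )
    order = rng.permutation(len(singles))
    singles = [singles[i] for i in order]
    scenes: list[list[tuple[str | None, EventClass, int]]] = []
    it = iter(singles)
    for event in two_point:  # 6 scenes with 2+1 points
        scenes.append([event, next(it)])
    for _ in range(4):  # 4 scenes with 1+1 points
        scenes.append([next(it), next(it)])
    for item in it:  # 16 scenes with a single point
        scenes.append([item])
    assert len(scenes) == 26
    return scenes


def generate_scene_set(config: SceneSetConfig) -> SceneSet:
    """Generate a synthetic scene set; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_hazard_scenes + config.n_normal_scenes

    if config.study_emulation:
        if (config.n_hazard_scenes, config.n_normal_scenes) != (26, 27):
            raise ContractError(
                "study emulation fixes 26 hazard and 27 normal scenes"
            )
        scene_items = _study_scene_items(rng)
        region_pool = [
            label
            for label, count in _STUDY_REGION_MIX.items()
            for _ in range(count)
        ]
    else:
        lo, hi = config.points_per_scene
        scene_items = []
        eid = 0
        non_lapse = [c for c in EventClass if c is not EventClass.ATTENTION_LAPSE]
        for _ in range(config.n_hazard_scenes):
            k = int(rng.integers(lo, hi + 1))
            items = []
            for _ in range(k):
                eid += 1
                cls = non_lapse[int(rng.integers(len(non_lapse)))]
                items.append((f"E{eid:02d}", cls, 1))
            scene_items.append(items)
        region_pool = [
            list(RegionLabel)[int(rng.integers(len(RegionLabel)))]
            for _ in range(n_total)
        ]

    region_order = rng.permutation(n_total)
    regions = [region_pool[i] for i in region_order]

    scenes: list[Scene] = []
    pid = 0
    for i, items in enumerate(scene_items):
        scene_id = f"H{i + 1:02d}"
        n_points = sum(size for _, _, size in items)
        circles = _place_circles(rng, n_points, config)
        areas: list[HazardArea] = []
        ci = 0
        for event_id, cls, size in items:
            for _ in range(size):
                pid += 1
                cx, cy, r = circles[ci]
                ci += 1
                areas.append(
                    HazardArea(
                        hazard_point_id=f"P{pid:02d}",
                        scene_id=scene_id,
                        center_x=cx,
                        center_y=cy,
                        radius=r,
                        event_id=event_id,
                        event_class=cls,
                    )
                )
        scenes.append(
            Scene(
                scene_id=scene_id,
                width=config.width,
                height=config.height,
                region_label=regions[i],
                hazard_areas=tuple(areas),
            )
        )
    for j in range(config.n_normal_scenes):
        scenes.append(
            Scene(
                scene_id=f"N{j + 1:02d}",
                width=config.width,
                height=config.height,
                region_label=regions[config.n_hazard_scenes + j],
                hazard_areas=(),
            )
        )
    return SceneSet(tuple(scenes))


# ---------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------

def _draw_rating(
    rng: np.random.Generator,
    shape: tuple[float, float],
    bounds: tuple[float, float],
) -> float:
    lo, hi = bounds
    value = lo + float(rng.beta(*shape)) * (hi - lo)
    return min(1.0, max(0.01, value))


def _uniform_in_circle(
    rng: np.random.Generator, area: HazardArea
) -> tuple[float, float]:
    radius = area.radius * math.sqrt(float(rng.random()))
    angle = 2.0 * math.pi * float(rng.random())
    return (
        area.center_x + radius * math.cos(angle),
        area.center_y + radius * math.sin(angle),
    )


def simulate_response(
    scene_set: SceneSet,
    model: ObserverModel,
    *,
    observer_id: str = "sim",
    group_label: str = "simulated",
    session_label: str = "s1",
) -> ObserverResponse:
    """Simulate one observer's marks over a scene set.

    Scenes are visited in sorted scene_id order, hazard points in sorted
    hazard_point_id order; with a fixed model seed the response is
    bit-for-bit reproducible.
    """
    rng = np.random.default_rng(model.seed)
    marks: list[Mark] = []
    for scene in sorted(scene_set.scenes, key=lambda s: s.scene_id):
        for area in sorted(
            scene.hazard_areas, key=lambda a: a.hazard_point_id
        ):
            if rng.random() < model.detect_probability(area.event_class):
                x, y = _uniform_in_circle(rng, area)
                marks.append(
                    Mark(
                        scene_id=scene.scene_id,
                        x=x,
                        y=y,
                        rating=_draw_rating(
                            rng, model.tp_rating, model.tp_rating_bounds
                        ),
                    )
                )
        n_fp = int(rng.poisson(model.fp_rate))
        for _ in range(n_fp):
            for _attempt in range(_PLACEMENT_RETRIES):
                x = float(rng.uniform(0.0, scene.width))
                y = float(rng.uniform(0.0, scene.height))
                if not any(a.contains(x, y) for a in scene.hazard_areas):
                    break
            else:
                raise GenerationError(
                    f"could not place an FP mark outside the hazard circles "
                    f"of scene {scene.scene_id!r}"
                )
            marks.append(
                Mark(
                    scene_id=scene.scene_id,
                    x=x,
                    y=y,
                    rating=_draw_rating(
                        rng, model.fp_rating, model.fp_rating_bounds
                    ),
                )
            )
    return ObserverResponse(
        observer_id=observer_id,
        group_label=group_label,
        session_label=session_label,
        marks=tuple(marks),
    )


def oracle_fom(
    model: ObserverModel,
    scene_set: SceneSet,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    variant: str = "normal_only",
) -> OracleFOM:
    """Brute-force Monte-Carlo estimate of the expected FOM of a model.

    Repeatedly simulates a response, scores it and computes the FOM;
    returns the replicate mean, its standard error, and the replicate
    standard deviation (the scale on which a single simulated observer's
    FOM scatters).
    """
    if n_replicates < 1:
        raise ContractError("n_replicates must be >= 1")
    seed_rng = np.random.default_rng(seed)
    foms = np.empty(n_replicates)
    for i in range(n_replicates):
        rep_model = dataclasses.replace(
            model, seed=int(seed_rng.integers(2**31))
        )
        response = simulate_response(scene_set, rep_model)
        result = classify_marks(scene_set, response, prevalidated=True)
        foms[i] = observer_fom(result, scene_set, variant)
    sd = float(foms.std(ddof=1)) if n_replicates > 1 else 0.0
    return OracleFOM(
        mean=float(foms.mean()),
        std_error=sd / math.sqrt(n_replicates),
        std_dev=sd,
        n_replicates=n_replicates,
    )
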