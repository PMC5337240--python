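"""Scene ground truth and observer mark-rating data, with file I/O.

The data model mirrors a free-response hazard-prediction observer study
(Kiken-Yochi Training, KYT): a *scene set* of workplace photographs, each
scene either containing one or more circular hazard areas ("lesions" in
FROC terms) or none at all, and *observer responses* consisting of
mouse-click marks, each carrying a continuous confidence rating in
(0, 1].

Conventions
-----------
* Coordinates are continuous pixels, origin at the top-left corner,
  x increasing rightward and y downward (mouse-click capture); no
  integer snapping is applied.
* Ratings are accepted at full floating precision within (0, 1]; a
  recording device's granularity (e.g. steps of 0.01) is not enforced.
* Hazard areas are circles only: a mark is *inside* an area iff its
  Euclidean distance from the centre is at most the radius.

File formats
------------
Scene set: JSON — ``{"scenes": [{scene fields..., "hazard_areas":
[{area fields...}]}]}``; see :func:`scene_set_to_dict`.

Responses: CSV with header
``observer_id,group_label,session_label,scene_id,x,y,rating``
(UTF-8, ``.`` decimal separator), one row per mark, rows of one
observer/session contiguous in entry order.
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "EventClass",
    "RegionLabel",
    "HazardArea",
    "Scene",
    "SceneSet",
    "Mark",
    "ObserverResponse",
    "ValidationReport",
    "load_scene_set",
    "save_scene_set",
    "scene_set_to_dict",
    "scene_set_from_dict",
    "load_responses",
    "save_responses",
    "responses_to_frame",
    "validate",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = [
    "observer_id",
    "group_label",
    "session_label",
    "scene_id",
    "x",
    "y",
    "rating",
]


class EventClass(str, enum.Enum):
    """Incident category a hazard point can cause.

    ``ATTENTION_LAPSE`` covers hazard points (staff looking away or
    absent) that are not tied to a concrete incident event and therefore
    carry no ``event_id``.
    """

    TUMBLING = "tumbling"
    FALLING = "falling"
    PATIENT_INJURY = "patient_injury"
    FINGER_CAUGHT = "finger_caught"
    TUBE_REMOVAL = "tube_removal"
    DEVICE_DAMAGE = "device_damage"
    ATTENTION_LAPSE = "attention_lapse"


class RegionLabel(str, enum.Enum):
    """Examination region depicted by a scene."""

    HEAD = "head"
    CHEST = "chest"
    ABDOMEN = "abdomen"
    PELVIS = "pelvis"
    UPPER_EXTREMITY = "upper_extremity"
    LOWER_EXTREMITY = "lower_extremity"
    PATIENT_MOVEMENT = "patient_movement"


@dataclass(frozen=True)
class HazardArea:
    """A circular hazard region within one scene.

    ``event_id`` is ``None`` for hazard points that are not attached to
    a concrete event (event_class ``attention_lapse``).
    """

    hazard_point_id: str
    scene_id: str
    center_x: float
    center_y: float
    radius: float
    event_id: str | None
    event_class: EventClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_class", EventClass(self.event_class))
        if not (self.radius > 0):
            raise ValidationError(
                f"hazard area {self.hazard_point_id!r}: radius must be > 0, "
                f"got {self.radius}"
            )
        if self.center_x < 0 or self.center_y < 0:
            raise ValidationError(
                f"hazard area {self.hazard_point_id!r}: negative centre "
                f"coordinates ({self.center_x}, {self.center_y})"
            )

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive circle membership test."""
        return math.hypot(x - self.center_x, y - self.center_y) <= self.radius


@dataclass(frozen=True)
class Scene:
    """One photographed scene; hazardous iff it owns hazard areas."""

    scene_id: str
    width: float
    height: float
    region_label: RegionLabel
    hazard_areas: tuple[HazardArea, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_label", RegionLabel(self.region_label))
        object.__setattr__(self, "hazard_areas", tuple(self.hazard_areas))
        if not (self.width > 0 and self.height > 0):
            raise ValidationError(
                f"scene {self.scene_id!r}: non-positive dimensions "
                f"{self.width}x{self.height}"
            )
        for area in self.hazard_areas:
            if area.scene_id != self.scene_id:
                raise ValidationError(
                    f"hazard area {area.hazard_point_id!r} claims scene "
                    f"{area.scene_id!r} but is attached to {self.scene_id!r}"
                )
            if (
                area.center_x - area.radius < 0
                or area.center_y - area.radius < 0
                or area.center_x + area.radius > self.width
                or area.center_y + area.radius > self.height
            ):
                raise ValidationError(
                    f"hazard area {area.hazard_point_id!r} extends outside "
                    f"scene {self.scene_id!r} bounds "
                    f"[0,{self.width}]x[0,{self.height}]"
                )

    @property
    def has_hazard(self) -> bool:
        return len(self.hazard_areas) > 0


@dataclass(frozen=True)
class SceneSet:
    """The full ground truth for one observer study."""

    scenes: tuple[Scene, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenes", tuple(self.scenes))
        seen_scenes: set[str] = set()
        seen_points: set[str] = set()
        for scene in self.scenes:
            if scene.scene_id in seen_scenes:
                raise ValidationError(f"duplicate scene_id {scene.scene_id!r}")
            seen_scenes.add(scene.scene_id)
            for area in scene.hazard_areas:
                if area.hazard_point_id in seen_points:
                    raise ValidationError(
                        f"duplicate hazard_point_id {area.hazard_point_id!r}"
                    )
                seen_points.add(area.hazard_point_id)

    # -- derived counts ------------------------------------------------
    @property
    def n_scenes(self) -> int:
        return len(self.scenes)

    @property
    def n_hazard_scenes(self) -> int:
        return sum(1 for s in self.scenes if s.has_hazard)

    @property
    def n_normal_scenes(self) -> int:
        return self.n_scenes - self.n_hazard_scenes

    @property
    def n_hazard_points(self) -> int:
        return sum(len(s.hazard_areas) for s in self.scenes)

    @property
    def n_events(self) -> int:
        return len(self.events)

    # -- lookup helpers ------------------------------------------------
    @property
    def scenes_by_id(self) -> dict[str, Scene]:
        return {s.scene_id: s for s in self.scenes}

    def scene(self, scene_id: str) -> Scene:
        try:
            return self.scenes_by_id[scene_id]
        except KeyError:
            raise KeyError(f"unknown scene_id {scene_id!r}") from None

    @property
    def hazard_areas_by_id(self) -> dict[str, HazardArea]:
        return {
            a.hazard_point_id: a for s in self.scenes for a in s.hazard_areas
        }

    @property
    def events(self) -> dict[str, tuple[str, ...]]:
        """Map event_id -> hazard point ids; points without an event are
        excluded."""
        out: dict[str, list[str]] = {}
        for scene in self.scenes:
            for area in scene.hazard_areas:
                if area.event_id is not None:
                    out.setdefault(area.event_id, []).append(
                        area.hazard_point_id
                    )
        return {k: tuple(v) for k, v in out.items()}

    @property
    def normal_scene_ids(self) -> tuple[str, ...]:
        return tuple(s.scene_id for s in self.scenes if not s.has_hazard)

    def check_emulation_constraints(self) -> None:
        """Enforce the study-emulation constraint that every hazardous
        scene carries one to three hazard points."""
        for scene in self.scenes:
            if scene.has_hazard and not (1 <= len(scene.hazard_areas) <= 3):
                raise ValidationError(
                    f"scene {scene.scene_id!r} has "
                    f"{len(scene.hazard_areas)} hazard areas; emulation "
                    "mode requires 1-3 per hazardous scene"
                )


@dataclass(frozen=True)
class Mark:
    """One localized response: a click position plus a confidence rating
    on the continuous (0, 1] hazard-likelihood scale."""

    scene_id: str
    x: float
    y: float
    rating: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"mark on scene {self.scene_id!r}: non-finite coordinates"
            )
        if not (0.0 < self.rating <= 1.0):
            raise ValidationError(
                f"mark on scene {self.scene_id!r}: rating {self.rating} "
                "outside (0, 1]"
            )


@dataclass(frozen=True)
class ObserverResponse:
    """All marks of one observer in one session, in entry order.

    Entry order is preserved because it breaks rating ties when a single
    hazard point receives several equally rated marks.
    """

    observer_id: str
    group_label: str
    session_label: str
    marks: tuple[Mark, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "marks", tuple(self.marks))

    def marks_on(self, scene_id: str) -> tuple[Mark, ...]:
        return tuple(m for m in self.marks if m.scene_id == scene_id)


# ---------------------------------------------------------------------
# Scene-set JSON I/O
# ---------------------------------------------------------------------

def scene_set_to_dict(scene_set: SceneSet) -> dict:
    return {
        "scenes": [
            {
                "scene_id": s.scene_id,
                "has_hazard": s.has_hazard,
                "width": s.width,
                "height": s.height,
                "region_label": s.region_label.value,
                "hazard_areas": [
                    {
                        "hazard_point_id": a.hazard_point_id,
                        "scene_id": a.scene_id,
                        "center_x": a.center_x,
                        "center_y": a.center_y,
                        "radius": a.radius,
                        "event_id": a.event_id,
                        "event_class": a.event_class.value,
                    }
                    for a in s.hazard_areas
                ],
            }
            for s in scene_set.scenes
        ]
    }


def _require(record: Mapping, key: str, context: str):
    if key not in record:
        raise SchemaError(f"{context}: missing field {key!r}")
    return record[key]


def scene_set_from_dict(data: Mapping) -> SceneSet:
    scenes_raw = _require(data, "scenes", "scene-set file")
    scenes: list[Scene] = []
    for i, s in enumerate(scenes_raw):
        ctx = f"scene record {i}"
        scene_id = str(_require(s, "scene_id", ctx))
        areas: list[HazardArea] = []
        for j, a in enumerate(s.get("hazard_areas", [])):
            actx = f"{ctx} ({scene_id!r}), hazard area {j}"
            try:
                areas.append(
                    HazardArea(
                        hazard_point_id=str(
                            _require(a, "hazard_point_id", actx)
                        ),
                        scene_id=str(_require(a, "scene_id", actx)),
                        center_x=float(_require(a, "center_x", actx)),
                        center_y=float(_require(a, "center_y", actx)),
                        radius=float(_require(a, "radius", actx)),
                        event_id=a.get("event_id"),
                        event_class=EventClass(
                            _require(a, "event_class", actx)
                        ),
                    )
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise SchemaError(f"{actx}: {exc}") from exc
        try:
            scene = Scene(
                scene_id=scene_id,
                width=float(_require(s, "width", ctx)),
                height=float(_require(s, "height", ctx)),
                region_label=RegionLabel(_require(s, "region_label", ctx)),
                hazard_areas=tuple(areas),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{ctx} ({scene_id!r}): {exc}") from exc
        if "has_hazard" in s and bool(s["has_hazard"]) != scene.has_hazard:
            raise ValidationError(
                f"{ctx} ({scene_id!r}): has_hazard flag inconsistent with "
                "hazard_areas"
            )
        scenes.append(scene)
    return SceneSet(tuple(scenes))


def load_scene_set(path: str | Path, *, emulation_mode: bool = False) -> SceneSet:
    """Load a scene-set JSON file.

    With ``emulation_mode`` the 1-3 hazard-points-per-scene constraint of
    the emulated study design is enforced on top of the schema.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    scene_set = scene_set_from_dict(data)
    if emulation_mode:
        scene_set.check_emulation_constraints()
    return scene_set


def save_scene_set(scene_set: SceneSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(scene_set_to_dict(scene_set), indent=2) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------
# Response CSV I/O
# ---------------------------------------------------------------------

def responses_to_frame(responses: Iterable[ObserverResponse]) -> pd.DataFrame:
    rows = [
        (
            r.observer_id,
            r.group_label,
            r.session_label,
            m.scene_id,
            m.x,
            m.y,
            m.rating,
        )
        for r in responses
        for m in r.marks
    ]
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def save_responses(
    responses: Iterable[ObserverResponse], path: str | Path
) -> None:
    """Write the long-format response CSV (one row per mark).

    Observers with zero marks leave no rows; round-tripping therefore
    preserves every mark but drops empty responses.
    """
    responses_to_frame(responses).to_csv(path, index=False)


def load_responses(path: str | Path) -> list[ObserverResponse]:
    """Load a response CSV into per-(observer, session) records.

    Rows are grouped by ``(observer_id, session_label)`` in file order;
    mark order within a group is file order.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            dtype={
                "observer_id": str,
                "group_label": str,
                "session_label": str,
                "scene_id": str,
            },
        )
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    responses: list[ObserverResponse] = []
    marks: list[Mark] = []
    current: tuple[str, str] | None = None
    current_group = ""

    def flush() -> None:
        if current is not None:
            responses.append(
                ObserverResponse(
                    observer_id=current[0],
                    group_label=current_group,
                    session_label=current[1],
                    marks=tuple(marks),
                )
            )

    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        key = (str(row.observer_id), str(row.session_label))
        if key != current:
            flush()
            current = key
            current_group = str(row.group_label)
            marks = []
        elif str(row.group_label) != current_group:
            raise ValidationError(
                f"{path} row {idx}: group_label {row.group_label!r} "
                f"conflicts with {current_group!r} for observer "
                f"{row.observer_id!r}"
            )
        try:
            x = float(row.x)
            y = float(row.y)
            rating = float(row.rating)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path} row {idx}: non-numeric value ({exc})")
        if not (math.isfinite(x) and math.isfinite(y)):
            raise SchemaError(f"{path} row {idx}: non-numeric coordinate")
        if not (0.0 < rating <= 1.0):
            raise ValidationError(
                f"{path} row {idx}: rating {rating} outside (0, 1]"
            )
        marks.append(Mark(scene_id=str(row.scene_id), x=x, y=y, rating=rating))
    flush()
    return responses


# ---------------------------------------------------------------------
# Cross validation
# ---------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of checking responses against a scene set.

    ``hard_errors`` block scoring; ``warnings`` do not.
    """

    hard_errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.hard_errors


def validate(
    scene_set: SceneSet, responses: Sequence[ObserverResponse]
) -> ValidationReport:
    """Check marks against the ground truth.

    Hard errors: a mark referencing an unknown scene, a mark outside the
    image bounds of its scene, and duplicate (observer, session) pairs.
    """
    report = ValidationReport()
    scenes = scene_set.scenes_by_id
    seen: set[tuple[str, str]] = set()
    for resp in responses:
        key = (resp.observer_id, resp.session_label)
        if key in seen:
            report.hard_errors.append(
                f"duplicate observer/session pair {key!r}"
            )
        seen.add(key)
        for i, mark in enumerate(resp.marks):
            where = (
                f"observer {resp.observer_id!r} session "
                f"{resp.session_label!r} mark {i}"
            )
            scene = scenes.get(mark.scene_id)
            if scene is None:
                report.hard_errors.append(
                    f"{where}: unknown scene {mark.scene_id!r}"
                )
                continue
            if not (0 <= mark.x <= scene.width and 0 <= mark.y <= scene.height):
                report.hard_errors.append(
                    f"{where}: position ({mark.x}, {mark.y}) outside scene "
                    f"{mark.scene_id!r} bounds "
                    f"[0,{scene.width}]x[0,{scene.height}]"
                )
    return report
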