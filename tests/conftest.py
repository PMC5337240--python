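"""Shared fixtures: tiny hand-built scene sets and the study-emulation
synthetic set."""
from __future__ import annotations

import pytest

from kyt_froc import (
    EventClass,
    HazardArea,
    Mark,
    ObserverResponse,
    Scene,
    SceneSet,
    SceneSetConfig,
    generate_scene_set,
)


def make_area(
    pid: str,
    scene_id: str,
    cx: float,
    cy: float,
    r: float,
    event_id: str | None = None,
    event_class: EventClass = EventClass.TUMBLING,
) -> HazardArea:
    return HazardArea(
        hazard_point_id=pid,
        scene_id=scene_id,
        center_x=cx,
        center_y=cy,
        radius=r,
        event_id=event_id,
        event_class=event_class,
    )


@pytest.fixture
def tiny_scene_set() -> SceneSet:
    """Two hazardous scenes (3 hazard points, 2 events) + two hazard-free
    scenes, 1000x800 px."""
    return SceneSet(
        (
            Scene(
                scene_id="h1",
                width=1000,
                height=800,
                region_label="chest",
                hazard_areas=(
                    make_area("hp1", "h1", 100, 100, 50, "e1"),
                    make_area(
                        "hp2", "h1", 600, 400, 80, "e1",
                        EventClass.FALLING,
                    ),
                ),
            ),
            Scene(
                scene_id="h2",
                width=1000,
                height=800,
                region_label="abdomen",
                hazard_areas=(
                    make_area(
                        "hp3", "h2", 300, 300, 60, None,
                        EventClass.ATTENTION_LAPSE,
                    ),
                ),
            ),
            Scene(scene_id="n1", width=1000, height=800, region_label="head"),
            Scene(
                scene_id="n2", width=1000, height=800, region_label="pelvis"
            ),
        )
    )


@pytest.fixture(scope="session")
def study_scene_set() -> SceneSet:
    """The 53-scene / 42-point / 30-event study-emulation set."""
    return generate_scene_set(SceneSetConfig.study(seed=7))


def response(marks: list[Mark], **kwargs) -> ObserverResponse:
    defaults = dict(
        observer_id="obs1", group_label="g1", session_label="before"
    )
    defaults.update(kwargs)
    return ObserverResponse(marks=tuple(marks), **defaults)
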