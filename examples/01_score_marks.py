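"""Score free-response marks against circular hazard ground truth.

Builds a four-scene set (two hazardous, two hazard-free), scores one
observer's marks, and prints the per-mark labels and detection metrics.
"""
from kyt_froc import (
    HazardArea,
    Mark,
    ObserverResponse,
    Scene,
    SceneSet,
    classify_marks,
    sensitivity_events,
    sensitivity_points,
    specificity,
)

scene_set = SceneSet((
    Scene("h1", 1000, 800, "chest", (
        HazardArea("hp1", "h1", 100, 100, 50, "e1", "tumbling"),
        HazardArea("hp2", "h1", 600, 400, 80, "e1", "falling"),
    )),
    Scene("h2", 1000, 800, "abdomen", (
        HazardArea("hp3", "h2", 300, 300, 60, None, "attention_lapse"),
    )),
    Scene("n1", 1000, 800, "head"),
    Scene("n2", 1000, 800, "pelvis"),
))

observer = ObserverResponse("reader1", "demo", "session1", (
    Mark("h1", 120, 110, 0.6),   # inside hp1
    Mark("h1", 90, 95, 0.4),     # also inside hp1 -> suppressed
    Mark("h1", 200, 200, 0.3),   # outside every circle -> FP
    Mark("n1", 50, 50, 0.2),     # FP on a hazard-free scene
))

result = classify_marks(scene_set, observer)
for scored in result.scored_marks:
    m = scored.mark
    print(
        f"{m.scene_id} ({m.x:4.0f},{m.y:4.0f}) rating {m.rating:.2f} "
        f"-> {scored.label.value:<10} {scored.matched_hazard_point_id or ''}"
    )
print(f"TP count      : {result.tp_count}  (distinct hazard points hit)")
print(f"FP count      : {result.fp_count}")
print(f"sensitivity   : {sensitivity_points(result, scene_set):.3f}  "
      "(hazard points detected / 3)")
print(f"event sens.   : {sensitivity_events(result, scene_set):.3f}  "
      "(events with any point detected / 1)")
print(f"specificity   : {specificity(result, scene_set):.3f}  "
      "(hazard-free scenes left unmarked / 2)")
# The duplicate mark inside hp1 is suppressed (only the highest-rated
# counts); both FPs hurt specificity only via the marked scene n1.
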