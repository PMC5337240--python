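# Methods

## The observer-study model

A study consists of a *scene set* — scenes of known pixel dimensions,
each carrying zero or more circular hazard areas — and per-observer
*responses*: localized marks, each with a confidence rating on the
continuous (0, 1] scale. Hazard areas may be grouped into *events* (a
potential incident such as a fall that one or several hazard points can
cause); hazard points with no associated event (attention-lapse points)
carry `event_id = None`. Coordinates are continuous pixels, origin
top-left, no snapping; ratings are accepted at full float precision
(the 0.01 granularity of typical collection software is a property of
the instrument, not of the analysis).

## Scoring rules and their edge cases

* **Hit test**: Euclidean distance from the circle centre ≤ radius.
  Boundary-inclusive, because the paper-thin alternative differs only on
  a measure-zero set and exclusivity creates avoidable ambiguity in
  tests with exact geometry.
* **One TP per hazard point**: among all inside-marks of one point the
  highest rating wins; equal ratings are broken by entry order (earliest
  wins) so classification is deterministic. The losers are *suppressed*:
  they are excluded from every downstream count, never converted to FPs.
* **Overlapping areas**: a mark inside several circles is assigned to
  the nearest centre, then lowest hazard-point id. The generator never
  produces overlapping circles; the rule exists so arbitrary ground
  truth is handled deterministically.
* **Specificity**: a hazard-free scene is correct iff it received zero
  marks. This is the only reading under which all attainable
  specificities on a 27-normal-scene set are k/27 (as the published
  percentages are) while FPs on hazardous scenes still exist.
* Reordering marks never changes the counts or detected sets, only
  which member of an exactly-tied duplicate pair is labelled TP versus
  suppressed.

## Figure of merit

The FOM is the two-sample Wilcoxon statistic between the lesion-rating
collection (one entry per hazard point, −∞ if undetected) and the
scene FP-maximum collection (one entry per FP-eligible scene, −∞ if
unmarked); ties at finite ratings score ½, and the (−∞, −∞) pair scores
0. Consequences: a mark-nothing observer scores 0, a perfect observer
scores 1, and θ never exceeds the observer's point sensitivity. The
trapezoidal area under the empirical AFROC polyline extended to (1, 1)
equals θ exactly when every rating is finite (tested on randomized
instances against a brute-force pairwise loop); with absent ratings the
polyline is a display object and θ is the definition of record — the
(1, 1) extension would otherwise credit a no-marks observer with area
0.5. Note that published FOM values computed under the
extended-polyline convention are systematically higher than θ for
imperfect observers; `AFROCCurve.trapezoid_area()` exposes that
convention where comparison is needed.

Two variants control which scenes contribute FP maxima: `normal_only`
(default: hazard-free scenes only, denominator N_S = number of normal
scenes) and `all_scenes`. They agree whenever the observer places no FP
on hazardous scenes.

**Curve averaging** is vertical: each observer polyline is sampled at
`grid_size + 1` (default 101) evenly spaced FPF values — vertical jumps
take their upper LLF value — and LLF is averaged pointwise. The area of
an averaged polyline is its trapezoidal integral; the mean group FOM is
always the arithmetic mean of member FOMs, never that area.

## Group statistics

Group summaries are arithmetic means of per-observer metrics.
Between-group comparisons use the pooled-variance Student t-test
(two-sided; Welch available via `equal_var=False`); repeated-session
comparisons use the paired form (one-sample t on after − before, n − 1
df). Zero-variance data short-circuits to the degenerate limits (t = 0,
p = 1 for equal means; p → 0, flagged, otherwise) instead of producing
NaNs. No multiple-testing correction is applied; the CLI notes when
more than one test was run. Report tables round half-up (away from
zero) — 3 decimals for FOMs, 1 decimal for percentages — because the
published averages this package reproduces (e.g. a mean FOM of 0.7315
printed as 0.732) follow that convention; all CSV outputs stay
unrounded.

## Synthetic data

The generator's study preset reproduces the canonical composition: 26
hazardous + 27 hazard-free scenes; 42 hazard points; 30 events — 10
tumbling (14 points), 5 falling, 5 patient-injury (7 points), 4
finger-caught, 4 tube-removal, 2 device-damage — plus 6 event-less
attention-lapse points; 1–3 points per hazardous scene; examination
regions mixed 4 head / 9 chest / 11 abdomen / 3 pelvis / 9 upper / 11
lower extremity / 6 patient-movement. Event-to-scene packing is
deterministic (six 3-point scenes, four 2-point scenes, sixteen
1-point scenes); the seed randomizes which single-point event lands
where, the region assignment, and the circle geometry (radii uniform in
40–90 px inside a 1200 × 900 px image, placed non-overlapping by
rejection sampling with a bounded retry budget). Image dimensions and
radii are arbitrary plausible values; no analysis result depends on
them.

The observer model detects each hazard point independently with
probability `p_detect` (globally or per event class), placing the mark
uniformly inside the circle, and adds Poisson(`fp_rate`) FP marks per
scene, placed uniformly outside all hazard circles. Ratings are
beta-distributed, affinely mapped into configurable bounds within
(0, 1] and floored at 0.01 (the rating scale's lower end); disjoint
TP/FP bounds give perfectly separated ratings, under which θ equals the
detected fraction exactly. Defaults emulate the published cohort's
operating level: `p_detect` 0.55 (before) / 0.64 (after) matching the
mean point sensitivities of 55.1% / 63.9%, `fp_rate` 0.14 / 0.21 so
that P(no FP on a scene) = e^(−rate) matches the mean specificities of
~87% / ~81%, TP ratings Beta(6, 2), FP ratings Beta(2, 5). Because the
model's detections are independent across points and scenes, simulated
Wilcoxon FOMs at these settings sit near 0.55–0.6 — below published
extended-polyline figures (~0.73) for the reason given above — and the
simulator does not reproduce real readers' within-scene behaviour
("satisfaction of search": having found one hazard in a scene,
real observers tend to miss its others). Passing simulation tests
therefore validates the pipeline's arithmetic and its statistical
behaviour under a known model, not the psychophysics of real readers.

All randomness flows through one explicitly seeded NumPy generator per
operation, with scenes and points visited in sorted-id order, so every
artefact is bit-reproducible across platforms.

## Event vs point sensitivity

Crediting an event when *any* of its points is detected can only help
per event, which yields the guaranteed bound

    event_sensitivity ≥ (1/n_events) Σ_e (detected points of e / points of e).

The stronger ordering "event sensitivity ≥ detected event-bearing
points / total event-bearing points" is **not** an identity: an
observer whose detections concentrate in multi-point events violates it
(detecting exactly both points of each 2-point event in the study
composition gives 6/30 < 12/36; a unit test documents this). For
unclustered observers it holds as a statistical tendency — under
independent detection the expected gap is positive (for the study
composition, E[event sens] − p = 0.2·p(1 − p) at detection probability
p) — and the test suite asserts the guaranteed bound in every run plus
the tendency over a simulated cohort.

## Problem sizes and numerical choices

The identity suite uses 1000 randomized instances with up to 8 lesions
and 8 scenes on a coarse rating grid (so ties actually occur),
asserting agreement to 1e−12. Monte-Carlo FOM recovery uses the full
53-scene set with a 2000-replicate oracle and 200 independent
observers, requiring the observer's θ inside the oracle's ±4 SD band in
≥ 99% of runs. Degenerate inputs raise typed errors
(`UndefinedQuantityError` for zero denominators, `GenerationError` when
circle placement is infeasible, `ContractError` for precondition
violations) rather than returning NaN.

## Known limitations

* Circular hazard areas only; no elliptical/polygonal regions, no
  partial credit.
* Empirical curves only: no binormal or search-model fits, no jackknife
  (multi-reader multi-case) variance components — the t-tests treat
  per-observer FOMs as the unit of analysis.
* The simulator has no within-scene detection correlation and uniform
  per-class detection rates by default; per-event-class `p_detect`
  mappings are supported but defaults are deliberately uniform.
* Scene *images* are out of scope; the package handles geometry and
  ratings only.
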