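# Methods

This note documents the models and procedures implemented in `bach`:
the two-step tracking algorithm, the synthetic tagged-colony simulator
used to exercise it, and the evaluation protocol, together with the
numerical and design choices that were genuinely open.

## The tracking algorithm

The tracker consumes two per-frame streams produced upstream by an
object detector and a fiducial-marker (ArUco-style) reader:

* **shape detections** — axis-aligned bounding boxes with a confidence
  in [0, 1]; only detections whose confidence *strictly exceeds* the
  configured threshold (default 0.5) enter the system;
* **marker detections** — a dictionary ID plus the marker's center
  point in pixels.

Each frame is processed in two consecutive steps.

**Step 1 — association.** Detections are processed in stream order.  A
detection whose box has no positive intersection area with any live
entity's box founds a new entity, which reports identity −1 until a
marker vote arrives.  Otherwise the entity with the largest raw
intersection area (px²) absorbs the detection: its box is replaced and
it is marked *seen*.  Entities already seen in the current frame are
ineligible for further matches, so two detections can never collapse
into one entity; the second one spills over to the next-best entity or
founds a new one.  Overlap is deliberately the raw intersection area,
not IoU — any strictly positive area counts as overlapping, and no
minimum-overlap gate is applied.

**Step 2 — identity voting.** Each marker whose center lies inside at
least one live entity box (closed boxes: the boundary counts) adds one
vote to exactly one entity: among containing boxes, the one whose
center is nearest to the marker center.  Every entity keeps an
insertion-ordered ledger of vote counts per marker ID and reports the
argmax as its identity.  A missed or misread marker therefore never
revokes an established identity, and an entity that stays detected
keeps reporting its identity even across long runs of unread markers.

**Lifecycle.** An entity missed in a frame is retained at its last box
(a "ghost") and re-attached if it is detected again; once its run of
consecutive misses exceeds the *ghost threshold* it is deleted.  With
threshold *g*, an entity last seen at frame *f* is deleted at frame
*f* + *g* + 1 exactly.  The condition presets are 1 frame (0.10 s at
10 fps) for the foraging arena and 5 frames (0.50 s) for the nest,
where ants move more slowly and misses are more often transient.  All
surviving entities — seen or ghost-retained — emit one output record
per frame; ghost rows are flagged `seen=false` so the evaluator can
exclude them.

**Determinism.** Every tie has a fixed resolution: equal overlap and
equal marker distance resolve to the lowest (oldest) entity key; an
exact vote tie resolves to the earliest-inserted marker ID.  Given the
same input ordering the tracker output is byte-identical across runs.
Entity keys are never reused.

## The synthetic colony simulator

The simulator emulates the detection-stream statistics of ~20 tagged
carpenter ants (body length 6.81 ± 0.93 mm, truncated at ±3 σ) walking
in a 170 × 120 mm arena filmed from above at 10 fps for 25 s (250
frames, labelled 0–249) at 12 px/mm on a 4096 × 2160 canvas.  Three
condition presets set the behavioural and noise parameters:

| condition    | speed mean ± sd (mm s⁻¹) | pause prob. | ghost preset |
|--------------|--------------------------|-------------|--------------|
| `nest-ir`    | 1.19 ± 2.20              | 0.60        | 5 frames     |
| `forage-ir`  | 2.44 ± 4.95              | 0.65        | 1 frame      |
| `forage-vis` | 6.71 ± 9.43              | 0.40        | 1 frame      |

### Speed model and its calibration

`speed_mean`/`speed_sd` are the **marginal** per-frame speed moments,
zeros included.  A frame is a pause (speed exactly 0) with probability
`pause_prob`; otherwise speed is drawn from a zero-truncated normal.
The marginal targets have coefficients of variation between 1.4 and
2.0, which no zero-truncated normal can reach on its own (its CV is
bounded below 1), so the zero-inflation carries part of the variance:
the pause probabilities above were chosen per condition to keep the
implied walking-phase CV near 0.9, and the truncated normal's
underlying location and scale are then solved numerically (Powell
hybrid root-finding on the truncated moments) so the marginal mean and
sd equal the configured values exactly in expectation.  Pause
probabilities are also ordered plausibly: ants pause most under
infrared in the foraging arena and least under stressful visible
light.

### Motion model

Positions follow a correlated random walk: per-frame heading
diffusion (wrapped normal, σ = 0.4 rad) applied only while walking — a
paused ant keeps its orientation — with displacement speed/fps along
the heading and reflective arena walls.  Three interaction rules make
the ants solid bodies rather than ghosts passing through one another:

* **hard-core exclusion** — no two centers may come closer than
  3.5 mm (side-by-side body contact); violations are resolved by
  symmetric pairwise push-apart;
* **steps stop at contact** — a step that would cross the exclusion
  distance of a neighbour's position is truncated at contact;
* **avoidance steering** — an ant heading at a neighbour within its
  look-ahead range (8 mm antennation range plus the step length) turns
  to the tangent around the most obstructing neighbour, re-checking a
  few times; an ant hemmed in on all sides turns straight back, or
  freezes for the frame if every direction is blocked.

Avoidance is suspended during **contact-seeking bouts** (entry
probability 0.02 per frame, exit 0.15), during which an ant walks at
its nearest nestmate — the behavioural source of close-proximity
configurations.  The recorded per-frame speed is the behavioural gait
speed drawn by the model; when a step is shortened by contact the
realised displacement is smaller than speed/fps for that frame.

### Appearance and noise channels

* **blur class** from current speed: sharp < 2 ≤ blurry ≤ 5 <
  very_blurry (mm s⁻¹), so fast ants appear blurred;
* **marker visibility** drawn i.i.d. per frame (horizontal / tilted /
  invisible, preset probabilities), forced invisible while grooming
  (a fraction of paused frames) or wall-climbing;
* **detection**: each non-climbing ant's shape is emitted with
  probability 0.90 (moving) / 0.80 (stationary); wall-climbing ants
  are undetectable;
* **merged detections**: non-climbing ants within 7.46 mm are paired
  closest-first; with probability 0.30 a pair is emitted as a single
  union box ("double"), and with probability 0.15 one partner is
  additionally emitted alone ("double plus one");
* **marker reads**: emitted at the ant's (clipped) box center with a
  probability depending on blur × visibility (0.90 for sharp ×
  horizontal down to 0.05 for very blurry × tilted, 0 when
  invisible); a read returns a uniformly drawn wrong dictionary ID
  with probability 0.02.

Each channel (motion, detection, marker, merge) draws from its own
generator spawned from the run seed, with a fixed number of draws per
ant per frame, so changing one parameter — say, raising `p_detect` —
flips individual outcomes without re-randomising anything else.  This
makes monotonicity properties testable at fixed seeds and keeps runs
bitwise reproducible.

The `noise_free_params` configuration switches every channel off
(perfect detection and reads, no merges, misreads, climbs, grooming or
contact-seeking).  Under it the tracker must recover every ant with
its correct identity and zero identity exchanges; this is the
pipeline's end-to-end correctness check.

### What the simulator does not emulate

No pixel images are rendered; detector behaviour is purely
probabilistic, so systematic detector biases (background confusion,
box mis-sizing on partial occlusion) are absent.  Marker visibility is
temporally uncorrelated, whereas real tilt episodes persist across
frames.  Nest-chamber geometry and the inter-area tunnel are not
modelled.  Passing tests on synthetic streams therefore validates the
tracking and scoring logic, not any particular detector's real-world
accuracy.

## Evaluation protocol

Scoring mirrors a frame-sampled human-annotation protocol: by default
only every tenth frame between 60 and 240 (19 frames) is analysed —
the early frames are skipped because real recordings need time for
camera focus to settle — with an `--all-frames` escape hatch.  Per
analysed frame, seen track records are matched one-to-one to
ground-truth ants by greedy nearest-center assignment within a gate of
half a body length (3.4 mm); the true matching rule of a human
annotator is unknowable, so this gate is an explicit stand-in.  Each
ant instance is then scored as *detected*, *identified* (a marker
identity was reported), and *correct* (the identity matches).  For a
merged pair, a matched partner whose partner went unmatched scores as
a "double" — detecting one ant of the two; if both partners matched
(union box plus a solo detection) the pair is a "double plus one" and
both count as detected.

The walking-speed proxy at analysed frame *f* is the Euclidean
distance between an individual's positions at *f* and *f − stride*,
divided by the elapsed time (1 s at the defaults).  The first analysed
frame has no speed and is omitted.  Raw values below 0.75 mm s⁻¹ are
rounded to exactly zero: box centers jitter as the detector re-fits a
box to a resting ant, and that jitter would otherwise masquerade as
locomotion.

Identity-exchange ("swap") episodes are maximal runs of consecutive
frames in which one entity's matched record reports a *different*
ant's identity; each episode carries its duration and the distance
between the two ants involved at onset.  Note that under this
definition a single misread marker on a freshly created entity counts
as a one-frame episode — the definition is purely observational and
does not distinguish causes.

`pearson_chi2` is the plain Pearson χ² test of independence on an r×c
count table (expected counts from the margins, no continuity
correction), provided because detection counts in independent frames
are naturally compared this way.  Model-based analyses (GLMMs,
post-hoc contrasts) are out of scope; the evaluator instead exports
tidy per-instance data for external statistics packages.

## Numerical and formatting choices

* CSV floats carry 3 decimals — sub-pixel precision beyond sensor
  noise is meaningless; headers are validated byte-exactly and
  malformed rows are reported as `file:line`.
* Boxes are closed regions; marker-in-box containment includes the
  boundary; a box touching another along an edge has zero overlap.
* Boxes extending past the canvas are clipped to it (with a warning);
  the truth table records the clipped box but the unclipped center.
* The χ² routine rejects tables with a zero margin rather than
  returning a degenerate statistic.
* Problem sizes in the shipped checks — 250-frame, 20-ant runs; ten
  runs per condition for distributional recovery; 1000 randomized
  frames for the association oracle — were chosen as the smallest
  sizes at which the statistical checks have comfortable power.

## Known limitations

* Greedy largest-overlap association can exchange entities when two
  boxes nearly coincide; the simulator's body exclusion makes this
  impossible for physically plausible configurations, but the
  algorithm itself has no safeguard — which is exactly the failure
  mode the evaluation module is designed to measure.
* The evaluator's nearest-center matching can mis-pair record and
  truth when two ants sit within the gate of the same record; matching
  is distance-only and identity-blind by design.
* The simulator's condition presets reproduce marginal speed moments
  and qualitative noise structure, not any particular empirical
  detection or identification rate.
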