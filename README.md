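# bach — tracking-by-detection for individually tagged insects

`bach` re-implements, as a testable Python library and CLI, a
real-time tracking-by-detection pipeline for groups of ants carrying
ArUco-style fiducial tags, together with a synthetic tagged-colony
simulator and an evaluation harness.  It is aimed at researchers who
study social-insect behaviour with marker-based video tracking and
want the tracking logic — association, identity assignment, entity
lifecycle — separated from cameras and neural-network detectors so it
can be verified, stress-tested and reused.

A camera/detector front-end produces two per-frame streams: candidate
ant bounding boxes with confidences, and decoded marker IDs with
center points.  `bach` consumes these streams (from CSV or any adapter
yielding `(frame, shapes, markers)` tuples) and maintains a set of
tracked entities:

1. **Association** — a detection overlapping no known box becomes a new
   entity with identity −1; otherwise the entity with the largest raw
   box-intersection area *A*(b_det ∩ b_ent) absorbs it and is marked
   seen.  An entity can absorb at most one detection per frame.
2. **Identity voting** — each marker whose center falls inside an
   entity's box adds one vote to that entity's ordered ledger (nearest
   box center wins when boxes overlap); the reported identity is
   argmax_id votes(id), so missed or misread markers never revoke an
   established identity.
3. **Ghost lifecycle** — an entity undetected for more than
   *g* consecutive frames is deleted; until then it is retained at its
   last position.  Presets: *g* = 1 (0.10 s) in the foraging arena,
   *g* = 5 (0.50 s) in the nest.

The simulator generates condition-specific synthetic colonies
(walking-speed distributions, motion blur, marker visibility, missed
and merged detections, misread markers) with exact ground truth, and
the evaluator scores trajectories the way a human annotator would:
detection / identification / correct-identification rates on a
one-in-ten frame subsample, double-detection bookkeeping, walking
speeds with a 0.75 mm s⁻¹ noise floor, identity-swap episodes, and a
Pearson χ² test for count tables.

## Worked example

Simulate a 20-ant, 250-frame colony in the foraging arena under
infrared light, track it, and score the result:

```sh
$ bach simulate --condition forage-ir --seed 42 --out dets.csv --truth truth.csv
INFO bach: simulate condition=forage-ir seed=42 ants=20 frames=250
INFO bach: wrote 4033 shape and 2339 marker detections to dets.csv; truth (5000 rows) to truth.csv

$ bach track --detections dets.csv --condition forage-ir --out tracks.csv
INFO bach: track condition=forage-ir ghost_threshold=1 (0.10 s) conf>0.50
INFO bach: wrote 4752 records (144 entities) to tracks.csv

$ bach evaluate --tracks tracks.csv --truth truth.csv --report report.json
INFO bach: detection 77.9%, identification 75.8%, correct 73.7%; 24 swap episodes
```

Reading the output: of the 5000 simulated ant instances, the detector
emulation dropped or merged enough boxes that 144 tracker entities
cover the 20 ants (entities die after one missed frame in this
condition and are re-founded).  On the 19 analysed frames (60, 70, …,
240) the tracker detected 77.9% of ant instances, reported an identity
for 75.8%, and was right for 73.7%; `report.json` itemises the rates,
the double/double-plus-one counts, every identity-swap episode with
its duration and onset proximity, and a walking-speed summary.  The
trajectory CSV has one row per live entity per frame:

```
frame,entity_key,id,x_min,y_min,x_max,y_max,cx,cy,seen
0,0,0,1595.435,1162.290,1686.138,1209.274,1640.786,1185.782,true
0,1,-1,132.546,807.434,222.359,842.452,177.452,824.943,true
```

Count tables (e.g. detected vs. missed per condition) can be tested
directly:

```sh
$ bach chi2 --table "318,62;305,75"
chi2 = 1.50, d.f. = 1, p = 0.22
```

All subcommands also accept `--config run.yaml` (a `RunConfig`
document); explicit flags override config values.

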