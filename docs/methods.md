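# Methods

This note documents the models behind `pir_adl`: what the synthetic home
emulates, how the two segmentation algorithms work, the tunable parameters
and their defaults, the numerical conventions, and what the package's
passing tests do and do not establish about real deployments.

## The sensing model

A flat is a set of rooms with wireless sensor boxes, each sampling at
0.2 Hz (one reading per channel per 5 s). The default reference layout has
six rooms and eight boxes: one ambient box (temperature, illuminance, PIR)
per room, two of them in the living room (one overseeing the dining table,
one the sofa), a humidity channel on the bathroom box and a dedicated
accelerometer box on the fridge door. All analysis assumes a **single
resident**; a second person is modelled only through short visitor
episodes.

Room codes are canonical (`KITCHEN`, `BATHROOM`, …) so that feature columns
align across homes; feature columns are named `{ROOM}_{channel}`, with
`_a`/`_b` suffixes when two boxes of one room share a channel.

## The synthetic resident

The generator draws a semi-Markov schedule per day: at each transition an
activity is selected among the specs whose clock-time windows cover the
current time, with probability proportional to its daily rate (immediate
self-repeats are avoided when an alternative exists), and its dwell time is
log-normal, `median · exp(σ·N(0,1))`, floored at 30 s. Away-from-home
periods are a room-less pseudo-activity in the same draw; together with the
activities they cover every day exactly, so the logbook plus the AWAY
entries partition simulated time. Defaults (label, room, median duration,
start windows, rate/day):

| activity | room | median | windows (h) | rate |
|---|---|---|---|---|
| Cooking | KITCHEN | 35 min | 7–9, 11.5–13.5, 17.5–19.5 | 2.5 |
| Eating | LIVING (table box) | 30 min | 7.5–9.5, 12–14, 18–20.5 | 2.5 |
| Get ready for bed | BEDROOM | 15 min | 20.5–23.5 | 1.0 |
| Grooming | BATHROOM | 20 min | 6.5–9.5, 20.5–23 | 1.5 |
| Seated activity | LIVING (sofa box) | 70 min | 5.5–20.5 | 2.0 |
| Sleeping (lights off) | BEDROOM | 7 h | 21–24, 0–4.5 | 1.0 |
| Toileting | BATHROOM | 4 min | all day | 5.0 |
| Watching TV | TV_ROOM | 90 min | 16.5–22.5 | 1.5 |
| away | — | 2 h | 8.5–18 | 1.5 |

These were chosen once as plausible for an older person living alone; the
two living-room zones reflect the two-box setup and make Eating and Seated
activity separable by which box fires (the off-zone box fires at a reduced
"cross-zone" probability of 0.15).

Sensor noise (`SensorNoiseModel`): PIR fires per 5-s sample with
probability 0.85 while the box's room is occupied and 0.005 otherwise;
temperature is a daily sinusoid (21 ± 2 °C, peak mid-afternoon);
illuminance switches between day (300 lx, 07–21 h) and night (5 lx) levels
plus a 150-lx lamp bonus in the occupied room for lights-on activities;
bathroom humidity is 9 g/m³ with a +6 spike during Grooming; the fridge
accelerometer shows door events only while Cooking. All channels carry
small Gaussian jitter. The PIR defaults sit inside the easy-noise regime
(hit ≥ 0.8, false ≤ 0.02) that the recovery checks assume.

Overlapping activities (probability `overlap_prob` per long activity)
interrupt the host activity with a nested second one: the logbook keeps
both intervals (overlapping), while the simulated occupant genuinely
changes rooms. Visitor episodes arrive as a Poisson process
(`visitor_rate`/day, 10–20 h, ~30 min), occupy a living/TV room and fire
its PIR concurrently; log intervals overlapping an episode get the visitor
flag.

Seeding: `SeedSequence([seed, day_index])` split into four independent
streams (schedule, overlaps, visitors, rendering), so every day is
reproducible in isolation and identical seeds give byte-identical datasets.

**What the generator does not emulate:** packet loss and clock drift,
analog PIR intensity, multi-resident households beyond the visitor model,
pets, seasonal/weekday behavioural variation (weekday is a feature but
behaviour does not depend on it), and logbook annotation noise — real
residents flip switches late or not at all, so real truth intervals are
noisier than the exact intervals emitted here. Pipeline scores on
synthetic data are therefore upper bounds, not forecasts of field
performance.

## Preprocessing conventions

Readings snap to the nearest 5-s grid point, half-up at exact ties.
Collisions take the maximum for PIR and the mean for continuous channels.
Missing continuous values are forward-filled (leading gaps backward-filled)
because a lost packet does not change the room's temperature; missing PIR
samples count as 0 (no evidence of motion). Truth intervals are half-open
`[start, end)`; where intervals overlap, the shorter one wins (the
interrupting activity is the current one). Rows outside every interval are
`NONE`, away periods are `AWAY`. The acceleration magnitude
`√(x²+y²+z²)` is added as a fourth fridge feature, and weekday is a single
ordinal 0–6 (trees and NB handle ordinals; switch to one-hot if a linear
model is added).

## Token segmentation

The token of a row is the bitmask of firing rooms in canonical order
(motionless = 0; with ≤ 62 rooms an int64 suffices). Change points follow
the last-active rule: a row opens a new episode iff its token is active and
differs from the most recent active token; the first active token opens the
first episode without being a change point. Compression computes, per
feature column, mean, **population** variance (0 for one-row episodes),
min, max and first/last values, plus the episode token, the neighbouring
episodes' tokens (sentinel −1 at the stream ends), the modal truth label
(ties broken by the label seen latest), a majority visitor flag, and the
activity degree (fraction of rows with any PIR firing).

## Room-based segmentation

Parameters (`RoomFilterConfig`), all exposed in the `room_clustering:` YAML
block:

| parameter | default | meaning |
|---|---|---|
| `short_window_s` | 15 | short centred moving average (3 rows) |
| `long_window_s` | 300 | long centred moving average (60 rows) |
| `room_weights` | BATHROOM: (2, 1) | per-room (short, long) weights |
| `default_weights` | (1, 1) | weights for unlisted rooms |
| `activity_threshold` | 0.5 | min score for a row to be active |
| `min_gap_s` | 300 | shorter no-activity gaps are absorbed |
| `edge_keep_s` | 10 | raw-PIR search span at period edges |
| `min_activity_s` | 20 | short-activity exclusion threshold |

The moving averages shrink symmetrically at the grid boundaries
(`pandas.rolling(center=True, min_periods=1)`). The bathroom's short-term
up-weighting exists because its dominant activity (toileting) is too brief
for the long filter.

Scores are computed per **PIR column** (sensor location), not per
aggregated room: where two boxes oversee one room, a move between their
zones (dining table → sofa) changes the argmax location and produces a
change point, which is what lets the pipeline separate back-to-back
same-room activities; the attribute saved on the segment is still the
winning sensor's room code. Activities that share a single sensor
(Grooming vs. Toileting; Get-ready-for-bed vs. Sleeping) can still merge
when adjacent — an inherent limit of location-driven segmentation.

The activity threshold of 0.5 (score scale is `short_w + long_w`, i.e. 2
for default rooms) was set so that sustained occupancy (score ≈ 1.7 at a
0.85 firing rate) clears it while an isolated false firing (short MA 1/3 ≈
0.35 at unit weight) does not. A much lower threshold qualitatively breaks
no-activity detection: every stray firing opens a 15-s "active" island,
and with stray firings a few minutes apart the gap-absorption step chains
the islands across entire away periods. Bathroom singles (score ≈ 0.7 via
the ×2 weight) still open candidate islands, but the 20-s short-activity
filter removes them.

Edge refinement is extension-only: each activity-period boundary moves
outward to the nearest raw firing within `edge_keep_s`, so brief
information peaks at the edges (the hall firing as the resident leaves)
stay inside the period instead of being smoothed away; extension-only also
keeps total active time monotone non-increasing in the threshold. Ties in
the location argmax go to the earliest canonical column, everywhere, for
determinism.

The short-activity filter removes **active** episodes strictly shorter
than 20 s (a 20-s episode survives) and annexes their span to the
preceding episode (following, if first), pooling means/variances by
duration so coverage and moments stay consistent; no-activity episodes are
never removed.

## Classification

Features per episode: every `*_mean`/`*_var` column, duration, activity
degree, and the categorical context (token, previous/next token, room,
weekday). Trees and NB receive categoricals as integer codes (unseen rooms
map to −1); the SVM receives one-hot categoricals (`handle_unknown=
"ignore"`) and standardized numerics. Defaults are the families' standard
ones: RF 100 unpruned trees with √p features per split, SVM RBF with C=1,
Gaussian NB; all seeds flow from `ClassifierSpec.random_seed`.

AWAY/NONE episodes are excluded from training; at prediction time an
episode is ruled AWAY when its room is NONE (room pipeline) or its
activity degree is below 0.05 (token/slot pipelines), before the
classifier is consulted — absence is a property of the PIR stream, not a
class to learn. Class imbalance is left uncorrected; balanced/weighted
forests are a possible extension, not implemented.

The visitor classifier is an independent random forest on binary visitor
labels. It never sees the token context (which is a joint-room feature)
and, when a room subset is given, only that subset's sensor features plus
the global duration/degree/weekday/room features. Restricting to bathroom,
TV room and living room matches where a second person is detectable while
the resident is busy elsewhere, and yields the conservative regime the
method aims for: specificity near 1, modest sensitivity (a visitor in the
same room as the resident is invisible to binary PIR).

## Evaluation

All scoring is at the 5-s slice level: episode labels are projected back
onto the grid and counted one-vs-rest per activity; slices whose truth is
NONE or AWAY act as negatives for every activity. Sensitivity, specificity
and precision are the usual ratios with the 0/0 → 0 convention; F is the
harmonic mean of precision and sensitivity. Leave-one-home-out
cross-validation pools confusion counts over folds before computing
metrics (micro over folds, macro over activities); per-fold tables are
kept as well because pooled and fold-averaged numbers differ in general,
and both views are reported. Macro means skip activities absent from the
truth (they would contribute 0/0 rows); in the standard report all eight
activities appear with an unweighted Mean row, percentages to two
decimals.

The label-permutation control refits the classifier on shuffled training
labels and compares held-out macro F against the chance level implied by
the predicted/true label marginals, `F_a = 2·p_a·q_a/(p_a+q_a)`.

## Problem sizes

The bundled studies simulate 10 homes × 3 days for cross-validated
recovery, ordering (room ≥ token ≥ 60-s slots), visitor and permutation
checks, 6 days for the Monte-Carlo firing-rate check, and 1–2 homes × 1–2
days for the unit-level fixtures; these sizes give stable slice counts
(≈ 520k slices in the cohort run) while keeping each study to minutes on a
single CPU.

## Known limitations

* Single-resident assumption throughout; the visitor model flags presence
  but never attributes firings to persons.
* Segmentation needs multiple rooms; a one-room home yields a single
  location and only activity/no-activity structure.
* Same-sensor activity pairs merge when adjacent (see above); their
  separation relies on the classifier's duration/ancillary features.
* The generator's cleanly parameterized signals (sharp lux switches, exact
  logbooks) make the synthetic task easier than field data; results on it
  validate the machinery, not clinical utility.
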