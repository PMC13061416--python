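# Methods

## Activity classification by frame differencing

A larva is annotated per frame as active or inactive from the number of
in-well pixels whose absolute intensity change from the previous frame
exceeds a per-pixel noise floor (default 10 on the 8-bit scale, ≈ 3.5 σ of
typical sensor noise). Counting changed pixels, rather than summing
absolute differences, makes the score insensitive to static illumination
gradients and to the absolute contrast of the animal. Frame 0 has no
predecessor and copies frame 1's score, so a recording never opens with a
spurious state. Classification is strict — `score > threshold` is active,
equality is inactive — a deliberate bias toward quiescence at the single
ambiguous point.

The score cutoff is calibrated, per recording session, in one of two ways:

- **Unlabeled (default):** an Otsu-style two-class split computed exactly
  on the empirical score values (no histogram binning); the threshold is
  placed at the midpoint of the between-class gap. Quiescent frames score
  near zero and crawling frames score in the hundreds, so the two classes
  are far apart in practice.
- **Labeled:** with per-frame truth labels, the threshold maximizing frame
  accuracy under the strict rule, found by an O(n log n) cumulative scan;
  ties resolve to the smallest threshold. "All frames active" is reachable
  only when every score is positive, since thresholds are constrained ≥ 0.

Cohorts recorded on the same rig are calibrated on the pooled score
histogram of all wells, which protects wells that happen to contain a
single behavioral class. No temporal smoothing is applied by default — the
bout-length criterion below already acts as a denoiser — but a 3-frame
median filter is available behind a flag.

## Sleep definition and architecture

Sleep is a maximal inactive run of at least `min_sleep_frames = 12`
consecutive frames. The criterion is applied in frames, not seconds; at
the 0.87 fps acquisition rate this corresponds to ≈ 13.8 s, but the
seconds value is derived, never configured. Bout intervals are half-open
`[start, end)` in 0-based frames, which makes adjacency and intersection
arithmetic unambiguous. Bouts truncated by the recording edges count if
they meet the threshold; excluding them would bias short recordings toward
wake. Within any analysis window, total sleep + total wake equals the
window length exactly (the partition is computed, not re-measured), and
sleep latency with no bouts is NaN rather than 0 or the window length.

Wake-gated locomotion speed divides centroid travel distance by wake time,
where a frame-to-frame displacement enters the numerator only when both
frames are classified wake and both are validly tracked, and exactly those
frame intervals form the denominator. This makes the speed invariant to
inserting quiescent stretches into a fixed wake trajectory — slow mutants
cannot be explained away by sleeping more — and drops tracking dropouts
from both terms instead of imputing them.

## Centroid tracking

The background of each well is modeled as a per-pixel temporal median over
a sliding 101-frame window (subsampled every 5th frame; the larva occupies
any pixel a minority of the time, so the subsampled median converges to
the substrate). Foreground detection combines two cues, reflecting that
the animal images darker than the substrate: the signed deviation below
the background model, and a dark-object cut at half the background level.
The union is needed because a larva parked longer than about half the
window is absorbed into the median — the deviation cue alone then sees
only the un-absorbed sliver of the body and biases the centroid by several
pixels, while the dark-object cue recovers the whole body; conversely a
bright "ghost" left at a vacated resting site is rejected by the sign of
the deviation. The reported position is the weighted centroid of the
strongest connected component, preferring the (uniform) dark-object weight
where defined. On noise-free synthetic renderings the per-frame error
against the generator's path is below 0.4 px. Frames with no foreground
are flagged invalid and carry the last valid position forward; a stack
with no foreground anywhere raises an empty-well error. Bright animals on
dark substrate are outside the model.

## Sleep deprivation and rebound

The deprivation schedule is one baseline hour without stimulation followed
by one hour of repeated LED cycles of 90 s ON / 30 s OFF; a final partial
ON interval is truncated at session end. At the defaults this yields 30
full ON intervals totaling 2700 s. The light-response index is sleep in
the ON hour divided by sleep in the OFF hour (NaN with a warning when the
baseline is zero). The rebound index is post-deprivation over
pre-deprivation sleep, with rebound defined as values above 1; the ratio
form is a declared convention of this package, chosen because it is
dimensionless and comparable across animals with different baselines.

## Adult sleep from DAM files

DAM2 monitor text is the vendor's fixed 42-column tab-separated export
(reading index, date, time, status, six metadata fields, 32 channel
counts); rows with a non-valid status code are retained but flagged
excluded. Timestamps must advance in uniform 1-min bins. Sleep is a
maximal run of at least `adult_min_gap_min = 5` zero-count valid bins —
the conventional adult criterion; whether an exactly-5-min gap counted in
the original analyses is not stated, so the ≥ 5 reading follows the
convention and the threshold is configurable. Excluded bins break
immobility runs rather than being imputed as zeros: immobility is never
fabricated from missing data. Bout minutes are apportioned to day and
night by clock time under the 9 AM–9 PM light cycle (a bout crossing the
transition splits in exact minute proportion), and multi-day recordings
are additionally broken into 24-h windows aligned to the recording start.

## Reporter translocation (NLI) and image quantification

Cell ROIs are segmented from the activity-insensitive reference channel by
a two-level Otsu split (background / cell / brighter nucleus), with
connected components below 30 px discarded and nucleus-fills-cell ROIs
flagged invalid. Background is the median intensity of non-cell pixels,
subtracted and floored at 0. F_nuc and F_cyto are region-*mean* reporter
intensities over the nucleus and over cell-minus-nucleus; the mean reading
keeps NLI = (F_nuc − F_cyto)/(F_nuc + F_cyto) within [−1, 1], makes it
invariant to reporter expression level, and antisymmetric under swapping
the compartments. An alternative formulation in terms of whole-cell minus
nuclear signal is dimensionally inconsistent for means; an `integrated`
mode (region sums) is provided for comparison. NLI is NaN when both region
means vanish. Cytosolic marker (e.g. Dilp3) intensity is the
background-subtracted mean over the cytoplasmic mask. Cells are the
statistical unit: per-cell results from several brains are pooled by
concatenation, never averaged within brain.

Food intake is the stained-area / body-area ratio: the body is the largest
connected component below a luminance cutoff (dark animal on a light
slide), the stain class is pixels whose red channel exceeds both others by
a configurable margin, and the ratio is computed within the body mask.

## Group statistics

Two-group comparisons use the two-sided Mann–Whitney U test: exact null
enumeration when both groups have ≤ 8 observations and no ties, otherwise
the normal approximation with tie correction and continuity correction
(exact-with-ties is out of scope). Multi-group comparisons use
Kruskal–Wallis with tie correction (H = 0 and an undefined p when every
value ties); contingency tables use the Pearson chi-square statistic
without continuity correction. Bonferroni families are declared
explicitly — the family is the set of planned comparisons in one analysis,
never inferred silently. Group summaries are median and Q1–Q3 by linear
(type-7) interpolation. The standard tests are computed by scipy.stats
behind this module's interface; the test suite verifies them against
independent enumeration and rank-arithmetic oracles, and calibrates the
type-I error of the U test at 5% ± 1% over 10⁴ null simulations.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions for every benchmark in the test
suite:

- **Behavior**: alternating wake/sleep bouts with geometrically
  distributed frame counts (memoryless, support ≥ 1 frame) parameterized
  by mean durations — the simplest law with the right mean and easy
  analytic checks. Benchmarks default to 60 s mean wake and sleep bouts
  (minute-scale bout structure with both classes present in every
  recording).
- **Imaging**: one larva per well rendered as an ellipse (25 px body at
  0.1 mm/px ≈ 2.5 mm, second-instar scale) whose length oscillates
  sinusoidally during wake (peristalsis proxy, amplitude 2 px,
  area-conserving) and whose centroid follows a correlated random walk
  with mean step `crawl_speed_mean / fps` (0.4 mm/s default) reflected at
  the well walls; frozen during sleep. Additive Gaussian sensor noise
  (σ = 2 intensity units) clipped to 8 bits, a static 10% linear
  illumination gradient, 80 px wells, 0.87 fps. An optional ≤ 1 px
  micro-movement during sleep (off by default) stresses thresholding.
- **DAM**: minutes inside the programmed sleep schedule count zero;
  wake minutes draw from a zero-truncated Poisson so wake bins are never
  silent.
- **Cells**: the reference channel labels the whole cell with a brighter
  nucleus; the reporter distributes a fixed total signal between nucleus
  and cytoplasm so that the region-mean ratio equals the requested nuclear
  fraction f exactly (NLI = 2f − 1 by construction, total conserved with
  noise off).
- **Dye images**: a body-shaped ellipse on a light background with a
  contiguous anterior sub-region of the programmed area fraction rendered
  in the stain color.

All randomness flows through one explicitly passed seed; identical
arguments give bit-identical output. The generator does **not** emulate
posture, head/tail anatomy, feeding micro-movements, multi-animal wells,
reflections, focus drift, or photobleaching. Passing tests therefore show
that the measurement chain is correct and well calibrated under controlled
conditions — they do not certify the ~99% synthetic classification
accuracy on real video, where the practical target is the ≈ 90% accuracy
against manual annotation that motivated the benchmark's 90% floor.

## Problem sizes and numerical choices

Benchmark sizes were chosen so each estimator's sampling error is small
against its acceptance band: the classifier benchmark pools ten 1044-frame
videos; cohort-recovery runs use 12–20 animals × 1600–3000 s with bout
means (e.g. 50 s sleep / 117 s wake for a 30% cohort) long enough that the
12-frame criterion truncates only ~3% of sleep while keeping enough bout
cycles per recording for concentrated per-animal fractions; the cohort
sleep fraction is reported pooled (total sleep over total time), whose
standard error at these sizes is ~1.5 percentage points. NLI recovery uses
20 seeds per nuclear fraction across f = 0.1 … 0.9. Float comparisons on
rendered float32 images use 1e-6 tolerances; CSV round trips are exact for
integer and state fields and better than 1e-9 for floats. Well grids
refine an equal partition toward dark rim lines only when a candidate line
is clearly darker than the profile bulk, and otherwise keep the partition.

## Known limitations

Single animal per well; binary behavioral states only; no arousal
threshold or circadian analysis (larval sleep is clock-independent); no
video container decoding (frames are pre-extracted); dark-on-light imaging
polarity assumed; optical calibration (mm/px) must be supplied — without
it distances degrade to pixel units and outputs carry a `px` unit flag.
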