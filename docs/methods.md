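# Methods

## Data model

A *trace* is one egg's F340/F380 ratio series sampled at a fixed interval
(default 7.5 s) with a per-egg stimulus time carried explicitly, because
recordings may include pre-stimulus frames (strontium is added after
imaging starts). Datasets travel as plain TSV in a long dialect
(`egg_id, time_s, ratio` plus metadata columns `group, mode, replicate,
stimulus_time_s`) or a wide dialect (`time_s` plus one column per egg, with
a YAML metadata sidecar). Values are written at full `repr` precision and
parsed in round-trip mode, so write→read is bit-exact. A non-uniform time
axis, a non-finite or non-positive ratio, or a duplicate egg id is a typed
hard error — gaps are never interpolated.

## Transient detection

Baseline and noise are estimated per trace:

* **pre-stimulus branch** (≥ 8 pre-stimulus samples): baseline = median,
  noise = 1.4826 × MAD of the pre-stimulus segment;
* **rolling-percentile branch** otherwise: baseline = the median over time
  of a centred rolling 10th percentile (5 min window); noise from the
  residuals at or below their median (1.4826 × median |lower residuals|),
  which transients cannot inflate. This branch reads the baseline slightly
  low under heavy noise (the 10th percentile of a noise band sits ≈ 1.3 σ
  below its centre), so analyses of noisy recordings without pre-stimulus
  frames should prefer an explicit amplitude floor (`min_amplitude`) over
  the k·σ term.

Events are maximal runs of samples above
`baseline + max(k_sigma·noise, min_amplitude)` (defaults 3 and 0.05 ratio
units). The onset is the first sample of the run; the offset is the first
sample after the peak falling below
`baseline + offset_fraction·(peak − baseline)` (default 0.25 — scanning
from the peak matters when the offset level exceeds the threshold, which
happens for small-amplitude events). An event still elevated at the last
sample keeps its partial duration and is flagged right-truncated; it still
counts for frequency and persistence. Events whose gap (previous offset to
next onset) is under `min_gap_s` (default 30 s, well below the minutes-scale
inter-transient interval) merge into one; events shorter than
`min_duration_s` (default two sampling intervals) are discarded as noise
blips. Only onsets at or after the stimulus are reported. All knobs live in
`DetectionConfig` and are hashed into every run report.

Two systematic properties of this rule matter for interpretation. First,
the detected onset lags the true one by the threshold-crossing time of the
rising phase, `rise_time × threshold/amplitude`; group comparisons are
unaffected (the lag is common to both groups), and onset-accuracy checks in
the tests are stated net of this lag. Second, the measured duration runs
from the threshold crossing to the offset-fraction crossing, a fixed
proportion of the true duration for a fixed shape — so duration *ratios*
between groups are unbiased while absolute durations are convention-bound
(the field has no standard convention; return-to-baseline is one
`offset_fraction` setting away). Counting monotonicity in the threshold
holds over the practical range (k ≥ 2); below that the threshold enters the
noise band and run-merging makes counts non-monotone.

AUC is the trapezoidal integral of `max(sample − baseline, 0)` over a
window snapped outward to sample times (clipping negative deviations is the
default reading of "signal above baseline"; the raw integral is a flag
away). Trapezoid edge error is at most half a sampling interval times the
amplitude per discontinuous edge — under 2% for the pulse widths of
interest.

## Per-egg metrics

For each egg with at least one detected transient: time from stimulus to
first onset; first-transient duration; counts of onsets within 60 and
120 min of the first onset (the first transient counts as oscillation #1);
frequency per 10 min ≡ n60/6 by construction; AUC over
[first onset, +60 min) — anchoring at the first transient keeps the window
aligned across eggs with different latencies; anchoring at the stimulus is
a config switch; the window is clamped to the recording end. The cessation
time is the last onset minus the first ("oscillating at t" = "has an onset
after t"); an egg whose last onset falls within 10 min of the analysis
horizon (110 min strontium / 120 min IVF, per-mode configurable), or whose
last transient is right-truncated, is censored rather than scored as
ceased — one typical inter-transient interval of lookahead against
edge-of-recording bias. Eggs with no transients are non-responders: their
metric fields are undefined, they are excluded from per-metric tests but
kept in responder tallies.

The persistence curve reports, on a minute grid from each egg's first
onset, the fraction of responder eggs whose cessation time exceeds the grid
time, with censored eggs counting as oscillating throughout. The t = 0
point is pinned to 1.0: having a first transient is the entry criterion, so
every responder is oscillating at its own first onset even if it never
oscillates again (cessation 0).

## Statistics

Each scalar metric is compared with a two-sided Mann–Whitney U test.
With combined n ≤ 20 and no ties the exact permutation distribution is
used (the test suite verifies it against brute-force enumeration of all
group assignments); otherwise — including any tied data, so all count-based
metrics — the normal approximation with midranks, tie-corrected variance
and continuity correction. `U = min(U_x, U_y)` is reported; two identical
samples give `U = n_a n_b / 2, p = 1`. Persistence is compared with the
log-rank (Mantel–Cox) test on cessation times with right censoring,
computed via `lifelines` and verified against an independent O/E/V
tabulation. Six comparisons are reported per run (five Mann–Whitney, one
log-rank); no multiplicity correction is applied by default, matching
per-panel reporting practice, with Holm step-down available as an option. A
metric with fewer than three responders in either group is flagged
untestable rather than dropped.

## Synthetic traces

The generator writes the ground truth it samples, so detection and
inference can be scored against truth. Per responder egg it draws a
latency from the stimulus (truncated Gaussian, floor one sampling
interval), then alternating durations and inter-onset intervals; the k-th
interval mean is stretched by `iti_slowdown^k` (geometric slow-down gives
the k-th onset a closed-form expectation), intervals are redrawn if a
transient would overlap its successor, and drawing stops at a per-egg
cessation time (truncated Gaussian; eggs whose stop exceeds the recording
are the censored class). Each transient rises linearly over 20% of its
duration and decays exponentially with `τ = 0.8·d/5`, reaching < 1% of
amplitude within the stated duration; the shape's area has the closed form
`a·(0.1·d + τ·(1 − e⁻⁵))` used by the AUC oracle tests. A per-egg lognormal
amplitude scale (mean 1, CV `amp_cv`) multiplies both amplitudes; linear
drift and i.i.d. Gaussian noise are added last. Per-group seed streams are
spawned from one root seed and per-egg substreams from each group stream,
so enlarging one group never perturbs the other.

### Default regimes and how they were chosen

The strontium defaults are: baseline 0.8, noise SD 0.0125, drift
5 × 10⁻⁵ /min, latency 300 ± 75 s, first transient 120 ± 40 s at amplitude
0.43, subsequent transients 110 ± 35 s at 0.42, intervals 240 ± 120 s with
5% stretching, cessation 3300 ± 3300 s, amplitude CV 0.3, 110 min
recordings with the stimulus at 60 s (8 pre-stimulus frames), group sizes
75/78. The IVF regime is sparser and slower (latency 900 ± 240 s,
intervals 540 ± 200 s, 120 min recordings, groups 68/92). Four canonical
scenarios pair these: `sr_null` / `ivf_null` (identical groups),
`sr_paper` (group B latency × 1.15, first duration × 1.5 — "slightly
delayed onset, ~50% longer first transient"), and `ivf_shift`
(latency × 1.5, a positive control).

These values were set, before the verification suite was frozen, to
reproduce the qualitative outcome structure of the strontium experiment
they emulate: a delayed and lengthened first transient that is clearly
detectable at n ≈ 75/group, while frequency, total AUC, oscillation counts
and persistence remain indistinguishable. The last constraint is the
binding one: a 50% longer first transient adds a fixed increment of area,
so total AUC only stays non-significant if between-egg variability in total
signal dominates. Two realistic heterogeneity sources provide that
dominance and are part of the study conditions: widely dispersed cessation
times (the persistence curve declines steadily across the recording, so the
number of transients inside the AUC window varies strongly between eggs)
and per-egg response scale (dye loading and egg-to-egg amplitude variation,
the lognormal CV 0.3). For the same reason the first transient is only
modestly longer and larger than its successors in the default regime.
Noise SD and drift are set so that the detector's fixed amplitude floor
(0.05 ratio units) sits at ≈ 4 σ and total drift stays an order of
magnitude below it: a scalar-baseline detector has no drift correction, and
its cessation estimate (a *last*-event statistic) is the quantity most
sensitive to rare false positives.

### What the generator does not emulate

Piecewise-linear/exponential transients with i.i.d. Gaussian noise stand in
for real Fura-2 kinetics: no biophysical ER/IP₃ dynamics, no shot-noise or
photobleaching structure, no amplitude decline across a train, no
within-egg interval autocorrelation beyond the deterministic stretch, and
no image-plane artifacts (focus drift, egg movement). Tests passing on
these simulations certify the pipeline's algorithmic correctness and
operating characteristics under the stated regime, not performance on any
particular microscope's exports.

## Operating characteristics measured by the test suite

With the defaults above, the acceptance tests measure: per-metric type-I
error of the full pipeline within [0.03, 0.07] at α = 0.05 (2000 null
replicates at n = 75/78; run at a 40 min recording length, which preserves
the per-egg feature structure while keeping 2000 full pipeline replicates
inside a few minutes); the strontium contrast flagged on latency and first
duration in ≥ 80% of 200 replicates with the other four panels ≤ 10%; the
IVF null non-significant ≥ 90% per metric; detection recall, precision and
exact per-egg counts ≥ 95% on 200 ground-truth traces at SNR 5 (long, slow
transients; amplitude floor at 70% of the transient amplitude); and median
onset error within one sampling interval net of the deterministic crossing
lag in a steep-rise regime at SNR 8. At SNR 5 the crossing-lag jitter of a
slow rise exceeds one sample, and a steep rise leaves too few
above-threshold samples for 95% exact counts — the two demands meet only
at higher SNR, which is why the onset bound is checked in the SNR 8 regime.

## Numerical and degenerate-input choices

Uniform sampling is verified at relative tolerance 10⁻⁶; the inferred
interval is the first difference. Truncated-Gaussian draws use exact
rejection sampling. All-tied Mann–Whitney inputs short-circuit to
`U = n_a n_b/2, p = 1`; a zero log-rank statistic reports p = 1 exactly.
Empty transient lists produce non-responder records, never errors; an empty
trace set writes a header-only file. Pipeline failures are wrapped with the
stage name and egg id, and partially written outputs are removed. Output
TSV/JSON is written with sorted keys and full-precision floats, making
reruns with identical config and seed byte-identical.
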