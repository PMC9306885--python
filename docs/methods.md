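# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Stimulus timelines

**Continuous vigilance.** The task presents four gratings ticking at 120
ticks/min (500 ms period); a target is a deviant tick, so target times are
snapped to the tick grid. Defaults: 30 min, 6 targets/min (180 total),
inter-target gaps in [6, 30] s, no target within 2 s of either end, exactly
equal counts over 4 locations with the assignment shuffled over the whole
run. The sampler draws the total span of the target train uniformly over
the top 5 % of feasible spans (so the six-per-minute density holds
throughout the session, not merely on average), distributes the span over
per-gap excesses above the 6 s minimum proportionally to uniform draws on
the tick grid, and validates every constraint, rejecting and resampling on
violation (cap 10,000 attempts, never observed to need more than a few).
A consequence of spreading 180 targets over ~30 min is that realised gaps
concentrate in roughly [6, 15] s; the 30 s bound is enforced but not
approached.

**PVT.** Trials are grouped into blocks (default 3 × 90). Each trial's ISI
is a fixed 2,000 ms plus a random component drawn uniformly within one
tertile of [2,000, 10,000] ms; tertile labels are balanced within block
(counts differ by at most one when the block size is not divisible by 3)
and shuffled. The ISI clock is response-initiated: flip *n* occurs ISI_n
after press *n−1*.

## Synthetic observers and pupil streams

The generator's defaults define the reference conditions every
downstream check assumes:

| parameter | default | basis |
|---|---|---|
| hit probability by period | .692 / .625 / .596 | reference per-period hit percentages (declining, ~64 % overall) |
| false-alarm rate per neutral | .0109 | reference false-alarm percentage (~1 % of neutral events) |
| hit RT median by period (ms) | 640 / 676 / 693 | reference per-period hit RTs of ~651/687/704 ms means (medians set slightly lower because log-normal means exceed medians) |
| hit RT log-sd | 0.16 | reproduces the reference RT spread (~SD 80–160 ms) |
| PVT non-lapse RT (ms) | mean 420, sd 79 | reference values for a low-contrast RT-initiating stimulus |
| lapse probability | 27.6/270 | reference lapse count per 270 trials |
| lapse RT (ms) | log-normal, mean 960, log-sd 0.6 | reference lapse mean; heavy right tail |
| pupil baseline | 4,000 a.u., random-walk step sd 0.2/sample | a.u. scale arbitrary; drift ~3 % of baseline over 30 min |
| sample noise sd | 20 a.u. (0.5 %) | plausible measurement noise |
| event kernel | n = 10.1, t_max = 930 ms | classic pupil impulse-response parameterisation |
| evoked amplitude (% of baseline) | hit 5.6, FA 7.0, miss 2.7, PVT 6.0 | anchored to reference peak modulations of ~2.7–7 % |
| amplitude decay | 2.5 %/min compounding | produces an evoked decline of a few percentage points across three watch periods |
| blink rate / duration | 0.15 Hz, U[100, 400] ms | yields ~6–9 % interpolated data after the 100 ms padding, matching the ~6.5 % reference interpolation fraction |
| post-press blink probability | 0.5 within 1 s | emulates task-correlated blinking |

The dilation for hits and false alarms is locked to the button press (as in
the analyses); misses dilate at the stimulus. RTs are log-normal because
detection RT distributions are right-skewed; lapses are a second mixture
component rather than a shifted tail so the lapse rate is directly
controllable. Blinks are a renewal process with an extra press-locked
component; blink samples carry the missing code 0, which is what the
preprocessing detector keys on.

**What the generator does not emulate:** luminance effects and the
pupillary light reflex, gaze dynamics beyond stationary jitter,
foreshortening artefacts, slow oscillatory arousal dynamics (the baseline
is a pure random walk), and the blink-induced pupillary response (blinks
only remove samples; they do not perturb the recovered trace). Passing
recovery tests therefore demonstrate that the pipeline recovers what the
generative model injects — not that the model captures every property of
real recordings. Two visible consequences: correct-rejection traces can
show small but consistent modulation (dilation tails from neighbouring
presses overlap the 2.5 s epochs at a 2 Hz event rate), and the negative
baseline–evoked correlation emerges in the vigilance configuration (where
the baseline window abuts the epoch, so baseline-window noise mean-reverts
inside the trace) but not reliably in the PVT configuration.

## Preprocessing

Order-exact chain: detect blinks (maximal runs of the missing code) →
extend endpoints by 100 ms per side and linearly interpolate between the
nearest valid samples (edge-touching intervals filled with the nearest
valid value; an all-missing series is an error) → zero-phase third-order
4 Hz low-pass Butterworth (`scipy.signal.sosfiltfilt`; zero-phase chosen
because forward-only filtering would bias peak latencies) → 250 → 50 Hz by
5-sample block averaging (anti-aliasing already ensured by the 4 Hz
low-pass; the interpolation mask propagates by block-wise OR) → session
z-transform with the population-SD convention, computed on the 50 Hz
series. One-minute bins average the z-series per whole minute, with a
trailing partial minute averaged over what exists.

## Classification

The vigilance assignment is the three-pass rule described in the README.
Conventions where the rule is underdetermined: "nearest elapsed neutral
event" is the latest neutral at or before the press (a press before any
event binds to the earliest neutral and is logged); each neutral carries at
most one false alarm, and a press whose nearest elapsed neutrals are all
taken falls back to earlier, then later, unused neutrals, so the
conservation laws #HIT+#MISS = #targets, #FA+#CR = #neutrals and
#HIT+#FA = #presses hold exactly; the first in-window press on a target is
the hit and surplus presses become false alarms; a zero-MAD RT pool widens
the window to ±1 ms. The hit window is pooled across the cohort
(group-level median/MAD); PVT lapse thresholds are per participant and
one-sided (median + 2·MAD above). The MAD scale constant 1.4826 is exposed
rather than fixed because a recorded cohort's exact window (e.g., the
reference 225–1,156 ms range) depends on its raw RT pool.

## Epochs and scalar measures

Windows (50 Hz, endpoints inclusive, so a 2,500 ms window has 126 samples;
off-grid lock times keep the fixed length, shifting the grid by < 20 ms):

- vigilance stimulus-locked: [−500, +2000] ms, baseline [−500, 0) ms;
- vigilance button-locked: [−1000, +1500] ms, baseline [−1000, −500) ms
  (offset to avoid motor-preparation contamination);
- PVT: [−1000, +1500] ms around the press, baseline = 500 ms before the
  flip, evoked window [−500, +1500] ms.

The vigilance epoch extents are a package choice (they cover the span over
which event-locked dilations play out at these kernel settings) and are
configurable. Percent modulation is divisive, 100·(x − b)/b, after
subtractive referencing to the trial baseline b — percent signal change
requires a divisor and the trial baseline is the only available reference.
Baseline scalars use the z-series, evoked scalars the percent series; the
evoked window always excludes the baseline window. An epoch is invalid if
any baseline sample is interpolation-masked or more than 25 % of its
samples are. Watch periods partition epochs by event time into three
equal thirds of the session.

## Cluster permutation tests

Pointwise one-sample (or paired-difference) t statistics are thresholded
at the two-tailed critical t for df = n−1 at α = .05; maximal
uniform-sign runs above threshold form clusters with mass = summed t
(signed-mass is the standard choice; max-|t| is configurable in principle
but not exposed). The null distribution of the maximal |mass| uses random
per-participant sign flips (paired contrasts reduce to sign flips on the
differences); when 2^n ≤ n_perm the full set is enumerated. Corrected p
uses the inclusive (+1) convention, so the resolution floor is
1/(n_perm+1) — and 3/(2^n+1) for exhaustive small-n nulls, because the
identity and global flip both reach the observed two-tailed mass.
Zero-variance time points get t = 0 with a warning. The permutation engine
is vectorised over permutations (runs are found on a row-flattened matrix
with sentinel separators), which is what makes 2,000-cohort calibration
runs affordable. The 1-min-bin test treats each participant's 30-bin
z-series (session mean 0 by construction) as the trace.

## Group statistics

Repeated-measures ANOVAs are computed by pingouin behind the module
surface; the wrapper fixes the reporting conventions: partial eta squared
from F·df1/(F·df1 + df2) (exact in balanced within designs), Mauchly's
test gating the Greenhouse–Geisser correction at p < .05 for effects with
more than two levels (two-level effects are trivially spherical), and an
epsilon-based gate for interaction terms, where a Mauchly statistic is not
exposed. Degenerate inputs follow explicit contracts: identical cell
means give F = 0, p = 1; identical paired samples give t = 0, adjusted
p = 1; subjects with missing cells are dropped listwise. Simple main
effects are one-way ANOVAs per slice with per-slice error terms. Note the
GG correction is only guaranteed to raise p in the significance region;
for F well below 1 the epsilon-shrunken dfs can lower it. Bootstrap CIs
are percentile intervals over participant resamples; at n = 28 the
percentile method is known to undercover slightly (~93 % for a nominal
95 %), which the calibration suite makes visible rather than hiding.
Trial-level correlations pool all valid trials across participants, so
their df reflect total trial counts.

## Problem sizes

Unit tests use 6-minute vigilance sessions and 30-trial PVT blocks; the
cohort-level recovery suite uses 12-minute sessions (three 4-minute watch
periods) with 28 observers, which preserves every stage of the chain while
keeping repeated cohorts affordable; the analysis drivers run the full
30-minute / 3×90-trial designs. The acceptance script uses 100 schedules
per design audit, 2,000 null cohorts for the cluster-test error rate, and
1,000 blocks for the duration simulation. These sizes are package choices
balancing Monte-Carlo error against runtime on a single CPU.

## Known limitations

- The EyeLink parser's velocity-based blink detection is replaced by
  missing-sample run detection; downstream logic depends only on the
  resulting intervals.
- No deconvolution of overlapping events: at the vigilance task's 2 Hz
  event rate, epochs overlap neighbouring responses, visible in
  correct-rejection traces.
- Unequal-variance SDT, ROC fitting, Huynh–Feldt correction and
  mixed-effects models are out of scope.
- The simulator's arbitrary-unit scale and kernel shape are conventional
  choices; absolute evoked percentages depend on them, so cross-study
  comparisons should rely on the relative (per-period, per-condition)
  patterns the tests assert.
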