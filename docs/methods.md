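# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, in the order the method runs.

## Conventions

All times are seconds, float, zero-based from recording start. Every epoch
interval is half-open `[start, end)`, so a spike landing exactly on a
boundary is counted in exactly one epoch. Electrode adjacency is supplied
as data (a JSON map), never inferred from probe geometry: probe layouts
vary and the analysis must not hard-code one. Spike tables carry event
times only — spike detection and sorting are upstream of this package.

## Synthetic data: what it emulates, and what it does not

The generators exist so that every downstream stage can be validated
against exact ground truth; they reproduce the *statistical structure* the
analysis assumes, not the biophysics.

**Protocol.** `default_timeline()` lays out a 2700 s study: a 600 s
pre-intervention baseline containing the antidromic identification
stimulation (60 pulses at 1 Hz) and the mechanical (2 × 15 s touch) and
nociceptive (60 s bradykinin, 60 s capsaicin) stimulus epochs; a 180 s
coronary occlusion and 300 s reperfusion; a 1200 s stimulation period; a
60 s post-intervention baseline; and a second 180 s occlusion with 180 s
reperfusion. The durations mirror the experimental protocol (3 min
occlusions, 1 min antidromic stimulation, 1 min baseline reference window)
with the long idle stretches shortened.

**Electrograms.** Each beat is an analytic template: the QRS is a biphasic
Gaussian-derivative lobe whose *second* derivative is extremal exactly at
the configured activation time, and the T wave is a Gaussian bump whose
center is placed one σ after (upright) or before (inverted) the configured
repolarization time, so the steepest positive slope falls exactly at the
true RT for either polarity. Ground truth is therefore exact by
construction, which a recorded beat could not provide. Defaults: 1 mV QRS
amplitude (σ = 8 ms), 0.8 mV T amplitude (σ = 22 ms), RR = 600 ms,
AT = 40 ms, RT = 340 ms (ARI 300 ms, in the physiological range for a
paced large-animal ventricle). During occlusion epochs, electrodes in the
ischemic mask receive a +0.2 mV ST plateau (smoothstep edges, so the
offset adds no spurious slope extremes) and their repolarization advances
by 100 ms — the magnitude of ischemic ARI shortening the method is meant
to detect. Noise is additive white Gaussian; real electrograms add drift,
motion and far-field components the template omits, so passing recovery
tests bound algorithmic error, not performance on noisy clinical data.

**Spike trains.** Each neuron is an inhomogeneous Poisson process with a
piecewise-constant rate: baseline rate (default 2 Hz, a typical spinal
background rate) multiplied by an epoch gain — `ischemia_gain` during the
pre-intervention occlusion, `post_scs_gain` during the post-intervention
occlusion, optional reperfusion and stimulus-epoch gains. Generation uses
thinning (one homogeneous draw at the rate ceiling, then acceptance with
probability λ(t)/λmax), which is exact for piecewise-constant rates and
single-pass seedable. Antidromic units additionally fire at
pulse + latency + Gaussian jitter (SD = `latency_jitter_ms`) with
probability `follow_prob` per pulse; synchronized pairs receive common
injected events placed in both trains with a uniform lag within
±`max_lag_ms`. A 1 ms refractory merge is applied last, which changes
rates by well under 1% at the default settings. Real neurons burst, adapt
and drift; the generator's Poisson assumption matches the test's own null
model, which is the point — calibration results transfer to real data only
to the extent real baselines are Poisson-like at the 1–3 min counting
scale.

## Electrogram analysis

Derivatives come from least-squares local polynomial (Savitzky–Golay)
differentiation. The QRS deflection is fast and deep, so a 5 ms
quadratic window suffices for AT. The T-wave slope maximum is shallow, so
RT uses a wider 51 ms window at polynomial order 4: order 2 at this width
biases the detected peak by about one sample because the T-derivative
profile is asymmetric, while order 4 removes that bias at a modest noise
cost. Both detections are refined to sub-sample precision by the vertex of
a parabola fitted over ±8 ms of the smoothed derivative around the coarse
argmax; the refinement is skipped when the extremum is a plateau
(near-ties within float tolerance resolve to the earliest sample, for
determinism) or when the fitted vertex leaves the fit window. With these
defaults, noise-free recovery error is ≤ 0.8 ms at 1 kHz and the median
ARI error at a noise SD of 5% of QRS amplitude is ≈ 1.3 ms
(56 electrodes × 20 beats).

Beats whose peak-to-peak amplitude is below 0.05 mV (configurable) are
flagged undefined rather than measured. ST deviation is the mean over an
ST window (default 90–180 ms after beat onset) minus the mean over a
pre-QRS isoelectric window (0–10 ms); depression is reported with a
negative sign. The ischemic zone is the set of electrodes with ST ≥
0.1 mV; the threshold is configurable because clinical ST adjudication is
partly manual and no universal mV criterion exists.

DOR is the across-electrode *sample* variance (n−1 denominator) of the
per-electrode mean repolarization time, measured relative to beat onset so
the statistic is invariant to beat alignment; a config switch
(`dor_metric="ari"`) uses ARI variance instead. Both are exposed because
"dispersion of repolarization" is reported in ms² in the literature with
the underlying quantity (RT vs ARI) often unstated; RT variance is the
default reading.

## Artifact rejection

A true extracellular spike cannot appear on more than a couple of
electrodes, so events coinciding within 0.5 ms across *more than two
mutually adjacent* electrodes are treated as artifacts and removed from
every involved train. Coincidence is chained (consecutive inter-event gaps
≤ tolerance form one cluster) and "mutually adjacent" means a connected
component of size ≥ 3 in the adjacency map restricted to the cluster's
electrodes. The 0.5 ms default reflects that sub-millisecond cross-channel
coincidence from distinct somata is non-physiological; it is configurable.
The operation is idempotent and logs every removed event. At the default
synthetic scale (250 neurons, ~500 spikes/s total) chance triples remove
≈ 0.15% of events — a known, logged cost of the rule.

## Skellam rate-change test

For counting windows of equal length the difference of the two counts is
Skellam-distributed; under the no-change null both means equal the pooled
rate times the window length, and the two-sided p doubles the smaller tail
(capped at 1), a standard conservative choice for a discrete statistic.
The pmf is evaluated in log space with the exponentially scaled Bessel
function `ive`, so means in the thousands do not overflow; tail sums run
over the ±40 SD effective support.

The protocol compares a 1 min baseline against a 3 min occlusion. Both
counts are scaled to the shorter duration T\*; scaling a Poisson count by
s = T\*/d keeps its rate but shrinks its variance to s·λ·T\*, so the null
uses the variance-matched symmetric Skellam with

    μ₀ = λ̂ · T\* · (s_ref + s_test) / 2,

which reduces exactly to the classic pooled-rate null for equal windows.
Without this correction the unequal-window test is markedly conservative
(empirical type-I ≈ 0.015 at a nominal 0.05 for 1 vs 3 min windows);
variance-matched, the measured type-I error is ≈ 0.044 with power ≈ 1.0
for a 2→4 Hz doubling. An alternative `equalize="truncate"` strategy uses
only the first baseline-length slice of the occlusion, giving an exactly
equal-window test at the cost of discarding two thirds of the data.

Ischemia-sensitive classification uses the *final* minute of the baseline
(closest to occlusion onset) versus the full occlusion, one test per
neuron at α = 0.05 with no multiplicity correction — the screening is per
neuron, followed by within-neuron tracking, and a Benjamini–Hochberg
option is available but off by default. Rate deltas for each occlusion and
reperfusion epoch are taken relative to the matching 1 min baseline
(pre-intervention baseline for the pre epochs, post-intervention baseline
for the post epochs).

## Antidromic IML identification

For each stimulation pulse, the first spike in `(pulse, pulse + 50 ms]`
not already claimed by an earlier pulse is the candidate response
(one-to-one: a burst after one pulse counts once). A unit is IML when the
follow fraction strictly exceeds 0.6 *and* the response-latency spread is
≤ 5 ms. The spread statistic defaults to the normal-scaled median absolute
deviation rather than the classical SD: a spontaneously active unit
occasionally has a chance background spike claim a response slot, and a
single contaminated latency can multiply an SD several-fold while the
antidromic locking itself is perfect; the robust spread captures
"consistent delay" without that fragility (`consistency="sd"` restores the
classical statistic). With 60 pulses, follow probability 0.9 and 1 ms
latency jitter the classifier is essentially always positive; note that a
unit following 50% of pulses still crosses the 60% threshold in ≈ 5% of
realizations purely by binomial fluctuation (P(Binom(60, 0.5) ≥ 37) =
0.046), an irreducible property of a fixed-threshold rule at 60 pulses.
Units failing the test are labeled DH; units are never relabeled across
epochs (identity is the sorter's).

Modality labels test each stimulus epoch against an equal-length window
immediately preceding it (matched-duration Skellam comparison):
mechanosensitive = significant increase during either touch epoch,
nociceptive = during bradykinin or capsaicin, multimodal = both. Only
ischemia-sensitive neurons are profiled in the study report, matching the
protocol's focus.

## Synchrony

Coincidences use greedy one-to-one nearest matching in time order with
|Δt| ≤ 40 ms (a config switch reads the window as total width instead,
i.e. ±20 ms). Greedy nearest matching prevents one burst spike from
generating several coincidences and is deterministic (distance ties take
the earlier target). The null displaces every target spike independently,
uniformly within ±200 ms — wide enough (≫ 40 ms) to destroy fine-timescale
synchrony, narrow enough (≪ epoch length and rate-modulation timescale) to
preserve slow co-modulation — clips to the epoch, and recounts; 1000
surrogates by default (200 in the calibration checks, where the p
granularity of 1/201 suffices for α = 0.05). SI = (c − n̄)/(c + n̄) is 0
at chance level, → 1 when observed coincidences dominate, and is defined
as exactly 0 when both terms vanish; pairs with an empty train in the
epoch are flagged undefined and excluded from aggregates. Significance is
the one-sided surrogate rank p = (1 + #{surrogate ≥ c}) / (1 + n), which
is valid (conservative) by construction; measured type-I fraction over 500
independent 5 Hz pairs is ≈ 0.04 at α = 0.05, and injected 1 Hz common
drive over 300 s is detected in ≈ 100% of seeds.

Pairwise analysis evaluates every DH–DH and DH–IML pair per epoch and
reports two aggregate scales per category × epoch — the number of
significant pairs and the summed SI over significant pairs — because the
field's aggregate plotting unit is not standardized. Per-pair RNG streams
derive from the study seed and a CRC of the pair's neuron ids, so results
are independent of iteration order.

## Pipeline and group statistics

`run_study` executes clean → antidromic labeling → ischemia-sensitivity
screening (pre-intervention occlusion) → modality labels → per-epoch
deltas for the sensitive roster → electrogram metrics → synchrony →
group tests, with per-stage in/out counts logged and any failure reported
with its stage name. Synchrony cost grows quadratically with the roster,
so `sync_max_pairs_per_category` (default 200) caps the evaluated pairs;
the cap is a stated analysis parameter, not a silent truncation.

Group-level comparisons delegate to standard routines: Friedman's test
across the four occlusion/reperfusion deltas with Dunn's pairwise
z-comparisons on within-subject mean ranks (z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n),
Bonferroni-adjusted — implemented directly, as no suitable post-hoc
routine is available in the dependency set); Kruskal–Wallis across the
modality groups' occlusion deltas; Wilcoxon signed-rank on paired pre/post
synchrony indices. Every reported p carries its test name and n; groups
with n < 3 are skipped with a note, and all-identical samples report p = 1
with a note rather than a numerical failure. Outliers in delta tables are
*flagged* by a median-absolute-deviation rule (3.5 robust SDs) and never
silently removed.

## Known limitations

- The Poisson assumptions of the Skellam test and the jitter null are also
  the generator's assumptions; bursty or strongly non-stationary real data
  will inflate both tests' false-positive rates, and the calibration
  figures above do not cover that regime.
- The electrogram landmark windows (QRS search, T window, ST and
  isoelectric windows) are fixed offsets from the beat mark; severely
  variable RR intervals would need beat-adaptive windows.
- Beat detection is out of scope: electrograms must arrive with beat
  marks (the generator provides them).
- The antidromic rule's specificity is limited by pulse count, as
  quantified above; collision testing, the definitive confirmation, is a
  wet-lab procedure outside this package.
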