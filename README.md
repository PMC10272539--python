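# cardiospinal

Analysis toolkit for cardio-spinal electrophysiology experiments that ask
how spinal cord stimulation (SCS) modulates spinal processing of myocardial
ischemia. The experimental design it supports: a brief coronary-artery
occlusion is applied before and again after an SCS intervention while
recording (a) multichannel unipolar epicardial electrograms from a sock
electrode array and (b) sorted extracellular spike trains from dorsal horn
(DH) and intermediolateral column (IML) neurons on a penetrating spinal
microelectrode array. The package quantifies, per occlusion, the cardiac
sympathoexcitation markers and the spinal network response, so the pre- vs
post-SCS comparison falls out of one pipeline run.

## What it computes

**Electrogram markers.** On each unipolar electrogram beat, activation time
(AT) is the instant of steepest negative slope in the QRS and
repolarization time (RT) the steepest positive slope in the T window
regardless of T-wave polarity (the Wyatt convention); the activation
recovery interval ARI = RT − AT is a surrogate of local action-potential
duration. ST-segment deviation defines the ischemic zone, ARI shortening
during occlusion is averaged over that zone, and the dispersion of
repolarization (DOR) is the across-electrode sample variance of
repolarization time in ms².

**Ischemia-sensitive neurons.** A neuron's spike count in the final minute
of baseline is compared with its count during the 3-minute occlusion using
a test based on the Skellam distribution — the law of the difference of two
independent Poisson counts,

    P(K = k) = e^{-(μ₁+μ₂)} (μ₁/μ₂)^{k/2} I_{|k|}(2√(μ₁μ₂)).

Counts from unequal windows are scaled to the shorter duration and compared
against a variance-matched symmetric Skellam null at the pooled rate; a
significant increase labels the neuron ischemia-sensitive, and the same
neurons are then followed through the post-SCS occlusion via per-epoch rate
deltas.

**IML identification.** Stimulating the paravertebral chain drives
sympathetic preganglionic IML neurons antidromically. A unit is IML when it
follows more than 60% of the 1 Hz stimulation pulses one-to-one within
50 ms with a consistent latency (robust spread ≤ 5 ms); all other units are
labeled DH.

**Spike synchrony.** Pairs of neurons coincide when they fire within 40 ms,
matched greedily one-to-one. The observed coincidence count c is referenced
to a jitter-surrogate null (each target spike displaced uniformly within
±200 ms, destroying fine-timescale synchrony but preserving slow rate
co-modulation), giving the normalized synchrony index

    SI = (c − n̄) / (c + n̄)

with a one-sided surrogate-rank p-value. DH–DH and DH–IML pairs are
evaluated per epoch and aggregated.

**Synthetic data.** Because such recordings are rarely shareable, the
package ships seeded generators that produce ground-truthed electrograms
(analytic beat templates whose true AT/RT/ST are exact by construction) and
spike populations (piecewise-constant-rate Poisson processes with epoch
gains, antidromically driven units, and injected common-drive coincidences)
so every stage of the pipeline can be validated against known truth.

## Worked example

```python
import numpy as np
from cardiospinal import *
from cardiospinal.synthetic import default_timeline

tl = default_timeline()                  # 2700 s protocol, both occlusions
gains = np.ones(30); gains[:6] = 3.0     # 6 ischemia-sensitive neurons
post  = np.ones(30); post[:6]  = 1.2     # suppressed response post-SCS
anti = {i: AntidromicSpec(20.0, 1.0, 0.9) for i in (27, 28, 29)}  # 3 IML units

spikes, truth = gen_spike_population(
    SynthSpikeConfig(n_neurons=30, ischemia_gain=gains, post_scs_gain=post,
                     antidromic_neurons=anti,
                     sync_pairs=[SyncPairSpec(0, 1, 1.0, 10.0)], seed=42), tl)

e_pre  = SynthEGMConfig(n_electrodes=8, n_beats=10, noise_sd_mv=0.02,
                        ischemic_mask=frozenset(range(3)),
                        ari_shortening_ms=100.0, seed=42)
e_post = SynthEGMConfig(n_electrodes=8, n_beats=10, noise_sd_mv=0.02,
                        ischemic_mask=frozenset(range(3)),
                        ari_shortening_ms=85.0, seed=43)
egm = {ep: gen_electrograms(e_pre, tl, start_time_s=tl.epochs[ep][0])[0]
       for ep in ("baseline_pre", "lad_pre")}
egm |= {ep: gen_electrograms(e_post, tl, start_time_s=tl.epochs[ep][0])[0]
        for ep in ("baseline_post", "lad_post")}

report = run_study(StudyConfig(spikes=spikes, timeline=tl, egm_segments=egm,
                               seed=7, sync_max_pairs_per_category=10,
                               sync_cfg=SynchronyConfig(n_surrogates=200)))
print(report.counts)
print(report.egm_metrics.query("metric == 'ari_shortening_ms'").to_string(index=False))
print(f"mean delta LAD pre:  {report.deltas.delta_lad_pre_hz.mean():+.2f} Hz")
print(f"mean delta LAD post: {report.deltas.delta_lad_post_hz.mean():+.2f} Hz")
```

prints

```
{'neurons_recorded': 30, 'spikes_recorded': 172151, 'artifact_events_removed': 42,
 'iml_neurons': 3, 'dh_neurons': 27, 'ischemia_sensitive_neurons': 7}

   epoch            metric      value  n
 lad_pre ari_shortening_ms -99.878058  3
lad_post ari_shortening_ms -84.968930  3

mean delta LAD pre:  +3.60 Hz
mean delta LAD post: +0.21 Hz
```

Reading this: all 3 antidromically driven units were recovered as IML; 7
neurons test ischemia-sensitive (the 6 true positives plus one chance
rejection at α = 0.05); the ischemic-zone ARI shortening recovers the
generator's configured 100 ms (pre) and 85 ms (post) advances to within a
fraction of a millisecond; and the mean firing-rate response to occlusion
collapses from +3.6 Hz pre-SCS to +0.2 Hz post-SCS, the suppression
signature the pipeline exists to measure. `report.group_tests` adds the
Friedman/Dunn, Kruskal–Wallis and Wilcoxon group-level statistics with
their n, and `report.synchrony_agg` the significant-pair counts and summed
SI per category and epoch.

The same pipeline is scriptable from the shell (`cardiospinal --help`):
subcommands `synth egm`, `synth spikes`, `egm analyze`, `spikes
clean|ratechange|classify|synchrony` and `run` read and write plain
CSV/TSV/JSON (electrograms also HDF5).

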