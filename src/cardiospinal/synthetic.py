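"""Seeded generators for ground-truthed electrograms and spike populations.

The generators emulate the statistical structure the downstream analysis
assumes — they are fixtures with exact ground truth, not biophysical models:

* unipolar epicardial electrograms built from an analytic beat template
  (sums of Gaussian lobes) whose steepest-negative-slope and
  steepest-positive-slope samples sit *exactly* at the configured activation
  and repolarization times, with an ST-segment plateau added on ischemic
  electrodes during coronary-occlusion epochs;
* spike-train populations as inhomogeneous Poisson processes with
  piecewise-constant, epoch-gated rates, plus antidromically driven units
  (fixed latency responses to paravertebral stimulation pulses) and neuron
  pairs with injected common-drive coincidences.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .core_io import ElectrogramSet, ProtocolTimeline, SpikeTrain, SpikeTrainSet

__all__ = [
    "SynthEGMConfig",
    "SynthSpikeConfig",
    "AntidromicSpec",
    "SyncPairSpec",
    "gen_electrograms",
    "gen_spike_population",
    "default_timeline",
    "grid_adjacency",
]

#: epochs during which ischemia morphology/gains apply
_ISCHEMIA_EPOCHS = ("lad_pre", "lad_post")


def default_timeline(t2_pulse_hz: float = 1.0) -> ProtocolTimeline:
    """Build the default synthetic protocol timeline (2700 s total).

    Layout mirrors the experimental protocol at reduced scale: a long
    pre-intervention baseline containing the antidromic-identification
    stimulation (1 min at 1 Hz) and the mechanical/nociceptive stimulus
    epochs, a 3 min coronary occlusion with reperfusion, the stimulation
    period, a 1 min post-stimulation baseline, and a second occlusion and
    reperfusion.
    """
    epochs = {
        "baseline_pre": (0.0, 600.0),
        "lad_pre": (600.0, 780.0),
        "rep_pre": (780.0, 1080.0),
        "scs": (1080.0, 2280.0),
        "baseline_post": (2280.0, 2340.0),
        "lad_post": (2340.0, 2520.0),
        "rep_post": (2520.0, 2700.0),
        # stimulus epochs sit inside the pre baseline
        "touch_rv": (180.0, 195.0),
        "touch_lv": (240.0, 255.0),
        "bradykinin": (330.0, 390.0),
        "capsaicin": (450.0, 510.0),
    }
    pulses = 60.0 + np.arange(60) / t2_pulse_hz
    return ProtocolTimeline(epochs, {"t2": pulses})


def grid_adjacency(n_rows: int = 8, n_cols: int = 8) -> dict[int, set[int]]:
    """4-neighbour adjacency for a rectangular electrode grid (row-major ids)."""
    adj: dict[int, set[int]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            e = r * n_cols + c
            nbrs = set()
            if r > 0:
                nbrs.add(e - n_cols)
            if r < n_rows - 1:
                nbrs.add(e + n_cols)
            if c > 0:
                nbrs.add(e - 1)
            if c < n_cols - 1:
                nbrs.add(e + 1)
            adj[e] = nbrs
    return adj


# ---------------------------------------------------------------------------
# electrograms
# ---------------------------------------------------------------------------


@dataclass
class SynthEGMConfig:
    """Configuration of the synthetic electrogram generator.

    ``at_ms`` / ``rt_ms`` are true per-electrode activation and
    repolarization offsets from beat onset (scalar broadcast to all
    electrodes).  ``t_amp_mv`` may be negative per electrode to produce an
    inverted T wave.  During ischemia epochs, electrodes in
    ``ischemic_mask`` get ``st_shift_mv`` added over the ST segment and
    their repolarization advanced by ``ari_shortening_ms``.
    """

    n_electrodes: int = 56
    fs: float = 1000.0
    n_beats: int = 20
    rr_interval_s: float = 0.6
    at_ms: float | np.ndarray = 40.0
    rt_ms: float | np.ndarray = 340.0
    ischemic_mask: frozenset[int] = frozenset()
    st_shift_mv: float = 0.2
    ari_shortening_ms: float = 100.0
    noise_sd_mv: float = 0.0
    qrs_amp_mv: float = 1.0
    t_amp_mv: float | np.ndarray = 0.8
    sigma_qrs_ms: float = 8.0
    sigma_t_ms: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        at = np.broadcast_to(np.asarray(self.at_ms, float), (self.n_electrodes,))
        rt = np.broadcast_to(np.asarray(self.rt_ms, float), (self.n_electrodes,))
        if np.any(at >= rt):
            raise ValueError("true AT must precede true RT on every electrode")
        if self.fs < 500.0:
            raise ValueError("fs must be at least 500 Hz")
        min_rt = float(np.min(rt)) - (
            self.ari_shortening_ms if self.ischemic_mask else 0.0
        )
        if min_rt - self.sigma_t_ms * 3 <= at.max() + 3 * self.sigma_qrs_ms:
            raise ValueError("repolarization template would overlap the QRS")
        if self.rr_interval_s * 1000.0 < rt.max() + 5 * self.sigma_t_ms:
            raise ValueError("rr_interval too short for the beat template")

    @property
    def at_offsets_ms(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.at_ms, float), (self.n_electrodes,)
        ).copy()

    @property
    def rt_offsets_ms(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.rt_ms, float), (self.n_electrodes,)
        ).copy()

    @property
    def t_amps_mv(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.t_amp_mv, float), (self.n_electrodes,)
        ).copy()


def _qrs_wave(t_ms: np.ndarray, at_ms: float, amp: float, sigma: float) -> np.ndarray:
    # biphasic R-then-S deflection; d/dt is minimal exactly at at_ms
    x = (t_ms - at_ms) / sigma
    return amp * (-x) * np.exp(0.5 - 0.5 * x * x)

def _t_wave(t_ms: np.ndarray, rt_ms: float, amp: float, sigma: float) -> np.ndarray:
    # Gaussian T wave whose steepest *positive* slope is exactly at rt_ms
    # for either polarity: upright T peaks one sigma after rt, inverted T
    # bottoms one sigma before rt.
    center = rt_ms + sigma if amp >= 0 else rt_ms - sigma
    x = (t_ms - center) / sigma
    return amp * np.exp(-0.5 * x * x)

def _st_plateau(
    t_ms: np.ndarray, start_ms: float, end_ms: float, shift: float, ramp_ms: float
) -> np.ndarray:
    # smoothstep-edged plateau so the added offset creates no slope spikes
    def smooth(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        return u * u * (3.0 - 2.0 * u)

    rise = smooth((t_ms - start_ms) / ramp_ms)
    fall = smooth((end_ms - t_ms) / ramp_ms)
    return shift * rise * fall


def st_window_ms(cfg: SynthEGMConfig, electrode: int, ischemic_beat: bool) -> tuple[float, float]:
    """Flat portion of the ST segment (offsets from beat onset, ms)."""
    at = cfg.at_offsets_ms[electrode]
    rt = cfg.rt_offsets_ms[electrode]
    if ischemic_beat and electrode in cfg.ischemic_mask:
        rt = rt - cfg.ari_shortening_ms
    t_onset = (rt + cfg.sigma_t_ms if cfg.t_amps_mv[electrode] >= 0 else rt - cfg.sigma_t_ms) - 3 * cfg.sigma_t_ms
    return at + 4 * cfg.sigma_qrs_ms, t_onset - 4.0


def gen_electrograms(
    cfg: SynthEGMConfig,
    timeline: ProtocolTimeline,
    start_time_s: float = 0.0,
) -> tuple[ElectrogramSet, pd.DataFrame]:
    """Generate ``cfg.n_beats`` consecutive beats starting at ``start_time_s``.

    A beat whose onset falls inside an ischemia epoch of ``timeline`` gets
    ischemia morphology on the masked electrodes.  Returns the electrograms
    (with ``beat_marks``) and a truth table with columns
    ``electrode_id, beat_index, at_s, rt_s, ari_ms, st_mv, ischemic``.
    """
    rng = np.random.default_rng(cfg.seed)
    beat_len = int(round(cfg.rr_interval_s * cfg.fs))
    n_samples = beat_len * cfg.n_beats
    t_beat_ms = np.arange(beat_len) / cfg.fs * 1000.0

    isch_windows = [
        timeline.epochs[name] for name in _ISCHEMIA_EPOCHS if name in timeline.epochs
    ]
    at_off = cfg.at_offsets_ms
    rt_off = cfg.rt_offsets_ms
    t_amp = cfg.t_amps_mv

    samples = np.zeros((cfg.n_electrodes, n_samples))
    truth = []
    beat_marks = start_time_s + np.arange(cfg.n_beats) * cfg.rr_interval_s
    ramp_ms = 12.0

    for b in range(cfg.n_beats):
        onset = beat_marks[b]
        ischemic_beat = any(s <= onset < e for s, e in isch_windows)
        sl = slice(b * beat_len, (b + 1) * beat_len)
        for e in range(cfg.n_electrodes):
            in_mask = ischemic_beat and e in cfg.ischemic_mask
            rt = rt_off[e] - (cfg.ari_shortening_ms if in_mask else 0.0)
            st = cfg.st_shift_mv if in_mask else 0.0
            w = _qrs_wave(t_beat_ms, at_off[e], cfg.qrs_amp_mv, cfg.sigma_qrs_ms)
            w = w + _t_wave(t_beat_ms, rt, t_amp[e], cfg.sigma_t_ms)
            if st != 0.0:
                a, bnd = st_window_ms(cfg, e, True)
                w = w + _st_plateau(t_beat_ms, a - ramp_ms, bnd + ramp_ms, st, ramp_ms)
            samples[e, sl] += w
            truth.append(
                {
                    "electrode_id": e,
                    "beat_index": b,
                    "at_s": onset + at_off[e] / 1000.0,
                    "rt_s": onset + rt / 1000.0,
                    "ari_ms": rt - at_off[e],
                    "st_mv": st,
                    "ischemic": in_mask,
                }
            )
    if cfg.noise_sd_mv > 0:
        samples += rng.normal(0.0, cfg.noise_sd_mv, samples.shape)
    egm = ElectrogramSet(
        samples=samples,
        fs=cfg.fs,
        electrode_ids=list(range(cfg.n_electrodes)),
        beat_marks=beat_marks,
    )
    return egm, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# spike populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AntidromicSpec:
    """Fixed-latency response of an antidromically driven (IML) unit."""

    latency_ms: float = 20.0
    latency_jitter_ms: float = 1.0
    follow_prob: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.follow_prob <= 1.0:
            raise ValueError("follow_prob must lie in [0, 1]")
        if self.latency_ms <= 0:
            raise ValueError("latency must be positive")


@dataclass(frozen=True)
class SyncPairSpec:
    """Common-drive coincidence injection between two neurons."""

    neuron_a: int
    neuron_b: int
    injection_rate_hz: float = 1.0
    max_lag_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.injection_rate_hz < 0:
            raise ValueError("injection_rate_hz must be non-negative")


@dataclass
class SynthSpikeConfig:
    """Configuration of the synthetic spike-population generator.

    Per-neuron arrays broadcast from scalars.  ``ischemia_gain`` multiplies
    the baseline rate during the pre-intervention occlusion (``lad_pre``),
    ``post_scs_gain`` during the post-intervention occlusion (``lad_post``);
    ``rep_pre_gain`` / ``rep_post_gain`` cover the reperfusion epochs.
    ``stimulus_gains`` optionally gates extra epochs (e.g. touch/bradykinin)
    with per-neuron gain arrays.  A neuron is ground-truth ischemia-sensitive
    iff its ``ischemia_gain`` exceeds 1.
    """

    n_neurons: int = 250
    baseline_rate_hz: float | np.ndarray = 2.0
    ischemia_gain: float | np.ndarray = 1.0
    post_scs_gain: float | np.ndarray = 1.0
    rep_pre_gain: float | np.ndarray = 1.0
    rep_post_gain: float | np.ndarray = 1.0
    stimulus_gains: dict[str, np.ndarray] = field(default_factory=dict)
    antidromic_neurons: dict[int, AntidromicSpec] = field(default_factory=dict)
    sync_pairs: list[SyncPairSpec] = field(default_factory=list)
    duration_s: float = 2700.0
    n_electrode_rows: int = 8
    n_electrode_cols: int = 8
    refractory_ms: float = 1.0
    seed: int = 0

    def _per_neuron(self, x) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(x, float), (self.n_neurons,)).copy()
        if np.any(arr < 0):
            raise ValueError("rates and gains must be non-negative")
        return arr

    def __post_init__(self) -> None:
        self._per_neuron(self.baseline_rate_hz)
        for p in self.sync_pairs:
            if not (0 <= p.neuron_a < self.n_neurons and 0 <= p.neuron_b < self.n_neurons):
                raise ValueError("sync pair references unknown neuron index")
        for idx in self.antidromic_neurons:
            if not 0 <= idx < self.n_neurons:
                raise ValueError("antidromic spec references unknown neuron index")


_EPOCH_GAIN_FIELDS = {
    "lad_pre": "ischemia_gain",
    "lad_post": "post_scs_gain",
    "rep_pre": "rep_pre_gain",
    "rep_post": "rep_post_gain",
}


def _rate_profile(
    cfg: SynthSpikeConfig, timeline: ProtocolTimeline, neuron: int
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate: change-point times and rate per segment."""
    base = cfg._per_neuron(cfg.baseline_rate_hz)[neuron]
    cuts = {0.0, cfg.duration_s}
    windows: list[tuple[float, float, float]] = []
    for epoch, fld in _EPOCH_GAIN_FIELDS.items():
        if epoch in timeline.epochs:
            g = cfg._per_neuron(getattr(cfg, fld))[neuron]
            s, e = timeline.epochs[epoch]
            windows.append((s, min(e, cfg.duration_s), g))
    for epoch, gains in cfg.stimulus_gains.items():
        g = cfg._per_neuron(gains)[neuron]
        s, e = timeline.epochs[epoch]
        windows.append((s, min(e, cfg.duration_s), g))
    for s, e, _ in windows:
        cuts.update((s, e))
    edges = np.array(sorted(c for c in cuts if 0.0 <= c <= cfg.duration_s))
    rates = np.full(edges.size - 1, base)
    mid = 0.5 * (edges[:-1] + edges[1:])
    for s, e, g in windows:
        rates[(mid >= s) & (mid < e)] *= g
    return edges, rates


def _thinned_poisson(
    edges: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson via thinning of a homogeneous process at λmax."""
    lam_max = float(rates.max(initial=0.0))
    T = edges[-1] - edges[0]
    if lam_max <= 0 or T <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * T)
    t = np.sort(rng.uniform(edges[0], edges[-1], n))
    seg = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, rates.size - 1)
    keep = rng.uniform(0.0, 1.0, n) < rates[seg] / lam_max
    return t[keep]


def _refractory_merge(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Sort and drop spikes closer than the refractory period to the last kept."""
    t = np.sort(times)
    if t.size < 2 or refractory_s <= 0:
        return t
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] >= refractory_s:
            keep.append(x)
    return np.asarray(keep)


def gen_spike_population(
    cfg: SynthSpikeConfig,
    timeline: ProtocolTimeline,
    stim_train: str = "t2",
) -> tuple[SpikeTrainSet, dict]:
    """Generate the spike population and its ground-truth labels.

    Returns ``(SpikeTrainSet, truth)`` where ``truth`` holds
    ``ischemia_sensitive`` (neuron ids with ischemia_gain > 1), ``iml``
    (antidromically driven neuron ids), and ``sync_pairs`` (id pairs with
    injected common drive).
    """
    rng = np.random.default_rng(cfg.seed)
    n_elec = cfg.n_electrode_rows * cfg.n_electrode_cols
    adjacency = grid_adjacency(cfg.n_electrode_rows, cfg.n_electrode_cols)
    pulses = timeline.stim_pulses.get(stim_train, np.empty(0))

    ids = [f"n{i:03d}" for i in range(cfg.n_neurons)]
    spikes: list[np.ndarray] = []
    for i in range(cfg.n_neurons):
        edges, rates = _rate_profile(cfg, timeline, i)
        t = _thinned_poisson(edges, rates, rng)
        if i in cfg.antidromic_neurons and pulses.size:
            spec = cfg.antidromic_neurons[i]
            follow = rng.uniform(size=pulses.size) < spec.follow_prob
            lat = (
                spec.latency_ms
                + rng.normal(0.0, spec.latency_jitter_ms, pulses.size)
            ) / 1000.0
            t = np.concatenate([t, (pulses + lat)[follow]])
        spikes.append(t)

    for pair in cfg.sync_pairs:
        n_inj = rng.poisson(pair.injection_rate_hz * cfg.duration_s)
        base_t = rng.uniform(0.0, cfg.duration_s, n_inj)
        lag = rng.uniform(-pair.max_lag_ms, pair.max_lag_ms, n_inj) / 1000.0
        spikes[pair.neuron_a] = np.concatenate([spikes[pair.neuron_a], base_t])
        spikes[pair.neuron_b] = np.concatenate(
            [spikes[pair.neuron_b], np.clip(base_t + lag, 0.0, cfg.duration_s)]
        )

    trains = []
    for i, t in enumerate(spikes):
        t = _refractory_merge(t, cfg.refractory_ms / 1000.0)
        t = t[(t >= 0.0) & (t <= cfg.duration_s)]
        # region stays UNKNOWN: labeling is the classifier's job, the truth
        # dict is the ground truth for recovery tests
        trains.append(SpikeTrain(ids[i], i % n_elec, t))

    gains = cfg._per_neuron(cfg.ischemia_gain)
    truth = {
        "ischemia_sensitive": {ids[i] for i in range(cfg.n_neurons) if gains[i] > 1.0},
        "iml": {ids[i] for i in cfg.antidromic_neurons},
        "sync_pairs": [(ids[p.neuron_a], ids[p.neuron_b]) for p in cfg.sync_pairs],
    }
    return SpikeTrainSet(trains, adjacency, cfg.duration_s), truth
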