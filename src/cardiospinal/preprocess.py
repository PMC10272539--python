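"""Cross-electrode artifact rejection and epoch-windowed rate estimation.

A recording artifact (movement, stimulus breakthrough) appears as
near-simultaneous deflections across many sites, whereas a real
extracellular spike cannot be seen on more than a couple of electrodes.
Events coinciding within a sub-millisecond tolerance on a *connected set of
more than two adjacent electrodes* are therefore removed from every
involved train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SpikeTrain, SpikeTrainSet

__all__ = ["RateSeries", "remove_artifacts", "count_in_epoch", "rate_series"]


@dataclass
class RateSeries:
    """Binned firing rate of one neuron (contiguous bins, Hz)."""

    neuron_id: str
    bin_edges: np.ndarray
    rate_hz: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.rate_hz < 0):
            raise ValueError("rates cannot be negative")
        if self.bin_edges.size != self.rate_hz.size + 1:
            raise ValueError("bin_edges must have one more entry than rate_hz")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def remove_artifacts(
    sts: SpikeTrainSet, tol_ms: float = 0.5
) -> tuple[SpikeTrainSet, pd.DataFrame]:
    """Drop coincident events spanning >2 mutually adjacent electrodes.

    Events are chained into temporal clusters (consecutive gaps ≤ ``tol_ms``);
    within a cluster the electrodes present are joined along the adjacency
    map, and every connected component covering at least three electrodes has
    all of its spikes removed from all involved trains.  Returns the cleaned
    set plus a removal log (``neuron_id, electrode_id, t_seconds``).

    The operation is idempotent and never touches events confined to one or
    two electrodes.
    """
    n_ev = sum(tr.n_spikes for tr in sts.trains)
    times = np.empty(n_ev)
    elec = np.empty(n_ev, dtype=np.int64)
    train_idx = np.empty(n_ev, dtype=np.int64)
    spike_idx = np.empty(n_ev, dtype=np.int64)
    pos = 0
    for ti, tr in enumerate(sts.trains):
        n = tr.n_spikes
        sl = slice(pos, pos + n)
        times[sl] = tr.spike_times
        elec[sl] = tr.electrode_id
        train_idx[sl] = ti
        spike_idx[sl] = np.arange(n)
        pos += n
    order = np.argsort(times, kind="stable")
    times, elec, train_idx, spike_idx = (
        times[order], elec[order], train_idx[order], spike_idx[order]
    )
    tol = tol_ms / 1000.0
    # temporal clusters: chains of consecutive gaps <= tol
    breaks = np.flatnonzero(np.diff(times) > tol)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [n_ev]))

    removed: dict[int, set[int]] = {ti: set() for ti in range(len(sts.trains))}
    log_rows = []
    for i, j in zip(starts, ends):
        if j - i < 3:
            continue  # an artifact needs >2 electrodes, hence >=3 events
        electrodes = set(elec[i:j].tolist())
        if len(electrodes) <= 2:
            continue
        uf = _UnionFind(electrodes)
        for e in electrodes:
            for n in sts.adjacency.get(e, ()):
                if n in electrodes:
                    uf.union(e, n)
        comp: dict[int, set[int]] = {}
        for e in electrodes:
            comp.setdefault(uf.find(e), set()).add(e)
        bad = set().union(
            *(c for c in comp.values() if len(c) > 2), set()
        )
        if not bad:
            continue
        for k in range(i, j):
            if elec[k] in bad:
                ti = int(train_idx[k])
                removed[ti].add(int(spike_idx[k]))
                log_rows.append(
                    (sts.trains[ti].neuron_id, int(elec[k]), float(times[k]))
                )

    trains = []
    for ti, tr in enumerate(sts.trains):
        if removed[ti]:
            keep = np.ones(tr.n_spikes, dtype=bool)
            keep[list(removed[ti])] = False
            trains.append(
                SpikeTrain(tr.neuron_id, tr.electrode_id, tr.spike_times[keep], tr.region_label)
            )
        else:
            trains.append(tr)
    log = pd.DataFrame(log_rows, columns=["neuron_id", "electrode_id", "t_seconds"])
    return SpikeTrainSet(trains, sts.adjacency, sts.duration), log


def count_in_epoch(train: SpikeTrain, epoch: tuple[float, float]) -> int:
    """Spikes with ``start <= t < end`` (half-open, no double counting)."""
    start, end = epoch
    t = train.spike_times
    return int(np.searchsorted(t, end, side="left") - np.searchsorted(t, start, side="left"))


def rate_series(
    train: SpikeTrain, bin_s: float, duration: float | None = None
) -> RateSeries:
    """Firing rate in contiguous bins of ``bin_s`` seconds (counts / bin_s).

    The last bin is truncated at ``duration`` but still normalized by its
    actual width so the rate stays unbiased.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if duration is None:
        duration = float(train.spike_times[-1]) if train.n_spikes else bin_s
    edges = np.arange(0.0, duration + bin_s, bin_s)
    edges = edges[edges <= duration]
    if edges[-1] < duration:
        edges = np.append(edges, duration)
    t = train.spike_times[train.spike_times < duration]  # half-open record
    counts, _ = np.histogram(t, bins=edges)
    widths = np.diff(edges)
    return RateSeries(train.neuron_id, edges, counts / widths)
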