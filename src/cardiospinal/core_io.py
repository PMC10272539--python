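"""Shared domain types and file I/O.

All times are seconds, float, zero-based from recording start.  Every epoch
interval is half-open ``[start, end)`` so a spike landing exactly on a
boundary is counted once.  Electrode adjacency is always supplied as data
(JSON map), never inferred from probe geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "SpikeTrain",
    "SpikeTrainSet",
    "ElectrogramSet",
    "ProtocolTimeline",
    "ResultTable",
    "FormatError",
    "ANALYSIS_EPOCHS",
    "STIMULUS_EPOCHS",
    "METRIC_VOCABULARY",
    "read_spike_table",
    "write_spike_table",
    "read_electrograms",
    "write_electrograms",
    "read_timeline",
    "write_timeline",
]

#: Protocol epochs that partition the recording and must not overlap.
ANALYSIS_EPOCHS = (
    "baseline_pre",
    "lad_pre",
    "rep_pre",
    "scs",
    "baseline_post",
    "lad_post",
    "rep_post",
)

#: Stimulus epochs; these may sit inside a baseline epoch.
STIMULUS_EPOCHS = ("touch_rv", "touch_lv", "bradykinin", "capsaicin")

#: Registered metric names allowed in a ResultTable.
METRIC_VOCABULARY = frozenset(
    {
        "ari_ms",
        "ari_shortening_ms",
        "dor_ms2",
        "st_mv",
        "rate_hz",
        "delta_hz",
        "count",
        "follow_fraction",
        "latency_mean_ms",
        "latency_sd_ms",
        "si",
        "c_obs",
        "null_mean",
        "null_sd",
        "n_significant_pairs",
        "sum_si_significant",
        "statistic",
    }
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class Region(str, Enum):
    """Anatomical label of a recorded spinal neuron."""

    DH = "DH"  # dorsal horn (afferent processing)
    IML = "IML"  # intermediolateral column (sympathetic preganglionic)
    UNKNOWN = "UNKNOWN"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    """One sorted neuron's spike times with electrode/region metadata.

    ``spike_times`` is strictly increasing, in seconds from recording start.
    """

    neuron_id: str
    electrode_id: int
    spike_times: np.ndarray
    region_label: Region = Region.UNKNOWN

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size and t[0] < 0:
            raise ValueError(f"neuron {self.neuron_id}: negative spike time")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"neuron {self.neuron_id}: spike_times must be strictly increasing"
            )
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class SpikeTrainSet:
    """A population of sorted spike trains plus the electrode adjacency map."""

    trains: list[SpikeTrain]
    adjacency: dict[int, set[int]]
    duration: float

    def __post_init__(self) -> None:
        for tr in self.trains:
            if tr.electrode_id not in self.adjacency:
                raise ValueError(
                    f"electrode {tr.electrode_id} of neuron {tr.neuron_id} "
                    "missing from adjacency map"
                )
            if tr.n_spikes and tr.spike_times[-1] > self.duration:
                raise ValueError(
                    f"neuron {tr.neuron_id}: spike beyond recording duration"
                )

    def __iter__(self):
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    def by_id(self, neuron_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.neuron_id == neuron_id:
                return tr
        raise KeyError(neuron_id)


@dataclass
class ElectrogramSet:
    """Multichannel unipolar electrograms.

    ``samples`` is an ``(n_electrodes, n_samples)`` matrix in mV;
    ``beat_marks`` are optional beat-onset times in seconds.
    """

    samples: np.ndarray
    fs: float
    electrode_ids: list[int]
    beat_marks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if self.samples.shape[0] != len(self.electrode_ids):
            raise FormatError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.electrode_ids)} electrode_ids"
            )
        if self.beat_marks is not None:
            self.beat_marks = np.asarray(self.beat_marks, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class ProtocolTimeline:
    """Named protocol epochs and stimulus pulse trains.

    Analysis epochs are mutually non-overlapping half-open intervals;
    stimulus epochs (touch, bradykinin, capsaicin) may lie inside baselines.
    """

    epochs: dict[str, tuple[float, float]]
    stim_pulses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (s, e) in self.epochs.items():
            if not e > s:
                raise ValueError(f"epoch {name!r}: end ({e}) must exceed start ({s})")
        for name in ("lad_pre", "lad_post"):
            if name in self.epochs:
                s, e = self.epochs[name]
                if e - s < 10.0:
                    warnings.warn(
                        f"epoch {name!r} shorter than 10 s; the protocol uses "
                        "a 3 min coronary occlusion",
                        stacklevel=2,
                    )
        analysis = [
            (n, *self.epochs[n]) for n in ANALYSIS_EPOCHS if n in self.epochs
        ]
        analysis.sort(key=lambda x: x[1])
        for (na, _, ea), (nb, sb, _) in zip(analysis, analysis[1:]):
            if sb < ea:
                raise ValueError(f"analysis epochs {na!r} and {nb!r} overlap")
        self.stim_pulses = {
            k: np.asarray(v, dtype=float) for k, v in self.stim_pulses.items()
        }
        for name, pulses in self.stim_pulses.items():
            if pulses.size > 1 and np.any(np.diff(pulses) <= 0):
                raise ValueError(f"stim_pulses[{name!r}] must be strictly increasing")

    def epoch(self, name: str) -> tuple[float, float]:
        if name not in self.epochs:
            raise KeyError(f"timeline has no epoch {name!r}")
        return self.epochs[name]

    @property
    def end(self) -> float:
        return max(e for _, e in self.epochs.values())


_RESULT_COLUMNS = ["entity_id", "epoch", "metric", "value", "p_value", "flags"]


@dataclass
class ResultTable:
    """Long-format result rows with a registered metric vocabulary."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"ResultTable missing columns: {missing}")
        bad = set(df["metric"]) - METRIC_VOCABULARY
        if bad:
            raise FormatError(f"unregistered metric names: {sorted(bad)}")
        self.rows = df[_RESULT_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "ResultTable":
        df = pd.DataFrame.from_records(list(records))
        for col, default in (("p_value", np.nan), ("flags", "")):
            if col not in df.columns:
                df[col] = default
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "ResultTable":
        df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "flags": str})
        df["flags"] = df["flags"].fillna("")
        return cls(df)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_adjacency(path: str | Path) -> dict[int, set[int]]:
    with open(path) as fh:
        raw = json.load(fh)
    adj = {int(k): {int(x) for x in v} for k, v in raw.items()}
    # symmetrize: adjacency is an undirected relation
    for e, nbrs in list(adj.items()):
        for n in nbrs:
            adj.setdefault(n, set()).add(e)
    return adj


def read_spike_table(
    path: str | Path, adjacency_path: str | Path, duration: float | None = None
) -> SpikeTrainSet:
    """Read a sorted-spike CSV (``neuron_id,electrode_id,t_seconds``).

    Rows are grouped by neuron and times sorted ascending, so the result is
    independent of input row order.  Duplicate timestamps within one neuron
    are collapsed with a warning.  Malformed rows raise :class:`FormatError`
    with line numbers.
    """
    df = pd.read_csv(path, dtype={"neuron_id": str})
    required = {"neuron_id", "electrode_id", "t_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"spike table missing columns: {sorted(missing)}")
    bad = df.index[
        df["neuron_id"].isna()
        | pd.to_numeric(df["electrode_id"], errors="coerce").isna()
        | pd.to_numeric(df["t_seconds"], errors="coerce").isna()
    ]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:20]]  # +2: header + 1-based
        raise FormatError(f"malformed spike-table rows at lines {lines}")

    adjacency = _read_adjacency(adjacency_path)
    trains = []
    for nid, grp in df.groupby("neuron_id", sort=True):
        electrodes = grp["electrode_id"].astype(int).unique()
        if len(electrodes) > 1:
            raise FormatError(
                f"neuron {nid} listed on multiple electrodes: {sorted(electrodes)}"
            )
        t = np.sort(grp["t_seconds"].astype(float).to_numpy())
        tu = np.unique(t)
        if tu.size < t.size:
            warnings.warn(
                f"neuron {nid}: {t.size - tu.size} duplicate timestamps collapsed",
                stacklevel=2,
            )
        trains.append(SpikeTrain(str(nid), int(electrodes[0]), tu))
    if duration is None:
        duration = max((tr.spike_times[-1] for tr in trains if tr.n_spikes), default=0.0)
    return SpikeTrainSet(trains, adjacency, float(duration))


def write_spike_table(sts: SpikeTrainSet, path: str | Path) -> None:
    recs = [
        (tr.neuron_id, tr.electrode_id, t)
        for tr in sts.trains
        for t in tr.spike_times
    ]
    pd.DataFrame(recs, columns=["neuron_id", "electrode_id", "t_seconds"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_adjacency(adjacency: Mapping[int, set[int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): sorted(v) for k, v in adjacency.items()}, fh)


def read_electrograms(path: str | Path) -> ElectrogramSet:
    """Read electrograms from HDF5 (datasets samples/fs/electrode_ids,
    optional beat_marks) or from a wide CSV whose first line is ``fs=<Hz>``."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "fs" not in f:
                raise FormatError("HDF5 electrogram file missing 'fs' dataset")
            beat = f["beat_marks"][()] if "beat_marks" in f else None
            return ElectrogramSet(
                samples=f["samples"][()],
                fs=float(f["fs"][()]),
                electrode_ids=[int(x) for x in f["electrode_ids"][()]],
                beat_marks=beat,
            )
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise FormatError("CSV electrogram file must start with 'fs=<Hz>'")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise FormatError(f"unparseable sampling rate {header!r}") from exc
        df = pd.read_csv(fh, index_col=0)
    return ElectrogramSet(
        samples=df.to_numpy(dtype=float),
        fs=fs,
        electrode_ids=[int(i) for i in df.index],
    )


def write_electrograms(egm: ElectrogramSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=egm.samples)
            f.create_dataset("fs", data=egm.fs)
            f.create_dataset("electrode_ids", data=np.asarray(egm.electrode_ids))
            if egm.beat_marks is not None:
                f.create_dataset("beat_marks", data=egm.beat_marks)
        return
    with open(path, "w") as fh:
        fh.write(f"fs={egm.fs:g}\n")
        pd.DataFrame(egm.samples, index=egm.electrode_ids).to_csv(
            fh, float_format="%.6f"
        )


def read_timeline(path: str | Path) -> ProtocolTimeline:
    with open(path) as fh:
        doc = json.load(fh)
    if "epochs" not in doc:
        raise FormatError("timeline JSON missing 'epochs'")
    epochs = {k: (float(v[0]), float(v[1])) for k, v in doc["epochs"].items()}
    pulses = {k: np.asarray(v, float) for k, v in doc.get("stim_pulses", {}).items()}
    return ProtocolTimeline(epochs, pulses)


def write_timeline(tl: ProtocolTimeline, path: str | Path) -> None:
    doc = {
        "epochs": {k: list(v) for k, v in tl.epochs.items()},
        "stim_pulses": {k: [float(x) for x in v] for k, v in tl.stim_pulses.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
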