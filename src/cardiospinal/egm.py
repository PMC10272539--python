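"""Unipolar electrogram analysis: AT, RT, ARI, ST elevation, DOR.

Activation time (AT) is the instant of steepest negative slope within the
QRS search window; repolarization time (RT) is the instant of steepest
positive slope within the T-wave window irrespective of T-wave polarity
(Wyatt convention).  ARI = RT − AT is a surrogate of local action-potential
duration.  Dispersion of repolarization (DOR) is the across-electrode
sample variance (ms²) of the per-electrode mean repolarization time.

Derivatives come from least-squares local polynomial (Savitzky-Golay)
differentiation.  The QRS deflection is fast, so a short window suffices;
the T wave is slow and its slope maximum is shallow, so a wider window is
used there (both configurable).  Ties in the extremal derivative resolve to
the earliest sample for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import savgol_filter

from .core_io import ElectrogramSet

__all__ = [
    "EGMAnalysisConfig",
    "BeatMeasurement",
    "ARIMap",
    "DORResult",
    "detect_activation_time",
    "detect_repolarization_time",
    "measure_st_elevation",
    "measure_beats",
    "compute_ari",
    "define_ischemic_zone",
    "ari_shortening",
    "compute_dor",
]


@dataclass(frozen=True)
class EGMAnalysisConfig:
    """Windows (ms, relative to beat onset) and numerical parameters."""

    qrs_window_ms: tuple[float, float] = (0.0, 120.0)
    t_window_ms: tuple[float, float] = (150.0, 560.0)
    deriv_window_ms: float = 5.0
    t_deriv_window_ms: float = 51.0
    deriv_polyorder: int = 2
    t_deriv_polyorder: int = 4
    vertex_fit_half_ms: float = 8.0
    min_amplitude_mv: float = 0.05
    iso_window_ms: tuple[float, float] = (0.0, 10.0)
    st_window_ms: tuple[float, float] = (90.0, 180.0)
    st_threshold_mv: float = 0.1
    dor_metric: str = "rt"
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.dor_metric not in {"rt", "ari"}:
            raise ValueError("dor_metric must be 'rt' or 'ari'")
        if self.iso_window_ms[1] > self.st_window_ms[0]:
            raise ValueError("isoelectric and ST windows overlap")


@dataclass
class BeatMeasurement:
    """Per-electrode, per-beat landmark measurements (absolute seconds)."""

    electrode_id: int
    beat_index: int
    at_s: float | None
    rt_s: float | None
    st_mv: float | None
    flags: str = ""
    onset_s: float = 0.0

    @property
    def ari_ms(self) -> float | None:
        if self.at_s is None or self.rt_s is None:
            return None
        return (self.rt_s - self.at_s) * 1000.0

    @property
    def valid(self) -> bool:
        return self.at_s is not None and self.rt_s is not None


@dataclass
class ARIMap:
    """Per-electrode mean ARI (ms) over an epoch."""

    epoch: str
    ari_ms: dict[int, float]
    ischemic_mask: set[int] = field(default_factory=set)
    flagged: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.ischemic_mask <= set(self.ari_ms) | self.flagged:
            raise ValueError("ischemic mask contains unknown electrodes")


@dataclass
class DORResult:
    epoch: str
    dor_ms2: float
    n_electrodes: int

    def __post_init__(self) -> None:
        if self.dor_ms2 < 0:
            raise ValueError("dispersion cannot be negative")


def _smooth_derivative(
    x: np.ndarray, fs: float, window_ms: float, polyorder: int
) -> np.ndarray:
    """Savitzky-Golay first derivative, mV/s."""
    n = max(polyorder + 2, int(round(window_ms * fs / 1000.0)))
    if n % 2 == 0:
        n += 1
    n = min(n, x.size if x.size % 2 else x.size - 1)
    if n <= polyorder:
        raise ValueError("segment too short for derivative window")
    return savgol_filter(x, n, polyorder, deriv=1, delta=1.0 / fs)


def _extremal_slope_time(
    dv: np.ndarray, i0: int, i1: int, fs: float, mode: str, fit_half_ms: float
) -> float:
    """Locate the extremal derivative in ``dv[i0:i1]`` with sub-sample
    refinement: coarse argmax/argmin (earliest sample on ties), then the
    vertex of a local least-squares parabola.  Falls back to the coarse
    sample when the fit is degenerate or the vertex leaves the fit window."""
    d = dv[i0:i1]
    k = int(np.argmax(d) if mode == "max" else np.argmin(d))
    # near-ties (within float jitter of the extremum) resolve to the
    # earliest sample, without sub-sample refinement
    tol = 1e-9 * max(1.0, float(np.abs(d).max()))
    ties = np.flatnonzero(np.abs(d - d[k]) <= tol)
    if ties.size > 1:
        return (i0 + int(ties[0])) / fs
    L = int(round(fit_half_ms * fs / 1000.0))
    lo, hi = max(k - L, 0), min(k + L + 1, d.size)
    if L > 0 and hi - lo >= 5:
        u = np.arange(lo, hi, dtype=float) - k
        a, b, _ = np.polyfit(u, d[lo:hi], 2)
        if a != 0.0:
            delta = -b / (2.0 * a)
            if abs(delta) <= L:
                return (i0 + k + delta) / fs
    return (i0 + k) / fs


def detect_activation_time(
    beat_segment: np.ndarray, fs: float, cfg: EGMAnalysisConfig = EGMAnalysisConfig()
) -> float | None:
    """AT (s, relative to segment start): minimum dV/dt in the segment.

    The segment should cover the QRS search window only.  Returns ``None``
    when peak-to-peak amplitude is below the noise floor.
    """
    seg = np.asarray(beat_segment, dtype=float)
    if np.ptp(seg) < cfg.min_amplitude_mv:
        return None
    dv = _smooth_derivative(seg, fs, cfg.deriv_window_ms, cfg.deriv_polyorder)
    return _extremal_slope_time(dv, 0, seg.size, fs, "min", cfg.vertex_fit_half_ms)


def detect_repolarization_time(
    beat_segment: np.ndarray,
    fs: float,
    t_window: tuple[float, float],
    cfg: EGMAnalysisConfig = EGMAnalysisConfig(),
) -> float | None:
    """RT (s, relative to segment start): maximum dV/dt inside ``t_window``.

    Polarity-agnostic (Wyatt): the steepest positive slope marks local
    repolarization for upright and inverted T waves alike.
    """
    seg = np.asarray(beat_segment, dtype=float)
    i0 = int(np.ceil(t_window[0] * fs))
    i1 = int(np.floor(t_window[1] * fs))
    i0, i1 = max(i0, 0), min(i1, seg.size)
    if i1 <= i0:
        raise ValueError("empty T-wave search window")
    if np.ptp(seg[i0:i1]) < cfg.min_amplitude_mv:
        return None
    dv = _smooth_derivative(seg, fs, cfg.t_deriv_window_ms, cfg.t_deriv_polyorder)
    return _extremal_slope_time(dv, i0, i1, fs, "max", cfg.vertex_fit_half_ms)


def measure_st_elevation(
    beat_segment: np.ndarray, fs: float, cfg: EGMAnalysisConfig = EGMAnalysisConfig()
) -> float:
    """ST deviation (mV, signed): mean over the ST window minus mean over
    the pre-QRS isoelectric window.  Depression comes out negative."""
    seg = np.asarray(beat_segment, dtype=float)

    def mean_over(win_ms: tuple[float, float]) -> float:
        i0 = int(np.ceil(win_ms[0] * fs / 1000.0))
        i1 = int(np.floor(win_ms[1] * fs / 1000.0))
        if i1 <= i0 or i1 > seg.size:
            raise ValueError(f"measurement window {win_ms} outside beat segment")
        return float(seg[i0:i1].mean())

    return mean_over(cfg.st_window_ms) - mean_over(cfg.iso_window_ms)


def measure_beats(
    egm: ElectrogramSet,
    cfg: EGMAnalysisConfig = EGMAnalysisConfig(),
) -> list[BeatMeasurement]:
    """Run AT/RT/ST detection for every electrode × beat.

    Requires ``egm.beat_marks``; each beat spans from its mark to the next
    (or the end of the record).
    """
    if egm.beat_marks is None or len(egm.beat_marks) == 0:
        raise ValueError("electrogram set has no beat marks")
    marks = np.asarray(egm.beat_marks, float)
    fs = egm.fs
    ends = np.append(marks[1:], egm.samples.shape[1] / fs + marks[0])
    out: list[BeatMeasurement] = []
    q0, q1 = (v / 1000.0 for v in cfg.qrs_window_ms)
    t_win = (cfg.t_window_ms[0] / 1000.0, cfg.t_window_ms[1] / 1000.0)
    rec_t0 = marks[0]
    for b, (m, e) in enumerate(zip(marks, ends)):
        i0 = int(round((m - rec_t0) * fs))
        i1 = min(int(round((e - rec_t0) * fs)), egm.samples.shape[1])
        for row, eid in enumerate(egm.electrode_ids):
            seg = egm.samples[row, i0:i1]
            flags = []
            qi0, qi1 = int(round(q0 * fs)), min(int(round(q1 * fs)), seg.size)
            at_rel = detect_activation_time(seg[qi0:qi1], fs, cfg)
            if at_rel is None:
                flags.append("at_undefined")
                at_s = None
            else:
                at_s = m + q0 + at_rel
            rt_rel = detect_repolarization_time(seg, fs, t_win, cfg)
            if rt_rel is None:
                flags.append("rt_undefined")
                rt_s = None
            else:
                rt_s = m + rt_rel
            st = measure_st_elevation(seg, fs, cfg)
            out.append(
                BeatMeasurement(
                    electrode_id=int(eid),
                    beat_index=b,
                    at_s=at_s,
                    rt_s=rt_s,
                    st_mv=st,
                    flags=";".join(flags),
                    onset_s=float(m),
                )
            )
    return out


def compute_ari(
    measurements: Iterable[BeatMeasurement],
    epoch: str = "",
    cfg: EGMAnalysisConfig = EGMAnalysisConfig(),
) -> ARIMap:
    """Per-electrode mean ARI over valid beats.

    Electrodes where fewer than ``min_valid_fraction`` of beats are valid
    are flagged; electrodes with no valid beat are excluded with a warning.
    """
    by_el: dict[int, list[BeatMeasurement]] = {}
    for m in measurements:
        by_el.setdefault(m.electrode_id, []).append(m)
    ari: dict[int, float] = {}
    flagged: set[int] = set()
    for eid, ms in sorted(by_el.items()):
        valid = [m.ari_ms for m in ms if m.valid]
        if not valid:
            warnings.warn(f"electrode {eid}: no valid beats, excluded from ARI map")
            flagged.add(eid)
            continue
        if len(valid) < cfg.min_valid_fraction * len(ms):
            flagged.add(eid)
        ari[eid] = float(np.mean(valid))
    return ARIMap(epoch=epoch, ari_ms=ari, flagged=flagged)


def define_ischemic_zone(
    st_mv: Mapping[int, float], threshold_mv: float = 0.1
) -> set[int]:
    """Electrodes whose ST deviation reaches the elevation threshold."""
    mask = {e for e, v in st_mv.items() if v >= threshold_mv and v > 0}
    if not mask:
        warnings.warn("no electrode exceeds the ST-elevation threshold")
    return mask


def ari_shortening(
    map_baseline: ARIMap, map_ischemia: ARIMap, mask: set[int]
) -> float:
    """Mean ARI change (ms) over the ischemic-zone electrodes.

    Negative values mean shortening (sympathoexcitation).
    """
    if not mask:
        raise ValueError("ischemic mask is empty")
    missing = mask - (set(map_baseline.ari_ms) & set(map_ischemia.ari_ms))
    if missing:
        raise ValueError(f"mask electrodes missing from a map: {sorted(missing)}")
    deltas = [map_ischemia.ari_ms[e] - map_baseline.ari_ms[e] for e in sorted(mask)]
    return float(np.mean(deltas))


def compute_dor(
    measurements: Iterable[BeatMeasurement],
    epoch: str = "",
    cfg: EGMAnalysisConfig = EGMAnalysisConfig(),
) -> DORResult:
    """Dispersion of repolarization: across-electrode sample variance (ms²)
    of the per-electrode mean repolarization time (or ARI, per config)."""
    by_el: dict[int, list[float]] = {}
    for m in measurements:
        if not m.valid:
            continue
        v = (m.rt_s - m.onset_s) * 1000.0 if cfg.dor_metric == "rt" else m.ari_ms
        by_el.setdefault(m.electrode_id, []).append(v)
    per_el = [float(np.mean(v)) for _, v in sorted(by_el.items())]
    if len(per_el) < 2:
        raise ValueError("dispersion needs at least 2 electrodes with valid beats")
    return DORResult(
        epoch=epoch,
        dor_ms2=float(np.var(per_el, ddof=1)),
        n_electrodes=len(per_el),
    )
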