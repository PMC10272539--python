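"""Full study orchestration: clean → classify → test → synchrony → report.

The protocol compares a coronary-occlusion challenge before and after a
spinal-stimulation intervention: neurons are screened for ischemia
sensitivity on the pre-intervention occlusion, the *same* neurons (tracked
by sorter identity) are followed through the post-intervention occlusion,
and per-epoch rate deltas, electrogram markers (ARI shortening, DOR) and
pairwise synchrony are assembled into one report with group-level
statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_modalities, label_regions
from .core_io import (
    ElectrogramSet,
    ProtocolTimeline,
    Region,
    SpikeTrainSet,
    read_electrograms,
    read_spike_table,
    read_timeline,
)
from .egm import (
    ARIMap,
    EGMAnalysisConfig,
    ari_shortening,
    compute_ari,
    compute_dor,
    define_ischemic_zone,
    measure_beats,
)
from .preprocess import remove_artifacts
from .skellam import Direction, classify_ischemia_sensitive, response_delta
from .synchrony import SynchronyConfig, pairwise_synchrony

__all__ = ["StudyConfig", "StudyReport", "run_study", "group_compare",
           "friedman_dunn", "mad_outlier_flags"]

log = logging.getLogger("cardiospinal")

_DELTA_EPOCHS = ("lad_pre", "rep_pre", "lad_post", "rep_post")


@dataclass
class StudyConfig:
    """Inputs and parameters of one study run.

    Data can be supplied in memory (``spikes``, ``timeline``,
    ``egm_segments``) or as paths; in-memory objects win.  ``stages``
    selects which analysis stages run — electrogram and synchrony stages
    are skipped automatically when their inputs are absent.
    """

    spikes: SpikeTrainSet | None = None
    timeline: ProtocolTimeline | None = None
    egm_segments: dict[str, ElectrogramSet] = field(default_factory=dict)

    spikes_path: str | None = None
    adjacency_path: str | None = None
    timeline_path: str | None = None
    egm_paths: dict[str, str] = field(default_factory=dict)

    alpha: float = 0.05
    seed: int = 0
    artifact_tol_ms: float = 0.5
    equalize: str = "scale"
    egm_cfg: EGMAnalysisConfig = field(default_factory=EGMAnalysisConfig)
    sync_cfg: SynchronyConfig = field(default_factory=SynchronyConfig)
    sync_epochs: tuple[str, ...] = ("lad_pre", "lad_post")
    sync_max_pairs_per_category: int | None = 200
    outlier_flagging: bool = True
    stages: tuple[str, ...] = (
        "clean", "classify", "sensitivity", "modalities", "deltas",
        "egm", "synchrony", "group",
    )


@dataclass
class StudyReport:
    """Structured result tables of :func:`run_study`."""

    counts: dict[str, int] = field(default_factory=dict)
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)
    modalities: pd.DataFrame = field(default_factory=pd.DataFrame)
    deltas: pd.DataFrame = field(default_factory=pd.DataFrame)
    egm_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    synchrony_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    synchrony_agg: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.Series(self.counts, dtype=object).to_csv(
            out / "counts.tsv", sep="\t", header=False
        )
        for name in (
            "labels", "sensitivity", "modalities", "deltas", "egm_metrics",
            "synchrony_pairs", "synchrony_agg", "group_tests",
        ):
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(cfg: StudyConfig) -> tuple[SpikeTrainSet, ProtocolTimeline, dict]:
    timeline = cfg.timeline or (
        read_timeline(cfg.timeline_path) if cfg.timeline_path else None
    )
    if timeline is None:
        raise ValueError("study needs a timeline (in memory or via timeline_path)")
    spikes = cfg.spikes
    if spikes is None:
        if not (cfg.spikes_path and cfg.adjacency_path):
            raise ValueError("study needs spike data (in memory or via paths)")
        spikes = read_spike_table(cfg.spikes_path, cfg.adjacency_path, duration=timeline.end)
    egm = dict(cfg.egm_segments)
    for epoch, path in cfg.egm_paths.items():
        egm.setdefault(epoch, read_electrograms(path))
    return spikes, timeline, egm


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the configured stages and assemble the study report.

    Deterministic under a fixed config + seed.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    report = StudyReport()
    # input problems are configuration errors, not stage failures
    spikes, timeline, egm = _load_inputs(cfg)
    stage = "start"
    try:
        report.counts["neurons_recorded"] = len(spikes)
        report.counts["spikes_recorded"] = sum(tr.n_spikes for tr in spikes)

        if "clean" in cfg.stages:
            stage = "clean"
            spikes, removal_log = remove_artifacts(spikes, cfg.artifact_tol_ms)
            report.counts["artifact_events_removed"] = len(removal_log)
            log.info("clean: removed %d artifact events", len(removal_log))

        labels = {}
        if "classify" in cfg.stages and "t2" in timeline.stim_pulses:
            stage = "classify"
            anti = label_regions(spikes, timeline)
            labels = {
                nid: ("IML" if r.is_iml else "DH") for nid, r in anti.items()
            }
            report.labels = pd.DataFrame(
                [
                    {
                        "neuron_id": r.neuron_id,
                        "region": labels[r.neuron_id],
                        "n_pulses": r.n_pulses,
                        "n_responses": r.n_responses,
                        "follow_fraction": r.follow_fraction,
                        "latency_mean_ms": r.latency_mean_ms,
                        "latency_sd_ms": r.latency_sd_ms,
                    }
                    for r in anti.values()
                ]
            )
            report.counts["iml_neurons"] = sum(v == "IML" for v in labels.values())
            report.counts["dh_neurons"] = sum(v == "DH" for v in labels.values())

        sensitive: set[str] = set()
        if "sensitivity" in cfg.stages:
            stage = "sensitivity"
            tests = classify_ischemia_sensitive(
                spikes, timeline, alpha=cfg.alpha, equalize=cfg.equalize
            )
            sensitive = {
                nid for nid, r in tests.items() if r.direction is Direction.INCREASE
            }
            report.sensitivity = pd.DataFrame(
                [
                    {
                        "neuron_id": r.neuron_id,
                        "region": labels.get(r.neuron_id, "UNKNOWN"),
                        "count_ref": r.count_ref,
                        "rate_ref_hz": r.rate_ref_hz,
                        "count_test": r.count_test,
                        "rate_test_hz": r.rate_test_hz,
                        "delta_hz": r.delta_hz,
                        "p_value": r.p_two_sided,
                        "direction": r.direction.value,
                        "ischemia_sensitive": r.neuron_id in sensitive,
                    }
                    for r in tests.values()
                ]
            )
            report.counts["ischemia_sensitive_neurons"] = len(sensitive)
            log.info("sensitivity: %d / %d neurons", len(sensitive), len(spikes))

        if "modalities" in cfg.stages and sensitive and any(
            e in timeline.epochs for e in ("touch_rv", "touch_lv", "bradykinin", "capsaicin")
        ):
            stage = "modalities"
            rows = []
            for tr in spikes:
                if tr.neuron_id not in sensitive:
                    continue  # only ischemia-sensitive neurons are profiled
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lab = classify_modalities(tr, timeline, cfg.alpha, True)
                rows.append(
                    {
                        "neuron_id": lab.neuron_id,
                        "mechano": lab.mechano,
                        "nociceptive": lab.nociceptive,
                        "multimodal": lab.multimodal,
                    }
                )
            report.modalities = pd.DataFrame(rows)

        if "deltas" in cfg.stages and sensitive:
            stage = "deltas"
            rows = []
            for tr in spikes:
                if tr.neuron_id not in sensitive:
                    continue
                row = {"neuron_id": tr.neuron_id, "region": labels.get(tr.neuron_id, "UNKNOWN")}
                for ep in _DELTA_EPOCHS:
                    if ep in timeline.epochs:
                        base = "baseline_pre" if ep.endswith("_pre") else "baseline_post"
                        row[f"delta_{ep}_hz"] = response_delta(tr, timeline, ep, base)
                rows.append(row)
            deltas = pd.DataFrame(rows)
            if cfg.outlier_flagging and not deltas.empty:
                for ep in _DELTA_EPOCHS:
                    col = f"delta_{ep}_hz"
                    if col in deltas:
                        deltas[f"outlier_{ep}"] = mad_outlier_flags(deltas[col].to_numpy())
            report.deltas = deltas

        if "egm" in cfg.stages and egm:
            stage = "egm"
            report.egm_metrics = _egm_stage(egm, cfg.egm_cfg)

        if "synchrony" in cfg.stages and labels:
            stage = "synchrony"
            sync_epochs = {
                e: timeline.epochs[e] for e in cfg.sync_epochs if e in timeline.epochs
            }
            pairs, agg = pairwise_synchrony(
                spikes, sync_epochs, cfg.sync_cfg, cfg.seed,
                cfg.sync_max_pairs_per_category,
            )
            report.synchrony_pairs, report.synchrony_agg = pairs, agg

        if "group" in cfg.stages:
            stage = "group"
            report.group_tests = group_compare(report, cfg.alpha)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return report


def _epoch_st(measurements) -> dict[int, float]:
    by_el: dict[int, list[float]] = {}
    for m in measurements:
        if m.st_mv is not None:
            by_el.setdefault(m.electrode_id, []).append(m.st_mv)
    return {e: float(np.mean(v)) for e, v in by_el.items()}


def _egm_stage(egm: dict[str, ElectrogramSet], ecfg: EGMAnalysisConfig) -> pd.DataFrame:
    """Per-epoch ARI map, DOR and ST; ARI shortening over the ischemic zone
    for each occlusion relative to its preceding baseline."""
    meas = {ep: measure_beats(e, ecfg) for ep, e in egm.items()}
    maps = {ep: compute_ari(m, ep, ecfg) for ep, m in meas.items()}
    rows = []
    for ep, m in meas.items():
        dor = compute_dor(m, ep, ecfg)
        st = _epoch_st(m)
        rows.append(
            {
                "epoch": ep,
                "metric": "dor_ms2",
                "value": dor.dor_ms2,
                "n": dor.n_electrodes,
            }
        )
        rows.append(
            {
                "epoch": ep,
                "metric": "mean_ari_ms",
                "value": float(np.mean(list(maps[ep].ari_ms.values()))),
                "n": len(maps[ep].ari_ms),
            }
        )
        rows.append(
            {"epoch": ep, "metric": "max_st_mv", "value": max(st.values()), "n": len(st)}
        )
    for occl, base in (("lad_pre", "baseline_pre"), ("lad_post", "baseline_post")):
        if occl in meas and base in meas:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = define_ischemic_zone(_epoch_st(meas[occl]), ecfg.st_threshold_mv)
            if mask:
                delta = ari_shortening(maps[base], maps[occl], mask)
                rows.append(
                    {
                        "epoch": occl,
                        "metric": "ari_shortening_ms",
                        "value": delta,
                        "n": len(mask),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def mad_outlier_flags(x: np.ndarray, n_mads: float = 3.5) -> np.ndarray:
    """Flag (never remove) values beyond ``n_mads`` robust SDs of the median."""
    x = np.asarray(x, float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - med) > n_mads * mad


def friedman_dunn(wide: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Friedman test across related columns + Dunn's pairwise comparisons.

    Rows are subjects (neurons), columns the repeated conditions.  Dunn's
    z uses within-subject ranks, ``z = (R̄_i − R̄_j) / sqrt(k(k+1)/(6n))``,
    with Bonferroni-adjusted two-sided normal p-values.
    """
    data = wide.dropna().to_numpy(dtype=float)
    n, k = data.shape
    rows = []
    if n < 3 or k < 2:
        return pd.DataFrame(
            [{"test": "friedman", "p_value": np.nan, "n": n,
              "note": "skipped: fewer than 3 complete subjects"}]
        )
    if np.all(np.ptp(data, axis=1) == 0):
        # every subject identical across conditions: nothing to test
        return pd.DataFrame(
            [{"test": "friedman", "statistic": np.nan, "p_value": 1.0,
              "n": n, "note": "identical samples"}]
        )
    stat, p = stats.friedmanchisquare(*data.T)
    rows.append({"test": "friedman", "statistic": float(stat), "p_value": float(p),
                 "n": n, "note": ""})
    ranks = stats.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    cols = list(wide.columns)
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            rows.append(
                {"test": f"dunn:{cols[i]}|{cols[j]}", "statistic": float(z),
                 "p_value": float(p_adj), "n": n, "note": "bonferroni-adjusted"}
            )
    return pd.DataFrame(rows)


def group_compare(report: StudyReport, alpha: float = 0.05) -> pd.DataFrame:
    """Group-level tests on the study tables.

    Friedman + Dunn across the four occlusion/reperfusion deltas of the
    ischemia-sensitive neurons; Kruskal-Wallis across modality groups'
    pre-intervention occlusion deltas; Wilcoxon signed-rank on paired
    pre- vs post-intervention synchrony indices.
    """
    frames = []
    deltas = report.deltas
    delta_cols = [f"delta_{e}_hz" for e in _DELTA_EPOCHS]
    if not deltas.empty and all(c in deltas for c in delta_cols):
        frames.append(friedman_dunn(deltas[delta_cols], alpha))

    if not deltas.empty and not report.modalities.empty and "delta_lad_pre_hz" in deltas:
        merged = deltas.merge(report.modalities, on="neuron_id")
        groups = {
            "mechano": merged.loc[
                merged.mechano.fillna(False) & ~merged.multimodal.fillna(False),
                "delta_lad_pre_hz"],
            "nociceptive": merged.loc[
                merged.nociceptive.fillna(False) & ~merged.multimodal.fillna(False),
                "delta_lad_pre_hz"],
            "multimodal": merged.loc[
                merged.multimodal.fillna(False), "delta_lad_pre_hz"],
        }
        groups = {k: v.to_numpy() for k, v in groups.items() if len(v) >= 3}
        if len(groups) >= 2:
            stat, p = stats.kruskal(*groups.values())
            frames.append(pd.DataFrame([{
                "test": "kruskal:" + "|".join(groups),
                "statistic": float(stat), "p_value": float(p),
                "n": int(sum(len(v) for v in groups.values())), "note": ""}]))
        else:
            frames.append(pd.DataFrame([{
                "test": "kruskal", "statistic": np.nan, "p_value": np.nan,
                "n": 0, "note": "skipped: fewer than 2 groups with n >= 3"}]))

    sp = report.synchrony_pairs
    if not sp.empty and {"lad_pre", "lad_post"} <= set(sp["epoch"]):
        piv = sp.pivot_table(
            index=["category", "ref_id", "target_id"], columns="epoch", values="si"
        ).dropna()
        for cat, sub in piv.groupby(level="category"):
            x, y = sub["lad_pre"].to_numpy(), sub["lad_post"].to_numpy()
            if len(x) < 3:
                note, stat, p = "skipped: fewer than 3 pairs", np.nan, np.nan
            elif np.allclose(x, y):
                note, stat, p = "identical samples", np.nan, 1.0
            else:
                res = stats.wilcoxon(x, y)
                note, stat, p = "", float(res.statistic), float(res.pvalue)
            frames.append(pd.DataFrame([{
                "test": f"wilcoxon_synchrony:{cat}", "statistic": stat,
                "p_value": p, "n": len(x), "note": note}]))

    if not frames:
        return pd.DataFrame(columns=["test", "statistic", "p_value", "n", "note"])
    return pd.concat(frames, ignore_index=True)
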