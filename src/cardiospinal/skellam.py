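"""Skellam-distribution test for firing-rate change between two windows.

The difference of two independent Poisson counts with means ``mu1, mu2``
follows the Skellam distribution,

    P(K = k) = exp(-(mu1+mu2)) * (mu1/mu2)**(k/2) * I_|k|(2*sqrt(mu1*mu2)),

with ``I`` the modified Bessel function of the first kind.  A neuron's spike
count in a reference window is compared against its count in a test window;
under the no-change null both counts share the pooled rate and their
(duration-normalized) difference is approximately Skellam around zero.

Unequal windows are handled by scaling both counts to the shorter duration
``T* = min(d_ref, d_test)``.  Scaling a Poisson count by ``s = T*/d``
preserves its mean rate but shrinks its variance to ``s * lambda * T*``, so
the null is taken as a symmetric Skellam whose total variance matches the
scaled difference:

    mu0 = pooled_rate * T* * (s_ref + s_test) / 2.

For equal durations this reduces to the plain pooled-rate Skellam null.
A ``truncate`` strategy (discard test-window data beyond ``T*``) is
available one level up, where the raw spike trains are accessible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special, stats

from .core_io import ProtocolTimeline, SpikeTrain, SpikeTrainSet
from .preprocess import count_in_epoch

__all__ = [
    "Direction",
    "SkellamTestResult",
    "skellam_pmf",
    "skellam_cdf",
    "skellam_sf",
    "skellam_test",
    "classify_ischemia_sensitive",
    "response_delta",
]


class Direction(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"


@dataclass
class SkellamTestResult:
    """Per-neuron rate-change test between a reference and a test window."""

    neuron_id: str
    count_ref: int
    dur_ref_s: float
    count_test: int
    dur_test_s: float
    p_two_sided: float
    direction: Direction
    alpha: float = 0.05

    @property
    def rate_ref_hz(self) -> float:
        return self.count_ref / self.dur_ref_s

    @property
    def rate_test_hz(self) -> float:
        return self.count_test / self.dur_test_s

    @property
    def delta_hz(self) -> float:
        return self.rate_test_hz - self.rate_ref_hz


def skellam_pmf(k, mu1: float, mu2: float):
    """P(K = k) for K = N1 - N2, N_i ~ Poisson(mu_i), evaluated in log space.

    Uses the exponentially scaled Bessel function so large means do not
    overflow.  Degenerate means reduce to (reflected) Poisson masses.
    """
    if mu1 < 0 or mu2 < 0:
        raise ValueError("Poisson means must be non-negative")
    k = np.asarray(k)
    scalar = k.ndim == 0
    k = np.atleast_1d(k).astype(int)
    if mu1 == 0.0 and mu2 == 0.0:
        out = (k == 0).astype(float)
    elif mu2 == 0.0:
        out = np.where(k >= 0, stats.poisson.pmf(np.maximum(k, 0), mu1), 0.0)
    elif mu1 == 0.0:
        out = np.where(k <= 0, stats.poisson.pmf(np.maximum(-k, 0), mu2), 0.0)
    else:
        x = 2.0 * np.sqrt(mu1 * mu2)
        # ive = Iv(x) * exp(-x)  =>  log Iv = log(ive) + x;  ive underflows
        # to 0 far in the tails, where the pmf is a clean 0
        with np.errstate(divide="ignore"):
            log_bessel = np.log(special.ive(np.abs(k), x)) + x
        logp = -(mu1 + mu2) + 0.5 * k * (np.log(mu1) - np.log(mu2)) + log_bessel
        out = np.exp(logp)
    return float(out[0]) if scalar else out


def _support(mu1: float, mu2: float) -> tuple[int, int]:
    mean = mu1 - mu2
    sd = np.sqrt(mu1 + mu2)
    lo = int(np.floor(mean - 40.0 * sd - 5.0))
    hi = int(np.ceil(mean + 40.0 * sd + 5.0))
    return lo, hi


def skellam_cdf(k: int, mu1: float, mu2: float) -> float:
    """P(K <= k) by direct pmf summation over the effective support."""
    lo, hi = _support(mu1, mu2)
    if k < lo:
        return 0.0
    ks = np.arange(lo, min(k, hi) + 1)
    return float(min(1.0, skellam_pmf(ks, mu1, mu2).sum()))


def skellam_sf(k: int, mu1: float, mu2: float) -> float:
    """P(K >= k) by direct pmf summation over the effective support."""
    lo, hi = _support(mu1, mu2)
    if k > hi:
        return 0.0
    ks = np.arange(max(k, lo), hi + 1)
    return float(min(1.0, skellam_pmf(ks, mu1, mu2).sum()))


def skellam_test(
    count_ref: int,
    dur_ref: float,
    count_test: int,
    dur_test: float,
    alpha: float = 0.05,
    neuron_id: str = "",
) -> SkellamTestResult:
    """Two-sided Skellam test of rate change between two counting windows.

    Both counts are scaled to the shorter duration; the observed difference
    is compared against the variance-matched symmetric Skellam null at the
    pooled rate.  The two-sided p doubles the smaller tail (capped at 1).
    With both counts zero the test is vacuous: p = 1.
    """
    if dur_ref <= 0 or dur_test <= 0:
        raise ValueError("window durations must be positive")
    if count_ref < 0 or count_test < 0:
        raise ValueError("counts must be non-negative")

    if count_ref == 0 and count_test == 0:
        return SkellamTestResult(
            neuron_id, count_ref, dur_ref, count_test, dur_test, 1.0, Direction.NONE, alpha
        )

    t_star = min(dur_ref, dur_test)
    s_ref, s_test = t_star / dur_ref, t_star / dur_test
    k_obs = int(round(count_test * s_test - count_ref * s_ref))
    pooled = (count_ref + count_test) / (dur_ref + dur_test)
    mu0 = pooled * t_star * (s_ref + s_test) / 2.0
    p = 2.0 * min(skellam_cdf(k_obs, mu0, mu0), skellam_sf(k_obs, mu0, mu0))
    p = float(min(1.0, p))

    delta = count_test / dur_test - count_ref / dur_ref
    if p < alpha and delta > 0:
        direction = Direction.INCREASE
    elif p < alpha and delta < 0:
        direction = Direction.DECREASE
    else:
        direction = Direction.NONE
    return SkellamTestResult(
        neuron_id, count_ref, dur_ref, count_test, dur_test, p, direction, alpha
    )


def _baseline_tail(timeline: ProtocolTimeline, tail_s: float = 60.0) -> tuple[float, float]:
    s, e = timeline.epoch("baseline_pre")
    if e - s < tail_s:
        raise ValueError(f"baseline_pre shorter than the {tail_s:g} s reference window")
    return e - tail_s, e


def classify_ischemia_sensitive(
    sts: SpikeTrainSet,
    timeline: ProtocolTimeline,
    alpha: float = 0.05,
    equalize: str = "scale",
    adjust: str = "none",
    lad_epoch: str = "lad_pre",
) -> dict[str, SkellamTestResult]:
    """Label neurons whose rate significantly increases during occlusion.

    Compares the final 1 min of the pre-occlusion baseline against the 3 min
    occlusion window for every neuron.  A neuron is ischemia-sensitive iff
    its test comes out ``direction=increase``.

    ``equalize='scale'`` (default) scales both windows to the shorter
    duration; ``'truncate'`` uses only the first baseline-length slice of
    the occlusion epoch.  ``adjust='bh'`` applies Benjamini-Hochberg across
    neurons (off by default: the protocol screens neurons one at a time and
    then follows them).
    """
    if equalize not in {"scale", "truncate"}:
        raise ValueError("equalize must be 'scale' or 'truncate'")
    ref_win = _baseline_tail(timeline)
    lad_s, lad_e = timeline.epoch(lad_epoch)
    dur_ref = ref_win[1] - ref_win[0]
    if equalize == "truncate":
        lad_e = min(lad_e, lad_s + dur_ref)

    results: dict[str, SkellamTestResult] = {}
    for tr in sts:
        c_ref = count_in_epoch(tr, ref_win)
        c_test = count_in_epoch(tr, (lad_s, lad_e))
        results[tr.neuron_id] = skellam_test(
            c_ref, dur_ref, c_test, lad_e - lad_s, alpha=alpha, neuron_id=tr.neuron_id
        )

    if adjust == "bh":
        ids = list(results)
        p_adj = stats.false_discovery_control(
            [results[i].p_two_sided for i in ids], method="bh"
        )
        for nid, padj in zip(ids, p_adj):
            r = results[nid]
            direction = Direction.NONE
            if padj < alpha:
                direction = (
                    Direction.INCREASE if r.delta_hz > 0
                    else Direction.DECREASE if r.delta_hz < 0
                    else Direction.NONE
                )
            results[nid] = SkellamTestResult(
                r.neuron_id, r.count_ref, r.dur_ref_s, r.count_test, r.dur_test_s,
                float(padj), direction, alpha,
            )
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'bh'")
    return results


def response_delta(
    train: SpikeTrain,
    timeline: ProtocolTimeline,
    epoch: str,
    baseline_epoch: str = "baseline_pre",
    baseline_tail_s: float | None = 60.0,
) -> float:
    """Firing-rate change (Hz): rate in ``epoch`` minus the baseline rate.

    Negative values mean the neuron slowed down relative to baseline.  By
    default the baseline rate comes from the final ``baseline_tail_s``
    seconds of the baseline epoch (matching the classification reference
    window); pass ``None`` to use the whole epoch.
    """
    s, e = timeline.epoch(epoch)
    bs, be = timeline.epoch(baseline_epoch)
    if baseline_tail_s is not None and be - bs > baseline_tail_s:
        bs = be - baseline_tail_s
    rate_epoch = count_in_epoch(train, (s, e)) / (e - s)
    rate_base = count_in_epoch(train, (bs, be)) / (be - bs)
    return rate_epoch - rate_base
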