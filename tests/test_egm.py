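import numpy as np
import pandas as pd
import pytest

from cardiospinal import (
    ARIMap,
    BeatMeasurement,
    EGMAnalysisConfig,
    SynthEGMConfig,
    ari_shortening,
    compute_ari,
    compute_dor,
    define_ischemic_zone,
    detect_activation_time,
    detect_repolarization_time,
    gen_electrograms,
    measure_beats,
    measure_st_elevation,
)
from cardiospinal.synthetic import default_timeline

FS = 1000.0


@pytest.fixture(scope="module")
def tl():
    return default_timeline()


def _one_beat(tl, **kw):
    cfg = SynthEGMConfig(n_electrodes=1, n_beats=1, noise_sd_mv=0.0, **kw)
    egm, truth = gen_electrograms(cfg, tl)
    return egm.samples[0], truth


class TestDetectors:
    def test_at_recovered_within_one_sample(self, tl):
        seg, truth = _one_beat(tl, at_ms=40.0, rt_ms=340.0)
        at = detect_activation_time(seg[:120], FS)
        assert at == pytest.approx(0.040, abs=1.0 / FS)

    def test_rt_recovered_within_one_sample(self, tl):
        seg, truth = _one_beat(tl, at_ms=40.0, rt_ms=340.0)
        rt = detect_repolarization_time(seg, FS, (0.150, 0.560))
        assert rt == pytest.approx(0.340, abs=1.0 / FS)

    def test_inverted_t_wave_still_recovers_rt(self, tl):
        """Wyatt convention: max positive dV/dt marks RT for either T polarity."""
        seg, truth = _one_beat(tl, at_ms=40.0, rt_ms=340.0, t_amp_mv=-0.8)
        rt = detect_repolarization_time(seg, FS, (0.150, 0.560))
        assert rt == pytest.approx(0.340, abs=1.0 / FS)

    def test_constant_slope_ramp_returns_earliest_sample(self):
        seg = np.linspace(0.0, -1.0, 200)  # constant negative slope
        at = detect_activation_time(seg, FS)
        assert at == 0.0

    def test_flat_segment_flagged_undefined(self):
        assert detect_activation_time(np.zeros(100), FS) is None

    def test_empty_t_window_rejected(self, tl):
        seg, _ = _one_beat(tl)
        with pytest.raises(ValueError, match="window"):
            detect_repolarization_time(seg, FS, (0.5, 0.4))


class TestSTElevation:
    def test_generator_shift_recovered(self, tl):
        cfg = SynthEGMConfig(n_electrodes=1, n_beats=1, noise_sd_mv=0.0,
                             ischemic_mask=frozenset({0}), st_shift_mv=0.2)
        lad0 = tl.epochs["lad_pre"][0]
        egm, _ = gen_electrograms(cfg, tl, start_time_s=lad0)
        st = measure_st_elevation(egm.samples[0], FS)
        assert st == pytest.approx(0.2, abs=0.01)

    def test_no_shift_near_zero(self, tl):
        seg, _ = _one_beat(tl)
        assert measure_st_elevation(seg, FS) == pytest.approx(0.0, abs=0.01)

    def test_depression_reported_with_sign(self, tl):
        cfg = SynthEGMConfig(n_electrodes=1, n_beats=1, noise_sd_mv=0.0,
                             ischemic_mask=frozenset({0}), st_shift_mv=-0.1)
        lad0 = tl.epochs["lad_pre"][0]
        egm, _ = gen_electrograms(cfg, tl, start_time_s=lad0)
        assert measure_st_elevation(egm.samples[0], FS) == pytest.approx(-0.1, abs=0.01)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EGMAnalysisConfig(iso_window_ms=(0, 100), st_window_ms=(90, 180))


def _meas(eid, beat, at_ms, rt_ms, onset=0.0):
    return BeatMeasurement(eid, beat, onset + at_ms / 1000.0, onset + rt_ms / 1000.0,
                           0.0, onset_s=onset)


class TestARIMap:
    def test_constant_ari(self):
        ms = [_meas(0, b, 40.0, 340.0) for b in range(3)]
        amap = compute_ari(ms)
        assert amap.ari_ms[0] == pytest.approx(300.0)

    def test_mean_of_two_beats(self):
        ms = [_meas(0, 0, 40.0, 340.0), _meas(0, 1, 40.0, 350.0)]
        assert compute_ari(ms).ari_ms[0] == pytest.approx(305.0)

    def test_all_invalid_electrode_excluded(self):
        ms = [BeatMeasurement(0, b, None, None, 0.0, flags="at_undefined")
              for b in range(3)]
        ms += [_meas(1, b, 40.0, 340.0) for b in range(3)]
        with pytest.warns(UserWarning, match="no valid beats"):
            amap = compute_ari(ms)
        assert 0 not in amap.ari_ms
        assert 0 in amap.flagged

    def test_minority_valid_flagged(self):
        ms = [_meas(0, 0, 40.0, 340.0)]
        ms += [BeatMeasurement(0, b, None, None, 0.0) for b in range(1, 4)]
        amap = compute_ari(ms)
        assert 0 in amap.flagged and 0 in amap.ari_ms


class TestIschemicZone:
    def test_threshold_rule(self):
        mask = define_ischemic_zone({0: 0.3, 1: 0.0, 2: 0.15}, 0.1)
        assert mask == {0, 2}

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="threshold"):
            mask = define_ischemic_zone({0: 0.05, 1: 0.01}, 0.1)
        assert mask == set()

    def test_zero_threshold_takes_positive_only(self):
        assert define_ischemic_zone({0: 0.3, 1: -0.1, 2: 0.0}, 0.0) == {0}


class TestARIShortening:
    def test_subtraction(self):
        base = ARIMap("baseline_pre", {0: 310.0, 1: 310.0})
        isch = ARIMap("lad_pre", {0: 210.0, 1: 210.0})
        assert ari_shortening(base, isch, {0, 1}) == pytest.approx(-100.0)

    def test_identity_is_zero(self):
        m = ARIMap("x", {0: 300.0, 1: 280.0})
        assert ari_shortening(m, m, {0, 1}) == 0.0

    def test_empty_mask_rejected(self):
        m = ARIMap("x", {0: 300.0})
        with pytest.raises(ValueError, match="empty"):
            ari_shortening(m, m, set())

    def test_end_to_end_recovery_from_generator(self, tl):
        """Noise-free synthetic occlusion: the configured 100 ms advance of
        repolarization is recovered as −100 ms ARI shortening."""
        mask = frozenset(range(4))
        cfg = SynthEGMConfig(n_electrodes=8, n_beats=5, noise_sd_mv=0.0,
                             ischemic_mask=mask, ari_shortening_ms=100.0,
                             st_shift_mv=0.2)
        egm_b, _ = gen_electrograms(cfg, tl, start_time_s=0.0)
        egm_i, _ = gen_electrograms(cfg, tl, start_time_s=tl.epochs["lad_pre"][0])
        mb = measure_beats(egm_b)
        mi = measure_beats(egm_i)
        st = {m.electrode_id: m.st_mv for m in mi}
        zone = define_ischemic_zone(st, 0.1)
        assert zone == set(mask)
        delta = ari_shortening(compute_ari(mb), compute_ari(mi), zone)
        assert delta == pytest.approx(-100.0, abs=2.0)


class TestDOR:
    def test_equal_rts_zero(self):
        ms = [_meas(e, 0, 40.0, 340.0) for e in range(4)]
        assert compute_dor(ms).dor_ms2 == pytest.approx(0.0)

    def test_sample_variance_example(self):
        rts = [200.0, 210.0, 220.0, 230.0]
        ms = [_meas(e, 0, 40.0, rt) for e, rt in enumerate(rts)]
        assert compute_dor(ms).dor_ms2 == pytest.approx(166.6667, abs=1e-3)

    def test_single_electrode_rejected(self):
        with pytest.raises(ValueError, match="2 electrodes"):
            compute_dor([_meas(0, 0, 40.0, 340.0)])

    def test_invariant_to_constant_shift(self):
        rts = [200.0, 215.0, 260.0]
        ms1 = [_meas(e, 0, 40.0, rt) for e, rt in enumerate(rts)]
        ms2 = [_meas(e, 0, 40.0, rt + 50.0) for e, rt in enumerate(rts)]
        assert compute_dor(ms1).dor_ms2 == pytest.approx(compute_dor(ms2).dor_ms2)

    def test_quadratic_scaling(self):
        rts = np.array([200.0, 215.0, 260.0])
        ms1 = [_meas(e, 0, 0.0, rt) for e, rt in enumerate(rts)]
        ms2 = [_meas(e, 0, 0.0, 2 * rt) for e, rt in enumerate(rts)]
        assert compute_dor(ms2).dor_ms2 == pytest.approx(4 * compute_dor(ms1).dor_ms2)

    def test_ari_metric_option(self):
        ms = [_meas(e, 0, 40.0, rt) for e, rt in enumerate([240.0, 260.0])]
        cfg = EGMAnalysisConfig(dor_metric="ari")
        assert compute_dor(ms, cfg=cfg).dor_ms2 == pytest.approx(200.0)
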