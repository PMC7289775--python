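import numpy as np
import pytest

from ahcascade import (
    AH,
    N,
    PreprocessConfig,
    Recording,
    RespiratoryEvent,
    SynthConfig,
    align_spo2,
    filter_nf,
    generate_recording,
    label_segments,
    remove_artifacts,
    segmentize,
)
from ahcascade.preprocess import Segment


def make_rec(nf, spo2, fs=8.0, annotations=()):
    return Recording("t", fs, np.asarray(nf, float), np.asarray(spo2, float),
                     annotations=list(annotations))


class TestRemoveArtifacts:
    def test_samples_below_floor_masked(self):
        rec = make_rec([0, 0, 0], [97, 45, 96])
        out = remove_artifacts(rec)
        np.testing.assert_array_equal(out.valid_mask, [True, False, True])
        np.testing.assert_array_equal(out.spo2, rec.spo2)  # values untouched

    def test_all_clean_mask_unchanged(self):
        rec = make_rec(np.zeros(100), np.full(100, 95.0))
        assert remove_artifacts(rec).valid_mask.all()

    def test_dropout_rate_recovered_on_synthetic_recording(self):
        cfg = SynthConfig(duration_s=1800, target_ahi=0, artifact_rate=0.056, seed=5)
        out = remove_artifacts(generate_recording(cfg))
        frac = np.mean(~out.valid_mask)
        assert frac == pytest.approx(0.056, abs=0.012)


class TestFilterNf:
    def test_dc_rejected(self):
        out = filter_nf(np.full(4000, 3.7))
        assert np.abs(out[500:-500]).max() < 1e-3  # DC gone up to the transient tail

    def test_passband_sinusoid_amplitude_within_5pct(self):
        t = np.arange(0, 120, 1 / 8)
        out = filter_nf(np.sin(2 * np.pi * 0.3 * t))
        amp = np.abs(out[240:-240]).max()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_drift_removed_sinusoid_kept(self):
        t = np.arange(0, 300, 1 / 8)
        clean = np.sin(2 * np.pi * 0.3 * t)
        drift = 5 * np.sin(2 * np.pi * 0.005 * t)
        core = slice(400, -400)
        # centered moving average: no group delay, waveform preserved
        out = filter_nf(clean + drift, PreprocessConfig(ma_centered=True))
        assert np.corrcoef(out[core], clean[core])[0, 1] > 0.99
        # causal default: same shape up to the 1.5-sample average delay
        out_causal = filter_nf(clean + drift)
        assert np.corrcoef(out_causal[core], clean[core])[0, 1] > 0.9

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            filter_nf(np.zeros(10))


class TestAlignSpo2:
    def test_dip_advanced_by_tau(self):
        n = 8 * 200
        spo2 = np.full(n, 97.0)
        spo2[100 * 8] = 88.0  # impulse dip at t=100
        out = align_spo2(make_rec(np.zeros(n), spo2), PreprocessConfig(tau_s=23))
        assert out.spo2[77 * 8] == 88.0
        assert not out.valid_mask[-23 * 8 :].any()  # trailing tau invalid

    def test_tau_bounds_enforced_by_config(self):
        for bad in (0, 30):
            with pytest.raises(ValueError, match="tau_s"):
                PreprocessConfig(tau_s=bad)

    def test_recording_shorter_than_tau_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            align_spo2(make_rec(np.zeros(80), np.full(80, 97.0)))

    def test_inverse_shift_restores_spo2(self):
        rng = np.random.default_rng(0)
        n = 8 * 120
        spo2 = 95 + rng.normal(0, 1, n)
        rec = make_rec(np.zeros(n), spo2)
        out = align_spo2(rec, PreprocessConfig(tau_s=23))
        shift = 23 * 8
        np.testing.assert_allclose(out.spo2[: n - shift], spo2[shift:])

    def test_desat_lag_compensated_on_synthetic_event(self):
        cfg = SynthConfig(duration_s=900, target_ahi=20, desat_lag_s=23,
                          artifact_rate=0.0, seed=9)
        rec = generate_recording(cfg)
        out = align_spo2(rec, PreprocessConfig(tau_s=23))
        ev = rec.annotations[0]
        # after alignment the desaturation dip onset sits within +-2 s of
        # the flow event onset
        i0 = int((ev.onset_s - 2) * 8)
        i1 = int((ev.onset_s + 10) * 8)
        pre = out.spo2[int((ev.onset_s - 15) * 8) : i0]
        assert out.spo2[i0:i1].min() <= pre.min() - 1


class TestSegmentize:
    @pytest.mark.parametrize("window_s,expected", [(60, 61), (10, 111)])
    def test_segment_count_120s(self, window_s, expected):
        rec = make_rec(np.zeros(8 * 120), np.full(8 * 120, 97.0))
        segs = segmentize(rec, window_s)
        assert len(segs) == expected
        assert [s.start_s for s in segs] == list(range(expected))

    def test_window_longer_than_recording_gives_empty(self):
        rec = make_rec(np.zeros(8 * 9), np.full(8 * 9, 97.0))
        assert segmentize(rec, 10) == []

    def test_invalid_fraction_flags_unusable(self):
        rec = make_rec(np.zeros(8 * 30), np.full(8 * 30, 97.0))
        rec.valid_mask[: 8 * 2] = False  # 2 s invalid
        segs = segmentize(rec, 10)
        # windows overlapping >1 s (10%) of the invalid block are unusable
        assert not segs[0].usable
        assert segs[2].usable


class TestLabelSegments:
    def seg(self, start, window=10):
        return Segment(start_s=start, window_s=window, recording_ref="t")

    def test_overlap_above_threshold_is_ah(self):
        (out,) = label_segments([self.seg(100)], [RespiratoryEvent(104, 26)])
        assert out.label == AH

    def test_exact_5s_overlap_is_n(self):
        (out,) = label_segments([self.seg(100)], [RespiratoryEvent(105, 25)])
        assert out.label == N

    def test_union_of_two_events_counts_once(self):
        events = [RespiratoryEvent(0, 4), RespiratoryEvent(6, 4)]
        (out,) = label_segments([self.seg(0)], events)
        assert out.label == AH  # union overlap 8 s

    def test_invariant_to_order_and_event_splitting(self):
        rng = np.random.default_rng(7)
        segs = [self.seg(s) for s in range(0, 50)]
        events = [RespiratoryEvent(12.0, 20.0), RespiratoryEvent(40.0, 11.0)]
        base = [s.label for s in label_segments(segs, events)]
        shuffled = [s.label for s in label_segments(segs, events[::-1])]
        # split the first event into abutting sub-events
        split = [RespiratoryEvent(12.0, 7.0), RespiratoryEvent(19.0, 13.0), events[1]]
        rng.shuffle(split)
        split_labels = [s.label for s in label_segments(segs, split)]
        assert base == shuffled == split_labels

    def test_overlapping_events_not_double_counted(self):
        # two overlapping 3-s events cover only [0, 4): union 4 s -> N
        events = [RespiratoryEvent(0, 3), RespiratoryEvent(1, 3)]
        (out,) = label_segments([self.seg(0)], events)
        assert out.label == N
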