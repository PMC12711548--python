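"""Filtering, channel rejection, baseline correction and block splitting."""

import numpy as np
import pytest
from scipy import signal as sps

from respconn.preprocessing import (
    DEFAULT_BANDS,
    Annotation,
    BandDefinition,
    Recording,
    bandpass,
    bandpass_array,
    baseline_correct,
    reject_channels,
    split_conditions_and_bands,
)
from respconn.spectral import welch_psd
from respconn.synthetic_data import default_paradigm, default_coupling, generate_subject

FS = 500.0


def _sine_recording(freq, duration=10.0, n_ch=1, amp=1.0):
    t = np.arange(int(duration * FS)) / FS
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    names = tuple(f"ch{i}" for i in range(n_ch))
    return Recording(data, FS, names)


class TestBandpass:
    def test_in_band_sinusoid_passes_with_little_attenuation(self):
        rec = bandpass(_sine_recording(10.0), 8.0, 13.0)
        steady = rec.data[0, 1000:-1000]
        assert steady.max() > 0.95  # < 5% amplitude loss

    def test_out_of_band_sinusoid_suppressed_per_frequency_response(self):
        """Residual RMS matches the filter's own frequency response at 50 Hz."""
        rec = _sine_recording(50.0)
        out = bandpass(rec, 1.0, 45.0)
        rms_ratio = np.sqrt(np.mean(out.data[0, 1000:-1000] ** 2)) / np.sqrt(0.5)
        sos = sps.butter(4, [1.0, 45.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=FS)
        expected = np.abs(h[0]) ** 2  # forward-backward doubles the attenuation
        assert rms_ratio == pytest.approx(expected, rel=0.05)
        # a 4th-order Butterworth rolls off gently over the 45->50 Hz
        # transition; far out of band (100 Hz) suppression is essentially total
        far = bandpass(_sine_recording(100.0), 1.0, 45.0)
        assert np.sqrt(np.mean(far.data[0, 1000:-1000] ** 2)) / np.sqrt(0.5) < 0.01

    def test_lowpassed_noise_has_little_high_frequency_mass(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(25_000)
        y = bandpass_array(x, FS, 1.0, 4.0)
        psd = welch_psd(y, FS, window_len=1024, nfft=2048)
        total = psd.power.sum()
        high = psd.power[0, psd.frequencies > 6.0].sum()
        assert high / total < 0.01

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_sine_recording(10.0), 10.0, 300.0)

    def test_length_and_annotations_preserved(self):
        rec = _sine_recording(10.0)
        rec.annotations = [Annotation("SB", 0, rec.n_samples)]
        out = bandpass(rec, 8.0, 13.0)
        assert out.n_samples == rec.n_samples
        assert out.annotations == rec.annotations


class TestRejectChannels:
    def _recording_with_spikes(self, shares):
        """One channel per requested share of 2-s epochs containing a 200 uV spike."""
        n_epochs, n_epoch = 10, int(2.0 * FS)
        data = np.zeros((len(shares), n_epochs * n_epoch))
        for ch, share in enumerate(shares):
            for e in range(int(round(share * n_epochs))):
                data[ch, e * n_epoch + 5] = 200.0
        names = tuple(f"ch{i}" for i in range(len(shares)))
        return Recording(data, FS, names)

    def test_spiky_channel_discarded(self):
        rec = self._recording_with_spikes([0.3, 0.0])
        kept, rejected = reject_channels(rec)
        assert rejected == ["ch0"]
        assert kept.channel_names == ("ch1",)

    def test_all_zero_recording_keeps_everything(self):
        rec = Recording(np.zeros((3, int(20 * FS))), FS, ("a", "b", "c"))
        _, rejected = reject_channels(rec)
        assert rejected == []

    def test_exactly_20_percent_is_retained(self):
        """The rule is strict '>': 2 of 10 bad epochs keeps, 3 of 10 drops."""
        rec = self._recording_with_spikes([0.2, 0.3])
        # oracle: direct count of violating epochs
        counts = (np.abs(rec.data.reshape(2, 10, -1)) > 100).any(axis=2).sum(axis=1)
        assert list(counts) == [2, 3]
        _, rejected = reject_channels(rec)
        assert rejected == ["ch1"]

    def test_all_rejected_raises(self):
        rec = self._recording_with_spikes([1.0, 1.0])
        with pytest.raises(ValueError, match="all channels"):
            reject_channels(rec)

    def test_order_independent(self):
        rec = self._recording_with_spikes([0.3, 0.0, 0.5])
        flipped = Recording(rec.data[::-1].copy(), FS, tuple(reversed(rec.channel_names)))
        _, r1 = reject_channels(rec)
        _, r2 = reject_channels(flipped)
        assert set(r1) == set(r2) == {"ch0", "ch2"}


class TestBaselineCorrect:
    def test_constant_offset_removed(self):
        seg = np.full((2, 1000), 7.0)
        out = baseline_correct(seg, FS, onset=200)
        assert np.allclose(out, 0.0)

    def test_ramp_mean_zeroed_slope_unchanged(self):
        t = np.arange(1000)
        seg = (0.5 * t)[None, :]
        out = baseline_correct(seg, FS, onset=500)
        lo, hi = 500 - 100, 500
        assert out[0, lo:hi].mean() == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(np.diff(out[0]), 0.5)

    def test_default_window_uses_100_samples_at_500hz(self):
        seg = np.zeros((1, 1000))
        seg[0, 100:200] = 1.0  # samples 100..200 have mean 1 -> subtracted everywhere
        out = baseline_correct(seg, FS, onset=200)
        assert np.allclose(out[0, :100], -1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        seg = rng.standard_normal((3, 2000))
        once = baseline_correct(seg, FS, onset=300)
        twice = baseline_correct(once, FS, onset=300)
        assert np.allclose(once, twice)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="zero samples"):
            baseline_correct(np.zeros((1, 100)), FS, window=(0.0, 0.0))


class TestSplit:
    def test_default_paradigm_yields_four_bh_segments_of_20s(self, small_cohort_blocks):
        blocks = next(iter(small_cohort_blocks.values()))
        bh = blocks.broadband["BH"]
        assert len(bh) == 4
        # one-tenth scale paradigm: 2-s holds
        assert all(seg.shape[1] == int(2.0 * blocks.fs) for seg in bh)

    def test_four_bands_emitted_per_condition(self, small_cohort_blocks):
        blocks = next(iter(small_cohort_blocks.values()))
        for cond in ("SB", "BH", "PB"):
            assert set(blocks.segments[cond]) == {b.name for b in DEFAULT_BANDS}

    def test_missing_condition_raises(self):
        rec = _sine_recording(10.0)
        rec.annotations = [Annotation("SB", 0, rec.n_samples)]
        with pytest.raises(ValueError, match="PB"):
            split_conditions_and_bands(rec)

    def test_segment_lengths_match_blocks(self, small_cohort_blocks):
        blocks = next(iter(small_cohort_blocks.values()))
        for cond, segs in blocks.broadband.items():
            for band_segs in blocks.segments[cond].values():
                assert [s.shape[1] for s in band_segs] == [s.shape[1] for s in segs]

    def test_filter_commutes_with_segmentation_in_the_interior(self):
        sub = generate_subject(default_paradigm(block_scale=0.1), default_coupling(), seed=2)
        rec = sub.recording
        ann = rec.annotations[2]  # an interior block
        whole = bandpass_array(rec.data, rec.fs, 8.0, 13.0)[:, ann.start : ann.stop]
        part = bandpass_array(rec.data[:, ann.start : ann.stop], rec.fs, 8.0, 13.0)
        pad = int(rec.fs)  # discard 1 s of edge effects
        a, b = whole[:, pad:-pad], part[:, pad:-pad]
        err = np.abs(a - b).max() / np.abs(a).max()
        assert err < 0.02


class TestBandDefinition:
    def test_default_table_is_a_partition_without_gamma(self):
        edges = [(b.lo, b.hi) for b in DEFAULT_BANDS]
        assert edges == [(1, 4), (4, 8), (8, 13), (13, 30)]
        for a, b in zip(DEFAULT_BANDS, DEFAULT_BANDS[1:]):
            assert a.hi == b.lo
            assert a.contains(a.lo) and not a.contains(a.hi)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 8.0, 4.0)
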