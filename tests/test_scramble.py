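from itertools import permutations

import numpy as np
import pytest

from trwmap.audio import AudioTrack
from trwmap.scramble import (
    ScrambleOrder,
    compress_dynamics,
    is_valid_order,
    make_order,
    reassemble,
    reverse,
    scramble_track,
    segment_audio,
)
from trwmap.segmentation import SegmentationSpec


def _tone(duration, sr=8000, freq=440.0, amp=0.5):
    t = np.arange(round(duration * sr)) / sr
    return AudioTrack(samples=amp * np.sin(2 * np.pi * freq * t), sample_rate=sr)


def _two_segment_spec():
    return SegmentationSpec(
        total_duration=2.0,
        levels=("measure",),
        boundaries={"measure": [(0.0, 1.0), (1.0, 2.0)]},
    )


class TestSegmentAudio:
    def test_partition_and_round_trip(self, rng):
        track = AudioTrack(samples=rng.standard_normal(16000) * 0.1, sample_rate=8000)
        segs = segment_audio(track, _two_segment_spec(), "measure")
        assert [s.n_samples for s in segs] == [8000, 8000]
        recon = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(recon, track.samples)

    def test_single_segment_is_whole_track(self):
        track = _tone(2.0)
        spec = SegmentationSpec(
            total_duration=2.0, levels=("all",), boundaries={"all": [(0.0, 2.0)]}
        )
        (seg,) = segment_audio(track, spec, "all")
        np.testing.assert_array_equal(seg.samples, track.samples)

    def test_sample_counts_partition_arbitrary_boundaries(self, rng):
        # boundary times that don't fall on integer samples still partition
        cuts = np.sort(rng.uniform(0.1, 2.9, size=5))
        pts = [0.0, *cuts, 3.0]
        spec = SegmentationSpec(
            total_duration=3.0,
            levels=("m",),
            boundaries={"m": [(a, b) for a, b in zip(pts[:-1], pts[1:])]},
        )
        track = AudioTrack(samples=rng.standard_normal(3 * 8000) * 0.1, sample_rate=8000)
        segs = segment_audio(track, spec, "m")
        assert sum(s.n_samples for s in segs) == track.n_samples

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown level"):
            segment_audio(_tone(2.0), _two_segment_spec(), "phrase")


class TestMakeOrder:
    def test_n1_identity(self):
        assert make_order(1, seed=5).permutation == (0,)

    def test_n2_unique_valid_order(self):
        for seed in range(10):
            assert make_order(2, seed=seed).permutation == (1, 0)

    def test_n3_valid_set_and_uniformity(self):
        valid = {p for p in permutations(range(3)) if is_valid_order(p)}
        assert valid == {(0, 2, 1), (1, 0, 2), (2, 1, 0)}
        draws = [make_order(3, seed=s).permutation for s in range(10_000)]
        for p in valid:
            freq = sum(d == p for d in draws) / len(draws)
            assert abs(freq - 1 / 3) <= 0.03

    def test_never_identity_for_n_ge_2(self):
        for n in range(2, 9):
            for seed in range(20):
                perm = make_order(n, seed=seed).permutation
                assert perm != tuple(range(n))

    def test_invalid_order_constructor_rejects(self):
        with pytest.raises(ValueError, match="adjacent"):
            ScrambleOrder(permutation=(2, 0, 1), seed=0)
        with pytest.raises(ValueError, match="permutation"):
            ScrambleOrder(permutation=(0, 0, 1), seed=0)


class TestReassemble:
    def test_crossfade_shortens_by_n_minus_1_fades(self):
        segs = [_tone(1.0, sr=44100), _tone(1.0, sr=44100, freq=660)]
        out = reassemble(segs, ScrambleOrder((1, 0), 0), crossfade_s=0.010)
        assert out.n_samples == 2 * 44100 - 441  # 87,759 samples

    def test_zero_crossfade_identity_order_bit_exact(self, rng):
        track = AudioTrack(samples=rng.standard_normal(16000) * 0.1, sample_rate=8000)
        segs = segment_audio(track, _two_segment_spec(), "measure")
        out = reassemble(segs, order=None, crossfade_s=0.0)
        np.testing.assert_array_equal(out.samples, track.samples)

    def test_linear_fades_sum_to_unity(self):
        ones = AudioTrack(samples=np.ones(8000), sample_rate=8000)
        out = reassemble([ones, ones], order=None, crossfade_s=0.010)
        np.testing.assert_allclose(out.samples, 1.0, atol=1e-12)

    def test_crossfade_longer_than_segment_rejected(self):
        with pytest.raises(ValueError, match="crossfade"):
            reassemble([_tone(0.005), _tone(1.0)], crossfade_s=0.010)


class TestReverse:
    def test_reverses_samples(self):
        track = AudioTrack(samples=np.array([1.0, 0.5, -0.25]), sample_rate=8000)
        np.testing.assert_array_equal(reverse(track).samples, [-0.25, 0.5, 1.0])

    def test_involution_bit_exact(self, rng):
        track = AudioTrack(samples=rng.standard_normal(1000), sample_rate=8000)
        np.testing.assert_array_equal(reverse(reverse(track)).samples, track.samples)

    def test_magnitude_spectrum_preserved(self, rng):
        track = AudioTrack(samples=rng.standard_normal(1024) * 0.2, sample_rate=8000)
        fwd = np.abs(np.fft.rfft(track.samples))
        rev = np.abs(np.fft.rfft(reverse(track).samples))
        np.testing.assert_allclose(fwd, rev, atol=1e-9)


class TestCompressor:
    def test_static_gain_law_on_steady_tone(self):
        # -6 dBFS peak tone, threshold -20 dBFS, ratio 4 -> -16.5 dBFS peak
        track = _tone(2.0, amp=10 ** (-6 / 20))
        out = compress_dynamics(track, threshold_db=-20.0, ratio=4.0)
        steady = out.samples[out.n_samples // 2 :]
        peak_db = 20 * np.log10(np.max(np.abs(steady)))
        assert abs(peak_db - (-16.5)) <= 0.5

    def test_below_threshold_unchanged(self):
        track = _tone(1.0, amp=10 ** (-40 / 20))
        out = compress_dynamics(track, threshold_db=-20.0, ratio=4.0, makeup=False)
        np.testing.assert_allclose(out.samples, track.samples, atol=1e-6)

    def test_loud_soft_rms_ratio_decreases(self):
        sr = 8000
        t = np.arange(sr) / sr
        loud = 0.7 * np.sin(2 * np.pi * 440 * t)
        soft = 0.05 * np.sin(2 * np.pi * 440 * t)
        track = AudioTrack(samples=np.concatenate([loud, soft]), sample_rate=sr)
        out = compress_dynamics(track, makeup=False)
        def ratio(x):
            return np.sqrt(np.mean(x[:sr] ** 2)) / np.sqrt(np.mean(x[sr:] ** 2))
        assert ratio(out.samples) < ratio(track.samples)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            compress_dynamics(_tone(0.5), ratio=0.5)


class TestScrambleEndToEnd:
    def test_energy_preserved_within_1pct(self, rng):
        from trwmap.segmentation import gen_segmentation

        sr = 8000
        spec = gen_segmentation(24.0, {"measure": (2.0, 0.2), "phrase": (8.0, 1.0)}, seed=1)
        n = round(spec.total_duration * sr)
        track = AudioTrack(samples=0.1 * rng.standard_normal(n), sample_rate=sr)
        for level in spec.levels:
            out = scramble_track(track, spec, level, seed=4)
            e_in = np.sum(track.samples**2)
            e_out = np.sum(out.samples**2)
            assert abs(e_out - e_in) / e_in < 0.01

    def test_section_scramble_preserves_within_section_order(self, rng):
        sr = 8000
        spec = SegmentationSpec(
            total_duration=4.0,
            levels=("measure", "section"),
            boundaries={
                "measure": [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0)],
                "section": [(0.0, 2.0), (2.0, 4.0)],
            },
        )
        track = AudioTrack(samples=rng.standard_normal(4 * sr) * 0.1, sample_rate=sr)
        out = scramble_track(track, spec, "section", seed=0, crossfade_s=0.0)
        # only valid 2-section order is (1, 0): second half first, order intact inside
        np.testing.assert_array_equal(out.samples[: 2 * sr], track.samples[2 * sr :])
        np.testing.assert_array_equal(out.samples[2 * sr :], track.samples[: 2 * sr])
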