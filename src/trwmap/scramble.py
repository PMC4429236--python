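"""Stimulus-condition construction: segment shuffling, reversal, compression.

The scrambled conditions of the experiment are built by cutting the intact
waveform at the boundaries of one segmentation level, shuffling the segments
under a no-sequential-adjacency constraint, and splicing them back together
with short crossfades. A "backward" condition is the time-reversed waveform.
Dynamic-range compression evens out loudness contrasts between reordered
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioTrack
from .segmentation import SegmentationSpec


@dataclass(frozen=True)
class ScrambleOrder:
    """A permutation of segment indices with no pair (i, i+1) adjacent in output order."""

    permutation: tuple
    seed: int

    def __post_init__(self) -> None:
        perm = tuple(int(i) for i in self.permutation)
        n = len(perm)
        if sorted(perm) != list(range(n)):
            raise ValueError("not a permutation of 0..n-1")
        if any(b == a + 1 for a, b in zip(perm[:-1], perm[1:])):
            raise ValueError("permutation contains a sequentially adjacent pair")
        object.__setattr__(self, "permutation", perm)

    def __len__(self) -> int:
        return len(self.permutation)


def is_valid_order(perm) -> bool:
    """True if perm is a permutation of 0..n-1 with no (i, i+1) in adjacent output slots."""
    perm = list(perm)
    if sorted(perm) != list(range(len(perm))):
        return False
    return not any(b == a + 1 for a, b in zip(perm[:-1], perm[1:]))


def make_order(n: int, seed: int = 0, max_tries: int = 100_000) -> ScrambleOrder:
    """Sample a scramble order uniformly over valid permutations.

    Rejection sampling from the uniform distribution over all permutations,
    keeping the first draw in which no segment is immediately followed by its
    original successor. For n = 1 the identity is returned (vacuously valid);
    for n = 2 the only valid order is (1, 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return ScrambleOrder(permutation=(0,), seed=seed)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if is_valid_order(perm):
            return ScrambleOrder(permutation=tuple(perm), seed=seed)
    raise RuntimeError(f"no valid order found in {max_tries} tries (n={n})")


def segment_audio(track: AudioTrack, spec: SegmentationSpec, level: str) -> list:
    """Cut a track at the boundaries of one segmentation level.

    Boundary times are rounded to the nearest sample; intervals are half-open
    so the segments partition the samples exactly and concatenating them in
    original order reproduces the track over [0, total_duration).
    """
    if level not in spec.levels:
        raise ValueError(f"unknown level {level!r}; spec has {spec.levels}")
    n_total = round(spec.total_duration * track.sample_rate)
    if n_total > track.n_samples + 1:
        raise ValueError(
            f"spec duration {spec.total_duration:.3f}s exceeds track duration "
            f"{track.duration:.3f}s"
        )
    sr = track.sample_rate
    segments = []
    for start_s, end_s in spec.boundaries[level]:
        i = round(start_s * sr)
        j = min(round(end_s * sr), track.n_samples)
        segments.append(AudioTrack(samples=track.samples[i:j], sample_rate=sr))
    return segments


def reassemble(
    segments: list,
    order: ScrambleOrder | None = None,
    crossfade_s: float = 0.010,
    fade: str = "linear",
    clip_guard: bool = True,
) -> AudioTrack:
    """Splice segments in the given order with overlap-add crossfades.

    Each joint overlaps the tail of one segment with the head of the next over
    ``crossfade_s`` seconds, applying complementary fades (linear by default,
    ``fade="equal_power"`` for sine/cosine fades). The output is therefore
    shorter than the plain concatenation by (n-1) * crossfade_s.
    """
    if not segments:
        raise ValueError("no segments to reassemble")
    sr = segments[0].sample_rate
    if any(s.sample_rate != sr for s in segments):
        raise ValueError("segments must share a sample rate")
    idx = list(order.permutation) if order is not None else list(range(len(segments)))
    parts = [segments[i].samples for i in idx]
    n_fade = round(crossfade_s * sr)
    if n_fade > 0 and n_fade >= min(p.size for p in parts):
        raise ValueError("crossfade longer than the shortest segment")
    if fade == "linear":
        ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False) if n_fade else np.array([])
        fade_in, fade_out = ramp, 1.0 - ramp
    elif fade == "equal_power":
        theta = np.linspace(0.0, np.pi / 2, n_fade, endpoint=False) if n_fade else np.array([])
        fade_in, fade_out = np.sin(theta), np.cos(theta)
    else:
        raise ValueError(f"unknown fade shape {fade!r}")

    total = sum(p.size for p in parts) - n_fade * (len(parts) - 1)
    out = np.zeros(total)
    pos = 0
    for k, p in enumerate(parts):
        p = p.copy()
        if n_fade and k > 0:
            p[:n_fade] *= fade_in
        if n_fade and k < len(parts) - 1:
            p[-n_fade:] *= fade_out
        out[pos : pos + p.size] += p
        pos += p.size - (n_fade if k < len(parts) - 1 else 0)
    if clip_guard:
        out = np.clip(out, -1.0, 1.0)
    return AudioTrack(samples=out, sample_rate=sr)


def reverse(track: AudioTrack) -> AudioTrack:
    """Time-reverse the waveform (the "backward" condition)."""
    if track.n_samples == 0:
        raise ValueError("cannot reverse an empty track")
    return AudioTrack(samples=track.samples[::-1].copy(), sample_rate=track.sample_rate)


def compress_dynamics(
    track: AudioTrack,
    threshold_db: float = -20.0,
    ratio: float = 4.0,
    attack_s: float = 0.010,
    release_s: float = 0.100,
    makeup: bool = False,
) -> AudioTrack:
    """Downward dynamic-range compression with a static gain law.

    Above the threshold, output level follows
    ``out_db = threshold_db + (in_db - threshold_db) / ratio``; below it the
    signal is untouched. The level detector is an instantaneous-peak
    follower with exponential release decay (so a steady tone is detected at
    its true peak level); the resulting gain is smoothed with first-order
    attack/release time constants. With ``makeup`` the output is rescaled to
    the input RMS.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    x = track.samples
    if x.size == 0:
        return track
    sr = track.sample_rate
    a_att = np.exp(-1.0 / (max(attack_s, 1e-6) * sr))
    a_rel = np.exp(-1.0 / (max(release_s, 1e-6) * sr))

    # peak detector: jump to new peaks, decay at the release rate between them
    rect = np.abs(x)
    env = np.empty_like(rect)
    level = rect[0]
    for i, v in enumerate(rect):
        level = v if v > level else a_rel * level + (1.0 - a_rel) * v
        env[i] = level

    env_db = 20.0 * np.log10(np.maximum(env, 1e-12))
    over = env_db > threshold_db
    gain_db = np.zeros_like(env_db)
    gain_db[over] = (threshold_db + (env_db[over] - threshold_db) / ratio) - env_db[over]
    target = np.power(10.0, gain_db / 20.0)

    # attack when the gain drops (compression engages), release when it recovers
    gain = np.empty_like(target)
    g = target[0]
    for i, tg in enumerate(target):
        coef = a_att if tg < g else a_rel
        g = coef * g + (1.0 - coef) * tg
        gain[i] = g
    out = x * gain

    if makeup:
        out_rms = np.sqrt(np.mean(np.square(out)))
        in_rms = np.sqrt(np.mean(np.square(x)))
        if out_rms > 0:
            out = out * (in_rms / out_rms)
    return AudioTrack(samples=out, sample_rate=sr)


def scramble_track(
    track: AudioTrack,
    spec: SegmentationSpec,
    level: str,
    seed: int = 0,
    crossfade_s: float = 0.010,
    compress: bool = False,
) -> AudioTrack:
    """Build one scrambled condition: segment, shuffle, splice, optionally compress."""
    segments = segment_audio(track, spec, level)
    order = make_order(len(segments), seed=seed)
    out = reassemble(segments, order, crossfade_s=crossfade_s)
    if compress:
        out = compress_dynamics(out, makeup=True)
    return out
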