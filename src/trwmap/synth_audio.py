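"""Synthetic musical audio with hierarchical envelope structure.

A stand-in stimulus for pipeline testing: one tone event per measure, with
pitch and loudness profiles organized per section and per phrase so that the
amplitude envelope carries structure at every segmentation level. This is
deliberately schematic — it provides a waveform whose envelope and boundary
structure are known exactly, not realistic music.
"""

from __future__ import annotations

import numpy as np

from .audio import AudioTrack
from .segmentation import SegmentationSpec


def _level_index(spec: SegmentationSpec, level: str, times: np.ndarray) -> np.ndarray:
    """Index of the level-`level` interval containing each time."""
    starts = np.array([a for a, _ in spec.boundaries[level]])
    return np.clip(np.searchsorted(starts, times, side="right") - 1, 0, starts.size - 1)


def design_amplitudes(spec: SegmentationSpec, seed: int = 0) -> np.ndarray:
    """Per-measure target amplitudes with section/phrase-level structure.

    Each section gets a base loudness, each phrase a multiplicative swell,
    each measure a small jitter; the product is clipped to [0.05, 0.95].
    """
    rng = np.random.default_rng(seed)
    fine = spec.levels[0]
    n = spec.n_segments(fine)
    mids = np.array([(a + b) / 2 for a, b in spec.boundaries[fine]])
    amp = np.ones(n)
    for level in spec.levels[1:]:
        idx = _level_index(spec, level, mids)
        per = rng.uniform(0.4, 1.0, size=spec.n_segments(level))
        amp *= per[idx]
    amp *= rng.uniform(0.75, 1.0, size=n)  # per-measure jitter
    return np.clip(0.95 * amp / amp.max(), 0.05, 0.95)


def gen_audio(
    spec: SegmentationSpec,
    sample_rate: int = 11025,
    seed: int = 0,
    amplitudes: np.ndarray | None = None,
    ramp_s: float = 0.020,
) -> AudioTrack:
    """Render one tone per finest-level segment (measure).

    Pitch follows a per-section random walk; amplitude follows
    :func:`design_amplitudes` unless an explicit per-measure profile is
    given (all zeros yields a silent track). Tones have short linear
    attack/release ramps to avoid clicks at measure boundaries.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if not spec.levels:
        raise ValueError("empty segmentation spec")
    rng = np.random.default_rng(seed)
    fine = spec.levels[0]
    intervals = spec.boundaries[fine]
    n = len(intervals)
    if amplitudes is None:
        amplitudes = design_amplitudes(spec, seed=seed)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != n:
        raise ValueError(f"amplitudes has size {amplitudes.size}, expected {n}")

    mids = np.array([(a + b) / 2 for a, b in intervals])
    coarse = spec.levels[-1]
    section_idx = _level_index(spec, coarse, mids)
    base_midi = rng.uniform(48, 72, size=spec.n_segments(coarse))
    midi = base_midi[section_idx] + np.cumsum(rng.integers(-2, 3, size=n)) * 0.5
    midi = np.clip(midi, 36, 84)
    freqs = 440.0 * 2.0 ** ((midi - 69.0) / 12.0)

    n_total = round(spec.total_duration * sample_rate)
    out = np.zeros(n_total)
    for (a, b), amp, f in zip(intervals, amplitudes, freqs):
        i, j = round(a * sample_rate), min(round(b * sample_rate), n_total)
        m = j - i
        if m <= 0 or amp == 0:
            continue
        t = np.arange(m) / sample_rate
        tone = np.sin(2 * np.pi * f * t)
        n_ramp = min(round(ramp_s * sample_rate), m // 2)
        env = np.ones(m)
        if n_ramp > 0:
            env[:n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
            env[-n_ramp:] = np.linspace(1, 0, n_ramp, endpoint=False)
        out[i:j] = amp * env * tone
    return AudioTrack(samples=out, sample_rate=sample_rate)
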