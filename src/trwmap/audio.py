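"""Audio containers and WAV I/O.

The stimulus side of the pipeline works on mono floating-point waveforms in
[-1, 1]. WAV files are read/written via :mod:`scipy.io.wavfile`, accepting
16-bit PCM and float32 on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioTrack:
    """A mono audio waveform.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes, nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioTrack is mono: samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Track length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if self.samples.size else 0.0


def read_wav(path) -> AudioTrack:
    """Read a mono WAV file (PCM16/PCM32/float32/float64) into an AudioTrack."""
    rate, data = wavfile.read(path)
    if data.ndim == 2:  # take first channel of multichannel files
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioTrack(samples=data, sample_rate=int(rate))


def write_wav(path, track: AudioTrack, subtype: str = "float32") -> None:
    """Write an AudioTrack to WAV, as float32 (default) or 16-bit PCM."""
    if subtype == "float32":
        wavfile.write(path, track.sample_rate, track.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(track.samples, -1.0, 1.0)
        wavfile.write(path, track.sample_rate, np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype: {subtype!r}")
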