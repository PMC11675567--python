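"""Mono waveform container and RIFF/WAV I/O.

Audio is held as float64 samples in [-1, 1]. Files are written as 16-bit
PCM mono (no dither); on read, integer PCM is rescaled to [-1, 1] and
multi-channel input is mixed down by averaging.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = ["Waveform", "read_wav", "write_wav"]


@dataclass(frozen=True)
class Waveform:
    """A sampled mono audio signal with amplitude in [-1, 1]."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D samples)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("sample amplitudes must lie in [-1, 1]")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.size


def write_wav(path: str | os.PathLike, waveform: Waveform) -> None:
    """Write *waveform* as 16-bit PCM mono RIFF/WAV."""
    clipped = np.clip(waveform.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), int(waveform.sample_rate_hz), pcm)


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a PCM WAV file; integer formats are rescaled to [-1, 1]."""
    rate, data = wavfile.read(os.fspath(path))
    data = np.asarray(data)
    if data.ndim == 2:  # mix down to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    np.clip(data, -1.0, 1.0, out=data)
    return Waveform(samples=data, sample_rate_hz=int(rate))
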