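"""HNR, pitch statistics, formant tracking and duration.

The harmonics-to-noise ratio uses the normalized-autocorrelation
estimator: per voiced frame the correlation r at the detected period lag
estimates the periodic energy fraction, so the frame HNR is
10*log10(r / (1 - r)); the definitional closed form over an explicit
harmonic decomposition is kept as :func:`hnr_from_decomposition`.

Formants come from linear-prediction root finding on the signal resampled
to 10 kHz (pre-emphasis 0.97, 25 ms frames, order 10); roots with
bandwidth under 400 Hz are kept and the lowest four assigned to F1-F4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .._missing import MissingValue
from ..waveform import Waveform
from .periods import FrameAnalysis, analyze_frames

__all__ = [
    "HarmonicDecomposition",
    "PitchTrack",
    "FormantTrack",
    "FormantStats",
    "hnr_from_decomposition",
    "compute_hnr",
    "track_pitch",
    "f0_statistics",
    "track_formants",
    "formant_statistics",
    "measure_duration",
]

_HNR_CAP_DB = 40.0


@dataclass(frozen=True)
class HarmonicDecomposition:
    """Explicit split of signal energy into harmonic and noise parts."""

    harmonic_energy: float  # sum of squared harmonic amplitudes
    noise_energy: float
    n_harmonics: int
    f0_hz: float

    def __post_init__(self) -> None:
        if self.harmonic_energy < 0 or self.noise_energy < 0:
            raise ValueError("energies must be non-negative")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


def hnr_from_decomposition(decomposition: HarmonicDecomposition) -> float:
    """HNR in dB: 10 * log10(harmonic energy / noise energy)."""
    if decomposition.noise_energy == 0:
        return math.inf
    return 10.0 * math.log10(decomposition.harmonic_energy / decomposition.noise_energy)


def compute_hnr(
    waveform: Waveform,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
) -> float | MissingValue:
    """Mean over voiced frames of 10*log10(r/(1-r)), capped at +40 dB.

    Voicing is decided on a low-passed copy (robust to perturbation), but
    r itself comes from the full-band correlation so broadband noise is
    counted as noise energy.
    """
    voicing = analyze_frames(
        waveform, f0_min, f0_max, frame_s=frame_s, hop_s=hop_s,
        voicing_threshold=voicing_threshold, lowpass_hz=2.5 * f0_max,
    )
    analysis = analyze_frames(
        waveform, f0_min, f0_max, frame_s=frame_s, hop_s=hop_s,
        voicing_threshold=voicing_threshold,
    )
    r = analysis.periodicity[voicing.voiced]
    if r.size == 0:
        return MissingValue("unvoiced")
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    frame_db = 10.0 * np.log10(r / (1.0 - r))
    return float(min(np.mean(np.clip(frame_db, None, _HNR_CAP_DB)), _HNR_CAP_DB))


@dataclass(frozen=True)
class PitchTrack:
    """Framewise fundamental-frequency estimates."""

    frame_times: np.ndarray  # s
    f0_values: np.ndarray  # Hz, NaN on unvoiced frames
    voicing_flags: np.ndarray


def track_pitch(
    waveform: Waveform,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
) -> PitchTrack:
    """Autocorrelation pitch track; f0 = fs / fractional best lag."""
    analysis = analyze_frames(
        waveform, f0_min, f0_max, frame_s=frame_s, hop_s=hop_s,
        voicing_threshold=voicing_threshold, lowpass_hz=2.5 * f0_max,
    )
    f0 = np.full(analysis.times.size, np.nan)
    voiced = analysis.voiced & (analysis.lags > 0)
    f0[voiced] = analysis.sample_rate_hz / analysis.lags[voiced]
    in_range = np.zeros_like(voiced)
    in_range[voiced] = (f0[voiced] >= f0_min) & (f0[voiced] <= f0_max)
    f0[~in_range] = np.nan
    return PitchTrack(frame_times=analysis.times, f0_values=f0, voicing_flags=in_range)


def f0_statistics(
    track: PitchTrack,
) -> tuple[float | MissingValue, float | MissingValue]:
    """(meanF0, stdevF0) over voiced frames; stdev uses the n-1 denominator."""
    f0 = track.f0_values[track.voicing_flags]
    if f0.size == 0:
        return MissingValue("unvoiced"), MissingValue("unvoiced")
    mean = float(np.mean(f0))
    if f0.size < 2:
        return mean, MissingValue("single_voiced_frame")
    return mean, float(np.std(f0, ddof=1))


# --------------------------------------------------------------------------
# Formants
# --------------------------------------------------------------------------

_FORMANT_FS = 10_000
_PREEMPHASIS = 0.97
_LPC_ORDER = 10
_MAX_BANDWIDTH = 400.0
_MIN_FORMANT_HZ = 90.0


@dataclass(frozen=True)
class FormantTrack:
    """Per-frame F1-F4 estimates on retained (voiced, resolvable) frames."""

    frame_times: np.ndarray
    formants: np.ndarray  # shape (n_frames, 4), Hz


def _lpc_autocorrelation(frame: np.ndarray, order: int) -> np.ndarray | None:
    """LPC coefficients from the Yule-Walker (autocorrelation) equations."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1 : frame.size + order]
    if r[0] <= 0:
        return None
    try:
        coeffs = solve_toeplitz(r[:order], -r[1 : order + 1])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coeffs)):
        return None
    return np.concatenate([[1.0], coeffs])


def track_formants(
    waveform: Waveform,
    f0_min: float = 60.0,
    f0_max: float = 400.0,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
) -> FormantTrack:
    """LPC root-finding formant track over voiced frames.

    Frames without four resonances of bandwidth < 400 Hz are dropped.
    """
    fs = waveform.sample_rate_hz
    x = waveform.samples
    if fs != _FORMANT_FS:
        g = math.gcd(fs, _FORMANT_FS)
        x = sps.resample_poly(x, _FORMANT_FS // g, fs // g)
    # voicing from the original-rate analysis, mapped by time
    analysis = analyze_frames(
        waveform, f0_min, f0_max, voicing_threshold=voicing_threshold,
        lowpass_hz=2.5 * f0_max,
    )
    voiced_times = analysis.times[analysis.voiced]
    emphasized = np.empty_like(x)
    emphasized[0] = x[0]
    emphasized[1:] = x[1:] - _PREEMPHASIS * x[:-1]
    frame_len = int(round(frame_s * _FORMANT_FS))
    hop = int(round(hop_s * _FORMANT_FS))
    window = np.hamming(frame_len)
    times: list[float] = []
    rows: list[np.ndarray] = []
    n_frames = max(0, 1 + (emphasized.size - frame_len) // hop)
    for i in range(n_frames):
        lo = i * hop
        t = (lo + frame_len / 2) / _FORMANT_FS
        if voiced_times.size == 0 or np.min(np.abs(voiced_times - t)) > 0.02:
            continue
        frame = emphasized[lo : lo + frame_len] * window
        a = _lpc_autocorrelation(frame, _LPC_ORDER)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        with np.errstate(divide="ignore"):
            freqs = np.angle(roots) * _FORMANT_FS / (2 * math.pi)
            bands = -np.log(np.abs(roots)) * _FORMANT_FS / math.pi
        keep = (
            (freqs > _MIN_FORMANT_HZ)
            & (freqs < _FORMANT_FS / 2 - 50)
            & (bands < _MAX_BANDWIDTH)
        )
        freqs = np.sort(freqs[keep])
        if freqs.size < 4:
            continue
        times.append(t)
        rows.append(freqs[:4])
    if not rows:
        return FormantTrack(frame_times=np.array([]), formants=np.empty((0, 4)))
    return FormantTrack(frame_times=np.asarray(times), formants=np.vstack(rows))


@dataclass(frozen=True)
class FormantStats:
    means: tuple[float, float, float, float]
    medians: tuple[float, float, float, float]
    avg_formant: float  # arithmetic mean of the four per-formant means


def formant_statistics(track: FormantTrack) -> FormantStats | MissingValue:
    """Per-formant means/medians over retained frames plus their average."""
    if track.formants.shape[0] == 0:
        return MissingValue("no_formant_frames")
    means = tuple(float(v) for v in track.formants.mean(axis=0))
    medians = tuple(float(v) for v in np.median(track.formants, axis=0))
    return FormantStats(means=means, medians=medians, avg_formant=float(np.mean(means)))


def measure_duration(
    waveform: Waveform,
    frame_s: float = 0.020,
    hop_s: float = 0.010,
    threshold_db: float = 25.0,
) -> float:
    """Active speech duration from an RMS endpoint detector.

    Time spanned by frames whose RMS is within ``threshold_db`` of the
    loudest frame; 0.0 for silence.
    """
    x = waveform.samples
    fs = waveform.sample_rate_hz
    frame_len = max(int(round(frame_s * fs)), 1)
    hop = max(int(round(hop_s * fs)), 1)
    n_frames = max(0, 1 + (x.size - frame_len) // hop)
    if n_frames == 0:
        return 0.0
    rms = np.array(
        [np.sqrt(np.mean(x[i * hop : i * hop + frame_len] ** 2)) for i in range(n_frames)]
    )
    peak = rms.max()
    if peak <= 0:
        return 0.0
    active = np.flatnonzero(rms >= peak * 10 ** (-threshold_db / 20.0))
    first, last = int(active[0]), int(active[-1])
    return (last - first) * hop / fs + frame_len / fs
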