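"""Shared fixtures. Heavy simulations are session-scoped so the recovery
and calibration studies run once and are reused by unit and acceptance
tests alike."""

from __future__ import annotations

import numpy as np
import pytest

from voicecog.features import compute_hnr, compute_jitter, compute_shimmer, detect_periods
from voicecog.synthesis import (
    VoiceSynthesisParams,
    cycle_schedule,
    synthesize_vowel_detailed,
)

PERTURBATION_LEVELS = (0.5, 1.0, 2.0, 4.0)
SNR_LEVELS_DB = (0.0, 10.0, 20.0, 30.0)


@pytest.fixture(scope="session")
def clean_vowel_100hz():
    """Unperturbed 100 Hz pulse train, 1 s at 44.1 kHz, with ground truth."""
    params = VoiceSynthesisParams(f0_hz=100.0, duration_s=1.0, sample_rate_hz=44100)
    return synthesize_vowel_detailed(params, seed=0)


@pytest.fixture(scope="session")
def calibration_study():
    """Ground-truth cycle-list statistics per target level, 200 seeds each."""
    out = {}
    for level in PERTURBATION_LEVELS:
        params = VoiceSynthesisParams(
            f0_hz=100.0, duration_s=2.0, jitter_pct=level, shimmer_pct=level
        )
        jit, shi = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            periods, amplitudes = cycle_schedule(params, rng)
            jit.append(np.mean(np.abs(np.diff(periods))) / periods.mean() * 100)
            shi.append(np.mean(np.abs(np.diff(amplitudes))) / amplitudes.mean() * 100)
        out[level] = (float(np.mean(jit)), float(np.mean(shi)))
    return out


@pytest.fixture(scope="session")
def recovery_study():
    """Detected local jitter/shimmer per injected level, 200 seeds each."""
    out = {}
    for level in PERTURBATION_LEVELS:
        params = VoiceSynthesisParams(
            f0_hz=100.0,
            duration_s=2.0,
            sample_rate_hz=44100,
            jitter_pct=level,
            shimmer_pct=level,
        )
        jit, shi = [], []
        for seed in range(200):
            result = synthesize_vowel_detailed(params, seed=seed)
            seq = detect_periods(result.waveform, 60.0, 400.0)
            jit.append(compute_jitter(seq, "local"))
            shi.append(compute_shimmer(seq, "local"))
        out[level] = (float(np.mean(jit)), float(np.mean(shi)))
    return out


@pytest.fixture(scope="session")
def hnr_recovery_study():
    """Estimated HNR per injected SNR level, 20 seeds each."""
    out = {}
    for snr in SNR_LEVELS_DB:
        params = VoiceSynthesisParams(
            f0_hz=100.0, duration_s=1.0, sample_rate_hz=44100, noise_snr_db=snr
        )
        values = [
            compute_hnr(synthesize_vowel_detailed(params, seed=s).waveform, 60.0, 400.0)
            for s in range(20)
        ]
        out[snr] = float(np.mean(values))
    return out
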