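"""Generators: parameter validation, determinism, calibration, DDK gating,
cohort simulation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voicecog.features import detect_periods, indicator_names, measure_duration
from voicecog.synthesis import (
    CohortSimulationParams,
    DDKSynthesisParams,
    VoiceSynthesisParams,
    generate_cohort,
    generate_roster,
    synthesize_ddk,
    synthesize_ddk_detailed,
    synthesize_vowel,
    synthesize_vowel_detailed,
)


class TestVoiceParams:
    def test_rejects_f0_at_or_above_nyquist(self):
        with pytest.raises(ValueError):
            VoiceSynthesisParams(f0_hz=22050.0, duration_s=1.0, sample_rate_hz=44100)

    def test_rejects_negative_perturbation(self):
        with pytest.raises(ValueError):
            VoiceSynthesisParams(f0_hz=100.0, duration_s=1.0, jitter_pct=-1.0)

    def test_rejects_non_increasing_formants(self):
        with pytest.raises(ValueError):
            VoiceSynthesisParams(
                f0_hz=100.0, duration_s=1.0, formants_hz=((800, 80), (700, 90))
            )

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            VoiceSynthesisParams(f0_hz=100.0, duration_s=0.0)


class TestVowel:
    def test_unperturbed_pulse_train_periods(self, clean_vowel_100hz):
        seq = detect_periods(clean_vowel_100hz.waveform, 60.0, 400.0)
        assert 90 <= seq.n <= 101
        assert np.max(np.abs(seq.periods - 0.010)) / 0.010 < 0.001

    def test_determinism_same_seed(self):
        params = VoiceSynthesisParams(
            f0_hz=120.0, duration_s=0.5, sample_rate_hz=16000,
            jitter_pct=1.0, shimmer_pct=2.0, noise_snr_db=20.0,
        )
        a = synthesize_vowel(params, seed=42)
        b = synthesize_vowel(params, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        params = VoiceSynthesisParams(
            f0_hz=120.0, duration_s=0.5, sample_rate_hz=16000, jitter_pct=1.0
        )
        a = synthesize_vowel(params, seed=1)
        b = synthesize_vowel(params, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_peak_normalized(self):
        params = VoiceSynthesisParams(f0_hz=100.0, duration_s=0.5, sample_rate_hz=16000)
        wave = synthesize_vowel(params, seed=0)
        assert np.max(np.abs(wave.samples)) == pytest.approx(0.9, abs=1e-9)

    def test_length_matches_duration(self):
        params = VoiceSynthesisParams(f0_hz=100.0, duration_s=1.25, sample_rate_hz=16000)
        assert len(synthesize_vowel(params, seed=0)) == 20000

    def test_injected_jitter_detected_in_band(self):
        # 2 % jitter, 3 s: detected local jitter within the simulation band
        params = VoiceSynthesisParams(
            f0_hz=100.0, duration_s=3.0, sample_rate_hz=44100, jitter_pct=2.0
        )
        from voicecog.features import compute_jitter

        jitters = [
            compute_jitter(
                detect_periods(
                    synthesize_vowel_detailed(params, seed).waveform, 60.0, 400.0
                ),
                "local",
            )
            for seed in range(10)
        ]
        assert 1.5 <= float(np.mean(jitters)) <= 2.5

    def test_calibration_within_10pct(self, calibration_study):
        for level, (jitter_mean, shimmer_mean) in calibration_study.items():
            assert abs(jitter_mean - level) / level < 0.10
            assert abs(shimmer_mean - level) / level < 0.10

    def test_hnr_monotone_in_noise(self, hnr_recovery_study):
        ordered = [hnr_recovery_study[snr] for snr in sorted(hnr_recovery_study)]
        assert all(a < b for a, b in zip(ordered, ordered[1:]))


class TestDDK:
    @staticmethod
    def _params(**kw):
        base = VoiceSynthesisParams(
            f0_hz=120.0, duration_s=1.0, sample_rate_hz=16000,
            jitter_pct=kw.pop("jitter_pct", 0.5), shimmer_pct=kw.pop("shimmer_pct", 1.0),
        )
        defaults = dict(base=base, syllable_rate_hz=5.0, n_syllables=10, gap_fraction=0.4)
        defaults.update(kw)
        return DDKSynthesisParams(**defaults)

    def test_duration_matches_gate_schedule(self):
        wave = synthesize_ddk(self._params(), seed=0)
        assert 1.8 <= measure_duration(wave) <= 2.2
        assert wave.duration_s == pytest.approx(2.0, abs=0.01)

    def test_zero_gap_has_no_silence(self):
        wave = synthesize_ddk(self._params(gap_fraction=0.0), seed=0)
        # RMS of every 50 ms chunk stays well above silence
        x = wave.samples
        n = len(x) // 40
        rms = [np.sqrt(np.mean(x[i * n : (i + 1) * n] ** 2)) for i in range(40)]
        assert min(rms) > 0.05 * max(rms)

    def test_determinism(self):
        a = synthesize_ddk(self._params(), seed=9)
        b = synthesize_ddk(self._params(), seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_voiced_segments_recorded(self):
        result = synthesize_ddk_detailed(self._params(), seed=3)
        assert len(result.voiced_segments) == 10
        starts = [s for s, _ in result.voiced_segments]
        assert starts == sorted(starts)

    def test_rejects_too_short_syllables(self):
        base = VoiceSynthesisParams(f0_hz=80.0, duration_s=1.0, sample_rate_hz=16000)
        with pytest.raises(ValueError):
            # voiced span 0.02 s < 2 cycles of 80 Hz (0.025 s)
            DDKSynthesisParams(
                base=base, syllable_rate_hz=10.0, n_syllables=5, gap_fraction=0.8
            )


class TestCohort:
    def test_printed_group_sizes(self):
        params = CohortSimulationParams(group_sizes=(72, 54, 97), seed=0)
        table, roster = generate_cohort(params)
        groups = [s.group.value for s in roster]
        assert len(roster) == 223
        assert groups.count("severe") == 72
        assert groups.count("mild") == 54
        assert groups.count("normal") == 97
        assert table.shape == (223, 184)
        assert list(table.columns) == indicator_names()

    def test_single_group_edge(self):
        params = CohortSimulationParams(group_sizes=(0, 0, 5), n_features=10, seed=1)
        table, roster = generate_cohort(params)
        assert table.shape[0] == 5
        assert all(s.group.value == "normal" for s in roster)

    def test_effect_map_unknown_indicator_rejected(self):
        params = CohortSimulationParams(
            group_sizes=(5, 0, 5), n_features=10,
            effect_map={"nonexistent": {"severe": 1.0}}, seed=0,
        )
        with pytest.raises(ValueError, match="unknown indicator"):
            generate_cohort(params)

    def test_effect_map_shifts_group_mean(self):
        params = CohortSimulationParams(
            group_sizes=(200, 0, 200), n_features=5,
            effect_map={"ind000": {"severe": 2.0}}, seed=3,
        )
        table, roster = generate_cohort(params)
        sev = [s.group.value == "severe" for s in roster]
        diff = table.loc[sev, "ind000"].mean() - table.loc[np.logical_not(sev), "ind000"].mean()
        assert diff == pytest.approx(2.0, abs=0.35)

    def test_null_cohorts_have_no_group_signal(self):
        # all effects zero: group-mean differences non-significant at
        # alpha = 0.01 in >= 95 % of simulated cohorts
        rejections = 0
        n_reps = 100
        for seed in range(n_reps):
            params = CohortSimulationParams(group_sizes=(25, 0, 25), n_features=1, seed=seed)
            table, roster = generate_cohort(params)
            sev = np.array([s.group.value == "severe" for s in roster])
            x = table.iloc[:, 0].to_numpy()
            p = stats.ttest_ind(x[sev], x[~sev]).pvalue
            rejections += p < 0.01
        assert rejections <= 5

    def test_determinism(self):
        params = CohortSimulationParams(group_sizes=(10, 5, 10), n_features=20, seed=11)
        t1, r1 = generate_cohort(params)
        t2, r2 = generate_cohort(params)
        pd.testing.assert_frame_equal(t1, t2)
        assert r1 == r2

    def test_kmmse_within_group_ranges(self):
        roster = generate_roster((30, 30, 30), seed=5)
        for s in roster:
            g = s.group.value
            lo, hi = {"severe": (0, 19), "mild": (20, 23), "normal": (24, 30)}[g]
            assert lo <= s.kmmse <= hi

    def test_demographics_in_printed_ranges(self):
        roster = generate_roster((50, 50, 50), seed=2)
        severe_ages = [s.age for s in roster if s.group.value == "severe"]
        assert min(severe_ages) >= 46 and max(severe_ages) <= 87
        assert all(0 <= s.education <= 16 for s in roster)
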