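# voicecog

Voice-based cognitive-status analysis as a tested, reusable pipeline:

- **synthesis** — sustained-vowel and syllable-train (DDK) waveform
  generators with exact ground-truth cycle perturbation (jitter/shimmer
  calibrated in closed form), plus a synthetic cohort generator (roster +
  184-indicator feature table with configurable group effects).
- **features** — glottal cycle detection, the jitter family (local,
  absolute, RAP, PPQ5, DDP), the shimmer family (local, local-dB,
  APQ3/5/11, DDA), harmonics-to-noise ratio, F0 statistics, LPC formant
  statistics and duration; 23 features × 8 speech tasks = 184 indicator
  columns per subject.
- **cohort** — K-MMSE grouping (0–19 severe / 20–23 mild / 24–30 normal)
  and non-parametric demographics: Kruskal–Wallis, Pearson chi-square,
  pairwise Mann–Whitney with Bonferroni correction, Shapiro–Wilk and
  Levene checks.
- **classify** — three binary tasks (severe, mild, combined impaired vs
  normal), deterministic 8:2 stratified split, seeded random
  hyperparameter search over four model families scored by 5-fold CV
  PR-AUC (average precision), evaluated against the analytic prevalence
  baseline with relative-improvement reporting.
- **explain** — Shapley-value attribution with an exact enumeration
  oracle (≤ 15 features), a seeded permutation-sampling estimator with
  Monte-Carlo standard errors at full dimension, and top-k rankings with
  a value-vs-attribution direction readout.
- **cli / pipeline** — `voicecog` command-line front end orchestrating
  synth → extract → demographics → classify → explain with per-stage
  seeds and a digest manifest for byte-level reproducibility.

## Command line

```sh
voicecog run --config study.toml            # full study
voicecog synth --config study.toml          # roster + WAVs only
voicecog extract --config study.toml --wav-dir out/wav --out features.csv
voicecog demographics --roster out/roster.csv --out-dir out
voicecog classify --config study.toml --features out/features.csv --roster out/roster.csv
```

A minimal config (TOML; all blocks required, unknown keys rejected):

```toml
seed = 7
output_dir = "out"

[synthesis]
n_severe = 10
n_mild = 8
n_normal = 12
sample_rate_hz = 16000

[features]
f0_min = 60.0
f0_max = 400.0

[classification]
families = ["linear_logistic", "random_forest", "gradient_boosting", "feedforward_nn"]
search_budget = 30

[explain]
background_size = 50
n_permutations = 200
top_k = 20
```

Exit codes: 0 ok, 1 stage failure, 2 configuration error. Re-running with
the same config and seed reproduces identical artifact digests
(`manifest.json`).

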