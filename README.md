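# thalcortex

Phase-synchronisation analysis of combined thalamic DBS local field
potentials (LFP) and high-density scalp EEG, for studying thalamo-cortical
oscillatory networks in Tourette Syndrome.

Patients with sensing-enabled deep-brain-stimulation implants can stream
bipolar thalamic LFP (250 Hz, one channel per hemisphere) while 63-channel
EEG is recorded in parallel (5000 Hz). `thalcortex` implements the full
analysis chain for such sessions:

- **I/O** — Percept-style BrainSense streaming JSON, BrainVision
  `.vhdr`/`.vmrk`/`.eeg` triplets (both binary orientations, float32 and
  int16), clinical-score tables, and clock synchronisation of the two
  streams from stimulation-artifact markers
  (`t_EEG = offset + (1 + drift) · t_LFP`, least squares).
- **Epoching** — tic annotation cleaning (tics < 2 s apart merge into one
  sequence; only tics with ≥ 2 s tic-free history are analysed), 4-s rest
  epochs tiled into tic- and movement-free stretches, and tic-onset-locked
  epochs.
- **Spectral** — complex Morlet decomposition (2–40 Hz, 5 cycles), power
  normalised to percent of total 2–40 Hz power, theta (3–7 Hz), alpha
  (8–12 Hz) and beta (13–30 Hz) band summaries.
- **Connectivity** — the phase-synchronisation index (PSI), i.e. the
  phase-locking value across trials and samples,

  `PSI = | ⟨ exp(i(φ_thalamus − φ_channel)) ⟩_{trials, samples} |`,

  with trial-shuffled surrogate nulls, and sliding-window PSI (0.3 s
  window, 4 ms steps) for event-locked dynamics.
- **Statistics** — Monte-Carlo permutation inference throughout: paired
  t-tests (sign-flip null), N-way fixed-effects ANOVA (Type II SS,
  restricted label shuffling), post-hoc pairwise contrasts,
  Benjamini–Hochberg FDR, cluster-size Monte-Carlo correction for
  time-window series (binarize at α = 0.05, compare run lengths to the
  99.9th percentile of shuffled-sequence maxima), exact (n ≤ 8) and
  Monte-Carlo Spearman correlations, and linear trend regression with
  adjusted R².
- **Pipelines** — the three study analyses (rest, tic suppression,
  tic-locked dynamics, each thalamus treated as one independent sample),
  plus a synthetic-cohort generator with von Mises phase coupling whose
  expected PSI has the closed form `I₁(κ)/I₀(κ)`, used for end-to-end
  parameter-recovery testing.

## Worked example

```python
import numpy as np
from thalcortex.synth import generate_cohort
from thalcortex.pipeline import (AnalysisConfig, compute_rest_features,
                                 run_rest_analysis, run_tic_analysis)
from thalcortex.stats import StatsConfig

channels = ["Fz", "F1", "F2", "FC1", "FC2", "F3", "C3", "Cz1",
            "Pz", "P3", "Oz", "O1"]
cohort = generate_cohort(n_patients=6, seed=3, eeg_rate=250.0,
                         eeg_channels=channels,
                         frontal=("Fz", "F1", "F2", "FC1", "FC2"),
                         durations={"tic_freely": 300.0},
                         clinical_noise_sd=0.0)
cfg = AnalysisConfig(stats=StatsConfig(n_permutations=200, seed=7),
                     surrogate_iters=40)

feats = compute_rest_features(cohort.patients, cfg)
rest = run_rest_analysis(feats, cohort.clinical, cfg)
print("flagged:", rest.flagged_channels)
print("peak:", rest.peak_channel, round(rest.peak_psi_mean, 3),
      "+-", round(rest.peak_psi_sem, 3))
print("rho(YGTSS):", round(rest.correlations["ygtss_tts"].rho, 2))

tic = run_tic_analysis(cohort.patients, cfg, targets=("psi_coi",))
r = tic["psi_coi"]
for c, sig in zip(r.cluster.clusters, r.cluster.significant):
    if sig:
        print("cluster:", round(r.window_starts[c[0]], 2), "to",
              round(r.window_starts[c[1] - 1] + cfg.test_window, 2), "s")
```

Output:

```
flagged: ['Fz', 'F1', 'F2', 'FC1', 'FC2']
peak: Fz 0.228 +- 0.008
rho(YGTSS): -0.83
cluster: -0.18 to 0.18 s
```

Reading: the rest analysis flags exactly the five channels the generator
coupled to the thalamic alpha oscillator (an original-vs-surrogate PSI
difference confined to the alpha band), the strongest coupling sits at Fz
with a mean alpha PSI of 0.23 across the twelve hemispheres, stronger
coupling goes with lower simulated tic severity (negative Spearman rho),
and the tic-locked analysis recovers the programmed pre-onset decoupling as
a significant cluster straddling tic onset.

A command-line interface mirrors this flow on files
(`thalcortex simulate|epoch|rest|suppression|tic|report --config run.yaml`).

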