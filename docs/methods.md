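# Methods

## Signals and their alignment

Two recording streams are modelled: bipolar thalamic LFP streamed by a
sensing-enabled pulse generator (250 Hz, one channel per hemisphere,
exported as a Percept-style JSON whose time-domain section we read and
write), and scalp EEG in BrainVision triplets (63 channels, 5000 Hz).  The
streams run on independent clocks; brief stimulation bursts at the start
and end of each streaming leave artifacts in both, and their marker times
are fitted by least squares to the linear clock map
`t_EEG = offset + (1 + drift) · t_LFP`.  Markers are matched by rank order.
With a single marker pair only the offset is estimable and the model is
flagged `offset_only`.  All events are stored on the EEG clock; LFP epochs
are cut through the inverse map.  How the artifact instants are localised
within each signal is outside this package's scope — marker times are taken
as given in the event table.

EEG is polyphase-resampled to the 250 Hz analysis rate before epoching so
the two streams share one sample grid; 250 Hz retains the 2–40 Hz analysis
band with a wide margin.

## Epoch types and tic selection

Tic annotations are cleaned in two passes: tics separated by less than 2 s
merge into a single sequence spanning first onset to last offset, and a tic
is analysed only if no other tic ends within 2 s before its onset (the
bound is inclusive: a gap of exactly 2 s keeps the tic).  Rest epochs are
4 s long, tiled greedily left-to-right and non-overlapping into stretches
that avoid every tic/movement/sync interval padded by a 1 s guard margin
(the guard and the non-overlap rule are this package's choices; overlap
would inflate effective trial counts in the PSI).  Tic epochs span −2.1 to
+0.9 s around onset: the −1.8 to +0.6 s analysis range padded by 0.3 s on
each side so that 0.3 s sliding windows never touch the epoch edge.

## Time–frequency decomposition

Complex Morlet wavelets, 5 cycles, on a 1 Hz grid from 2 to 40 Hz (both
power and phase from one transform; the 5-cycle Morlet is the field
default).  Samples within half a wavelet "cycle width" (`n_cycles / 2f`) of
an epoch edge are flagged per frequency; static averages exclude them,
sliding series keep them because the epoch padding already protects the
analysis range.  The strict ±5σ wavelet support is enforced only as a
lower bound on epoch length.  Power spectra are normalised per channel to
percent of total 2–40 Hz power — a scale-invariant convention that makes
spectra comparable across patients and devices.  Band summaries are
unweighted means over the grid frequencies inside theta (3–7 Hz), alpha
(8–12 Hz) and beta (13–30 Hz), bounds inclusive.

## Phase-synchronisation index

The PSI of a channel pair at a frequency is the phase-locking value: the
modulus of the mean unit cross-phasor `exp(i(φ_a − φ_b))` over trials and
valid samples.  Whether one phase estimate per epoch or the sample-and-trial
mean is intended in comparable studies is often ambiguous; the
sample-and-trial mean is declared here.  For N uncoupled trials the PSI
concentrates near `(√π/2)/√N`, the expected resultant of N random unit
phasors — the chance floor every comparison must beat.

Surrogates permute the trial pairing of one stream against the other
(non-identity permutations only) and recompute the PSI; the ensemble mean
is the surrogate PSI.  Pairing permutation (rather than Fourier phase
randomisation) preserves within-trial spectral structure and trial count,
which the original-vs-surrogate ANOVA requires matched.  Sliding PSI uses
centred 0.3 s windows stepped at 4 ms, computed per frequency and then
band-averaged (matching the order "PSI per frequency, then grouped into
bands").

## Permutation inference

Every p-value is Monte-Carlo: `p = (1 + #{|s_perm| ≥ |s_obs|}) / (n_perm + 1)`,
two-sided, including the observed labelling so p is never exactly zero.

- Paired t-test: sign-flip null on the within-pair differences.
- N-way fixed-effects ANOVA, Type II sums of squares (robust to unbalanced
  hemisphere counts; reduces to the textbook decomposition when balanced;
  cross-checked against statsmodels `anova_lm(typ=2)` on balanced designs).
  A main effect's null permutes that factor's labels; an interaction's null
  permutes the first-named factor within level combinations of the others,
  preserving lower-order structure.
- Post-hoc contrasts: difference of cell means, labels shuffled between the
  two cells; all p-values returned raw so the caller builds one FDR family.
- BH-FDR via statsmodels' step-up implementation.
- Cluster-size correction for time series: binarize the p series at
  α = 0.05, find maximal runs, shuffle the binary sequence 10 000 times,
  and call a run significant if it exceeds the 99.9th percentile of the
  null maximum run lengths.  Two properties follow from this construction
  and are deliberate: (i) on a fully saturated series the null max equals
  the series length identically, so a run covering every window can never
  be "exceeding" — the correction is degenerate there; (ii) the shuffle
  destroys the autocorrelation of smooth sliding-window p series, so for
  such series the correction is anti-conservative relative to standard
  cluster-permutation tests that re-compute statistics under permutation.
  Both are documented rather than repaired, because the procedure is the
  one under study; the false-positive rate on *independent* null series of
  length 116 is verified ≤ 1%.
- Spearman correlation: average ranks for ties; exact two-sided p by full
  enumeration of all n! orderings when n ≤ 8 (for n = 6: multiples of
  1/720), Monte-Carlo otherwise.
- Trend regression: OLS `v = a + b·t`, `F = MS_model/MS_res` with df
  (1, n−2), adjusted `R²_adj = 1 − (1−R²)(n−1)/(n−2)` (which can be
  negative — the signature of an adjusted statistic), permutation p for the
  slope.
- Shapiro–Wilk is exposed as a descriptive diagnostic only; it never
  switches the inference path, which is permutation-based regardless.

## The three analyses

Each implanted thalamus is one independent sample for t-tests and ANOVA;
patients are the unit for clinical correlations (hemisphere-averaged).

**Rest.**  Per EEG channel, band-averaged original and surrogate PSI per
hemisphere enter a 2 × 3 × 2 ANOVA (Condition × Frequency × Hemisphere).
FDR runs over the family of all channels' Condition × Frequency interaction
p-values plus all per-band post-hoc p-values; a channel is flagged when its
interaction survives and its original-vs-surrogate difference survives in
alpha but in neither theta nor beta.  The alpha-peak channel is tested
against the mean of all other channels (paired over hemispheres), and
hemisphere-averaged alpha PSI at the channel of interest (default Fz) is
rank-correlated with tic and urge severity; thalamic and frontal alpha
power are run as specificity controls.

**Suppression.**  Paired permutation t-tests comparing tic-freely with
tic-suppression: per-patient tic rate in the task blocks (rest recordings
excluded for comparability), alpha PSI at the channel of interest and LFP
alpha power per hemisphere, channel alpha power per patient.  Patients
without suppression data are dropped with a log entry.

**Tic.**  Tic epochs are pooled over conditions.  Per hemisphere the
sliding alpha PSI (0.3 s / 4 ms) is aggregated into 0.1 s test windows
stepped at 0.02 s whose left edges run from −1.8 to 0.5 s (116 windows; a
window's value is the mean of sliding centers in `[t, t + 0.1)` — the grid
alignment is this package's choice, since only length/step/range are
standard).  Each window is compared against a static rest PSI
bootstrap-matched in trial count (50 bootstrap draws of rest trials at the
tic trial count, averaged), equalising the trial-count-dependent PSI bias;
the 116 p-values enter the cluster correction; the hemisphere-mean sliding
series over −1.8–0 s (451 centers, hence trend df (1, 449)) is regressed
on time.  The same machinery runs on LFP and frontal-channel alpha power,
and — when reconstructed source ROI time series are supplied as a
SOURCE-modality recording — on thalamo-ROI PSI and ROI power.  No inverse
modelling is performed here; source signals are consumed as given.

## Synthetic cohorts and what they do (not) show

The generator writes the same file formats the readers consume, so the
whole pipeline can run from disk with no external data.

A narrowband alpha oscillator (instantaneous frequency wandering smoothly
inside the band, default centre 10 Hz) is observed by both LFP channels;
EEG channel *c* carries the same oscillation with von Mises(0, κ_c) phase
jitter, redrawn every 2 s with short smooth blends, on top of 1/f
background noise.  The jitter model gives the closed-form expected
phase-locking `E[PLV] = I₁(κ)/I₀(κ)`, the analytic oracle for the
estimators (checked at the oscillator centre frequency, where the model
speaks; 200 epochs, tolerance 0.03).  Two deliberate deviations from the
naive model:

- **κ = 0 channels get an independent oscillator.**  A channel sharing the
  master oscillator with uniform jitter still beats trial-shuffled
  surrogates, because its phase difference is constant within a trial but
  random across trials, while surrogate pairings decorrelate within trials.
  Physically an uncoupled cortical alpha source *is* an independent
  oscillator, so that is what κ = 0 generates; original PSI then matches
  the surrogate ensemble.
- **Cohorts use a weak-SNR regime with masking rhythms.**  A strong clean
  tone leaks through the Morlet spectral skirt into the 13–16 Hz bins, so
  the band-edge beta phases track the alpha oscillator and every coupled
  channel shows beta-band "coupling" — alpha-specific topography would be
  unrecoverable.  Real recordings do not behave like a clean tone: their
  theta and low-beta bands contain genuine independent rhythms whose phases
  dominate those bins.  Cohort recordings therefore use a weak alpha
  oscillation (EEG 2.5 µV against 5 µV of 1/f noise; LFP 1.0 against
  2.0 µV) plus independent band-limited theta (3–7.5 Hz) and low-beta
  (12.5–19 Hz) background rhythms at twice the oscillation amplitude, in
  both streams.  This puts sensor PSI in the 0.2–0.4 range typical of real
  LFP-EEG coupling and confines detectable coupling to alpha.  Single
  recordings generated directly from `GroundTruth` keep clean defaults so
  the Bessel-ratio oracle holds tightly.

Tic events are drawn with inter-tic gaps of ~5–9 s, so the generator's own
output already satisfies the merging/isolation rules.  In a window
`[ramp_start, 0]` before each tic onset (default −0.3 s, recovering over
0.3 s after onset) the coupled oscillation of every coupled channel is
cross-faded into an independent oscillator, removing `ramp_depth` (default
0.8) of the coupling at onset.  Per-patient κ values are spaced over
[2, 30] so the expected PLVs are evenly separated, Fz carries each
patient's maximal κ (other frontal-preset channels 75%), and severity
scores fall linearly in expected PLV plus truncated Gaussian noise —
whence the negative PSI–severity rank correlation the pipeline should
recover.  The LFP stream's clock is offset by 1–3 s against the EEG clock
to exercise the synchronisation path.

The generator does **not** model head-volume conduction, ocular or muscle
artifacts, amplitude-modulated (waxing/waning) alpha, cross-frequency
coupling, or non-stationary tic rates.  Passing recovery tests therefore
demonstrates that the estimators and inference recover the programmed
coupling structure under realistic SNR and spectral masking — not that the
pipeline is robust to every artifact class of real scalp data.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down problem sizes, chosen as
the smallest designs that preserve the study's statistical structure:
6 patients × 2 hemispheres, a 12-channel montage containing the 5-channel
frontal preset, 300 s of tic-freely data per patient (≈ 40 rest epochs and
≈ 35 tics), EEG generated directly at the 250 Hz analysis rate, 200
permutations and 40 surrogate iterations for pipeline-level inference
(10 000 and 100 remain the defaults), and 20 seeded replicates for the
recovery properties.  Tic-locked decompositions restrict the wavelet grid
to the alpha band, which also keeps the 2 Hz wavelet-length constraint away
from the 3 s tic epochs.

Degenerate inputs are errors, not silent fixes: zero-amplitude wavelet
coefficients (undefined phase), zero baseline in relative change, constant
inputs to correlation/regression, empty ANOVA cells, epochs shorter than
the longest wavelet.  Zero-variance paired differences return p = 1 with a
flag.  Monte-Carlo p-values use the +1 convention everywhere, so no test
can report p = 0.  Ties in ranks use average ranks.  BrainVision float32
round trips are exact at float32 precision (up to one µV↔V rescaling in
float64); Percept-style JSON round trips are bit-exact.
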