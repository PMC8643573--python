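# Methods

This note documents the models, conventions and numerical choices behind
`mrcplab`, and what the synthetic-cohort experiments do and do not establish.

## Recording model and epoching

Sessions carry 17 scalp EEG channels (10–20 positions FP1…P4) at 250 Hz and
four surface EMG channels (tibialis anterior and soleus, both legs) at
1000 Hz on one shared clock, with per-trial 'ready'/'go' cues 2 s apart and
≥ 10 s between trials (15 s default). Times are stored in seconds as reals;
sample indices are derived by rounding to the nearest sample, so the two
sampling rates share one time base.

Epochs are onset-locked and half-open: [−4, +4) s at 250 Hz, exactly 2000
samples, with index 1000 at t = 0. The user-facing analysis window is the
'Go' window [−2, +4) s; the earlier buffer exists for the oscillation
baseline. For left-foot-dominant participants the lateral EEG pairs
(FP1↔FP2 … P3↔P4) are swapped before analysis so "contralateral" is always
the same label; the swap is an involution and leaves midline channels
untouched.

EDF storage uses 1-second records with per-channel rates and symmetric
16-bit scaling per channel; cue annotations live in a sidecar TSV and
subject metadata (id, group, dominant foot, unpadded sample counts) in a
sidecar YAML. Round-trip error is bounded by half a quantization step of
each channel's physical range.

## EMG onset detection

Chain: zero-phase 2nd-order Butterworth band-pass 20–120 Hz → Teager–Kaiser
energy ψ[n] = x[n]² − x[n−1]x[n+1] (endpoints zero; homogeneous of degree
2) → detection on the native 1000 Hz series.

The per-subject threshold replaces manual visual selection: on the
concatenated quiet pre-'ready' stretches ([ready−3, ready−0.2] s), threshold
= median + k · 1.4826 · MAD of the 50 ms-smoothed energy, k = 8 (configurable,
with a manual override).

Detection is a double-threshold scheme chosen so that an ideal energy step
is localized to the exact first supra-threshold sample while noise cannot
trigger it: a burst is *confirmed* where the 50 ms-smoothed energy exceeds
the threshold and at least half the raw samples in the following 50 ms hold
window do too (a majority condition — an isolated spike of any height
fails it); the confirmation is then backtracked along the smoothed energy
to where it last left a lower threshold (baseline + 0.15 of the threshold
excess), and the onset is the first raw sample above that lower threshold.
Measured on synthetic bursts at 6 dB burst-to-baseline SNR, the median
absolute onset error is ~12–15 ms over 100 trials; the false-detection rate
on burst-free EMG is ≤ 2%. Error variance decreases monotonically with SNR
(0 → 6 → 12 dB); at 0 dB most bursts are left undetected, which is the
intended QC outcome rather than an error.

EMG features use the amplitude envelope (rectified band-passed EMG,
zero-phase 6 Hz low-pass, decimated to 250 Hz): the TA peak and its time in
[0, +4] s, and the TA–SOL onset lag from each muscle's own half-rise
crossing referenced to its quiet-baseline level — using the same fractional
rise for both muscles cancels the smoothing-induced rise time in the lag.

## MRCP features

All features are read at the nearest sample (4 ms ≪ the feature time
scales; no interpolation). Peak negativity is the minimum on the closed
window [−1, +1.5] s, ties to the earliest sample. NS1, NS2 and rebound are
two-point slopes at the offsets given in the README. The outlier window
[−1.5, 2] s is treated as closed; note that because the peak search window
is a subset of it, the rule can only remove trials when peak times are
supplied from elsewhere (it is kept as the documented QC contract). The
peak-search window being a subset also means `flag_outlier` never fires on
features computed by this package's own search — the rule matters for
externally supplied peak times.

The coefficient of variation of the waveform is
mean over t ∈ [−2, +4) of SD(t) / max(|mean(t)|, ε), ε = 0.1 µV. The floor
prevents blow-up at zero crossings of the mean; the aggregation window is
fixed to the 'Go' window. Alternative definitions (CoV of per-trial peak
amplitude or peak time) are available via `mode=` since the waveform
convention is a documented choice among several plausible ones. Grand
averages use the population SD convention (a single trial has SD 0).

## Oscillation analysis

The small Laplacian subtracts the mean of four surrounding electrodes from
the center. The true orthogonal neighbors of Cz/FC1/FC2 are absent from the
17-channel montage, so the nearest members stand in (Cz→{C3, C4, Fz, Pz},
FC1→{F3, Fz, C3, Cz}, FC2→{F4, Fz, C4, Cz}); the mapping is a montage field
and can be overridden.

Time–frequency power uses 5-cycle zero-mean complex Morlet wavelets on a
1–50 Hz grid (1 Hz step; the step is a choice, only the range is given by
convention). Decomposition runs on windows padded by 1 s on each side and
the pad is cropped afterwards: without the pad, columns near the left epoch
edge — inside the ERD baseline — retain ~2–3% power attenuation from the
wavelet tails, which biased every null ERD pixel by ≈ +0.35 SE and pushed
the bootstrap null significant-pixel rate to ~7.5%; with padding the null
rates are ~5.5%, near nominal. A per-frequency `edge_valid` mask (2.5
cycles) is still attached for unpadded use.

ERD normalization averages power across trials first, then scales each
frequency row by its mean baseline power over [−4, −2] s
(ERD% = 100·(P−B)/B). The baseline-window mean of every row is therefore
zero by construction, and the map is exactly invariant to a global power
rescaling. Per-trial normalization is deliberately not the default.

## Resampling statistics

Bootstrap significance resamples trials with replacement (default
n_boot = 1000; ≥ 200 enforced), recomputes the group ERD per resample, and
marks pixels whose percentile (α/2, 1−α/2) interval excludes zero. The
permutation difference test shuffles trial-to-group labels (default
n_perm = 1000; ≥ 500), with two-sided add-one-smoothed p-values
p = (1 + #{|d*| ≥ |d|}) / (n_perm + 1). To make the test exactly symmetric
under swapping the two groups, the permutation stream is attached to a
canonical ordering of the two samples (by content hash) and only the sign
of the difference map follows the argument order. Both procedures are
deterministic under a fixed seed. Significance is pointwise at α (an
optional interpretation caveat: no correction across pixels); pipelines run
them on a time-decimated grid for tractability.

The feature ANOVA is the classical one-way decomposition at the single-trial
level pooled across subjects (matching degrees of freedom like F(2, 284)
for ~287 trials in three groups); Tukey HSD adjusted pairwise p-values are
computed only when the omnibus p ≤ α. Subject-level analysis is available by
passing per-subject means. Within-group variance of exactly zero skips the
post hoc (degenerate SE).

## Synthetic cohort generator

The generator is the study-condition model, not a test dial; its defaults
encode the protocol (15 trials/session, cues 2 s apart, 15 s spacing) and
group profiles that qualitatively mirror the clinical contrasts (controls:
NS1 ≈ −3 µV/s, peak ≈ −16 µV, strong low/high-beta ERD and post-movement
beta rebound, TA peak ≈ 946 µV; severe FOG: NS1 ≈ −0.6 µV/s, absent
low-beta ERD, pre-movement theta ERS ≈ +25%, TA peak ≈ 512 µV, larger
TA–SOL onset lag). Profile values are test parameters for recovery and
contrast detection, not claims about any cohort.

* **Background EEG**: 1/f pink noise (default 4 µV RMS) plus white sensor
  noise (1 µV RMS), independent per channel.
* **MRCP template**: piecewise linear, so every feature has an exact
  analytic target — approach from 0 at t_p−2.4 s to the pre-NS1 level,
  NS1 segment over [t_p−1.4, t_p−0.4], NS2 segment to the trough, then a
  two-segment recovery: a brief steep motor-potential rebound (slope −NS2
  for 0.24 s) followed by a slower segment passing *exactly* through
  peak + 1.5·rebound at t_p+1.5 s, and a decay to zero at +4 s. The steep
  initial recovery keeps the trough sharply localized on both flanks, as in
  recorded motor potentials; with a single shallow linear rebound the
  single-trial argmin drifted ~200 ms into the flat flank under smooth
  in-band noise and biased the recovered features. Spatial weighting peaks
  at Cz (FC1/FC2 0.8, falling off frontally/posteriorly).
* **ERD/ERS**: band-passed noise carriers on the scheduled channels whose
  amplitude is rescaled inside windows tied to each true onset. The gain is
  chosen per channel as g² = 1 + (pct/100)·(1 + V_bg/V_carrier), i.e. it
  compensates for the broadband background power in the band so that the
  requested percentage is the *measured* total band-power change (verified:
  Welch band power −40.0% for a −40% schedule). Raised-cosine ramps (0.1 s)
  sit just outside the window edges so the whole window is at plateau gain.
* **EMG**: 20–120 Hz noise carriers; bursts are trapezoidal envelopes with
  a 20 ms rise (a ballistic dorsiflexion front), ~0.9 s plateau and 0.4 s
  fall, scaled so the rectified-mean plateau equals the profile's EMG peak;
  SOL starts a configurable lag after TA; burst-to-baseline SNR is a
  profile parameter (12 dB default). The measured envelope *maximum*
  exceeds the plateau calibration by a max-statistic factor (~20–30%), so
  recovered envelope peaks are compared across groups, not to the injected
  value.
* **Blinks**: Poisson-timed 0.3 s squared-Hann transients with a
  frontal-dominant spatial pattern, recorded in the ground truth.

Cohorts are bit-reproducible: per-subject RNG streams are spawned from one
root `SeedSequence`.

What the generator does **not** emulate: volume conduction beyond fixed
spatial weight maps, head-motion or electrode-drift artifacts, non-Gaussian
EMG statistics, tremor, FOG episodes or gait. Passing recovery tests
therefore demonstrate correctness of the analysis chain under the stated
noise model, not robustness to every failure mode of clinical recordings.

## Artifact rejection

Extended-infomax ICA (seeded) replaces manual two-expert component
labeling with two automated criteria: |correlation| of a component's time
course with the FP1/FP2 mean > 0.8 (blink proxy), or 25–50 Hz power more
than 1.0× the 1–10 Hz power (broadband muscle). Non-convergence passes data
through with a warning status; rejection reports carry per-component
scores. Trial QC for the oscillation path rejects sustained (≥ 100 ms)
supra-threshold envelope activity before the 'go' cue or on the
contralateral TA during [0, +4] s, with robust per-trial thresholds
(median + 8·MAD-SD). A head-motion criterion would need a motion channel,
which the data model does not carry; it is a hook only.

## Recovery experiments and problem sizes

The validation experiments (test suite and `scripts/acceptance.py`) use:
100 trials for MRCP feature recovery (in-band noise SD ≈ 2 µV; mean
recovered peak within ±0.5 µV, NS1 within ±0.6 µV/s, rebound within
±0.5 µV/s of injected); 100 bursts at 6 dB for onset error and 60 pure-noise
trials for the false-detection rate; 200 trials for ERD-tile recovery
(−40 ± 5 points) and for resampling calibration on a reduced 20×40 grid
(frequency rows spread 2 Hz apart to decorrelate neighboring Morlet bands;
n_boot = n_perm = 500; null rates averaged over three independent
cohorts); 2000 replicates for ANOVA type-I error; and a 3-group,
3-subject × 15-trial cohort for the end-to-end contrast run.

Two deliberate choices in the MRCP recovery experiment: epochs are cut at
the *true* onsets (isolating feature recovery from detector error, which is
quantified separately), and denoising uses the 5 Hz low-pass alone. The
0.05 Hz high-pass exists to remove electrode drift; the synthetic data
carry none, and ~70% of the template's energy lies below 0.1 Hz, so the
high-pass would subtract the slow potential's own local mean (≈ 4.5 µV at
the trough) — a known property of high-passed unipolar potentials, visible
in the full pipeline as compressed absolute feature values. The full
band-pass remains the pipeline default.

## Known limitations

* The measured ERD tile mean (≈ −39 for an injected −40%) carries a ~1-point
  dilution from wavelet temporal smearing at the tile edges.
* Single-trial peak-time estimates retain a small rightward bias under
  noise; NS1 estimates mix in NS2-segment samples when the peak time is
  overestimated, which compresses between-group NS1 contrasts at small
  cohort sizes (visible in the worked example: p ≈ 0.09 at 3 subjects per
  group).
* Percentile bootstrap intervals at 200 trials are mildly anti-conservative
  (~5.5% pixels at α = 0.05); the pointwise maps carry no multiplicity
  correction by design.
* ICA component criteria are tuned for the generator's blink/EMG morphology;
  real recordings may need different cutoffs (all exposed in the config).
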