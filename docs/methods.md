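# Methods

## The measurement problem

In a frequency-altered-feedback (FAF) experiment a speaker sustains a vowel
while their voice, fed back through earphones, is briefly pitch-shifted
(here: downward by 50 or 200 cents for 200 ms, once per 3-s vocalization,
1500–2000 ms after vocal onset). Most speakers oppose the shift — the
pitch-shift reflex — and the reflex's magnitude, its latency, the
stimulus-locked cortical response (N1/P2), and their association with a
biallelic genotype (AA/AG/GG) are the quantities of interest. This package
implements the complete measurement and inference chain plus a synthetic
cohort generator that provides ground truth for every stage.

## Vocal pipeline

F0 contours (frame rate 100 Hz by default) are converted to cents,
`1200·log2(F0/reference)` with reference 195.997 Hz (G3), and segmented
into epochs spanning **[−200, 700) ms** around each perturbation onset
(half-open; epoch time zero is the first frame at or after the onset; a
100-Hz contour yields 20 baseline + 70 response frames). Numerical choices
where the procedure is conventionally under-specified:

* **Classification window.** A trial is *compensatory* when the mean of its
  baseline-normalised values over **100–500 ms** opposes the perturbation
  sign, *following* otherwise. The window excludes pre-response baseline
  noise and the post-offset decay; it is configurable.
* **Bad trials.** Visual "waterfall" inspection is replaced by two explicit
  rules (config-exposed, not claimed equivalent to inspection): more than
  20 % missing frames, or any excursion beyond 600 cents from the baseline
  mean (vocal interruptions, octave errors).
* **Peak search.** The response magnitude is the maximum of the averaged
  compensatory contour over **[0, 700) ms** — the full epoch, avoiding an
  invented onset detector — with ties resolved to the earliest sample and
  an "edge peak" warning when the maximum sits on the window boundary.
* **Baseline variability.** Implemented as the across-trial SD (ddof = 1)
  of per-trial baseline means over all retained trials, matching the
  construct "variability of the voice across productions"; the alternative
  (SD of the averaged contour's baseline samples) is available via
  `VocalMeasureConfig.variability_mode`.

The optional F0 estimator (for WAV input) is a frame-based autocorrelation
method (60-ms frames, 10-ms hop, 75–500 Hz search range): the three
autocorrelation samples around the peak are corrected for the rectangular
window taper before parabolic refinement, keeping pure-tone errors below
0.5 Hz in the speech range; frames with a normalised peak below 0.5 are
unvoiced. It is a deliberately simple, deterministic estimator — adequate
for clean sustained vowels, not a replacement for a production pitch
tracker on running speech.

## EEG pipeline

Continuous recordings are band-passed 1–20 Hz with a 4th-order Butterworth
applied forward–backward (zero phase; order and realization config-exposed)
and segmented into **[−200, 500) ms** epochs. Artifact detection flags an
(epoch, channel) pair when any sample deviates more than **±55 μV** from
the **80-ms moving average** (centred window, reflect-padded edges; a
trailing-window alternative sits behind a flag). Note the rule is a
high-pass criterion: it catches fast transients, which is why the simulated
blink template (below) carries a sharp onset. A channel is bad when flagged
in **more than 20 %** of the subject's pooled epochs; a subject is excluded
above **10 bad channels**; epochs flagged on any retained channel are
dropped. Retained epochs are re-referenced to the mastoid average (labels
M1/M2 in the default montage; real-data users map their mastoid sensors in
the config), averaged per condition, baseline-corrected over [−200, 0) ms,
and N1/P2 are measured as the extreme samples in **80–160 ms** (minimum)
and **180–280 ms** (maximum) at FC1–4, FCz, C1–4, Cz, ties to the earliest
sample. On simulated cohorts the band-pass stage is a no-op because the
generator emits epochs whose deterministic content is already band-limited;
filtering applies when continuous recordings are the input.

## Statistics

* **Hardy–Weinberg χ²** with df = 1 (one estimated allele frequency,
  biallelic): on the genotyped sample 55/71/24 this gives χ² = 0.018,
  p = 0.892.
* **Split-plot ANOVA.** Each subject's within-cell profile is projected
  onto orthonormal (Helmert) contrasts; each within-effect stratum becomes
  a one-way between-group analysis of the contrast scores, pooled over
  contrast columns. Between-group sums of squares are Type III (the
  standard choice for the unbalanced 49/63/21 design); within-effect main
  terms test the unweighted marginal mean. The Greenhouse–Geisser ε comes
  from the stratum's pooled within-group residual covariance,
  ε = tr(Σ)²/(q·tr(Σ²)), clipped to [1/q, 1]; a two-level factor has
  ε = 1 exactly. Corrected p values are always reported alongside the
  uncorrected ones (no hidden "correct only if Mauchly rejects" decision).
  Effect sizes are partial η² = SS_eff/(SS_eff + SS_err). The
  implementation is verified to 1e−8 against an independent brute-force
  oracle (long-format Type III projection computation) on random small
  unbalanced designs and against pingouin on balanced two-way designs.
* **Post hocs** are Bonferroni-adjusted pairwise comparisons using the
  error term pooled over all groups (df = N − G), the conventional choice
  when the source ANOVA's error term is unnamed.
* **Correlations** are Pearson r with two-sided t-based p (df = n − 2).
  The study battery correlates each subject's mean compensation magnitude
  (across the two shift sizes) with the baseline-SD index per genotype —
  per-shift correlations are also emitted, since the collapsed-vs-per-shift
  choice is conventionally ambiguous. Groups with n < 3 yield a flagged
  degenerate result rather than an error.

## Synthetic cohort generator

Defaults reproduce the study structure: 49/63/21 subjects across AA/AG/GG,
100 trials per magnitude (−50, −200 cents), 200-ms perturbations at
1500–2000 ms, 3-s vocalizations at a 100-Hz contour rate, 64-channel
montage, 1-kHz EEG.

**Vocal model.** Each trial's cents contour is `baseline + jitter +
direction · gain · bump(t)`. The bump rises (raised cosine) from a 150-ms
onset latency to its peak (subject latency ≈ N(350, 40) ms, quantised to
the frame grid so noise-free recovery is exact to one frame) and decays
over 300 ms; 15 % of trials "follow" (sign flipped), motivated by typical
compensatory-trial retention rates. The jitter has two components with
total variance `baseline_sd_cents²` (subject scale ≈ N(15, 5) cents,
floored at 2): a **per-trial level offset** (70 % of variance — the voice
sits at a slightly different pitch each production) and **fast
within-trial microvariation** (Gaussian-kernel-smoothed white noise,
σ = 25 ms, circular so the process is stationary with autocorrelation
exp(−d²/4σ²)). The offset drives the baseline-variability index but
cancels in baseline normalisation, so it cannot bias classification or
peak measurement — the property that keeps the measured
compensation-vs-variability correlations close to their generative
targets.

**Effects.** Subject compensation gains are drawn from genotype-conditional
normals (means 18/24 cents for −50/−200, SD 8, cross-magnitude correlation
0.7) through a Gaussian copula that links them to the baseline-SD scale at
ρ = 0.53/0.26/0.10 for AA/AG/GG; the GG mean at −200 cents is reduced by
0.8 pooled SD. P2 amplitudes (means 4/6 μV, SD 1.5) get the mirrored GG
enhancement (+0.8 SD at −200); N1 (−3/−5 μV, SD 1) is
genotype-independent. `EffectParams.null()` switches every genotype effect
off for Type-I studies.

**EEG model.** Epoch = topographic weight × (N1·G(t; lat, 20 ms) +
P2·G(t; lat, 25 ms)) + 1/f noise (8 μV RMS, spectrum flattened below
1 Hz). Weights are 1.0 at FCz grading down fronto-centrally and exactly 0
at the mastoids, so vertex- and mastoid-referenced noise-free data agree.
Recovery tests compare the measured peaks against the clean template's
window extrema evaluated analytically: the pipeline recovers those exactly
(to 1e−9, latencies to one sample). Where the N1/P2 Gaussians overlap, the
window extremum differs from the isolated component amplitude by a small
leakage (well under 0.1 μV for the default widths and latency ranges);
that leakage is part of the generated waveform, reported separately, and
not a pipeline error. Blink artifacts (rate 0.15 per
epoch, the level at which epoch retention is in the low-80 % range typical
of such studies) add a 150-μV template to the eight fronto-polar channels:
a **10-ms linear rise** followed by a 290-ms half-cosine decay. The sharp
onset is deliberate — a smooth 300-ms half-sine deviates at most ~15 μV
from its own 80-ms moving average and would be invisible to the ±55 μV
rule, whereas real blinks have an abrupt lid-closure onset; with the sharp
onset the rule detects injected blinks with sensitivity and specificity
≥ 0.95 at the default noise level.

**What the generator does not emulate.** Formant structure, loudness and
voice-quality variation, the acoustic feedback loop and harmonizer latency,
non-stationary or spatially correlated EEG noise, ocular/EMG artifacts
other than the blink template, genuine per-trial coupling between vocal and
cortical responses, and drifts across the session. Passing tests therefore
demonstrate correctness of the measurement and inference chain under the
stated statistical structure, not robustness to every pathology of real
recordings.

## Simulation studies and problem sizes

`faflab.studies` packages the calibration experiments the test suite and
`scripts/acceptance.py` run: Type-I error of the magnitude × genotype
interaction over 2000 null cohorts at a reduced size (12 subjects per
genotype, 20 trials per magnitude — the test's null calibration does not
depend on cohort size, and thousands of replicates stay cheap); power and
correlation ordering over 200 full-size cohorts (49/63/21, 100 trials);
QC fidelity on a 6-subject, 50-trial cohort scored per (epoch, channel)
pair; and noise-free recovery on a 7-subject cohort. The orchestrated
default-structure run used for subject accounting keeps the full 133
subjects but 20 trials per magnitude, since the exclusion rules act on
flag fractions, not epoch counts.

## Known limitations

* The vocal peak is measured on the averaged contour only; per-trial
  magnitudes are not provided (the averaged definition is the conventional
  one, and per-trial peak-picking is badly biased by noise).
* The F0 estimator targets clean sustained vowels; no octave-error
  post-processing.
* EDF files can be read (via mne) but not written; the cohort writer uses
  the package's float32 + JSON fixture format.
* The ANOVA requires a complete within-design per subject; missing cells
  are an error, not imputed.
* Greenhouse–Geisser ε uses the pooled within-group covariance; tools that
  estimate it from the grand covariance (e.g. pingouin's mixed model) will
  differ slightly when group means differ.
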