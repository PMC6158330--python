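"""Synthetic FAF cohort generator.

Emulates the structure of a frequency-altered-feedback genotype study:
133 subjects split 49/63/21 across the AA/AG/GG genotypes, 100 vocal
trials per subject for each downward pitch perturbation (-50 and -200
cents, 200 ms long, onset 1500-2000 ms after vocal onset), plus
stimulus-locked EEG epochs carrying an N1/P2 complex with a fronto-central
topography and 1/f background noise.

Generative structure (ground truth the pipelines must recover):

* each subject has a baseline voice F0, a smooth within-trial F0 jitter
  whose scale is the subject's intrinsic voice variability, a compensatory
  gain (cents) and peak latency per perturbation magnitude, N1/P2
  amplitudes and latencies per magnitude, and an artifact rate;
* the GG group's mean compensation for -200 cents is reduced by a
  configurable effect size (default 0.8 pooled SD); the GG group's P2 for
  -200 cents is raised by the same device; N1 is genotype-independent;
* within each genotype the compensatory gain is correlated with the
  baseline-variability parameter through a Gaussian copula (default
  targets 0.53 / 0.26 / 0.10 for AA / AG / GG);
* a configurable fraction of trials "follows" the perturbation (response
  in the same direction) instead of opposing it;
* blink-like artifacts (sharp rise, slow half-cosine decay, default
  150 uV / 300 ms) are injected on frontal channels at the artifact rate,
  with ground-truth (epoch, channel) contamination labels.

The F0 jitter has two components whose total variance is the square of
the subject's ``baseline_sd_cents``: a per-trial level offset (the voice
sits at a slightly different pitch on every production; weight
``jitter_slow_weight`` of the variance) and a fast within-trial
microvariation, unit-variance Gaussian white noise smoothed with a
Gaussian kernel of scale ``jitter_smooth_ms`` (circular convolution, so
the fast process is stationary with autocorrelation
``rho(d) = exp(-d^2 / (4 sigma^2))`` in frames). The level offset cancels
in baseline normalisation, so it feeds the baseline-variability index
without biasing response classification or peak measurement.

Vocal traces are materialised at generation time; EEG epochs are
generated lazily per subject from seeds derived from the cohort seed, so
a full-size cohort stays within ordinary memory. Everything is
bit-reproducible given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import montage as mtg
from .eeg import EEGEpochSet
from .vocal import F0Trace, cents_to_hz, hz_to_cents

__all__ = [
    "EffectParams",
    "CohortSpec",
    "SubjectParams",
    "CohortDataset",
    "simulate_cohort",
    "simulate_vocal_trial",
    "simulate_eeg_epochs",
    "inject_artifacts",
    "render_audio",
]


@dataclass(frozen=True)
class EffectParams:
    """Population-level effect structure of the simulated cohort."""

    comp_gain_mean_cents: dict = field(
        default_factory=lambda: {-50.0: 18.0, -200.0: 24.0})
    comp_gain_sd_cents: float = 8.0
    #: GG compensation deficit at the largest shift, in pooled-SD units
    gg_comp_deficit_sd: float = 0.8
    #: target correlation (per genotype) between baseline variability and gain
    comp_corr: dict = field(
        default_factory=lambda: {"AA": 0.53, "AG": 0.26, "GG": 0.10})
    #: correlation of a subject's gains across the two magnitudes
    cross_condition_corr: float = 0.7
    comp_latency_mean_ms: float = 350.0
    comp_latency_sd_ms: float = 40.0
    onset_latency_ms: float = 150.0
    decay_ms: float = 300.0
    following_fraction: float = 0.15
    baseline_sd_mean_cents: float = 15.0
    baseline_sd_spread_cents: float = 5.0
    #: share of the jitter variance carried by the per-trial level offset
    jitter_slow_weight: float = 0.7
    jitter_smooth_ms: float = 25.0
    n1_amp_mean_uv: dict = field(default_factory=lambda: {-50.0: -3.0, -200.0: -5.0})
    n1_amp_sd_uv: float = 1.0
    p2_amp_mean_uv: dict = field(default_factory=lambda: {-50.0: 4.0, -200.0: 6.0})
    p2_amp_sd_uv: float = 1.5
    #: GG P2 enhancement at the largest shift, in subject-SD units
    gg_p2_boost_sd: float = 0.8
    n1_lat_mean_ms: float = 120.0
    n1_lat_sd_ms: float = 10.0
    p2_lat_mean_ms: float = 230.0
    p2_lat_sd_ms: float = 15.0
    sigma_n1_ms: float = 20.0
    sigma_p2_ms: float = 25.0
    eeg_noise_rms_uv: float = 8.0
    artifact_rate: float = 0.15
    blink_amp_uv: float = 150.0
    blink_duration_ms: float = 300.0
    blink_rise_ms: float = 10.0

    def null(self) -> "EffectParams":
        """Copy with all genotype effects switched off (Type-I studies)."""
        return replace(self, gg_comp_deficit_sd=0.0, gg_p2_boost_sd=0.0,
                       comp_corr={g: 0.0 for g in self.comp_corr})


@dataclass(frozen=True)
class CohortSpec:
    """Structure of the simulated study (defaults follow the study design)."""

    n_per_genotype: dict = field(default_factory=lambda: {"AA": 49, "AG": 63, "GG": 21})
    trials_per_condition: int = 100
    magnitudes_cents: tuple = (-50.0, -200.0)
    perturbation_duration_ms: float = 200.0
    perturbation_onset_range_ms: tuple = (1500.0, 2000.0)
    vocalization_duration_s: float = 3.0
    vocal_fs_hz: float = 100.0
    eeg_fs_hz: float = 1000.0
    eeg_channels: tuple = tuple(mtg.DEFAULT_64)
    effects: EffectParams = field(default_factory=EffectParams)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_genotype.items():
            if n <= 0:
                raise ValueError(f"n_per_genotype[{g!r}] must be > 0, got {n}")
        if self.trials_per_condition <= 0:
            raise ValueError("trials_per_condition must be > 0")
        if any(m >= 0 for m in self.magnitudes_cents):
            raise ValueError("magnitudes_cents must be negative (downward shifts)")
        lo, hi = self.perturbation_onset_range_ms
        if not (0 < lo <= hi):
            raise ValueError("perturbation_onset_range_ms must be an increasing positive interval")
        if hi + 700.0 > self.vocalization_duration_s * 1000.0 or lo < 200.0:
            raise ValueError(
                "perturbation_onset_range_ms must leave 200 ms of baseline and "
                "700 ms of response inside the vocalization")
        if len(set(self.eeg_channels)) != len(self.eeg_channels):
            raise ValueError("eeg_channels labels must be unique")
        if not 0.0 <= self.effects.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if not 0.0 <= self.effects.following_fraction <= 1.0:
            raise ValueError("following_fraction must be in [0, 1]")


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one subject."""

    subject_id: str
    genotype: str
    sex: str
    age: int
    baseline_f0_hz: float
    baseline_sd_cents: float
    comp_gain: dict            # magnitude -> cents (positive: opposes shift)
    comp_latency_ms: float
    n1_amp_uv: dict            # magnitude -> uV (negative)
    p2_amp_uv: dict            # magnitude -> uV (positive)
    n1_lat_ms: float
    p2_lat_ms: float
    artifact_rate: float

    def __post_init__(self) -> None:
        if self.baseline_f0_hz <= 0:
            raise ValueError("baseline_f0_hz must be > 0")
        if self.baseline_sd_cents < 0:
            raise ValueError("baseline_sd_cents must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        if any(g < 0 for g in self.comp_gain.values()):
            raise ValueError("comp_gain must oppose a downward shift (>= 0)")


# ---------------------------------------------------------------------------
# subject parameter draws
# ---------------------------------------------------------------------------

_MALE_FRACTION = {"AA": 14 / 49, "AG": 18 / 63, "GG": 4 / 21}


def _draw_subjects(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectParams]:
    ef = spec.effects
    mags = list(spec.magnitudes_cents)
    big = min(mags)  # most negative = largest shift
    frame_ms = 1000.0 / spec.vocal_fs_hz
    subjects = []
    k = 0
    for g in sorted(spec.n_per_genotype):
        n = spec.n_per_genotype[g]
        rho = float(ef.comp_corr.get(g, 0.0))
        cc = ef.cross_condition_corr
        r_shared = (cc - rho**2) / (1 - rho**2) if abs(rho) < 1 else 0.0
        r_shared = float(np.clip(r_shared, 0.0, 1.0))
        z_sd = rng.standard_normal(n)
        u = rng.standard_normal(n)
        for i in range(n):
            k += 1
            sid = f"S{k:03d}"
            bsd = max(2.0, ef.baseline_sd_mean_cents + ef.baseline_sd_spread_cents * z_sd[i])
            gains = {}
            for m in mags:
                v = rng.standard_normal()
                z = (rho * z_sd[i]
                     + np.sqrt(max(0.0, 1 - rho**2))
                     * (np.sqrt(r_shared) * u[i] + np.sqrt(1 - r_shared) * v))
                mean = ef.comp_gain_mean_cents[m]
                if g == "GG" and m == big:
                    mean -= ef.gg_comp_deficit_sd * ef.comp_gain_sd_cents
                gains[m] = max(1.0, mean + ef.comp_gain_sd_cents * z)
            lat = ef.comp_latency_mean_ms + ef.comp_latency_sd_ms * rng.standard_normal()
            lat = float(np.clip(np.round(lat / frame_ms) * frame_ms, 250.0, 550.0))
            z_n1 = rng.standard_normal()
            z_p2 = rng.standard_normal()
            n1 = {m: min(-0.5, ef.n1_amp_mean_uv[m] + ef.n1_amp_sd_uv * z_n1)
                  for m in mags}
            p2 = {}
            for m in mags:
                mean = ef.p2_amp_mean_uv[m]
                if g == "GG" and m == big:
                    mean += ef.gg_p2_boost_sd * ef.p2_amp_sd_uv
                p2[m] = max(0.5, mean + ef.p2_amp_sd_uv * z_p2)
            eeg_step = 1000.0 / spec.eeg_fs_hz
            n1_lat = float(np.clip(np.round(
                (ef.n1_lat_mean_ms + ef.n1_lat_sd_ms * rng.standard_normal()) / eeg_step)
                * eeg_step, 90.0, 150.0))
            p2_lat = float(np.clip(np.round(
                (ef.p2_lat_mean_ms + ef.p2_lat_sd_ms * rng.standard_normal()) / eeg_step)
                * eeg_step, 190.0, 270.0))
            male = rng.random() < _MALE_FRACTION.get(g, 0.27)
            f0 = (max(80.0, 120.0 + 20.0 * rng.standard_normal()) if male
                  else max(150.0, 220.0 + 30.0 * rng.standard_normal()))
            subjects.append(SubjectParams(
                subject_id=sid, genotype=g, sex="M" if male else "F",
                age=int(rng.integers(18, 30)), baseline_f0_hz=f0,
                baseline_sd_cents=bsd, comp_gain=gains, comp_latency_ms=lat,
                n1_amp_uv=n1, p2_amp_uv=p2, n1_lat_ms=n1_lat, p2_lat_ms=p2_lat,
                artifact_rate=ef.artifact_rate))
    return subjects


# ---------------------------------------------------------------------------
# vocal trials
# ---------------------------------------------------------------------------

def _smooth_jitter(rng: np.random.Generator, shape: tuple, fs_hz: float,
                   smooth_ms: float) -> np.ndarray:
    """Unit-variance stationary smooth noise (Gaussian kernel, circular)."""
    white = rng.standard_normal(shape)
    sigma = smooth_ms / 1000.0 * fs_hz
    if sigma <= 0:
        return white
    sm = gaussian_filter1d(white, sigma=sigma, axis=-1, mode="wrap")
    # normalise by the kernel's l2 norm so the output has unit variance
    n = shape[-1]
    delta = np.zeros(n)
    delta[n // 2] = 1.0
    k = gaussian_filter1d(delta, sigma=sigma, mode="wrap")
    return sm / np.sqrt(np.sum(k**2))


def _comp_bump(t_rel_s: np.ndarray, onset_lat_s: float, peak_lat_s: float,
               decay_s: float) -> np.ndarray:
    """Smooth compensatory response template, max exactly 1 at peak latency.

    Zero until the onset latency, raised-cosine rise to 1 at the peak
    latency, half-cosine decay back to zero over ``decay_s``.
    """
    out = np.zeros_like(t_rel_s)
    rise = (t_rel_s >= onset_lat_s) & (t_rel_s <= peak_lat_s)
    if peak_lat_s > onset_lat_s:
        out[rise] = 0.5 * (1 - np.cos(
            np.pi * (t_rel_s[rise] - onset_lat_s) / (peak_lat_s - onset_lat_s)))
    fall = (t_rel_s > peak_lat_s) & (t_rel_s < peak_lat_s + decay_s)
    out[fall] = 0.5 * (1 + np.cos(np.pi * (t_rel_s[fall] - peak_lat_s) / decay_s))
    return out


def _vocal_block(params: SubjectParams, magnitude: float, spec: CohortSpec,
                 rng: np.random.Generator, n_trials: int,
                 jitter: bool = True) -> dict:
    """All vocal trials of one subject x condition as a trial x frame matrix."""
    ef = spec.effects
    fs = spec.vocal_fs_hz
    T = int(round(spec.vocalization_duration_s * fs))
    lo, hi = spec.perturbation_onset_range_ms
    onset_idx = rng.integers(int(round(lo / 1000.0 * fs)),
                             int(round(hi / 1000.0 * fs)) + 1, size=n_trials)
    following = rng.random(n_trials) < ef.following_fraction
    t = np.arange(T) / fs
    t_rel = t[None, :] - onset_idx[:, None] / fs
    bump = _comp_bump(t_rel, ef.onset_latency_ms / 1000.0,
                      params.comp_latency_ms / 1000.0, ef.decay_ms / 1000.0)
    direction = np.where(following, -1.0, 1.0)
    cents = direction[:, None] * params.comp_gain[magnitude] * bump
    if jitter and params.baseline_sd_cents > 0:
        w = ef.jitter_slow_weight
        offsets = rng.standard_normal(n_trials)
        cents = cents + params.baseline_sd_cents * (
            np.sqrt(w) * offsets[:, None]
            + np.sqrt(1 - w) * _smooth_jitter(rng, (n_trials, T), fs,
                                              ef.jitter_smooth_ms))
    cents = cents + hz_to_cents(params.baseline_f0_hz)
    return {"f0_hz": cents_to_hz(cents), "onset_idx": onset_idx,
            "following": following}


def simulate_vocal_trial(params: SubjectParams, event, rng: np.random.Generator,
                         spec: CohortSpec | None = None,
                         force_following: bool | None = None) -> F0Trace:
    """One vocal trial as an Hz-scale :class:`F0Trace`.

    ``event`` carries ``onset_s`` and ``magnitude_cents`` (dict or object).
    The trial follows the perturbation (same direction) with probability
    ``following_fraction`` unless ``force_following`` pins the label.
    """
    spec = spec or CohortSpec()
    ev = event if isinstance(event, dict) else vars(event)
    onset_s = float(ev["onset_s"])
    if not 0 <= onset_s <= spec.vocalization_duration_s:
        raise ValueError("event onset outside the vocalization")
    ef = spec.effects
    fs = spec.vocal_fs_hz
    T = int(round(spec.vocalization_duration_s * fs))
    t = np.arange(T) / fs
    following = (rng.random() < ef.following_fraction
                 if force_following is None else force_following)
    bump = _comp_bump(t - onset_s, ef.onset_latency_ms / 1000.0,
                      params.comp_latency_ms / 1000.0, ef.decay_ms / 1000.0)
    cents = (-1.0 if following else 1.0) * params.comp_gain[float(ev["magnitude_cents"])] * bump
    if params.baseline_sd_cents > 0:
        w = ef.jitter_slow_weight
        cents = cents + params.baseline_sd_cents * (
            np.sqrt(w) * rng.standard_normal()
            + np.sqrt(1 - w) * _smooth_jitter(rng, (T,), fs, ef.jitter_smooth_ms))
    cents = cents + hz_to_cents(params.baseline_f0_hz)
    return F0Trace(t, cents_to_hz(cents), "hz", fs)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple, fs_hz: float,
                rms_uv: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, scaled to the requested overall RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(np.maximum(f[1:], 1.0))   # flat below 1 Hz, no DC
    x = np.fft.irfft(spec * gain, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2))
    return x * (rms_uv / rms) if rms > 0 else x


def _blink_shape(fs_hz: float, amp_uv: float, duration_ms: float,
                 rise_ms: float) -> np.ndarray:
    """Blink template: sharp linear rise, half-cosine decay back to zero."""
    n_rise = max(1, int(round(rise_ms / 1000.0 * fs_hz)))
    n_total = int(round(duration_ms / 1000.0 * fs_hz))
    n_fall = max(1, n_total - n_rise)
    rise = np.linspace(0.0, 1.0, n_rise + 1)[1:]
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_fall + 1) / n_fall))
    return amp_uv * np.concatenate([rise, fall])


def inject_artifacts(data: np.ndarray, ch_names: list[str], fs_hz: float,
                     rate: float, rng: np.random.Generator,
                     amp_uv: float = 150.0, duration_ms: float = 300.0,
                     rise_ms: float = 10.0,
                     channels: list[str] | None = None) -> np.ndarray:
    """Add blink-like deflections in place; return ground-truth flags.

    Each epoch is contaminated with probability ``rate``; contamination
    adds the blink template to every frontal channel (or ``channels``) at a
    random onset. Returns a boolean (n_epochs, n_channels) truth array.
    """
    chans = channels if channels is not None else [
        c for c in mtg.FRONTAL_CHANNELS if c in ch_names]
    cidx = [ch_names.index(c) for c in chans]
    n_ep, _, n_t = data.shape
    truth = np.zeros((n_ep, len(ch_names)), dtype=bool)
    if rate <= 0 or not cidx:
        return truth
    shape = _blink_shape(fs_hz, amp_uv, duration_ms, rise_ms)
    hit = rng.random(n_ep) < rate
    max_onset = n_t - shape.size
    for e in np.where(hit)[0]:
        s = int(rng.integers(0, max_onset + 1))
        data[e, cidx, s : s + shape.size] += shape
        truth[e, cidx] = True
    return truth


def simulate_eeg_epochs(params: SubjectParams, magnitude: float,
                        rng: np.random.Generator,
                        spec: CohortSpec | None = None,
                        n_trials: int | None = None,
                        noise: bool = True,
                        artifacts: bool = True) -> tuple[EEGEpochSet, np.ndarray]:
    """Simulate one subject x condition's EEG epochs plus artifact truth.

    Epochs span [-200, 500) ms. The deterministic part is
    ``w_ch * (n1 * G(t; n1_lat, sigma_n1) + p2 * G(t; p2_lat, sigma_p2))``
    with the fronto-central topographic weight ``w_ch`` (zero at the
    mastoids); 1/f noise and blink artifacts are added on top.
    """
    spec = spec or CohortSpec()
    ef = spec.effects
    fs = spec.eeg_fs_hz
    n = n_trials if n_trials is not None else spec.trials_per_condition
    ch = list(spec.eeg_channels)
    n_t = int(round(0.7 * fs))
    t_ms = (np.arange(n_t) - int(round(0.2 * fs))) / fs * 1000.0
    g1 = np.exp(-0.5 * ((t_ms - params.n1_lat_ms) / ef.sigma_n1_ms) ** 2)
    g2 = np.exp(-0.5 * ((t_ms - params.p2_lat_ms) / ef.sigma_p2_ms) ** 2)
    comp = (params.n1_amp_uv[magnitude] * g1 + params.p2_amp_uv[magnitude] * g2)
    w = np.array(mtg.topographic_weights(ch))
    clean = w[:, None] * comp[None, :]                    # (C, T)
    data = np.tile(clean, (n, 1, 1))
    if noise and ef.eeg_noise_rms_uv > 0:
        data = data + _pink_noise(rng, (n, len(ch), n_t), fs, ef.eeg_noise_rms_uv)
    if artifacts and params.artifact_rate > 0:
        truth = inject_artifacts(data, ch, fs, params.artifact_rate, rng,
                                 ef.blink_amp_uv, ef.blink_duration_ms,
                                 ef.blink_rise_ms)
    else:
        truth = np.zeros((n, len(ch)), dtype=bool)
    return EEGEpochSet(data, fs, ch), truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A simulated cohort: ground truth, vocal trial matrices, lazy EEG."""

    spec: CohortSpec
    subjects: list
    vocal: dict                      # (subject_id, magnitude) -> block dict
    eeg_seeds: dict                  # (subject_id, magnitude) -> int

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, sid: str) -> SubjectParams:
        for s in self.subjects:
            if s.subject_id == sid:
                return s
        raise KeyError(sid)

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for m in self.spec.magnitudes_cents:
                rows.append(dict(
                    subject_id=s.subject_id, genotype=s.genotype, sex=s.sex,
                    age=s.age, magnitude_cents_shift=m,
                    baseline_f0_hz=s.baseline_f0_hz,
                    baseline_sd_cents=s.baseline_sd_cents,
                    comp_gain_cents=s.comp_gain[m],
                    comp_latency_ms=s.comp_latency_ms,
                    n1_amp_uv=s.n1_amp_uv[m], p2_amp_uv=s.p2_amp_uv[m],
                    n1_lat_ms=s.n1_lat_ms, p2_lat_ms=s.p2_lat_ms))
        return pd.DataFrame(rows)

    def genotype_table(self) -> pd.DataFrame:
        return pd.DataFrame([dict(subject_id=s.subject_id, genotype=s.genotype,
                                  sex=s.sex, age=s.age) for s in self.subjects])

    def events(self, sid: str, magnitude: float) -> pd.DataFrame:
        block = self.vocal[(sid, magnitude)]
        fs = self.spec.vocal_fs_hz
        return pd.DataFrame(dict(
            trial_id=[f"{sid}_m{int(magnitude)}_t{i:03d}"
                      for i in range(block["onset_idx"].size)],
            onset_s=block["onset_idx"] / fs,
            magnitude_cents=magnitude,
            duration_ms=self.spec.perturbation_duration_ms))

    def f0_trace(self, sid: str, magnitude: float, trial: int) -> F0Trace:
        block = self.vocal[(sid, magnitude)]
        fs = self.spec.vocal_fs_hz
        vals = block["f0_hz"][trial]
        return F0Trace(np.arange(vals.size) / fs, vals.copy(), "hz", fs)

    def eeg_epochs(self, sid: str, magnitude: float,
                   noise: bool = True, artifacts: bool = True):
        """Generate this subject x condition's epochs (deterministic seed)."""
        rng = np.random.default_rng(self.eeg_seeds[(sid, magnitude)])
        return simulate_eeg_epochs(self.subject(sid), magnitude, rng,
                                   self.spec, noise=noise, artifacts=artifacts)


def simulate_cohort(spec: CohortSpec | None = None,
                    vocal_jitter: bool = True) -> CohortDataset:
    """Simulate a full cohort under ``spec`` (deterministic given its seed).

    ``vocal_jitter=False`` produces noise-free vocal traces for
    ground-truth-recovery studies.
    """
    spec = spec or CohortSpec()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_params, ss_vocal, ss_eeg = root.spawn(3)
    subjects = _draw_subjects(spec, np.random.default_rng(ss_params))

    n_pairs = len(subjects) * len(spec.magnitudes_cents)
    vocal_seeds = ss_vocal.spawn(n_pairs)
    eeg_seeds_seq = ss_eeg.generate_state(n_pairs)
    vocal, eeg_seeds = {}, {}
    k = 0
    for s in subjects:
        for m in spec.magnitudes_cents:
            rng = np.random.default_rng(vocal_seeds[k])
            vocal[(s.subject_id, m)] = _vocal_block(
                s, m, spec, rng, spec.trials_per_condition, jitter=vocal_jitter)
            eeg_seeds[(s.subject_id, m)] = int(eeg_seeds_seq[k])
            k += 1
    return CohortDataset(spec=spec, subjects=subjects, vocal=vocal,
                         eeg_seeds=eeg_seeds)


# ---------------------------------------------------------------------------
# optional audio rendering (to exercise the F0 estimator)
# ---------------------------------------------------------------------------

def render_audio(trace: F0Trace, fs: float = 16000.0,
                 vibrato_cents: float = 0.0, vibrato_hz: float = 5.0) -> np.ndarray:
    """Render an F0 contour as a unit-amplitude sine (optional vibrato).

    Phase-continuous oscillator; frames are held between F0 samples.
    Unvoiced (NaN) frames render as silence.
    """
    tr = trace if trace.unit == "hz" else F0Trace(
        trace.times_s, cents_to_hz(trace.values), "hz", trace.fs_hz)
    n = int(round((tr.times_s[-1] + 1.0 / tr.fs_hz) * fs))
    t = np.arange(n) / fs
    idx = np.minimum((t * tr.fs_hz).astype(int), tr.values.size - 1)
    f0 = tr.values[idx]
    if vibrato_cents > 0:
        f0 = f0 * 2.0 ** (vibrato_cents * np.sin(2 * np.pi * vibrato_hz * t) / 1200.0)
    voiced = np.isfinite(f0)
    inst = np.where(voiced, f0, 0.0)
    phase = 2 * np.pi * np.cumsum(inst) / fs
    return np.where(voiced, np.sin(phase), 0.0)
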