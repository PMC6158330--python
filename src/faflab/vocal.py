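"""Vocal pitch-compensation measurement.

Turns voice fundamental-frequency (F0) data into per-subject compensation
magnitude, latency, and a baseline-variability index. The processing chain
mirrors standard frequency-altered-feedback (FAF) practice:

1. convert the F0 contour from Hz to cents relative to a fixed musical
   reference (195.997 Hz, the G3 note);
2. segment into epochs of -200 to +700 ms around each pitch-perturbation
   onset;
3. classify each trial as compensatory (opposing the perturbation),
   following (same direction), or bad (vocal interruptions / gross errors);
4. subtract the 200-ms pre-perturbation baseline mean from every trial;
5. average the compensatory trials and take the peak of the averaged
   contour as the response magnitude, its time as the latency;
6. take the across-trial SD of the per-trial baseline means as an index of
   the speaker's intrinsic voice variability.

All functions operate on plain numpy arrays; a vectorised batch entry point
(:func:`measure_trial_matrix`) processes every trial of a subject/condition
at once and is what the cohort-level drivers use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CentsReference",
    "F0Trace",
    "VocalEpoch",
    "AveragedVocalResponse",
    "VocalMeasureConfig",
    "hz_to_cents",
    "cents_to_hz",
    "estimate_f0",
    "segment_vocal_trials",
    "classify_trial",
    "baseline_normalize",
    "average_vocal_response",
    "measure_vocal_peak",
    "baseline_variability",
    "measure_trial_matrix",
]

#: default reference frequency for the cents scale: G3.
DEFAULT_REFERENCE_HZ = 195.997

# Epoch geometry (ms relative to perturbation onset). Half-open convention:
# baseline is [-200, 0), response is [0, 700).
EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 700.0


@dataclass(frozen=True)
class CentsReference:
    """Reference frequency for the cents conversion (default G3 = 195.997 Hz)."""

    reference_hz: float = DEFAULT_REFERENCE_HZ

    def __post_init__(self) -> None:
        if not self.reference_hz > 0:
            raise ValueError(f"reference_hz must be > 0, got {self.reference_hz}")


@dataclass
class F0Trace:
    """A sampled F0 contour for one vocalization.

    Parameters
    ----------
    times_s : array of strictly increasing sample times (s)
    values : F0 per frame; NaN marks unvoiced/missing frames
    unit : "hz" or "cents"
    fs_hz : frame rate (frames per second)
    """

    times_s: np.ndarray
    values: np.ndarray
    unit: str
    fs_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("hz", "cents"):
            raise ValueError(f"unit must be 'hz' or 'cents', got {self.unit!r}")
        if self.times_s.shape != self.values.shape:
            raise ValueError("times_s and values must have the same shape")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        voiced = self.values[np.isfinite(self.values)]
        if self.unit == "hz" and voiced.size and np.any(voiced <= 0):
            raise ValueError("F0 in Hz must be positive where voiced")

    def to_cents(self, ref: CentsReference | None = None) -> "F0Trace":
        if self.unit == "cents":
            return self
        ref = ref or CentsReference()
        return F0Trace(self.times_s, hz_to_cents(self.values, ref), "cents", self.fs_hz)


@dataclass
class VocalEpoch:
    """One trial's F0 segment aligned to perturbation onset.

    ``times_ms`` spans [-200, 700) ms; ``values_cents`` are raw until
    :func:`baseline_normalize` sets ``normalized``. ``label`` is one of
    "compensatory", "following", "bad" (set by :func:`classify_trial`) or
    None before classification.
    """

    trial_id: object
    times_ms: np.ndarray
    values_cents: np.ndarray
    baseline_mean_cents: float | None = None
    label: str | None = None
    reason: str | None = None
    normalized: bool = False


@dataclass
class AveragedVocalResponse:
    """Average compensatory response for one subject x condition."""

    times_ms: np.ndarray
    contour_cents: np.ndarray
    n_trials: int
    magnitude_cents: float = np.nan
    latency_ms: float = np.nan
    baseline_sd_cents: float = np.nan
    edge_peak: bool = False


@dataclass(frozen=True)
class VocalMeasureConfig:
    """Tunable rules of the vocal pipeline (defaults follow the study design)."""

    reference: CentsReference = field(default_factory=CentsReference)
    #: window whose mean sign decides compensatory vs following (ms)
    classify_window_ms: tuple[float, float] = (100.0, 500.0)
    #: peak search window on the averaged contour (ms)
    peak_window_ms: tuple[float, float] = (0.0, 700.0)
    #: fraction of missing frames above which a trial is bad
    max_missing_fraction: float = 0.20
    #: |value - baseline| beyond this marks a vocal interruption / gross error
    outlier_bound_cents: float = 600.0
    #: baseline-variability construct: across-trial SD of per-trial baseline
    #: means ("across_trials", default) or SD of the averaged contour's
    #: baseline samples ("averaged_contour")
    variability_mode: str = "across_trials"


# ---------------------------------------------------------------------------
# cents scale
# ---------------------------------------------------------------------------

def hz_to_cents(f0_hz, ref: CentsReference | None = None):
    """Convert frequency to cents: ``100 * 12 * log2(f0 / reference)``.

    100 cents is one semitone; the default reference is G3 (195.997 Hz).
    NaN passes through (unvoiced frames); non-positive finite values raise.
    """
    ref = ref or CentsReference()
    f0 = np.asarray(f0_hz, dtype=float)
    bad = np.isfinite(f0) & (f0 <= 0)
    if np.any(bad):
        raise ValueError("hz_to_cents requires positive frequencies")
    out = 1200.0 * np.log2(f0 / ref.reference_hz)
    return float(out) if np.isscalar(f0_hz) else out


def cents_to_hz(cents, ref: CentsReference | None = None):
    """Inverse of :func:`hz_to_cents`."""
    ref = ref or CentsReference()
    c = np.asarray(cents, dtype=float)
    out = ref.reference_hz * np.exp2(c / 1200.0)
    return float(out) if np.isscalar(cents) else out


# ---------------------------------------------------------------------------
# F0 estimation (autocorrelation, frame-based)
# ---------------------------------------------------------------------------

def estimate_f0(
    audio: np.ndarray,
    fs: float,
    frame_ms: float = 60.0,
    hop_ms: float = 10.0,
    f0_range_hz: tuple[float, float] = (75.0, 500.0),
    voicing_threshold: float = 0.5,
) -> F0Trace:
    """Per-frame autocorrelation F0 estimator for mono audio.

    Frames of ``frame_ms`` advance by ``hop_ms``; in each frame the highest
    normalised autocorrelation peak within the lag range implied by
    ``f0_range_hz`` gives the period. The three samples around the peak are
    corrected for the rectangular-window taper (divided by ``n - lag``)
    before parabolic refinement, which keeps pure-tone errors well under
    half a hertz in the speech range. Frames whose peak falls below
    ``voicing_threshold`` (or which are near silence) are marked unvoiced
    (NaN). Deterministic.
    """
    if fs < 8000:
        raise ValueError(f"sampling rate must be >= 8 kHz, got {fs}")
    lo, hi = f0_range_hz
    if not (50.0 <= lo < hi <= 600.0):
        raise ValueError(f"f0_range_hz must lie within [50, 600] Hz, got {f0_range_hz}")
    x = np.asarray(audio, dtype=float).ravel()
    frame = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    lag_min = int(np.floor(fs / hi))
    lag_max = int(np.ceil(fs / lo))
    if lag_max >= frame:
        raise ValueError("frame too short for the requested f0 range")

    n_frames = max(0, 1 + (x.size - frame) // hop)
    times = (np.arange(n_frames) * hop + frame / 2) / fs
    f0 = np.full(n_frames, np.nan)
    # silence floor relative to overall signal scale
    rms_all = np.sqrt(np.mean(x**2)) if x.size else 0.0
    if rms_all == 0.0:
        warnings.warn("all-silent input: F0 trace is all missing", stacklevel=2)
        return F0Trace(times, f0, "hz", 1000.0 / hop_ms)

    for i in range(n_frames):
        seg = x[i * hop : i * hop + frame]
        seg = seg - seg.mean()
        e0 = np.dot(seg, seg)
        if e0 < (1e-4 * rms_all) ** 2 * frame:
            continue
        ac = np.correlate(seg, seg, mode="full")[frame - 1 :]
        ac = ac / ac[0]
        sl = ac[lag_min : lag_max + 1]
        k = int(np.argmax(sl)) + lag_min
        if ac[k] < voicing_threshold:
            continue
        # taper-corrected parabolic refinement around the peak
        if 0 < k < ac.size - 1:
            y = ac[k - 1 : k + 2] / (frame - np.arange(k - 1, k + 2))
            denom = y[0] - 2 * y[1] + y[2]
            delta = 0.5 * (y[0] - y[2]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[i] = fs / (k + delta)
    if not np.any(np.isfinite(f0)):
        warnings.warn("no voiced frames detected", stacklevel=2)
    return F0Trace(times, f0, "hz", 1000.0 / hop_ms)


# ---------------------------------------------------------------------------
# segmentation / classification / normalisation
# ---------------------------------------------------------------------------

def _epoch_sample_counts(fs_hz: float) -> tuple[int, int]:
    """(baseline, response) frame counts for the [-200, 700) ms epoch."""
    n_base = int(round(-EPOCH_START_MS / 1000.0 * fs_hz))
    n_resp = int(round(EPOCH_STOP_MS / 1000.0 * fs_hz))
    return n_base, n_resp


def segment_vocal_trials(trace: F0Trace, events) -> list[VocalEpoch]:
    """Cut a cents-scale F0 trace into [-200, 700) ms epochs, one per event.

    ``events`` is an iterable of records with attributes/keys ``trial_id``
    and ``onset_s``. Epoch time zero sits on the first frame at/after the
    event onset. Events too close to the trace edge yield a "bad" epoch with
    an explanatory reason rather than raising.
    """
    if trace.unit != "cents":
        raise ValueError("segment_vocal_trials expects a cents-scale trace")
    fs = trace.fs_hz
    n_base, n_resp = _epoch_sample_counts(fs)
    rel_ms = (np.arange(-n_base, n_resp) / fs) * 1000.0
    epochs: list[VocalEpoch] = []
    for ev in events:
        tid = ev["trial_id"] if isinstance(ev, dict) else ev.trial_id
        onset = float(ev["onset_s"] if isinstance(ev, dict) else ev.onset_s)
        i0 = int(np.searchsorted(trace.times_s, onset - 1e-12))
        if i0 - n_base < 0:
            epochs.append(VocalEpoch(tid, rel_ms, np.full(rel_ms.size, np.nan),
                                     label="bad", reason="insufficient baseline"))
            continue
        if i0 + n_resp > trace.values.size:
            epochs.append(VocalEpoch(tid, rel_ms, np.full(rel_ms.size, np.nan),
                                     label="bad", reason="insufficient post-onset data"))
            continue
        vals = trace.values[i0 - n_base : i0 + n_resp].copy()
        epochs.append(VocalEpoch(tid, rel_ms, vals))
    return epochs


def classify_trial(
    epoch: VocalEpoch,
    perturbation_sign: float,
    config: VocalMeasureConfig | None = None,
) -> str:
    """Label an epoch compensatory / following / bad and store the label.

    The mean of the baseline-normalised values inside the classification
    window (default 100-500 ms) opposes the perturbation sign for a
    compensatory trial. Trials with too many missing frames or excursions
    beyond the outlier bound (vocal interruptions, tracking errors) are bad.
    """
    cfg = config or VocalMeasureConfig()
    if epoch.label == "bad":
        return "bad"
    vals = epoch.values_cents
    base_mask = epoch.times_ms < 0
    if epoch.normalized:
        base = 0.0
    else:
        bvals = vals[base_mask]
        bvals = bvals[np.isfinite(bvals)]
        if bvals.size == 0:
            epoch.label, epoch.reason = "bad", "empty baseline"
            return "bad"
        base = float(np.mean(bvals))
        epoch.baseline_mean_cents = base
    missing = np.mean(~np.isfinite(vals))
    if missing > cfg.max_missing_fraction:
        epoch.label, epoch.reason = "bad", f"missing frames {missing:.0%} > {cfg.max_missing_fraction:.0%}"
        return "bad"
    dev = np.abs(vals - base)
    if np.nanmax(dev) > cfg.outlier_bound_cents:
        epoch.label, epoch.reason = "bad", "excursion beyond outlier bound"
        return "bad"
    w0, w1 = cfg.classify_window_ms
    win = (epoch.times_ms >= w0) & (epoch.times_ms <= w1)
    m = np.nanmean(vals[win] - base)
    if m == 0:
        epoch.label, epoch.reason = "bad", "zero mean response"
        return "bad"
    epoch.label = "compensatory" if np.sign(m) == -np.sign(perturbation_sign) else "following"
    return epoch.label


def baseline_normalize(epoch: VocalEpoch) -> VocalEpoch:
    """Subtract the [-200, 0) ms baseline mean from the whole epoch."""
    if epoch.normalized:
        return epoch
    base_mask = epoch.times_ms < 0
    bvals = epoch.values_cents[base_mask]
    bvals = bvals[np.isfinite(bvals)]
    if bvals.size == 0:
        raise ValueError(f"trial {epoch.trial_id}: empty baseline, cannot normalize")
    base = float(np.mean(bvals))
    out = replace(epoch)
    out.values_cents = epoch.values_cents - base
    out.baseline_mean_cents = base
    out.normalized = True
    return out


def average_vocal_response(epochs: list[VocalEpoch]) -> AveragedVocalResponse:
    """Point-wise mean of baseline-normalised compensatory epochs.

    With zero usable epochs an explicit empty ("no-response") result is
    returned and a warning is issued; the caller flags the subject.
    """
    comp = [e for e in epochs if e.label == "compensatory"]
    if not comp:
        warnings.warn("no compensatory epochs: no-response result", stacklevel=2)
        return AveragedVocalResponse(np.array([]), np.array([]), 0)
    comp = [baseline_normalize(e) for e in comp]
    mat = np.vstack([e.values_cents for e in comp])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        contour = np.nanmean(mat, axis=0)
    return AveragedVocalResponse(comp[0].times_ms.copy(), contour, len(comp))


def measure_vocal_peak(
    avg: AveragedVocalResponse,
    search_window_ms: tuple[float, float] = (0.0, 700.0),
) -> tuple[float, float]:
    """Peak magnitude (max of the averaged contour) and its latency.

    Ties resolve to the earliest sample; a maximum on the window edge sets
    ``edge_peak`` on the result. Updates ``avg`` in place and returns
    ``(magnitude_cents, latency_ms)``.
    """
    if avg.n_trials == 0 or avg.contour_cents.size == 0:
        raise ValueError("cannot measure a peak of an empty averaged response")
    w0, w1 = search_window_ms
    mask = (avg.times_ms >= w0) & (avg.times_ms < w1)
    if not np.any(mask):
        raise ValueError(f"empty peak search window {search_window_ms}")
    idx = np.where(mask)[0]
    vals = avg.contour_cents[idx]
    k = int(np.nanargmax(vals))
    avg.magnitude_cents = float(vals[k])
    avg.latency_ms = float(avg.times_ms[idx[k]])
    avg.edge_peak = k in (0, vals.size - 1)
    if avg.edge_peak:
        warnings.warn("edge peak: contour maximum at the search-window boundary", stacklevel=2)
    return avg.magnitude_cents, avg.latency_ms


def baseline_variability(
    epochs: list[VocalEpoch],
    config: VocalMeasureConfig | None = None,
) -> float:
    """Across-trial SD (ddof=1) of per-trial baseline means, in cents.

    The index of the speaker's voice variability in the absence of
    perturbation. Uses all retained (non-bad) epochs. Fewer than two
    retained epochs yields NaN with a warning.
    """
    cfg = config or VocalMeasureConfig()
    good = [e for e in epochs if e.label in ("compensatory", "following")]
    if len(good) < 2:
        warnings.warn("fewer than 2 retained epochs: variability undefined", stacklevel=2)
        return float("nan")
    if cfg.variability_mode == "averaged_contour":
        avg = average_vocal_response(epochs)
        if avg.contour_cents.size == 0:
            return float("nan")
        base = avg.contour_cents[avg.times_ms < 0]
        return float(np.nanstd(base, ddof=1))
    means = []
    for e in good:
        if e.baseline_mean_cents is None:
            b = e.values_cents[e.times_ms < 0]
            b = b[np.isfinite(b)]
            e.baseline_mean_cents = float(np.mean(b))
        means.append(e.baseline_mean_cents)
    return float(np.std(means, ddof=1))


# ---------------------------------------------------------------------------
# vectorised batch measurement
# ---------------------------------------------------------------------------

def measure_trial_matrix(
    cents: np.ndarray,
    onset_idx: np.ndarray,
    fs_hz: float,
    perturbation_sign: float = -1.0,
    config: VocalMeasureConfig | None = None,
) -> dict:
    """Run the whole vocal chain on all trials of one subject x condition.

    Parameters
    ----------
    cents : (n_trials, n_samples) F0 traces in cents (NaN = unvoiced)
    onset_idx : per-trial perturbation-onset frame index
    fs_hz : frame rate
    perturbation_sign : sign of the pitch shift (-1 for downward)

    Returns a dict with keys ``n_compensatory``, ``n_following``, ``n_bad``,
    ``magnitude_cents``, ``latency_ms``, ``baseline_sd_cents``, ``contour``
    (baseline-normalised average), ``times_ms``, ``labels``. Implements the
    same rules as the per-epoch functions, vectorised.
    """
    cfg = config or VocalMeasureConfig()
    cents = np.asarray(cents, dtype=float)
    onset_idx = np.asarray(onset_idx, dtype=int)
    n_trials, n_samp = cents.shape
    n_base, n_resp = _epoch_sample_counts(fs_hz)
    if np.any(onset_idx - n_base < 0) or np.any(onset_idx + n_resp > n_samp):
        raise ValueError("perturbation onset too close to the trace edge")
    cols = np.arange(-n_base, n_resp)
    ep = cents[np.arange(n_trials)[:, None], onset_idx[:, None] + cols]  # (n, T)
    times_ms = cols / fs_hz * 1000.0

    base_mask = times_ms < 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(ep[:, base_mask], axis=1)
    norm = ep - base[:, None]

    missing = np.mean(~np.isfinite(ep), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        excursion = np.nanmax(np.abs(norm), axis=1)
    bad = (missing > cfg.max_missing_fraction) | (excursion > cfg.outlier_bound_cents) | ~np.isfinite(base)

    w0, w1 = cfg.classify_window_ms
    cwin = (times_ms >= w0) & (times_ms <= w1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        resp_mean = np.nanmean(norm[:, cwin], axis=1)
    comp = ~bad & (np.sign(resp_mean) == -np.sign(perturbation_sign)) & (resp_mean != 0)
    follow = ~bad & ~comp

    labels = np.where(bad, "bad", np.where(comp, "compensatory", "following"))
    out = {
        "n_compensatory": int(comp.sum()),
        "n_following": int(follow.sum()),
        "n_bad": int(bad.sum()),
        "labels": labels,
        "times_ms": times_ms,
    }
    retained = ~bad
    if retained.sum() >= 2:
        out["baseline_sd_cents"] = float(np.std(base[retained], ddof=1))
    else:
        out["baseline_sd_cents"] = float("nan")
    if comp.sum() >= 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            contour = np.nanmean(norm[comp], axis=0)
        out["contour"] = contour
        pw0, pw1 = cfg.peak_window_ms
        pmask = (times_ms >= pw0) & (times_ms < pw1)
        pidx = np.where(pmask)[0]
        k = int(np.nanargmax(contour[pidx]))
        out["magnitude_cents"] = float(contour[pidx[k]])
        out["latency_ms"] = float(times_ms[pidx[k]])
        out["edge_peak"] = bool(k in (0, pidx.size - 1))
    else:
        out.update(contour=None, magnitude_cents=float("nan"),
                   latency_ms=float("nan"), edge_peak=False)
    return out
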