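"""ERP analysis: filtering, epoching, QC, re-referencing, N1/P2 measurement.

The chain follows standard auditory-feedback ERP practice: 1-20 Hz zero
phase band-pass on the continuous record, segmentation into [-200, 500) ms
epochs around perturbation onset, moving-average artifact detection
(+/-55 uV from the 80-ms local mean), rejection of channels bad in more
than 20% of epochs, exclusion of subjects with more than 10 bad channels,
re-referencing of retained epochs to the mastoid average, baseline-corrected
averaging, and extraction of the N1 (most negative sample, 80-160 ms) and
P2 (most positive sample, 180-280 ms) peaks at ten fronto-central sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .montage import MASTOIDS, MEASUREMENT_ELECTRODES

__all__ = [
    "QCParams",
    "ComponentWindows",
    "QCReport",
    "EEGEpochSet",
    "bandpass_filter",
    "segment_eeg",
    "detect_artifact",
    "artifact_flags",
    "apply_rejection_rules",
    "rereference_mastoids",
    "average_erp",
    "measure_erp_peaks",
]

EPOCH_START_MS = -200.0
EPOCH_STOP_MS = 500.0


@dataclass(frozen=True)
class QCParams:
    """Artifact / channel / subject rejection thresholds."""

    artifact_threshold_uv: float = 55.0
    moving_window_ms: float = 80.0
    max_bad_epoch_fraction: float = 0.20
    max_bad_channels: int = 10
    #: moving-average alignment: "centered" (default) or "trailing"
    window_alignment: str = "centered"

    def __post_init__(self) -> None:
        for name in ("artifact_threshold_uv", "moving_window_ms",
                     "max_bad_epoch_fraction", "max_bad_channels"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ComponentWindows:
    """Search windows (ms) and measurement sites for the N1/P2 complex."""

    n1_ms: tuple[float, float] = (80.0, 160.0)
    p2_ms: tuple[float, float] = (180.0, 280.0)
    electrodes: tuple[str, ...] = tuple(MEASUREMENT_ELECTRODES)


@dataclass
class QCReport:
    """Counts and reasons produced by :func:`apply_rejection_rules`."""

    n_epochs: int = 0
    n_channels: int = 0
    flagged_pairs: int = 0
    bad_channels: list = field(default_factory=list)
    n_epochs_dropped: int = 0
    n_epochs_retained: int = 0
    subject_excluded: bool = False
    reason: str | None = None


@dataclass
class EEGEpochSet:
    """Trial x channel x time voltages (uV) aligned to perturbation onset.

    ``data`` has shape (n_epochs, n_channels, n_times) spanning
    [-200, 500) ms; ``reference`` transitions "vertex" -> "mastoid-average"
    exactly once via :func:`rereference_mastoids`. QC state (artifact flags
    per epoch x channel, bad-channel list, retained-epoch mask, subject
    exclusion) is set only by the QC operations.
    """

    data: np.ndarray
    fs_hz: float
    ch_names: list[str]
    reference: str = "vertex"
    flags: np.ndarray | None = None            # (n_epochs, n_channels) bool
    bad_channels: list[str] = field(default_factory=list)
    retained: np.ndarray | None = None         # (n_epochs,) bool
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count does not match ch_names")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        n_expect = int(round((EPOCH_STOP_MS - EPOCH_START_MS) / 1000.0 * self.fs_hz))
        if self.data.shape[2] != n_expect:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != expected {n_expect} samples "
                f"for [-200, 500) ms at {self.fs_hz} Hz")

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        n_base = int(round(-EPOCH_START_MS / 1000.0 * self.fs_hz))
        return (np.arange(n) - n_base) / self.fs_hz * 1000.0


# ---------------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, fs_hz: float, low_hz: float = 1.0,
                    high_hz: float = 20.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward application (``sosfiltfilt``) of an ``order``-th order
    Butterworth; output length equals input length.
    """
    if fs_hz <= 2 * high_hz:
        raise ValueError(f"sampling rate {fs_hz} Hz too low for a {high_hz} Hz band edge")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def segment_eeg(recording: np.ndarray, fs_hz: float, ch_names: list[str],
                event_samples) -> tuple[EEGEpochSet, list]:
    """Cut a continuous (n_channels, n_times) record into [-200, 500) ms epochs.

    Epoch time zero is the event sample. Events whose window would leave
    the recording are dropped; the returned list gives (event, reason) for
    each drop.
    """
    rec = np.asarray(recording, dtype=float)
    n_base = int(round(-EPOCH_START_MS / 1000.0 * fs_hz))
    n_post = int(round(EPOCH_STOP_MS / 1000.0 * fs_hz))
    epochs, dropped = [], []
    for s in event_samples:
        s = int(s)
        if s - n_base < 0:
            dropped.append((s, "insufficient pre-stimulus data"))
        elif s + n_post > rec.shape[1]:
            dropped.append((s, "insufficient post-stimulus data"))
        else:
            epochs.append(rec[:, s - n_base : s + n_post])
    data = np.stack(epochs) if epochs else np.empty((0, rec.shape[0], n_base + n_post))
    return EEGEpochSet(data, fs_hz, list(ch_names)), dropped


def _moving_average(trace: np.ndarray, fs_hz: float, window_ms: float,
                    alignment: str = "centered") -> np.ndarray:
    win = max(1, int(round(window_ms / 1000.0 * fs_hz)))
    if alignment == "centered":
        return uniform_filter1d(trace, size=win, axis=-1, mode="reflect")
    if alignment == "trailing":
        return uniform_filter1d(trace, size=win, axis=-1, mode="reflect",
                                origin=(win - 1) // 2)
    raise ValueError(f"unknown window alignment {alignment!r}")


def detect_artifact(trace: np.ndarray, fs_hz: float,
                    qc: QCParams | None = None) -> bool:
    """True iff any sample deviates more than +/-55 uV from the 80-ms moving
    average (reflect-padded at the edges)."""
    qc = qc or QCParams()
    trace = np.asarray(trace, dtype=float)
    ma = _moving_average(trace, fs_hz, qc.moving_window_ms, qc.window_alignment)
    return bool(np.any(np.abs(trace - ma) > qc.artifact_threshold_uv))


def artifact_flags(epochs: EEGEpochSet, qc: QCParams | None = None) -> np.ndarray:
    """Apply the moving-average rule to every (epoch, channel) trace.

    Stores and returns a boolean (n_epochs, n_channels) flag array.
    """
    qc = qc or QCParams()
    ma = _moving_average(epochs.data, epochs.fs_hz, qc.moving_window_ms,
                         qc.window_alignment)
    flags = np.any(np.abs(epochs.data - ma) > qc.artifact_threshold_uv, axis=-1)
    epochs.flags = flags
    return flags


def apply_rejection_rules(epochs: EEGEpochSet,
                          qc: QCParams | None = None) -> QCReport:
    """Channel, epoch and subject rejection from the artifact flags.

    A channel is bad if flagged in more than ``max_bad_epoch_fraction`` of
    epochs (strictly more than 20% by default); a subject is excluded if
    strictly more than ``max_bad_channels`` channels are bad; epochs flagged
    on any retained channel are dropped from averaging. Exclusion is a
    reported state, not an exception.
    """
    qc = qc or QCParams()
    if epochs.flags is None:
        artifact_flags(epochs, qc)
    flags = epochs.flags
    n_ep, n_ch = flags.shape
    frac = flags.mean(axis=0)
    bad_ch = [epochs.ch_names[i] for i in range(n_ch) if frac[i] > qc.max_bad_epoch_fraction]
    epochs.bad_channels = bad_ch
    report = QCReport(n_epochs=n_ep, n_channels=n_ch,
                      flagged_pairs=int(flags.sum()), bad_channels=bad_ch)
    if len(bad_ch) > qc.max_bad_channels:
        epochs.excluded = True
        epochs.exclusion_reason = f"bad channels > {qc.max_bad_channels} ({len(bad_ch)})"
        epochs.retained = np.zeros(n_ep, dtype=bool)
        report.subject_excluded = True
        report.reason = epochs.exclusion_reason
        report.n_epochs_dropped = n_ep
        return report
    keep_ch = np.array([name not in bad_ch for name in epochs.ch_names])
    retained = ~np.any(flags[:, keep_ch], axis=1)
    epochs.retained = retained
    report.n_epochs_retained = int(retained.sum())
    report.n_epochs_dropped = int(n_ep - retained.sum())
    return report


def pooled_rejection_rules(epoch_sets: list[EEGEpochSet],
                           qc: QCParams | None = None) -> QCReport:
    """Channel/subject rules over conditions pooled within one recording.

    Channel badness and subject exclusion are judged on all of a subject's
    epochs together (the recording is one file); epoch retention is then
    applied within each condition's epoch set. Same thresholds and boundary
    semantics as :func:`apply_rejection_rules`.
    """
    qc = qc or QCParams()
    for es in epoch_sets:
        if es.flags is None:
            artifact_flags(es, qc)
        if es.ch_names != epoch_sets[0].ch_names:
            raise ValueError("pooled QC requires identical montages")
    flags = np.concatenate([es.flags for es in epoch_sets], axis=0)
    n_ep, n_ch = flags.shape
    ch_names = epoch_sets[0].ch_names
    frac = flags.mean(axis=0)
    bad_ch = [ch_names[i] for i in range(n_ch) if frac[i] > qc.max_bad_epoch_fraction]
    report = QCReport(n_epochs=n_ep, n_channels=n_ch,
                      flagged_pairs=int(flags.sum()), bad_channels=bad_ch)
    excluded = len(bad_ch) > qc.max_bad_channels
    keep_ch = np.array([name not in bad_ch for name in ch_names])
    for es in epoch_sets:
        es.bad_channels = bad_ch
        if excluded:
            es.excluded = True
            es.exclusion_reason = f"bad channels > {qc.max_bad_channels} ({len(bad_ch)})"
            es.retained = np.zeros(es.data.shape[0], dtype=bool)
        else:
            es.retained = ~np.any(es.flags[:, keep_ch], axis=1)
    report.subject_excluded = excluded
    if excluded:
        report.reason = epoch_sets[0].exclusion_reason
        report.n_epochs_dropped = n_ep
    else:
        report.n_epochs_retained = int(sum(es.retained.sum() for es in epoch_sets))
        report.n_epochs_dropped = n_ep - report.n_epochs_retained
    return report


def rereference_mastoids(epochs: EEGEpochSet,
                         mastoid_labels: tuple[str, str] = tuple(MASTOIDS)) -> EEGEpochSet:
    """Subtract the mastoid average from every channel (vertex -> mastoid ref)."""
    if epochs.reference != "vertex":
        raise ValueError(f"re-reference requires vertex-referenced data, got {epochs.reference!r}")
    idx = []
    for lab in mastoid_labels:
        if lab not in epochs.ch_names:
            raise ValueError(f"mastoid channel {lab!r} not in montage")
        idx.append(epochs.ch_names.index(lab))
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    epochs.data = epochs.data - ref
    epochs.reference = "mastoid-average"
    return epochs


def average_erp(epochs: EEGEpochSet) -> np.ndarray:
    """Mean over retained epochs, baseline-corrected over [-200, 0) ms.

    Returns a (n_channels, n_times) waveform; raises if the subject is
    excluded or no epoch survives QC.
    """
    if epochs.excluded:
        raise ValueError(f"subject excluded: {epochs.exclusion_reason}")
    mask = epochs.retained if epochs.retained is not None else np.ones(epochs.data.shape[0], bool)
    if mask.sum() == 0:
        raise ValueError("no retained epochs to average")
    erp = epochs.data[mask].mean(axis=0)
    base = erp[:, epochs.times_ms < 0].mean(axis=1, keepdims=True)
    return erp - base


def measure_erp_peaks(erp: np.ndarray, times_ms: np.ndarray, ch_names: list[str],
                      windows: ComponentWindows | None = None) -> dict:
    """N1 (minimum) and P2 (maximum) amplitude/latency per electrode.

    Extreme-sample definition with earliest-sample tie-breaking. Returns
    ``{electrode: {"n1_amp_uv", "n1_lat_ms", "p2_amp_uv", "p2_lat_ms"}}``.
    """
    win = windows or ComponentWindows()
    out = {}
    for lab in win.electrodes:
        if lab not in ch_names:
            raise ValueError(f"electrode {lab!r} not present in the data")
        tr = erp[ch_names.index(lab)]
        m1 = (times_ms >= win.n1_ms[0]) & (times_ms <= win.n1_ms[1])
        m2 = (times_ms >= win.p2_ms[0]) & (times_ms <= win.p2_ms[1])
        i1 = np.where(m1)[0]
        i2 = np.where(m2)[0]
        k1 = i1[int(np.argmin(tr[i1]))]
        k2 = i2[int(np.argmax(tr[i2]))]
        out[lab] = {
            "n1_amp_uv": float(tr[k1]), "n1_lat_ms": float(times_ms[k1]),
            "p2_amp_uv": float(tr[k2]), "p2_lat_ms": float(times_ms[k2]),
        }
    return out
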