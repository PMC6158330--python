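"""File formats: delimited text tables, the EEG fixture format, WAV, EDF.

Delimited text is tab-separated with a mandatory header; readers validate
the schema and name the missing column in errors. EEG epochs travel as a
little-endian float32 binary matrix (epoch x channel x time, C order) with
a JSON sidecar describing the sampling rate, channel labels, epoch window
and shape. EDF recordings are read through mne when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EEGEpochSet
from .vocal import F0Trace

__all__ = [
    "read_table", "write_table",
    "read_f0_trace", "write_f0_trace",
    "read_events", "write_events",
    "read_genotypes", "write_genotypes",
    "read_eeg_fixture", "write_eeg_fixture",
    "read_wav", "read_edf",
    "write_cohort", "read_cohort",
]

GENOTYPES = ("AA", "AG", "GG")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r} "
                             f"(found {list(df.columns)})")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, path)
    return df


# -- F0 traces --------------------------------------------------------------

def write_f0_trace(trace: F0Trace, path) -> Path:
    if trace.unit != "hz":
        raise ValueError("F0 trace files store Hz; convert before writing")
    return write_table(pd.DataFrame({"time_s": trace.times_s,
                                     "f0_hz": trace.values}), path)


def read_f0_trace(path, fs_hz: float | None = None) -> F0Trace:
    df = read_table(path, required=("time_s", "f0_hz"))
    t = df["time_s"].to_numpy(float)
    if fs_hz is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer frame rate from {t.size} frames")
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return F0Trace(t, df["f0_hz"].to_numpy(float), "hz", fs_hz)


# -- events -----------------------------------------------------------------

EVENT_COLUMNS = ("trial_id", "onset_s", "magnitude_cents", "duration_ms")


def write_events(events: pd.DataFrame, path) -> Path:
    _require_columns(events, EVENT_COLUMNS, "events table")
    return write_table(events[list(EVENT_COLUMNS)], path)


def read_events(path) -> pd.DataFrame:
    return read_table(path, required=EVENT_COLUMNS)


# -- genotypes --------------------------------------------------------------

def write_genotypes(genotypes: pd.DataFrame, path) -> Path:
    _require_columns(genotypes, ("subject_id", "genotype"), "genotype table")
    return write_table(genotypes, path)


def read_genotypes(path) -> pd.DataFrame:
    df = read_table(path, required=("subject_id", "genotype"))
    bad = sorted(set(df["genotype"]) - set(GENOTYPES))
    if bad:
        raise ValueError(f"{path}: invalid genotype values {bad}; expected {GENOTYPES}")
    return df


# -- EEG fixture format -----------------------------------------------------

def write_eeg_fixture(epochs: EEGEpochSet, path_prefix) -> tuple[Path, Path]:
    """Write epochs as <prefix>.f32 (binary) + <prefix>.json (sidecar)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bin_path = prefix.with_suffix(".f32")
    meta_path = prefix.with_suffix(".json")
    data = epochs.data.astype("<f4")
    data.tofile(bin_path)
    meta = {
        "fs_hz": epochs.fs_hz,
        "ch_names": list(epochs.ch_names),
        "window_ms": [-200.0, 500.0],
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "unit": "uV",
        "reference": epochs.reference,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return bin_path, meta_path


def read_eeg_fixture(path_prefix) -> EEGEpochSet:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    for key in ("fs_hz", "ch_names", "shape", "dtype"):
        if key not in meta:
            raise ValueError(f"{prefix}.json: missing sidecar field {key!r}")
    data = np.fromfile(prefix.with_suffix(".f32"), dtype=meta["dtype"])
    data = data.reshape(meta["shape"]).astype(float)
    return EEGEpochSet(data, meta["fs_hz"], list(meta["ch_names"]),
                       reference=meta.get("reference", "vertex"))


# -- audio / EDF ------------------------------------------------------------

def read_wav(path) -> tuple[float, np.ndarray]:
    """Mono waveform as float in [-1, 1] plus its sampling rate.

    PCM integer formats are rescaled by their full-scale value; multichannel
    files are averaged to mono.
    """
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return float(fs), data


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Continuous EDF recording as (channels x samples in uV, fs, labels).

    Requires mne; header scaling is applied by the reader (mne returns
    volts, converted here to microvolts).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


# -- cohort directory layout ------------------------------------------------

def write_cohort(dataset, out_dir, include_eeg: bool = False) -> Path:
    """Write a simulated cohort to a directory.

    Layout: ``ground_truth.tsv`` and ``genotypes.tsv`` at the root; per
    subject a directory with, per perturbation magnitude, the F0 trial
    matrix (``f0_m<mag>.tsv``: time_s column then one column per trial),
    the event table, and (optionally) the EEG fixture pair.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.ground_truth(), out / "ground_truth.tsv")
    write_genotypes(dataset.genotype_table(), out / "genotypes.tsv")
    fs = dataset.spec.vocal_fs_hz
    for s in dataset.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        for m in dataset.spec.magnitudes_cents:
            tag = f"m{int(abs(m))}"
            block = dataset.vocal[(s.subject_id, m)]
            n, T = block["f0_hz"].shape
            cols = {"time_s": np.arange(T) / fs}
            for i in range(n):
                cols[f"trial_{i:03d}"] = block["f0_hz"][i]
            write_table(pd.DataFrame(cols), sdir / f"f0_{tag}.tsv")
            write_events(dataset.events(s.subject_id, m), sdir / f"events_{tag}.tsv")
            if include_eeg:
                epochs, truth = dataset.eeg_epochs(s.subject_id, m)
                write_eeg_fixture(epochs, sdir / f"eeg_{tag}")
                np.savetxt(sdir / f"eeg_{tag}_artifact_truth.tsv",
                           truth.astype(int), fmt="%d", delimiter="\t")
    return out


def read_cohort(in_dir, include_eeg: bool = False) -> dict:
    """Read a cohort directory back into trial matrices and tables."""
    root = Path(in_dir)
    truth = read_table(root / "ground_truth.tsv",
                       required=("subject_id", "magnitude_cents_shift"))
    genotypes = read_genotypes(root / "genotypes.tsv")
    vocal, eeg = {}, {}
    for sid in sorted(genotypes["subject_id"]):
        sdir = root / sid
        for f0_file in sorted(sdir.glob("f0_m*.tsv")):
            tag = f0_file.stem.split("_")[1]          # e.g. "m200"
            events = read_events(sdir / f"events_{tag}.tsv")
            mag = float(events["magnitude_cents"].iloc[0])
            df = read_table(f0_file, required=("time_s",))
            trial_cols = [c for c in df.columns if c.startswith("trial_")]
            t = df["time_s"].to_numpy(float)
            fs = 1.0 / float(np.median(np.diff(t)))
            mat = df[trial_cols].to_numpy(float).T
            onset_idx = np.searchsorted(t, events["onset_s"].to_numpy(float) - 1e-12)
            vocal[(sid, mag)] = {"f0_hz": mat, "onset_idx": onset_idx,
                                 "fs_hz": fs, "events": events}
            if include_eeg and (sdir / f"eeg_{tag}.json").exists():
                eeg[(sid, mag)] = read_eeg_fixture(sdir / f"eeg_{tag}")
    return {"truth": truth, "genotypes": genotypes, "vocal": vocal, "eeg": eeg}
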