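"""End-to-end orchestration: cohort -> vocal -> EEG -> statistics -> report.

`run_all` drives the whole analysis from a single :class:`RunConfig`:
simulate (or load) a cohort, measure per-subject vocal compensation, run
EEG QC and N1/P2 measurement, then the statistical battery, writing
delimited result tables, a JSON results manifest with per-stage counts and
output checksums. Deterministic given the seed; every rejection is logged
with the rule that fired.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .eeg import (ComponentWindows, QCParams, average_erp, measure_erp_peaks,
                  pooled_rejection_rules, rereference_mastoids)
from .simulate import CohortDataset, CohortSpec, EffectParams, simulate_cohort
from .stats import replicate_study_analyses
from .vocal import CentsReference, VocalMeasureConfig, hz_to_cents, measure_trial_matrix

logger = logging.getLogger("faflab")

__all__ = ["RunConfig", "RunManifest", "run_all",
           "vocal_summary", "erp_summary"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    vocal: VocalMeasureConfig = field(default_factory=VocalMeasureConfig)
    qc: QCParams = field(default_factory=QCParams)
    windows: ComponentWindows = field(default_factory=ComponentWindows)
    include_eeg: bool = True
    alpha: float = 0.05
    out_dir: str = "faflab_out"
    input_dir: str | None = None        # load a cohort instead of simulating

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples/dataclass nesting to plain structures handled by asdict;
        # make dict keys YAML-safe (floats stay floats)
        return json.loads(json.dumps(d, default=list), parse_float=float)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _floatkeys(m):
            return {float(k): v for k, v in m.items()}

        c = dict(d.get("cohort", {}))
        if "effects" in c:
            e = dict(c["effects"])
            for key in ("comp_gain_mean_cents", "n1_amp_mean_uv", "p2_amp_mean_uv"):
                if key in e:
                    e[key] = _floatkeys(e[key])
            c["effects"] = EffectParams(**e)
        for key in ("magnitudes_cents", "perturbation_onset_range_ms", "eeg_channels"):
            if key in c:
                c[key] = tuple(c[key])
        v = dict(d.get("vocal", {}))
        if "reference" in v:
            v["reference"] = CentsReference(**v["reference"])
        for key in ("classify_window_ms", "peak_window_ms"):
            if key in v:
                v[key] = tuple(v[key])
        w = dict(d.get("windows", {}))
        for key in ("n1_ms", "p2_ms", "electrodes"):
            if key in w:
                w[key] = tuple(w[key])
        return cls(cohort=CohortSpec(**c), vocal=VocalMeasureConfig(**v),
                   qc=QCParams(**d.get("qc", {})), windows=ComponentWindows(**w),
                   include_eeg=d.get("include_eeg", True),
                   alpha=d.get("alpha", 0.05),
                   out_dir=d.get("out_dir", "faflab_out"),
                   input_dir=d.get("input_dir"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Reproducibility record: config, versions, counts, exclusions, hashes."""

    config: dict
    version: str
    counts: dict
    exclusions: list
    checksums: dict

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                   default=str))
        return path


# ---------------------------------------------------------------------------
# stage drivers
# ---------------------------------------------------------------------------

def vocal_summary(dataset: CohortDataset,
                  config: VocalMeasureConfig | None = None) -> pd.DataFrame:
    """Per subject x magnitude vocal measurements (whole vocal chain)."""
    cfg = config or VocalMeasureConfig()
    rows = []
    for s in dataset.subjects:
        for m in dataset.spec.magnitudes_cents:
            block = dataset.vocal[(s.subject_id, m)]
            cents = hz_to_cents(block["f0_hz"], cfg.reference)
            res = measure_trial_matrix(cents, block["onset_idx"],
                                       dataset.spec.vocal_fs_hz,
                                       perturbation_sign=np.sign(m), config=cfg)
            rows.append(dict(
                subject_id=s.subject_id, genotype=s.genotype,
                magnitude_cents_shift=m,
                n_trials=block["f0_hz"].shape[0],
                n_compensatory=res["n_compensatory"],
                n_following=res["n_following"], n_bad=res["n_bad"],
                magnitude_cents=res["magnitude_cents"],
                latency_ms=res["latency_ms"],
                baseline_sd_cents=res["baseline_sd_cents"],
                edge_peak=res.get("edge_peak", False)))
    return pd.DataFrame(rows)


def erp_summary(dataset: CohortDataset, qc: QCParams | None = None,
                windows: ComponentWindows | None = None) -> tuple[pd.DataFrame, list]:
    """Per subject x magnitude x electrode N1/P2 measurements plus exclusions.

    EEG epochs are generated per subject (lazily), artifact-flagged, and the
    channel/subject rules are applied across the subject's pooled conditions
    before mastoid re-referencing, averaging and peak measurement.
    """
    qc = qc or QCParams()
    win = windows or ComponentWindows()
    rows, exclusions = [], []
    for s in dataset.subjects:
        sets = {m: dataset.eeg_epochs(s.subject_id, m)[0]
                for m in dataset.spec.magnitudes_cents}
        report = pooled_rejection_rules(list(sets.values()), qc)
        if report.subject_excluded:
            exclusions.append((s.subject_id, report.reason))
            logger.info("subject %s excluded: %s", s.subject_id, report.reason)
            continue
        for m, es in sets.items():
            if es.retained.sum() == 0:
                exclusions.append((s.subject_id, f"no retained epochs at {m}"))
                continue
            rereference_mastoids(es)
            erp = average_erp(es)
            peaks = measure_erp_peaks(erp, es.times_ms, es.ch_names, win)
            for lab, p in peaks.items():
                rows.append(dict(subject_id=s.subject_id, genotype=s.genotype,
                                 magnitude_cents_shift=m, electrode=lab,
                                 n_retained=int(es.retained.sum()), **p))
    return pd.DataFrame(rows), exclusions


# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig | None = None) -> RunManifest:
    """Simulate (or load) -> vocal -> EEG -> stats -> report.

    Writes the summary tables, ANOVA/post-hoc/correlation tables, a JSON
    results manifest; returns the :class:`RunManifest`. Idempotent given
    the seed.
    """
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.input_dir:
        raise NotImplementedError(
            "loading a recorded cohort directory into run_all: use the "
            "stage drivers (io.read_cohort + vocal/erp summaries) directly")
    logger.info("simulating cohort (seed %s)", cfg.cohort.seed)
    dataset = simulate_cohort(cfg.cohort)
    n_subj = len(dataset.subjects)

    vs = vocal_summary(dataset, cfg.vocal)
    fio.write_table(vs, out / "vocal_summary.tsv")

    exclusions: list = []
    es = None
    if cfg.include_eeg:
        es, exclusions = erp_summary(dataset, cfg.qc, cfg.windows)
        fio.write_table(es, out / "erp_summary.tsv")
        excluded_ids = {sid for sid, _ in exclusions}
        vs_stats = vs[~vs["subject_id"].isin(excluded_ids)]
    else:
        vs_stats = vs

    results = replicate_study_analyses(vs_stats, es, dataset.genotype_table(),
                                       alpha=cfg.alpha)
    tables = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            tables[name] = fio.write_table(obj, out / f"{name}.tsv")
    cor_rows = []
    for key in ("compensation_vs_variability", "compensation_vs_variability_by_shift"):
        for k, c in results.get(key, {}).items():
            label = k if isinstance(k, str) else f"{k[0]}@{k[1]:g}"
            cor_rows.append(dict(scope=key, group=label, r=c.r, n=c.n, p=c.p))
    if cor_rows:
        tables["correlations"] = fio.write_table(pd.DataFrame(cor_rows),
                                                 out / "correlations.tsv")
    hwe_path = out / "hwe.json"
    hwe_path.write_text(json.dumps(results["hwe"], indent=1))

    from . import __version__
    counts = {
        "n_subjects": n_subj,
        "n_subjects_excluded_eeg": len({sid for sid, _ in exclusions}),
        "n_subjects_entering_stats": int(vs_stats["subject_id"].nunique()),
        "vocal_trials_total": int(vs["n_trials"].sum()),
        "vocal_trials_compensatory": int(vs["n_compensatory"].sum()),
        "vocal_trials_following": int(vs["n_following"].sum()),
        "vocal_trials_bad": int(vs["n_bad"].sum()),
    }
    if es is not None and len(es):
        per_cond = es.drop_duplicates(["subject_id", "magnitude_cents_shift"])
        counts["eeg_epochs_retained"] = int(per_cond["n_retained"].sum())
    assert (counts["vocal_trials_compensatory"] + counts["vocal_trials_following"]
            + counts["vocal_trials_bad"]) == counts["vocal_trials_total"], \
        "trial counts do not reconcile"

    files = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}
    files["hwe.json"] = _sha256(hwe_path)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__,
                           counts=counts,
                           exclusions=[list(e) for e in exclusions],
                           checksums=files)
    manifest.to_json(out / "manifest.json")
    return manifest
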