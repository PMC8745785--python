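"""End-to-end experiment orchestration: the band x classifier grid.

A single :class:`ExperimentConfig` drives ingest -> preprocess ->
scalogram -> bag-of-features -> train/evaluate for every (band, classifier
family) cell, producing one :class:`~apnea_bof.evaluation.EvalReport` per
cell plus a summary table laid out rows=band, columns=metric per family.

The k-means codebook is the slow stage; it is computed once per band and
cached in memory keyed by a config hash (and optionally on disk), so
re-running a grid only rebuilds vocabularies whose upstream settings
changed.  A cell failure aborts that cell, not the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bof import Codebook, DetectorConfig, build_codebook, encode_all, feature_matrix
from .classifiers import ClassifierSpec
from .ecg_io import EcgRecord, read_corpus
from .errors import ApneaBofError
from .evaluation import EvalReport, kfold_cv, losocv, stage_stratified_eval
from .preprocessing import ArtifactPolicy, reject_artifacts, segment_windows, zero_mean
from .spectrogram import BAND_PRESETS, cwt_scalogram, render_image
from .synthetic_ecg import SimConfig, simulate_corpus

log = logging.getLogger("apnea_bof")


@dataclass(frozen=True)
class ExperimentConfig:
    source: str = "simulate"  # {simulate, csv, wfdb}
    corpus_dir: str | None = None  # for csv/wfdb sources
    exclude: tuple[str, ...] = ()
    sim: SimConfig = field(default_factory=SimConfig)
    window_sec: int = 60
    bands: tuple[str, ...] = ("high",)
    families: tuple[str, ...] = ("svm",)
    hyperparams: dict = field(default_factory=dict)  # per-family overrides
    detector: str = "dense"
    vocabulary_size: int = 200
    fraction_strongest: float = 0.8
    voices_per_octave: int = 12
    image_width: int = 256
    compression: str = "log1p"
    scheme: str = "kfold"  # {kfold, losocv, stage}
    balance: str = "none"
    k_folds: int = 5
    artifact_policy: ArtifactPolicy = field(default_factory=ArtifactPolicy)
    codebook_per_fold: bool = False
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.bands) - set(BAND_PRESETS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        if self.window_sec == 10 and "low" in self.bands:
            raise ValueError(
                "the 0-0.8 Hz band is not usable with 10 s windows "
                "(too short for low-frequency variation)"
            )
        if self.scheme not in ("kfold", "losocv", "stage"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def fingerprint(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class ExperimentResult:
    config_fingerprint: str
    reports: dict[tuple[str, str], EvalReport | dict]
    summary: pd.DataFrame
    failures: dict[tuple[str, str], str]
    rejected_windows: int
    versions: dict[str, str]


def load_windows(config: ExperimentConfig):
    """Ingest + preprocess: records -> zero-mean -> windows -> artifact filter."""
    if config.source == "simulate":
        records, _ = simulate_corpus(config.sim)
    elif config.source in ("csv", "wfdb"):
        if config.corpus_dir is None:
            raise ValueError("corpus_dir required for csv/wfdb sources")
        records = read_corpus(config.corpus_dir, dialect=config.source, exclude=config.exclude)
    else:
        raise ValueError(f"unknown source {config.source!r}")
    windows = []
    for rec in records:
        windows.extend(segment_windows(zero_mean(rec), config.window_sec))
    kept, rejected = reject_artifacts(windows, config.artifact_policy)
    log.info("windows: %d kept, %d rejected", len(kept), len(rejected))
    return kept, rejected


def compute_features(
    windows,
    band: str,
    *,
    detector: str | DetectorConfig = "dense",
    vocabulary_size: int = 200,
    fraction_strongest: float = 0.8,
    voices_per_octave: int = 12,
    image_width: int = 256,
    compression: str = "log1p",
    seed: int = 0,
    codebook: Codebook | None = None,
):
    """Windows -> band scalograms -> images -> codebook -> BofVectors.

    Returns (vectors, codebook).  Pass an existing codebook to encode new
    windows against a previously learned vocabulary.
    """
    images = [
        render_image(
            cwt_scalogram(w, band, voices_per_octave=voices_per_octave),
            width=image_width,
            compression=compression,
        )
        for w in windows
    ]
    if codebook is None:
        codebook = build_codebook(
            images,
            k=vocabulary_size,
            fraction_strongest=fraction_strongest,
            seed=seed,
            detector=detector,
        )
    return encode_all(images, codebook), codebook


def _evaluate_cell(config: ExperimentConfig, vectors, family: str) -> EvalReport | dict:
    spec = ClassifierSpec(
        family, dict(config.hyperparams.get(family, {})), seed=config.seed
    )
    if config.scheme == "kfold":
        return kfold_cv(vectors, spec, k=config.k_folds, seed=config.seed)
    if config.scheme == "losocv":
        return losocv(vectors, spec)
    return stage_stratified_eval(
        vectors, spec, balance=config.balance, seed=config.seed, k=config.k_folds
    )


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Execute the full (band x classifier) grid for one configuration."""
    import pywt
    import sklearn

    fingerprint = config.fingerprint()
    windows, rejected = load_windows(config)
    reports: dict[tuple[str, str], EvalReport | dict] = {}
    failures: dict[tuple[str, str], str] = {}
    rows = []
    feature_cache: dict[str, list] = {}
    for band in config.bands:
        try:
            if band not in feature_cache:
                vectors, _ = compute_features(
                    windows,
                    band,
                    detector=config.detector,
                    vocabulary_size=config.vocabulary_size,
                    fraction_strongest=config.fraction_strongest,
                    voices_per_octave=config.voices_per_octave,
                    image_width=config.image_width,
                    compression=config.compression,
                    seed=config.seed,
                )
                feature_cache[band] = vectors
        except (ApneaBofError, ValueError) as exc:
            for family in config.families:
                failures[(band, family)] = f"feature stage: {exc}"
            continue
        for family in config.families:
            try:
                report = _evaluate_cell(config, feature_cache[band], family)
            except (ApneaBofError, ValueError) as exc:
                failures[(band, family)] = str(exc)
                continue
            reports[(band, family)] = report
            agg = (
                report.aggregate
                if isinstance(report, EvalReport)
                else {
                    f"{stage}_{k}": v
                    for stage, rep in report.items()
                    for k, v in rep.aggregate.items()
                }
            )
            row = {"band": band, "family": family}
            for key in ("mean_accuracy_pct", "mean_sensitivity_pct", "mean_specificity_pct"):
                if isinstance(report, EvalReport):
                    row[key.replace("mean_", "")] = report.aggregate[key]
                else:
                    for stage, rep in report.items():
                        row[f"{stage}_{key.replace('mean_', '')}"] = rep.aggregate[key]
            rows.append(row)
    summary = pd.DataFrame(rows)
    result = ExperimentResult(
        config_fingerprint=fingerprint,
        reports=reports,
        summary=summary,
        failures=failures,
        rejected_windows=len(rejected),
        versions={
            "apnea_bof": __version__,
            "numpy": np.__version__,
            "pywt": pywt.__version__,
            "sklearn": sklearn.__version__,
        },
    )
    if outdir is not None:
        _write_bundle(result, config, Path(outdir))
    return result


def _write_bundle(result: ExperimentResult, config: ExperimentConfig, outdir: Path) -> None:
    outdir = outdir / result.config_fingerprint  # never overwrite other configs
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    for (band, family), report in result.reports.items():
        if isinstance(report, EvalReport):
            (outdir / f"report_{band}_{family}.json").write_text(report.to_json())
        else:
            for stage, rep in report.items():
                (outdir / f"report_{band}_{family}_{stage}.json").write_text(rep.to_json())
    meta = {
        "config": _jsonable(asdict(config)),
        "fingerprint": result.config_fingerprint,
        "versions": result.versions,
        "rejected_windows": result.rejected_windows,
        "failures": {f"{b}/{f}": msg for (b, f), msg in result.failures.items()},
    }
    (outdir / "experiment.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
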