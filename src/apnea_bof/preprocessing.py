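"""Zero-mean, fixed-length windowing, and artifact-contaminated window removal.

The detection method operates on the raw zero-meaned trace: no baseline
filtering, QRS detection, or R-peak correction is applied.  The mean is
removed at the record level (windows inherit the centred signal and are not
re-centred, so concatenating windows reproduces the record exactly).

The source databases removed "contaminated" windows without stating
criteria; here contamination is three explicit, configurable tests applied
in order — amplitude clipping, flatline runs, and in-band power ratio — and
a rejected window carries the first criterion it violated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .ecg_io import EcgRecord
from .errors import EmptySignalError, UnsupportedDurationError

SUPPORTED_DURATIONS = (10, 60)


@dataclass
class EcgWindow:
    """One fixed-length labeled ECG segment (the ``x(t)`` fed to the CWT)."""

    record_id: str
    start_sec: float
    duration_sec: int
    samples: np.ndarray
    fs: float
    label: str  # {N, A}
    stage: str = "UNKNOWN"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = int(round(self.duration_sec * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"window needs {expected} samples "
                f"({self.duration_sec} s at {self.fs} Hz), got {len(self.samples)}"
            )


@dataclass(frozen=True)
class ArtifactPolicy:
    """Thresholds defining a contaminated window.

    ``max_abs_mv``: amplitude clipping bound (mV).
    ``max_flatline_sec``: longest tolerated near-constant run (s), at
    ``flat_tol_mv`` amplitude tolerance (default 1 µV).
    ``min_band_power_ratio``: minimum fraction of spectral power that must
    lie in the 0.5–40 Hz ECG band.
    """

    max_abs_mv: float = 5.0
    max_flatline_sec: float = 1.0
    min_band_power_ratio: float = 0.5
    flat_tol_mv: float = 1e-3

    def __post_init__(self):
        if min(self.max_abs_mv, self.max_flatline_sec, self.min_band_power_ratio) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_band_power_ratio >= 1:
            raise ValueError("min_band_power_ratio must be < 1")


@dataclass(frozen=True)
class RejectedWindow:
    window: EcgWindow
    reason: str  # first violated criterion


def zero_mean(record: EcgRecord) -> EcgRecord:
    """Subtract the signal mean, eliminating trend/DC offset effects."""
    if len(record.samples) == 0:
        raise EmptySignalError(f"record {record.record_id} has no samples")
    return replace(record, samples=record.samples - record.samples.mean())


def segment_windows(record: EcgRecord, duration_sec: int = 60) -> list[EcgWindow]:
    """Cut a record into consecutive non-overlapping labeled windows.

    60 s windows take the minute label directly; 10 s windows inherit their
    parent minute's label (the native annotation granularity is one minute).
    """
    if duration_sec not in SUPPORTED_DURATIONS:
        raise UnsupportedDurationError(
            f"duration_sec must be one of {SUPPORTED_DURATIONS}, got {duration_sec}"
        )
    spw = int(round(duration_sec * record.fs))
    per_minute = 60 // duration_sec
    windows = []
    for minute, label in enumerate(record.labels):
        stage = record.stage_of_minute(minute)
        for j in range(per_minute):
            start = minute * 60 + j * duration_sec
            i0 = int(round(start * record.fs))
            seg = record.samples[i0 : i0 + spw]
            if len(seg) < spw:
                break  # trailing partial window: dropped
            windows.append(
                EcgWindow(
                    record_id=record.record_id,
                    start_sec=float(start),
                    duration_sec=duration_sec,
                    samples=seg.copy(),
                    fs=record.fs,
                    label=label,
                    stage=stage,
                )
            )
    return windows


def _longest_flat_run(x: np.ndarray, tol: float) -> int:
    """Length in samples of the longest near-constant run."""
    flat = np.abs(np.diff(x)) <= tol
    if not flat.any():
        return 1
    # runs of True in `flat`; a run of k flat diffs spans k+1 samples
    edges = np.diff(flat.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if flat[0]:
        starts = np.r_[0, starts]
    if flat[-1]:
        ends = np.r_[ends, len(flat)]
    return int((ends - starts).max()) + 1


def _band_power_ratio(x: np.ndarray, fs: float, f_lo: float = 0.5, f_hi: float = 40.0) -> float:
    freqs, psd = sps.welch(x, fs=fs, nperseg=min(len(x), 1024))
    total = psd.sum()
    if total <= 0:
        return 0.0
    in_band = psd[(freqs >= f_lo) & (freqs <= f_hi)].sum()
    return float(in_band / total)


def reject_artifacts(
    windows: list[EcgWindow], policy: ArtifactPolicy | None = None
) -> tuple[list[EcgWindow], list[RejectedWindow]]:
    """Partition windows into kept and rejected-with-reason.

    Criteria are tested in a fixed order (clipping, flatline, band power)
    and the first violation is reported.  ``kept + rejected`` is always a
    partition of the input; an empty kept list is legal.
    """
    policy = policy or ArtifactPolicy()
    kept: list[EcgWindow] = []
    rejected: list[RejectedWindow] = []
    for w in windows:
        if np.abs(w.samples).max(initial=0.0) > policy.max_abs_mv:
            rejected.append(RejectedWindow(w, "clipping"))
        elif (
            _longest_flat_run(w.samples, policy.flat_tol_mv)
            > policy.max_flatline_sec * w.fs
        ):
            rejected.append(RejectedWindow(w, "flatline"))
        elif _band_power_ratio(w.samples, w.fs) < policy.min_band_power_ratio:
            rejected.append(RejectedWindow(w, "band_power"))
        else:
            kept.append(w)
    return kept, rejected
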