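"""Readers/writers for annotated single-lead ECG records and AHI-based grouping.

Two on-disk dialects are supported:

* ``wfdb`` — the PhysioNet layout: a ``.hea`` header, a format-16 ``.dat``
  signal file, and an MIT-format annotation stream (default extension
  ``.apn``) carrying one annotation per minute.  Only the single-signal,
  format-16 subset needed for nocturnal apnea ECG records is implemented.
* ``csv`` — a plain-text dialect: two columns ``t_sec,mv`` plus a sidecar
  ``<record>.labels`` file with one row per minute, ``N`` or ``A``,
  optionally followed by a sleep stage (``REM``/``NREM``).

Per-minute labels follow the Apnea-ECG convention: minute ``i`` covers
samples ``[i*60*fs, (i+1)*60*fs)``; a trailing partial minute of signal is
dropped.  Any non-normal apnea-family annotation symbol maps to ``A``
(apnea and hypopnea are merged into a single disordered-breathing class).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import AlignmentError, FormatError, InsufficientMetadataError

LABEL_NORMAL = "N"
LABEL_APNEA = "A"
STAGES = ("REM", "NREM", "UNKNOWN")

# MIT annotation code for a normal label; every other non-control code is
# treated as a member of the apnea/disordered-breathing family.
_ANN_NORMAL = 1
_ANN_APNEA = 8
_ANN_SKIP, _ANN_NUM, _ANN_SUB, _ANN_CHN, _ANN_AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True)
class RecordMeta:
    """Subject-level metadata; ``ahi`` in events/hour drives group assignment."""

    ahi: float | None = None
    age: float | None = None
    weight: float | None = None
    sex: str = "unknown"

    def __post_init__(self):
        if self.ahi is not None and self.ahi < 0:
            raise ValueError(f"ahi must be >= 0, got {self.ahi}")


@dataclass
class EcgRecord:
    """A subject's continuous single-lead ECG with per-minute apnea labels."""

    record_id: str
    samples: np.ndarray  # voltage, mV
    fs: float  # Hz
    labels: list[str]  # one of {N, A} per full minute
    stage_labels: list[str] | None = None  # {REM, NREM, UNKNOWN} per minute
    meta: RecordMeta = field(default_factory=RecordMeta)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        bad = set(self.labels) - {LABEL_NORMAL, LABEL_APNEA}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.stage_labels is not None:
            if len(self.stage_labels) != len(self.labels):
                raise ValueError("stage_labels must match labels in length")
            bad = set(self.stage_labels) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")

    @property
    def n_minutes(self) -> int:
        return len(self.labels)

    @property
    def duration_sec(self) -> float:
        return len(self.samples) / self.fs

    def stage_of_minute(self, minute: int) -> str:
        if self.stage_labels is None:
            return "UNKNOWN"
        return self.stage_labels[minute]


@dataclass(frozen=True)
class DatasetGroup:
    """A named subset of record ids selected by a human-readable AHI rule."""

    name: str
    record_ids: tuple[str, ...]
    criterion: str

    def __post_init__(self):
        if len(set(self.record_ids)) != len(self.record_ids):
            raise ValueError("record_ids must be unique")


@dataclass(frozen=True)
class GroupRule:
    """A closed predicate on :class:`RecordMeta` with a display name."""

    name: str
    predicate: Callable[[RecordMeta], bool]
    criterion: str = ""


# ---------------------------------------------------------------------------
# WFDB dialect (minimal: single signal, format 16)
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea_path}: record line needs name/nsig/fs/nsamples")
    name = head[0].split("/")[0]
    try:
        nsig = int(head[1])
        fs = float(head[2].split("/")[0])
        nsamp = int(head[3])
    except ValueError as exc:
        raise FormatError(f"{hea_path}: garbled record line: {exc}") from exc
    if nsig != 1:
        raise FormatError(f"{hea_path}: only single-signal records supported (nsig={nsig})")
    if len(lines) < 2:
        raise FormatError(f"{hea_path}: missing signal specification line")
    sig = lines[1].split()
    try:
        dat_name = sig[0]
        fmt = int(sig[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = sig[2] if len(sig) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain = float(gain_str[: gain_str.index("(")])
            baseline = int(gain_str[gain_str.index("(") + 1 : gain_str.index(")")])
        else:
            gain = float(gain_str)
            baseline = int(sig[4]) if len(sig) > 4 else 0  # adc zero
        if gain == 0:
            gain = 200.0
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{hea_path}: garbled signal line: {exc}") from exc
    if fmt != 16:
        raise FormatError(f"{hea_path}: only format 16 supported, got {fmt}")
    return name, fs, nsamp, dat_name, gain, baseline


def _read_annotations(ann_path: Path) -> list[tuple[int, int]]:
    """Return (sample_time, code) pairs from an MIT-format annotation file."""
    data = ann_path.read_bytes()
    out: list[tuple[int, int]] = []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _ANN_SKIP:
            if i + 3 >= n:
                raise FormatError(f"{ann_path}: truncated SKIP pseudo-annotation")
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            t += (hi << 16) | lo
        elif code == _ANN_AUX:
            i += delta + (delta & 1)  # aux string, padded to even length
        elif code in (_ANN_NUM, _ANN_SUB, _ANN_CHN):
            continue
        else:
            t += delta
            out.append((t, code))
    return out


def _write_annotations(ann_path: Path, events: Sequence[tuple[int, int]]) -> None:
    buf = bytearray()
    prev = 0
    for t, code in events:
        delta = t - prev
        if delta > 0x3FF:
            buf += struct.pack("<H", _ANN_SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = t
    buf += struct.pack("<H", 0)
    ann_path.write_bytes(bytes(buf))


def _labels_from_annotations(
    anns: list[tuple[int, int]], fs: float, n_sig_minutes: int, path: Path
) -> list[str]:
    spm = int(round(60 * fs))
    per_minute: dict[int, str] = {}
    for t, code in anns:
        minute = t // spm
        per_minute[minute] = LABEL_NORMAL if code == _ANN_NORMAL else LABEL_APNEA
    if not per_minute:
        raise AlignmentError(f"{path}: annotation stream contains no labels")
    n_labeled = max(per_minute) + 1
    deficit = n_sig_minutes - n_labeled
    if deficit > 1:
        raise AlignmentError(
            f"{path}: label stream shorter than signal by {deficit} minutes"
        )
    n_minutes = min(n_labeled, n_sig_minutes)
    # Un-annotated interior minutes default to N (absent marks are rare and
    # the databases annotate every minute; a gap is not an alignment fault).
    return [per_minute.get(i, LABEL_NORMAL) for i in range(n_minutes)]


# ---------------------------------------------------------------------------
# Public reading / writing
# ---------------------------------------------------------------------------


def read_record(
    path: str | Path,
    dialect: str = "wfdb",
    *,
    annotation_ext: str = "apn",
    meta: RecordMeta | None = None,
) -> EcgRecord:
    """Read one ECG record with per-minute labels.

    ``path`` names the record stem (``.hea``/``.csv`` suffix optional).
    Label ``i`` covers samples ``[i*60*fs, (i+1)*60*fs)``; signal beyond the
    last labeled minute (a trailing partial minute, or one trailing
    unlabeled full minute) is discarded.
    """
    path = Path(path)
    if dialect == "wfdb":
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        if not hea.exists():
            raise FormatError(f"missing header file {hea}")
        name, fs, nsamp, dat_name, gain, baseline = _parse_header(hea)
        dat = hea.parent / dat_name
        if not dat.exists():
            raise FormatError(f"missing signal file {dat}")
        raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
        if nsamp and len(raw) < nsamp:
            raise FormatError(
                f"{dat}: header declares {nsamp} samples, file holds {len(raw)}"
            )
        raw = raw[:nsamp] if nsamp else raw
        samples = (raw.astype(np.float64) - baseline) / gain
        ann = hea.with_suffix(f".{annotation_ext}")
        if not ann.exists():
            raise FormatError(f"missing annotation stream {ann}")
        spm = int(round(60 * fs))
        labels = _labels_from_annotations(
            _read_annotations(ann), fs, len(samples) // spm, ann
        )
        stage_labels = None
    elif dialect == "csv":
        csv = path if path.suffix == ".csv" else path.with_suffix(".csv")
        if not csv.exists():
            raise FormatError(f"missing CSV file {csv}")
        name = csv.stem
        try:
            arr = np.loadtxt(csv, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{csv}: cannot parse t_sec,mv columns: {exc}") from exc
        if arr.shape[1] != 2 or arr.shape[0] < 2:
            raise FormatError(f"{csv}: expected >=2 rows of t_sec,mv")
        t, samples = arr[:, 0], arr[:, 1]
        fs = float(np.round((len(t) - 1) / (t[-1] - t[0]), 6))
        sidecar = csv.with_suffix(".labels")
        if not sidecar.exists():
            raise FormatError(f"missing sidecar label file {sidecar}")
        labels, stage_labels = [], []
        for row in sidecar.read_text().splitlines():
            row = row.strip()
            if not row:
                continue
            parts = [p.strip() for p in row.split(",")]
            lab = parts[0] if parts[0] == LABEL_NORMAL else LABEL_APNEA
            labels.append(lab)
            stage_labels.append(parts[1] if len(parts) > 1 else "UNKNOWN")
        if all(s == "UNKNOWN" for s in stage_labels):
            stage_labels = None
        spm = int(round(60 * fs))
        n_sig_minutes = len(samples) // spm
        deficit = n_sig_minutes - len(labels)
        if deficit > 1:
            raise AlignmentError(
                f"{sidecar}: label stream shorter than signal by {deficit} minutes"
            )
        if len(labels) > n_sig_minutes:
            labels = labels[:n_sig_minutes]
            if stage_labels is not None:
                stage_labels = stage_labels[:n_sig_minutes]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    spm = int(round(60 * fs))
    samples = np.asarray(samples, dtype=np.float64)[: len(labels) * spm]
    return EcgRecord(
        record_id=name,
        samples=samples,
        fs=fs,
        labels=list(labels),
        stage_labels=stage_labels,
        meta=meta or RecordMeta(),
    )


def write_record(
    record: EcgRecord,
    path: str | Path,
    dialect: str = "csv",
    *,
    annotation_ext: str = "apn",
    gain: float = 200.0,
) -> Path:
    """Write a record in the given dialect; returns the primary file path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spm = int(round(60 * record.fs))
    if dialect == "csv":
        csv = path if path.suffix == ".csv" else path.with_suffix(".csv")
        t = np.arange(len(record.samples)) / record.fs
        with open(csv, "w") as fh:
            fh.write("t_sec,mv\n")
            for ti, vi in zip(t, record.samples):
                fh.write(f"{ti:.6f},{vi:.6f}\n")
        with open(csv.with_suffix(".labels"), "w") as fh:
            for i, lab in enumerate(record.labels):
                stage = record.stage_of_minute(i)
                fh.write(f"{lab},{stage}\n" if stage != "UNKNOWN" else f"{lab}\n")
        return csv
    if dialect == "wfdb":
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        raw = np.round(record.samples * gain).astype("<i2")
        hea.write_text(
            f"{record.record_id} 1 {record.fs:g} {len(raw)}\n"
            f"{hea.stem}.dat 16 {gain:g} 16 0 {int(raw[0]) if len(raw) else 0} 0 0 ECG\n"
        )
        (hea.parent / f"{hea.stem}.dat").write_bytes(raw.tobytes())
        events = [
            (i * spm, _ANN_NORMAL if lab == LABEL_NORMAL else _ANN_APNEA)
            for i, lab in enumerate(record.labels)
        ]
        _write_annotations(hea.with_suffix(f".{annotation_ext}"), events)
        return hea
    raise ValueError(f"unknown dialect {dialect!r}")


def read_corpus(
    directory: str | Path,
    dialect: str = "csv",
    *,
    exclude: Iterable[str] = (),
    metadata: dict[str, RecordMeta] | None = None,
) -> list[EcgRecord]:
    """Read every record in a directory, honouring an exclusion list.

    Exclusions (e.g. the conventional ``b05``/``c05`` drops) are a
    configuration concern, never hard-coded.
    """
    directory = Path(directory)
    ext = ".csv" if dialect == "csv" else ".hea"
    excl = set(exclude)
    records = []
    for f in sorted(directory.glob(f"*{ext}")):
        if f.stem in excl:
            continue
        meta = (metadata or {}).get(f.stem)
        records.append(read_record(f, dialect=dialect, meta=meta))
    return records


# ---------------------------------------------------------------------------
# AHI-based grouping
# ---------------------------------------------------------------------------


def group_records(
    metadata: Sequence[tuple[str, RecordMeta]],
    rules: Sequence[GroupRule],
) -> list[DatasetGroup]:
    """Assign records to named groups by AHI predicates.

    A record may satisfy several rules (the whole-corpus group overlaps the
    severity groups).  A predicate that cannot be evaluated because metadata
    is missing raises :class:`InsufficientMetadataError` listing the ids.
    """
    groups = []
    for rule in rules:
        ids, missing = [], []
        for rec_id, meta in metadata:
            try:
                ok = bool(rule.predicate(meta))
            except TypeError:
                missing.append(rec_id)
                continue
            if ok:
                ids.append(rec_id)
        if missing:
            raise InsufficientMetadataError(rule.name, missing)
        groups.append(
            DatasetGroup(name=rule.name, record_ids=tuple(ids), criterion=rule.criterion)
        )
    return groups


def ahi_rule(name: str, lo: float | None = None, hi: float | None = None) -> GroupRule:
    """Convenience rule ``lo < AHI <= hi`` (either bound optional)."""

    def pred(meta: RecordMeta) -> bool:
        ahi = meta.ahi
        if lo is not None and not ahi > lo:
            return False
        if hi is not None and not ahi <= hi:
            return False
        return ahi is not None or lo is None and hi is None

    lo_s = f"{lo} < " if lo is not None else ""
    hi_s = f" <= {hi}" if hi is not None else ""
    return GroupRule(name=name, predicate=pred, criterion=f"{lo_s}AHI{hi_s}" or "all")
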