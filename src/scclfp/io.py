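"""Reading and writing of LFP recordings (EDF+) and sidecar tables.

Signals travel as EDF+ (16-bit European Data Format) files, one per
patient, with channels named after the DBS lead contacts ``L1..L4`` /
``R1..R4`` (ventral to dorsal within each hemisphere).  Three plain CSV
sidecars drive the analysis:

``artifacts.csv``
    ``channel,start_s,end_s`` — manually annotated artifact intervals,
    seconds from recording start, half-open ``[start, end)``.  A channel
    of ``all`` applies to every channel.
``cycles.csv``
    ``patient_id,stim_contact,hemisphere,role,stim_on_s,stim_off_s`` —
    one row per stimulation cycle (1 min pre, 3 min stimulation, 1 min
    post); ``role`` is ``effective``, ``ineffective`` or ``sham``.
``clinical.csv``
    ``patient_id,baseline_hdrs17,month6_hdrs17,weekly_hdrs17,
    time_to_stable_weeks`` — HDRS-17 depression scores; the weekly
    series is optional and semicolon-joined; time-to-stable may be
    given directly (in weeks) or derived from the weekly series.

Writing EDF is implemented here directly (a compact EDF+C encoder);
reading goes through MNE, so a write/read roundtrip crosses two
independent codebases.
"""

from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateCycleError,
    EmptyRecordingError,
    FormatError,
    SchemaError,
)

CONTACTS = ("L1", "L2", "L3", "L4", "R1", "R2", "R3", "R4")

_LABEL_RE = re.compile(r"([LR])\s*-?\s*([1-4])", re.IGNORECASE)


def normalize_label(label: str) -> str:
    """Canonicalize a channel label to ``L1..R4`` when recognizable.

    Matching is case-insensitive and tolerant of prefixes/separators
    (``"EEG l2"`` -> ``"L2"``).  Unrecognized labels are returned
    verbatim (stripped).
    """
    m = _LABEL_RE.search(label)
    if m:
        return f"{m.group(1).upper()}{m.group(2)}"
    return label.strip()


def _canonical_order(labels: list[str]) -> list[int]:
    """Row permutation putting recognized contacts in L1..R4 order."""
    def key(i: int) -> tuple:
        lab = labels[i]
        if lab in CONTACTS:
            return (0, CONTACTS.index(lab))
        return (1, i)

    return sorted(range(len(labels)), key=key)


@dataclass
class LfpRecording:
    """Multi-channel referential LFP signal matrix in microvolts.

    ``samples`` has shape ``(n_channels, n_times)``; ``start_time`` is
    the offset in seconds of the first sample (0 at record start).
    """

    patient_id: str
    channel_labels: list[str]
    rate_hz: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.rate_hz

    def get(self, label: str) -> np.ndarray:
        """Return the sample vector for one channel label."""
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r} in recording") from None


@dataclass(frozen=True)
class ArtifactAnnotation:
    """One annotated artifact interval ``[start_s, end_s)`` on a channel.

    ``channel`` is a contact label or ``"all"`` (applies everywhere).
    """

    channel: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise SchemaError(
                f"invalid artifact interval [{self.start_s}, {self.end_s})"
            )


@dataclass(frozen=True)
class CycleMetadata:
    """One stimulation cycle: contact, retrospective role, on/off times."""

    patient_id: str
    stim_contact: str
    hemisphere: str
    role: str
    stim_on_s: float
    stim_off_s: float

    def __post_init__(self) -> None:
        if self.stim_contact not in CONTACTS:
            raise SchemaError(f"unknown contact {self.stim_contact!r}")
        if self.hemisphere not in ("L", "R"):
            raise SchemaError(f"unknown hemisphere {self.hemisphere!r}")
        if self.hemisphere != self.stim_contact[0]:
            raise SchemaError("hemisphere does not match stim_contact")
        if self.role not in ("effective", "ineffective", "sham"):
            raise SchemaError(f"unknown role {self.role!r}")
        if self.stim_on_s < 0 or self.stim_off_s <= self.stim_on_s:
            raise SchemaError("require 0 <= stim_on_s < stim_off_s")


# ---------------------------------------------------------------------
# EDF+ writing (compact EDF+C encoder, 16-bit samples)
# ---------------------------------------------------------------------

_ANNOT_BYTES = 60  # per-record TAL payload for the annotations channel


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: LfpRecording, path) -> Path:
    """Write a recording to an EDF+C file (16-bit, 1-second records).

    Each channel is scaled to its own symmetric physical range, so the
    roundtrip error is at most one 16-bit quantization step per channel.
    Non-integer sampling rates are not representable with 1-second
    records and raise ``ValueError``; partial trailing seconds are
    zero-padded (the synthetic generator always emits whole seconds).
    """
    path = Path(path)
    x = recording.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    rate = recording.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_ch, n_t = x.shape
    n_rec = int(np.ceil(n_t / spr)) if n_t else 0

    # Per-channel symmetric physical range; the ASCII header fields are
    # authoritative for scaling, so parse back exactly what is written.
    pmax_str, gains = [], []
    for ch in range(n_ch):
        a = float(np.max(np.abs(x[ch]))) if n_t else 0.0
        a = max(a, 1e-6) * (1 + 1e-6)
        for prec in (6, 5, 4, 3, 2):  # "-" + value must fit 8 ASCII chars
            s = f"{a:.{prec}g}"
            if len(s) <= 7:
                break
        pmax_str.append(s)
        # EDF convention: physical = (d - dig_min) * (pmax - pmin) /
        # (dig_max - dig_min) + pmin; digitize with the exact inverse
        gains.append(65535.0 / (2.0 * float(s)))

    ns = n_ch + 1  # + EDF Annotations channel
    header = bytearray()
    header += _ascii("0", 8)
    pid = recording.patient_id or "X"
    header += _ascii(f"{pid} X X X"[:80], 80)
    header += _ascii(f"Startdate 01-JAN-2000 X X X"[:80], 80)
    dt = datetime.datetime(2000, 1, 1)
    header += _ascii(dt.strftime("%d.%m.%y"), 8)
    header += _ascii(dt.strftime("%H.%M.%S"), 8)
    header += _ascii(256 * (ns + 1), 8)
    header += _ascii("EDF+C", 44)
    header += _ascii(n_rec, 8)
    header += _ascii(1, 8)  # record duration, seconds
    header += _ascii(ns, 4)

    labels = list(recording.channel_labels) + ["EDF Annotations"]
    for lab in labels:
        header += _ascii(lab[:16], 16)
    for _ in labels:
        header += _ascii("", 80)  # transducer
    for i in range(ns):
        header += _ascii("uV" if i < n_ch else "", 8)
    for i in range(ns):
        header += _ascii(f"-{pmax_str[i]}"[:8] if i < n_ch else -1, 8)
    for i in range(ns):
        header += _ascii(pmax_str[i] if i < n_ch else 1, 8)
    for i in range(ns):
        header += _ascii(-32768, 8)
    for i in range(ns):
        header += _ascii(32767, 8)
    for _ in labels:
        header += _ascii("", 80)  # prefiltering
    for i in range(ns):
        header += _ascii(spr if i < n_ch else _ANNOT_BYTES // 2, 8)
    for _ in labels:
        header += _ascii("", 32)

    # Digitize all channels once, zero-padding the trailing record.
    dig = np.zeros((n_ch, n_rec * spr), dtype="<i2")
    for ch in range(n_ch):
        a = float(pmax_str[ch])
        d = np.rint((x[ch] + a) * gains[ch] - 32768.0)
        dig[ch, :n_t] = np.clip(d, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            block = dig[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            fh.write(tal.ljust(_ANNOT_BYTES, b"\x00"))
    return path


def read_edf(path, patient_id: str | None = None) -> LfpRecording:
    """Read an EDF/EDF+ file into an :class:`LfpRecording` (microvolts).

    Channel labels are canonicalized to ``L1..R4`` where recognizable
    (case-insensitive) and recognized channels are reordered ventral to
    dorsal, left before right; unrecognized labels are kept verbatim in
    their original order after the recognized ones.  Mixed per-channel
    rates are resampled by MNE to a common rate on read.

    ``patient_id`` defaults to the file stem.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on bad files
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # volts -> microvolts
    if data.shape[0] == 0:
        raise EmptyRecordingError(f"no signal channels in {path}")

    labels = [normalize_label(ch) for ch in raw.ch_names]
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels after normalization: {labels}")
    order = _canonical_order(labels)
    return LfpRecording(
        patient_id=patient_id if patient_id is not None else path.stem,
        channel_labels=[labels[i] for i in order],
        rate_hz=float(raw.info["sfreq"]),
        samples=data[order],
        start_time=0.0,
    )


# ---------------------------------------------------------------------
# Sidecar tables
# ---------------------------------------------------------------------


def merge_annotations(
    annotations: list[ArtifactAnnotation],
) -> list[ArtifactAnnotation]:
    """Union overlapping/abutting intervals per channel (idempotent,
    order-independent)."""
    out: list[ArtifactAnnotation] = []
    by_channel: dict[str, list[ArtifactAnnotation]] = {}
    for a in annotations:
        by_channel.setdefault(a.channel, []).append(a)
    for channel in sorted(by_channel):
        ivs = sorted((a.start_s, a.end_s) for a in by_channel[channel])
        merged: list[list[float]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend(ArtifactAnnotation(channel, s, e) for s, e in merged)
    return out


def read_artifact_table(path) -> list[ArtifactAnnotation]:
    """Read ``artifacts.csv``; rows are validated and overlapping
    intervals on one channel merged."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"channel", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise SchemaError(f"artifact table needs columns {sorted(required)}")
    anns = []
    for row in df.itertuples(index=False):
        channel = str(row.channel).strip()
        if channel != "all":
            channel = normalize_label(channel)
        try:
            s, e = float(row.start_s), float(row.end_s)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric artifact times in row {row}") from exc
        anns.append(ArtifactAnnotation(channel, s, e))
    return merge_annotations(anns)


def read_artifact_table_by_patient(path) -> dict[str, list[ArtifactAnnotation]]:
    """Read ``artifacts.csv`` grouped by its optional ``patient_id``
    column (cohort datasets).  Without that column every annotation is
    filed under the wildcard key ``"*"`` (single-recording datasets)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        return {"*": read_artifact_table(path)}
    out: dict[str, list[ArtifactAnnotation]] = {}
    for pid, group in df.groupby("patient_id"):
        anns = []
        for row in group.itertuples(index=False):
            channel = str(row.channel).strip()
            if channel != "all":
                channel = normalize_label(channel)
            anns.append(ArtifactAnnotation(channel, float(row.start_s), float(row.end_s)))
        out[str(pid)] = merge_annotations(anns)
    return out


def read_cycle_table(path) -> list[CycleMetadata]:
    """Read ``cycles.csv`` into validated :class:`CycleMetadata` rows."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {
        "patient_id", "stim_contact", "hemisphere", "role",
        "stim_on_s", "stim_off_s",
    }
    if not required.issubset(df.columns):
        raise SchemaError(f"cycle table needs columns {sorted(required)}")
    cycles, seen = [], set()
    for row in df.itertuples(index=False):
        c = CycleMetadata(
            patient_id=str(row.patient_id),
            stim_contact=normalize_label(str(row.stim_contact)),
            hemisphere=str(row.hemisphere).strip().upper(),
            role=str(row.role).strip().lower(),
            stim_on_s=float(row.stim_on_s),
            stim_off_s=float(row.stim_off_s),
        )
        key = (c.patient_id, c.stim_contact)
        if key in seen:
            raise DuplicateCycleError(f"duplicate cycle for {key}")
        seen.add(key)
        cycles.append(c)
    return cycles


@dataclass
class ClinicalRecord:
    """One patient's HDRS-17 clinical row as read from ``clinical.csv``.

    ``weekly_hdrs17`` maps week number -> score when the optional weekly
    series is present; ``time_to_stable_weeks`` is None when it can
    neither be read nor derived.
    """

    patient_id: str
    baseline_hdrs17: float
    month6_hdrs17: float
    weekly_hdrs17: dict[int, float] | None = None
    time_to_stable_weeks: float | None = None


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read ``clinical.csv``; weekly series and time-to-stable optional."""
    df = pd.read_csv(path, dtype={"patient_id": str, "weekly_hdrs17": str})
    required = {"patient_id", "baseline_hdrs17", "month6_hdrs17"}
    if not required.issubset(df.columns):
        raise SchemaError(f"clinical table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        baseline = float(row.baseline_hdrs17)
        month6 = float(row.month6_hdrs17)
        for score in (baseline, month6):
            if not (0 <= score <= 52):
                raise SchemaError(f"HDRS17 score {score} outside [0, 52]")
        weekly = None
        raw_weekly = getattr(row, "weekly_hdrs17", None)
        if raw_weekly is not None and not pd.isna(raw_weekly) and str(raw_weekly):
            vals = [float(v) for v in str(raw_weekly).split(";")]
            weekly = {w + 1: v for w, v in enumerate(vals)}
        ttr = getattr(row, "time_to_stable_weeks", None)
        if ttr is None or pd.isna(ttr):
            ttr = None
        else:
            ttr = float(ttr)
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id),
                baseline_hdrs17=baseline,
                month6_hdrs17=month6,
                weekly_hdrs17=weekly,
                time_to_stable_weeks=ttr,
            )
        )
    return records
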