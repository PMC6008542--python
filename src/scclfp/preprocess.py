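"""Signal conditioning: zero-phase filtering, decimation, artifact
pruning, bipolar differential derivation, and epoch extraction.

The pipeline order is fixed: bandpass (1-50 Hz, zero phase) ->
decimate to 128 Hz -> prune annotated artifacts -> derive differential
signals -> cut the 1-minute pre/post epochs around each stimulation
cycle.  Artifact samples are *discarded* (concatenated out), never
zero-filled, so downstream spectral estimates see only clean samples;
``lost_fraction`` tracks how much of each epoch was removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import (
    EmptyEpochError,
    EpochBoundsError,
    NoDifferentialError,
    NyquistError,
)
from .io import ArtifactAnnotation, CycleMetadata, LfpRecording, merge_annotations

ANALYSIS_RATE_HZ = 128.0
EPOCH_S = 60.0

#: contacts that have two flanking neighbors and admit a differential
DIFFERENTIABLE = ("L2", "L3", "R2", "R3")


def bandpass_zero_phase(
    x: np.ndarray,
    rate_hz: float,
    low_hz: float = 1.0,
    high_hz: float = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward filtering).

    A 4th-order Butterworth applied with ``sosfiltfilt`` gives a net
    phase shift of zero and squared-magnitude (8th-order) rolloff.
    """
    if rate_hz <= 2 * high_hz:
        raise NyquistError(
            f"rate {rate_hz} Hz too low for a {high_hz} Hz band edge"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def decimate_to_rate(
    x: np.ndarray, rate_hz: float, target_hz: float = ANALYSIS_RATE_HZ
) -> np.ndarray:
    """Resample a band-limited signal to ``target_hz`` (default 128 Hz).

    Integer ratios reduce to polyphase decimation; non-integer ratios
    (e.g. 1525 -> 128) use rational-factor polyphase resampling with the
    realized rate within 1e-6 of the target.  The output has
    ``ceil(n * target / rate)`` samples — 60 s in yields 7,680 out.
    """
    if target_hz > rate_hz:
        raise ValueError("target rate exceeds source rate")
    frac = (Fraction(target_hz) / Fraction(rate_hz)).limit_denominator(10**6)
    realized = rate_hz * float(frac)
    if abs(realized - target_hz) > 1e-6 * target_hz:
        raise ValueError(f"cannot realize {target_hz} Hz from {rate_hz} Hz")
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def detect_artifacts(
    x: np.ndarray,
    rate_hz: float,
    channel: str = "all",
    amp_uV: float = 100.0,
    min_dur_ms: float = 250.0,
) -> list[ArtifactAnnotation]:
    """Flag maximal intervals where ``|x|`` exceeds ``amp_uV`` for at
    least ``min_dur_ms``.

    This is a QC helper mirroring the manual annotation rule (large
    deflections sustained for a quarter second); manually annotated
    artifact tables remain authoritative for the analysis.
    """
    x = np.asarray(x, dtype=float)
    over = np.abs(x) > amp_uV
    if not over.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], over.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    min_samples = min_dur_ms / 1000.0 * rate_hz
    out = [
        ArtifactAnnotation(channel, s / rate_hz, e / rate_hz)
        for s, e in zip(starts, ends)
        if (e - s) >= min_samples
    ]
    return out


def invalid_mask(
    n: int,
    rate_hz: float,
    annotations: list[ArtifactAnnotation],
    channels: tuple[str, ...] | None = None,
    start_time: float = 0.0,
) -> np.ndarray:
    """Boolean mask, True where a sample falls inside any annotation.

    Sample ``i`` (time ``start_time + i/rate``) is invalid when it lies
    in an annotated half-open interval ``[start_s, end_s)`` on one of
    ``channels`` (or on ``"all"``).  ``channels=None`` applies every
    annotation regardless of channel.
    """
    bad = np.zeros(n, dtype=bool)
    t0 = start_time
    for a in annotations:
        if channels is not None and a.channel != "all" and a.channel not in channels:
            continue
        i0 = int(np.ceil((a.start_s - t0) * rate_hz - 1e-9))
        i1 = int(np.ceil((a.end_s - t0) * rate_hz - 1e-9))
        if i1 <= 0 or i0 >= n:
            continue
        bad[max(i0, 0) : min(i1, n)] = True
    return bad


def prune_segments(
    x: np.ndarray,
    rate_hz: float,
    annotations: list[ArtifactAnnotation],
    channels: tuple[str, ...] | None = None,
    start_time: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Remove annotated samples (discard, not blank) and report the
    lost fraction.

    Returns the concatenation of the retained samples and
    ``removed / total``.  Raises :class:`EmptyEpochError` when nothing
    survives.
    """
    x = np.asarray(x, dtype=float)
    bad = invalid_mask(len(x), rate_hz, annotations, channels, start_time)
    lost = float(bad.mean()) if len(x) else 0.0
    kept = x[~bad]
    if len(x) and kept.size == 0:
        raise EmptyEpochError("all samples removed by artifact pruning")
    return kept, lost


@dataclass
class DifferentialSignal:
    """Bipolar signal around a contact of interest.

    ``samples = minuend - subtrahend`` where the minuend is the next
    more ventral contact and the subtrahend the next more dorsal one
    (center L2 -> L1 - L3).  ``valid_mask`` is False where either
    flanking contact carries an artifact annotation.
    """

    center_contact: str
    minuend: str
    subtrahend: str
    rate_hz: float
    samples: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.samples), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.valid_mask) != len(self.samples):
            raise ValueError("valid_mask must match samples in length")


def derive_differential(
    recording: LfpRecording,
    center_contact: str,
    annotations: list[ArtifactAnnotation] | None = None,
) -> DifferentialSignal:
    """Derive the bipolar signal flanking ``center_contact``.

    Only the middle contacts (L2, L3, R2, R3) have two neighbors; edge
    contacts raise :class:`NoDifferentialError` and yield missing values
    downstream.  An annotation on either flanking contact (or ``all``)
    invalidates those samples of the pair.
    """
    if center_contact not in DIFFERENTIABLE:
        raise NoDifferentialError(
            f"contact {center_contact} has only one neighbor; "
            "no differential signal exists"
        )
    hemi, idx = center_contact[0], int(center_contact[1])
    minuend, subtrahend = f"{hemi}{idx - 1}", f"{hemi}{idx + 1}"
    samples = recording.get(minuend) - recording.get(subtrahend)
    mask = np.ones(len(samples), dtype=bool)
    if annotations:
        bad = invalid_mask(
            len(samples),
            recording.rate_hz,
            merge_annotations(annotations),
            channels=(minuend, subtrahend),
            start_time=recording.start_time,
        )
        mask = ~bad
    return DifferentialSignal(
        center_contact=center_contact,
        minuend=minuend,
        subtrahend=subtrahend,
        rate_hz=recording.rate_hz,
        samples=samples,
        valid_mask=mask,
        start_time=recording.start_time,
    )


@dataclass
class EpochPair:
    """Pruned 1-minute pre- and post-stimulation epochs of one cycle."""

    pre: np.ndarray
    post: np.ndarray
    cycle: CycleMetadata
    lost_fraction_pre: float
    lost_fraction_post: float
    rate_hz: float = ANALYSIS_RATE_HZ


def _cut(
    diff: DifferentialSignal, t0: float, t1: float, guard_s: float
) -> tuple[np.ndarray, float]:
    fs = diff.rate_hz
    i0 = int(round((t0 - diff.start_time) * fs))
    i1 = int(round((t1 - diff.start_time) * fs))
    if i0 < 0 or i1 > len(diff.samples):
        raise EpochBoundsError(
            f"recording does not cover window [{t0}, {t1}) s"
        )
    seg = diff.samples[i0:i1]
    mask = diff.valid_mask[i0:i1].copy()
    if guard_s > 0 and (~mask).any():
        # widen each invalid run by guard_s on both sides: splices after
        # discard-not-blank concatenation inject broadband energy
        w = int(round(guard_s * fs))
        bad = ~mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            mask[max(s - w, 0) : min(e + w, len(mask))] = False
    lost = float((~mask).mean()) if len(mask) else 0.0
    kept = seg[mask]
    if len(seg) and kept.size == 0:
        raise EmptyEpochError("epoch fully removed by artifact pruning")
    return kept, lost


def extract_epoch_pair(
    diff: DifferentialSignal,
    cycle: CycleMetadata,
    epoch_s: float = EPOCH_S,
    splice_guard_s: float = 0.0,
) -> EpochPair:
    """Cut ``[stim_on - 60, stim_on)`` and ``[stim_off, stim_off + 60)``
    from a differential signal, dropping invalid samples.

    ``splice_guard_s`` optionally discards that many extra seconds on
    each side of every pruned gap (default 0: plain concatenation).
    """
    pre, lost_pre = _cut(
        diff, cycle.stim_on_s - epoch_s, cycle.stim_on_s, splice_guard_s
    )
    post, lost_post = _cut(
        diff, cycle.stim_off_s, cycle.stim_off_s + epoch_s, splice_guard_s
    )
    return EpochPair(
        pre=pre,
        post=post,
        cycle=cycle,
        lost_fraction_pre=lost_pre,
        lost_fraction_post=lost_post,
    )


def preprocess_recording(
    recording: LfpRecording,
    low_hz: float = 1.0,
    high_hz: float = 50.0,
    target_hz: float = ANALYSIS_RATE_HZ,
) -> LfpRecording:
    """Bandpass-filter and decimate every channel (the first two
    pipeline stages), returning a new recording at the analysis rate."""
    rows = [
        decimate_to_rate(
            bandpass_zero_phase(ch, recording.rate_hz, low_hz, high_hz),
            recording.rate_hz,
            target_hz,
        )
        for ch in recording.samples
    ]
    return LfpRecording(
        patient_id=recording.patient_id,
        channel_labels=list(recording.channel_labels),
        rate_hz=target_hz,
        samples=np.vstack(rows),
        start_time=recording.start_time,
    )
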