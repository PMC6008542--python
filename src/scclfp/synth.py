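"""Synthetic LFP cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: each contact
records a 1/f^chi Gaussian background plus shared band-limited
oscillations (delta through gamma) whose amplitudes are scaled
multiplicatively after the stimulation interval, so the expected
relative change of median CWT magnitude in a band is ``multiplier - 1``
(``multiplier**2 - 1`` on squared power).  Cycles follow the
intraoperative protocol: 1 min pre, 3 min stimulation (amplifier
saturation emulated by clipped high-amplitude oscillation), 1 min
post.  High-amplitude artifact transients are injected at a Poisson
rate and reported as ground-truth annotations.

Oscillations are shared across contacts with a ventral-to-dorsal gain
gradient, so bipolar differencing of the flanking contacts retains
them (a spatially uniform source would cancel); an additional
common-mode drift is added identically to all contacts to exercise
exactly what differencing removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .clinical import classify_response
from .io import (
    ArtifactAnnotation,
    CONTACTS,
    CycleMetadata,
    LfpRecording,
    write_edf,
)
from .spectral import BAND_NAMES, BANDS

#: oscillation gain per contact, ventral (1) to dorsal (4); the
#: differential around a middle contact keeps gain[i-1] - gain[i+1]
CONTACT_GAINS = (1.0, 0.75, 0.5, 0.25)

PRE_S = 60.0
STIM_S = 180.0
POST_S = 60.0
CYCLE_S = PRE_S + STIM_S + POST_S


def generate_background(
    duration_s: float,
    rate_hz: float,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Stationary Gaussian 1/f^exponent noise via spectral shaping,
    normalized to standard deviation ``scale`` (microvolts)."""
    if not (0 <= exponent <= 2):
        raise ValueError("exponent must lie in [0, 2]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def generate_band_oscillation(
    band: str,
    amplitude: float,
    duration_s: float,
    rate_hz: float,
    seed=None,
) -> np.ndarray:
    """Narrowband Gaussian oscillation confined to one canonical band.

    White noise is bandpassed (zero-phase, 6th order) to the inner 80%
    of the band so at least 90% of the power stays inside the band
    edges; ``amplitude`` is the equivalent-sinusoid amplitude (RMS *
    sqrt(2)), so doubling it quadruples band power.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    if amplitude == 0:
        return np.zeros(int(round(duration_s * rate_hz)))
    lo, hi = BANDS[band]
    margin = 0.1 * (hi - lo)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    sos = sps.butter(
        6, [lo + margin, hi - margin], btype="bandpass", fs=rate_hz, output="sos"
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = x.std()
    return x * (amplitude / np.sqrt(2) / rms) if rms > 0 else x


def _default_amplitudes() -> dict[str, float]:
    return {name: 15.0 for name in BAND_NAMES}


def _unit_multipliers() -> dict[str, float]:
    return {name: 1.0 for name in BAND_NAMES}


@dataclass
class SyntheticCycleSpec:
    """Ground-truth parameters of one synthetic stimulation cycle.

    Amplitudes are per-band equivalent-sinusoid amplitudes in
    microvolts (pre epoch); ``post_multipliers`` scale them after the
    stimulation interval, so the expected band change is
    ``multiplier - 1``.
    """

    band_amplitudes_pre: dict[str, float] = field(default_factory=_default_amplitudes)
    post_multipliers: dict[str, float] = field(default_factory=_unit_multipliers)
    noise_exponent: float = 1.0
    noise_scale: float = 1.5
    common_mode_uV: float = 40.0
    artifact_rate_per_min: float = 1.0
    artifact_amp_uV: float = 150.0
    artifact_dur_s: float = 0.5
    saturation_uV: float = 3000.0
    rate_hz: float = 1024.0
    seed: int | None = 0
    #: share the oscillation realization between the pre and post
    #: epochs (common random numbers): the post epoch replays the pre
    #: oscillation scaled by the multiplier, so the ground-truth band
    #: change is pinned to multiplier - 1 rather than riding on the
    #: realization noise of two 1-minute medians.  Set False for fully
    #: independent epochs.
    paired_realization: bool = True

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.post_multipliers.values()):
            raise ValueError("post multipliers must be positive")

    def truth(self) -> dict[str, dict[str, float]]:
        """Expected band changes under the analysis: amplitude truth is
        multiplier - 1, squared-power truth multiplier^2 - 1."""
        return {
            "amplitude": {b: self.post_multipliers[b] - 1.0 for b in BAND_NAMES},
            "power": {b: self.post_multipliers[b] ** 2 - 1.0 for b in BAND_NAMES},
        }


@dataclass
class SyntheticCycle:
    """One generated cycle: recording segment, metadata, annotations,
    and the ground-truth band changes."""

    recording: LfpRecording
    cycle: CycleMetadata
    artifacts: list[ArtifactAnnotation]
    truth: dict[str, dict[str, float]]


def _hemisphere_signals(
    spec: SyntheticCycleSpec,
    multipliers: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Four contact signals for one hemisphere over a full cycle."""
    fs = spec.rate_hz
    n = int(round(CYCLE_S * fs))
    n_pre_end = int(round(PRE_S * fs))
    n_post_start = int(round((PRE_S + STIM_S) * fs))

    osc = np.zeros(n)
    for band in BAND_NAMES:
        amp = spec.band_amplitudes_pre.get(band, 0.0)
        if amp == 0:
            continue
        m = multipliers.get(band, 1.0)
        if spec.paired_realization:
            x = generate_band_oscillation(band, amp, CYCLE_S, fs, seed=rng)
            # post epoch replays the pre-epoch oscillation, scaled
            n_epoch = n - n_post_start
            x[n_post_start:] = m * x[:n_epoch]
        else:
            x = generate_band_oscillation(band, amp, CYCLE_S, fs, seed=rng)
            if m != 1.0:
                x[n_post_start:] *= m
        osc = osc + x

    n_epoch = n - n_post_start
    contacts = np.empty((4, n))
    for c in range(4):
        noise = generate_background(
            CYCLE_S, fs, spec.noise_exponent, spec.noise_scale, seed=rng
        )
        if spec.paired_realization:
            # common random numbers across the contrast: the post epoch
            # sees the pre epoch's background, so the configured
            # multipliers are the only systematic pre/post difference
            noise[n_post_start:] = noise[:n_epoch]
        contacts[c] = CONTACT_GAINS[c] * osc + noise
    if spec.common_mode_uV:
        drift = generate_background(CYCLE_S, fs, 2.0, spec.common_mode_uV, seed=rng)
        contacts += drift  # identical on every contact; differencing removes it

    # amplifier saturation during stimulation
    t_stim = np.arange(n_post_start - n_pre_end) / fs
    sat = np.clip(
        2 * spec.saturation_uV * np.sin(2 * np.pi * 130.0 * t_stim),
        -spec.saturation_uV,
        spec.saturation_uV,
    )
    contacts[:, n_pre_end:n_post_start] = sat
    return contacts


def _inject_artifacts(
    contacts: np.ndarray,
    spec: SyntheticCycleSpec,
    rng: np.random.Generator,
    epoch_windows: list[tuple[float, float]],
) -> list[ArtifactAnnotation]:
    """Poisson artifact transients within the analysis epochs, added to
    every contact with random per-contact polarity/gain so bipolar
    differencing cannot cancel them."""
    fs = spec.rate_hz
    anns = []
    for w0, w1 in epoch_windows:
        count = rng.poisson(spec.artifact_rate_per_min * (w1 - w0) / 60.0)
        for _ in range(count):
            start = rng.uniform(w0, w1 - spec.artifact_dur_s)
            i0 = int(round(start * fs))
            i1 = i0 + int(round(spec.artifact_dur_s * fs))
            gains = rng.uniform(0.8, 1.6, size=contacts.shape[0])
            gains *= rng.choice([-1.0, 1.0], size=contacts.shape[0])
            pulse = spec.artifact_amp_uV * np.ones(i1 - i0)
            contacts[:, i0:i1] += gains[:, None] * pulse[None, :]
            anns.append(ArtifactAnnotation("all", start, start + spec.artifact_dur_s))
    return anns


def synthesize_cycle(
    spec: SyntheticCycleSpec,
    patient_id: str = "p01",
    stim_contact: str = "L2",
    role: str = "effective",
) -> SyntheticCycle:
    """Generate one full 5-minute cycle for both hemispheres.

    The stimulated hemisphere carries the configured post multipliers;
    the contralateral hemisphere stays at multiplier 1 (ipsilateral
    effects only).
    """
    rng = np.random.default_rng(spec.seed)
    stim_hemi = stim_contact[0]
    sides = {}
    for hemi in ("L", "R"):
        mult = spec.post_multipliers if hemi == stim_hemi else _unit_multipliers()
        sides[hemi] = _hemisphere_signals(spec, mult, rng)
    samples = np.vstack([sides["L"], sides["R"]])
    windows = [(0.0, PRE_S), (PRE_S + STIM_S, CYCLE_S)]
    artifacts = _inject_artifacts(samples, spec, rng, windows)
    recording = LfpRecording(
        patient_id=patient_id,
        channel_labels=list(CONTACTS),
        rate_hz=spec.rate_hz,
        samples=samples,
    )
    cycle = CycleMetadata(
        patient_id=patient_id,
        stim_contact=stim_contact,
        hemisphere=stim_hemi,
        role=role,
        stim_on_s=PRE_S,
        stim_off_s=PRE_S + STIM_S,
    )
    return SyntheticCycle(recording, cycle, artifacts, spec.truth())


def _left_effective() -> dict[str, float]:
    # broadband ipsilateral decrease, alpha largest then theta
    return {"delta": 1.0, "theta": 0.65, "alpha": 0.55, "beta": 0.7, "gamma": 0.75}


def _right_effective() -> dict[str, float]:
    # decreases restricted to beta and gamma
    return {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 0.7, "gamma": 0.65}


def _left_ineffective() -> dict[str, float]:
    # alpha/beta/gamma decrease but theta spared
    return {"delta": 1.0, "theta": 1.0, "alpha": 0.8, "beta": 0.7, "gamma": 0.75}


def _right_ineffective() -> dict[str, float]:
    return {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 0.75, "gamma": 0.8}


@dataclass
class SyntheticCohortSpec:
    """Cohort-level generator parameters (defaults mirror the study
    design: 14 patients, 11 responders, 4 analyzed cycles each)."""

    n_patients: int = 14
    n_responders: int = 11
    effect_profiles: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {
            ("L", "effective"): _left_effective(),
            ("L", "ineffective"): _left_ineffective(),
            ("R", "effective"): _right_effective(),
            ("R", "ineffective"): _right_ineffective(),
        }
    )
    cycle_spec: SyntheticCycleSpec = field(default_factory=SyntheticCycleSpec)
    n_edge_contact_patients: int = 1
    n_fully_artifacted_epochs: int = 1
    inter_cycle_gap_s: float = 20.0
    master_seed: int = 0


def synthesize_cohort(spec: SyntheticCohortSpec, outdir) -> Path:
    """Generate a full dataset directory.

    Layout: ``patient_XX.edf`` (one continuous 8-channel recording per
    patient holding 4 cycles: left/right effective/ineffective),
    ``cycles.csv``, ``artifacts.csv``, ``clinical.csv`` and
    ``truth.json`` (per-patient ground-truth multipliers and responder
    flags).  Deterministic given ``master_seed``.  The first
    ``n_edge_contact_patients`` responders get an effective left
    contact of L4 (no differential; exercises the missing-value path),
    and the first pre-stimulation epoch of patient 1 is fully
    artifact-annotated (exercises the empty-epoch path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.master_seed)
    fs = spec.cycle_spec.rate_hz
    period = CYCLE_S + spec.inter_cycle_gap_s

    cycle_rows, artifact_rows, clinical_rows = [], [], []
    truth: dict = {
        "master_seed": spec.master_seed,
        "profiles": {
            f"{h}_{r}": prof for (h, r), prof in spec.effect_profiles.items()
        },
        "patients": {},
    }

    for p in range(spec.n_patients):
        pid = f"{p + 1:02d}"
        p_seed = np.random.SeedSequence([spec.master_seed, p])
        rng = np.random.default_rng(p_seed)
        responder = p < spec.n_responders
        edge = responder and p < spec.n_edge_contact_patients

        eff = {"L": "L4" if edge else f"L{rng.integers(2, 4)}", "R": f"R{rng.integers(2, 4)}"}
        ine = {h: {"L2": "L3", "L3": "L2", "L4": "L3", "R2": "R3", "R3": "R2"}[c]
               for h, c in eff.items()}

        plan = [
            ("L", "effective", eff["L"]),
            ("L", "ineffective", ine["L"]),
            ("R", "effective", eff["R"]),
            ("R", "ineffective", ine["R"]),
        ]
        segments, patient_truth = [], {"responder": responder, "cycles": []}
        for k, (hemi, role, contact) in enumerate(plan):
            mult = spec.effect_profiles[(hemi, role)]
            cyc_seed = int(
                np.random.SeedSequence([spec.master_seed, p, k]).generate_state(1)[0]
                % (2**31)
            )
            cspec = replace(spec.cycle_spec, post_multipliers=dict(mult), seed=cyc_seed)
            syn = synthesize_cycle(cspec, pid, contact, role)
            offset = k * period
            segments.append(syn.recording.samples)
            cycle_rows.append(
                {
                    "patient_id": pid,
                    "stim_contact": contact,
                    "hemisphere": hemi,
                    "role": role,
                    "stim_on_s": offset + PRE_S,
                    "stim_off_s": offset + PRE_S + STIM_S,
                }
            )
            for a in syn.artifacts:
                artifact_rows.append(
                    {
                        "patient_id": pid,
                        "channel": a.channel,
                        "start_s": round(a.start_s + offset, 6),
                        "end_s": round(a.end_s + offset, 6),
                    }
                )
            patient_truth["cycles"].append(
                {
                    "hemisphere": hemi,
                    "role": role,
                    "stim_contact": contact,
                    "multipliers": dict(mult),
                    "truth_amplitude": {b: mult[b] - 1.0 for b in BAND_NAMES},
                    "truth_power": {b: mult[b] ** 2 - 1.0 for b in BAND_NAMES},
                }
            )
            if spec.inter_cycle_gap_s:
                gap = np.zeros((8, int(round(spec.inter_cycle_gap_s * fs))))
                segments.append(gap)
        truth["patients"][pid] = patient_truth

        # blanket one whole pre epoch -> EmptyEpochError path; patient 2,
        # whose differentials exist (patient 1 may carry the edge contact)
        if p == min(1, spec.n_patients - 1) and spec.n_fully_artifacted_epochs:
            artifact_rows.append(
                {"patient_id": pid, "channel": "all", "start_s": 0.0, "end_s": PRE_S}
            )

        samples = np.hstack(segments)
        rec = LfpRecording(pid, list(CONTACTS), fs, samples)
        write_edf(rec, outdir / f"patient_{pid}.edf")

        baseline = float(np.round(rng.uniform(20.0, 29.5) * 4) / 4)
        if responder:
            month6 = float(np.round(baseline * rng.uniform(0.2, 0.45)))
            ttr_week = int(rng.integers(3, 25))
        else:
            month6 = float(np.round(baseline * rng.uniform(0.6, 0.85)))
            ttr_week = None
        assert classify_response(baseline, month6) == responder
        weekly = _weekly_series(baseline, month6, ttr_week, rng)
        clinical_rows.append(
            {
                "patient_id": pid,
                "baseline_hdrs17": baseline,
                "month6_hdrs17": month6,
                "weekly_hdrs17": ";".join(f"{v:g}" for v in weekly) if weekly else "",
                "time_to_stable_weeks": "",
            }
        )

    pd.DataFrame(
        artifact_rows, columns=["patient_id", "channel", "start_s", "end_s"]
    ).to_csv(outdir / "artifacts.csv", index=False)
    pd.DataFrame(
        cycle_rows,
        columns=["patient_id", "stim_contact", "hemisphere", "role", "stim_on_s", "stim_off_s"],
    ).to_csv(outdir / "cycles.csv", index=False)
    pd.DataFrame(
        clinical_rows,
        columns=["patient_id", "baseline_hdrs17", "month6_hdrs17", "weekly_hdrs17", "time_to_stable_weeks"],
    ).to_csv(outdir / "clinical.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir


def _weekly_series(
    baseline: float,
    month6: float,
    ttr_week: int | None,
    rng: np.random.Generator,
    n_weeks: int = 26,
) -> list[float]:
    """Weekly HDRS trajectory consistent with the responder flag and
    target time-to-stable-response week."""
    half = baseline / 2.0
    series = []
    for w in range(1, n_weeks + 1):
        if ttr_week is not None and w >= ttr_week:
            score = min(month6, half) * rng.uniform(0.7, 1.0)
        else:
            score = rng.uniform(half * 1.05, baseline)
        series.append(round(min(score, 52.0), 1))
    return series
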