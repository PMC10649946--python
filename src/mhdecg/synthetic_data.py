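"""Synthetic ECGs, ground-truth distortions, and HF/FF pairs.

Every pipeline stage is testable without downloading clinical data:

* :func:`synth_clean_ecg` builds sum-of-Gaussians beats (P, Q, R, S, T
  bumps) at jittered RR intervals, so the R-peak sample indices are known
  analytically rather than re-detected.
* :func:`synth_distortion` builds a band-limited random 3-component
  waveform whose amplitude envelope is concentrated after the QRS complex
  (the region the magnetohydrodynamic effect mostly elevates), in a
  250-sample R-anchored window.
* :func:`synth_hf_ff_pair` emulates the polarity flip of the distortion
  between head-first and feet-first postures: HF = clean + D + noise,
  FF = clean - D + noise, so (HF - FF)/2 recovers D exactly at zero noise.

These generators reproduce the statistical/temporal structure the
pipeline assumes (post-QRS concentration, beat-locked repetition,
posture polarity flip); they are not a physical model of blood-flow
induced voltages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mhd_extraction import (DistortionTemplate, KORS_MATRIX, KORS_LEADS,
                             TEMPLATE_LENGTH, kors_transform,
                             normalize_template)
from .preprocessing import BeatSegment, WORKING_FS, r_offset_samples
from .signal_io import (EcgRecording, STANDARD_LEADS, ValidationError,
                        VcgRecording, write_csv_recording)

#: Default wave dictionary: (center s relative to R, width s, amplitude mV).
DEFAULT_WAVES = {
    "P": (-0.18, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.12),
    "R": (0.0, 0.016, 1.0),
    "S": (0.035, 0.012, -0.25),
    "T": (0.25, 0.055, 0.35),
}

#: Relative lead amplitudes for a 12-lead projection of the beat shape.
DEFAULT_LEAD_GAINS = {
    "I": 0.55, "II": 1.0, "III": 0.45, "AVR": -0.78, "AVL": 0.18,
    "AVF": 0.72, "V1": -0.35, "V2": 0.45, "V3": 0.85, "V4": 1.15,
    "V5": 1.05, "V6": 0.9,
}


@dataclass
class BeatModel:
    """Sum-of-Gaussians beat morphology with RR jitter and additive noise."""

    waves: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    lead_gains: dict = field(default_factory=lambda: dict(DEFAULT_LEAD_GAINS))
    heart_rate_bpm: float = 60.0
    rr_jitter: float = 0.03
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.heart_rate_bpm <= 220.0):
            raise ValidationError(
                f"heart rate must be in [30, 220] bpm, got {self.heart_rate_bpm}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if any(w[1] <= 0 for w in self.waves.values()):
            raise ValidationError("wave widths must be positive")


@dataclass
class DistortionModel:
    """Band-limited random distortion with a post-QRS amplitude envelope.

    Two ingredients emulate the magnetohydrodynamic artifact's structure:
    an oscillatory elevation concentrated over the T-wave region, and one
    narrow QRS-mimicking pseudo-peak later in diastole.  The pseudo-peak is
    the part that makes the artifact clinically troublesome — detectors
    trained on clean data mistake it for a beat — so a synthetic distortion
    without it would not reproduce the failure mode this package studies.
    """

    n_components: int = 4
    freq_band: tuple[float, float] = (2.0, 12.0)
    envelope_center_fraction: float = 0.52  # of the 0.5 s window
    envelope_width_s: float = 0.05
    spike_position_range: tuple[float, float] = (0.70, 0.88)  # window fraction
    spike_width_s: float = 0.016
    spike_amplitude_range: tuple[float, float] = (1.0, 1.6)  # x burst peak
    amplitude: float = 1.0
    seed: int = 0


def _beat_trace(t: np.ndarray, r_times: np.ndarray, waves: dict) -> np.ndarray:
    x = np.zeros_like(t)
    for center, width, amp in waves.values():
        for r in r_times:
            mu = r + center
            lo = np.searchsorted(t, mu - 6 * width)
            hi = np.searchsorted(t, mu + 6 * width)
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / width) ** 2)
    return x


def _r_times(model: BeatModel, duration: float,
             rng: np.random.Generator) -> np.ndarray:
    rr = 60.0 / model.heart_rate_bpm
    times = []
    t = 0.4  # leave room for the P wave of the first beat
    while t < duration - 0.35:
        times.append(t)
        t += rr * (1.0 + model.rr_jitter * rng.uniform(-1.0, 1.0))
    if len(times) < 1:
        raise ValidationError("duration too short for a single beat")
    return np.asarray(times)


def synth_clean_ecg(model: BeatModel | None = None, duration: float = 30.0,
                    fs: float = WORKING_FS, leads: int = 12,
                    subject_id: str = "synth") -> EcgRecording | VcgRecording:
    """A distortion-free recording with exact R-peak ground truth.

    ``leads=12`` returns a 12-lead :class:`EcgRecording`; ``leads=3``
    returns its Kors-projected :class:`VcgRecording`.
    """
    model = model or BeatModel()
    if leads not in (3, 12):
        raise ValidationError("leads must be 3 or 12")
    rng = np.random.default_rng(model.seed)
    r_times = _r_times(model, duration, rng)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    base = _beat_trace(t, r_times, model.waves)
    gains = np.array([model.lead_gains[l] for l in STANDARD_LEADS])
    signal = base[:, None] * gains[None, :]
    if model.noise_sd > 0:
        signal = signal + rng.normal(0.0, model.noise_sd, size=signal.shape)
    r_peaks = np.unique(np.rint(r_times * fs).astype(np.int64))
    rec = EcgRecording(signal=signal, fs=fs, lead_names=STANDARD_LEADS,
                       r_peaks=r_peaks, subject_id=subject_id)
    if leads == 12:
        return rec
    idx = [STANDARD_LEADS.index(l) for l in KORS_LEADS]
    xyz = rec.signal[:, idx] @ KORS_MATRIX.T
    return VcgRecording(signal=xyz, fs=fs, r_peaks=r_peaks,
                        subject_id=subject_id, provenance="measured")


def _distortion_window(n: int, fs: float, model: DistortionModel,
                       rng: np.random.Generator, k: int) -> np.ndarray:
    """(n, k) distortion: per-channel enveloped oscillation plus one
    pseudo-peak shared in time and polarity across channels (the artifact
    is one physical source seen through several leads)."""
    t = np.arange(n) / fs
    out = np.zeros((n, k))
    center = model.envelope_center_fraction * (n / fs)
    env = np.exp(-0.5 * ((t - center) / model.envelope_width_s) ** 2)
    for c in range(k):
        burst = np.zeros(n)
        for _ in range(model.n_components):
            f = rng.uniform(*model.freq_band)
            phase = rng.uniform(0, 2 * np.pi)
            burst += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t + phase)
        out[:, c] = burst * env
    sc = rng.uniform(*model.spike_position_range) * (n / fs)
    spike = np.exp(-0.5 * ((t - sc) / model.spike_width_s) ** 2)
    amp = rng.uniform(*model.spike_amplitude_range) * max(np.abs(out).max(), 1e-12)
    polarity = rng.choice([-1.0, 1.0])
    for c in range(k):
        out[:, c] += polarity * amp * rng.uniform(0.8, 1.0) * spike
    return out


def synth_distortion_raw(model: DistortionModel | None = None,
                         fs: float = WORKING_FS) -> np.ndarray:
    """Un-normalized ground-truth 250 x 3 distortion window (mV scale)."""
    model = model or DistortionModel()
    rng = np.random.default_rng(model.seed)
    win = _distortion_window(TEMPLATE_LENGTH, fs, model, rng, 3)
    return model.amplitude * win


def synth_distortion(model: DistortionModel | None = None,
                     fs: float = WORKING_FS) -> DistortionTemplate:
    """Normalized ground-truth distortion template in [-1, 1]."""
    raw = synth_distortion_raw(model, fs)
    peak = np.max(np.abs(raw))
    if peak == 0:
        raise ValidationError("degenerate distortion model produced all zeros")
    return DistortionTemplate(window=raw / peak, fs=fs,
                              r_offset=r_offset_samples(TEMPLATE_LENGTH),
                              provenance="synthesized",
                              source_id=f"synthmodel:{model.seed if model else 0}")


def synth_distortion_12lead(model: DistortionModel | None = None,
                            fs: float = WORKING_FS,
                            seed: int | None = None) -> BeatSegment:
    """A 12-lead ground-truth distortion beat (independent burst per
    independent lead; derived limb leads filled in by their identities)."""
    model = model or DistortionModel()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    window = np.zeros((TEMPLATE_LENGTH, 12))
    independent = model.amplitude * _distortion_window(
        TEMPLATE_LENGTH, fs, model, rng, len(KORS_LEADS))
    by_name = {lead: independent[:, j] for j, lead in enumerate(KORS_LEADS)}
    by_name["III"] = by_name["II"] - by_name["I"]
    by_name["AVR"] = -(by_name["I"] + by_name["II"]) / 2.0
    by_name["AVL"] = by_name["I"] - by_name["II"] / 2.0
    by_name["AVF"] = by_name["II"] - by_name["I"] / 2.0
    for j, lead in enumerate(STANDARD_LEADS):
        window[:, j] = by_name[lead]
    return BeatSegment(window=window, fs=fs,
                       r_offset=r_offset_samples(TEMPLATE_LENGTH),
                       lead_names=STANDARD_LEADS)


def tile_window(window: np.ndarray, r_offset: int, r_peaks: np.ndarray,
                n_samples: int) -> np.ndarray:
    """R-anchored overlap-add tiling of an L x k window over a zero track."""
    L, k = window.shape
    track = np.zeros((n_samples, k))
    for r in np.asarray(r_peaks, dtype=np.int64):
        start = int(r) - r_offset
        lo = max(0, -start)
        hi = L - max(0, start + L - n_samples)
        if lo < hi:
            track[start + lo:start + hi] += window[lo:hi]
    return track


def synth_hf_ff_pair(clean: EcgRecording, distortion_12lead: BeatSegment,
                     noise_sd: float = 0.0, seed: int = 0
                     ) -> tuple[EcgRecording, EcgRecording]:
    """HF/FF recording pair: clean +- the tiled distortion, plus noise."""
    if distortion_12lead.n_channels != clean.n_leads:
        raise ValidationError(
            f"distortion has {distortion_12lead.n_channels} channels, "
            f"recording has {clean.n_leads} leads")
    track = tile_window(distortion_12lead.window, distortion_12lead.r_offset,
                        clean.r_peaks, clean.n_samples)
    rng = np.random.default_rng(seed)
    eps1 = rng.normal(0, noise_sd, clean.signal.shape) if noise_sd > 0 else 0.0
    eps2 = rng.normal(0, noise_sd, clean.signal.shape) if noise_sd > 0 else 0.0
    hf = clean.with_(signal=clean.signal + track + eps1, posture="HF")
    ff = clean.with_(signal=clean.signal - track + eps2, posture="FF")
    return hf, ff


@dataclass
class BenchmarkSuite:
    """A miniature analogue of the full study setup, with ground truth."""

    train_clean: list[EcgRecording]
    hf_ff_pairs: list[tuple[EcgRecording, EcgRecording]]
    held_out_distorted: VcgRecording
    held_out_clean: VcgRecording
    ground_truth_templates: list[DistortionTemplate]
    manifest: dict


def make_benchmark_suite(seed: int = 0, out_dir: str | Path | None = None,
                         n_train: int = 6, n_subjects: int = 3,
                         duration: float = 30.0,
                         noise_sd: float = 0.005,
                         distortion_amplitude: float = 0.6) -> BenchmarkSuite:
    """Build (and optionally write as CSV) the full synthetic study setup:

    ``n_train`` clean training recordings, ``n_subjects`` HF/FF recording
    pairs for template extraction, and one held-out distorted recording
    (never part of training) with its clean twin for reference.
    """
    rng = np.random.default_rng(seed)
    train = []
    for i in range(n_train):
        model = BeatModel(heart_rate_bpm=float(rng.uniform(55, 85)),
                          noise_sd=noise_sd, seed=int(rng.integers(2 ** 31)))
        train.append(synth_clean_ecg(model, duration=duration,
                                     subject_id=f"train{i:02d}"))
    pairs, gt_templates = [], []
    for i in range(n_subjects):
        model = BeatModel(heart_rate_bpm=float(rng.uniform(55, 85)),
                          noise_sd=0.0, seed=int(rng.integers(2 ** 31)))
        clean = synth_clean_ecg(model, duration=duration,
                                subject_id=f"scan{i:02d}")
        dmodel = DistortionModel(amplitude=distortion_amplitude,
                                 seed=int(rng.integers(2 ** 31)))
        d12 = synth_distortion_12lead(dmodel)
        pairs.append(synth_hf_ff_pair(clean, d12, noise_sd=noise_sd,
                                      seed=int(rng.integers(2 ** 31))))
        gt_templates.append(normalize_template(kors_transform(d12),
                                               provenance="measured"))

    ho_model = BeatModel(heart_rate_bpm=float(rng.uniform(55, 85)),
                         noise_sd=noise_sd, seed=int(rng.integers(2 ** 31)))
    ho_clean = synth_clean_ecg(ho_model, duration=duration, leads=3,
                               subject_id="heldout")
    peak = np.max(np.abs(ho_clean.signal))
    ho_clean = ho_clean.with_(signal=ho_clean.signal / peak)
    ho_template = synth_distortion(
        DistortionModel(amplitude=1.0, seed=int(rng.integers(2 ** 31))))
    track = tile_window(ho_template.window, ho_template.r_offset,
                        ho_clean.r_peaks, ho_clean.n_samples)
    ho_dist = ho_clean.with_(signal=ho_clean.signal + track,
                             provenance="augmented")

    manifest = {
        "seed": seed,
        "train": [r.subject_id for r in train],
        "hf_ff_subjects": [hf.subject_id for hf, _ in pairs],
        "held_out": ho_dist.subject_id,
        "duration_s": duration,
        "noise_sd": noise_sd,
        "distortion_amplitude": distortion_amplitude,
    }
    suite = BenchmarkSuite(train_clean=train, hf_ff_pairs=pairs,
                           held_out_distorted=ho_dist,
                           held_out_clean=ho_clean,
                           ground_truth_templates=gt_templates,
                           manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in train:
            write_csv_recording(rec, out / f"{rec.subject_id}.csv")
        for hf, ff in pairs:
            write_csv_recording(hf, out / f"{hf.subject_id}_hf.csv")
            write_csv_recording(ff, out / f"{ff.subject_id}_ff.csv")
        write_csv_recording(ho_dist, out / "heldout_distorted.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return suite
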