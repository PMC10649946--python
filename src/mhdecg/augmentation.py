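"""Injection of distortion templates into distortion-free recordings.

One template is repeated across a whole recording, R-anchored: at every
annotated heartbeat the 250-sample window is added with its R-offset
(sample 62) aligned to the R-peak.  Windows that would cross a recording
edge are clipped; when consecutive beats are closer than the window
length the copies are overlap-added by default (a truncate-at-RR-midpoint
mode is available).  Annotations are never modified, so augmented
recordings remain valid detector training material with unchanged ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mhd_extraction import DistortionTemplate, TemplateDatabase
from .signal_io import ValidationError, VcgRecording

logger = logging.getLogger(__name__)


def build_distortion_track(template: DistortionTemplate, r_peaks: np.ndarray,
                           n_samples: int, fs: float,
                           overlap_mode: str = "add") -> np.ndarray:
    """Tile one template over an ``n_samples`` x 3 zero track, one copy per
    R-peak, R-anchored.  ``overlap_mode``: "add" overlap-adds colliding
    windows; "truncate" cuts each window at the midpoint to the next beat."""
    if fs != template.fs:
        raise ValidationError(
            f"sampling-rate mismatch: track {fs} Hz vs template {template.fs} Hz")
    if overlap_mode not in ("add", "truncate"):
        raise ValidationError(f"unknown overlap_mode {overlap_mode!r}")
    track = np.zeros((n_samples, 3))
    L = template.window.shape[0]
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    for k, r in enumerate(r_peaks):
        start = int(r) - template.r_offset
        stop = start + L
        w_lo = max(0, -start)
        w_hi = L - max(0, stop - n_samples)
        if overlap_mode == "truncate":
            if k + 1 < len(r_peaks):
                mid = (int(r) + int(r_peaks[k + 1])) // 2
                w_hi = min(w_hi, mid - start)
            if k > 0:
                prev_mid = (int(r_peaks[k - 1]) + int(r)) // 2
                w_lo = max(w_lo, prev_mid - start)
        if w_lo >= w_hi:
            continue
        track[start + w_lo:start + w_hi] += template.window[w_lo:w_hi]
    return track


def normalize_recording(rec: VcgRecording) -> VcgRecording:
    """Joint max-abs normalization of all three components (per recording),
    bringing carrier amplitudes onto the templates' [-1, 1] scale."""
    peak = float(np.max(np.abs(rec.signal)))
    if peak == 0.0:
        raise ValidationError("cannot normalize an all-zero recording")
    return rec.with_(signal=rec.signal / peak)


def augment_recording(rec: VcgRecording, template: DistortionTemplate,
                      scale: float = 1.0,
                      overlap_mode: str = "add") -> VcgRecording:
    """Return ``rec + scale * distortion_track`` with unchanged annotations."""
    track = build_distortion_track(template, rec.r_peaks, rec.n_samples,
                                   rec.fs, overlap_mode=overlap_mode)
    return rec.with_(signal=rec.signal + scale * track, provenance="augmented")


@dataclass
class AugmentedDataset:
    """Original recordings plus their distorted copies, with a manifest
    recording which template (and scale/seed) produced each copy."""

    recordings: list[VcgRecording] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def originals(self) -> list[VcgRecording]:
        return [r for r in self.recordings if r.provenance != "augmented"]

    @property
    def augmented(self) -> list[VcgRecording]:
        return [r for r in self.recordings if r.provenance == "augmented"]


def build_augmented_dataset(recs: list[VcgRecording], db: TemplateDatabase,
                            templates_per_recording: int = 2,
                            scale: float = 1.0, seed: int = 0,
                            normalize: bool = True,
                            overlap_mode: str = "add") -> AugmentedDataset:
    """All originals plus ``templates_per_recording`` distorted copies each.

    Templates are drawn without replacement across the whole dataset when
    the database is large enough (e.g. 150 templates onto 75 recordings at
    2 per recording), otherwise with replacement plus a warning.  Total
    size is ``(1 + templates_per_recording) * len(recs)``.
    """
    if not recs:
        raise ValidationError("no recordings to augment")
    if len(db) == 0:
        raise ValidationError("empty template database")
    rng = np.random.default_rng(seed)
    needed = len(recs) * templates_per_recording
    if len(db) >= needed:
        assignment = rng.choice(len(db), size=needed, replace=False)
    else:
        logger.warning("template database (%d) smaller than %d assignments; "
                       "sampling with replacement", len(db), needed)
        assignment = rng.choice(len(db), size=needed, replace=True)

    out: list[VcgRecording] = []
    manifest: dict = {"seed": seed, "scale": scale,
                      "templates_per_recording": templates_per_recording,
                      "assignments": {}}
    k = 0
    for rec in recs:
        carrier = normalize_recording(rec) if normalize else rec
        out.append(carrier.with_(provenance="original"))
        for copy in range(templates_per_recording):
            tmpl_idx = int(assignment[k])
            k += 1
            aug = augment_recording(carrier, db[tmpl_idx], scale=scale,
                                    overlap_mode=overlap_mode)
            aug = aug.with_(subject_id=f"{rec.subject_id}+t{tmpl_idx}")
            out.append(aug)
            manifest["assignments"][aug.subject_id] = {
                "source": rec.subject_id, "template_index": tmpl_idx}
    return AugmentedDataset(recordings=out, manifest=manifest)
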