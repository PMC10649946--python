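"""Extraction of measured MHD distortion templates from HF/FF recordings.

Blood flowing through the aorta inside a strong static magnetic field
induces a voltage (the magnetohydrodynamic, MHD, effect) superimposed on
the ECG.  The induced component reverses polarity when the subject is
turned from head-first (HF) to feet-first (FF), while the cardiac signal
does not; the distortion is therefore isolated beat-by-beat as
``(ECG_HF - ECG_FF) / 2``.

The 12-lead distortion beats are reduced to a 3-component vectorcardiogram
(X, Y, Z) with the Kors regression transformation and normalized to
[-1, 1], forming the measured-template database that the generative model
trains on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json

import numpy as np
import pandas as pd

from .preprocessing import (BeatSegment, FilterSpec, WORKING_FS,
                            apply_filters, extract_beat_segments,
                            resample_recording)
from .signal_io import EcgRecording, ValidationError

logger = logging.getLogger(__name__)

#: The 8 independent leads the Kors regression uses, in column order.
KORS_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Kors regression coefficients (rows X, Y, Z; columns as in KORS_LEADS).
KORS_MATRIX = np.array([
    [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
    [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
    [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
])

TEMPLATE_LENGTH = 250
TEMPLATE_COMPONENTS = 3


@dataclass
class DistortionTemplate:
    """One normalized 3D distortion beat: a 250 x 3 window in [-1, 1],
    R-peak anchored at sample ``r_offset`` (62)."""

    window: np.ndarray
    fs: float = WORKING_FS
    r_offset: int = 62
    provenance: str = "measured"  # measured | synthesized
    source_id: str = ""

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.shape != (TEMPLATE_LENGTH, TEMPLATE_COMPONENTS):
            raise ValidationError(
                f"template must be {TEMPLATE_LENGTH}x{TEMPLATE_COMPONENTS}, "
                f"got {self.window.shape}")
        if np.max(np.abs(self.window)) > 1.0 + 1e-9:
            raise ValidationError("template values must lie in [-1, 1]")


@dataclass
class TemplateDatabase:
    """An ordered collection of uniformly shaped distortion templates."""

    templates: list[DistortionTemplate] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, i: int) -> DistortionTemplate:
        return self.templates[i]

    def stack(self) -> np.ndarray:
        """All templates as one (n, 250, 3) array."""
        if not self.templates:
            raise ValidationError("empty template database")
        return np.stack([t.window for t in self.templates])

    def component_traces(self, component: int) -> np.ndarray:
        """(n, 250) matrix of one component's traces across templates."""
        return self.stack()[:, :, component]

    # -- CSV serialization: one row per template, X-block/Y-block/Z-block --

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, t in enumerate(self.templates):
            rows.append([f"t{i:04d}", t.provenance, t.source_id]
                        + list(t.window.T.ravel()))
        cols = (["id", "provenance", "source_id"]
                + [f"{c}{k}" for c in "XYZ" for k in range(TEMPLATE_LENGTH)])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                                float_format="%.9g")
        meta = dict(self.metadata)
        meta.setdefault("n_templates", len(self.templates))
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemplateDatabase":
        path = Path(path)
        df = pd.read_csv(path)
        vals = df.iloc[:, 3:].to_numpy(float)
        templates = []
        for row, prov, src in zip(vals, df["provenance"], df["source_id"]):
            window = row.reshape(TEMPLATE_COMPONENTS, TEMPLATE_LENGTH).T
            templates.append(DistortionTemplate(
                window=window, provenance=str(prov),
                source_id="" if pd.isna(src) else str(src)))
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(templates=templates, metadata=metadata)


def pair_hf_ff_segments(hf: Sequence[BeatSegment], ff: Sequence[BeatSegment]
                        ) -> list[tuple[BeatSegment, BeatSegment]]:
    """Pair the i-th HF beat with the i-th FF beat, truncated to the shorter
    list.  Both lists must share window length and sampling rate."""
    pairs = list(zip(hf, ff))
    for a, b in pairs:
        if a.length != b.length or a.fs != b.fs:
            raise ValidationError(
                f"HF/FF segment mismatch: {a.length}@{a.fs} vs {b.length}@{b.fs}")
    return pairs


def compute_mhd_segment(hf_seg: BeatSegment, ff_seg: BeatSegment) -> BeatSegment:
    """The distortion beat (ECG_HF - ECG_FF) / 2; the shared cardiac signal
    cancels, the polarity-reversing MHD component survives."""
    if hf_seg.window.shape != ff_seg.window.shape:
        raise ValidationError(
            f"shape mismatch {hf_seg.window.shape} vs {ff_seg.window.shape}")
    if hf_seg.fs != ff_seg.fs:
        raise ValidationError("sampling-rate mismatch between HF and FF segments")
    return BeatSegment(window=(hf_seg.window - ff_seg.window) / 2.0,
                       fs=hf_seg.fs, r_offset=hf_seg.r_offset,
                       source_subject=hf_seg.source_subject,
                       source_beat_index=hf_seg.source_beat_index,
                       lead_names=hf_seg.lead_names)


def kors_transform(seg12: BeatSegment) -> BeatSegment:
    """Map a 12-lead (or 8-lead) segment to the 3-component vectorcardiogram.

    Only the 8 independent leads (I, II, V1-V6) enter the regression; the
    derived limb leads (III, aVR, aVL, aVF) are ignored if present.
    """
    names = [n.upper() for n in seg12.lead_names]
    try:
        idx = [names.index(lead) for lead in KORS_LEADS]
    except ValueError as exc:
        missing = [l for l in KORS_LEADS if l not in names]
        raise ValidationError(f"missing leads for Kors transform: {missing}") from exc
    xyz = seg12.window[:, idx] @ KORS_MATRIX.T
    return BeatSegment(window=xyz, fs=seg12.fs, r_offset=seg12.r_offset,
                       source_subject=seg12.source_subject,
                       source_beat_index=seg12.source_beat_index,
                       lead_names=("X", "Y", "Z"))


def ecg_to_vcg(rec: EcgRecording, provenance: str = "measured"):
    """Kors-project a whole 12-lead recording to a 3-component VCG,
    carrying the annotations over unchanged."""
    from .signal_io import VcgRecording
    names = [n.upper() for n in rec.lead_names]
    try:
        idx = [names.index(lead) for lead in KORS_LEADS]
    except ValueError:
        missing = [l for l in KORS_LEADS if l not in names]
        raise ValidationError(f"missing leads for Kors transform: {missing}")
    return VcgRecording(signal=rec.signal[:, idx] @ KORS_MATRIX.T, fs=rec.fs,
                        r_peaks=rec.r_peaks.copy(), subject_id=rec.subject_id,
                        provenance=provenance)


def normalize_template(seg3: BeatSegment,
                       provenance: str = "measured") -> DistortionTemplate:
    """Scale all three components jointly by the window's maximum absolute
    value, so the template lies in [-1, 1] with at least one entry at +-1 and
    inter-component amplitude ratios preserved."""
    peak = float(np.max(np.abs(seg3.window)))
    if peak == 0.0:
        raise ValidationError("cannot normalize an all-zero segment")
    return DistortionTemplate(
        window=seg3.window / peak, fs=seg3.fs, r_offset=seg3.r_offset,
        provenance=provenance,
        source_id=f"{seg3.source_subject}:{seg3.source_beat_index}")


def build_distortion_database(hf_recs: Iterable[EcgRecording],
                              ff_recs: Iterable[EcgRecording],
                              filter_spec: FilterSpec | None = None,
                              target_fs: float = WORKING_FS,
                              seed: int | None = None) -> TemplateDatabase:
    """Full measured-template pipeline:
    resample -> filter -> segment -> HF/FF pair -> difference -> Kors -> normalize.

    HF and FF recordings are matched by ``subject_id``; per-subject segment
    and pair counts go to the metadata log.  ``seed`` is recorded for
    provenance only (the pipeline is deterministic).
    """
    hf_by_subject = {r.subject_id: r for r in hf_recs}
    ff_by_subject = {r.subject_id: r for r in ff_recs}
    subjects = [s for s in hf_by_subject if s in ff_by_subject]
    counts: dict[str, dict[str, int]] = {}
    templates: list[DistortionTemplate] = []
    for subject in subjects:
        segs = {}
        for tag, rec in (("hf", hf_by_subject[subject]), ("ff", ff_by_subject[subject])):
            rec = resample_recording(rec, target_fs)
            rec = apply_filters(rec, filter_spec)
            segs[tag] = extract_beat_segments(rec)
        pairs = pair_hf_ff_segments(segs["hf"], segs["ff"])
        counts[subject] = {"hf_segments": len(segs["hf"]),
                           "ff_segments": len(segs["ff"]),
                           "pairs": len(pairs)}
        for hf_seg, ff_seg in pairs:
            diff = compute_mhd_segment(hf_seg, ff_seg)
            templates.append(normalize_template(kors_transform(diff)))
    if not templates:
        raise ValidationError("no valid HF/FF pairs; cannot build database")
    logger.info("distortion database: %d templates from %d subject(s): %s",
                len(templates), len(subjects), counts)
    return TemplateDatabase(templates=templates,
                            metadata={"per_subject_counts": counts,
                                      "target_fs": target_fs, "seed": seed})
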