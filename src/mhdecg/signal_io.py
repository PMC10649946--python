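"""Core recording containers and readers/writers for WFDB and CSV formats.

The package's universal carrier is :class:`EcgRecording` (multi-lead surface
ECG) and its 3-component sibling :class:`VcgRecording` (vectorcardiogram).
R-peak annotations are stored as 0-based sample indices regardless of the
source format's convention, so that segmentation arithmetic is unambiguous.

WFDB support covers the subset needed for Holter-style records: a text
header (``.hea``), a single 16-bit little-endian signal file (format 16),
and MIT-format binary annotation files.  Amplitudes are converted to mV
using the per-channel ADC gain from the header.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical 12-lead names, uppercase.
STANDARD_LEADS = ("I", "II", "III", "AVR", "AVL", "AVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

#: Patient orientations in the scanner bore.  The magnetohydrodynamic
#: distortion reverses polarity between head-first (HF) and feet-first (FF).
POSTURES = ("HF", "FF", "NONE")


class ValidationError(ValueError):
    """Raised when a recording or annotation violates its invariants."""


def _normalize_lead_name(name: str) -> str:
    canon = name.strip().upper()
    if canon not in STANDARD_LEADS:
        logger.info("non-standard lead label kept verbatim: %r", name)
        return name.strip()
    return canon


@dataclass
class EcgRecording:
    """A multi-lead ECG: ``signal`` is n_samples x n_leads in mV."""

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    subject_id: str = ""
    posture: str = "NONE"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.lead_names = tuple(_normalize_lead_name(n) for n in self.lead_names)
        self._validate()

    def _validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2 or self.n_samples < 1:
            raise ValidationError("signal must be a non-empty n_samples x n_leads matrix")
        if len(self.lead_names) != self.n_leads:
            raise ValidationError(
                f"{len(self.lead_names)} lead names for {self.n_leads} channels")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValidationError(f"duplicate lead names: {self.lead_names}")
        if self.posture not in POSTURES:
            raise ValidationError(f"posture must be one of {POSTURES}, got {self.posture!r}")
        self._validate_peaks()

    def _validate_peaks(self) -> None:
        rp = self.r_peaks
        if rp.size and (rp.min() < 0 or rp.max() >= self.n_samples):
            raise ValidationError(
                f"r_peak index out of range [0, {self.n_samples}): "
                f"min {rp.min()}, max {rp.max()}")
        if rp.size > 1 and not np.all(np.diff(rp) > 0):
            raise ValidationError("r_peaks must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's trace by (case-insensitive) name."""
        canon = _normalize_lead_name(name)
        try:
            return self.signal[:, self.lead_names.index(canon)]
        except ValueError:
            raise KeyError(f"lead {name!r} not in {self.lead_names}") from None

    def with_(self, **changes) -> "EcgRecording":
        return replace(self, **changes)


@dataclass
class VcgRecording:
    """A 3-component vectorcardiogram (X, Y, Z)."""

    signal: np.ndarray
    fs: float
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    subject_id: str = ""
    provenance: str = "measured"  # measured | synthesized | augmented | original

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2 or self.signal.shape[1] != 3:
            raise ValidationError(
                f"VCG must have exactly 3 components, got shape {self.signal.shape}")
        if self.signal.shape[0] < 1:
            raise ValidationError("empty VCG signal")
        EcgRecording._validate_peaks(self)  # same index invariants

    n_samples = EcgRecording.n_samples
    duration = EcgRecording.duration

    @property
    def component_names(self) -> tuple[str, str, str]:
        return ("X", "Y", "Z")

    def with_(self, **changes) -> "VcgRecording":
        return replace(self, **changes)


# --------------------------------------------------------------------------
# WFDB (subset): .hea header, format-16 .dat, MIT annotation file
# --------------------------------------------------------------------------

_FMT16 = "16"
_ANN_NORMAL = 1     # MIT annotation code for a normal beat
_ANN_SKIP = 59      # MIT "SKIP" pseudo-annotation carrying a 4-byte interval


def write_wfdb_record(rec: EcgRecording, path: str | Path,
                      annotation_extension: str = "atr",
                      gain: float = 200.0) -> None:
    """Write ``rec`` as a WFDB record (header + format-16 signal + annotations).

    ``path`` is the record path without extension.  Quantization is
    ``1/gain`` mV per ADC unit; values are clipped to the int16 range.
    No annotation file is written when ``rec.r_peaks`` is empty.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name

    adc = np.clip(np.round(rec.signal * gain), -32768, 32767).astype("<i2")
    (path.parent / f"{name}.dat").write_bytes(adc.tobytes())  # sample-interleaved

    lines = [f"{name} {rec.n_leads} {rec.fs:g} {rec.n_samples}"]
    for ch, lead in enumerate(rec.lead_names):
        first = int(adc[0, ch])
        checksum = int(np.sum(adc[:, ch], dtype=np.int64) % 65536)
        lines.append(f"{name}.dat {_FMT16} {gain:g}(0)/mV 16 0 {first} {checksum} 0 {lead}")
    lines.append(f"# subject_id={rec.subject_id} posture={rec.posture}")
    (path.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")

    if rec.r_peaks.size:
        _write_mit_annotations(path.parent / f"{name}.{annotation_extension}",
                               rec.r_peaks)


def read_wfdb_record(path: str | Path,
                     annotation_extension: str = "atr") -> EcgRecording:
    """Read a WFDB record written by :func:`write_wfdb_record` (format 16 only)."""
    path = Path(path)
    hea = path.parent / f"{path.name}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip()]
    rec_line = lines[0].split()
    n_sig, fs, n_samples = int(rec_line[1]), float(rec_line[2]), int(rec_line[3])

    subject_id, posture = "", "NONE"
    sig_lines = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if tok.startswith("subject_id="):
                    subject_id = tok.split("=", 1)[1]
                elif tok.startswith("posture="):
                    posture = tok.split("=", 1)[1]
        else:
            sig_lines.append(ln.split())
    if len(sig_lines) != n_sig:
        raise ValidationError(f"header announces {n_sig} signals, found {len(sig_lines)}")

    dat_name = sig_lines[0][0]
    dat = path.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    gains, leads = [], []
    for fields in sig_lines:
        if fields[1] != _FMT16:
            raise ValidationError(f"unsupported WFDB format {fields[1]!r} (only 16)")
        gains.append(float(fields[2].split("(")[0]))
        leads.append(fields[-1])
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2").reshape(n_samples, n_sig)
    signal = raw.astype(float) / np.asarray(gains)[None, :]

    ann = path.parent / f"{path.name}.{annotation_extension}"
    r_peaks = _read_mit_annotations(ann) if ann.exists() else np.empty(0, np.int64)
    if r_peaks.size and r_peaks.max() >= n_samples:
        raise ValidationError(
            f"annotation index {r_peaks.max()} beyond signal length {n_samples}")
    return EcgRecording(signal=signal, fs=fs, lead_names=tuple(leads),
                        r_peaks=r_peaks, subject_id=subject_id, posture=posture)


def _write_mit_annotations(path: Path, samples: np.ndarray) -> None:
    if np.any(np.asarray(samples) < 0):
        raise ValidationError("annotation sample indices must be non-negative")
    out = bytearray()
    prev = 0
    for s in np.asarray(samples, dtype=np.int64):
        delta = int(s - prev)
        prev = int(s)
        if delta >= 1024:
            out += struct.pack("<H", (_ANN_SKIP << 10))
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (_ANN_NORMAL << 10) | delta)
    out += struct.pack("<H", 0)  # end of file
    path.write_bytes(bytes(out))


def _read_mit_annotations(path: Path) -> np.ndarray:
    data = path.read_bytes()
    samples: list[int] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _ANN_SKIP:
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        t += interval + pending_skip
        pending_skip = 0
        samples.append(t)
    return np.asarray(samples, dtype=np.int64)


# --------------------------------------------------------------------------
# CSV (one column per lead) + plain-text annotation sidecar
# --------------------------------------------------------------------------

def _csv_ann_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".rpeaks")


def write_csv_recording(rec: EcgRecording | VcgRecording, path: str | Path) -> None:
    """Write one column per lead (header row = lead names) plus an annotation
    sidecar ``<path>.rpeaks`` holding one 0-based sample index per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = rec.lead_names if isinstance(rec, EcgRecording) else rec.component_names
    pd.DataFrame(rec.signal, columns=list(names)).to_csv(
        path, index=False, float_format="%.9g")
    ann = _csv_ann_path(path)
    ann.write_text("".join(f"{int(s)}\n" for s in rec.r_peaks))


def read_csv_recording(path: str | Path, fs: float,
                       subject_id: str = "", posture: str = "NONE") -> EcgRecording:
    """Read a CSV recording written by :func:`write_csv_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CSV recording not found: {path}")
    df = pd.read_csv(path)
    ann = _csv_ann_path(path)
    if ann.exists():
        text = ann.read_text().split()
        r_peaks = np.asarray([int(v) for v in text], dtype=np.int64)
    else:
        r_peaks = np.empty(0, np.int64)
    return EcgRecording(signal=df.to_numpy(float), fs=fs,
                        lead_names=tuple(df.columns), r_peaks=r_peaks,
                        subject_id=subject_id, posture=posture)


def read_csv_vcg(path: str | Path, fs: float, subject_id: str = "",
                 provenance: str = "measured") -> VcgRecording:
    rec = read_csv_recording(path, fs)
    if rec.n_leads != 3:
        raise ValidationError(f"expected 3 components for a VCG, got {rec.n_leads}")
    return VcgRecording(signal=rec.signal, fs=fs, r_peaks=rec.r_peaks,
                        subject_id=subject_id, provenance=provenance)
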