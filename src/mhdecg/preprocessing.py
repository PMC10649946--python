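"""Resampling, zero-phase filtering, and R-anchored beat segmentation.

The pipeline-wide working rate is 500 Hz.  Beats are cut into equal-sized
0.5 s windows with the annotated R-peak placed at 25% of the window, i.e.
sample 62 of a 250-sample segment.  Filtering applies, in order, a
Butterworth band-pass, an IIR notch at the power-line frequency, and a
Butterworth high-pass, each forward-backward (zero phase).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import EcgRecording, ValidationError, VcgRecording

logger = logging.getLogger(__name__)

#: Working sampling rate of the distortion pipeline (Hz).
WORKING_FS = 500.0
#: Window length in seconds and the fraction of it preceding the R-peak.
SEGMENT_SECONDS = 0.5
R_FRACTION = 0.25


def r_offset_samples(segment_length: int, r_fraction: float = R_FRACTION) -> int:
    """R-peak offset inside a window: floor(r_fraction * L) (62 for L=250)."""
    return math.floor(r_fraction * segment_length)


@dataclass
class FilterSpec:
    """Filter chain parameters: band-pass order/range, notch, high-pass."""

    bandpass_order: int = 3
    bandpass_range: tuple[float, float] = (0.05, 150.0)
    notch_freq: float = 50.0
    notch_q: float = 30.0
    highpass_cutoff: float = 0.05
    highpass_order: int = 3

    def validate(self, fs: float) -> None:
        low, high = self.bandpass_range
        nyq = fs / 2.0
        if not (0 < low < high):
            raise ValidationError(f"invalid band-pass range {self.bandpass_range}")
        if high >= nyq:
            raise ValidationError(
                f"band-pass upper edge {high} Hz >= Nyquist {nyq} Hz")
        if self.notch_freq >= nyq:
            raise ValidationError(f"notch frequency {self.notch_freq} Hz >= Nyquist")
        if not (0 < self.highpass_cutoff < nyq):
            raise ValidationError(f"invalid high-pass cutoff {self.highpass_cutoff}")


@dataclass
class BeatSegment:
    """A fixed-length window around one annotated beat.

    ``window`` is L x k (samples x leads/components); the R-peak sits at
    ``r_offset`` samples from the window start.
    """

    window: np.ndarray
    fs: float
    r_offset: int
    source_subject: str = ""
    source_beat_index: int = -1
    lead_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.window = np.atleast_2d(np.asarray(self.window, dtype=float))

    @property
    def length(self) -> int:
        return self.window.shape[0]

    @property
    def n_channels(self) -> int:
        return self.window.shape[1]


def resample_recording(rec, target_fs: float):
    """Polyphase rational resampling of every lead; R-peaks are remapped
    arithmetically by ``target_fs/fs`` (rounded to nearest), not re-detected."""
    if target_fs <= 0:
        raise ValidationError(f"target_fs must be positive, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(rec.signal, up, down, axis=0)
    n_out = out.shape[0]
    peaks = np.rint(rec.r_peaks * (target_fs / rec.fs)).astype(np.int64)
    peaks = peaks[peaks < n_out]
    return rec.with_(signal=out, fs=float(target_fs), r_peaks=peaks)


def _sos_chain(spec: FilterSpec, fs: float):
    low, high = spec.bandpass_range
    band = sps.butter(spec.bandpass_order, [low, high], btype="bandpass",
                      fs=fs, output="sos")
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    notch = sps.tf2sos(b, a)
    highp = sps.butter(spec.highpass_order, spec.highpass_cutoff,
                       btype="highpass", fs=fs, output="sos")
    return [band, notch, highp]


def apply_filters(rec, spec: FilterSpec | None = None):
    """Zero-phase band-pass -> notch -> high-pass on every lead.

    R-peak annotations are unchanged: forward-backward filtering introduces
    no group delay.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    x = rec.signal
    for sos in _sos_chain(spec, rec.fs):
        x = sps.sosfiltfilt(sos, x, axis=0)
    return rec.with_(signal=np.ascontiguousarray(x))


def extract_beat_segments(rec: EcgRecording | VcgRecording,
                          segment_seconds: float = SEGMENT_SECONDS,
                          r_fraction: float = R_FRACTION) -> list[BeatSegment]:
    """Cut one fixed-length window per annotated R-peak.

    The window spans ``[r - r_offset, r - r_offset + L)``; beats whose window
    would cross either edge of the recording are skipped (and counted in the
    log).  Returns an empty list when no beat fits.
    """
    L = round(segment_seconds * rec.fs)
    off = r_offset_samples(L, r_fraction)
    names = (rec.lead_names if isinstance(rec, EcgRecording)
             else rec.component_names)
    segments: list[BeatSegment] = []
    skipped = 0
    for k, r in enumerate(rec.r_peaks):
        start = int(r) - off
        if start < 0 or start + L > rec.n_samples:
            skipped += 1
            continue
        segments.append(BeatSegment(
            window=rec.signal[start:start + L].copy(), fs=rec.fs, r_offset=off,
            source_subject=rec.subject_id, source_beat_index=k,
            lead_names=tuple(names)))
    if skipped:
        logger.info("extract_beat_segments: skipped %d edge beat(s) of %d",
                    skipped, len(rec.r_peaks))
    return segments
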