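"""Windowed Fourier analysis of per-base arrays.

Pipeline, applied per chromosome to a reference-base probability array or
to a GC/AT indicator array:

1. split the chromosome into adjacent 1 Mb segments (trailing remainder
   dropped); exclude segments where more than 10% of positions are
   disqualified;
2. discrete-Fourier transform each segment; keep one-sided coefficient
   magnitudes at integer frequencies (cycles per segment);
3. slide a window of 1,000 consecutive frequencies in steps of 100 over
   frequencies 1..L/2 (DC always excluded) and record the Euclidean norm
   of the coefficient magnitudes in each window — the square root of the
   windowed power ("cumulative power spectrum in a running window");
4. convert frequency windows to base-pair period windows: a window
   [f0, f0+W) of a length-L segment spans periods L/(f0+W)..L/f0, with
   the peak conventionally assigned to the mid-frequency period
   L/(f0+W/2).

Shuffle and randomization controls destroy (fully or partially) the phase
coherence of a planted periodic signal and are used to rule out
computational artifacts.  Peak identification itself is by inspection of
the exported spectra; only an argmax-window helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import C, G, N
from .sequences import GenomeSequence, PositionMask

__all__ = [
    "SegmentSet",
    "WindowedSpectrum",
    "PeriodWindow",
    "segment_chromosome",
    "gc_indicator",
    "fourier_magnitudes",
    "windowed_norm_spectrum",
    "frequency_window_to_periods",
    "shuffle_control",
    "randomize_control",
    "peak_window",
]

DEFAULT_SEGMENT_LENGTH = 1_000_000
DEFAULT_WINDOW = 1_000
DEFAULT_STEP = 100
DEFAULT_MAX_DISQUALIFIED = 0.10


@dataclass
class SegmentSet:
    """Adjacent fixed-length segments of one chromosome with quality flags."""

    segment_length: int
    starts: np.ndarray
    quality_fraction: np.ndarray  # fraction of disqualified positions
    included: np.ndarray

    @property
    def n_segments(self) -> int:
        return int(self.starts.size)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start": self.starts,
            "end": self.starts + self.segment_length,
            "disqualified_fraction": self.quality_fraction,
            "included": self.included,
        })


def segment_chromosome(length: int, mask, segment_length: int = DEFAULT_SEGMENT_LENGTH,
                       max_disqualified: float = DEFAULT_MAX_DISQUALIFIED) -> SegmentSet:
    """Adjacent segments from position 0; the sub-segment remainder is dropped.

    A segment is excluded when *strictly more than* ``max_disqualified``
    of its positions are disqualified (a fraction of exactly 10% is kept).
    ``mask`` may be a PositionMask, a boolean disqualification array, or
    None (no disqualified positions).
    """
    n = length // segment_length
    starts = np.arange(n, dtype=np.int64) * segment_length
    if mask is None:
        frac = np.zeros(n)
    else:
        disq = mask.disqualified if isinstance(mask, PositionMask) else np.asarray(mask, dtype=bool)
        cums = np.concatenate([[0], np.cumsum(disq[: n * segment_length])])
        frac = (cums[starts + segment_length] - cums[starts]) / segment_length
    return SegmentSet(segment_length, starts, frac, frac <= max_disqualified)


def gc_indicator(genome: GenomeSequence, start: int = 0, end: int | None = None):
    """(indicator, n_flags): 1.0 at G/C, 0.0 at A/T; N positions emit 0 and
    are flagged (segment inclusion already accounts for the N load)."""
    end = len(genome) if end is None else end
    if not 0 <= start <= end <= len(genome):
        raise ValueError("window outside the genome")
    codes = genome.codes[start:end]
    indicator = ((codes == G) | (codes == C)).astype(float)
    return indicator, codes == N


def fourier_magnitudes(values) -> np.ndarray:
    """One-sided DFT coefficient magnitudes at frequencies 0..floor(L/2).

    Raw unnormalized DFT amplitudes: a pure cosine of amplitude a and
    integer frequency f contributes magnitude a*L/2 at f.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError("input contains non-finite values")
    return np.abs(np.fft.rfft(values))


@dataclass
class WindowedSpectrum:
    """Running-window Euclidean norms of Fourier magnitudes for one segment."""

    start_frequencies: np.ndarray
    norms: np.ndarray
    window: int
    step: int
    segment_length: int | None = None
    segment_start: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"f_start": self.start_frequencies, "norm": self.norms})
        if self.segment_length:
            pw = [frequency_window_to_periods(int(f), self.window, self.segment_length)
                  for f in self.start_frequencies]
            df["period_low"] = [p.period_low for p in pw]
            df["period_mid"] = [p.period_mid for p in pw]
            df["period_high"] = [p.period_high for p in pw]
        return df


def windowed_norm_spectrum(magnitudes, window: int = DEFAULT_WINDOW,
                           step: int = DEFAULT_STEP, squared: bool = False,
                           segment_length: int | None = None,
                           segment_start: int | None = None) -> WindowedSpectrum:
    """Norm of the Fourier magnitudes in sliding frequency windows.

    Windows start at frequencies 1, 1+step, ...; frequency 0 (the segment
    mean) is never included.  The norm is Euclidean — the square root of
    the summed power in the window — or the plain summed power with
    ``squared=True``.  A window extending past the top frequency is
    truncated; if even the first window is truncated a single shortened
    window is returned.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    mags = np.asarray(magnitudes, dtype=float)
    f_max = mags.size - 1  # highest available frequency
    if f_max < 1:
        raise ValueError("no non-DC frequencies available")
    power = mags ** 2
    cums = np.concatenate([[0.0], np.cumsum(power)])
    starts = np.arange(1, max(f_max - window + 2, 2), step, dtype=np.int64)
    ends = np.minimum(starts + window, f_max + 1)
    sums = cums[ends] - cums[starts]
    norms = sums if squared else np.sqrt(sums)
    if segment_length is None:
        segment_length = mags.size * 2 - 2 if mags.size > 1 else None
    return WindowedSpectrum(starts, norms, window, step, segment_length, segment_start)


@dataclass
class PeriodWindow:
    """Base-pair periods spanned by a frequency window of a length-L segment."""

    f_start: int
    width: int
    segment_length: int
    period_low: int = field(init=False)
    period_high: int = field(init=False)
    period_mid: int = field(init=False)

    def __post_init__(self) -> None:
        L = self.segment_length
        self.period_low = round(L / (self.f_start + self.width))
        self.period_high = round(L / self.f_start)
        self.period_mid = round(L / (self.f_start + self.width / 2))


def frequency_window_to_periods(f_start: int, width: int, segment_length: int) -> PeriodWindow:
    """Periods (bp, nearest integer) for frequencies [f_start, f_start+width].

    period_high = L/f_start, period_low = L/(f_start+width), and the
    conventional single period assigned to the window is the one at its
    mid frequency, L/(f_start + width/2).
    """
    if f_start < 1:
        raise ValueError("f_start must be >= 1")
    return PeriodWindow(f_start, width, segment_length)


def shuffle_control(values, seed: int = 0) -> np.ndarray:
    """Uniform random permutation of the array (value multiset preserved)."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(values, dtype=float))


def randomize_control(values, positions, seed: int = 0) -> np.ndarray:
    """Replace entries at ``positions`` with independent Uniform(0,1) draws."""
    values = np.array(values, dtype=float, copy=True)
    positions = np.asarray(positions, dtype=np.int64)
    rng = np.random.default_rng(seed)
    values[positions] = rng.random(positions.size)
    return values


def peak_window(spectrum: WindowedSpectrum) -> tuple[int, float]:
    """(start frequency, norm) of the window with the largest norm."""
    i = int(np.argmax(spectrum.norms))
    return int(spectrum.start_frequencies[i]), float(spectrum.norms[i])
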