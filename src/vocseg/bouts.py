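"""Song-bout detection and syllable extraction.

Bouts are found by silence annotation: stretches where the intensity envelope
stays more than 45 dB below its peak for at least one second are silence, the
rest are vocalizations, and vocalizations longer than 2.5 s are song. A song
is band-filtered (Hann-edged 1-15 kHz pass band) and split into syllables at
gaps where the linear RMS envelope (25 ms window, 5 ms step) dips below 1/6 of
the whole-song RMS for longer than 10 ms. All thresholds are relative, so the
boundaries are invariant to global gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annot_io import Interval, IntervalTier, Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "BoutConfig",
    "detect_bouts",
    "band_filter",
    "extract_syllables",
    "classify_complexity",
]


@dataclass(frozen=True)
class BoutConfig:
    silence_threshold_db: float = -45.0  # relative to peak intensity
    min_silence_s: float = 1.0
    song_min_s: float = 2.5
    band_low: float = 1000.0
    band_high: float = 15000.0
    band_smooth: float = 100.0
    env_window_s: float = 0.025
    env_step_s: float = 0.005
    dip_ratio: float = 1.0 / 6.0
    min_dip_s: float = 0.010

    def __post_init__(self):
        if not 0 < self.dip_ratio < 1:
            raise ValueError("dip_ratio must lie in (0, 1)")
        if self.env_step_s > self.env_window_s:
            raise ValueError("env_step_s must not exceed env_window_s")
        if self.band_low >= self.band_high:
            raise ValueError("band_low must be below band_high")


def _envelope(wav: Waveform, window_s: float, step_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear RMS envelope (Hann-tapered windows): (frame centers, rms)."""
    win = max(2, int(round(window_s * wav.rate)))
    hop = max(1, int(round(step_s * wav.rate)))
    n = len(wav.samples)
    if n < win:
        raise ValueError(f"signal shorter ({n / wav.rate:.4f} s) than envelope window")
    starts = np.arange(0, n - win + 1, hop)
    idx = starts[:, None] + np.arange(win)[None, :]
    w = np.hanning(win)
    rms = np.sqrt((wav.samples[idx] ** 2 * w**2).sum(axis=1) / (w**2).sum())
    centers = wav.start_time + (starts + win / 2.0) / wav.rate
    return centers, rms


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def _refine_crossing(
    centers: np.ndarray, values: np.ndarray, i: int, j: int, level: float
) -> float:
    """Linear interpolation of the level crossing between envelope frames i, j."""
    vi, vj = values[i], values[j]
    if vj == vi:
        return float(0.5 * (centers[i] + centers[j]))
    frac = (level - vi) / (vj - vi)
    frac = float(np.clip(frac, 0.0, 1.0))
    return float(centers[i] + frac * (centers[j] - centers[i]))


def detect_bouts(wav: Waveform, cfg: BoutConfig | None = None) -> IntervalTier:
    """Label the recording as silence / vocalization / song intervals.

    Silence = intensity more than |silence_threshold_db| below the peak of the
    intensity envelope for at least min_silence_s; the complement is
    vocalization, relabeled song when longer than song_min_s.
    """
    cfg = cfg or BoutConfig()
    centers, rms = _envelope(wav, cfg.env_window_s, cfg.env_step_s)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.maximum(rms, 1e-12))
    # -100 dB re full scale is treated as absolute silence regardless of peak,
    # so an all-quiet recording does not become one long "vocalization"
    level = max(db.max() + cfg.silence_threshold_db, -100.0)
    quiet = db < level
    t0, t1 = wav.start_time, wav.end_time

    silences: list[tuple[float, float]] = []
    for i, j in _runs(quiet):
        start = t0 if i == 0 else _refine_crossing(centers, db, i - 1, i, level)
        end = t1 if j == len(quiet) - 1 else _refine_crossing(centers, db, j, j + 1, level)
        if end - start >= cfg.min_silence_s:
            silences.append((start, end))

    intervals: list[Interval] = []
    cursor = t0
    for s, e in silences:
        if s > cursor + 1e-9:
            dur = s - cursor
            intervals.append(Interval(cursor, s, "song" if dur > cfg.song_min_s else "vocalization"))
        intervals.append(Interval(cursor if s <= cursor else s, e, "silence"))
        cursor = e
    if t1 > cursor + 1e-9:
        dur = t1 - cursor
        intervals.append(Interval(cursor, t1, "song" if dur > cfg.song_min_s else "vocalization"))
    return IntervalTier("bouts", intervals)


def band_filter(wav: Waveform, cfg: BoutConfig | None = None) -> Waveform:
    """Frequency-domain Hann-edged band-pass (band_low-band_high, smoothed edges).

    The gain ramps from 0 to 1 over band_smooth Hz around each band edge with a
    raised-cosine shape; DC is always removed. Output length equals input.
    """
    cfg = cfg or BoutConfig()
    nyq = wav.rate / 2.0
    if cfg.band_high >= nyq:
        raise ValueError(
            f"band_high ({cfg.band_high} Hz) must be below Nyquist ({nyq} Hz); "
            "resample the recording or lower the band"
        )
    n = len(wav.samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / wav.rate)
    gain = np.zeros_like(freqs)
    s = cfg.band_smooth
    lo, hi = cfg.band_low, cfg.band_high
    inside = (freqs >= lo + s / 2) & (freqs <= hi - s / 2)
    gain[inside] = 1.0
    rise = (freqs > lo - s / 2) & (freqs < lo + s / 2)
    gain[rise] = 0.5 * (1 + np.sin(np.pi * (freqs[rise] - lo) / s))
    fall = (freqs > hi - s / 2) & (freqs < hi + s / 2)
    gain[fall] = 0.5 * (1 - np.sin(np.pi * (freqs[fall] - hi) / s))
    gain[freqs == 0] = 0.0
    out = np.fft.irfft(np.fft.rfft(wav.samples) * gain, n)
    return Waveform(out, wav.rate, wav.start_time)


def extract_syllables(song: Waveform, cfg: BoutConfig | None = None) -> IntervalTier:
    """Split a (band-filtered) song into syllables at RMS-envelope dips.

    Gaps are maximal stretches where the linear RMS envelope stays below
    dip_ratio x whole-song RMS for longer than min_dip_s; their complements are
    the syllables, labeled syll_001, ... Boundary times are refined to the
    envelope's threshold crossings by linear interpolation. Syllables shorter
    than one envelope step are discarded.
    """
    cfg = cfg or BoutConfig()
    centers, rms = _envelope(song, cfg.env_window_s, cfg.env_step_s)
    song_rms = float(np.sqrt(np.mean(song.samples**2)))
    level = cfg.dip_ratio * song_rms
    low = rms < level
    t0, t1 = song.start_time, song.end_time

    gaps: list[tuple[float, float]] = []
    for i, j in _runs(low):
        start = t0 if i == 0 else _refine_crossing(centers, rms, i - 1, i, level)
        end = t1 if j == len(low) - 1 else _refine_crossing(centers, rms, j, j + 1, level)
        if end - start > cfg.min_dip_s:
            gaps.append((start, end))

    intervals: list[Interval] = []
    cursor = t0
    k = 0
    for s, e in gaps + [(t1, t1)]:
        if s - cursor > cfg.env_step_s:
            k += 1
            intervals.append(Interval(cursor, s, f"syll_{k:03d}"))
        cursor = max(cursor, e)
    return IntervalTier("syllables", intervals)


def classify_complexity(syll: Interval, segments: IntervalTier, min_segments: int = 3) -> str:
    """'complex' iff the syllable holds at least min_segments segments.

    A deliberately simple complexity heuristic used as pipeline plumbing for
    separating single-gesture syllables from compound ones.
    """
    inside = [
        s
        for s in segments.labeled()
        if s.start >= syll.start - 1e-9 and s.end <= syll.end + 1e-9
    ]
    return "complex" if len(inside) >= min_segments else "simple"
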