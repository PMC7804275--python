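"""Acoustic measurement tracks at windows and steps scaled by species minimum F0.

Three tracks are computed on one shared frame grid so per-frame deltas are
aligned across channels: intensity (dB re full scale), fundamental frequency
(autocorrelation, Hz, with a voiced flag) and Wiener entropy (log ratio of
geometric to arithmetic mean of the power spectrum; 0 for white noise,
large-negative for a pure tone).

All window and step durations derive from the species minimum fundamental
frequency: the correlation window (and buffer) is 0.5/min_f0, the frame step a
quarter of that window, the intensity/entropy window 1/min_f0 and the pitch
window 3/min_f0 (three periods at the pitch floor, the minimum for a reliable
autocorrelation peak). A 50 Hz floor therefore gives the 10 ms correlation
window / buffer used for human speech; 400 Hz gives 1.25 ms for budgerigars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annot_io import Waveform

__all__ = [
    "SpeciesProfile",
    "HUMAN",
    "BUDGERIGAR",
    "FeatureTrack",
    "frame_times",
    "intensity_track",
    "f0_track",
    "wiener_entropy_track",
    "compute_tracks",
    "wiener_entropy_of_power",
    "INTENSITY_FLOOR_DB",
]

INTENSITY_FLOOR_DB = -100.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Species scaling for the segmenter: everything follows from min_f0.

    Explicit overrides for the derived durations are possible but rarely needed.
    """

    min_f0: float
    max_f0: float | None = None  # default 15 * min_f0, capped at 0.45 * rate
    voicing_threshold: float = 0.45
    we_smooth_bins: int = 4  # adjacent power-spectrum bins averaged before WE
    corr_window_override: float | None = None
    step_override: float | None = None
    intensity_window_override: float | None = None
    pitch_window_override: float | None = None

    def __post_init__(self):
        if not self.min_f0 > 0:
            raise ValueError("min_f0 must be positive")

    @property
    def corr_window(self) -> float:
        return self.corr_window_override or 0.5 / self.min_f0

    @property
    def buffer(self) -> float:
        return self.corr_window

    @property
    def step(self) -> float:
        return self.step_override or 0.25 / self.min_f0

    @property
    def intensity_window(self) -> float:
        return self.intensity_window_override or 1.0 / self.min_f0

    @property
    def pitch_window(self) -> float:
        return self.pitch_window_override or 3.0 / self.min_f0

    def max_f0_at(self, rate: float) -> float:
        ceiling = 0.45 * rate
        return min(self.max_f0 if self.max_f0 else 15.0 * self.min_f0, ceiling)


HUMAN = SpeciesProfile(min_f0=50.0)
BUDGERIGAR = SpeciesProfile(min_f0=400.0)


@dataclass
class FeatureTrack:
    """Time-stamped series of one acoustic measurement at a regular step."""

    kind: str  # intensity_db | f0_hz | wiener_entropy
    times: np.ndarray  # frame centers, seconds
    values: np.ndarray  # NaN where undefined
    voiced: np.ndarray | None = None  # f0 only
    step: float = field(default=0.0)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("frame times must have a constant step")
            if self.step == 0.0:
                self.step = float(steps[0])

    def __len__(self):
        return len(self.times)

    def to_table(self) -> str:
        """Tab-separated (time, value[, voiced]) export for inspection."""
        lines = ["time\tvalue" + ("\tvoiced" if self.voiced is not None else "")]
        for i, (t, v) in enumerate(zip(self.times, self.values)):
            row = f"{t:.6f}\t{v:.6f}"
            if self.voiced is not None:
                row += f"\t{int(self.voiced[i])}"
            lines.append(row)
        return "\n".join(lines) + "\n"


def frame_times(wav: Waveform, profile: SpeciesProfile) -> np.ndarray:
    """Shared frame-center grid: centers where every analysis window fits."""
    half = max(profile.pitch_window, profile.intensity_window) / 2.0
    n = int(np.floor((wav.duration - 2.0 * half) / profile.step)) + 1
    if n < 1:
        raise ValueError(
            f"waveform too short ({wav.duration:.4f} s) for the analysis windows "
            f"({2 * half:.4f} s needed)"
        )
    return wav.start_time + half + profile.step * np.arange(n)


def _frames(wav: Waveform, centers: np.ndarray, window_s: float) -> np.ndarray:
    """(n_frames, win_len) sample matrix around each frame center."""
    win = max(2, int(round(window_s * wav.rate)))
    rel = (centers - wav.start_time) * wav.rate
    starts = np.round(rel - win / 2.0).astype(int)
    starts = np.clip(starts, 0, max(0, len(wav.samples) - win))
    idx = starts[:, None] + np.arange(win)[None, :]
    return wav.samples[idx]


def intensity_track(
    wav: Waveform, profile: SpeciesProfile, centers: np.ndarray | None = None
) -> FeatureTrack:
    """Windowed-RMS intensity in dB re digital full scale (Hann-tapered)."""
    if centers is None:
        centers = frame_times(wav, profile)
    frames = _frames(wav, centers, profile.intensity_window)
    w = np.hanning(frames.shape[1])
    rms = np.sqrt((frames**2 * w**2).sum(axis=1) / (w**2).sum())
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    db = np.maximum(db, INTENSITY_FLOOR_DB)
    return FeatureTrack("intensity_db", centers, db, step=profile.step)


def _parabolic_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location/height by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return i + d, b - 0.25 * (a - c) * d


def f0_track(
    wav: Waveform, profile: SpeciesProfile, centers: np.ndarray | None = None
) -> FeatureTrack:
    """Autocorrelation pitch per frame, searched in [min_f0, max_f0].

    A frame is voiced when the bias-corrected normalized autocorrelation peak
    reaches the voicing threshold. Among candidate lags whose peak is within
    90% of the best, the shortest lag wins (guards against octave-down errors
    on strongly harmonic signals). Unvoiced frames carry NaN.
    """
    if centers is None:
        centers = frame_times(wav, profile)
    frames = _frames(wav, centers, profile.pitch_window)
    n = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    max_f0 = profile.max_f0_at(wav.rate)
    lag_min = max(2, int(np.floor(wav.rate / max_f0)))
    lag_max = min(n - 1, int(np.ceil(wav.rate / profile.min_f0)))
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec.real**2 + spec.imag**2, nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0]
    silent = r0 < (1e-6) ** 2 * n
    r0 = np.where(silent, 1.0, r0)
    lags = np.arange(ac.shape[1])
    # mild bias correction for the shrinking overlap at larger lags
    rn = ac / (r0[:, None] * np.maximum(1.0 - lags[None, :] / n, 1e-6))

    f0 = np.full(len(centers), np.nan)
    voiced = np.zeros(len(centers), dtype=bool)
    band = rn[:, lag_min : lag_max + 1]
    for i in range(len(centers)):
        if silent[i]:
            continue
        r = band[i]
        # local maxima within the search band
        interior = np.zeros(len(r), dtype=bool)
        interior[1:-1] = (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])
        if not interior.any():
            continue
        peaks = np.flatnonzero(interior)
        best = peaks[np.argmax(r[peaks])]
        if r[best] < profile.voicing_threshold:
            continue
        good = peaks[r[peaks] >= 0.9 * r[best]]
        chosen = int(good.min())
        lag_f, _ = _parabolic_peak(rn[i], chosen + lag_min)
        f0[i] = wav.rate / lag_f
        voiced[i] = True
    return FeatureTrack("f0_hz", centers, f0, voiced=voiced, step=profile.step)


def wiener_entropy_of_power(power: np.ndarray) -> float:
    """ln(geometric mean / arithmetic mean) of a power spectrum; <= 0, 0 iff flat."""
    p = np.asarray(power, dtype=float)
    p = p[p >= 0]
    if len(p) == 0 or p.sum() <= 0:
        return np.nan
    tiny = p[p > 0].max() * 1e-300
    logs = np.log(np.maximum(p, tiny))
    return float(logs.mean() - np.log(p.mean()))


def _block_average(power: np.ndarray, block: int) -> np.ndarray:
    if block <= 1:
        return power
    nb = power.shape[-1] // block
    if nb < 2:
        return power
    return power[..., : nb * block].reshape(*power.shape[:-1], nb, block).mean(axis=-1)


def wiener_entropy_track(
    wav: Waveform, profile: SpeciesProfile, centers: np.ndarray | None = None
) -> FeatureTrack:
    """Per-frame Wiener entropy on the Hann-windowed power spectrum (DC excluded).

    Adjacent bins are block-averaged (profile.we_smooth_bins) before the
    geometric/arithmetic-mean ratio, which removes most of the chi-square bias
    of the raw periodogram so white noise sits near the flat-spectrum limit 0.
    """
    if centers is None:
        centers = frame_times(wav, profile)
    frames = _frames(wav, centers, profile.intensity_window)
    w = np.hanning(frames.shape[1])
    power = np.abs(np.fft.rfft(frames * w, axis=1)) ** 2
    power = power[:, 1:]  # exclude DC
    power = _block_average(power, profile.we_smooth_bins)
    total = power.sum(axis=1)
    values = np.full(len(centers), np.nan)
    ok = total > 0
    if ok.any():
        p = power[ok]
        tiny = p.max(axis=1, keepdims=True) * 1e-300
        logs = np.log(np.maximum(p, tiny))
        values[ok] = logs.mean(axis=1) - np.log(p.mean(axis=1))
    return FeatureTrack("wiener_entropy", centers, values, step=profile.step)


def compute_tracks(
    wav: Waveform, profile: SpeciesProfile
) -> tuple[FeatureTrack, FeatureTrack, FeatureTrack]:
    """Intensity, F0 and Wiener entropy on one shared frame grid."""
    centers = frame_times(wav, profile)
    return (
        intensity_track(wav, profile, centers),
        f0_track(wav, profile, centers),
        wiener_entropy_track(wav, profile, centers),
    )
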