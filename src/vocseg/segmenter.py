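"""Segment boundary detection at rapid acoustic transitions.

A segment boundary is placed at a frame edge where intensity, F0 or Wiener
entropy changes faster than a large per-frame threshold (pass 1), or where a
smaller intensity change co-occurs — within one correlation window — with a
small-or-larger change in F0 or Wiener entropy (pass 2). F0/WE co-changes are
never combined with each other: a change in F0 necessarily perturbs Wiener
entropy, so such a correlation carries no extra evidence. A buffer equal to
the correlation window keeps any two admitted boundaries at least
0.5/min_f0 s apart, and pass-1 (stronger-evidence) candidates are admitted
before pass-2 candidates, earliest first within each pass.

Default thresholds: large 6 dB / 190 Hz / 150 (intensity, F0, Wiener entropy)
per frame; small 2 dB / 7 Hz / 90 per frame. Intensity and F0 deltas are
absolute in their stated units by default, Wiener entropy is a percent change
(its thresholds are unitless); every channel's mode is switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annot_io import Interval, IntervalTier, Waveform
from .tracks import FeatureTrack, SpeciesProfile, compute_tracks

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionThresholds",
    "Boundary",
    "BoundarySet",
    "channel_deltas",
    "detect_boundaries",
    "segment_unit",
    "segment_corpus",
]


@dataclass(frozen=True)
class TransitionThresholds:
    large_intensity: float = 6.0  # dB per frame
    large_f0: float = 190.0  # Hz per frame
    large_we: float = 150.0  # percent per frame
    small_intensity: float = 2.0
    small_f0: float = 7.0
    small_we: float = 90.0
    intensity_mode: str = "absolute"
    f0_mode: str = "absolute"
    we_mode: str = "percent"
    voicing_flip_is_large_f0: bool = True

    def __post_init__(self):
        for small, large, name in (
            (self.small_intensity, self.large_intensity, "intensity"),
            (self.small_f0, self.large_f0, "f0"),
            (self.small_we, self.large_we, "we"),
        ):
            if not (0 < small < large):
                raise ValueError(f"{name}: need 0 < small < large thresholds")


@dataclass(frozen=True)
class Boundary:
    time: float
    provenance: str  # "large:<channel>" or "correlated:intensity+<channel>"


@dataclass
class BoundarySet:
    boundaries: list[Boundary] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([b.time for b in self.boundaries])

    def __len__(self):
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)


_EPS = 1e-6


def channel_deltas(track: FeatureTrack, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge deltas between consecutive frames.

    Returns (edge_times, deltas, valid). Edge i sits midway between frames i
    and i+1. Absolute mode: |x[i+1] - x[i]|; percent mode:
    100 |x[i+1] - x[i]| / max(|x[i]|, eps). Edges touching an undefined frame
    (NaN, e.g. unvoiced F0) are invalid and carry NaN.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 frames for deltas")
    x = track.values
    edge_times = 0.5 * (track.times[:-1] + track.times[1:])
    diff = np.abs(x[1:] - x[:-1])
    if mode == "absolute":
        deltas = diff
    elif mode == "percent":
        deltas = 100.0 * diff / np.maximum(np.abs(x[:-1]), _EPS)
    else:
        raise ValueError(f"unknown delta mode {mode!r}")
    valid = np.isfinite(x[:-1]) & np.isfinite(x[1:])
    deltas = np.where(valid, deltas, np.nan)
    return edge_times, deltas, valid


def _voicing_flips(track: FeatureTrack) -> np.ndarray:
    if track.voiced is None:
        return np.zeros(len(track) - 1, dtype=bool)
    v = track.voiced.astype(bool)
    return v[:-1] != v[1:]


def _local_maxima(d: np.ndarray) -> np.ndarray:
    """Edges where the delta series peaks (plateaus count once, at their left edge).

    The predicate is threshold-free, so raising a threshold can only remove
    candidates, never create new ones.
    """
    x = np.where(np.isfinite(d), d, -np.inf)
    n = len(x)
    out = np.zeros(n, dtype=bool)
    if n == 1:
        return np.isfinite(d)
    left_up = np.empty(n, dtype=bool)
    left_up[0] = True
    left_up[1:] = x[1:] > x[:-1]
    right_down = np.empty(n, dtype=bool)
    right_down[-1] = True
    right_down[:-1] = x[:-1] >= x[1:]
    out = left_up & right_down & np.isfinite(d)
    return out


def _dedupe_flips(flips: np.ndarray, edges: np.ndarray, radius: float) -> np.ndarray:
    """Collapse voicing-flag chatter: flips closer than `radius` to a previous
    kept flip are the same transition event; keep the first of each run."""
    kept = np.zeros_like(flips)
    last = -np.inf
    for i in np.flatnonzero(flips):
        if edges[i] - last >= radius:
            kept[i] = True
            last = edges[i]
    return kept


def detect_boundaries(
    intensity: FeatureTrack,
    f0: FeatureTrack,
    we: FeatureTrack,
    profile: SpeciesProfile,
    thr: TransitionThresholds | None = None,
) -> BoundarySet:
    """Two-pass transition detection with a minimum-separation buffer.

    Pass 1 takes, per channel, the local maxima of the delta series that exceed
    the channel's large threshold (one acoustic transition smears over several
    adjacent frame edges; its delta profile peaks once), plus voicing
    onsets/offsets when flagged as large F0 events (flag chatter within half a
    pitch window is collapsed to its first flip). Pass 2 takes intensity-delta
    peaks between the small and large thresholds that are supported by a
    small-or-larger F0 or Wiener-entropy change within +-corr_window.

    Admission: every candidate carries the temporal uncertainty of its sourcing
    evidence - half the channel's analysis window (the pitch channel is blunter
    than intensity/entropy), plus the correlation window for pass-2 candidates,
    whose support is only localized to within that window. Pass-1 candidates
    are admitted sharpest channel first (time order within a channel), then
    pass-2 in time order; a candidate is dropped when an admitted boundary lies
    within max(buffer, its own uncertainty). Admitted boundaries therefore
    always sit >= buffer apart.
    """
    thr = thr or TransitionThresholds()
    grids = [intensity.times, f0.times, we.times]
    if not all(len(g) == len(grids[0]) for g in grids) or not all(
        np.allclose(g, grids[0], atol=1e-9) for g in grids[1:]
    ):
        raise ValueError("tracks must share one frame grid")

    edges, d_int, _ = channel_deltas(intensity, thr.intensity_mode)
    _, d_f0, _ = channel_deltas(f0, thr.f0_mode)
    _, d_we, _ = channel_deltas(we, thr.we_mode)
    flips = _voicing_flips(f0)

    u_sharp = profile.intensity_window / 2.0
    u_pitch = profile.pitch_window / 2.0

    with np.errstate(invalid="ignore"):
        large_int = _local_maxima(d_int) & (d_int > thr.large_intensity)
        large_f0 = _local_maxima(d_f0) & (d_f0 > thr.large_f0)
        large_we = _local_maxima(d_we) & (d_we > thr.large_we)
        small_f0_any = d_f0 > thr.small_f0
        small_we_any = d_we > thr.small_we
        small_int = (
            _local_maxima(d_int) & (d_int > thr.small_intensity) & ~(d_int > thr.large_intensity)
        )
    if thr.voicing_flip_is_large_f0:
        flips_kept = _dedupe_flips(flips, edges, u_pitch)
    else:
        flips_kept = np.zeros_like(flips)

    # pass 2: small intensity peak supported by any F0 or WE change >= small
    f0_support = small_f0_any
    if thr.voicing_flip_is_large_f0:
        f0_support = f0_support | flips
    win = profile.corr_window + 1e-9
    f_sup = np.flatnonzero(f0_support)
    w_sup = np.flatnonzero(small_we_any)
    pass2 = []
    for i in np.flatnonzero(small_int):
        has_f0 = bool(len(f_sup) and np.any(np.abs(edges[f_sup] - edges[i]) <= win))
        has_we = bool(len(w_sup) and np.any(np.abs(edges[w_sup] - edges[i]) <= win))
        if not (has_f0 or has_we):
            continue
        chans = (["f0"] if has_f0 else []) + (["we"] if has_we else [])
        # the candidate is only localized to the correlation window plus the
        # blur of its sharpest supporting channel
        u2 = profile.corr_window + (u_sharp if has_we else u_pitch)
        pass2.append((int(i), u2, "correlated:intensity+" + "+".join(chans)))

    # candidate queue: (pass, uncertainty, time, index, provenance)
    queue = []
    for i in np.flatnonzero(large_int):
        queue.append((1, u_sharp, edges[i], int(i), "large:intensity"))
    for i in np.flatnonzero(large_we):
        queue.append((1, u_sharp, edges[i], int(i), "large:we"))
    for i in np.flatnonzero(large_f0 | flips_kept):
        prov = "large:f0" + ("+flip" if flips_kept[i] else "")
        queue.append((1, u_pitch, edges[i], int(i), prov))
    for i, u2, prov in pass2:
        queue.append((2, u2, edges[i], int(i), prov))
    queue.sort(key=lambda c: (c[0], c[1], c[2]))

    admitted: list[Boundary] = []
    for _pass, u, t, _i, prov in queue:
        radius = max(profile.buffer, u)
        if any(abs(b.time - t) < radius - 1e-12 for b in admitted):
            continue
        admitted.append(Boundary(float(t), prov))
        logger.debug("boundary at %.6f s (%s)", t, prov)
    admitted.sort(key=lambda b: b.time)
    return BoundarySet(admitted)


def segment_unit(
    wav: Waveform,
    unit: Interval,
    profile: SpeciesProfile,
    thr: TransitionThresholds | None = None,
    name_prefix: str = "seg",
) -> IntervalTier:
    """Divide one silence-bounded unit into segments at detected transitions.

    Tracks are computed on the unit's audio only (unit-relative measures cannot
    leak across units); boundaries become a tier of consecutive segments that
    tile [unit.start, unit.end]. A unit too short to analyze is returned as a
    single segment with a warning.
    """
    try:
        piece = wav.slice(unit.start, unit.end)
        tr_int, tr_f0, tr_we = compute_tracks(piece, profile)
        if len(tr_int) < 3:
            raise ValueError("fewer than 3 frames")
        bset = detect_boundaries(tr_int, tr_f0, tr_we, profile, thr)
        cuts = [t for t in bset.times if unit.start + 1e-9 < t < unit.end - 1e-9]
    except ValueError as exc:
        logger.warning("unit [%.4f, %.4f] too short to segment (%s)", unit.start, unit.end, exc)
        cuts = []
    edges = [unit.start] + sorted(cuts) + [unit.end]
    intervals = [
        Interval(a, b, f"{name_prefix}_{k:03d}")
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1)
    ]
    return IntervalTier("segments", intervals)


def segment_corpus(
    wav_paths,
    profile: SpeciesProfile,
    thr: TransitionThresholds | None = None,
    cfg=None,
    manifest: dict | None = None,
):
    """Full pipeline per file: bouts -> syllables -> segments.

    Returns (tiers_per_file, metadata DataFrame). Per-file failures are logged
    and the run continues. `manifest` maps file path -> dict with 'individual'
    and 'group' labels for the metadata table.
    """
    import pandas as pd

    from . import bouts as bouts_mod
    from .annot_io import read_wav

    cfg = cfg or bouts_mod.BoutConfig()
    results: dict = {}
    rows = []
    for path in wav_paths:
        try:
            wav = read_wav(path)
            bout_tier = bouts_mod.detect_bouts(wav, cfg)
            if cfg.band_high < wav.rate / 2:
                filtered = bouts_mod.band_filter(wav, cfg)
            else:
                logger.warning(
                    "%s: band filter skipped (band_high %.0f Hz >= Nyquist %.0f Hz)",
                    path, cfg.band_high, wav.rate / 2,
                )
                filtered = wav
            syll_intervals = []
            seg_intervals = []
            for bout in bout_tier:
                if bout.label not in ("song", "vocalization"):
                    continue
                song = filtered.slice(bout.start, bout.end)
                sylls = bouts_mod.extract_syllables(song, cfg)
                for si, syll in enumerate(sylls.labeled(), start=len(syll_intervals) + 1):
                    syll = Interval(syll.start, syll.end, f"syll_{si:03d}")
                    syll_intervals.append(syll)
                    segs = segment_unit(filtered, syll, profile, thr)
                    seg_intervals.extend(segs.intervals)
            tiers = [
                bout_tier,
                IntervalTier("syllables", syll_intervals),
                IntervalTier("segments", seg_intervals),
            ]
            results[str(path)] = tiers
            meta = (manifest or {}).get(str(path), {})
            for syll in syll_intervals:
                inside = [s for s in seg_intervals if s.start >= syll.start - 1e-9 and s.end <= syll.end + 1e-9]
                rows.append(
                    {
                        "file": str(path),
                        "unit": syll.label,
                        "start": syll.start,
                        "end": syll.end,
                        "n_segments": len(inside),
                        "individual": meta.get("individual", ""),
                        "group": meta.get("group", ""),
                    }
                )
            logger.info("%s: %d syllables, %d segments", path, len(syll_intervals), len(seg_intervals))
        except Exception as exc:  # noqa: BLE001 - per-file robustness is the contract
            logger.error("failed on %s: %s", path, exc)
    columns = ["file", "unit", "start", "end", "n_segments", "individual", "group"]
    return results, pd.DataFrame(rows, columns=columns)
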