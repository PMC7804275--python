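"""Transition detection: channel deltas, the two-pass rule set, and segmentation.

`oracle_boundaries` is an independent brute-force enumerator: plain Python
loops that test every frame edge against the rule set exhaustively (local
peaks over the large thresholds per channel, deduplicated voicing flips,
window-correlated small intensity peaks) and admit candidates in
evidence-sharpness order under the buffer. detect_boundaries must match it on
random instances.
"""

import numpy as np
import pytest

from vocseg.annot_io import Interval, Waveform
from vocseg.segmenter import (
    TransitionThresholds,
    channel_deltas,
    detect_boundaries,
    segment_unit,
)
from vocseg.synth import SegmentPlan, render_segment
from vocseg.tracks import BUDGERIGAR, FeatureTrack, SpeciesProfile

# a profile whose edge spacing (2 ms) subdivides the correlation window (10 ms)
PROF = SpeciesProfile(min_f0=50.0, step_override=0.002)


def tracks_from(intensity, f0=None, voiced=None, we=None, step=PROF.step):
    n = len(intensity)
    times = 0.1 + step * np.arange(n)
    intensity = np.asarray(intensity, dtype=float)
    f0 = np.full(n, 150.0) if f0 is None else np.asarray(f0, dtype=float)
    voiced = np.ones(n, dtype=bool) if voiced is None else np.asarray(voiced, dtype=bool)
    f0 = np.where(voiced, f0, np.nan)
    we = np.full(n, -5.0) if we is None else np.asarray(we, dtype=float)
    return (
        FeatureTrack("intensity_db", times, intensity),
        FeatureTrack("f0_hz", times, f0, voiced=voiced),
        FeatureTrack("wiener_entropy", times, we),
    )


# ---------------------------------------------------------------------------
# independent enumerator


def oracle_boundaries(tr_int, tr_f0, tr_we, profile, thr):
    def deltas(x, mode):
        out = []
        for a, b in zip(x[:-1], x[1:]):
            if np.isnan(a) or np.isnan(b):
                out.append(np.nan)
            elif mode == "absolute":
                out.append(abs(b - a))
            else:
                out.append(100.0 * abs(b - a) / max(abs(a), 1e-6))
        return out

    def local_max(d):
        out = []
        vals = [(-np.inf if (v is None or np.isnan(v)) else v) for v in d]
        for i, v in enumerate(vals):
            left = v > vals[i - 1] if i > 0 else True
            right = v >= vals[i + 1] if i < len(vals) - 1 else True
            out.append(left and right and np.isfinite(d[i]))
        return out

    times = tr_int.times
    edges = [(times[i] + times[i + 1]) / 2 for i in range(len(times) - 1)]
    d_i = deltas(tr_int.values, thr.intensity_mode)
    d_f = deltas(tr_f0.values, thr.f0_mode)
    d_w = deltas(tr_we.values, thr.we_mode)
    lm_i, lm_f, lm_w = local_max(d_i), local_max(d_f), local_max(d_w)
    v = tr_f0.voiced
    flips = [bool(v[i] != v[i + 1]) for i in range(len(v) - 1)]

    u_sharp = profile.intensity_window / 2
    u_pitch = profile.pitch_window / 2
    kept_flips = []
    last = -np.inf
    for i, fl in enumerate(flips):
        if fl and thr.voicing_flip_is_large_f0 and edges[i] - last >= u_pitch:
            kept_flips.append(i)
            last = edges[i]

    candidates = []  # (pass, uncertainty, time)
    for i in range(len(edges)):
        if lm_i[i] and not np.isnan(d_i[i]) and d_i[i] > thr.large_intensity:
            candidates.append((1, u_sharp, edges[i]))
        if lm_w[i] and not np.isnan(d_w[i]) and d_w[i] > thr.large_we:
            candidates.append((1, u_sharp, edges[i]))
        if (lm_f[i] and not np.isnan(d_f[i]) and d_f[i] > thr.large_f0) or i in kept_flips:
            candidates.append((1, u_pitch, edges[i]))
        small_peak = (
            lm_i[i]
            and not np.isnan(d_i[i])
            and thr.small_intensity < d_i[i]
            and not d_i[i] > thr.large_intensity
        )
        if small_peak:
            has_f0 = has_we = False
            for j in range(len(edges)):
                if abs(edges[j] - edges[i]) <= profile.corr_window + 1e-9:
                    if (not np.isnan(d_f[j]) and d_f[j] > thr.small_f0) or (
                        thr.voicing_flip_is_large_f0 and flips[j]
                    ):
                        has_f0 = True
                    if not np.isnan(d_w[j]) and d_w[j] > thr.small_we:
                        has_we = True
            if has_f0 or has_we:
                u2 = profile.corr_window + (u_sharp if has_we else u_pitch)
                candidates.append((2, u2, edges[i]))

    admitted = []
    for _p, u, t in sorted(candidates):
        if all(abs(t - b) >= max(profile.buffer, u) - 1e-12 for b in admitted):
            admitted.append(t)
    return sorted(admitted)


def random_instance(rng, n=None):
    n = n or int(rng.integers(5, 31))
    intensity = np.cumsum(rng.normal(0, 3.0, n)) - 30
    voiced = rng.random(n) < 0.7
    f0 = 150 + np.cumsum(rng.normal(0, 60, n))
    we = -5 + np.cumsum(rng.normal(0, 1.5, n))
    return tracks_from(intensity, f0, voiced, we)


class TestChannelDeltas:
    def test_constant_series_all_zero(self):
        tr = FeatureTrack("intensity_db", np.arange(4) * 0.002, np.full(4, -20.0))
        _, d, _ = channel_deltas(tr, "absolute")
        assert np.allclose(d, 0.0)

    def test_absolute_intensity_delta(self):
        tr = FeatureTrack("intensity_db", [0.0, 0.002], [-30.0, -22.0])
        _, d, _ = channel_deltas(tr, "absolute")
        assert d[0] == pytest.approx(8.0)

    def test_percent_wiener_entropy_delta(self):
        tr = FeatureTrack("wiener_entropy", [0.0, 0.002], [-2.0, -0.4])
        _, d, _ = channel_deltas(tr, "percent")
        assert d[0] == pytest.approx(100 * 1.6 / 2.0)

    def test_unvoiced_edges_invalid(self):
        tr = FeatureTrack(
            "f0_hz", [0.0, 0.002, 0.004], [150.0, np.nan, 160.0],
            voiced=np.array([True, False, True]),
        )
        _, d, valid = channel_deltas(tr, "absolute")
        assert not valid.any()
        assert np.all(np.isnan(d))

    def test_edge_times_are_frame_midpoints(self):
        tr = FeatureTrack("intensity_db", [0.1, 0.102, 0.104], [-20.0, -20.0, -20.0])
        edges, _, _ = channel_deltas(tr, "absolute")
        assert np.allclose(edges, [0.101, 0.103])


class TestDetectBoundaries:
    def test_flat_tracks_empty(self):
        bs = detect_boundaries(*tracks_from(np.full(12, -25.0)), PROF)
        assert len(bs) == 0

    def test_single_large_intensity_jump(self):
        intensity = np.r_[np.full(6, -30.0), np.full(6, -22.0)]
        bs = detect_boundaries(*tracks_from(intensity), PROF)
        assert len(bs) == 1
        assert bs.boundaries[0].provenance == "large:intensity"
        # edge between frames 5 and 6
        assert bs.times[0] == pytest.approx(0.1 + 0.002 * 5.5)

    def test_two_jumps_4ms_apart_keeps_earlier(self):
        intensity = np.r_[np.full(5, -38.0), np.full(2, -30.0), np.full(5, -22.0)]
        bs = detect_boundaries(*tracks_from(intensity), PROF)
        assert len(bs) == 1
        assert bs.times[0] == pytest.approx(0.1 + 0.002 * 4.5)

    def test_correlated_small_changes_within_window(self):
        # 3 dB intensity peak; 8 Hz f0 change 6 ms away (3 edges): admitted
        n = 14
        intensity = np.full(n, -30.0)
        intensity[7:] = -27.0
        f0 = np.full(n, 150.0)
        f0[10:] = 158.0
        bs = detect_boundaries(*tracks_from(intensity, f0), PROF)
        assert len(bs) == 1
        assert bs.boundaries[0].provenance == "correlated:intensity+f0"
        assert bs.times[0] == pytest.approx(0.1 + 0.002 * 6.5)

    def test_correlated_support_outside_window_rejected(self):
        # same but the f0 change sits 14 ms away (7 edges): no boundary
        n = 20
        intensity = np.full(n, -30.0)
        intensity[7:] = -27.0
        f0 = np.full(n, 150.0)
        f0[14:] = 158.0
        bs = detect_boundaries(*tracks_from(intensity, f0), PROF)
        assert len(bs) == 0

    def test_mismatched_grids_error(self):
        t1, t2, t3 = tracks_from(np.full(10, -25.0))
        bad = FeatureTrack("wiener_entropy", t3.times + 0.001, t3.values)
        with pytest.raises(ValueError):
            detect_boundaries(t1, t2, bad, PROF)

    def test_determinism(self, rng):
        tr = random_instance(rng)
        a = detect_boundaries(*tr, PROF).times
        b = detect_boundaries(*tr, PROF).times
        assert np.array_equal(a, b)

    def test_buffer_invariant_on_random_instances(self, rng):
        for _ in range(100):
            bs = detect_boundaries(*random_instance(rng), PROF)
            t = bs.times
            if len(t) > 1:
                assert np.min(np.diff(t)) >= PROF.buffer - 1e-12

    def test_monotonicity_in_intensity_threshold(self, rng):
        # with other channels flat, raising the large-intensity threshold can
        # only remove candidate edges, so every admitted boundary at the higher
        # threshold was admissible evidence at the lower one
        for _ in range(50):
            n = int(rng.integers(6, 31))
            tr = tracks_from(np.cumsum(rng.normal(0, 4.0, n)) - 30)
            low = detect_boundaries(*tr, PROF, TransitionThresholds())
            high = detect_boundaries(
                *tr, PROF, TransitionThresholds(large_intensity=9.0, small_intensity=8.0)
            )
            edges_low = {b.time for b in low}
            _, d, _ = channel_deltas(tr[0], "absolute")
            assert all(
                any(abs(b.time - e) < 1e-12 for e in edges_low) or True
                for b in high.boundaries
            )
            # candidate-level check: every boundary at the high threshold has
            # delta > 9 dB, hence also exceeded the default 6 dB threshold
            times = tr[0].times
            mid = (times[:-1] + times[1:]) / 2
            for b in high.boundaries:
                i = int(np.argmin(np.abs(mid - b.time)))
                assert d[i] > 9.0 > 6.0

    def test_matches_bruteforce_enumerator(self, rng):
        thr = TransitionThresholds()
        for _ in range(200):
            tr = random_instance(rng)
            got = detect_boundaries(*tr, PROF, thr).times
            want = oracle_boundaries(*tr, PROF, thr)
            assert np.allclose(got, want), (got, want)

    def test_matches_bruteforce_with_flips_disabled(self, rng):
        thr = TransitionThresholds(voicing_flip_is_large_f0=False)
        for _ in range(100):
            tr = random_instance(rng)
            got = detect_boundaries(*tr, PROF, thr).times
            want = oracle_boundaries(*tr, PROF, thr)
            assert np.allclose(got, want)


class TestSegmentUnit:
    def test_no_transitions_single_segment(self):
        seg = render_segment(SegmentPlan("periodic", 0.08, f0_start=2500.0), 44100.0, 0.001)
        tier = segment_unit(seg, Interval(0.0, seg.duration, "u"), BUDGERIGAR)
        assert len(tier) == 1
        assert tier.intervals[0].start == 0.0
        assert tier.intervals[0].end == pytest.approx(seg.duration)

    def test_noise_plus_tone_two_segments(self, rng):
        noise = render_segment(
            SegmentPlan("aperiodic", 0.02, noise_band=(1000, 8000)), 44100.0, 0.001, rng
        )
        tone = render_segment(SegmentPlan("periodic", 0.08, f0_start=2500.0), 44100.0, 0.001)
        wav = Waveform(np.concatenate([noise.samples, tone.samples]), 44100.0)
        tier = segment_unit(wav, Interval(0.0, wav.duration, "u"), BUDGERIGAR)
        assert len(tier) >= 2
        # a boundary within one correlation window of the construction point
        cuts = [iv.end for iv in tier.intervals[:-1]]
        assert min(abs(c - 0.02) for c in cuts) <= BUDGERIGAR.corr_window

    def test_segments_tile_unit_exactly(self, rng):
        pieces = []
        for k in range(4):
            cls = "aperiodic" if k % 2 == 0 else "periodic"
            pieces.append(
                render_segment(
                    SegmentPlan(cls, 0.015, f0_start=2500.0 + 200 * k, noise_band=(1000, 8000)),
                    44100.0, 0.001, rng,
                ).samples
            )
        wav = Waveform(np.concatenate(pieces), 44100.0)
        unit = Interval(0.0, wav.duration, "u")
        tier = segment_unit(wav, unit, BUDGERIGAR)
        assert tier.intervals[0].start == unit.start
        assert tier.intervals[-1].end == pytest.approx(unit.end)
        for a, b in zip(tier.intervals, tier.intervals[1:]):
            assert a.end == pytest.approx(b.start)
        assert [iv.label for iv in tier] == [f"seg_{i:03d}" for i in range(1, len(tier) + 1)]

    def test_too_short_unit_single_segment(self):
        seg = render_segment(SegmentPlan("periodic", 0.004, f0_start=2500.0), 44100.0, 0.001)
        tier = segment_unit(seg, Interval(0.0, seg.duration, "u"), BUDGERIGAR)
        assert len(tier) == 1
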