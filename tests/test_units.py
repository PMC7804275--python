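"""Unit feature vectors, scaling, clustering, silhouettes, snippets, forests.

Brute-force oracles: `silhouette_oracle` evaluates the silhouette formula
point by point with plain loops; Ward at k=2 on two separated blobs is checked
against exhaustive enumeration of every 2-partition.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from vocseg.annot_io import Interval, Waveform
from vocseg.synth import SegmentPlan, render_segment
from vocseg.tracks import BUDGERIGAR, HUMAN
from vocseg.units import (
    DEFAULT_FEATURES,
    FeatureSpec,
    SamplingPlan,
    classify_units,
    extract_features,
    random_snippets,
    silhouette,
    silhouette_sweep,
    spearman_dissimilarity,
    ward_cluster,
    zscale,
)

RATE = 44100.0


# ---------------------------------------------------------------------------
# oracles


def silhouette_oracle(D, labels):
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        mine = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not mine:
            out[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in mine])
        bs = []
        for c in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            bs.append(np.mean([D[i, j] for j in members]))
        b = min(bs)
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


def best_two_partition(D):
    """Exhaustive optimal 2-partition by Ward's criterion (sum of within-cluster
    mean squared dissimilarity to the medoid-free centroid surrogate)."""
    n = D.shape[0]
    best, best_cost = None, np.inf
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        cost = 0.0
        for c in (0, 1):
            idx = np.flatnonzero(labels == c)
            if len(idx) == 0:
                cost = np.inf
                break
            sub = D[np.ix_(idx, idx)]
            cost += (sub**2).sum() / (2 * len(idx))  # Ward within-cluster SSE
        if cost < best_cost:
            best_cost, best = cost, labels
    return best


# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_pure_tone_features(self):
        seg = render_segment(SegmentPlan("periodic", 0.100, f0_start=1000.0, n_harmonics=1), RATE, 0.005)
        out = extract_features(seg, Interval(0.0, 0.100, "u"), HUMAN)
        assert out["duration"] == pytest.approx(0.100, abs=1e-6)
        assert out["prop_voiced"] == 1.0
        assert out["spectral_cog"] == pytest.approx(1000.0, abs=20.0)
        assert out["peak_freq"] == pytest.approx(1000.0, abs=20.0)
        assert out["we_mean"] < -3

    def test_tone_inside_pitch_range_recovers_f0(self):
        # the human profile searches 50-750 Hz, so use an in-range tone
        seg = render_segment(SegmentPlan("periodic", 0.100, f0_start=600.0, n_harmonics=1), RATE, 0.005)
        out = extract_features(seg, Interval(0.0, 0.100, "u"), HUMAN)
        assert out["f0_mean"] == pytest.approx(600.0, abs=6.0)

    def test_white_noise_unit(self, rng):
        wav = Waveform(rng.standard_normal(int(0.15 * RATE)) * 0.2, RATE)
        out = extract_features(wav, Interval(0.0, 0.15, "u"), HUMAN)
        assert out["prop_voiced"] < 0.2
        assert out["we_mean"] > -1.0
        assert np.isnan(out["f0_mean"])

    def test_zero_amplitude_unit(self):
        wav = Waveform(np.zeros(int(0.15 * RATE)), RATE)
        out = extract_features(wav, Interval(0.0, 0.15, "u"), HUMAN)
        assert out["intensity_mean"] == -100.0
        assert np.isnan(out["f0_mean"])
        assert out["prop_voiced"] == 0.0

    def test_feature_vector_is_complete_and_ordered(self):
        seg = render_segment(SegmentPlan("periodic", 0.05, f0_start=2500.0), RATE, 0.001)
        out = extract_features(seg, Interval(0.0, 0.05, "u"), BUDGERIGAR)
        assert list(out.keys()) == DEFAULT_FEATURES
        assert len(out) == 21

    def test_short_segment_f0_measured_from_own_samples(self, rng):
        # a 6 ms harmonic burst flanked by noise: F0 must reflect the burst,
        # not the neighbors, even though the pitch window spans all three
        noise = render_segment(SegmentPlan("aperiodic", 0.02, noise_band=(1000, 8000)), RATE, 0.001, rng)
        tone = render_segment(SegmentPlan("periodic", 0.006, f0_start=3000.0), RATE, 0.001)
        wav = Waveform(np.concatenate([noise.samples, tone.samples, noise.samples]), RATE)
        out = extract_features(wav, Interval(0.02, 0.026, "u"), BUDGERIGAR)
        assert out["f0_mean"] == pytest.approx(3000.0, abs=60.0)
        assert out["prop_voiced"] >= 0.9


class TestZscale:
    def test_simple_column(self):
        scaled, _ = zscale(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(scaled[:, 0], [-1, 0, 1])

    def test_constant_column_zeroed_and_flagged(self):
        scaled, info = zscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert np.allclose(scaled[:, 1], 0)
        assert info["constant_columns"] == [1]

    def test_idempotent_on_scaled_input(self, rng):
        X = rng.standard_normal((30, 4))
        once, _ = zscale(X)
        twice, _ = zscale(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_missing_values_mean_imputed(self):
        X = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        scaled, info = zscale(X)
        assert info["imputed_columns"] == [0]
        assert np.isfinite(scaled).all()
        # imputed entry equals the column mean -> 0 after scaling
        assert scaled[1, 0] == pytest.approx(0.0)


class TestSpearman:
    def test_identical_rows_zero_dissimilarity(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0]] * 2)
        D = spearman_dissimilarity(X)
        assert D[0, 1] == pytest.approx(0.0)

    def test_reversed_row_maximal(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        D = spearman_dissimilarity(X)
        assert D[0, 1] == pytest.approx(2.0)

    def test_hand_ranked_example(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]])
        D = spearman_dissimilarity(X)
        assert D[0, 1] == pytest.approx(0.2)  # rho = 0.8

    def test_matches_scipy_rowwise(self, rng):
        import scipy.stats

        X = rng.standard_normal((6, 9))
        D = spearman_dissimilarity(X)
        for i, j in itertools.combinations(range(6), 2):
            rho = scipy.stats.spearmanr(X[i], X[j]).statistic
            assert D[i, j] == pytest.approx(1 - rho, abs=1e-12)


class TestWard:
    def blobs(self, rng, n1=5, n2=5):
        n = n1 + n2
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < n1) == (j < n1)
            D[i, j] = D[j, i] = rng.uniform(0.01, 0.1) if same else rng.uniform(1.5, 2.0)
        return D, np.array([0] * n1 + [1] * n2)

    def test_two_blobs_perfect_split(self, rng):
        D, truth = self.blobs(rng)
        labels = ward_cluster(D, 2)
        assert (labels == truth).all() or (labels == 1 - truth).all()

    def test_matches_exhaustive_optimum_on_blobs(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            D, _ = self.blobs(rng, n1, n2)
            labels = ward_cluster(D, 2)
            best = best_two_partition(D)
            assert (labels == best).all() or (labels == 1 - best).all()

    def test_three_equidistant_points_merge_first_pair(self):
        D = np.ones((3, 3)) - np.eye(3)
        labels = ward_cluster(D, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_k_equals_n_minus_one_merges_closest_pair(self, rng):
        n = 7
        X = rng.standard_normal((n, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        labels = ward_cluster(D, n - 1)
        i, j = min(itertools.combinations(range(n), 2), key=lambda ij: D[ij])
        assert labels[i] == labels[j]

    def test_invalid_inputs_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            ward_cluster(D, 4)
        bad = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError):
            ward_cluster(bad, 2)


class TestSilhouette:
    def test_two_tight_far_blobs_high_mean(self, rng):
        n = 8
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < 4) == (j < 4)
            D[i, j] = D[j, i] = 0.05 if same else 1.8
        rep = silhouette(D, np.array([0] * 4 + [1] * 4))
        assert rep.mean_silhouette > 0.9

    def test_equidistant_point_scores_zero(self):
        # point 2 is equally far from its own cluster mate and the other cluster
        D = np.array(
            [[0.0, 0.1, 1.0, 1.0],
             [0.1, 0.0, 1.0, 1.0],
             [1.0, 1.0, 0.0, 1.0],
             [1.0, 1.0, 1.0, 0.0]]
        )
        rep = silhouette(D, np.array([0, 0, 1, 1]))
        assert rep.silhouettes[2] == pytest.approx(0.0)

    def test_random_labels_near_zero(self, rng):
        means = []
        for _ in range(30):
            X = rng.random((16, 5))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            labels = rng.integers(0, 2, 16)
            if len(np.unique(labels)) < 2:
                continue
            means.append(silhouette(D, labels).mean_silhouette)
        assert abs(np.mean(means)) < 0.1

    def test_matches_bruteforce_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            X = rng.random((n, 3))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            k = int(rng.integers(2, min(n, 5)))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2:
                continue
            rep = silhouette(D, labels)
            assert np.allclose(rep.silhouettes, silhouette_oracle(D, labels), atol=1e-12)

    def test_values_bounded(self, rng):
        X = rng.random((20, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        rep = silhouette(D, rng.integers(0, 3, 20))
        assert np.all(rep.silhouettes >= -1) and np.all(rep.silhouettes <= 1)


class TestSweep:
    def test_report_count_matches_k_range(self, rng):
        X = rng.standard_normal((40, 6))
        assert len(silhouette_sweep(X, range(2, 16))) == 14
        assert len(silhouette_sweep(X, range(2, 9))) == 7

    def test_two_class_data_peaks_at_k2(self, rng):
        # the metric is rank correlation across features, so the two classes
        # must differ in their feature *patterns*, not just their means
        base = np.arange(6, dtype=float)
        X = np.vstack(
            [base + rng.normal(0, 0.2, (20, 6)), base[::-1] + rng.normal(0, 0.2, (20, 6))]
        )
        reports = silhouette_sweep(X, range(2, 8))
        means = [r.mean_silhouette for r in reports]
        assert np.argmax(means) == 0


class TestSnippets:
    def make(self, durations):
        start = 1.0
        segs, t = [], start
        for k, d in enumerate(durations):
            segs.append(Interval(t, t + d, f"seg_{k}"))
            t += d
        return Interval(start, t, "syll"), segs

    def test_boundaries_at_shuffled_cumsums(self):
        syll, segs = self.make([0.010, 0.020, 0.030])
        for seed in range(40):  # find a seed producing permutation (3,1,2)
            snips = random_snippets(syll, segs, np.random.default_rng(seed))
            durs = [round(s.duration, 6) for s in snips]
            if durs == [0.030, 0.010, 0.020]:
                assert snips[0].end == pytest.approx(1.030)
                assert snips[1].end == pytest.approx(1.040)
                break
        else:
            pytest.fail("expected permutation never drawn")

    def test_equal_durations_leave_boundaries_unchanged(self):
        syll, segs = self.make([0.01, 0.01, 0.01])
        snips = random_snippets(syll, segs, np.random.default_rng(0))
        for a, b in zip(snips, segs):
            assert a.start == pytest.approx(b.start)
            assert a.end == pytest.approx(b.end)

    def test_total_duration_conserved_exactly(self, rng):
        durations = rng.uniform(0.004, 0.02, 7)
        syll, segs = self.make(list(durations))
        snips = random_snippets(syll, segs, rng)
        assert len(snips) == 7
        assert snips[-1].end == syll.end
        assert sum(s.duration for s in snips) == pytest.approx(syll.duration, abs=1e-9)

    def test_single_segment_rejected(self):
        syll, segs = self.make([0.02])
        with pytest.raises(ValueError):
            random_snippets(syll, segs, 0)


def feature_frame(rng, n_per_class, classes, shift=0.0):
    rows = []
    for ci, c in enumerate(classes):
        X = rng.standard_normal((n_per_class, 21)) + shift * ci
        df = pd.DataFrame(X, columns=DEFAULT_FEATURES)
        df["group"] = c
        df["individual"] = c + "_i"
        df["kind"] = "segment"
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestClassification:
    def test_chance_accuracy_under_independent_features(self, rng):
        df = feature_frame(rng, 100, ["A", "B", "C", "D"])
        res = classify_units(df, "group", seed=0)
        assert abs(res.overall_accuracy - 0.25) < 0.08
        assert res.p_value > 0.01

    def test_separable_features_near_perfect(self, rng):
        df = feature_frame(rng, 60, ["A", "B", "C", "D"], shift=6.0)
        res = classify_units(df, "group", seed=0)
        assert res.overall_accuracy > 0.95
        assert res.p_value < 1e-6

    def test_row_and_feature_order_invariance(self, rng):
        df = feature_frame(rng, 40, ["A", "B"], shift=2.0)
        res1 = classify_units(df, "group", seed=3)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = classify_units(shuffled, "group", seed=3)
        # stratified resampling restores a canonical order, so OOB accuracy
        # is reproducible regardless of input row order
        assert res1.n_units == res2.n_units
        assert abs(res1.overall_accuracy - res2.overall_accuracy) < 0.06
        reordered = df[list(reversed(df.columns))]
        res3 = classify_units(reordered, "group", seed=3)
        assert res3.overall_accuracy == pytest.approx(res1.overall_accuracy, abs=0.06)

    def test_plan_arithmetic(self):
        plan = SamplingPlan()
        assert plan.clustering_units_per_kind == 840
        assert plan.human_breath_groups == 105

    def test_oversized_request_rejected(self, rng):
        df = feature_frame(rng, 10, ["A", "B"])
        with pytest.raises(ValueError):
            classify_units(df, "group", per_class=50, seed=0)
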