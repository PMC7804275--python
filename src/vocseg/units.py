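"""Per-unit acoustic feature vectors and the two validation batteries.

Units (segments, syllables, duration-shuffled snippets) are summarized by a
21-variable acoustic feature vector covering time (duration), amplitude
(intensity statistics and slope), pitch (F0 statistics, slope and the
proportion of voiced frames), spectral dispersion (Wiener entropy statistics)
and spectral shape (moments of the average power spectrum and the peak
frequency and its variability). Feature matrices are z-scaled, converted to a
Spearman rank-correlation dissimilarity between units, clustered with Ward.D2
linkage, and scored by silhouette widths over a sweep of cluster counts.
Identity prediction uses a random forest (500 trees, 3 candidate predictors
per split) scored by out-of-bag accuracy with exact binomial tests against
chance and Holm correction across the models of one battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .annot_io import Interval, Waveform
from .tracks import FeatureTrack, SpeciesProfile, compute_tracks

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureSpec",
    "SamplingPlan",
    "ClusterReport",
    "extract_features",
    "zscale",
    "spearman_dissimilarity",
    "ward_cluster",
    "silhouette",
    "silhouette_sweep",
    "random_snippets",
    "classify_units",
    "classification_battery",
]

DEFAULT_FEATURES = [
    "duration",
    "intensity_mean",
    "intensity_min",
    "intensity_max",
    "intensity_sd",
    "intensity_slope",
    "f0_mean",
    "f0_min",
    "f0_max",
    "f0_sd",
    "f0_slope",
    "prop_voiced",
    "we_mean",
    "we_min",
    "we_sd",
    "spectral_cog",
    "spectral_sd",
    "spectral_skew",
    "spectral_kurtosis",
    "peak_freq",
    "peak_freq_sd",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature list; the default is the package's 21-variable set."""

    names: tuple = tuple(DEFAULT_FEATURES)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


@dataclass(frozen=True)
class SamplingPlan:
    """Stratified sample sizes for the clustering and classification analyses.

    Defaults follow the published study design: 60 units per individual across
    14 individuals (840 per unit kind) for the clustering sweeps; 500 segments
    per individual and per group, 60 syllables per individual, 384 per group
    for the identity models; 15 vocalizations from each of 7 speakers (105
    breath groups, with the segment subset matched to 105) on the human side.
    """

    units_per_individual: int = 60
    n_individuals: int = 14
    segments_per_individual: int = 500
    segments_per_group: int = 500
    syllables_per_individual: int = 60
    syllables_per_group: int = 384
    human_vocalizations_per_speaker: int = 15
    n_speakers: int = 7

    @property
    def clustering_units_per_kind(self) -> int:
        return self.units_per_individual * self.n_individuals

    @property
    def human_breath_groups(self) -> int:
        return self.human_vocalizations_per_speaker * self.n_speakers


@dataclass
class ClusterReport:
    k: int
    assignments: np.ndarray
    silhouettes: np.ndarray

    @property
    def mean_silhouette(self) -> float:
        return float(np.mean(self.silhouettes))


# ---------------------------------------------------------------------------
# feature extraction


def _lin_slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2 or np.ptp(t) == 0:
        return np.nan
    return float(np.polyfit(t, y, 1)[0])


def _frames_in(track: FeatureTrack, unit: Interval, margin: float = 0.0) -> np.ndarray:
    """Frames belonging to the unit, preferring those whose window fits inside.

    `margin` is half the analysis window: frames within [start+margin,
    end-margin] carry no neighboring-unit content. Falls back to center-inside
    frames, then to the single nearest frame, so short units always measure.
    """
    if margin > 0:
        sel = (track.times >= unit.start + margin - 1e-9) & (
            track.times <= unit.end - margin + 1e-9
        )
        if sel.any():
            return sel
    sel = (track.times >= unit.start - 1e-9) & (track.times < unit.end - 1e-9)
    if not sel.any():  # very short unit: fall back to the nearest frame
        sel = np.zeros(len(track), dtype=bool)
        sel[int(np.argmin(np.abs(track.times - 0.5 * (unit.start + unit.end))))] = True
    return sel


def _slice_f0_stats(samples: np.ndarray, rate: float, profile: SpeciesProfile) -> dict:
    """F0 statistics measured on the unit's own samples.

    The track-based pitch frames use windows of 3/min_f0 s, which for units
    shorter than that window unavoidably mix in neighboring material. Here the
    unit is scanned with sub-windows clipped to its own extent (half-window
    hop); each sub-window gets a normalized-autocorrelation pitch estimate with
    the search floor raised to 2 cycles per sub-window, so a short harmonic
    burst is measured from its own periods only.
    """
    n = len(samples)
    out = dict(f0_mean=np.nan, f0_min=np.nan, f0_max=np.nan, f0_sd=np.nan,
               f0_slope=np.nan, prop_voiced=0.0)
    win = int(min(n, round(profile.pitch_window * rate)))
    win = max(win, 16)
    if n < 16:
        return out
    hop = max(1, win // 2)
    starts = list(range(0, max(1, n - win + 1), hop))
    max_f0 = profile.max_f0_at(rate)
    floor = max(profile.min_f0, 2.0 * rate / win)
    if floor >= max_f0:
        return out
    lag_min = max(2, int(np.floor(rate / max_f0)))
    lag_max = min(win - 2, int(np.ceil(rate / floor)))
    times, f0s, voiced = [], [], []
    for s in starts:
        x = samples[s : s + win].astype(float)
        x = x - x.mean()
        r0 = float(x @ x)
        if r0 < (1e-6) ** 2 * win:
            voiced.append(False)
            continue
        nfft = 1 << int(np.ceil(np.log2(2 * len(x))))
        spec = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(spec.real**2 + spec.imag**2, nfft)[: lag_max + 2]
        lags = np.arange(len(ac))
        rn = ac / (r0 * np.maximum(1.0 - lags / len(x), 1e-6))
        band = rn[lag_min : lag_max + 1]
        if len(band) < 3:
            voiced.append(False)
            continue
        interior = np.zeros(len(band), dtype=bool)
        interior[1:-1] = (band[1:-1] >= band[:-2]) & (band[1:-1] >= band[2:])
        peaks = np.flatnonzero(interior)
        if len(peaks) == 0 or band[peaks].max() < profile.voicing_threshold:
            voiced.append(False)
            continue
        best = band[peaks].max()
        chosen = int(peaks[band[peaks] >= 0.9 * best].min()) + lag_min
        a, b, c = rn[chosen - 1], rn[chosen], rn[chosen + 1]
        denom = a - 2 * b + c
        d = 0.5 * (a - c) / denom if denom < 0 else 0.0
        lag_f = chosen + float(np.clip(d, -0.5, 0.5))
        f0s.append(rate / lag_f)
        times.append((s + win / 2.0) / rate)
        voiced.append(True)
    out["prop_voiced"] = float(np.mean(voiced)) if voiced else 0.0
    if f0s:
        f0s = np.asarray(f0s)
        out.update(
            f0_mean=float(f0s.mean()),
            f0_min=float(f0s.min()),
            f0_max=float(f0s.max()),
            f0_sd=float(np.std(f0s, ddof=1)) if len(f0s) > 1 else np.nan,
            f0_slope=_lin_slope(np.asarray(times), f0s) if len(f0s) > 1 else np.nan,
        )
    return out


def _spectral_shape(samples: np.ndarray, rate: float) -> dict:
    w = np.hanning(len(samples))
    power = np.abs(np.fft.rfft(samples * w)) ** 2
    freqs = np.fft.rfftfreq(len(samples), 1.0 / rate)
    power, freqs = power[1:], freqs[1:]
    total = power.sum()
    if total <= 0:
        return {k: np.nan for k in ("spectral_cog", "spectral_sd", "spectral_skew", "spectral_kurtosis", "peak_freq")}
    p = power / total
    cog = float((freqs * p).sum())
    var = float(((freqs - cog) ** 2 * p).sum())
    sd = np.sqrt(var)
    skew = float(((freqs - cog) ** 3 * p).sum() / sd**3) if sd > 0 else np.nan
    kurt = float(((freqs - cog) ** 4 * p).sum() / sd**4) if sd > 0 else np.nan
    return {
        "spectral_cog": cog,
        "spectral_sd": float(sd),
        "spectral_skew": skew,
        "spectral_kurtosis": kurt,
        "peak_freq": float(freqs[np.argmax(power)]),
    }


def extract_features(
    wav: Waveform,
    unit: Interval,
    profile: SpeciesProfile,
    spec: FeatureSpec | None = None,
    tracks: tuple[FeatureTrack, FeatureTrack, FeatureTrack] | None = None,
) -> dict:
    """Acoustic feature vector of one unit; undefined values are NaN.

    `tracks` may carry precomputed (intensity, f0, we) tracks of `wav` so the
    per-file analysis is done once and shared across that file's units.
    """
    spec = spec or FeatureSpec()
    if tracks is None:
        tracks = compute_tracks(wav, profile)
    tr_int, _tr_f0, tr_we = tracks
    sel = _frames_in(tr_int, unit, margin=profile.intensity_window / 2.0)
    t = tr_int.times[sel]

    out: dict = {"duration": unit.duration}
    db = tr_int.values[sel]
    out.update(
        intensity_mean=float(np.mean(db)),
        intensity_min=float(np.min(db)),
        intensity_max=float(np.max(db)),
        intensity_sd=float(np.std(db, ddof=1)) if len(db) > 1 else np.nan,
        intensity_slope=_lin_slope(t, db),
    )
    we = tr_we.values[sel]
    we = we[np.isfinite(we)]
    out.update(
        we_mean=float(np.mean(we)) if len(we) else np.nan,
        we_min=float(np.min(we)) if len(we) else np.nan,
        we_sd=float(np.std(we, ddof=1)) if len(we) > 1 else np.nan,
    )

    piece = wav.slice(unit.start, unit.end)
    out.update(_slice_f0_stats(piece.samples, wav.rate, profile))
    out.update(_spectral_shape(piece.samples, wav.rate))

    # peak frequency variability across short frames within the unit
    win = max(4, int(round(profile.intensity_window * wav.rate)))
    x = piece.samples
    if len(x) >= 2 * win:
        starts = np.arange(0, len(x) - win + 1, max(1, win // 2))
        idx = starts[:, None] + np.arange(win)[None, :]
        pw = np.abs(np.fft.rfft(x[idx] * np.hanning(win), axis=1)) ** 2
        fr = np.fft.rfftfreq(win, 1.0 / wav.rate)
        peaks = fr[1:][np.argmax(pw[:, 1:], axis=1)]
        out["peak_freq_sd"] = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    else:
        out["peak_freq_sd"] = 0.0

    return {name: out.get(name, np.nan) for name in spec.names}


# ---------------------------------------------------------------------------
# scaling, dissimilarity, clustering


def zscale(matrix) -> tuple[np.ndarray, dict]:
    """Column-wise z-scaling (sample SD) with mean imputation of missing values.

    Returns (scaled, info) where info records imputed and zero-variance columns
    (zero-variance columns are set to 0).
    """
    X = np.array(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    imputed, constant = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            fill = np.nanmean(np.where(np.isfinite(col), col, np.nan))
            if not np.isfinite(fill):
                fill = 0.0
            col[miss] = fill
            imputed.append(j)
        mu = col.mean()
        sd = col.std(ddof=1)
        if sd == 0:
            X[:, j] = 0.0
            constant.append(j)
        else:
            X[:, j] = (col - mu) / sd
    if imputed:
        logger.info("zscale: mean-imputed missing values in columns %s", imputed)
    if constant:
        logger.info("zscale: zero-variance columns set to 0: %s", constant)
    return X, {"imputed_columns": imputed, "constant_columns": constant}


def spearman_dissimilarity(matrix) -> np.ndarray:
    """d(i, j) = 1 - Spearman rank correlation between unit feature vectors.

    The correlation runs across features (row-wise, average ranks for ties),
    so d lies in [0, 2] with 0 on the diagonal.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need at least 3 features per unit")
    R = scipy.stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(R, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    R = R / norms[:, None]
    rho = np.clip(R @ R.T, -1.0, 1.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return d


def ward_cluster(dissimilarity: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative Ward.D2 clustering of a precomputed dissimilarity, cut at k.

    Uses the Lance-Williams Ward update on the dissimilarities as if Euclidean
    (the ward.D2 convention: the criterion works on squared dissimilarities,
    results are reported on the original scale). Returns 0-based labels.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    cond = scipy.spatial.distance.squareform(D, checks=False)
    Z = scipy.cluster.hierarchy.linkage(cond, method="ward")
    # cut_tree yields exactly k clusters even under tied merge heights
    return scipy.cluster.hierarchy.cut_tree(Z, n_clusters=k).ravel()


def silhouette(dissimilarity: np.ndarray, assignments: np.ndarray) -> ClusterReport:
    """Per-point silhouette widths s = (b - a) / max(a, b); singletons get 0."""
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    s = silhouette_samples(np.asarray(dissimilarity, dtype=float), labels, metric="precomputed")
    return ClusterReport(k=len(uniq), assignments=labels, silhouettes=s)


def silhouette_sweep(
    features,
    k_range=range(2, 16),
    spec: FeatureSpec | None = None,
) -> list[ClusterReport]:
    """Z-scale, build the Spearman dissimilarity, then Ward + silhouette per k.

    `features` is a feature matrix or DataFrame (feature columns only).
    """
    if isinstance(features, pd.DataFrame):
        cols = list(spec.names) if spec else [c for c in features.columns if c in DEFAULT_FEATURES] or list(features.columns)
        features = features[cols].to_numpy(dtype=float)
    scaled, _ = zscale(features)
    D = spearman_dissimilarity(scaled)
    reports = []
    for k in k_range:
        labels = ward_cluster(D, k)
        reports.append(silhouette(D, labels))
    return reports


# ---------------------------------------------------------------------------
# duration-shuffled snippets


def random_snippets(syllable: Interval, segments, rng) -> list[Interval]:
    """Null units: permute the syllable's segment durations and re-cut boundaries.

    New boundaries sit at the cumulative sums of the shuffled durations from
    the syllable start; the snippet count and total duration are preserved.
    `rng` is a numpy Generator or a seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    segs = list(segments)
    if len(segs) < 2:
        raise ValueError("need at least 2 segments to shuffle")
    durations = np.array([s.duration for s in segs])
    perm = rng.permutation(len(durations))
    cuts = syllable.start + np.cumsum(durations[perm])
    edges = np.concatenate(([syllable.start], cuts))
    edges[-1] = syllable.end  # exact conservation
    return [
        Interval(a, b, f"snip_{i:03d}")
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1)
    ]


# ---------------------------------------------------------------------------
# identity classification


def _stratified_subsample(df: pd.DataFrame, target: str, per_class: int | None, rng) -> pd.DataFrame:
    parts = []
    for _, grp in df.groupby(target, sort=True):
        n = per_class if per_class is not None else df.groupby(target).size().min()
        if n > len(grp):
            raise ValueError(
                f"requested {n} units per {target!r} but only {len(grp)} available"
            )
        parts.append(grp.sample(n=n, random_state=rng))
    return pd.concat(parts)


@dataclass
class ClassificationResult:
    target: str
    n_classes: int
    n_units: int
    overall_accuracy: float
    per_class_accuracy: dict
    p_value: float
    p_adjusted: float | None = None
    importances: dict | None = None


def classify_units(
    df: pd.DataFrame,
    target: str,
    per_class: int | None = None,
    seed: int | None = 0,
    spec: FeatureSpec | None = None,
    n_trees: int = 500,
    mtry: int = 3,
) -> ClassificationResult:
    """Random-forest identity prediction scored by out-of-bag accuracy.

    A stratified subsample of `per_class` units per class (the smallest class
    size when None) is drawn with `seed`; the forest uses `n_trees` trees and
    `mtry` candidate predictors per split. Chance performance is tested with an
    exact binomial test of the OOB-correct count against 1/n_classes.
    """
    spec = spec or FeatureSpec()
    classes = df[target].dropna().unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.RandomState(seed)
    sub = _stratified_subsample(df.dropna(subset=[target]), target, per_class, rng)
    feature_cols = [c for c in spec.names if c in sub.columns]
    X = sub[feature_cols].to_numpy(dtype=float)
    # column-mean imputation; forests cannot take NaN
    means = np.nanmean(X, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    X = np.where(np.isfinite(X), X, means[None, :])
    y = sub[target].to_numpy()

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mtry, X.shape[1]),
        oob_score=True,
        random_state=rng,
        n_jobs=1,
    )
    forest.fit(X, y)
    oob_pred = forest.classes_[np.argmax(forest.oob_decision_function_, axis=1)]
    correct = oob_pred == y
    per_class_acc = {
        str(c): float(np.mean(correct[y == c])) for c in sorted(map(str, np.unique(y)))
    }
    acc = float(np.mean(correct))
    p = scipy.stats.binomtest(int(correct.sum()), len(y), 1.0 / len(np.unique(y))).pvalue
    return ClassificationResult(
        target=target,
        n_classes=int(len(np.unique(y))),
        n_units=int(len(y)),
        overall_accuracy=acc,
        per_class_accuracy=per_class_acc,
        p_value=float(p),
        importances=dict(zip(feature_cols, forest.feature_importances_.round(6))),
    )


def classification_battery(
    df: pd.DataFrame,
    plan: SamplingPlan | None = None,
    seed: int = 0,
    spec: FeatureSpec | None = None,
) -> list[ClassificationResult]:
    """The four identity models (segments/syllables x group/individual), Holm-corrected.

    `df` needs columns 'kind' (segment / simple_syllable / complex_syllable),
    'individual', 'group' and the feature columns. Sample sizes follow `plan`,
    clipped to availability.
    """
    plan = plan or SamplingPlan()
    seg = df[df["kind"] == "segment"]
    syl = df[df["kind"].isin(["simple_syllable", "complex_syllable", "syllable"])]
    specs = [
        (seg, "individual", plan.segments_per_individual),
        (seg, "group", plan.segments_per_group),
        (syl, "individual", plan.syllables_per_individual),
        (syl, "group", plan.syllables_per_group),
    ]
    results = []
    for data, target, n in specs:
        avail = data.groupby(target).size().min() if len(data) else 0
        if avail < 2:
            logger.warning("classification %s: not enough data, skipped", target)
            continue
        results.append(
            classify_units(data, target, per_class=min(n, int(avail)), seed=seed, spec=spec)
        )
    if results:
        adj = multipletests([r.p_value for r in results], method="holm")[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results
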