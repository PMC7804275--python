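"""Frame-based boundary scoring and the paired signed-rank comparison.

The unit extent is tiled into consecutive 25 ms frames (frames are half-open
and anchored at the extent start; a trailing partial frame is kept). Each
frame is scored for the presence of reference and predicted boundaries; the
resulting confusion counts give accuracy, sensitivity and specificity. Unit
start/end boundaries are excluded by default - they are shared by construction
and would inflate the hit count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "EvalConfig",
    "ConfusionReport",
    "frame_confusion",
    "match_boundaries",
    "paired_signed_rank",
]


@dataclass(frozen=True)
class EvalConfig:
    frame_s: float = 0.025
    include_unit_edges: bool = False

    def __post_init__(self):
        if not self.frame_s > 0:
            raise ValueError("frame_s must be positive")


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float | None:
        n = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / n if n else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None


def _boundary_times(obj) -> np.ndarray:
    times = getattr(obj, "times", obj)
    if callable(times):
        times = times()
    return np.atleast_1d(np.asarray(times, dtype=float))


def frame_confusion(reference, predicted, extent, cfg: EvalConfig | None = None) -> ConfusionReport:
    """Frame-wise confusion of predicted vs reference boundary presence.

    `reference`/`predicted` may be BoundarySets or arrays of times; `extent`
    is an object with .start/.end (an Interval) bounding the scored unit.
    """
    cfg = cfg or EvalConfig()
    start, end = float(extent.start), float(extent.end)
    duration = end - start
    if duration < cfg.frame_s:
        raise ValueError(f"extent ({duration:.4f} s) shorter than one frame ({cfg.frame_s} s)")
    n_frames = int(np.ceil(duration / cfg.frame_s - 1e-9))

    def presence(times: np.ndarray) -> np.ndarray:
        has = np.zeros(n_frames, dtype=bool)
        for t in times:
            if t < start - 1e-9 or t > end + 1e-9:
                raise ValueError(f"boundary {t} outside extent [{start}, {end}]")
            if not cfg.include_unit_edges and (
                abs(t - start) < 1e-9 or abs(t - end) < 1e-9
            ):
                continue
            # half-open frames anchored at the extent start; a boundary exactly
            # on a frame edge belongs to the later frame
            idx = int((t - start) / cfg.frame_s + 1e-9)
            has[min(idx, n_frames - 1)] = True
        return has

    ref = presence(_boundary_times(reference))
    pred = presence(_boundary_times(predicted))
    tp = int(np.sum(ref & pred))
    fp = int(np.sum(~ref & pred))
    fn = int(np.sum(ref & ~pred))
    tn = int(np.sum(~ref & ~pred))
    return ConfusionReport(tp=tp, fp=fp, tn=tn, fn=fn)


def match_boundaries(reference, predicted, tol: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of predicted to reference boundary times.

    A prediction matches the closest unmatched reference within +-tol seconds.
    Returns (n_matched, n_reference, n_predicted); recall is matched/reference,
    spurious rate is (predicted - matched)/predicted.
    """
    ref = sorted(_boundary_times(reference).tolist())
    pred = sorted(_boundary_times(predicted).tolist())
    used = [False] * len(ref)
    matched = 0
    for t in pred:
        best, best_d = -1, tol
        for i, r in enumerate(ref):
            if used[i]:
                continue
            d = abs(r - t)
            if d <= best_d:
                best, best_d = i, d
        if best >= 0:
            used[best] = True
            matched += 1
    return matched, len(ref), len(pred)


def paired_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired condition means.

    Returns (V, p) where V is the sum of the ranks of the positive differences
    (the statistic R's wilcox.test prints). With 14 pairs all in one direction
    V saturates at 14*15/2 = 105. p is exact for n <= 25 without ties, normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and paired")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; the test is degenerate")
    ranks = scipy.stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    method = "exact" if (len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)) else "approx"
    res = scipy.stats.wilcoxon(d, alternative="two-sided", method=method)
    return v, float(res.pvalue)
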