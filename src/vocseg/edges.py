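"""Positional (initial / medial / final) labeling and syllable edge-effect tests.

The first segment of a syllable is initial, the last is final, and everything
in between is medial; single-segment syllables are labeled 'sole' and excluded
from positional analyses. Position summaries are means of per-individual means
(each individual weighted equally). The four edge-effect analyses fit mixed
models with position and group as fixed effects and a random intercept per
individual, and compare each against a null without position by a
likelihood-ratio chi-square with 2 degrees of freedom: mean F0 with a Gaussian
log-link model, duration with an inverse-Gaussian identity-link model,
periodicity (binary: at least half of a segment's frames voiced) with a
binomial logit model, and intensity with a linear (Gaussian identity) mixed
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import lrt

logger = logging.getLogger(__name__)

__all__ = [
    "assign_positions",
    "add_positions",
    "position_summaries",
    "EdgeModelResult",
    "edge_effect_tests",
    "PERIODIC_VOICED_THRESHOLD",
]

PERIODIC_VOICED_THRESHOLD = 0.5  # proportion of voiced frames for a 'periodic' segment

POSITIONS = ("initial", "medial", "final")

RESPONSE_FAMILIES = {
    "f0": "gaussian_log",
    "duration": "inverse_gaussian_identity",
    "intensity": "gaussian_identity",
    "periodicity": "binomial_logit",
}


def assign_positions(segments) -> list[str]:
    """Position label per segment of one syllable, in order.

    One segment -> ['sole']; otherwise initial, medial..., final.
    """
    n = len(list(segments))
    if n == 0:
        return []
    if n == 1:
        return ["sole"]
    return ["initial"] + ["medial"] * (n - 2) + ["final"]


def add_positions(df: pd.DataFrame, syllable_col: str = "syllable_id") -> pd.DataFrame:
    """Attach a 'position' column to a segment table ordered within syllables."""
    df = df.copy()
    labels = np.empty(len(df), dtype=object)
    for _, idx in df.groupby(syllable_col, sort=False).indices.items():
        order = np.argsort(df.iloc[idx]["start"].to_numpy())
        labels[np.asarray(idx)[order]] = assign_positions(range(len(idx)))
    df["position"] = labels
    return df


def position_summaries(df: pd.DataFrame) -> pd.DataFrame:
    """Grand means of per-individual means, per position.

    Expects columns individual, position, and any of f0 (Hz), duration (s),
    intensity (dB), periodic (bool/0-1). Positions without segments for an
    individual are simply absent (missing, never zero), and each individual
    counts once regardless of its segment count.
    """
    value_cols = [c for c in ("f0", "duration", "intensity", "periodic") if c in df.columns]
    sub = df[df["position"].isin(POSITIONS)]
    if sub.empty:
        raise ValueError("no segments in initial/medial/final positions")
    per_ind = (
        sub.assign(periodic=lambda d: d["periodic"].astype(float) if "periodic" in d else np.nan)
        .groupby(["individual", "position"], observed=True)[value_cols]
        .mean()
    )
    grand = per_ind.groupby("position", observed=True).mean()
    grand = grand.reindex([p for p in POSITIONS if p in grand.index])
    if "periodic" in grand.columns:
        grand = grand.rename(columns={"periodic": "prop_periodic"})
    return grand


@dataclass
class EdgeModelResult:
    response: str
    family: str
    statistic: float
    df: int
    p: float
    converged: bool
    max_vif: float


def _design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X_null, position block, column names): intercept + group dummies, then
    position contrasts (initial as the reference level)."""
    groups = pd.get_dummies(df["group"], prefix="group", drop_first=True, dtype=float)
    pos = pd.Categorical(df["position"], categories=POSITIONS)
    pos_d = pd.get_dummies(pos, prefix="pos", drop_first=True, dtype=float)
    X_null = np.column_stack([np.ones(len(df)), groups.to_numpy()])
    names = ["intercept", *groups.columns, *pos_d.columns]
    return X_null, pos_d.to_numpy(), names


def _max_vif(X: np.ndarray) -> float:
    """Largest variance inflation factor among the non-intercept columns."""
    if X.shape[1] <= 2:
        return 1.0
    vifs = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        ss_res = float(resid @ resid)
        centered = X[:, j] - X[:, j].mean()
        ss_tot = float(centered @ centered)
        if ss_tot <= 0:
            continue
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        vifs.append(1.0 / max(1e-12, 1.0 - r2))
    return max(vifs) if vifs else 1.0


def edge_effect_tests(
    df: pd.DataFrame,
    responses=("f0", "duration", "intensity", "periodicity"),
    n_quad: int = 15,
) -> list[EdgeModelResult]:
    """Likelihood-ratio tests of segment position for each acoustic response.

    `df` needs columns individual, group, position, and per response: f0 (Hz,
    may be missing for aperiodic segments), duration (s), intensity (dB),
    periodic (bool). Segments outside initial/medial/final are dropped. The
    duration model works in milliseconds internally (pure rescaling; the test
    is invariant). Non-convergent fits are returned flagged, never dropped.
    """
    data = df[df["position"].isin(POSITIONS)].copy()
    if data["individual"].nunique() < 2 or data["group"].nunique() < 2:
        raise ValueError("need at least 2 individuals and 2 groups")
    if set(data["position"].unique()) != set(POSITIONS):
        raise ValueError("all three positions must be present")

    results = []
    for resp in responses:
        family = RESPONSE_FAMILIES[resp]
        if resp == "f0":
            sub = data.dropna(subset=["f0"])
            y = sub["f0"].to_numpy(dtype=float)
        elif resp == "duration":
            sub = data.dropna(subset=["duration"])
            y = sub["duration"].to_numpy(dtype=float) * 1000.0
        elif resp == "intensity":
            sub = data.dropna(subset=["intensity"])
            y = sub["intensity"].to_numpy(dtype=float)
        else:
            sub = data.dropna(subset=["periodic"])
            y = sub["periodic"].to_numpy(dtype=float)
        X_null, pos_block, names = _design(sub)
        X_full = np.column_stack([X_null, pos_block])
        out = lrt(y, X_full, X_null, sub["individual"].to_numpy(), family, n_quad=n_quad)
        vif = _max_vif(X_full)
        if not out["converged"]:
            logger.warning("edge model %s did not fully converge", resp)
        results.append(
            EdgeModelResult(
                response=resp,
                family=family,
                statistic=float(out["statistic"]),
                df=int(out["df"]),
                p=float(out["p"]),
                converged=bool(out["converged"]),
                max_vif=float(vif),
            )
        )
    return results
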