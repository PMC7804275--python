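"""Silhouette validation: are segments more discrete units than syllables?

Segments a small synthetic corpus, extracts the 21-variable feature vectors
for recovered segments, whole complex syllables and duration-shuffled snippet
nulls, sweeps hierarchical clusterings over k = 2..15 and compares mean
silhouette widths with the paired signed-rank test. Higher silhouettes for
segments than for both controls indicate the recovered segments are the more
basic, repeatable units.
"""

import numpy as np

from vocseg.evaluation import paired_signed_rank
from vocseg.pipeline import analyze_corpus
from vocseg.synth import budgerigar_plan, synthesize_corpus
from vocseg.tracks import BUDGERIGAR
from vocseg.units import silhouette_sweep

plan = budgerigar_plan(seed=1, groups=4, individuals_per_group=2, syllables_per_individual=20)
analysis = analyze_corpus(synthesize_corpus(plan), BUDGERIGAR, seed=1)

means = {}
for kind in ("segment", "complex_syllable", "snippet"):
    sub = analysis.features[analysis.features["kind"] == kind]
    reports = silhouette_sweep(sub, range(2, 16))
    means[kind] = np.array([r.mean_silhouette for r in reports])
    print(f"{kind:>17}: mean silhouette over k=2..15 = {means[kind].mean():.3f} "
          f"(k=2: {means[kind][0]:.3f})")

for control in ("complex_syllable", "snippet"):
    v, p = paired_signed_rank(means["segment"], means[control])
    print(f"segments vs {control}: V = {v:.0f}, p = {p:.2e}")
# V = 105 means segments scored higher at every one of the 14 cluster sizes.
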