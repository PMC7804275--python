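"""Shared fixtures: small synthetic corpora and their pipeline analyses.

The budgerigar corpus + analysis pair is session-scoped because several test
modules (segmenter closed-loop, clustering, edge effects, acceptance) all
measure different aspects of the same study conditions.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from vocseg.pipeline import analyze_corpus
from vocseg.synth import budgerigar_plan, human_plan, synthesize_corpus
from vocseg.tracks import BUDGERIGAR, HUMAN

logging.getLogger("vocseg").setLevel(logging.ERROR)

CORPUS_SEED = 0  # one fixed draw of the study conditions


@pytest.fixture(scope="session")
def budgie_plan():
    return budgerigar_plan(
        seed=CORPUS_SEED, groups=4, individuals_per_group=2, syllables_per_individual=30
    )


@pytest.fixture(scope="session")
def budgie_corpus(budgie_plan):
    return synthesize_corpus(budgie_plan)


@pytest.fixture(scope="session")
def budgie_analysis(budgie_corpus):
    return analyze_corpus(budgie_corpus, BUDGERIGAR, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def human_corpus():
    plan = human_plan(seed=CORPUS_SEED, groups=2, individuals_per_group=2, syllables_per_individual=8)
    return synthesize_corpus(plan)


@pytest.fixture(scope="session")
def human_analysis(human_corpus):
    return analyze_corpus(human_corpus, HUMAN, seed=CORPUS_SEED, with_snippets=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
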