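"""Shared fixtures: a tiny cohort, small bags for fast model tests, and the
session-scoped full synthetic benchmark run used by the acceptance suite."""

import warnings

import numpy as np
import pytest

from lnmil.cohort import SlideParams, generate_cohort
from lnmil.model import pretrain_fe, train_end_to_end
from lnmil.pipeline import build_bags, run_benchmark

warnings.filterwarnings("ignore", category=FutureWarning)

#: Fast hyperparameters for structural (non-performance) model tests.
FAST_TRAINER = {"pretrain_epochs": 2, "epochs": 4, "pretrain_max_patches": 600}

SMALL_SLIDE = SlideParams(size=256, patch_size=64)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(20, 30, 0.2, 0.2, seed=7)


@pytest.fixture(scope="session")
def small_bags():
    """~30 small bags (256-px slides, 64-px patches) with evidence coverage."""
    cohort = generate_cohort(14, 14, 0.5, 0.5, seed=3)
    bags, evidence_frac = build_bags(cohort, SMALL_SLIDE, 64, 0.5, seed=3)
    assert {b.inherited_label for b in bags} == {0, 1}
    return bags, evidence_frac


@pytest.fixture(scope="session")
def trained_small(small_bags):
    """A quickly trained model on the small bags (structure, not performance)."""
    bags, _ = small_bags
    fe = pretrain_fe(bags, hyper=FAST_TRAINER, seed=5)
    model = train_end_to_end(bags, init=fe, hyper=FAST_TRAINER, seed=6)
    return model


@pytest.fixture(scope="session")
def benchmark_run():
    """The full desk-scale synthetic benchmark (single seeded run)."""
    return run_benchmark(seed=1)
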