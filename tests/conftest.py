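"""Shared fixtures: synthetic datasets and cached benchmark runs.

The full-scale benchmark (default generator, 5 seeds) is expensive, so it
is computed once per session and shared by every test that compares
methods on it.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import metarf as mf

logging.getLogger("metarf").setLevel(logging.ERROR)

BENCH_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-cross HTE-style dataset at the default (Buchwald) scale."""
    dataset, truth = mf.gen_dataset(mf.SynthConfig(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def default_split(default_dataset):
    dataset, _ = default_dataset
    return mf.split_by_group(dataset, n_train=4, n_val=1, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small combinatorial dataset for fast unit-level checks."""
    cfg = mf.SynthConfig(
        roles=(
            mf.RoleSpec("aryl_halide", 4, 3),
            mf.RoleSpec("ligand", 3, 3),
            mf.RoleSpec("base", 2, 3),
            mf.RoleSpec("additive", 6, 3),
        ),
        seed=7,
    )
    dataset, truth = mf.gen_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def benchmark_results(default_dataset, default_split):
    """MetaRF vs enlarged-training RF baseline, 5 seeds, shared supports."""
    dataset, _ = default_dataset
    return mf.run_method_comparison(
        dataset, default_split, n_finetune=5, seeds=BENCH_SEEDS
    )


@pytest.fixture(scope="session")
def random_sampling_results(default_dataset, default_split):
    """The random-support ablation (10 repetitions per seed), 5 seeds."""
    dataset, _ = default_dataset
    return mf.run_ablation(
        dataset, default_split, "metarf_random_sampling",
        n_finetune=5, seeds=BENCH_SEEDS,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
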