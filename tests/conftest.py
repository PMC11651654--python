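"""Shared fixtures: synthetic bundles and pipeline runs reused across test modules.

The two full pipeline runs (null background and planted-loop benchmark) are
session-scoped because they are the expensive part of the suite; everything
else is generated per test.
"""

import pandas as pd
import pytest

import nucleocall as nc
from nucleocall import pipeline as pl

NULL_SEED = 11
BENCH_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def null_bundle():
    return nc.simulate_experiment(nc.SimConfig(seed=NULL_SEED))


@pytest.fixture(scope="session")
def null_result(null_bundle):
    return pl.run_pipeline(null_bundle)


@pytest.fixture(scope="session")
def bench_runs():
    """Planted-loop benchmark pipelines over the fixed seed panel."""
    runs = []
    for seed in BENCH_SEEDS:
        bundle = nc.simulate_experiment(nc.default_benchmark_config(seed=seed))
        runs.append((bundle, pl.run_pipeline(bundle)))
    return runs


@pytest.fixture()
def toy_viewpoints():
    """Three well-separated 1 kb viewpoints on one 10 Mb chromosome."""
    return [
        nc.Viewpoint(id=0, chrom="chr1", start=100_000, end=101_000, mono_occupancy=2.0),
        nc.Viewpoint(id=1, chrom="chr1", start=300_000, end=301_000, mono_occupancy=4.0),
        nc.Viewpoint(id=2, chrom="chr1", start=700_000, end=701_000, mono_occupancy=1.0),
    ]


def make_pairs(rows):
    return pd.DataFrame(rows, columns=list(nc.pairs.PAIR_FIELDS))
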