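"""Shared fixtures: toy call builders and a cached simulation grid.

The simulation grid (10 seeds x 6 cell counts x 2 replicates on the
default genome) backs both the module-level Monte Carlo tests and the
acceptance properties; it is built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsecellqc import AmplificationModel, build_genome, simulate_assay
from sparsecellqc.synthetic_data import assay_seed
from sparsecellqc.variant_io import AssayReplicate, VariantCall

CELL_COUNTS = [1, 2, 5, 10, 25, 50]
N_SEEDS = 10


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gt="het",
    ad=(15, 15),
    dp=None,
    pl=(40, 0, 40),
    filter_status="PASS",
) -> VariantCall:
    if dp is None:
        dp = ad[0] + ad[1]
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotype_class=gt,
        ref_depth=ad[0], alt_depth=ad[1], total_depth=dp, pl=tuple(pl),
        filter_status=filter_status,
    )


def make_replicate(calls, sample_id="toy", cell_count=1, replicate_index=0) -> AssayReplicate:
    return AssayReplicate(
        sample_id=sample_id, cell_count=cell_count,
        replicate_index=replicate_index, calls=list(calls),
    )


@pytest.fixture(scope="session")
def genome():
    return build_genome(seed=0)


@pytest.fixture(scope="session")
def model():
    return AmplificationModel()


@pytest.fixture(scope="session")
def sim_grid(genome, model):
    """replicates[seed][cell_count] -> [rep0, rep1] on the default genome."""
    grid = {}
    for seed in range(N_SEEDS):
        grid[seed] = {
            cc: [
                simulate_assay(genome, model, cc, seed=assay_seed(seed, cc, r), replicate_index=r)
                for r in range(2)
            ]
            for cc in CELL_COUNTS
        }
    return grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
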