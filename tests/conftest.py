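"""Shared fixtures: small genomes, founder sets, and the desk-scale
scenario experiment reused by the acceptance-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from pulsegs.founders import simulate_founders
from pulsegs.genmap import build_map
from pulsegs.program import run_experiment
from pulsegs.traits import partition_loci, sample_architecture

DESK_SCENARIOS = [
    "GS_SSD_STG2", "GS_aSSD_STG2", "GS_SSD_F6", "GS_aSSD_F6",
    "GS_SSD_F2", "GS_SSD_F1", "GS_SSD_F2_DP", "GS_aSSD_F2_PH",
]


@pytest.fixture(scope="session")
def small_map():
    # two chromosomes, enough loci for a marker panel plus QTL after the
    # founder MAF filter prunes the low-frequency tail
    return build_map(2, (500, 550), (150.0, 300.0), seed=11)


@pytest.fixture(scope="session")
def small_founders(small_map):
    return simulate_founders(small_map, n_lines=200, burn_in_generations=30,
                             seed=5)


@pytest.fixture(scope="session")
def small_panel(small_founders):
    markers, qtl_pool = partition_loci(small_founders.map, 150, seed=2)
    return markers, qtl_pool


@pytest.fixture(scope="session")
def small_arch(small_founders, small_panel):
    markers, qtl_pool = small_panel
    return sample_architecture(small_founders.map, qtl_pool, n_qtl=60,
                               seed=7, founders=small_founders.population)


@pytest.fixture(scope="session")
def desk_metrics():
    """Replicated desk-scale comparison of all strategy branches.

    One shared 10-replicate experiment: phenotypic selection plus the six
    generation-interval scenarios, the diversity-preservation branch and
    the F2-phenotyping branch, all branched from common warm starts.
    """
    return run_experiment(DESK_SCENARIOS, replicates=10, base_seed=1,
                          preset="desk")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
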