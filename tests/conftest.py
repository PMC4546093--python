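"""Shared fixtures: a small seeded synthetic study and its pipeline result."""
from __future__ import annotations

import numpy as np
import pytest

from dupscan.pipeline import PipelineConfig, analyze
from dupscan.synthetic_genome import EventSpec, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two chromosomes, twelve background genes, five planted events covering
    every structural class plus a conversion tract."""
    cfg = SimConfig(n_chromosomes=2, genes_per_chromosome=6)
    specs = [
        EventSpec("complete", "intra", "direct", target_ks=0.02),
        EventSpec("partial", "intra", "inverse", target_ks=0.05),
        EventSpec("chimeric", "inter", "direct", target_ks=0.01),
        EventSpec("retro", "inter", "direct", target_ks=0.03),
        EventSpec("complete", "intra", "direct", target_ks=0.0,
                  conversion_tract=400),
    ]
    return simulate_study(cfg, seed=7, specs=specs)


@pytest.fixture(scope="session")
def small_result(small_study):
    return analyze(
        small_study.genome,
        [_copy_gene(g) for g in small_study.genes],
        PipelineConfig(seed=1, n_perm=2000),
        outgroup=(small_study.outgroup_genome,
                  [_copy_gene(g) for g in small_study.outgroup_genes]),
        centromeres=small_study.centromeres,
    )


def _copy_gene(gene):
    import copy

    return copy.deepcopy(gene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
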