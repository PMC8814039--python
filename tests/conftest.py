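"""Shared fixtures: one small hexaploid simulation reused across the suite.

The small scenario keeps the reference-scenario structure (K=3 subgenomes at
divergences 1/3/6%, diploid at 0.5%) at reduced chromosome size so tests on
every pipeline stage stay fast.
"""

import numpy as np
import pytest

from polyscaf.params import PipelineConfig, SimParams
from polyscaf import simdata


SMALL = dict(
    chromosome_length=200_000,
    n_contact_pairs=20_000,
    mean_contig_length=20_000,
    min_contig_length=4_000,
    telomere_copies=50,
    centromere_copies=50,
    seed=11,
)


@pytest.fixture(scope="session")
def small_params():
    return SimParams(**SMALL)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simdata.simulate(small_params)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free contacts: no mis-mapping, no inter-chromosomal background."""
    return simdata.simulate(
        SimParams(**SMALL, mismap_fraction=0.0, inter_chromosome_background=0.0)
    )


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig(n_subgenomes=3, seed=11)


@pytest.fixture(scope="session")
def small_assignment(small_sim, pipeline_cfg):
    from polyscaf.assign import assign_subgenomes

    return assign_subgenomes(
        small_sim.contigs, [small_sim.diploid], small_sim.pairs, pipeline_cfg
    )


@pytest.fixture(scope="session")
def small_build(small_sim, small_assignment, pipeline_cfg):
    from polyscaf.build import build_chromosomes

    assignment, _ = small_assignment
    return build_chromosomes(
        small_sim.contigs, assignment, small_sim.diploid, small_sim.pairs,
        pipeline_cfg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
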