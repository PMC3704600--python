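"""Shared fixtures: a compact simulated study run through the pipeline once.

The small study (depth 2e4, 60 kb chromosomes) keeps unit tests fast; the
full-scale study used by the acceptance tests lives in test_acceptance.py.
"""

from __future__ import annotations

import pytest

from soymir.design import library_ids, make_design
from soymir.reads import process_libraries
from soymir.simulate import SimConfig, Simulator


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    cfg = SimConfig(seed=7, depth=20_000, chrom_len=60_000)
    sim = Simulator(cfg)
    truth = sim.build_truth()
    libdir = tmp_path_factory.mktemp("small_sim_libs")
    fastq = sim.simulate_libraries(libdir)
    return {"config": cfg, "sim": sim, "truth": truth, "fastq": fastq}


@pytest.fixture(scope="session")
def small_processed(small_sim):
    cfg = small_sim["config"]
    truth = small_sim["truth"]
    tags, hits, stats = process_libraries(
        small_sim["fastq"], truth.genome, cfg.adapter3
    )
    return {"tags": tags, "hits": hits, "stats": stats}


@pytest.fixture(scope="session")
def libs():
    return library_ids()


@pytest.fixture(scope="session")
def genotype_of():
    return {d.library_id: d.genotype for d in make_design()}
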