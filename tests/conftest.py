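"""Shared synthetic dataset fixtures.

One small end-to-end simulation (600 triple sites + 200 control sites on a
3 Mb genome) is generated once per session and reused across module tests;
tests needing special generator settings build their own configs.
"""

import numpy as np
import pytest

import cooccupy as cp

SEED = 11


@pytest.fixture(scope="session")
def config():
    return cp.SimulationConfig(
        seed=SEED,
        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
        n_sites=600,
        n_control_sites=200,
        n_genes=500,
    )


@pytest.fixture(scope="session")
def genome_and_truth(config):
    genome = cp.generate_genome(config)
    truth = cp.plant_sites(genome, config)
    return genome, truth


@pytest.fixture(scope="session")
def genome(genome_and_truth):
    return genome_and_truth[0]


@pytest.fixture(scope="session")
def truth(genome_and_truth):
    return genome_and_truth[1]


@pytest.fixture(scope="session")
def tracks(genome_and_truth, config):
    genome, truth = genome_and_truth
    return cp.render_tracks(truth, genome, config)


@pytest.fixture(scope="session")
def peaksets(genome_and_truth, config):
    genome, truth = genome_and_truth
    return cp.emit_peaks(truth, genome, config)


@pytest.fixture(scope="session")
def occurrences(genome_and_truth, config):
    genome, _ = genome_and_truth
    return cp.scan_consensus(genome, config.motif_consensus)


@pytest.fixture(scope="session")
def genes_expression(genome_and_truth, config):
    genome, truth = genome_and_truth
    return cp.generate_genes_and_expression(truth, genome, config)


@pytest.fixture(scope="session")
def hmg20b_cohorts(peaksets):
    return cp.assign_cohorts(peaksets["hmg20b"], 10)
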