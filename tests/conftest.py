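"""Shared fixtures: a small simulated cohort reused across module tests."""
from types import SimpleNamespace

import numpy as np
import pytest

from migseq.library_sim import (CohortSpec, SimConfig, simulate_cohort,
                                simulate_genome, simulate_reads)
from migseq.preprocess import preprocess_reads, sample_reads_to_records
from migseq.primer_design import published_set1
from migseq.stack_genotyper import GenotyperConfig, genotype_samples

try:  # keep hypothesis deterministic when present
    from hypothesis import settings
    settings.register_profile("det", derandomize=True, max_examples=50)
    settings.load_profile("det")
except ImportError:  # pragma: no cover
    pass


def rand_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def set1():
    return published_set1()


@pytest.fixture(scope="session")
def small_sim():
    """20-locus megagametophyte cohort with default error rates."""
    cfg = SimConfig(seed=11, n_loci=20, genome_len=30_000, dropout_rate=0.1)
    genome, loci = simulate_genome(cfg)
    spec = CohortSpec(design="megagametophyte_panel", n_het_loci=8)
    truth = simulate_cohort(loci, spec, cfg)
    reads = simulate_reads(genome, truth)
    return SimpleNamespace(cfg=cfg, genome=genome, loci=loci, truth=truth,
                           reads=reads, spec=spec)


@pytest.fixture(scope="session")
def small_gm(small_sim):
    """Genotype matrix called from the small simulated cohort."""
    by_sample = {}
    for s, bundle in small_sim.reads.items():
        survivors, _ = preprocess_reads(sample_reads_to_records(bundle))
        by_sample[s] = [r.seq for r in survivors]
    ploidy = {s: int(p) for s, p in small_sim.truth.samples["ploidy"].items()}
    return genotype_samples(by_sample, GenotyperConfig(), ploidy_map=ploidy,
                            apply_population_filter=False)
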