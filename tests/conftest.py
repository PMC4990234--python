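"""Shared fixtures and instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mossdge.io import AlignmentInterval, GeneModel, SpliceJunction
from mossdge.simulate import SimConfig, simulate_experiment


def alignments_to_reads(alignments):
    """Group alignment segments into oracle-style read tuples
    (chrom, [(start, end), ...], sample)."""
    grouped = {}
    for i, a in enumerate(alignments):
        key = (a.sample, a.read_id) if a.read_id is not None else ("", i)
        grouped.setdefault(key, []).append(a)
    reads = []
    for segs in grouped.values():
        reads.append(
            (segs[0].chrom, sorted((s.start, s.end) for s in segs), segs[0].sample)
        )
    return reads


def junctions_to_tuples(junctions):
    return [(j.chrom, j.donor, j.acceptor) for j in junctions]


def models_to_tuples(models):
    return [(m.chrom, m.start, m.end, m.id) for m in models]


def random_instance(seed: int):
    """A random small problem: reads, junctions and models.

    Alternates between structured instances (simulated annotated
    genomes, including spliced reads) and unstructured ones (random
    read scatter with random junctions and random non-overlapping
    models), to exercise the rules away from gene-shaped coverage.
    """
    rng = np.random.default_rng(seed)
    if seed % 2 == 0:
        cfg = SimConfig(
            n_chroms=int(rng.integers(1, 3)),
            chrom_length=30_000,
            n_genes=int(rng.integers(2, 7)),
            gene_length_range=(400, 2500),
            min_intergenic_gap=int(rng.integers(200, 1200)),
            lib_size_control=int(rng.integers(50, 400)),
            lib_size_treated=int(rng.integers(50, 400)),
            fraction_spliced=float(rng.uniform(0, 0.8)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth, aln = simulate_experiment(cfg)
        return aln, truth.junctions, truth.gene_models
    # unstructured scatter
    length = 12_000
    n_reads = int(rng.integers(5, 200))
    aln = []
    for i in range(n_reads):
        s = int(rng.integers(0, length - 60))
        w = int(rng.integers(25, 60))
        sample = "control" if rng.random() < 0.5 else "treated"
        aln.append(AlignmentInterval("chr1", s, s + w, sample, f"r{i}"))
    junctions = []
    for _ in range(int(rng.integers(0, 6))):
        d = int(rng.integers(50, length - 2_000))
        span = int(rng.integers(80, 12_000))
        junctions.append(SpliceJunction("chr1", d, min(d + span, length - 10)))
    cuts = sorted(rng.choice(np.arange(100, length - 100), size=8, replace=False))
    models = []
    for k in range(0, len(cuts) - 1, 2):
        if rng.random() < 0.7:
            models.append(GeneModel("chr1", int(cuts[k]), int(cuts[k + 1]), f"m{k}"))
    return aln, junctions, models


@pytest.fixture
def small_sim():
    cfg = SimConfig(
        n_chroms=2,
        chrom_length=60_000,
        n_genes=12,
        lib_size_control=4_000,
        lib_size_treated=4_000,
        fraction_spliced=0.4,
        seed=42,
    )
    truth, aln = simulate_experiment(cfg)
    return cfg, truth, aln
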