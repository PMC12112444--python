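"""Shared fixtures: hand-built genotype tables and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popfinger import (
    CohortSimulator,
    GenotypeMatrix,
    PopulationMap,
    SimConfig,
)


def make_matrix(
    dosages,
    chrom="chr1",
    positions=None,
    ref="A",
    alt="G",
    types=None,
    samples=None,
    ids=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a samples x sites dosage array with
    minimal metadata; scalars are broadcast across sites."""
    d = np.asarray(dosages, dtype=np.int8)
    n_sites = d.shape[1]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites if isinstance(chrom, str) else list(chrom),
            "pos": list(positions),
            "ref": [ref] * n_sites if isinstance(ref, str) else list(ref),
            "alt": [alt] * n_sites if isinstance(alt, str) else list(alt),
            "type": ["snp"] * n_sites if types is None else list(types),
        }
    )
    if ids is not None:
        sites["id"] = list(ids)
    if samples is None:
        samples = [f"s{i}" for i in range(d.shape[0])]
    return GenotypeMatrix(d, sites, samples)


@pytest.fixture(scope="session")
def tilapia_fingerprint():
    """The seven-marker fingerprint of the three tilapia populations."""
    from popfinger.datasets import tilapia_fingerprint_example

    return tilapia_fingerprint_example()


@pytest.fixture(scope="session")
def default_cohort():
    """Default three-population cohort (planted sweep + diagnostics)."""
    config = SimConfig(seed=11, n_sites=4000)
    return config, CohortSimulator(config).run()


@pytest.fixture(scope="session")
def cascade_fixture():
    """Eight loci engineered so exactly one violates each filtering stage:

    L2 indel (stage 1), L3 low MAF (stage 2), L4 intergenic (stage 3),
    L5 MAF between the two thresholds (stage 5), L6 duplicate of L1 within
    the pruning window (stage 6).  L1/L7/L8 survive on separate
    chromosomes.
    """
    from popfinger import AnnotationIndex, GeneModel

    pops = {f"s{i}": f"P{i // 5 + 1}" for i in range(15)}
    popmap = PopulationMap(pops)

    def pattern(p1, p2, p3):
        return np.repeat([p1, p2, p3], 5)

    cols = {
        "L1": pattern(2, 0, 0),
        "L6": pattern(2, 0, 0),                      # r^2 = 1 with L1
        "L2": pattern(2, 0, 0),                      # indel
        "L3": np.array([2] + [0] * 14),              # MAF 2/30 < 0.2
        "L5": np.array([2, 2, 2, 2] + [0] * 11),     # MAF 8/30 in (0.2, 0.3]
        "L4": pattern(2, 0, 0),                      # intergenic (chr2)
        "L7": pattern(0, 2, 0),
        "L8": pattern(0, 0, 2),
    }
    order = ["L1", "L6", "L2", "L3", "L5", "L4", "L7", "L8"]
    chroms = ["chr1", "chr1", "chr1", "chr1", "chr1", "chr2", "chr3", "chr4"]
    positions = [100, 150, 300_000, 400_000, 600_000, 100, 100, 100]
    m = make_matrix(
        np.column_stack([cols[k] for k in order]),
        chrom=chroms,
        positions=positions,
        types=["snp", "snp", "indel", "snp", "snp", "snp", "snp", "snp"],
        ids=order,
        samples=list(pops),
    )
    ann = AnnotationIndex.from_gene_models(
        [
            GeneModel("g1", "chr1", 0, 1_000_000, ()),
            GeneModel("g3", "chr3", 0, 1_000, ()),
            GeneModel("g4", "chr4", 0, 1_000, ()),
        ],
        {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000, "chr4": 2_000_000},
    )
    return m, popmap, ann


def two_pop_config(seed: int, drift: float = 0.2, **kwargs) -> SimConfig:
    """A plain two-population divergence design (no hybrid, no planting)."""
    defaults = dict(
        pop_names=("P1", "P2"),
        samples_per_pop=30,
        n_sites=5_000,
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        drift_F={"P1": drift, "P2": drift},
        within_fis={"P1": 0.0, "P2": 0.0},
        hybrid_spec=None,
        n_diagnostic=0,
        sweep_specs=(),
        missing_rate=0.0,
        indel_rate=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)
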