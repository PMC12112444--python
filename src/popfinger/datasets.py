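"""Small built-in example datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd

from popfinger.io import GenotypeMatrix, PopulationMap


def tilapia_fingerprint_example() -> tuple[GenotypeMatrix, PopulationMap]:
    """Seven-marker fingerprint of three tilapia breeding populations.

    45 individuals: 15 blue tilapia, 15 Nile tilapia, 15 red tilapia.
    Five of the markers (SNP1, SNP3, SNP5, SNP6, SNP7) each fix one
    population for one homozygote and the other two populations for the
    alternative homozygote, so each can isolate one population.  SNP2 and
    SNP4 are heterogeneous within the Nile and red populations (a few
    individuals carry AA where most carry GG) and cannot separate the
    populations.
    """
    pops = ["blue_tilapia"] * 15 + ["nile_tilapia"] * 15 + ["red_tilapia"] * 15
    samples = [f"{p.split('_')[0]}_{i % 15 + 1:02d}" for i, p in enumerate(pops)]

    # marker, ref, alt, dosage in (blue, nile, red)
    spec = [
        ("SNP1", "C", "T", 2, 0, 0),  # blue TT, others CC
        ("SNP2", "G", "A", 2, 0, 0),  # nile/red heterogeneous, see below
        ("SNP3", "C", "T", 0, 2, 0),  # nile TT, others CC
        ("SNP4", "G", "A", 2, 0, 0),  # nile/red heterogeneous, see below
        ("SNP5", "C", "G", 2, 0, 0),  # blue GG, others CC
        ("SNP6", "G", "A", 2, 0, 0),  # blue AA, others GG
        ("SNP7", "T", "C", 2, 0, 0),  # blue CC, others TT
    ]
    cols = []
    for _, _, _, blue_d, nile_d, red_d in spec:
        col = np.empty(45, dtype=np.int8)
        col[0:15], col[15:30], col[30:45] = blue_d, nile_d, red_d
        cols.append(col)
    # SNP2/SNP4: some Nile and red individuals AA (dosage 2) instead of GG
    for j in (1, 3):
        cols[j][[16, 18, 33]] = 2

    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 7,
            "pos": [(k + 1) * 1_000_000 for k in range(7)],
            "ref": [s[1] for s in spec],
            "alt": [s[2] for s in spec],
            "type": ["snp"] * 7,
            "id": [s[0] for s in spec],
        }
    )
    matrix = GenotypeMatrix(np.column_stack(cols), sites, samples)
    popmap = PopulationMap(dict(zip(samples, pops)))
    return matrix, popmap
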