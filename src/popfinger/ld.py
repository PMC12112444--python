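"""Linkage disequilibrium from unphased genotypes.

The default pairwise statistic is the squared Pearson correlation of
dosages (Rogers & Huff 2009), which needs no phasing.  A two-locus
haplotype-frequency EM is available for D and D' (only the double
heterozygote is phase-ambiguous at biallelic loci).  Decay curves average
r^2 in distance bins over all (optionally subsampled) intra-chromosome
pairs per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from popfinger.io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


class LDPair(NamedTuple):
    r2: float
    d: float | None = None
    d_prime: float | None = None


def ld_pair(a, b, method: str = "dosage_r2", tol: float = 1e-10, max_iter: int = 200) -> LDPair:
    """LD between two loci from dosage vectors.

    ``dosage_r2``: squared Pearson correlation over pairwise-complete
    samples.  ``em_haplotype``: haplotype-frequency EM, returning r^2, D
    and D' = D / D_max.  Raises ValueError when fewer than two co-called
    samples remain or either locus is monomorphic among them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 co-called samples")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("monomorphic locus among co-called samples")
    if method == "dosage_r2":
        r = np.corrcoef(a, b)[0, 1]
        return LDPair(r2=float(r * r))
    if method != "em_haplotype":
        raise ValueError(f"unknown method {method!r}")

    n = a.size
    pA = float(np.mean(a)) / 2.0  # alt freq at locus 1
    pB = float(np.mean(b)) / 2.0
    # haplotypes over alleles (x, y), x from locus 1, y from locus 2; start at LE
    hap = np.array([
        (1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB
    ])
    dbl_het = (a == 1) & (b == 1)
    n_dbl = int(dbl_het.sum())
    # fixed haplotype counts from unambiguous genotypes
    base = np.zeros(4)
    combos, counts = np.unique(np.column_stack([a, b]), axis=0, return_counts=True)
    for (g1, g2), cnt in zip(combos, counts):
        if g1 == 1 and g2 == 1:
            continue
        # locus-1 alleles: g1 copies of alt, 2-g1 of ref; same locus 2
        base[0] += cnt * (2 - g1) * (2 - g2) / 2.0
        base[1] += cnt * (2 - g1) * g2 / 2.0
        base[2] += cnt * g1 * (2 - g2) / 2.0
        base[3] += cnt * g1 * g2 / 2.0
    for _ in range(max_iter):
        # double hets are ref-ref/alt-alt with prob prop. to h0*h3, else h1*h2
        p_coupling = hap[0] * hap[3]
        p_repulsion = hap[1] * hap[2]
        tot = p_coupling + p_repulsion
        w = 0.5 if tot == 0 else p_coupling / tot
        counts_new = base.copy()
        counts_new[0] += n_dbl * w
        counts_new[3] += n_dbl * w
        counts_new[1] += n_dbl * (1 - w)
        counts_new[2] += n_dbl * (1 - w)
        hap_new = counts_new / (2.0 * n)
        if np.max(np.abs(hap_new - hap)) < tol:
            hap = hap_new
            break
        hap = hap_new
    pA = hap[2] + hap[3]
    pB = hap[1] + hap[3]
    d = hap[3] - pA * pB
    if d >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else d / d_max
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else d * d / denom
    return LDPair(r2=float(r2), d=float(d), d_prime=float(d_prime))


@dataclass
class LDDecayCurve:
    """Binned mean r^2 against inter-site distance for one population."""

    bins: pd.DataFrame  # columns: bin_start, bin_end, mean_r2, n_pairs
    n_pairs: int
    n_skipped: int
    half_decay_distance: float | None  # bp, or None if not reached / no pairs

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def _pair_r2(D: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Vectorised pairwise-complete dosage r^2 for index pairs; NaN where
    undefined (monomorphic or < 2 co-called)."""
    A = D[:, i_idx].astype(float)
    B = D[:, j_idx].astype(float)
    M = (A != MISSING) & (B != MISSING)
    n = M.sum(axis=0).astype(float)
    A = np.where(M, A, 0.0)
    B = np.where(M, B, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = A.sum(axis=0) / n
        mb = B.sum(axis=0) / n
        cov = (A * B * 1.0).sum(axis=0) / n - ma * mb
        va = (A * A).sum(axis=0) / n - ma * ma
        vb = (B * B).sum(axis=0) / n - mb * mb
        r2 = cov * cov / (va * vb)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_decay(
    matrix: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    max_dist: int = 1_000_000,
    bin_width: int = 50_000,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> dict[str, LDDecayCurve]:
    """Per-population LD decay curves.

    All intra-chromosome site pairs within ``max_dist`` are scored (after
    random subsampling to ``max_pairs`` when larger); pairs where either
    locus is monomorphic among co-called samples are skipped and counted.
    The half-decay distance is the start of the first bin whose mean r^2
    falls to half the maximum bin mean, or None if never reached.
    """
    if popmap is None:
        groups = {"all": np.arange(matrix.n_samples)}
    else:
        groups = popmap.indices(matrix)
    rng = np.random.default_rng(seed)

    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        hi = np.searchsorted(p, p + max_dist, side="right")
        counts = hi - np.arange(idx.size) - 1
        if counts.sum() <= 0:
            continue
        ii = np.repeat(np.arange(idx.size), counts)
        jj = np.concatenate([np.arange(k + 1, h) for k, h in enumerate(hi) if h > k + 1])
        pair_i.append(idx[ii])
        pair_j.append(idx[jj])
    if not pair_i:
        empty = pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
        return {pop: LDDecayCurve(empty.copy(), 0, 0, None) for pop in groups}

    i_idx = np.concatenate(pair_i)
    j_idx = np.concatenate(pair_j)
    if i_idx.size > max_pairs:
        sub = rng.choice(i_idx.size, size=max_pairs, replace=False)
        i_idx, j_idx = i_idx[sub], j_idx[sub]
    dist = pos[j_idx] - pos[i_idx]

    edges = np.arange(0, max_dist + bin_width, bin_width)
    out: dict[str, LDDecayCurve] = {}
    for pop, samp in groups.items():
        r2 = _pair_r2(matrix.dosages[samp], i_idx, j_idx)
        ok = np.isfinite(r2)
        n_skipped = int((~ok).sum())
        d_ok, r_ok = dist[ok], r2[ok]
        which = np.clip(np.digitize(d_ok, edges) - 1, 0, len(edges) - 2)
        rows = []
        for b in range(len(edges) - 1):
            sel = which == b
            rows.append({
                "bin_start": int(edges[b]),
                "bin_end": int(edges[b + 1]),
                "mean_r2": float(np.mean(r_ok[sel])) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            })
        bins = pd.DataFrame(rows)
        half = None
        means = bins["mean_r2"].to_numpy()
        if np.isfinite(means).any():
            peak = np.nanmax(means)
            below = np.flatnonzero(np.isfinite(means) & (means <= peak / 2.0))
            if below.size:
                half = float(bins["bin_start"].iloc[below[0]])
        out[pop] = LDDecayCurve(bins=bins, n_pairs=int(ok.sum()),
                                n_skipped=n_skipped, half_decay_distance=half)
    return out
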