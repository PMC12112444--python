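"""Genotype data model and standard-format I/O.

The in-memory representation is a dense samples x sites matrix of diploid
alternate-allele dosages (0, 1, 2) with ``MISSING`` (-1) for uncalled
genotypes, plus a per-site metadata table and an ordered sample list.  All
downstream statistics consume this model.  Coordinates are 1-based in
VCF/GFF3 files and 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Dosage code for an uncalled (missing) genotype.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "type"]


class VcfParseError(ValueError):
    """Raised for malformed or unsupported VCF records."""


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing_cols:
        raise ValueError(f"site table missing columns: {missing_cols}")
    if "id" not in sites.columns:
        sites = sites.copy()
        sites["id"] = [
            f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])
        ]
    return sites.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with per-site metadata.

    Parameters
    ----------
    dosages
        Integer array of shape (n_samples, n_sites) with entries in
        {0, 1, 2, MISSING}.
    sites
        DataFrame with columns chrom, pos (1-based), ref, alt,
        type ('snp' or 'indel') and an 'id' column (added if absent),
        sorted by (chrom, pos).
    samples
        Ordered unique sample identifiers.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        self.sites = _check_sites(self.sites)
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs must be unique")
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0, 1, 2, MISSING}")
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(self.sites))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, same shape as ``dosages``."""
        return self.dosages != MISSING

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sites.iloc[index],
            self.samples,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.sites,
            [self.samples[i] for i in index],
        )

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass
class PopulationMap:
    """Sample -> population assignment.

    Iteration order of ``populations`` follows first appearance in the
    mapping, so simulator output and file round-trips are stable.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = dict(self.assignments)
        if not self.assignments:
            raise ValueError("population map is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def indices(self, matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Per-population sample indices into ``matrix`` (every matrix sample
        must be mapped)."""
        unmapped = [s for s in matrix.samples if s not in self.assignments]
        if unmapped:
            raise ValueError(f"samples missing from population map: {unmapped[:5]}")
        out: dict[str, np.ndarray] = {}
        for pop in self.populations:
            idx = [i for i, s in enumerate(matrix.samples) if self.assignments[s] == pop]
            if idx:
                out[pop] = np.array(idx, dtype=int)
        return out

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[s] for s in samples])


@dataclass
class AlleleStats:
    """Per-site allele summaries for one sample group.

    ``p`` is the alternate-allele frequency among called genotypes; sites
    with no called genotype have ``defined`` False and ``p`` NaN.
    """

    p: np.ndarray
    n_called: np.ndarray
    het_count: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.n_called > 0

    @property
    def polymorphic(self) -> np.ndarray:
        return self.defined & (self.p > 0) & (self.p < 1)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


def allele_freqs(matrix: GenotypeMatrix, group: np.ndarray | None = None) -> AlleleStats:
    """Alternate-allele frequency, called count and heterozygote count per site.

    Parameters
    ----------
    group
        Optional sample indices restricting the computation to one
        population; default is all samples.
    """
    d = matrix.dosages if group is None else matrix.dosages[np.asarray(group, dtype=int)]
    if d.shape[0] == 0:
        raise ValueError("sample group is empty")
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    het = ((d == 1) & called).sum(axis=0)
    return AlleleStats(p=p, n_called=n_called.astype(int), het_count=het.astype(int))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(matrix.samples)
    lines.append("\t".join(header))
    sites = matrix.sites
    dosages = matrix.dosages
    for j in range(matrix.n_sites):
        row = sites.iloc[j]
        gts = "\t".join(_GT_STRINGS[int(g)] for g in dosages[:, j])
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc


def read_vcf(path: str | Path, multiallelic: str = "drop") -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Half-missing genotypes are treated as missing.  Multi-allelic records are
    dropped (default) or split into one biallelic record per alternate
    allele (``multiallelic='split'``); split records count only the focal
    alternate allele in the dosage.  Site type is 'snp' when REF and ALT are
    both single bases, 'indel' otherwise.
    """
    from cyvcf2 import VCF

    path = str(path)
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str] = []
    cols: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        gts = var.genotypes
        for g in gts:
            if len(g) != 3:  # [allele1, allele2, phased]
                raise VcfParseError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS}"
                )
        alt_list = var.ALT
        if len(alt_list) == 0:
            continue
        if len(alt_list) > 1 and multiallelic == "drop":
            n_dropped += 1
            continue
        a1 = np.array([g[0] for g in gts], dtype=int)
        a2 = np.array([g[1] for g in gts], dtype=int)
        ok = (a1 >= 0) & (a2 >= 0)
        for k, alt in enumerate(alt_list, start=1):
            dose = (a1 == k).astype(np.int8) + (a2 == k).astype(np.int8)
            dose[~ok] = MISSING
            chroms.append(var.CHROM)
            positions.append(var.POS)
            refs.append(var.REF)
            alts.append(alt)
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            ids.append(vid if len(alt_list) == 1 else f"{vid}_{alt}")
            cols.append(dose)
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic records", n_dropped)
    if not cols:
        raise VcfParseError(f"no usable biallelic records in {path}")
    types = [
        "snp" if len(r) == 1 and len(a) == 1 else "indel"
        for r, a in zip(refs, alts)
    ]
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts, "type": types, "id": ids}
    )
    return GenotypeMatrix(np.column_stack(cols), sites, samples)


# ---------------------------------------------------------------------------
# Population map TSV
# ---------------------------------------------------------------------------

def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    """Write sample<TAB>population, one line per sample."""
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in popmap.assignments.items())
    )


def read_popmap(path: str | Path) -> PopulationMap:
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
        assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)
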