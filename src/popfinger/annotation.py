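"""Gene annotation index and functional classification of variant sites.

Genes and exons are held as per-chromosome interval trees (0-based
half-open).  A site is classified exonic if it falls in an exon, intronic if
it falls in a gene but not an exon, and intergenic otherwise — the coarse
classes a whole-genome SNP annotation reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from popfinger.io import GenotypeMatrix

logger = logging.getLogger(__name__)

CLASSES = ("exonic", "intronic", "intergenic")


class GeneModel(NamedTuple):
    """A gene with its exons; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]


@dataclass
class AnnotationIndex:
    """Interval store of gene and exon features per chromosome."""

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    exons: dict[str, IntervalTree] = field(default_factory=dict)
    chrom_lengths: dict[str, int] | None = None

    @classmethod
    def from_gene_models(
        cls,
        models: Sequence[GeneModel],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "AnnotationIndex":
        genes: dict[str, IntervalTree] = {}
        exons: dict[str, IntervalTree] = {}
        for m in models:
            if not m.start < m.end:
                raise ValueError(f"gene {m.gene_id}: invalid interval [{m.start},{m.end})")
            if chrom_lengths is not None and m.chrom in chrom_lengths:
                if m.end > chrom_lengths[m.chrom]:
                    raise ValueError(f"gene {m.gene_id} extends past chromosome end")
            genes.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m.gene_id)
            for s, e in m.exons:
                if not (m.start <= s < e <= m.end):
                    raise ValueError(f"gene {m.gene_id}: exon [{s},{e}) outside gene")
                exons.setdefault(m.chrom, IntervalTree()).addi(s, e, m.gene_id)
        return cls(genes=genes, exons=exons,
                   chrom_lengths=dict(chrom_lengths) if chrom_lengths else None)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationIndex":
        """Load gene/exon features from a GFF3 file (via gffutils)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        models: list[GeneModel] = []
        lengths: dict[str, int] = {}
        for gene in db.features_of_type("gene"):
            exons = tuple(
                (e.start - 1, e.end)
                for e in db.children(gene, featuretype="exon", order_by="start")
            )
            models.append(
                GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end, exons)
            )
        for d in db.directives:
            # ##sequence-region <chrom> <start> <end>
            parts = d.split()
            if parts and parts[0] == "sequence-region" and len(parts) == 4:
                lengths[parts[1]] = int(parts[3])
        return cls.from_gene_models(models, lengths or None)

    def classify_position(self, chrom: str, pos0: int) -> str:
        """Class of a single 0-based position."""
        if chrom in self.exons and self.exons[chrom].overlaps(pos0):
            return "exonic"
        if chrom in self.genes and self.genes[chrom].overlaps(pos0):
            return "intronic"
        return "intergenic"

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> list[str]:
        """Gene IDs overlapping a 0-based half-open interval, sorted."""
        if chrom not in self.genes:
            return []
        return sorted({iv.data for iv in self.genes[chrom].overlap(start0, end0)})


def classify_sites(
    matrix: GenotypeMatrix, annotation: AnnotationIndex
) -> tuple[np.ndarray, pd.Series]:
    """Assign each site exactly one functional class.

    Returns the per-site class array (aligned with ``matrix.sites``) and a
    tally Series over all classes.  Sites on chromosomes absent from the
    annotation are classed intergenic; their count is logged as a warning.
    """
    classes = np.empty(matrix.n_sites, dtype=object)
    unknown_chrom = 0
    known = set(annotation.genes) | set(annotation.exons)
    for j, (chrom, pos) in enumerate(zip(matrix.sites["chrom"], matrix.sites["pos"])):
        if chrom not in known:
            unknown_chrom += 1
            classes[j] = "intergenic"
        else:
            classes[j] = annotation.classify_position(chrom, int(pos) - 1)
    if unknown_chrom:
        logger.warning(
            "classify_sites: %d sites on chromosomes absent from annotation "
            "classed intergenic", unknown_chrom,
        )
    tally = pd.Series(
        {c: int((classes == c).sum()) for c in CLASSES}, name="n_sites"
    )
    return classes, tally


def write_gff3(
    models: Sequence[GeneModel],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write gene/exon features as GFF3 (1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##sequence-region {chrom} 1 {length}")
    for m in models:
        lines.append(
            f"{m.chrom}\tpopfinger\tgene\t{m.start + 1}\t{m.end}\t.\t+\t."
            f"\tID={m.gene_id}"
        )
        for k, (s, e) in enumerate(m.exons, start=1):
            lines.append(
                f"{m.chrom}\tpopfinger\texon\t{s + 1}\t{e}\t.\t+\t."
                f"\tID={m.gene_id}.exon{k};Parent={m.gene_id}"
            )
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot write GFF3 to {path}: {exc}") from exc
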