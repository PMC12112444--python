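"""Synthetic cohort simulator with machine-readable ground truth.

Emulates a three-population breeding-cohort design: a long-selected,
low-diversity strain ("OA"-like), a recently introduced wild population
("ON"-like), and a hybrid-origin, high-diversity strain ("OS"-like) formed
as an admixture of an ON-like parent and an outgroup parent.  Population
allele frequencies follow the Balding–Nichols model: for ancestral
frequency p and drift coefficient F, a population's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F), with mean p and variance F·p(1-p).
Genotypes are drawn per individual with inbreeding-adjusted probabilities
(p^2 + F_IS·pq, 2pq(1-F_IS), q^2 + F_IS·pq).

The simulator can plant selective-sweep regions (target-population
frequencies pushed toward fixation so windowed diversity drops), diagnostic
fixed-difference loci inside genic regions (so they survive the annotation
filter of the fingerprint cascade), optional LD blocks for decay tests,
missing genotypes and indel sites.  Everything is reproducible from one
seed, and the planted structure is recorded in a :class:`TruthSet`.

Sites are simulated in linkage equilibrium by default; LD blocks are an
opt-in feature that copies genotypes along a region with
distance-dependent refresh noise.  The hybrid population is drawn from
mixed frequencies, not per-individual mosaic haplotypes — sufficient for
the frequency-based statistics this package targets, and documented as a
simplification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from popfinger.annotation import AnnotationIndex, GeneModel, classify_sites, write_gff3
from popfinger.io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    write_popmap,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class HybridSpec:
    """Admixture origin of one population.

    ``target``'s allele frequencies are ``alpha * freq(parent1) +
    (1 - alpha) * freq(parent2)``.  A parent named ``"outgroup"`` denotes a
    latent parental population drawn with drift ``outgroup_F``.
    """

    target: str = "OS"
    parent1: str = "ON"
    parent2: str = "outgroup"
    alpha: float = 0.5
    outgroup_F: float = 0.3


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: inside [start, end) on ``chrom`` (0-based, bp), the
    target population's frequencies are moved toward the nearest fixation
    boundary by factor ``epsilon`` (p <- eps*p below 0.5, 1-eps*(1-p)
    above), so windowed diversity in the target drops by ~(1 - eps^2)."""

    pop: str
    chrom: str
    start: int
    end: int
    epsilon: float = 0.1


@dataclass(frozen=True)
class LDBlockSpec:
    """An opt-in LD block: sites inside [start, end) share one frequency and
    are generated by a positional Markov copy — each sample's genotype is
    refreshed with probability 1 - exp(-gap/decay_bp) per inter-site gap,
    giving pairwise correlation that decays with distance."""

    chrom: str
    start: int
    end: int
    decay_bp: float = 200_000.0


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the three-population design: 15 individuals per
    population, strong drift in the long-selected strain, mild drift in the
    wild introduction, a 50/50 hybrid third population with elevated
    within-population inbreeding, one planted 1 Mb sweep and two planted
    diagnostic loci per population.
    """

    pop_names: tuple[str, ...] = ("OA", "ON", "OS")
    samples_per_pop: int = 15
    n_sites: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 10_000_000 for i in range(1, 5)}
    )
    drift_F: dict[str, float] = field(
        default_factory=lambda: {"OA": 0.4, "ON": 0.15}
    )
    within_fis: dict[str, float] = field(
        default_factory=lambda: {"OA": 0.10, "ON": 0.05, "OS": 0.30}
    )
    hybrid_spec: HybridSpec | None = field(default_factory=HybridSpec)
    n_diagnostic: int = 2
    sweep_specs: tuple[SweepSpec, ...] = (
        SweepSpec(pop="OA", chrom="chr1", start=3_000_000, end=4_000_000, epsilon=0.1),
    )
    ld_blocks: tuple[LDBlockSpec, ...] = ()
    missing_rate: float = 0.02
    indel_rate: float = 0.05
    gene_fraction: float = 0.6
    gene_length: int = 30_000
    exon_fraction: float = 0.1
    exons_per_gene: int = 3
    diagnostic_min_spacing: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        hybrid_targets = {self.hybrid_spec.target} if self.hybrid_spec else set()
        for pop in self.pop_names:
            if pop in hybrid_targets:
                continue
            if pop not in self.drift_F:
                raise ConfigError(f"drift_F missing for population {pop!r}")
        for pop, f in self.drift_F.items():
            if not 0.0 < f < 1.0:
                raise ConfigError(f"drift_F[{pop!r}]={f} outside (0, 1)")
        for pop in self.pop_names:
            fis = self.within_fis.get(pop, 0.0)
            if not 0.0 <= fis < 1.0:
                raise ConfigError(f"within_fis[{pop!r}]={fis} outside [0, 1)")
        for rate, name in ((self.missing_rate, "missing_rate"),
                           (self.indel_rate, "indel_rate")):
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1)")
        if not 0.0 <= self.gene_fraction <= 1.0:
            raise ConfigError("gene_fraction outside [0, 1]")
        if self.hybrid_spec is not None:
            hs = self.hybrid_spec
            if hs.target not in self.pop_names:
                raise ConfigError(f"hybrid target {hs.target!r} not a population")
            if not 0.0 <= hs.alpha <= 1.0:
                raise ConfigError("hybrid alpha outside [0, 1]")
            for parent in (hs.parent1, hs.parent2):
                if parent != "outgroup" and parent not in self.pop_names:
                    raise ConfigError(f"hybrid parent {parent!r} unknown")
        for sw in self.sweep_specs:
            if sw.chrom not in self.chrom_lengths:
                raise ConfigError(f"sweep chromosome {sw.chrom!r} unknown")
            if not 0 <= sw.start < sw.end <= self.chrom_lengths[sw.chrom]:
                raise ConfigError(f"sweep interval [{sw.start},{sw.end}) outside {sw.chrom}")
            if not 0.0 < sw.epsilon <= 1.0:
                raise ConfigError(f"sweep epsilon={sw.epsilon} outside (0, 1]")
            if sw.pop not in self.pop_names:
                raise ConfigError(f"sweep population {sw.pop!r} unknown")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "pop_names" in d:
            d["pop_names"] = tuple(d["pop_names"])
        if "hybrid_spec" in d and d["hybrid_spec"] is not None:
            d["hybrid_spec"] = HybridSpec(**d["hybrid_spec"])
        if "sweep_specs" in d:
            d["sweep_specs"] = tuple(SweepSpec(**s) for s in d["sweep_specs"])
        if "ld_blocks" in d:
            d["ld_blocks"] = tuple(LDBlockSpec(**s) for s in d["ld_blocks"])
        return cls(**d)


@dataclass
class TruthSet:
    """Simulator ground truth for recovery tests."""

    ancestral_freqs: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    components: list[str]
    q_matrix: np.ndarray  # samples x components, rows sum to 1
    sample_ids: list[str]
    diagnostic_loci: list[dict]  # locus_id, target_pop, genotype per pop
    sweep_regions: list[dict]  # pop, chrom, start, end (0-based half-open), epsilon
    drift_F: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ancestral_freqs": np.round(self.ancestral_freqs, 8).tolist(),
            "pop_freqs": {k: np.round(v, 8).tolist() for k, v in self.pop_freqs.items()},
            "components": self.components,
            "q_matrix": np.round(self.q_matrix, 8).tolist(),
            "sample_ids": self.sample_ids,
            "diagnostic_loci": self.diagnostic_loci,
            "sweep_regions": self.sweep_regions,
            "drift_F": self.drift_F,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            ancestral_freqs=np.array(d["ancestral_freqs"]),
            pop_freqs={k: np.array(v) for k, v in d["pop_freqs"].items()},
            components=d["components"],
            q_matrix=np.array(d["q_matrix"]),
            sample_ids=d["sample_ids"],
            diagnostic_loci=d["diagnostic_loci"],
            sweep_regions=d["sweep_regions"],
            drift_F=d["drift_F"],
        )


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

def balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Draw population frequencies around ancestral ``p`` at drift ``F``.

    Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance F*p*(1-p).
    """
    if not 0.0 < F < 1.0:
        raise ConfigError(f"drift F={F} outside (0, 1)")
    p = np.asarray(p, dtype=float)
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def draw_population_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-population allele frequencies under the divergence model.

    Ancestral frequencies are Uniform(0.05, 0.95) per site; each non-hybrid
    population is an independent Balding–Nichols draw at its drift_F; the
    hybrid population's frequency is the alpha-mixture of its parents'
    frequencies, computed after the parental draws.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ancestral = rng.uniform(0.05, 0.95, size=config.n_sites)
    freqs: dict[str, np.ndarray] = {}
    hybrid = config.hybrid_spec
    for pop in config.pop_names:
        if hybrid is not None and pop == hybrid.target:
            continue
        freqs[pop] = balding_nichols(ancestral, config.drift_F[pop], rng)
    if hybrid is not None:
        parent_freqs = []
        for parent in (hybrid.parent1, hybrid.parent2):
            if parent == "outgroup":
                parent_freqs.append(balding_nichols(ancestral, hybrid.outgroup_F, rng))
            else:
                parent_freqs.append(freqs[parent])
        freqs[hybrid.target] = (
            hybrid.alpha * parent_freqs[0] + (1.0 - hybrid.alpha) * parent_freqs[1]
        )
    return freqs, ancestral


def plant_sweep_region(
    freqs: Mapping[str, np.ndarray],
    spec: SweepSpec,
    sites: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], dict]:
    """Push the target population's frequencies toward fixation inside the
    sweep interval; returns modified frequencies and a truth record."""
    if not 0.0 < spec.epsilon <= 1.0:
        raise ConfigError(f"sweep epsilon={spec.epsilon} outside (0, 1]")
    out = {k: v.copy() for k, v in freqs.items()}
    pos0 = sites["pos"].to_numpy() - 1
    in_region = (
        (sites["chrom"].to_numpy() == spec.chrom)
        & (pos0 >= spec.start)
        & (pos0 < spec.end)
    )
    p = out[spec.pop]
    lower = p <= 0.5
    p = np.where(
        in_region,
        np.where(lower, spec.epsilon * p, 1.0 - spec.epsilon * (1.0 - p)),
        p,
    )
    out[spec.pop] = p
    record = {
        "pop": spec.pop,
        "chrom": spec.chrom,
        "start": int(spec.start),
        "end": int(spec.end),
        "epsilon": float(spec.epsilon),
        "n_sites": int(in_region.sum()),
    }
    return out, record


# ---------------------------------------------------------------------------
# Sites and genotypes
# ---------------------------------------------------------------------------

def _draw_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    # global unique 0-based positions, rejection-sampled
    positions = np.unique(rng.integers(0, total, size=config.n_sites))
    while positions.size < config.n_sites:
        extra = rng.integers(0, total, size=config.n_sites - positions.size)
        positions = np.unique(np.concatenate([positions, extra]))
    positions = np.sort(positions[: config.n_sites])
    chrom_idx = np.searchsorted(offsets, positions, side="right") - 1
    local = positions - offsets[chrom_idx]

    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)
    is_indel = rng.random(config.n_sites) < config.indel_rate
    ins = rng.random(config.n_sites) < 0.5
    tail = _BASES[rng.integers(0, 4, size=config.n_sites)]
    for j in np.flatnonzero(is_indel):
        if ins[j]:
            alt[j] = str(ref[j]) + str(tail[j])
        else:
            ref[j] = str(ref[j]) + str(tail[j])
            alt[j] = str(ref[j])[0]
    return pd.DataFrame(
        {
            "chrom": [chroms[i] for i in chrom_idx],
            "pos": (local + 1).astype(np.int64),
            "ref": ref.astype(str),
            "alt": alt.astype(str),
            "type": np.where(is_indel, "indel", "snp"),
            "id": [f"{chroms[i]}:{p + 1}" for i, p in zip(chrom_idx, local)],
        }
    )


def _inbred_genotypes(
    p: np.ndarray, fis: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n individuals' dosages at sites with frequencies p under
    inbreeding coefficient fis."""
    q = 1.0 - p
    p_hom_ref = q * q + fis * p * q
    p_het = 2.0 * p * q * (1.0 - fis)
    u = rng.random((n, p.size))
    return (u >= p_hom_ref).astype(np.int8) + (u >= p_hom_ref + p_het).astype(np.int8)


def simulate_cohort(
    freqs: Mapping[str, np.ndarray],
    config: SimConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Draw the cohort's genotypes from per-population frequencies.

    Genotype probabilities use the within-population inbreeding coefficient
    (p^2 + F·pq, 2pq(1-F), q^2 + F·pq); missing entries are masked at
    ``missing_rate``; site metadata (positions, ref/alt, indel flags) is
    drawn uniformly along the chromosomes unless ``sites`` is supplied.
    """
    if sites is None:
        sites = _draw_sites(config, rng)
    blocks: list[np.ndarray] = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for pop in config.pop_names:
        fis = config.within_fis.get(pop, 0.0)
        g = _inbred_genotypes(freqs[pop], fis, config.samples_per_pop, rng)
        blocks.append(g)
        for i in range(config.samples_per_pop):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            assignments[name] = pop
    dosages = np.vstack(blocks)

    for block in config.ld_blocks:
        _apply_ld_block(dosages, sites, freqs, config, block, rng)

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    return GenotypeMatrix(dosages, sites, samples), PopulationMap(assignments)


def _apply_ld_block(
    dosages: np.ndarray,
    sites: pd.DataFrame,
    freqs: Mapping[str, np.ndarray],
    config: SimConfig,
    block: LDBlockSpec,
    rng: np.random.Generator,
) -> None:
    pos0 = sites["pos"].to_numpy() - 1
    idx = np.flatnonzero(
        (sites["chrom"].to_numpy() == block.chrom)
        & (pos0 >= block.start)
        & (pos0 < block.end)
    )
    if idx.size < 2:
        return
    anchor = idx[0]
    row = 0
    for pop in config.pop_names:
        n = config.samples_per_pop
        fis = config.within_fis.get(pop, 0.0)
        p_anchor = np.full(1, freqs[pop][anchor])
        prev = dosages[row : row + n, anchor].copy()
        for k in range(1, idx.size):
            gap = pos0[idx[k]] - pos0[idx[k - 1]]
            refresh = rng.random(n) < 1.0 - np.exp(-gap / block.decay_bp)
            fresh = _inbred_genotypes(p_anchor, fis, n, rng)[:, 0]
            cur = np.where(refresh, fresh, prev)
            dosages[row : row + n, idx[k]] = cur
            prev = cur
        row += n


def plant_diagnostic_loci(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    config: SimConfig,
    annotation: AnnotationIndex,
    rng: np.random.Generator,
    pop_freqs: Mapping[str, np.ndarray] | None = None,
) -> list[dict]:
    """Plant ``config.n_diagnostic`` fixed-difference loci per population.

    At each planted locus one population is homozygous alternate and every
    other population homozygous reference (missing entries overwritten, so
    within-population fixation holds by construction).  Loci are chosen
    among genic SNP sites, spaced at least ``diagnostic_min_spacing`` bp
    apart, so they survive the annotation and LD-pruning stages of the
    fingerprint cascade.  Modifies ``matrix`` (and ``pop_freqs`` if given)
    in place; returns truth records.
    """
    if config.n_diagnostic == 0:
        return []
    classes, _ = classify_sites(matrix, annotation)
    candidates = np.flatnonzero(
        (classes != "intergenic") & (matrix.sites["type"].to_numpy() == "snp")
    )
    rng.shuffle(candidates)
    groups = popmap.indices(matrix)
    records: list[dict] = []
    used_pos: list[tuple[str, int]] = []
    sites = matrix.sites
    for pop in config.pop_names:
        planted = 0
        for j in candidates:
            if planted >= config.n_diagnostic:
                break
            chrom = sites.at[j, "chrom"]
            pos = int(sites.at[j, "pos"])
            if any(
                c == chrom and abs(p - pos) < config.diagnostic_min_spacing
                for c, p in used_pos
            ):
                continue
            used_pos.append((chrom, pos))
            matrix.dosages[:, j] = 0
            matrix.dosages[groups[pop], j] = 2
            if pop_freqs is not None:
                for other in config.pop_names:
                    pop_freqs[other][j] = 1.0 if other == pop else 0.0
            ref, alt = sites.at[j, "ref"], sites.at[j, "alt"]
            records.append(
                {
                    "locus_id": sites.at[j, "id"],
                    "target_pop": pop,
                    "genotypes": {
                        other: (alt + alt if other == pop else ref + ref)
                        for other in config.pop_names
                    },
                }
            )
            planted += 1
        if planted < config.n_diagnostic:
            raise ConfigError(
                f"not enough spaced genic SNP sites to plant {config.n_diagnostic} "
                f"diagnostic loci for population {pop!r}"
            )
    return records


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def emit_annotation(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Tile genes over each chromosome at ``gene_fraction`` coverage.

    Genes have fixed length ``gene_length`` and ``exons_per_gene`` evenly
    spaced exons covering ``exon_fraction`` of the gene.  Gaps between
    genes are sized so genic bp approaches the requested fraction.
    """
    if config.gene_fraction == 0.0:
        return []
    models: list[GeneModel] = []
    counter = 1
    for chrom, length in config.chrom_lengths.items():
        gap = (
            0
            if config.gene_fraction >= 1.0
            else int(config.gene_length * (1.0 - config.gene_fraction) / config.gene_fraction)
        )
        pos = 0
        while pos + config.gene_length <= length:
            start, end = pos, pos + config.gene_length
            # at full genic coverage the terminal gene absorbs the remainder
            if gap == 0 and length - end < config.gene_length:
                end = length
            exons = _split_exons(start, end, config.exon_fraction, config.exons_per_gene)
            models.append(GeneModel(f"gene{counter:05d}", chrom, start, end, exons))
            counter += 1
            pos = end + gap
        # no partial terminal gene below full coverage
    return models


def _split_exons(
    start: int, end: int, exon_fraction: float, n_exons: int
) -> tuple[tuple[int, int], ...]:
    gene_len = end - start
    if exon_fraction >= 1.0:
        return ((start, end),)
    if exon_fraction <= 0.0 or n_exons < 1:
        return ()
    exon_len = max(1, int(gene_len * exon_fraction / n_exons))
    spacing = gene_len // n_exons
    exons = []
    for k in range(n_exons):
        s = start + k * spacing
        e = min(s + exon_len, end)
        if s < e:
            exons.append((s, e))
    return tuple(exons)


# ---------------------------------------------------------------------------
# Facade
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    matrix: GenotypeMatrix
    popmap: PopulationMap
    truth: TruthSet
    gene_models: list[GeneModel]
    annotation: AnnotationIndex

    def write(self, outdir: str | Path, chrom_lengths: Mapping[str, int]) -> dict[str, Path]:
        """Write VCF / GFF3 / population map / truth JSON; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "gff": outdir / "annotation.gff3",
            "popmap": outdir / "popmap.tsv",
            "truth": outdir / "truth.json",
        }
        write_vcf(self.matrix, paths["vcf"], chrom_lengths)
        write_gff3(self.gene_models, paths["gff"], chrom_lengths)
        write_popmap(self.popmap, paths["popmap"])
        self.truth.to_json(paths["truth"])
        return paths


class CohortSimulator:
    """Seeded end-to-end cohort generator.

    >>> result = CohortSimulator(SimConfig(seed=1)).run()
    >>> result.matrix.n_samples
    45
    """

    def __init__(self, config: SimConfig):
        self.config = config

    def run(self) -> SimResult:
        config = self.config
        rng = np.random.default_rng(config.seed)
        gene_models = emit_annotation(config, rng)
        annotation = AnnotationIndex.from_gene_models(gene_models, config.chrom_lengths)

        freqs, ancestral = draw_population_frequencies(config, rng)
        sites = _draw_sites(config, rng)
        sweep_records = []
        for spec in config.sweep_specs:
            freqs, record = plant_sweep_region(freqs, spec, sites)
            sweep_records.append(record)

        matrix, popmap = simulate_cohort(freqs, config, rng, sites=sites)
        pop_freqs = {k: v.copy() for k, v in freqs.items()}
        diag_records = plant_diagnostic_loci(
            matrix, popmap, config, annotation, rng, pop_freqs
        )

        components, q = self._true_q(popmap)
        truth = TruthSet(
            ancestral_freqs=ancestral,
            pop_freqs=pop_freqs,
            components=components,
            q_matrix=q,
            sample_ids=list(matrix.samples),
            diagnostic_loci=diag_records,
            sweep_regions=sweep_records,
            drift_F=dict(self.config.drift_F),
        )
        return SimResult(matrix, popmap, truth, gene_models, annotation)

    def _true_q(self, popmap: PopulationMap) -> tuple[list[str], np.ndarray]:
        config = self.config
        hybrid = config.hybrid_spec
        components = [
            p for p in config.pop_names if hybrid is None or p != hybrid.target
        ]
        if hybrid is not None and (
            hybrid.parent1 == "outgroup" or hybrid.parent2 == "outgroup"
        ):
            components = components + ["outgroup"]
        comp_idx = {c: i for i, c in enumerate(components)}
        samples = list(popmap.assignments)
        q = np.zeros((len(samples), len(components)))
        for i, s in enumerate(samples):
            pop = popmap.assignments[s]
            if hybrid is not None and pop == hybrid.target:
                q[i, comp_idx[hybrid.parent1]] = hybrid.alpha
                q[i, comp_idx[hybrid.parent2]] += 1.0 - hybrid.alpha
            else:
                q[i, comp_idx[pop]] = 1.0
        return components, q
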