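"""Core-SNP screening cascade, fingerprints and identification schemes.

The cascade reduces a genotype matrix to a small set of core loci through
ordered stages: (1) drop indels and off-whitelist chromosomes; (2) keep
loci with pooled MAF > maf1, pooled observed heterozygosity < het1 and
missing rate < miss1; (3) drop intergenic loci; (4) impute missing
genotypes with the per-population modal genotype; (5) re-filter at
MAF > maf2 and het < het2; (6) greedy position-ordered LD pruning at
r^2 >= ld_r2_max within a window.  Each stage's in/out counts are kept in
a ledger.

A locus is *diagnostic* when every population is fixed for one homozygous
genotype (up to ``max_discordant`` exceptions; missing calls ignored up to
a missing-rate cap) and at least two populations differ — exactly the
pure-genotype fingerprint pattern (TT/AA/GG/CC columns).  Diagnostic loci
induce partitions of the population set; minimal multi-step identification
schemes are enumerated by recursively choosing a marker that isolates at
least one population and recursing on the residual set.  Schemes with the
same sequence of isolated populations form a class within which markers
with identical partitions are interchangeable.

:class:`PopulationFingerprinter` wraps the whole pipeline as an estimator:
``fit`` runs cascade -> diagnostic discovery -> scheme enumeration, and
``predict`` assigns population labels to individuals from their genotypes
at the scheme markers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from popfinger.annotation import AnnotationIndex, classify_sites
from popfinger.io import MISSING, GenotypeMatrix, PopulationMap, allele_freqs

logger = logging.getLogger(__name__)

#: Decision sentinel: genotype matches the residual branch, go to next step.
CONTINUE = "__continue__"

#: Label returned when no branch of a scheme matches.
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the core-SNP screening cascade.

    ``het`` filters use the pooled observed heterozygote fraction per
    locus and ``miss`` the per-locus missing rate (Plink-style semantics);
    MAF at stage 5 is computed after imputation, as the stage order
    implies.
    """

    chromosomes: tuple[str, ...] | None = None  # whitelist; None = all
    maf1: float = 0.2
    het1: float = 0.05
    miss1: float = 0.1
    maf2: float = 0.3
    het2: float = 0.01
    ld_r2_max: float = 0.2
    ld_window: int = 500_000
    imputation: str = "pop_mode"  # pop_mode | none

    def __post_init__(self) -> None:
        if not 0.0 < self.maf1 <= self.maf2 <= 0.5:
            raise ValueError("require 0 < maf1 <= maf2 <= 0.5")
        for v, name in ((self.het1, "het1"), (self.het2, "het2"),
                        (self.miss1, "miss1"), (self.ld_r2_max, "ld_r2_max")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.imputation not in ("pop_mode", "none"):
            raise ValueError(f"unknown imputation mode {self.imputation!r}")


@dataclass
class CoreLocusSet:
    """Surviving locus IDs with the per-stage survival ledger."""

    locus_ids: list[str]
    ledger: list[dict]  # {"stage": str, "n_in": int, "n_out": int}

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ledger)

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            json.dumps({"locus_ids": self.locus_ids, "ledger": self.ledger}, indent=1)
            + "\n"
        )


def _pooled_stats(matrix: GenotypeMatrix):
    stats = allele_freqs(matrix)
    n = matrix.n_samples
    miss = 1.0 - stats.n_called / n
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(stats.n_called > 0, stats.het_count / stats.n_called, 0.0)
    maf = np.nan_to_num(stats.maf)
    return maf, het, miss


def impute_pop_mode(matrix: GenotypeMatrix, popmap: PopulationMap) -> GenotypeMatrix:
    """Fill missing genotypes with the per-population modal genotype.

    A stand-in for haplotype-based imputation that is exact at the
    fixed-difference loci the cascade targets.  Ties take the smaller
    dosage; a population with no calls at a locus falls back to the pooled
    mode; loci with no calls at all stay missing.
    """
    d = matrix.dosages.copy()
    groups = popmap.indices(matrix)

    def mode(col: np.ndarray) -> int:
        called = col[col != MISSING]
        if called.size == 0:
            return MISSING
        counts = np.bincount(called, minlength=3)
        return int(np.argmax(counts))  # ties -> smaller dosage

    missing_cols = np.flatnonzero((d == MISSING).any(axis=0))
    for j in missing_cols:
        pooled = mode(d[:, j])
        for pop, idx in groups.items():
            col = d[idx, j]
            holes = col == MISSING
            if not holes.any():
                continue
            fill = mode(col)
            if fill == MISSING:
                fill = pooled
            if fill != MISSING:
                col[holes] = fill
                d[idx, j] = col
    return GenotypeMatrix(d, matrix.sites, matrix.samples)


def _ld_prune_mask(matrix: GenotypeMatrix, r2_max: float, window: int) -> np.ndarray:
    """Greedy position-ordered pruning: drop a locus if its dosage-r^2 with
    any retained locus within ``window`` bp reaches ``r2_max`` (first kept
    wins)."""
    keep = np.zeros(matrix.n_sites, dtype=bool)
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    D = matrix.dosages
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        retained: list[int] = []
        for j in idx:
            linked = False
            for k in reversed(retained):
                if pos[j] - pos[k] > window:
                    break
                r2 = _safe_r2(D[:, j], D[:, k])
                if r2 is not None and r2 >= r2_max:
                    linked = True
                    break
            if not linked:
                keep[j] = True
                retained.append(j)
    return keep


def _safe_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    x, y = a[ok].astype(float), b[ok].astype(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def filter_cascade(
    matrix: GenotypeMatrix,
    annotation: AnnotationIndex,
    popmap: PopulationMap,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[CoreLocusSet, GenotypeMatrix]:
    """Run the core-SNP screening cascade; returns the survivor set with
    its stage ledger and the filtered (imputed) matrix.

    An empty survivor set at any stage short-circuits the remaining stages
    and is returned with the ledger — it is not an error.
    """
    ledger: list[dict] = []
    cur = matrix

    def record(stage: str, n_in: int, survivors: GenotypeMatrix) -> GenotypeMatrix:
        ledger.append({"stage": stage, "n_in": n_in, "n_out": survivors.n_sites})
        return survivors

    # 1: SNPs on whitelisted chromosomes
    mask = cur.sites["type"].to_numpy() == "snp"
    if config.chromosomes is not None:
        mask &= np.isin(cur.sites["chrom"].to_numpy(), list(config.chromosomes))
    cur = record("snp_chromosomes", cur.n_sites, cur.take_sites(mask))

    # 2: MAF / het / missing-rate
    if cur.n_sites:
        maf, het, miss = _pooled_stats(cur)
        mask = (maf > config.maf1) & (het < config.het1) & (miss < config.miss1)
        cur = record("maf_het_missing", cur.n_sites, cur.take_sites(mask))
    # 3: non-intergenic
    if cur.n_sites:
        classes, _ = classify_sites(cur, annotation)
        cur = record("genic", cur.n_sites, cur.take_sites(classes != "intergenic"))
    # 4: imputation (no site loss)
    if cur.n_sites and config.imputation == "pop_mode":
        cur = record("impute", cur.n_sites, impute_pop_mode(cur, popmap))
    # 5: stricter MAF / het
    if cur.n_sites:
        maf, het, _ = _pooled_stats(cur)
        mask = (maf > config.maf2) & (het < config.het2)
        cur = record("maf_het_strict", cur.n_sites, cur.take_sites(mask))
    # 6: LD pruning
    if cur.n_sites:
        mask = _ld_prune_mask(cur, config.ld_r2_max, config.ld_window)
        cur = record("ld_prune", cur.n_sites, cur.take_sites(mask))

    return CoreLocusSet(locus_ids=list(cur.sites["id"]), ledger=ledger), cur


# ---------------------------------------------------------------------------
# Diagnostic loci
# ---------------------------------------------------------------------------

def _genotype_string(ref: str, alt: str, dosage: int) -> str:
    if dosage == 0:
        return ref + ref
    if dosage == 1:
        return ref + alt
    if dosage == 2:
        return alt + alt
    return "--"


def _normalize_genotype(g: str) -> str:
    return "".join(sorted(g.upper()))


@dataclass
class DiagnosticLocus:
    """A locus at which every population is fixed homozygous and at least
    two populations differ."""

    locus_id: str
    site_index: int
    consensus: dict[str, str]        # population -> genotype string
    consensus_dosage: dict[str, int]  # population -> 0 or 2

    @property
    def partition(self) -> frozenset[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for pop, dose in self.consensus_dosage.items():
            groups.setdefault(dose, set()).add(pop)
        return frozenset(frozenset(g) for g in groups.values())


def find_diagnostic_loci(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    max_discordant: int = 0,
    max_missing: float = 0.1,
) -> list[DiagnosticLocus]:
    """Loci where each population is fixed for one homozygous genotype.

    A population passes at a locus when its missing rate is at most
    ``max_missing`` and all but at most ``max_discordant`` of its called
    genotypes equal one homozygote; heterozygotes count as discordant.
    The locus is diagnostic when every population passes and at least two
    consensus genotypes differ.
    """
    groups = popmap.indices(matrix)
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    L = matrix.n_sites
    pass_all = np.ones(L, dtype=bool)
    consensus_dosage: dict[str, np.ndarray] = {}
    for pop, idx in groups.items():
        d = matrix.dosages[idx]
        called = d != MISSING
        n_called = called.sum(axis=0)
        miss_rate = 1.0 - n_called / idx.size
        c0 = ((d == 0) & called).sum(axis=0)
        c2 = ((d == 2) & called).sum(axis=0)
        best = np.maximum(c0, c2)
        discordant = n_called - best
        ok = (n_called >= 1) & (miss_rate <= max_missing) & (discordant <= max_discordant)
        pass_all &= ok
        consensus_dosage[pop] = np.where(c2 > c0, 2, 0)
    pops = list(groups)
    stacked = np.stack([consensus_dosage[p] for p in pops])
    distinct = (stacked != stacked[0]).any(axis=0)
    hits = np.flatnonzero(pass_all & distinct)
    out = []
    for j in hits:
        ref, alt = matrix.sites.at[j, "ref"], matrix.sites.at[j, "alt"]
        doses = {p: int(consensus_dosage[p][j]) for p in pops}
        out.append(
            DiagnosticLocus(
                locus_id=matrix.sites.at[j, "id"],
                site_index=int(j),
                consensus={p: _genotype_string(ref, alt, d) for p, d in doses.items()},
                consensus_dosage=doses,
            )
        )
    return out


@dataclass
class FingerprintProfile:
    """Individuals x core-loci genotype table with population consensus."""

    individuals: pd.DataFrame  # index: sample, columns: locus ids
    consensus: pd.DataFrame    # index: population, columns: locus ids

    def to_tsv(self, path) -> None:
        block = pd.concat(
            [self.individuals,
             self.consensus.rename(index=lambda p: f"consensus:{p}")]
        )
        block.to_csv(path, sep="\t", index_label="individual")


def build_fingerprint(
    matrix: GenotypeMatrix,
    diagnostic_loci: Sequence[DiagnosticLocus],
    popmap: PopulationMap,
) -> FingerprintProfile:
    """Genotype-code fingerprint over the diagnostic loci."""
    if not diagnostic_loci:
        raise ValueError("no diagnostic loci supplied")
    id_to_index = {lid: j for j, lid in enumerate(matrix.sites["id"])}
    cols = {}
    for locus in diagnostic_loci:
        j = id_to_index.get(locus.locus_id)
        if j is None:
            raise ValueError(f"locus {locus.locus_id!r} not in matrix")
        ref, alt = matrix.sites.at[j, "ref"], matrix.sites.at[j, "alt"]
        cols[locus.locus_id] = [
            _genotype_string(ref, alt, int(d)) for d in matrix.dosages[:, j]
        ]
    individuals = pd.DataFrame(cols, index=matrix.samples)
    consensus = pd.DataFrame(
        {l.locus_id: l.consensus for l in diagnostic_loci}
    ).reindex(popmap.populations)
    return FingerprintProfile(individuals=individuals, consensus=consensus)


# ---------------------------------------------------------------------------
# Identification schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemeStep:
    """One decision step: look up the genotype at ``marker`` and either
    decide a population or continue to the next step."""

    marker: str
    decisions: Mapping[str, str]  # normalized genotype -> population | CONTINUE


@dataclass
class IdentificationScheme:
    """Ordered decision steps resolving every population exactly once."""

    steps: list[SchemeStep]

    @property
    def depth(self) -> int:
        return len(self.steps)

    def describe(self) -> str:
        lines = []
        for t, step in enumerate(self.steps, start=1):
            branches = ", ".join(
                f"{g} -> {'next step' if pop == CONTINUE else pop}"
                for g, pop in step.decisions.items()
            )
            lines.append(f"step {t}: {step.marker}: {branches}")
        return "\n".join(lines)


@dataclass
class SchemeClass:
    """Schemes sharing the same sequence of isolated populations; markers
    with identical partitions are interchangeable within a step."""

    isolated_sequence: tuple[tuple[str, ...], ...]
    step_markers: tuple[tuple[str, ...], ...]
    _loci: dict[str, DiagnosticLocus] = field(repr=False, default_factory=dict)
    _remaining_sequence: tuple[tuple[str, ...], ...] = ()

    @property
    def depth(self) -> int:
        return len(self.step_markers)

    def scheme(self, markers: Sequence[str] | None = None) -> IdentificationScheme:
        """A concrete scheme choosing one marker per step (default: first)."""
        if markers is None:
            markers = [m[0] for m in self.step_markers]
        if len(markers) != self.depth:
            raise ValueError("one marker per step required")
        steps = []
        for t, marker in enumerate(markers):
            if marker not in self.step_markers[t]:
                raise ValueError(f"marker {marker!r} not valid at step {t + 1}")
            locus = self._loci[marker]
            remaining = self._remaining_sequence[t]
            groups: dict[str, list[str]] = {}
            for pop in remaining:
                groups.setdefault(_normalize_genotype(locus.consensus[pop]), []).append(pop)
            decisions = {
                g: (pops[0] if len(pops) == 1 else CONTINUE)
                for g, pops in groups.items()
            }
            steps.append(SchemeStep(marker=marker, decisions=decisions))
        return IdentificationScheme(steps=steps)


@dataclass
class SchemeEnumeration:
    classes: list[SchemeClass]
    unresolvable_groups: list[frozenset[str]]  # empty when schemes exist

    @property
    def resolvable(self) -> bool:
        return bool(self.classes)


def enumerate_schemes(
    diagnostic_loci: Sequence[DiagnosticLocus],
    populations: Sequence[str] | None = None,
) -> SchemeEnumeration:
    """Minimal-depth identification scheme classes from diagnostic loci.

    Each step chooses a marker whose induced partition of the remaining
    populations isolates at least one of them; recursion continues on the
    residual set.  Only depth-minimal schemes are returned, grouped into
    classes by the sequence of isolated populations.
    """
    if populations is None:
        pops: set[str] = set()
        for locus in diagnostic_loci:
            pops.update(locus.consensus_dosage)
        populations = sorted(pops)
    loci = {l.locus_id: l for l in diagnostic_loci}
    all_pops = frozenset(populations)

    memo: dict[frozenset, tuple[int, list]] = {}

    def solve(remaining: frozenset) -> tuple[int, list]:
        """Min depth and branch list [(markers, isolated, residual)]."""
        if len(remaining) <= 1:
            return 0, []
        if remaining in memo:
            return memo[remaining]
        by_partition: dict[tuple, list[str]] = {}
        for lid, locus in loci.items():
            if not all(p in locus.consensus_dosage for p in remaining):
                continue
            groups: dict[int, tuple] = {}
            for pop in sorted(remaining):
                groups.setdefault(locus.consensus_dosage[pop], ())
                groups[locus.consensus_dosage[pop]] += (pop,)
            key = tuple(sorted(groups.values()))
            if len(key) < 2 or not any(len(g) == 1 for g in key):
                continue
            by_partition.setdefault(key, []).append(lid)
        best_depth = None
        branches = []
        for key, markers in by_partition.items():
            isolated = tuple(g[0] for g in key if len(g) == 1)
            residual = frozenset(p for g in key if len(g) > 1 for p in g)
            sub_depth, _ = solve(residual)
            depth = 1 + sub_depth
            branches.append((depth, tuple(sorted(markers)), isolated, residual))
            if best_depth is None or depth < best_depth:
                best_depth = depth
        if best_depth is None:
            memo[remaining] = (10**9, [])
            return memo[remaining]
        kept = [(m, i, r) for d, m, i, r in branches if d == best_depth]
        memo[remaining] = (best_depth, kept)
        return memo[remaining]

    depth, _ = solve(all_pops)
    if depth >= 10**9:
        return SchemeEnumeration(classes=[], unresolvable_groups=_indistinguishable(loci, all_pops))

    classes: list[SchemeClass] = []

    def walk(remaining: frozenset, iso_seq: tuple, marker_seq: tuple, rem_seq: tuple) -> None:
        if len(remaining) <= 1:
            classes.append(
                SchemeClass(
                    isolated_sequence=iso_seq,
                    step_markers=marker_seq,
                    _loci=loci,
                    _remaining_sequence=rem_seq,
                )
            )
            return
        _, branch_list = solve(remaining)
        for markers, isolated, residual in branch_list:
            walk(
                residual,
                iso_seq + (isolated,),
                marker_seq + (markers,),
                rem_seq + (tuple(sorted(remaining)),),
            )

    walk(all_pops, (), (), ())
    classes.sort(key=lambda c: c.isolated_sequence)
    return SchemeEnumeration(classes=classes, unresolvable_groups=[])


def _indistinguishable(
    loci: Mapping[str, DiagnosticLocus], pops: frozenset
) -> list[frozenset[str]]:
    """Equivalence classes of populations no marker separates."""
    pops_list = sorted(pops)
    sig = {
        p: tuple(loci[l].consensus_dosage.get(p) for l in sorted(loci))
        for p in pops_list
    }
    groups: dict[tuple, set[str]] = {}
    for p in pops_list:
        groups.setdefault(sig[p], set()).add(p)
    return [frozenset(g) for g in groups.values() if len(g) > 1]


def classify_individual(
    genotypes: Mapping[str, str],
    scheme: IdentificationScheme,
    detail: bool = False,
):
    """Apply a scheme's steps to one individual's marker genotypes.

    Returns the decided population label, or ``"unresolved"`` when a
    genotype is missing, heterozygous or matches no branch.  With
    ``detail=True`` returns ``(label, failed_step)`` where ``failed_step``
    is the 1-based step index that failed (None on success).
    """
    for t, step in enumerate(scheme.steps, start=1):
        g = genotypes.get(step.marker)
        decision = None if g is None else step.decisions.get(_normalize_genotype(g))
        if decision is None:
            return (UNRESOLVED, t) if detail else UNRESOLVED
        if decision == CONTINUE:
            continue
        return (decision, None) if detail else decision
    return (UNRESOLVED, len(scheme.steps)) if detail else UNRESOLVED


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class PopulationFingerprinter(BaseEstimator):
    """End-to-end fingerprint pipeline as a classifier.

    ``fit`` runs the screening cascade on a cohort, finds diagnostic loci
    among the survivors, builds the fingerprint profile and enumerates
    minimal identification schemes.  ``predict`` classifies individuals by
    applying the representative scheme of the first scheme class to their
    genotypes at the scheme markers.
    """

    def __init__(
        self,
        cascade: CascadeConfig | None = None,
        max_discordant: int = 0,
        max_missing: float = 0.1,
    ):
        self.cascade = cascade
        self.max_discordant = max_discordant
        self.max_missing = max_missing

    def fit(
        self,
        X: GenotypeMatrix,
        y: PopulationMap,
        annotation: AnnotationIndex | None = None,
    ) -> "PopulationFingerprinter":
        config = self.cascade or CascadeConfig()
        if annotation is None:
            annotation = AnnotationIndex()  # everything intergenic
        core, filtered = filter_cascade(X, annotation, y, config)
        self.core_ = core
        self.filtered_ = filtered
        self.diagnostic_loci_ = find_diagnostic_loci(
            filtered, y, self.max_discordant, self.max_missing
        )
        if self.diagnostic_loci_:
            self.fingerprint_ = build_fingerprint(filtered, self.diagnostic_loci_, y)
        else:
            self.fingerprint_ = None
        self.enumeration_ = enumerate_schemes(self.diagnostic_loci_, y.populations)
        self.scheme_ = (
            self.enumeration_.classes[0].scheme()
            if self.enumeration_.resolvable
            else None
        )
        return self

    def predict(self, X: GenotypeMatrix) -> np.ndarray:
        if getattr(self, "scheme_", None) is None:
            raise ValueError("no identification scheme available (fit first?)")
        id_to_index = {lid: j for j, lid in enumerate(X.sites["id"])}
        markers = [step.marker for step in self.scheme_.steps]
        missing = [m for m in markers if m not in id_to_index]
        if missing:
            raise ValueError(f"scheme markers absent from matrix: {missing}")
        ref_alt = {
            m: (X.sites.at[id_to_index[m], "ref"], X.sites.at[id_to_index[m], "alt"])
            for m in markers
        }
        labels = []
        for i in range(X.n_samples):
            genotypes = {
                m: _genotype_string(*ref_alt[m], int(X.dosages[i, id_to_index[m]]))
                for m in markers
            }
            labels.append(classify_individual(genotypes, self.scheme_))
        return np.array(labels)

    def score(self, X: GenotypeMatrix, y: PopulationMap) -> float:
        pred = self.predict(X)
        true = y.labels_for(X.samples)
        return float(np.mean(pred == true))
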