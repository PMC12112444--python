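"""Per-population diversity indices and pairwise differentiation.

Observed heterozygosity Ho is the called heterozygote fraction; expected
heterozygosity He uses the Nei small-sample correction
He = (2n/(2n-1)) * 2*p*(1-p) by default (toggle ``unbiased=False`` for the
raw 2pq).  Per-variant-site nucleotide diversity equals He at a biallelic
site, so the headline Pi here is the mean He over included loci; a per-bp
convention (summed He over a span) is also exposed for windowed scans.
The population-level inbreeding coefficient is the ratio of means,
F_IS = 1 - mean(Ho)/mean(He), which is stable at low-He loci.

F_ST defaults to the Weir & Cockerham (1984) estimator: per-locus variance
components a (between populations), b (between individuals within
populations) and c (within individuals), combined across loci as a ratio
of sums, sum(a)/sum(a+b+c).  Hudson's estimator (ratio of averages,
Bhatia et al. 2013 recommendation) is available as an alternative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popfinger.io import AlleleStats, GenotypeMatrix, PopulationMap, allele_freqs

logger = logging.getLogger(__name__)


@dataclass
class LocusDiversity:
    """Per-locus diversity vectors for one population; loci with fewer than
    two called genotypes are excluded (``included`` False, values NaN)."""

    ho: np.ndarray
    he: np.ndarray
    pi: np.ndarray
    fis: np.ndarray
    included: np.ndarray


def locus_diversity(stats: AlleleStats, unbiased: bool = True) -> LocusDiversity:
    """Ho, He, per-site Pi and per-locus F_IS from allele summaries."""
    n = stats.n_called.astype(float)
    included = stats.n_called >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(included, stats.het_count / n, np.nan)
        he = 2.0 * stats.p * (1.0 - stats.p)
        if unbiased:
            he = he * (2.0 * n) / (2.0 * n - 1.0)
        he = np.where(included, he, np.nan)
        fis = np.where(included & (he > 0), 1.0 - ho / he, np.nan)
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.debug("locus_diversity: %d loci with n_called < 2 excluded", n_excluded)
    return LocusDiversity(ho=ho, he=he, pi=he.copy(), fis=fis, included=included)


@dataclass
class DiversityTable:
    """Per-population mean diversity indices with per-locus vectors."""

    table: pd.DataFrame  # index: population
    per_locus: dict[str, LocusDiversity]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="population", float_format="%.6g")


def population_summary(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    unbiased: bool = True,
    pi_span_bp: float | None = None,
) -> DiversityTable:
    """Mean Ho, observed/expected homozygosity, He, Pi and F_IS per population.

    Means are over loci with >= 2 called genotypes; populations with fewer
    than two samples are excluded with a warning.  ``pi_span_bp``, when
    given, adds a per-bp Pi column (sum of per-site Pi over the span).
    """
    rows = {}
    per_locus: dict[str, LocusDiversity] = {}
    for pop, idx in popmap.indices(matrix).items():
        if idx.size < 2:
            logger.warning("population %r has < 2 samples; excluded", pop)
            continue
        stats = allele_freqs(matrix, idx)
        div = locus_diversity(stats, unbiased=unbiased)
        per_locus[pop] = div
        inc = div.included
        mean_ho = float(np.nanmean(div.ho[inc])) if inc.any() else np.nan
        mean_he = float(np.nanmean(div.he[inc])) if inc.any() else np.nan
        row = {
            "ho": mean_ho,
            "hom_obs": 1.0 - mean_ho,
            "he": mean_he,
            "hom_exp": 1.0 - mean_he,
            "pi": mean_he,
            "fis": 1.0 - mean_ho / mean_he if mean_he > 0 else np.nan,
            "n_loci": int(inc.sum()),
        }
        if pi_span_bp is not None:
            row["pi_per_bp"] = float(np.nansum(div.pi[inc])) / pi_span_bp
        rows[pop] = row
    if not rows:
        raise ValueError("no population with >= 2 samples")
    return DiversityTable(table=pd.DataFrame.from_dict(rows, orient="index"), per_locus=per_locus)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    estimator: str
    n_loci: int
    # per-locus components: (a, b, c) for weir_cockerham, (num, den) for hudson
    components: tuple[np.ndarray, ...] = ()
    usable: np.ndarray | None = None


def weir_cockerham_components(
    stats_a: AlleleStats, stats_b: AlleleStats
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components for two samples.

    Returns (a, b, c, usable); loci are usable when both populations have
    at least two called genotypes.  Components are zeroed at unusable loci.
    """
    r = 2.0
    n1 = stats_a.n_called.astype(float)
    n2 = stats_b.n_called.astype(float)
    usable = (stats_a.n_called >= 2) & (stats_b.n_called >= 2)
    n1s, n2s = np.where(usable, n1, 2.0), np.where(usable, n2, 2.0)
    p1, p2 = np.nan_to_num(stats_a.p), np.nan_to_num(stats_b.p)
    h1 = np.divide(stats_a.het_count, n1s)
    h2 = np.divide(stats_b.het_count, n2s)

    n_bar = (n1s + n2s) / r
    n_c = (r * n_bar - (n1s**2 + n2s**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1s * p1 + n2s * p2) / (r * n_bar)
    s2 = (n1s * (p1 - p_bar) ** 2 + n2s * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1s * h1 + n2s * h2) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (pq - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
    c = h_bar / 2.0
    for arr in (a, b, c):
        arr[~usable] = 0.0
    return a, b, c, usable


def hudson_components(
    stats_a: AlleleStats, stats_b: AlleleStats
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Hudson F_ST numerator/denominator (Bhatia et al. 2013)."""
    usable = (stats_a.n_called >= 2) & (stats_b.n_called >= 2)
    n1 = np.where(usable, 2.0 * stats_a.n_called, 4.0)
    n2 = np.where(usable, 2.0 * stats_b.n_called, 4.0)
    p1, p2 = np.nan_to_num(stats_a.p), np.nan_to_num(stats_b.p)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1.0) - p2 * (1 - p2) / (n2 - 1.0)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~usable] = 0.0
    den[~usable] = 0.0
    return num, den


def pairwise_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pairs: list[tuple[str, str]] | None = None,
    estimator: str = "weir_cockerham",
) -> list[FstResult]:
    """Multi-locus F_ST for each population pair (ratio of sums)."""
    if estimator not in ("weir_cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    groups = popmap.indices(matrix)
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    stats = {pop: allele_freqs(matrix, idx) for pop in {p for pr in pairs for p in pr}
             for idx in [groups[pop]]}
    results = []
    for pop_a, pop_b in pairs:
        sa, sb = stats[pop_a], stats[pop_b]
        if estimator == "weir_cockerham":
            a, b, c, usable = weir_cockerham_components(sa, sb)
            # monomorphic-across-both loci contribute nothing
            den = float(np.sum(a + b + c))
            if not usable.any() or den == 0.0:
                raise ValueError(f"no usable loci for pair ({pop_a}, {pop_b})")
            fst = float(np.sum(a)) / den
            comps: tuple[np.ndarray, ...] = (a, b, c)
        else:
            num, den_l = hudson_components(sa, sb)
            usable = den_l > 0
            if not usable.any():
                raise ValueError(f"no usable loci for pair ({pop_a}, {pop_b})")
            fst = float(np.sum(num[usable])) / float(np.sum(den_l[usable]))
            comps = (num, den_l)
        results.append(
            FstResult(pop_a=pop_a, pop_b=pop_b, fst=fst, estimator=estimator,
                      n_loci=int(usable.sum()), components=comps, usable=usable)
        )
    return results


def fst_matrix(results: list[FstResult]) -> pd.DataFrame:
    """Symmetric pairwise F_ST matrix from a list of results."""
    pops = sorted({r.pop_a for r in results} | {r.pop_b for r in results})
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for r in results:
        mat.loc[r.pop_a, r.pop_b] = r.fst
        mat.loc[r.pop_b, r.pop_a] = r.fst
    return mat
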