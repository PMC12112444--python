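"""Windowed selective-sweep scan.

Per sliding window (1 Mb window / 100 kb step by default) and population
pair: nucleotide diversity pi per population (per-bp by default: summed
per-site unbiased heterozygosity over the window span), their ratio
theta-pi ratio = pi_A / pi_B, and the Weir–Cockerham window F_ST
(ratio of summed variance components).  Outlier windows exceed the
empirical top-q quantile of both the ratio statistic and F_ST
(intersection rule by default; q = 5%).  Selected windows are merged into
regions and annotated with overlapping genes.

Edge conventions: windows are [start, start + window) per chromosome with
only full-length windows emitted (a chromosome shorter than one window
yields a single truncated window); a ratio of x/0 with x > 0 is +inf and
always counts as an outlier in the upper tail; 0/0 windows are excluded;
quantiles are empirical type-7 with strictly-greater tie breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popfinger.annotation import AnnotationIndex
from popfinger.diversity import weir_cockerham_components
from popfinger.io import GenotypeMatrix, PopulationMap, allele_freqs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    window_size: int = 1_000_000
    step: int = 100_000
    quantile: float = 0.05
    tail_mode: str = "ratio_top"  # ratio_top | abs_log_top | both_tails
    min_sites: int = 5
    join: str = "intersection"  # intersection | union
    pi_denominator: str = "bp"  # bp | sites
    sliding: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ValueError("require 0 < step <= window_size")
        if not 0.0 < self.quantile < 0.5:
            raise ValueError("require 0 < quantile < 0.5")
        if self.tail_mode not in ("ratio_top", "abs_log_top", "both_tails"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.join not in ("intersection", "union"):
            raise ValueError(f"unknown join {self.join!r}")
        if self.pi_denominator not in ("bp", "sites"):
            raise ValueError(f"unknown pi_denominator {self.pi_denominator!r}")


@dataclass
class WindowStat:
    """One window of the scan (row schema of the window-stat table)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    pi_a: float
    pi_b: float
    theta_pi_ratio: float
    fst: float


def _window_starts(length: int, config: ScanConfig) -> np.ndarray:
    step = config.step if config.sliding else config.window_size
    if length < config.window_size:
        return np.array([0])
    n = (length - config.window_size) // step + 1
    return np.arange(n) * step


def window_stats(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pair: tuple[str, str],
    config: ScanConfig = ScanConfig(),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Window-stat table for one ordered population pair (pi_A / pi_B).

    Columns: chrom, start, end (0-based half-open), n_sites, pi_a, pi_b,
    theta_pi_ratio, fst.  Windows with fewer than ``min_sites`` SNPs, or
    with zero diversity in both populations (0/0 ratio), are excluded.
    Chromosome lengths default to the last SNP position per chromosome.
    """
    pop_a, pop_b = pair
    groups = popmap.indices(matrix)
    for pop in pair:
        if pop not in groups:
            raise ValueError(f"population {pop!r} not in population map")
    snp = matrix.sites["type"].to_numpy() == "snp"
    stats_a = allele_freqs(matrix, groups[pop_a])
    stats_b = allele_freqs(matrix, groups[pop_b])

    def site_pi(stats):
        n = stats.n_called.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = 2.0 * stats.p * (1.0 - stats.p) * (2.0 * n) / (2.0 * n - 1.0)
        return np.where((stats.n_called >= 2) & snp, np.nan_to_num(pi), 0.0)

    pi_site_a = site_pi(stats_a)
    pi_site_b = site_pi(stats_b)
    a_comp, b_comp, c_comp, usable = weir_cockerham_components(stats_a, stats_b)
    a_comp = np.where(snp & usable, a_comp, 0.0)
    abc = np.where(snp & usable, a_comp + b_comp + c_comp, 0.0)
    countable = (snp & (stats_a.n_called >= 2) & (stats_b.n_called >= 2)).astype(float)

    chroms = matrix.sites["chrom"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    rows = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos0[sel]
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(p.max()) + 1
        )
        # cumulative sums for O(1) window aggregation
        cums = {
            "pi_a": np.concatenate([[0.0], np.cumsum(pi_site_a[sel])]),
            "pi_b": np.concatenate([[0.0], np.cumsum(pi_site_b[sel])]),
            "a": np.concatenate([[0.0], np.cumsum(a_comp[sel])]),
            "abc": np.concatenate([[0.0], np.cumsum(abc[sel])]),
            "n": np.concatenate([[0.0], np.cumsum(countable[sel])]),
        }
        for start in _window_starts(length, config):
            end = min(start + config.window_size, length)
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            n_sites = int(cums["n"][hi] - cums["n"][lo])
            if n_sites < config.min_sites:
                continue
            denom = float(end - start) if config.pi_denominator == "bp" else float(n_sites)
            pi_a = (cums["pi_a"][hi] - cums["pi_a"][lo]) / denom
            pi_b = (cums["pi_b"][hi] - cums["pi_b"][lo]) / denom
            if pi_a == 0.0 and pi_b == 0.0:
                continue  # 0/0 ratio undefined
            ratio = np.inf if pi_b == 0.0 else pi_a / pi_b
            abc_sum = cums["abc"][hi] - cums["abc"][lo]
            fst = (cums["a"][hi] - cums["a"][lo]) / abc_sum if abc_sum > 0 else np.nan
            rows.append(
                (chrom, int(start), int(end), n_sites, pi_a, pi_b, ratio, fst)
            )
        if not sel.size:
            logger.info("chromosome %s has no sites; no windows", chrom)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "pi_a", "pi_b", "theta_pi_ratio", "fst"],
    )


def _upper_threshold(values: np.ndarray, q: float) -> float:
    """Empirical (1-q) type-7 quantile over finite values; +inf entries are
    treated as exceeding any finite threshold."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.inf
    return float(np.quantile(finite, 1.0 - q))


def select_outliers(
    stats: pd.DataFrame, config: ScanConfig = ScanConfig()
) -> tuple[pd.DataFrame, dict]:
    """Windows in the joint top-q tails of the ratio statistic and F_ST.

    Returns the selected rows and the thresholds used.  Requires at least
    20 usable windows for the empirical quantiles to be meaningful.
    """
    usable = stats.dropna(subset=["fst"])
    if len(usable) < 20:
        raise ValueError(
            f"only {len(usable)} usable windows; need >= 20 — "
            "use a smaller window or step"
        )
    q = config.quantile
    ratio = usable["theta_pi_ratio"].to_numpy()
    fst = usable["fst"].to_numpy()

    thresholds: dict[str, float] = {}
    if config.tail_mode == "ratio_top":
        thr = _upper_threshold(ratio, q)
        ratio_pass = (ratio > thr) | np.isinf(ratio)
        thresholds["ratio_threshold"] = thr
    elif config.tail_mode == "abs_log_top":
        with np.errstate(divide="ignore"):
            stat = np.abs(np.log2(ratio))
        thr = _upper_threshold(stat, q)
        ratio_pass = (stat > thr) | np.isinf(stat)
        thresholds["abs_log2_ratio_threshold"] = thr
    else:  # both_tails
        hi = _upper_threshold(ratio, q / 2.0)
        finite = ratio[np.isfinite(ratio)]
        lo = float(np.quantile(finite, q / 2.0)) if finite.size else -np.inf
        ratio_pass = (ratio > hi) | np.isinf(ratio) | (ratio < lo)
        thresholds["ratio_threshold_high"] = hi
        thresholds["ratio_threshold_low"] = lo

    fst_thr = _upper_threshold(fst, q)
    fst_pass = fst > fst_thr
    thresholds["fst_threshold"] = fst_thr

    mask = (ratio_pass & fst_pass) if config.join == "intersection" else (ratio_pass | fst_pass)
    return usable.loc[mask].copy(), thresholds


@dataclass
class SelectedRegion:
    """A merged run of selected windows with overlapping gene IDs."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_ratio: float
    peak_fst: float
    genes: list[str] = field(default_factory=list)


def merge_and_annotate(
    selected: pd.DataFrame, annotation: AnnotationIndex | None = None
) -> list[SelectedRegion]:
    """Merge overlapping/book-ended selected windows; attach gene overlaps."""
    regions: list[SelectedRegion] = []
    for chrom, grp in selected.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur: SelectedRegion | None = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur.end:
                cur.end = max(cur.end, int(row.end))
                cur.n_windows += 1
                cur.peak_ratio = max(cur.peak_ratio, float(row.theta_pi_ratio))
                cur.peak_fst = max(cur.peak_fst, float(row.fst))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = SelectedRegion(
                    chrom=str(chrom), start=int(row.start), end=int(row.end),
                    n_windows=1, peak_ratio=float(row.theta_pi_ratio),
                    peak_fst=float(row.fst),
                )
        if cur is not None:
            regions.append(cur)
    if annotation is not None:
        for reg in regions:
            reg.genes = annotation.genes_overlapping(reg.chrom, reg.start, reg.end)
    return regions


def regions_to_bed(regions: list[SelectedRegion]) -> str:
    """Selected regions as BED text (0-based half-open)."""
    return "".join(
        f"{r.chrom}\t{r.start}\t{r.end}\t{';'.join(r.genes) or '.'}\t"
        f"{r.peak_fst:.6g}\n"
        for r in regions
    )
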