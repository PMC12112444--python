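"""Diversity indices and F_ST: formula checks, oracle equivalence, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popfinger import (
    CohortSimulator,
    PopulationMap,
    SimConfig,
    allele_freqs,
    locus_diversity,
    pairwise_fst,
    population_summary,
)
from popfinger.io import MISSING

from conftest import make_matrix, two_pop_config


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain python, per site)
# ---------------------------------------------------------------------------

def oracle_site_stats(column):
    """Ho/He/FIS of one locus from raw dosages, written from the textbook
    definitions (Nei unbiased He)."""
    called = [int(x) for x in column if x != MISSING]
    n = len(called)
    p = sum(called) / (2 * n)
    ho = sum(1 for x in called if x == 1) / n
    he = (2 * n / (2 * n - 1)) * 2 * p * (1 - p)
    fis = 1 - ho / he if he > 0 else None
    return ho, he, fis


def oracle_wc_fst(d1, d2):
    """Two-population Weir–Cockerham (1984) F_ST, plain per-site loops."""
    sum_a = sum_abc = 0.0
    for j in range(d1.shape[1]):
        c1 = [int(x) for x in d1[:, j] if x != MISSING]
        c2 = [int(x) for x in d2[:, j] if x != MISSING]
        n1, n2 = len(c1), len(c2)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = sum(c1) / (2 * n1), sum(c2) / (2 * n2)
        h1 = sum(1 for x in c1 if x == 1) / n1
        h2 = sum(1 for x in c2 if x == 1) / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


class TestLocusDiversity:
    def test_worked_example_n4(self):
        # dosages [0,1,1,2]: Ho = 0.5, He = (8/7)*0.5, FIS = 1 - 7/8
        m = make_matrix([[0], [1], [1], [2]])
        div = locus_diversity(allele_freqs(m))
        assert div.ho[0] == pytest.approx(0.5)
        assert div.he[0] == pytest.approx(8 / 7 * 0.5)
        assert div.fis[0] == pytest.approx(0.125)

    def test_monomorphic_locus(self):
        m = make_matrix([[0], [0], [0]])
        div = locus_diversity(allele_freqs(m))
        assert div.ho[0] == 0.0 and div.he[0] == 0.0
        assert np.isnan(div.fis[0])

    def test_single_called_genotype_excluded(self):
        m = make_matrix([[1, 1], [MISSING, 1]])
        div = locus_diversity(allele_freqs(m))
        assert not div.included[0] and div.included[1]

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        div = locus_diversity(allele_freqs(make_matrix(d)))
        for j in range(100):
            if not div.included[j]:
                continue
            ho, he, fis = oracle_site_stats(d[:, j])
            assert div.ho[j] == pytest.approx(ho, abs=1e-12)
            assert div.he[j] == pytest.approx(he, abs=1e-12)
            if fis is not None:
                assert div.fis[j] == pytest.approx(fis, abs=1e-12)


class TestPopulationSummary:
    def test_all_homozygous_population(self):
        d = np.array([[0, 2, 0], [2, 0, 2], [0, 0, 2]], dtype=np.int8)
        pm = PopulationMap({f"s{i}": "P" for i in range(3)})
        table = population_summary(make_matrix(d), pm).table
        assert table.loc["P", "ho"] == 0.0
        assert table.loc["P", "hom_obs"] == 1.0

    def test_duplicated_populations_give_identical_rows(self):
        rng = np.random.default_rng(11)
        block = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        d = np.vstack([block, block])
        pm = PopulationMap(
            {f"s{i}": ("A" if i < 8 else "B") for i in range(16)}
        )
        table = population_summary(make_matrix(d), pm).table
        assert np.allclose(table.loc["A"].to_numpy(), table.loc["B"].to_numpy())

    def test_expected_homozygosity_complements_he(self, default_cohort):
        _, res = default_cohort
        table = population_summary(res.matrix, res.popmap).table
        assert np.allclose(table["hom_exp"], 1.0 - table["he"])
        assert np.allclose(table["hom_obs"], 1.0 - table["ho"])

    def test_hwe_cohort_fis_near_zero(self):
        config = two_pop_config(seed=21, n_sites=20_000)
        res = CohortSimulator(config).run()
        table = population_summary(res.matrix, res.popmap).table
        assert np.all(np.abs(table["fis"]) < 0.01)

    def test_fis_parameter_recovery(self):
        config = two_pop_config(
            seed=22, n_sites=20_000, within_fis={"P1": 0.3, "P2": 0.1}
        )
        res = CohortSimulator(config).run()
        table = population_summary(res.matrix, res.popmap).table
        assert table.loc["P1", "fis"] == pytest.approx(0.30, abs=0.02)
        assert table.loc["P2", "fis"] == pytest.approx(0.10, abs=0.02)


class TestFst:
    def test_fixed_opposite_alleles_gives_one(self):
        d = np.vstack([np.full((6, 40), 2), np.zeros((6, 40))]).astype(np.int8)
        pm = PopulationMap({f"s{i}": ("A" if i < 6 else "B") for i in range(12)})
        (res,) = pairwise_fst(make_matrix(d), pm)
        assert res.fst == pytest.approx(1.0)

    def test_split_population_null_near_zero(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0.05, 0.95, 20_000)
        d = (rng.random((40, 20_000)) < p).astype(np.int8) + (
            rng.random((40, 20_000)) < p
        ).astype(np.int8)
        pm = PopulationMap({f"s{i}": ("A" if i < 20 else "B") for i in range(40)})
        (res,) = pairwise_fst(make_matrix(d), pm)
        assert abs(res.fst) < 0.01

    def test_matches_independent_oracle_and_monotone_in_drift(self):
        fsts = []
        for k, F in enumerate((0.05, 0.2, 0.5)):
            config = two_pop_config(seed=30 + k, drift=F, n_sites=4000,
                                    samples_per_pop=15, missing_rate=0.02)
            res = CohortSimulator(config).run()
            (r,) = pairwise_fst(res.matrix, res.popmap)
            groups = res.popmap.indices(res.matrix)
            oracle = oracle_wc_fst(
                res.matrix.dosages[groups["P1"]], res.matrix.dosages[groups["P2"]]
            )
            assert r.fst == pytest.approx(oracle, abs=1e-10)
            fsts.append(r.fst)
        assert fsts[0] < fsts[1] < fsts[2]

    def test_symmetry_and_single_locus_textbook_value(self):
        d = np.array([[0, 2], [1, 2], [2, 0], [2, 0]], dtype=np.int8)
        pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        m = make_matrix(d)
        (ab,) = pairwise_fst(m, pm, pairs=[("A", "B")])
        (ba,) = pairwise_fst(m, pm, pairs=[("B", "A")])
        assert ab.fst == pytest.approx(ba.fst)
        # with a single usable locus, ratio-of-sums equals the per-locus value
        single = m.take_sites([0])
        (r,) = pairwise_fst(single, pm)
        a, b, c = (comp[0] for comp in r.components)
        assert r.fst == pytest.approx(a / (a + b + c))

    def test_hudson_estimator_agrees_on_strong_divergence(self):
        config = two_pop_config(seed=33, drift=0.3, n_sites=3000, samples_per_pop=15)
        res = CohortSimulator(config).run()
        (wc,) = pairwise_fst(res.matrix, res.popmap, estimator="weir_cockerham")
        (hu,) = pairwise_fst(res.matrix, res.popmap, estimator="hudson")
        assert hu.fst == pytest.approx(wc.fst, abs=0.05)

    def test_no_usable_loci_raises(self):
        d = np.full((4, 3), MISSING, dtype=np.int8)
        pm = PopulationMap({f"s{i}": ("A" if i < 2 else "B") for i in range(4)})
        with pytest.raises(ValueError, match="no usable loci"):
            pairwise_fst(make_matrix(d), pm)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_allele_relabel_and_sample_order_invariance(seed):
    """Ho/He/Pi are invariant to swapping allele labels (d -> 2-d) and to
    sample reordering; F_ST is symmetric under both."""
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    d[rng.random(d.shape) < 0.1] = MISSING
    pm = PopulationMap({f"s{i}": ("A" if i < 6 else "B") for i in range(12)})
    m = make_matrix(d)

    flipped = np.where(d == MISSING, MISSING, 2 - d).astype(np.int8)
    perm = rng.permutation(12)
    shuffled = make_matrix(
        d[perm], samples=[f"s{i}" for i in perm]
    )

    base = population_summary(m, pm).table.sort_index()
    flip = population_summary(make_matrix(flipped), pm).table.sort_index()
    shuf = population_summary(shuffled, pm).table.sort_index()
    for col in ("ho", "he", "pi", "fis"):
        assert np.allclose(base[col], flip[col], equal_nan=True)
        assert np.allclose(base[col], shuf[col], equal_nan=True)
    try:
        (f0,) = pairwise_fst(m, pm)
        (f1,) = pairwise_fst(make_matrix(flipped), pm)
        (f2,) = pairwise_fst(shuffled, pm)
        assert f0.fst == pytest.approx(f1.fst, abs=1e-12)
        assert f0.fst == pytest.approx(f2.fst, abs=1e-12)
    except ValueError:
        pass  # all loci unusable in a degenerate draw
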