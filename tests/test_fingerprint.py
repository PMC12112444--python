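"""Core-SNP cascade, diagnostic markers, fingerprints and schemes."""

import numpy as np
import pytest

from popfinger import (
    AnnotationIndex,
    CascadeConfig,
    GeneModel,
    PopulationMap,
    PopulationFingerprinter,
    build_fingerprint,
    classify_individual,
    enumerate_schemes,
    filter_cascade,
    find_diagnostic_loci,
)
from popfinger.fingerprint import CONTINUE, UNRESOLVED, DiagnosticLocus
from popfinger.io import MISSING, GenotypeMatrix
from popfinger.sim import _inbred_genotypes

from conftest import make_matrix


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

class TestFilterCascade:
    def test_designed_fixture_loses_one_locus_per_stage(self, cascade_fixture):
        m, popmap, ann = cascade_fixture
        core, filtered = filter_cascade(m, ann, popmap, CascadeConfig())
        stages = [(s["stage"], s["n_in"], s["n_out"]) for s in core.ledger]
        assert stages == [
            ("snp_chromosomes", 8, 7),
            ("maf_het_missing", 7, 6),
            ("genic", 6, 5),
            ("impute", 5, 5),
            ("maf_het_strict", 5, 4),
            ("ld_prune", 4, 3),
        ]
        assert set(core.locus_ids) == {"L1", "L7", "L8"}

    def test_ledger_telescopes(self, cascade_fixture, default_cohort):
        for args in (cascade_fixture, None):
            if args is None:
                _, res = default_cohort
                m, popmap, ann = res.matrix, res.popmap, res.annotation
            else:
                m, popmap, ann = args
            core, filtered = filter_cascade(m, ann, popmap)
            for prev, nxt in zip(core.ledger, core.ledger[1:]):
                assert prev["n_out"] == nxt["n_in"]
                assert nxt["n_out"] <= nxt["n_in"]
            assert core.ledger[-1]["n_out"] == filtered.n_sites == len(core.locus_ids)

    def test_chromosome_whitelist(self, cascade_fixture):
        m, popmap, ann = cascade_fixture
        core, _ = filter_cascade(m, ann, popmap, CascadeConfig(chromosomes=("chr1",)))
        assert core.ledger[0]["n_out"] == 4  # chr1 SNPs only

    def test_pruned_set_has_no_linked_pair(self, default_cohort):
        _, res = default_cohort
        config = CascadeConfig()
        core, filtered = filter_cascade(res.matrix, res.annotation, res.popmap, config)
        from popfinger.fingerprint import _safe_r2

        pos = filtered.sites["pos"].to_numpy()
        chrom = filtered.sites["chrom"].to_numpy()
        for j in range(filtered.n_sites):
            for k in range(j + 1, filtered.n_sites):
                if chrom[j] != chrom[k] or pos[k] - pos[j] > config.ld_window:
                    continue
                r2 = _safe_r2(filtered.dosages[:, j], filtered.dosages[:, k])
                assert r2 is None or r2 < config.ld_r2_max

    def test_empty_survivors_is_not_an_error(self, cascade_fixture):
        m, popmap, ann = cascade_fixture
        core, filtered = filter_cascade(
            m, ann, popmap, CascadeConfig(chromosomes=("chr9",))
        )
        assert core.locus_ids == [] and filtered.n_sites == 0

    def test_imputation_fills_with_population_mode(self):
        d = np.array(
            [[2, 2], [2, MISSING], [2, 2], [0, 0], [0, 0], [0, MISSING]],
            dtype=np.int8,
        )
        m = make_matrix(d)
        popmap = PopulationMap({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        from popfinger.fingerprint import impute_pop_mode

        filled = impute_pop_mode(m, popmap)
        assert filled.dosages[1, 1] == 2  # A's mode
        assert filled.dosages[5, 1] == 0  # B's mode


# ---------------------------------------------------------------------------
# diagnostic loci
# ---------------------------------------------------------------------------

class TestFindDiagnosticLoci:
    def test_published_seven_marker_table(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        loci = find_diagnostic_loci(matrix, popmap)
        assert {l.locus_id for l in loci} == {"SNP1", "SNP3", "SNP5", "SNP6", "SNP7"}
        snp1 = next(l for l in loci if l.locus_id == "SNP1")
        assert snp1.consensus == {
            "blue_tilapia": "TT", "nile_tilapia": "CC", "red_tilapia": "CC"
        }

    def test_single_heterozygote_rejected_unless_tolerated(self):
        col = np.array([2] * 7 + [1] + [0] * 8, dtype=np.int8)
        m = make_matrix(col[:, None])
        popmap = PopulationMap({f"s{i}": ("A" if i < 8 else "B") for i in range(16)})
        assert find_diagnostic_loci(m, popmap, max_discordant=0) == []
        tolerant = find_diagnostic_loci(m, popmap, max_discordant=1)
        assert len(tolerant) == 1

    def test_excess_missingness_rejected(self):
        col = np.array([2, 2, MISSING, MISSING, 0, 0, 0, 0], dtype=np.int8)
        m = make_matrix(col[:, None])
        popmap = PopulationMap({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        assert find_diagnostic_loci(m, popmap, max_missing=0.1) == []
        assert len(find_diagnostic_loci(m, popmap, max_missing=0.5)) == 1

    def test_planted_loci_recovered_exactly(self, default_cohort):
        _, res = default_cohort
        found = {l.locus_id for l in find_diagnostic_loci(res.matrix, res.popmap)}
        planted = {d["locus_id"] for d in res.truth.diagnostic_loci}
        assert found == planted

    def test_invariant_to_sample_order_and_allele_swap(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        base = find_diagnostic_loci(matrix, popmap)
        perm = np.random.default_rng(0).permutation(matrix.n_samples)
        shuffled = matrix.take_samples(perm)
        assert {l.locus_id for l in find_diagnostic_loci(shuffled, popmap)} == {
            l.locus_id for l in base
        }
        flipped = GenotypeMatrix(
            np.where(matrix.dosages == MISSING, MISSING, 2 - matrix.dosages),
            matrix.sites.assign(ref=matrix.sites["alt"], alt=matrix.sites["ref"]),
            matrix.samples,
        )
        swapped = find_diagnostic_loci(flipped, popmap)
        assert {l.locus_id for l in swapped} == {l.locus_id for l in base}
        assert {frozenset(map(frozenset, l.partition)) for l in swapped} == {
            frozenset(map(frozenset, l.partition)) for l in base
        }

    def test_overlapping_populations_yield_no_diagnostics(self):
        from conftest import two_pop_config
        from popfinger import CohortSimulator

        total = 0
        for seed in range(5):
            config = two_pop_config(
                seed=100 + seed, drift=0.05, n_sites=800, samples_per_pop=15,
                within_fis={"P1": 0.1, "P2": 0.1}, missing_rate=0.02,
            )
            res = CohortSimulator(config).run()
            total += len(find_diagnostic_loci(res.matrix, res.popmap))
        assert total == 0


# ---------------------------------------------------------------------------
# fingerprint profile
# ---------------------------------------------------------------------------

class TestBuildFingerprint:
    def test_published_profile_columns(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        loci = find_diagnostic_loci(matrix, popmap)
        profile = build_fingerprint(matrix, loci, popmap)
        snp1 = profile.individuals["SNP1"]
        assert all(snp1.iloc[:15] == "TT")
        assert all(snp1.iloc[15:] == "CC")
        assert profile.consensus.loc["blue_tilapia", "SNP1"] == "TT"

    def test_missing_call_rendered_as_missing_code(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        m2 = GenotypeMatrix(matrix.dosages.copy(), matrix.sites, matrix.samples)
        m2.dosages[0, 0] = MISSING
        loci = find_diagnostic_loci(m2, popmap)
        profile = build_fingerprint(m2, loci, popmap)
        assert profile.individuals.iloc[0]["SNP1"] == "--"
        assert profile.consensus.loc["blue_tilapia", "SNP1"] == "TT"

    def test_simulated_profile_matches_truth(self, default_cohort):
        _, res = default_cohort
        loci = find_diagnostic_loci(res.matrix, res.popmap)
        profile = build_fingerprint(res.matrix, loci, res.popmap)
        for rec in res.truth.diagnostic_loci:
            for pop, genotype in rec["genotypes"].items():
                assert profile.consensus.loc[pop, rec["locus_id"]] == genotype

    def test_locus_absent_from_matrix_raises(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        loci = find_diagnostic_loci(matrix, popmap)
        ghost = DiagnosticLocus("SNP99", 0, loci[0].consensus, loci[0].consensus_dosage)
        with pytest.raises(ValueError, match="SNP99"):
            build_fingerprint(matrix, [ghost], popmap)


# ---------------------------------------------------------------------------
# schemes and classification
# ---------------------------------------------------------------------------

class TestEnumerateSchemes:
    def test_published_partitions_give_two_classes(self, tilapia_fingerprint):
        matrix, popmap = tilapia_fingerprint
        loci = find_diagnostic_loci(matrix, popmap)
        enum = enumerate_schemes(loci, popmap.populations)
        assert len(enum.classes) == 2
        by_first = {cls.isolated_sequence[0]: cls for cls in enum.classes}
        blue_first = by_first[("blue_tilapia",)]
        nile_first = by_first[("nile_tilapia",)]
        assert set(blue_first.step_markers[0]) == {"SNP1", "SNP5", "SNP6", "SNP7"}
        assert set(blue_first.step_markers[1]) == {"SNP3"}
        assert set(nile_first.step_markers[0]) == {"SNP3"}
        assert set(nile_first.step_markers[1]) == {"SNP1", "SNP5", "SNP6", "SNP7"}
        assert all(cls.depth == 2 for cls in enum.classes)

    def test_three_way_partition_gives_one_step_scheme(self):
        locus = DiagnosticLocus(
            "M1", 0,
            consensus={"A": "AA", "B": "AG", "C": "GG"},
            consensus_dosage={"A": 0, "B": 1, "C": 2},
        )
        enum = enumerate_schemes([locus], ["A", "B", "C"])
        assert len(enum.classes) == 1 and enum.classes[0].depth == 1

    def test_two_populations_one_marker_single_scheme(self):
        locus = DiagnosticLocus(
            "M1", 0, {"A": "AA", "B": "GG"}, {"A": 0, "B": 2}
        )
        enum = enumerate_schemes([locus], ["A", "B"])
        assert len(enum.classes) == 1
        scheme = enum.classes[0].scheme()
        assert classify_individual({"M1": "AA"}, scheme) == "A"
        assert classify_individual({"M1": "GG"}, scheme) == "B"

    def test_inseparable_populations_reported(self):
        locus = DiagnosticLocus(
            "M1", 0, {"A": "AA", "B": "GG", "C": "GG", "D": "GG"},
            {"A": 0, "B": 2, "C": 2, "D": 2},
        )
        enum = enumerate_schemes([locus], ["A", "B", "C", "D"])
        assert not enum.resolvable
        assert frozenset({"B", "C", "D"}) in enum.unresolvable_groups


@pytest.fixture(scope="module")
def schemes(tilapia_fingerprint):
    matrix, popmap = tilapia_fingerprint
    loci = find_diagnostic_loci(matrix, popmap)
    enum = enumerate_schemes(loci, popmap.populations)
    by_first = {cls.isolated_sequence[0]: cls for cls in enum.classes}
    combo1 = by_first[("blue_tilapia",)].scheme(["SNP1", "SNP3"])
    combo2 = by_first[("nile_tilapia",)].scheme(["SNP3", "SNP1"])
    return combo1, combo2


class TestClassifyIndividual:
    def test_published_decisions(self, schemes):
        combo1, combo2 = schemes
        # combination 1: SNP1 isolates blue, then SNP3 splits Nile from red
        assert classify_individual({"SNP1": "TT"}, combo1) == "blue_tilapia"
        assert classify_individual({"SNP1": "CC", "SNP3": "TT"}, combo1) == "nile_tilapia"
        assert classify_individual({"SNP1": "CC", "SNP3": "CC"}, combo1) == "red_tilapia"
        # combination 2: SNP3 isolates Nile, then SNP1: TT blue / CC red
        assert classify_individual({"SNP3": "TT"}, combo2) == "nile_tilapia"
        assert classify_individual({"SNP3": "CC", "SNP1": "TT"}, combo2) == "blue_tilapia"
        assert classify_individual({"SNP3": "CC", "SNP1": "CC"}, combo2) == "red_tilapia"

    def test_heterozygote_or_missing_unresolved(self, schemes):
        combo1, _ = schemes
        assert classify_individual({"SNP1": "CT"}, combo1) == UNRESOLVED
        label, failed = classify_individual({"SNP1": "CC"}, combo1, detail=True)
        assert label == UNRESOLVED and failed == 2  # SNP3 genotype absent

    def test_genotype_normalisation(self, schemes):
        combo1, _ = schemes
        assert classify_individual({"SNP1": "tt"}, combo1) == "blue_tilapia"


class TestPopulationFingerprinter:
    def test_end_to_end_holdout_classification(self, default_cohort):
        config, res = default_cohort
        est = PopulationFingerprinter().fit(res.matrix, res.popmap, res.annotation)
        assert est.score(res.matrix, res.popmap) == 1.0

        # fresh individuals drawn from the truth frequencies
        rng = np.random.default_rng(123)
        blocks, names, labels = [], [], {}
        for pop in config.pop_names:
            g = _inbred_genotypes(
                res.truth.pop_freqs[pop], config.within_fis[pop], 10, rng
            )
            blocks.append(g)
            for i in range(10):
                name = f"new_{pop}_{i}"
                names.append(name)
                labels[name] = pop
        fresh = GenotypeMatrix(np.vstack(blocks), res.matrix.sites, names)
        pred = est.predict(fresh)
        true = np.array([labels[s] for s in fresh.samples])
        assert np.mean(pred == true) == 1.0

    def test_predict_requires_scheme(self, cascade_fixture):
        est = PopulationFingerprinter()
        with pytest.raises(ValueError):
            est.predict(cascade_fixture[0])

    def test_sklearn_param_interface(self):
        est = PopulationFingerprinter(max_discordant=1)
        assert est.get_params()["max_discordant"] == 1
        est.set_params(max_discordant=0)
        assert est.max_discordant == 0
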