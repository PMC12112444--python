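# popfinger

Population-genomic analysis and SNP fingerprinting for breeding
populations of diploid organisms, built around the kind of question a
fish-breeding program asks: how much diversity does each strain retain,
how differentiated are the strains, where has selection depressed
diversity, and — practically — which handful of SNPs suffices to tell an
individual's population of origin when juveniles cannot be distinguished
morphologically?

The package is aimed at population geneticists and breeders working with
a few resequenced cohorts (tens of individuals per population, genome-wide
biallelic SNP calls in VCF). It provides:

* **Diversity and differentiation** — per-population observed/expected
  heterozygosity and homozygosity, per-variant-site nucleotide diversity
  π, inbreeding coefficient F_IS = 1 − H_o/H_e, and pairwise F_ST with
  the Weir–Cockerham (1984) variance-component estimator
  (F_ST = Σa / Σ(a+b+c), ratio of sums; Hudson's estimator as an
  alternative).
* **Population structure** — PCA of Patterson-normalised dosages
  ((g − 2p)/√(2p(1−p)) after MAF filtering and mean imputation), the
  VanRaden genomic relationship matrix G = ZZ′/2Σp(1−p), identity-by-state
  similarity/distance, neighbour-joining trees, and a binomial admixture
  model (genotype g_il ~ Binomial(2, Σ_k q_ik f_kl)) fitted by monotone
  EM with entry-masking cross-validation to choose the number of ancestral
  components K.
* **Linkage disequilibrium** — dosage r² (Rogers–Huff), two-locus
  haplotype EM for D and D′, and binned LD-decay curves per population.
* **Selective-sweep scanning** — sliding windows (1 Mb / 100 kb by
  default) of per-population π, their ratio θπ_A/θπ_B, and window F_ST;
  outlier windows in the joint top-5% tails of both statistics are merged
  into candidate regions and annotated with overlapping genes.
* **SNP fingerprinting** — a Plink-style core-SNP screening cascade
  (indel/chromosome filter → MAF/heterozygosity/missingness →
  genic-region filter → imputation → stricter MAF/het → LD pruning),
  discovery of *diagnostic* loci at which every population is fixed for a
  different homozygote, fingerprint genotype tables, and enumeration of
  minimal multi-step identification schemes with a scheme-based
  classifier.
* **Synthetic cohorts** — a seeded simulator
  (Balding–Nichols frequencies: population frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p at drift F; optional
  hybrid population, planted sweeps, planted diagnostic loci, LD blocks,
  missing calls and indels) with machine-readable ground truth for
  validation.

Estimator-shaped components follow scikit-learn conventions
(`GenotypePCA`, `AdmixtureEM`, `PopulationFingerprinter` with
`fit`/`transform`/`predict` and trailing-underscore fitted attributes);
everything else is plain functions over a `GenotypeMatrix` /
`PopulationMap` data model read from standard VCF, GFF3 and TSV files.

## Worked example

Simulate a three-population cohort mirroring a typical breeding design —
a long-selected strain (OA), a recently introduced wild population (ON)
and a hybrid-origin strain (OS, an even admixture of an ON-like parent
and an outgroup) — then compute diversity, differentiation and a
fingerprint-based identification scheme:

```python
from popfinger import (CohortSimulator, SimConfig, population_summary,
                       pairwise_fst, PopulationFingerprinter)

res = CohortSimulator(SimConfig(seed=1, n_sites=4000)).run()
print(population_summary(res.matrix, res.popmap).table.round(4))
for r in pairwise_fst(res.matrix, res.popmap):
    print(f"F_ST({r.pop_a},{r.pop_b}) = {r.fst:.4f}")

est = PopulationFingerprinter().fit(res.matrix, res.popmap, res.annotation)
print(est.scheme_.describe())
```

Output:

```
        ho  hom_obs      he  hom_exp      pi     fis  n_loci
OA  0.1915   0.8085  0.2132   0.7868  0.2132  0.1017    4000
ON  0.2949   0.7051  0.3085   0.6915  0.3085  0.0442    4000
OS  0.2260   0.7740  0.3210   0.6790  0.3210  0.2960    4000
F_ST(OA,ON) = 0.2839
F_ST(OA,OS) = 0.2615
F_ST(ON,OS) = 0.0619
step 1: chr4:3228174: AA -> OA, TT -> next step
step 2: chr1:6407498: GG -> ON, CC -> OS
```

The indices behave as the design dictates: the long-selected OA strain
has the lowest heterozygosity and π, the hybrid OS strain the highest π
together with a high F_IS (≈0.30, its configured within-population
inbreeding), and the hybrid pair ON/OS is far less differentiated
(F_ST ≈ 0.06) than either is from OA. The fitted fingerprinter finds the
planted diagnostic loci and prints a two-step decision scheme: one marker
isolates OA by its homozygous genotype, a second splits ON from OS;
`est.predict(matrix)` applies the scheme to new individuals.

The same stages run from the shell:

```bash
popfinger simulate --out cohort --seed 1
popfinger all --vcf cohort/cohort.vcf --popmap cohort/popmap.tsv \
              --gff cohort/annotation.gff3 --out results --seed 1
```

## Layout

```
src/popfinger/
  io.py           genotype matrix, population map, VCF/TSV I/O
  annotation.py   gene/exon interval index, GFF3, site classification
  sim.py          seeded cohort simulator + truth set
  diversity.py    Ho/He/π/F_IS and F_ST estimators
  structure.py    PCA, kinship, NJ tree, admixture EM + CV
  ld.py           LD statistics and decay curves
  sweep.py        windowed θπ-ratio × F_ST sweep scan
  fingerprint.py  core-SNP cascade, diagnostic loci, schemes, classifier
  cli.py          `popfinger` command-line interface
  datasets.py     built-in worked example
```

See `docs/methods.md` for the statistical methods, parameter defaults and
known limitations.
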