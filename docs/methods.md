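# Methods

This note documents the statistical models, estimator conventions,
parameter defaults and design choices behind `popfinger`, and states what
the simulation-based validation does and does not demonstrate.

## Data model

Genotypes are held as a dense samples × sites matrix of diploid
alternate-allele dosages {0, 1, 2} with −1 for missing calls, plus a
per-site table (chromosome, 1-based position, REF/ALT, snp/indel) and an
ordered sample list. Only biallelic records are modelled; multi-allelic
VCF records are dropped by default (or split per alternate allele on
request), and half-missing genotypes are treated as missing. Coordinates
are 1-based in VCF/GFF3 and 0-based half-open internally, including BED
output. Missing genotypes are never imputed at I/O time; imputation is an
explicit, documented stage of the fingerprint cascade only.

## Diversity indices

For a locus with n called genotypes, alternate frequency p̂ and h
heterozygotes:

* H_o = h/n; observed homozygosity = 1 − H_o.
* H_e = (2n/(2n−1)) · 2p̂(1−p̂), the Nei small-sample correction
  (`unbiased=False` gives raw 2p̂q̂). The correction is a convention
  choice; both are exposed because upstream pipelines differ.
* Per-variant-site nucleotide diversity π equals H_e at a biallelic
  site; the headline per-population Pi is the mean over included loci
  (loci with ≥ 2 called genotypes). A per-bp convention — the summed
  per-site π over a bp span — is used inside sweep windows and available
  via `pi_span_bp`; the two conventions differ by orders of magnitude and
  are always labelled.
* Population-level F_IS = 1 − mean(H_o)/mean(H_e), a ratio of means
  rather than a mean of per-locus ratios, which avoids instability at
  low-H_e loci. Per-locus F_IS is also reported, undefined where H_e = 0.

## F_ST

The default estimator is Weir & Cockerham (1984): per-locus variance
components a (among populations), b (among individuals within
populations) and c (within individuals) computed from the two samples'
sizes, allele frequencies and observed heterozygosities, combined across
loci as a ratio of sums Σa/Σ(a+b+c). Loci with fewer than two called
genotypes in either population are excluded; monomorphic loci contribute
zero to both sums. Hudson's estimator (ratio of sums of the Bhatia et
al. 2013 numerator/denominator) is available as `estimator="hudson"`.
Note that the Weir–Cockerham point estimate is slightly negative on
*duplicated* samples (the correction assumes independent sampling); on
independent samples of one population it is unbiased around zero.

## PCA, kinship, tree

PCA removes sites with minor allele frequency below 5% (configurable),
fills missing dosages with the locus mean, centres each locus by 2p̂ and
scales by √(2p̂(1−p̂)) (Patterson normalisation), and takes the SVD.
Variance-explained fractions are singular values squared over their total.
Component signs follow a fixed convention — the largest-magnitude score
entry of each component is positive — so runs are comparable and tests
stable.

The genomic relationship matrix is VanRaden method 1,
G = ZZ′/(2Σp̂(1−p̂)) with Z the 2p̂-centred dosage matrix and missing
entries contributing zero after centring. IBS similarity of two samples
is the mean over co-called loci of (2 − |g_i − g_j|)/2; the distance is
its complement; a pair with no co-called loci is an error.

The population/individual tree is Saitou–Nei neighbour joining on the IBS
distance matrix (scikit-bio's implementation, which clamps negative
branch lengths to zero and shifts the deficit to the adjacent branch).
This is a relationship summary, not a substitution-model phylogeny: a
maximum-likelihood tree on concatenated SNPs was deliberately not
reimplemented, since for cohort-level relationship display NJ on IBS
carries the same information.

## Admixture model

Each individual i has ancestry fractions q_i over K components with
component allele frequencies f_k; the dosage likelihood is
g_il ~ Binomial(2, x_il), x_il = Σ_k q_ik f_kl. Fitting uses the
FRAPPE-style multiplicative EM update, which is monotone in
log-likelihood; missing genotypes are dropped from the likelihood.
Parameters are floored at 10⁻⁶ away from {0, 1} and Q rows renormalised;
iteration stops when the log-likelihood gain falls below `tol` (default
10⁻⁴) or at `max_iter`. EM is slower than quasi-Newton alternatives but
simple, monotone and adequate at cohort scale. K = 1 is closed-form
(component frequencies equal the pooled frequencies).

K is chosen by entry-masking cross-validation: called genotype entries
are split into random folds, each fold masked in turn, the model refitted
and the prediction error over masked entries measured as
(g − 2x̂)²/2 (binomial deviance behind a flag); the selected K minimises
mean error. Masking entries rather than whole samples matches how
admixture cross-validation error is normally computed. Folds are seeded;
a fold that would empty a sample or site is re-randomised once and then
rejected.

## Linkage disequilibrium

The default pairwise statistic is squared Pearson correlation of dosages
over pairwise-complete samples (Rogers–Huff), which requires no phasing.
A two-locus haplotype-frequency EM (only the double heterozygote is
ambiguous at biallelic loci) provides D, D′ = D/D_max and haplotype-based
r². Decay curves average r² in distance bins over all intra-chromosome
pairs within `max_dist` (randomly subsampled above `max_pairs`); pairs
with a locus monomorphic among co-called samples are skipped and counted.
The half-decay summary — the start of the first bin whose mean r² is at
most half the maximum bin mean — is this package's own convenience
statistic and is reported as "not reached" when applicable. Note that
with n samples the null expectation of dosage r² is ≈ 1/(n−1), so decay
curves flatten onto that sampling floor rather than zero.

## Sweep scan

Windows are 1 Mb sliding in 100 kb steps per chromosome by default (a
non-overlapping mode is available); only full-length windows are emitted,
except that a chromosome shorter than one window yields a single
truncated window. Per window and ordered population pair (A, B):
π per population (per-bp by default: summed per-site unbiased
heterozygosity over the window span; per-site denominator optional), the
ratio θπ_A/θπ_B, and window F_ST as the ratio of summed Weir–Cockerham
components over the window's SNPs. Windows with fewer than `min_sites`
SNPs are excluded. A ratio x/0 with x > 0 is +inf and always counts as an
upper-tail outlier (fixation in the denominator population is the
strongest sweep signal); 0/0 windows are excluded.

Outliers are windows exceeding the empirical (1−q) quantile (type-7,
strictly-greater tie rule, q = 5% default) of both the ratio statistic
and F_ST — the intersection rule standard for joint π-ratio × F_ST
scans; union is available. The ratio tail defaults to one-sided per
ordered pair (`ratio_top`); `abs_log_top` (|log₂ ratio|) mirrors a
two-sided reading, and `both_tails` splits q across tails. Selected
windows are merged when overlapping or book-ended, and merged regions
annotated with overlapping gene IDs by interval intersection.

## Fingerprint cascade and identification schemes

The core-SNP screen applies, in order: (1) drop indels and
off-whitelist chromosomes; (2) keep loci with pooled MAF > 0.2, pooled
observed heterozygote fraction < 0.05 and missing rate < 0.1 (Plink-style
`maf`/`het`/`geno` semantics — "het" is read as the pooled per-locus
heterozygote fraction, "geno" as the per-locus missing rate); (3) drop
intergenic loci; (4) impute missing genotypes with the per-population
modal genotype (ties to the smaller dosage, pooled-mode fallback) — a
deliberately simple fill that is exact at the fixed-difference loci the
cascade targets, with the imputation stage pluggable; (5) keep MAF > 0.3
and het < 0.01, computed after imputation as the stage order implies;
(6) greedy position-ordered LD pruning: a locus is dropped if its dosage
r² with any already-retained locus within 500 kb reaches 0.2
(first-kept-wins, deterministic). Every stage records in/out counts in a
ledger; an empty survivor set is a valid result, not an error.

A locus is *diagnostic* when every population is fixed for one
homozygous genotype — at most `max_discordant` (default 0) called
exceptions, heterozygotes counting as exceptions, missing calls ignored
up to a 10% rate — and at least two populations differ. This matches the
pure-genotype fingerprint pattern (TT/AA/GG/CC columns) required for
unambiguous single-marker reads.

Identification schemes are enumerated recursively: a step chooses a
marker whose induced partition of the remaining populations isolates at
least one of them; the residual (non-isolated) populations are passed to
the next step. Only depth-minimal schemes are kept; schemes with the same
sequence of isolated populations form a class, within which markers
inducing identical partitions are interchangeable. Populations that no
marker separates are reported as explicit indistinguishable groups.
Classification applies the steps in order and returns "unresolved" (with
the failing step) for heterozygous, missing or novel genotypes — a
deliberate abstention rather than a guess.

## Simulator

The simulator emulates a three-population breeding design: a
long-selected low-diversity strain (default drift F = 0.4, F_IS = 0.10),
a recently introduced wild population (F = 0.15, F_IS = 0.05) and a
hybrid-origin strain formed as a 50/50 frequency mixture of the wild
population's frequencies and an outgroup parent (outgroup F = 0.3) with
elevated inbreeding (F_IS = 0.30) — fifteen individuals per population,
matching the small per-population cohorts typical of breeding-program
resequencing. Ancestral frequencies are Uniform(0.05, 0.95); population
frequencies are Balding–Nichols Beta draws; genotypes use
inbreeding-adjusted probabilities (p² + Fpq, 2pq(1−F), q² + Fpq).
Defaults plant one 1 Mb sweep (target-population frequencies moved toward
the nearest fixation boundary by ε = 0.1, so windowed π drops by
≈ 1 − ε²) and two diagnostic fixed-difference loci per population inside
genic regions, add 2% missing calls and 5% indel sites, and tile 60% of
each chromosome with 30 kb genes (three exons covering 10% of each gene).
Since no demographic parameters are published for real cohorts of this
kind at desk scale, these values were chosen once for realism and
testability, not historical fidelity.

Deliberate simplifications, and hence limits on what passing tests show
about real data: sites are in linkage equilibrium unless an LD block is
requested (the block model is a positional Markov copy with
distance-dependent refresh, giving exponentially decaying pairwise
correlation — not recombination); the hybrid population is drawn from
mixed *frequencies*, not per-individual mosaic haplotypes, which is
sufficient for frequency-based statistics (F_ST, PCA, admixture means)
but understates inter-individual ancestry variance; indels exist only to
exercise the cascade's indel-removal stage and are not length-classified;
there is no sequencing-error or depth model, so real-data genotyping
error modes (allele dropout, paralogy) are untested. Ground truth
(frequencies, ancestry matrix, planted loci and intervals, drift
parameters) is written as JSON with 0-based half-open intervals.

## Numerical and testing choices

All randomness flows from a single integer seed per run
(`numpy.random.default_rng`); identical configurations produce
byte-identical output files. Quantiles are empirical type-7 with
strictly-greater tie breaking, so all-equal statistics select nothing.
EM log-likelihood traces are asserted non-decreasing to within a 10⁻⁶
relative tolerance (parameter flooring can perturb the last digits).
Validation problem sizes — 2 × 10⁴ loci for moment and null F_ST checks,
30 individuals per population for parameter recovery, 4 × 10³ loci over
two 10 Mb chromosomes with 10–20 seeded replicates for the sweep
benchmark, K ∈ 1…5 with 3 folds at 1.5 × 10³ loci for admixture
cross-validation — were chosen so each check's sampling error is well
inside its assertion margin while the whole suite stays quick to run.

## Known limitations

* Two-population F_ST only per pair; no hierarchical/AMOVA variants.
* The admixture EM can need many iterations near convergence; CV uses a
  looser tolerance than final fits.
* NJ on IBS distances reflects relationship structure, not evolutionary
  branch lengths.
* The per-population modal-genotype imputation is inappropriate for loci
  segregating within populations; it exists to serve the fingerprint
  cascade, where surviving loci are near-fixed.
* Scheme enumeration assumes marker genotypes are read without error;
  the "unresolved" abstention is the only safeguard against novel
  genotypes.
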