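# Methods

This note documents the models, numerical conventions and design choices
behind the package, and states what the synthetic-data generator does and
does not emulate.

## The sex-determination model

Sex is a function of zygosity at one Z-linked locus. An embryo with a
single allele (karyotype WZ or Z0) is female; two distinct alleles (ZZ)
male; two identical alleles (ZZ homozygote) inviable. Homozygotes initiate
female-mode development in a karyotypically male background, fail to
down-regulate Z-linked expression, and die as late embryos. The package
treats allele identity at the amino-acid level of the exon-8–exon-9 region:
two haplotypes with the same protein sequence are the same allele. True
*functional* specificity classes (several amino-acid haplotypes sharing one
specificity) are not modelled; the simulator exposes the identity map as
the single supported specificity mapping, which is the conservative choice
when the number of functional classes is unknown.

## Forward simulator (`zsd.simcore`)

Discrete non-overlapping generations, random mating, equal fecundity, fixed
adult quotas (`n_females`, `n_males`). Each zygote draws a mother and
father uniformly; a WZ mother transmits W or her Z allele with probability
½ each, the father transmits either allele with probability ½. Homozygous
ZZ zygotes are discarded before adulthood, which implements the selection
regime exactly rather than through a fitness weight.

**Z0 females.** With probability `z0_rate` (default 0.004, matching the
~0.4% wild incidence of W-less females) a W-bearing egg loses the W and the
zygote becomes a Z0 female carrying the paternal allele. A Z0 mother's
unpaired Z univalent is assumed to segregate randomly — ½ of her eggs carry
her Z, ½ carry no sex chromosome. The real segregation ratio is unknown
(cytology suggests a self-pairing tendency of the univalent); the ½/½
assumption is the maximum-entropy choice and is confined to one code path.

**Haplotype structure.** An allele is a concrete coding haplotype: a
20-codon conserved exon-8 flank, a hypervariable region (HVR) of 7–24
residues, and a 97-codon exon 9 (within the observed 94–102-residue
range). HVR codons are drawn from {AAT (N), CAT (H), AGT (S), TAT (Y)} —
all matching the ANT/NAT pattern that dominates real HVRs. Tryptophan,
which occurs rarely in real HVRs, is encoded only by TGG and therefore
cannot satisfy the ANT/NAT constraint; the validator accepts W on input but
the generator never produces it. This is a deliberate simplification: the
generated codon set is exactly the constraint the diversity profiler tests
for.

**Mutation.** Three processes per transmitted allele copy: single-codon
HVR slippage (duplicate or delete one codon; draws crossing the 7/24
bounds are rejected, so a bell-shaped length distribution emerges from the
bounded walk rather than being imposed), HVR point substitution within the
four-codon alphabet, and nonsynonymous single-nucleotide substitution in
exon 9. Mutation rates are free parameters: no empirical rates exist for
this locus. Defaults (`mu_slip` 1e-3 per copy, `mu_point` 1e-4 per HVR
codon, `mu_e9` 1e-5 per codon) are order-of-magnitude placeholders chosen
so that mutation is slow relative to selection at default population
sizes.

**Scaled-down study conditions.** Simulations that emulate the wild
sampling regime use populations ~10³ smaller than a realistic butterfly
N<sub>e</sub>. Standing allelic richness at mutation–drift–selection
balance scales with N·μ, so the regime-emulating conditions (800 females +
800 males, 300 founder alleles, `mu_slip` 5e-2, `mu_point` 5e-3) scale
mutation up by roughly the same factor the population is scaled down,
holding the quantity that matters — the ratio of sample size to standing
richness (~0.2–0.3) — at the study's value. Under these conditions a
120-female sample shows ~80% singletons, a maximum allele count of 3–5 and
haplotype diversity ≈ 0.99.

**What the generator does not emulate.** No recombination within the gene
(none is expected to matter over the assayed 2-exon fragment), no
population structure or migration (wild differentiation at the locus is
near zero), no endosymbionts, no overlapping generations or fecundity
variance, no W-chromosome sequence evolution. Passing tests therefore show
that the analyses recover the truth of *this* idealised dynamic, not that
real data are free of alignment error, null alleles, genotyping dropout or
annotation-dependent expression quantification.

**Broods and expression.** `simulate_brood` draws a multinomial over the
zygote classes of the analytic cross expectation; homozygotes appear as
unhatched black eggs, every viable class hatches (background egg mortality
is zero by default). `simulate_expression_matrix` gives every gene a
lognormal baseline (log-mean 3.0, log-sd 1.2 — a TPM-like spread),
multiplies Z-linked genes by `z_a_ratio` (default 0.6, inside the
0.5–0.7 compensated band) in hem and het samples and additionally by
`hom_factor` (default 1.87, the observed hom/hem Z differential) in hom
samples, then applies multiplicative lognormal noise (log-sd 0.25). The
default replicate design is 3 hem / 3 het / 6 hom samples, mirroring the
embryo RNA-seq design it emulates.

## Diversity statistics (`zsd.diversity`)

**Nei–Gojobori.** The unweighted pathway method: per-codon synonymous site
fractions (each position contributes the fraction of its three possible
changes that are synonymous; changes to stop codons count as
nonsynonymous, so syn + nonsyn sites = 3 per codon), site counts averaged
over the two sequences, and differences averaged over all minimal
substitution pathways that avoid stop-codon intermediates (all pathways if
every one is blocked). Pairwise deletion operates at codon granularity: a
codon column is skipped for a pair if either member contains a gap,
ambiguity code or stop. The implementation is verified against an
independent brute-force pathway enumeration over all 61×61 sense-codon
pairs. Note that on degenerate inputs (a single codon) the synonymous
p-distance can exceed 1 — e.g. TTT vs TTC is 1 difference over ⅓ sites =
3.0 — which is the exact arithmetic of the method, not an error.

**Triplet indels.** Gaps in a codon alignment of this locus always occupy
whole codons. A codon column gapped in exactly one row of a pair counts as
one triplet indel; a maximal gap run of 3m nt therefore counts m indels.
This codon-wise convention is chosen because the indel proportion is
normalised per triplet (33 triplets in a 99-nt window), which presupposes
codon-wise counting; an event-wise mode (`count_events=True`) is provided
because the alternative reading cannot be excluded.

**Windows.** 99-nt windows stepping 24 nt (75-nt overlap) from alignment
position 0, the final partial window reported at its true length. All
haplotype pairs weighted equally. Bootstrap SEs resample codon columns
within the window (100 replicates by default); bootstrap draws come from
the caller-supplied RNG, so results are reproducible under a seed.

**π.** Total nucleotide diversity is the mean pairwise nucleotide
p-distance with site-level pairwise deletion, with an optional
Jukes–Cantor correction. The maximum-composite-likelihood estimator used
by some GUI packages is not reimplemented; for within-species distances of
this magnitude the difference is small and documented here rather than
hidden.

**AMOVA Φ_ST.** From squared pairwise distances: SS_total and SS_within
from mean squared distances, variance components via the standard
unbalanced-design coefficient n₀, Φ_ST = σ²_a/(σ²_a + σ²_w), permutation
p-values by shuffling individuals between the two populations of each
pair. Populations with fewer than two members are excluded with a warning.
No Python package in the stack computes distance-matrix AMOVA (PERMANOVA
is a different statistic), hence the in-package implementation, validated
by its boundary cases (Φ = 1 under perfect separation, ≈ 0 under
exchangeability) and by permutation-p uniformity under the null.

## Richness (`zsd.richness`)

The effective-wild correction counts each allele at most once within each
G1-flagged (laboratory-reared offspring) population, because sibship
structure in such samples re-counts parental alleles; truly wild samples
pass through unchanged. Spectra are exact integer bookkeeping. Chao1 uses
the bias-corrected form when f₂ = 0; iChao1 adds the f₃/f₄ improvement
term with f₄ replaced by 1 when absent. The variance uses the classic
delta-method covariance cov(f_i, f_j) = f_i(δ_ij − f_i/Ŝ) with numeric
partial derivatives over every observed abundance class, and the 95% CI
applies the log-transform to Ŝ − S_obs so the lower bound cannot fall
below the observed richness. Alleles are compared at amino-acid identity
by default; pooling samples before estimation is appropriate when
differentiation is negligible, as it is at this locus.

## Compatibility analysis (`zsd.compat`)

Distances between the two alleles of viable heterozygous males: (i)
absolute HVR length difference, (ii) Levenshtein distance of the unaligned
HVR amino-acid strings, (iii) Levenshtein distance of the aligned
exon-8–9 amino-acid sequences with HVR columns excised (gaps stripped
before comparison), and (iv) a composite replacing the mixed-model tree
distance used in some workflows: the equal-weight mean of (ii) normalised
by the maximum HVR length and (iii) normalised by the longer non-HVR
sequence. Conclusions from (iv) are approximate by construction. Edit
distances are computed with edlib; the test suite holds an independent
dynamic-programming oracle and a recursive brute force.

The resampling null draws allele pairs with replacement from the empirical
frequency distribution and rejects identical pairs, exactly reproducing
the "simulated heterozygous male" construction; the conditional pair
distribution is 2p_ip_j/(1 − Σp²), which the sampler matches to
Monte-Carlo error. Observed and simulated distance distributions are
compared with a two-sample Kolmogorov–Smirnov test — a deliberate
formalisation of what is otherwise a visual shape comparison;
non-rejection supports (but cannot prove) the hypothesis that all sampled
pairs are compatible.

## Mendelian tests (`zsd.mendel`)

Cross expectations enumerate egg × sperm classes at ½/½ segregation.
Classes with expected proportion zero (e.g. homozygotes in a non-sharing
cross) are treated as hard constraints: observations there are reported as
rule violations, never absorbed into the χ² — a violation falsifies the
genetic model rather than inflating a goodness-of-fit statistic. The
Hardy–Weinberg deficit test compares the observed homozygote/heterozygote
split in males against Σp², with frequencies estimated from females
(where the single Z makes every allele directly observable); with many
rare alleles the expected homozygote count collapses toward zero and the
result is flagged underpowered. The Fisher test is the standard two-sided
point-probability summation (for a marker in 8/8 daughters and 0/8 sons:
2/12870 ≈ 0.000155). The knockdown contingency χ² applies no continuity
correction by default: for 0/14 vs 11/20 the uncorrected test gives
p ≈ 0.0007 and the Yates-corrected variant p ≈ 0.0027, so only the
uncorrected convention reproduces the sub-millesimal significance this
comparison is reported at; both variants are exposed.

## Dosage compensation (`zsd.dosage`)

Genes are kept when strictly above `min_abund` (TPM-like) in at least
`min_samples` samples, the inclusion rule used for the embryo expression
data (default >1 TPM in ≥3 samples); a 36-cell sweep over
min_samples 1–12 × min_abund {0, 1, 2} shows the conclusions are
cutoff-robust. Within-class replicate means are taken per gene before
medians across genes (the per-gene aggregation is a documented choice —
per-sample-then-pooled medians are available through `class_means`).
Ratios with zero denominators are excluded and counted rather than
propagated as infinities. Rank-sum tests compare A and Z log₂-ratio
distributions (Mann–Whitney, two-sided) with Bonferroni correction over
the three zygosity-pair comparisons. Log base 2 throughout. Upstream
quantification (read mapping, TPM computation, shrinkage estimators) is
out of scope; the module consumes abundance tables.

## Numerical and interface conventions

All coordinates are 0-based half-open; annotation files carry nucleotide
alignment coordinates. Tables are tab-separated; FASTA wraps at 80
columns. Every stochastic function takes an explicit
`numpy.random.Generator`; no global RNG state is used anywhere, and
identical config + seed reproduces every output byte for byte. Pipeline
reports are JSON with a schema version and no timestamps. CLI exit codes:
0 success, 2 configuration error, 3 data validation error, 4 other stage
failure.

## Problem sizes

Test-suite and acceptance-script simulations use populations of 500–1600
adults, 5–40 generations, 150–200-observation samples, 200-replicate
calibration and coverage runs, and 500–10⁴ permutations/bootstrap
replicates — sizes chosen so the full suite completes in well under a
minute while keeping Monte-Carlo error far below every asserted margin.

## Known limitations

- Functional haplogroups are not modelled; all distinct amino-acid
  haplotypes are mutually compatible in the simulator, so the
  compatibility analysis can only be exercised under its null.
- Tryptophan never appears in generated HVRs (see above).
- The simulator's alignment helper relies on the shared-flank structure of
  generated haplotypes; arbitrary externally aligned data should come in
  through `validate_alignment` instead.
- Φ_ST uses squared distances from whatever metric the caller supplies;
  with non-Euclidean distances the variance decomposition is the usual
  AMOVA convention, not a guarantee of non-negativity.
- The iChao1 CI is asymptotic; with very sparse spectra (f₁ only) it can
  be wide and its coverage below nominal, which the coverage test's 85%
  floor acknowledges.
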