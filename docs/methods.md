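# Methods

This note documents the statistics lakescan implements, the synthetic data
model they are validated against, the numerical choices that matter, and
what the tests do and do not establish.

## The setting

A radiation of lake-dwelling fish in which the same ecomorph pairs (deep-
bodied benthic "Balchen" vs small zooplanktivorous "Albeli", with "Felchen"
intermediate) recur across lakes. The analyses ask three questions: (i) do
the recurrent ecomorph contrasts rest on parallel allele-frequency shifts at
shared loci, (ii) which genomic windows differentiate each sympatric species
pair, and (iii) where has admixture moved alleles between lakes. All
statistics operate on complete diploid dosage matrices (0/1/2 alternate-
allele counts) from biallelic-SNP VCFs; missing genotypes are rejected at
load because every estimator here assumes complete data.

Coordinates: VCF positions stay 1-based; every internal window and tract is
0-based half-open, with conversions confined to the I/O layer. A SNP at
1-based position p belongs to window (p−1)//size.

## Cluster separation score (CSS)

For one window with groups of sizes m and n, pairwise individual distances
are Euclidean distances between dosage vectors divided by the window's SNP
count. The distance matrix is embedded by classical multidimensional
scaling, retaining every positive-eigenvalue axis; for this metric the
embedding is distance-preserving, and it makes the statistic well defined if
a different dissimilarity is ever substituted. Then

CSS = mean between-group distance − (m · w1 + n · w2)/(m + n),

where w1, w2 are within-group means over the k(k−1)/2 unordered pairs. CSS
is 0 in expectation under exchangeability, invariant to SNP order and to
swapping the group labels.

**Null and outlier calling.** The null reshuffles group labels *within each
lake* (stratified permutation), preserving lake-level structure while
breaking the ecomorph contrast. One shared label set is evaluated against
all windows — a genome-wide null, and the reason permutations are cheap: the
per-window distance matrix never changes, only the group sums over it.
Sampled mode uses the add-one estimator p = (1 + #{perm ≥ obs})/(1 + N),
so p is never 0 and the identity permutation needs no special casing; exact
enumeration of all stratified assignments replaces sampling automatically
when their count is ≤ 200,000 (e.g. 20⁴ = 160,000 for four 3+3 lakes), with
p the exact tail fraction (a small tolerance keeps the observed assignment
in its own tail despite float rounding). Windows with fewer than 24 SNPs are
removed; outliers satisfy q ≤ 0.01 under Benjamini–Hochberg (Storey's
q-value with spline-smoothed π0 is available; π0 = 1 recovers BH).

**Downstream.** SNPs inside outlier windows are LD-pruned (r² > 0.1 within
50 kb) and decomposed by SVD on mean-centred dosages; each PC's sign is
fixed so its loading sum is non-negative. Traits are regressed on PC1 by
OLS with F-test p-values, overall and per lake system. Outgroup samples are
excluded from the PCA: their divergence would otherwise dominate PC1.

## Weir–Cockerham F_ST

Per SNP, the 1984 two-level variance components for two populations from
genotype counts, including the observed-heterozygosity term: a (between
populations), b (among individuals within populations), c (within
individuals), θ = a/(a+b+c), negative values retained. Windows report both
the ratio-of-sums Σa/Σ(a+b+c) ("weighted") and the mean of per-SNP θ;
outlier ranking uses the weighted form. Sites monomorphic in the pair are
removed first (minor allele count ≥ 1) and windows with fewer than 10
usable SNPs are dropped. Outliers are the ⌈0.01·W⌉ highest windows —
rank-based rather than a quantile threshold, so the chance-overlap formula
E[shared by k of L scans] = q^k · W · C(L, k) holds by construction. Both
"exactly k" and "at least k" sharing are reported; "at least" is the
headline count.

## F4, D, f4-admixture ratio, f-branch

F4(A,B;C,D) is the mean over SNPs of (p_A − p_B)(p_C − p_D). The topology
contrast computes F4 under the sympatric-pair arrangement
((Balchen1, Albeli1), (Balchen2, Albeli2)) and the ecomorph-pair arrangement
((Balchen1, Balchen2), (Albeli1, Albeli2)); the arrangement closer to zero
in absolute value is the more tree-like one, so |F4_1| < |F4_2| supports
independent within-lake origin. Signed values are always reported alongside
the verdict; exactly equal magnitudes give "indeterminate".

With an outgroup O, per-site ABBA = (1−p_A)p_B p_C(1−p_O) and
BABA = p_A(1−p_B)p_C(1−p_O); D = Σ(ABBA−BABA)/Σ(ABBA+BABA). The
f4-admixture ratio divides the same numerator by the donor-into-itself
denominator (C substituted for B), per site (1−p_O)(p_C² − p_A p_C). The
p_C² term is a squared *sample* frequency; with few sampled alleles its
upward bias inflates the denominator and attenuates f, so when the donor's
allele count n is known p_C² is replaced by the unbiased estimator
p̂² − p̂(1−p̂)/(n−1). At 3 diploids per species this matters a factor ~2.

f-branch: for every branch b (tips and internal nodes whose sister is not
the outgroup) with sister clade a, and every donor tip C outside both
clades, f_b(C) = median over recipients B below b of the minimum over
references A below a of f(A,B;C,O); negative values are floored at 0.
Cells where C sits inside b or a violate the required ((A,B),C) topology
and are marked untestable. Standard errors come from a delete-one-block
jackknife over contiguous equal-SNP-count blocks (default 20); the A
achieving the full-data minimum is held fixed across jackknife replicates.
Significance uses the one-sided normal quantile of α/(number of testable
cells) — one-sided because excess allele-sharing is a directional
alternative (for α = 0.01 over 1910 testable cells this gives Z > 4.41,
where two-sided would give 4.55).

## GWAS support

Thresholds: −log10(α/n) on the full SNP count and on the LD-pruned
effective count (greedy r² > 0.95 pruning in 50 kb windows, the later SNP
of an offending pair removed; the scan advances one variant at a time, the
strictest reading of a step parameter, so results do not depend on step).
The association scan is ordinary least squares of trait on dosage with an
optional principal-component covariate block handled by Frisch–Waugh
residualisation — a deliberately simple stand-in that makes the synthetic
large-effect-locus recovery testable end to end; mixed-model association
with kinship correction is out of scope. PVE uses the standard single-SNP
formula quoted in the README, monotone increasing in |β| and decreasing in
its standard error.

## The synthetic radiation generator

The generator is frequency-level: ancestral frequencies p0 ~ Beta(0.8, 0.8)
truncated (by rejection) to [0.05, 0.95]; lake frequencies follow the
Balding–Nichols distribution Beta(p0(1−F)/F, (1−p0)(1−F)/F) with a single
drift parameter F = fst_lake (default 0.10) for all lakes; optional
within-lake species drift; an outgroup population at F = 0.35; genotypes
are Binomial(2, p). A `single`-origin mode draws the deep split between
ecomorphs instead of lakes, so the F4 contrast has both generating scenarios
to recover. Defaults mirror the study panel the scans were designed around:
4 lakes × (Balchen, Albeli) × 3 diploids = 24 fish plus 4 outgroup fish.

Selected loci: 1% of SNPs carry parallel ecomorph shifts of ±shift/2
(default shift 0.8; one global sign per locus, opposite in the two contrast
ecomorphs, identical across lakes, clipped to [0,1]); another 1% are
shifted in one random lake only. Both classes are laid down as contiguous
25-SNP runs — linked blocks, as divergence hitchhiking produces — because a
single shifted SNP among ~100 neutral ones in a window is undetectable by
any windowed statistic; scattered singletons would make windowed recall
meaningless rather than hard.

Traits: gill-raker count = mid-value + 0.25 × (ecomorph baseline − mid)
+ effect × (dosage − 1) at one large-effect locus + N(0, 1), rounded,
floored at 12; ecomorph baselines are ordered Balchen < Felchen < Albeli
and most of the ecomorph difference is deliberately mediated by the locus
itself (its alt allele is pushed to high frequency in high-raker ecomorphs),
mirroring a single-major-locus architecture — without that, in a plain OLS
scan every parallel-shifted SNP is equally associated with the trait via
ecomorph membership and no single top hit exists. Standard length =
ecomorph baseline + a 100-locus polygenic score (effects N(0, 3) on centred
dosage) + N(0, 15) mm. Introgression copies donor-lake alleles (redrawn
Binomial at donor-lake frequencies) across non-overlapping tracts covering
a configured genome fraction in every recipient sample; tracts, locus
classes, shift signs and trait values are all recorded in truth tables.

A single numpy Generator seeded once drives every draw in a fixed order, so
a seed fully determines the output down to the VCF bytes.

**What the generator does not emulate:** coalescent genealogies and linked
neutral variation, recombination within tracts, mutation-rate or SNP-density
heterogeneity, genotyping error and missingness, sex chromosomes, and more
than one drift depth per mode. Passing recovery tests therefore shows the
estimators are correctly implemented and calibrated under drift +
sampling-noise conditions, not that they are robust to everything real data
does.

## Problem sizes and numerical choices

Test and demo runs use 20,000–50,000 SNPs, 200–500 windows of ~100 SNPs and
1,000–10,000 permutations (exact enumeration where the design allows),
sizes at which every stage's expected behaviour is measurable with
comfortable margins. The f4-ratio estimator's per-seed spread at 50,000
SNPs and 3 diploids/species is ~0.04, so recovery is asserted on a 3-seed
mean. Degenerate cases are explicit: zero jackknife variance yields an
infinite Z with a warning; a SNP with a+b+c = 0 is skipped in windowed
F_ST; a zero f4-ratio denominator reports NaN; LD r² with a monomorphic SNP
is treated as 0 (unlinked). FDR input p-values must lie in (0, 1] — which
the add-one rule guarantees.

## Known limitations

The OLS association scan does not correct for relatedness or structure
beyond optional PCs. The f-branch jackknife fixes the minimising A at the
full-data choice, slightly understating variance when two references are
nearly tied. The exact CSS weighting follows the corrected formulation of
the cluster-separation literature as specified here and is pinned by unit
tests; windowed medians reported on real data by other implementations may
differ if they weight within-group terms differently. Median CSS values
published for any particular empirical dataset are not reproducible without
that dataset and are out of scope.
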