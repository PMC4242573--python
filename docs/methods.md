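# Methods

`cubne` implements an end-to-end analysis of whether effective population
size (Ne) predicts codon usage bias (CUB) in mammalian-style genomes:
bias metrics corrected for mutational background, three independent tests
for selection on synonymous codon usage, phylogenetically controlled
comparative statistics, and a synthetic-data generator that produces every
input the analyses consume. This note records the models, the defaults and
why, the numerical choices, and what the synthetic data do and do not
establish.

## Codon families and notation

The standard genetic code is partitioned into synonymous families (the
codon set of one amino acid). Met and Trp are singletons and never enter
bias computation; Ile is the single threefold family; the sixfold amino
acids (Leu, Ser, Arg) are kept whole for the classic ENC degeneracy
classes (9 twofold, 1 threefold, 5 fourfold, 3 sixfold) but split into a
fourfold and a twofold subfamily wherever a single preferred/unpreferred
codon per family is needed (preference analyses, per-family reports). The
split is configurable through the `split_sixfold` argument.

## ENC and ENCp (`cubne.cub`)

For family *a* with *k_a* codons, *n_a* observations, and within-family
frequencies *p_i*, the homozygosity estimator is
F̂_a = (n_a Σ p_i² − 1)/(n_a − 1), and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

class means taken over families with n_a ≥ 2. ENCp replaces the uniform
null with expected within-family frequencies e_i proportional to the
product of the background base frequencies over a codon's three positions:
χ²_a = n_a Σ (p_i − e_i)²/e_i and F̂′_a = (χ²_a + n_a − k_a)/(k_a(n_a − 1)).
With a uniform background F̂′ reduces exactly to F̂, so ENCp == ENC (a
tested identity). Values are capped to [20, 61]; the raw value is kept
alongside.

Numerical and convention choices:

* a missing threefold class mean is imputed as (F̄₂ + F̄₄)/2, the standard
  ENC convention; if any other class is empty the gene's value is
  undefined (NaN, flagged) rather than guessed;
* a class mean of exactly zero (every family at maximal within-family
  diversity, possible at tiny counts) drives the raw value to +inf and is
  reported as the 61 cap;
* the per-gene significance χ² sums family χ²_a over families in which
  every expected count e_i·n_a ≥ 1 (Pearson validity guard), df = Σ(k_a−1);
* expected frequencies use the pooled background composition at all three
  codon positions — flank/intron sources carry no reading frame, so
  position-specific backgrounds would be fitting noise;
* the per-family bias report is 1/F̂′_a capped to [1, k_a] (the family's
  own effective codon number — 1 when one codon is used, k_a when all are
  used per expectation);
* background composition comes from up to 2 kb of flanking sequence on
  each side (4 kb total) or from concatenated introns with a minimum of
  1000 bp (genes below the minimum are dropped from the intron-background
  analysis, not silently kept).

The ENC estimator's finite-sample bias term is O(1/n_a): per-family counts
near 25 (a 500-codon gene) move the value by a few tenths when counts are
rescaled, which is why the scale-invariance test uses large per-family
counts, and why the generator's neutral GC-biased scenario yields mean
ENCp ≈ 60.4 rather than exactly 61 at 500-codon genes.

## Polarized McDonald–Kreitman test (`cubne.mk`)

Per (split) family, the genome-wide most used codon is "preferred" and
the least used "unpreferred" (ties broken lexicographically, logged).
Third-position sites are polarized against two outgroup genomes: the
ancestral state is the shared outgroup base; disagreeing outgroups and
triallelic samples are excluded. Only exchanges between a family's
preferred and unpreferred codon enter the 2×2 table (direction classes
unpreferred→preferred vs preferred→unpreferred; everything else is
"other"). The table contrasts polymorphic vs fixed counts with Pearson's
χ² (Yates continuity correction by default, df = 1); χ²/N is reported per
1,000 sites so tables of very different size compare.

The intron null forces each intronic segregating site (≥ 20 bp from any
exon–intron boundary, ≥ 2 bp of codon context) into the third position of
an "imaginary codon" built from the two preceding bases in coding
orientation; minus-strand genes are reverse-complemented first. The same
preference map and classification machinery then apply, so purely
mutational asymmetries register in the intron table.

CpG filter: a site is flagged when the outgroup-consensus quintet and the
ingroup-derived quintet match either hypermutable pattern — ··TG· →
··CG·, or ·CA·· → ·CG·· (two independent CpG deaminations on the outgroup
lineages mimic a derived CpG-creating change in the ingroup). Tables are
reported before and after dropping flagged sites.

Two properties worth stating plainly:

* the Yates correction makes the 2×2 test conservative at small counts;
  the calibration tests therefore check the uncorrected statistic against
  the nominal 5% level and the corrected one against "not anticonservative";
* the CpG filter removes the CpG channel of mis-polarization only. Under a
  biased mutation spectrum, ordinary double substitutions on the two
  outgroup lineages also mis-polarize sites asymmetrically (the rate from
  base a with apparent ancestor b scales as π*_a π*_b², which is not
  symmetric in a,b). This residual is real, is visible in the synthetic
  data, and is consistent with the intron contrast remaining significant
  after CpG filtering in human data; the filter-rescue tests use a uniform
  spectrum to isolate the CpG channel.

## FMutSel0 / FMutSel (`cubne.models`)

Codon substitution follows a mutation–selection model: for codons i → j
differing at one position by base change a → b,

    q_ij = κ^[transition] · π*_b · h(S_ij),   S_ij = F_j − F_i,
    h(S) = S/(1 − e^(−S)),  h(0) = 1,

with stationary distribution π_j ∝ π*_{j1} π*_{j2} π*_{j3} e^{F_j}
(detailed balance holds exactly; tested at 1e−10). Multi-nucleotide
changes have rate zero; stop codons are excluded from the state space
entirely. The generator is normalized to one expected substitution per
unit branch length, making t interpretable and identifiable.

FMutSel0 constrains F within amino acids (19 free fitness parameters, one
amino acid fixed at 0); FMutSel frees all codons (60, one codon fixed at
0). Both add κ, three free mutational base frequencies, and t: the LRT of
FMutSel against FMutSel0 has df = 41, with the 5% critical value 56.94.

The pairwise likelihood is Σ_sites log(π_i P_ij(t)) over observed codon
pairs, computed through the symmetric eigendecomposition of the
reversible generator (exact, no Padé approximation) and aggregated over a
61×61 pair-count matrix, so cost is independent of gene length.
Optimization is L-BFGS-B on log/logit-transformed parameters, tolerance
1e−8 on the log-likelihood, 5 restarts by default jittered around a
moment-style start (empirical base composition, empirical codon-frequency
residuals for F, divergence-based t). Swapping the two sequences leaves
the likelihood unchanged (reversibility, tested).

|Ne·s| per gene summarizes |S_ij|/2 over synonymous single-nucleotide
codon pairs under the S = 2Ne·s convention (the divisor is an explicit
argument, since the literature also writes S = Ne·s), reported as both an
unweighted median over pairs and a median weighted by the gene's usage of
the two codons.

Finite-sample behaviour: with 60 free fitness parameters the LRT is
mildly anticonservative at short alignments (mean statistic ≈ 47 at 300
codons vs the asymptotic 41) and well calibrated by 2,000 codons (mean
≈ 40); the type-I calibration test therefore runs at 2,000-codon
alignments, which costs nothing extra because the likelihood works on
pair counts. Parameter recovery at 10,000 codons: κ within a few percent;
the maximum synonymous fitness spread under truly uniform usage is pure
ML noise and shrinks from ≈ 0.3 (10k codons) to ≈ 0.15 (30k).

## Phylogenetic comparative statistics (`cubne.phylo`)

The Pagel-λ covariance has diagonal root-to-tip distances and
off-diagonal λ × shared path length; λ ∈ [0, 1] keeps the matrix positive
definite (it is a convex combination of the Brownian covariance and its
diagonal), and the bound is configurable with a Cholesky guard. PGLS
estimates λ by profile maximum likelihood (bounded scalar search with the
endpoints always evaluated), then reports the GLS slope with t = β/SE,
df = n − 2, and r = sign(β)·√(t²/(t²+df)). At λ = 0 the estimates equal
OLS to 1e−6 (tested).

`order_robustness` re-runs PGLS under permuted tip-input orders (all n!
orders for n ≤ 7 unless capped) and reports median statistics and the t
spread. A well-conditioned fit is order-invariant to ~1e−8; the report
exists because near-singular covariances (e.g. effectively duplicated
tips) can make the fit order-sensitive, and the spread makes that visible
rather than hiding it.

Independent contrasts follow the standard recursion (differences scaled
by √(summed adjusted branch lengths); node values are precision-weighted
means; daughter variance v₁v₂/(v₁+v₂) is added to the parent edge).
Polytomies are resolved into zero-length bifurcations, logged; a cherry
with zero summed branch length is an error naming the node. The sign test
orients every node so the x-contrast is positive, drops zero x-contrasts,
and tests the count of positive y-contrasts with a two-sided exact
binomial against 1/2 (chosen over a 2×2 Fisher construction, which is
ambiguous for a one-sample sign count; both views appear in the
literature).

Ancestral states are the Brownian GLS/ML reconstruction: the root is the
GLS mean and each internal node conditions on the tips through node–tip
shared-path covariances.

Compartment comparisons (X vs autosome, centromeric vs telomeric) use an
OLS ANCOVA `value ~ group + exon_length + intron_length` with the group
coefficient's t test; covariates enter untransformed by default (the
caller can log-transform). Bootstrap medians use the percentile interval
of 10,000 seeded resamples by default.

## Synthetic data (`cubne.simulate`)

The generator's defaults describe the emulated study system and were
chosen once, on biological grounds:

| parameter | default | rationale |
|---|---|---|
| codons per gene | 500 | typical mammalian CDS; the pipeline's own minimum is 100 |
| mutational base frequencies π* | (0.30, 0.20, 0.20, 0.30) | ≈40% GC, mammalian noncoding composition |
| κ | 2.0 | mammalian transition/transversion ratio |
| selection S | 0.0 | neutral base case; scenarios set S per analysis |
| sample size | 176 chromosomes | an African-population resequencing panel (~88 diploids) |
| ingroup substitution rate | 0.01/site | ingroup-lineage divergence to the outgroup split |
| polymorphism rate | 0.005/site | fraction of third positions segregating in such a panel |
| outgroup rate | 0.012/lineage | two outgroup lineages slightly deeper than the ingroup |
| CpG multiplier | 1.0 | no hypermutation unless a scenario switches it on |
| flanks / introns | 2 kb / 1500 bp × 2 | matches the background-composition windows |

Coding sequence is drawn i.i.d. per codon from the mutation–selection
stationary law π_j ∝ π*₁π*₂π*₃e^{F_j} — by construction the same law as
the substitution model's stationary distribution (identity tested at
1e−12), with one favored codon per family (lexicographically first, so
favoring is independent of mutation bias) carrying fitness S. Introns and
flanks are i.i.d. from π* alone.

Polymorphism/divergence at each third position (and each intron position)
follows a three-branch history: on the ingroup lineage a fixation to a
neighboring base arises with probability ∝ μ·h(S) and a polymorphism with
probability ∝ μ (the neutral per-mutation origination rate), with derived
sample counts from the 1/k neutral frequency spectrum; outgroup lineages
substitute neutrally except that CpG-context deaminations (C→T with a
following G; G→A with a preceding C) are accelerated by the configured
multiplier — two independent outgroup deaminations produce exactly the
quintet-pattern mis-polarization the CpG filter targets. Only sites at
which something happened are emitted (invariant sites cannot enter an MK
table). This two-allele scheme reproduces the fixed:polymorphic contrasts
the MK framework measures; it does not model linkage, demography, or
segregating-site interference, so the tests say nothing about those.

Pairwise alignments draw an ancestor from π and evolve the descendant
through exp(Qt). Trait trees are seeded pure-birth trees (tip branches
extended by the waiting time past the last speciation, keeping the tree
ultrametric and its covariance well-conditioned) or any supplied newick,
including polytomies such as an unresolved three-species trichotomy;
traits are Brownian with Pagel-λ structure and a linear x→y link.

What passing tests show — and what they do not: the synthetic data share
the analyses' distributional assumptions (independent codons,
equilibrium base composition, neutral intron background, Brownian
traits). Passing calibration/recovery tests demonstrates the estimators
and tests are correct under those assumptions; real genomes violate them
in known ways (isochores, gBGC, linked selection, alignment error), and
nothing here measures robustness to that.

## Problem sizes used by the test suite

Simulation sizes in the suite are the package's choices for routine runs:
MK calibration uses 200 replicates of 25 genes × 200 codons; LRT
calibration 50 replicates of 2,000-codon pairs; PGLS recovery 500
replicates of 41-tip trees; recovery fits use 10,000–30,000 codons.
Statistical assertions use exact binomial bands (tail 1e−3) around the
nominal rate rather than point equalities.
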