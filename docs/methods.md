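# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cohet`, and what the synthetic panels do and do not show about real
data.

## Synthetic panels

**Divergence model.** Two subspecies allele-frequency vectors are drawn
from the Balding–Nichols model: an ancestral frequency `p` (a uniform MAF
in `ancestral_maf_range`, default (0.05, 0.5], or its mirror `1 − p` with
probability 1/2) and, per subspecies,
`p_s ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, giving mean `p` and variance
`p(1−p)·F`. `F` is the F_ST-like divergence parameter (default 0.2, a
plausible magnitude for indicine-taurine divergence on a SNP chip
ascertained in both groups); an independent Weir–Cockerham estimator
applied to two simulated pure populations recovers it to within ±0.03.
Frequencies are clamped to [10⁻⁶, 1−10⁻⁶].

**Genotypes.** Each animal of a breed with indicine ancestry α draws, per
allele copy and per SNP, indicine descent with probability α and then the
allele from that pool's frequency — i.e. unlinked SNP and no LD, which is
all the downstream analyses assume. Genotypes are recoded to counts of the
panel-wide minor allele (ties toward the first-listed allele). Optional
MCAR missingness (`missing_rate`, default 0).

**Within-breed ancestry heterogeneity (`ancestry_sd`).** With per-allele
i.i.d. sampling, an admixed breed is itself a random-mating population and
sits exactly in Hardy–Weinberg equilibrium — no Wahlund effect, and the
per-breed HWE gene lists the pipeline feeds on would be pure noise. Real
composite breeds are heterogeneous: herd-mates differ in their indicine
fraction. `ancestry_sd` (default 0, i.e. the idealised i.i.d. model)
draws each BTI animal's α from a Beta with the breed mean and that
standard deviation; the two allele copies then share the animal's α, which
produces the classic heterozygote deficit (`χ² ≈ n·f²` with
`f = Var(α)/(ᾱ(1−ᾱ))`). The pipeline's default study configuration and
the Wahlund tests use `ancestry_sd = 0.15`, a spread consistent with
stabilised composites under ongoing crossing; at a fixed-difference SNP
with α = 0.5 and n = 500 this rejects HWE at the 1% level roughly 30% of
the time — far above nominal, as intended.

**Gene layout.** Genes are spread as evenly as possible over the
chromosomes; each gene span covers a contiguous block of `snp_per_gene`
SNP (default and minimum 6, matching the pipeline's SNP-count gate) spaced
200 bp; surplus SNP become intergenic decoys placed > 1 kb from every gene
span so the window rule never captures them. Positions are 1-based and
strictly increasing per chromosome; BED export is 0-based half-open.

**Skewed gene sets.** For each requested set, genes are drawn without
replacement and their SNP frequencies overwritten: high (≈ 0.35–0.9,
capped so the informative allele stays globally minor given the panel's
mean ancestry) in the designated component's pure lineage, low (0.02–0.08)
in the other. Such SNP land deep in the matching mode of the PC1-loading
mixture, so the set scores an extreme percentile in the permutation test —
the positive control for that machinery.

**What the generator does not emulate:** linkage disequilibrium,
selection/sweeps, recombination maps, sex chromosomes, genotyping error,
and SNP-chip ascertainment bias. Tests passing on these panels show the
pipeline's statistics behave as designed under its own assumptions; they
do not certify effect sizes on real cattle data, whose headline numbers
(e.g. PC1 variance share, the 31/69 SNP split) depend on the real breed
composition and chip design.

## Pre-processing

Sex-chromosome SNP are dropped; a SNP is assigned to every gene whose span
± 1 kb contains it (both boundaries inclusive; a SNP in two overlapping
padded spans counts for both genes — no arbitrary tie-break); genes with
fewer SNP than the median per-gene count are removed. The median over
genes with ≥ 1 SNP uses the lower of the two central values for even
counts, so the threshold is an attainable integer; it is resolved once
(the realised value on the study data is six) and re-application at that
integer is a no-op. The SNP retained for all later stages are exactly
those assigned to a retained gene.

## Ancestry

**Standardization.** `(g − 2p̂)/√(2p̂(1−p̂))` with `p̂` estimated over
non-missing genotypes; missing entries contribute 0 after centering;
monomorphic SNP are dropped with a logged count.

**PCA.** Exact eigendecomposition of the animal-side covariance
(animals ≪ SNP), loadings recovered by back-projection and unit-
normalized; variance shares are eigenvalues over the total Frobenius
norm. PC1's sign is oriented so pure indicine animals score negative
(indicine on the left of the axis); only PC1 is oriented, as only it
enters downstream analysis.

**Mixture.** Two-component univariate Normal mixture over PC1 loadings,
fitted by EM with deterministic initialisation (median split, component
moments from each half, weights ½/½), convergence at relative
log-likelihood change < 10⁻⁸ or 1,000 iterations, variance floor 10⁻¹²
against collapse. The lower-mean component is labelled indicine. EM is
deterministic and permutation-invariant; a sign flip of the loadings
relabels the components symmetrically. With strongly engineered SNP sets
the fit may devote one component to the engineered spike rather than a
broad left/right split — posteriors for the informative SNP remain
extreme either way, which is what gene membership uses.

**Gene and chromosome summaries.** A gene's Pr(indicine) is the unweighted
mean of its SNP m₁ (the minimal-assumption reduction of "collapsing" SNP
to genes); chromosome content is the unweighted mean over its genes.
Membership lists use a 0.95 cutoff by default. Profile statistics are
−log₁₀ of the *opposing* component's posterior (a gene of high indicine
content has a vanishing taurine posterior), clamped at 10⁻³⁰⁰, flagged
above 4.

## Heterozygosity and HWE

HET of a SNP in a breed is 100 × (heterozygous animals)/(non-missing
animals); gene HET averages the gene's SNP, lineage HET averages breeds
within lineage with equal weight, chromosome HET averages genes. The HWE
screen is the allelic-frequency Pearson χ² (1 df, no continuity
correction, no multiple-testing correction — nominal 1% by design);
monomorphic cells return p = 1, empty cells NaN. A gene is flagged for a
breed if any of its SNP deviates (a fraction-based rule is available);
"any SNP" matches the permissive candidate-pool role of these lists.
Breed clustering is agglomerative with Euclidean distance and average
(UPGMA) linkage on gene-HET profiles — a standard, deterministic stand-in
for seriation tools whose objective is unspecified; the dendrogram exports
to Newick with ultrametric branch lengths.

## Gene sets

The permutation test draws `|set|` genes without replacement per trial
(10,000 trials by default) and counts members with Pr(taurine) ≥ 0.5; the
percentile counts strictly smaller null counts only, so heavy ties push
the percentile down (documented convention; the degenerate all-hit
background gives percentile 0). Sampling uses the m-smallest-of-n uniform
keys construction, vectorised and deterministic under seed. The
percentile converges to the exhaustive hypergeometric percentile, checked
by full enumeration at small sizes. Over-representation of a term in a
target list is the exact one-sided hypergeometric upper tail — a
transparent substitute for ranked-list GO tools, taking a user-supplied
term→gene map. Attribute annotation (TF/TS/SE/KI/FE …) is boolean flags
from user lists, queryable with pandas boolean expressions.

## Network

Gene co-heterozygosity is the Pearson correlation of gene HET profiles
across *breeds* — the only axis on which gene HET varies in this design;
with few breeds the profiles are short, so high-|r| edges are plentiful
and the synthetic networks are denser than a 19-breed panel would give.
Correlations are clipped to ±(1 − 10⁻¹²) for partial-correlation
stability. PCIT evaluates every unordered trio once, in canonical index
order: the three first-order partials, a tolerance ε = mean of the signed
partial/raw ratios (ratios with a zero raw correlation are skipped; a
trio with no usable ratio discards nothing), and a non-strict double
comparison `|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|` discards an edge. An
edge is significant iff no trio discards it. The loop is numba-compiled
when available (pure-Python fallback is identical); because evaluation
order is canonical, the optimised kernel is floating-point-identical to
the naive oracle used in tests. Edges additionally require |r| ≥ 0.95
(absolute value: the correlation distribution is two-sided), and isolated
nodes are dropped from the reported sub-network.

Degree diagnostics regress log₁₀ frequency on log₁₀ degree over observed
degrees ≥ 1 (zero-frequency degrees undefined on the log scale; fewer
than two distinct degrees refuses the fit) and report max-degree hubs.
The trio-span search scores a fertility-gene trio by the fraction of
network nodes in its closed neighbourhood ("majority of the topology"
read as node coverage); it is exhaustive up to 10⁵ candidate trios and
otherwise a multi-start greedy search (grow from every candidate seed by
best marginal coverage, ties to the lexicographically smallest gene), a
scheme that matched the exhaustive optimum on all random-graph test
instances.

## Pipeline and reproducibility

Stages communicate through files in a run directory (PLINK text + TSV +
JSON), so any stage can be re-run alone and `--resume` skips completed
stages. The manifest lists version, seed, parameters and SHA-256 of every
output (logs excluded). All randomness flows from the configured seed
through `numpy.random.SeedSequence` spawns; reruns are byte-identical.
Problem sizes in the test suite and acceptance script (hundreds of
animals, 10²–10³ genes, ≤ 10⁴ SNP) are chosen as the smallest panels on
which the tested signals are decisively resolved.
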