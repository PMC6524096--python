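# Methods

## Scope and data model

`cecosucc` analyses cross-sectional gut-microbiota studies shaped as an
OTU × sample count table with per-sample metadata (host age in days, diet
group, dam/litter id), per-OTU taxonomy (kingdom…genus), and optionally a
rooted phylogeny whose tips are the OTU ids. All stages operate on a table
rarefied to a common depth so that diversity, prevalence and correlation
comparisons are not driven by library size.

## Rarefaction and alpha diversity

Rarefaction subsamples each sample without replacement to exactly the
target depth using multivariate hypergeometric draws — an exact uniform
subsample of reads, not a multinomial approximation. Samples below the
depth are dropped with a warning. The default depth is the minimum library
size; a single draw is taken (no averaging over draws) with the seed
recorded, because downstream presence/absence and correlation stages need
one concrete table.

Indices per sample, with `p_i = count_i / total`: observed OTUs
`#{i: count_i > 0}`, Shannon `−Σ p_i ln p_i` (natural log; zero-count
terms omitted), inverse Simpson `1 / Σ p_i²`. The Hill-number ordering
`1/Simpson ≤ exp(H) ≤ richness` is enforced as a property test.

## Beta diversity and ordination

Bray–Curtis is computed on the rarefied counts,
`d(x, y) = Σ_k |x_k − y_k| / Σ_k (x_k + y_k)`. Unweighted UniFrac uses
presence/absence over the rooted tree: a branch counts toward the
denominator when any tip below it is present in either sample and toward
the numerator when those tips appear in exactly one — i.e. the fraction of
observed branch length unique to one community, including the path up to
the root of the observed subtree. A multifurcating root is binarized by
inserting zero-length internal branches, which provably leaves every
UniFrac value unchanged. Both dissimilarities are symmetric, zero-diagonal
and bounded by 1; UniFrac is invariant to abundance rescaling.

Non-metric MDS minimises Kruskal stress-1 with monotone regression
(SMACOF). One start is initialised from classical metric scaling
(principal coordinates) and the remaining `n_restarts − 1` (default 19)
from random configurations; the lowest-stress solution wins, and the run
is deterministic given the seed. The configuration requires `n ≥ k + 1`
samples for `k` dimensions — the minimum for a non-degenerate embedding
(three equidistant points embed exactly in the plane).

## Permutation tests

PERMANOVA partitions the squared-distance sums into among- and
within-group components and forms a pseudo-F; significance comes from free
permutation of group labels with the unbiased estimator
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)`. Labels are permuted
freely — dam/litter nesting is not restricted, matching the default
behaviour of the distance-based ANOVA this mirrors. Pairwise mode runs all
group pairs and reports Benjamini–Hochberg-adjusted p-values. PERMDISP
embeds the distance matrix in principal-coordinate space, measures each
sample's distance to its group's spatial median, and permutes an ANOVA F
on those distances. Both tests are verified by null calibration: on
exchangeable labels (500 replicates, n = 30, 3 groups, 99 permutations)
the empirical type-I error at α = 0.05 must sit inside the binomial 95%
confidence interval. 99 permutations are used in the calibration loops
because the rejection mass at α = 0.05 is then exactly 5/100 under
exchangeability, and the loop stays fast; single analyses default to 999.

## Community maturity

Maturity of sample *s* is its mean dissimilarity to all reference-age
(default 49 d) samples of the same diet group; higher = further from the
mature community. At the reference age itself the sample is excluded from
its own reference set (leave-self-out), so the reference group keeps a
nonzero within-group baseline instead of a hard zero. Bray–Curtis is the
default metric — maturity then inherits its [0, 1] bound — with UniFrac
available by flag, since the underlying study does not state which metric
its maturity panel used.

## Core-OTU partition

An OTU is present at an age when detected (count > 0 on the rarefied
table) in at least `ceil(threshold · n_samples)` of that age's samples,
diet groups pooled; the default threshold 0.75 reads "at least 75% of the
samples" literally, hence the ceiling. The Venn partition assigns every
OTU in the union of per-age sets to its exact age-membership pattern.
Named regions: *persistent* (every age), *milk_only* (first age only),
*acquired* (absent at the first age, present at every later age),
*milk_late_shared* (first age plus the last two ages, and nothing else;
defined only when there are ≥ 4 ages, because with 3 ages the pattern
coincides with *persistent*). Percentages are relative to the union.
The partition equals a brute-force enumeration over all 2^#ages patterns
(property-tested), and raising the threshold can only shrink per-age sets.

## Co-occurrence networks

Within one age stratum, OTUs whose mean relative abundance is strictly
above 1% are correlated pairwise with Spearman's ρ (average ranks for
ties) on per-sample relative abundances. An edge requires `|ρ| > 0.7`
*and* a two-sided p-value below 2.32·10⁻⁵ from the t approximation with
df = n − 2. Design notes:

* The absolute value is used although the source analysis writes "ρ >
  0.7", because its network figures display negative (anticorrelated)
  edges; the sign is kept as an edge attribute.
* The p threshold is treated as a constant of the method, not a value
  derivable from ρ = 0.7 at a particular n (at n = 30 the t approximation
  gives p ≈ 1.7·10⁻⁵ at ρ = 0.7, inside the cap).
* No multiple-testing correction is applied to edges by default
  (matching the method being reproduced); Benjamini–Hochberg is available
  by flag.
* OTUs with constant abundance vectors have undefined ρ; their pairs are
  skipped with a warning.

Nodes are all abundance-filtered OTUs; metrics drop isolates by default.
Mean degree is exactly `2E/N`. Betweenness is normalized by
`(N−1)(N−2)/2`. The diameter is the longest shortest path on the largest
connected component with edge length `1 − |ρ|` (strongly correlated pairs
are "close"); the unweighted hop diameter is reported alongside. The
published normalized-degree and betweenness columns of the reference
tables cannot be reconstructed from their printed node/edge counts under
any standard normalization, so only the mean-degree identity is anchored.

The persistence (intersection) graph of two consecutive ages keeps the
shared nodes and the edges present in both parents *with equal sign* — a
sign flip is not a persistent relationship. Conservation rates are
`100·|∩|/|parent|` for nodes and edges. Keystone candidates are ranked by
degree, ties broken by betweenness then OTU id.

## Taxa utilities

Agglomeration sums counts over OTUs sharing a rank label; empty labels
pool into an explicit `unassigned` bucket so column totals are conserved
exactly. Ratios are computed per sample (zero-denominator samples are
flagged and excluded from summaries, not errors) and are scale-invariant.
The pathway filter takes a pathway × genome completeness matrix
(scores in [0, 1]), counts a pathway present in a genome when its
completeness reaches a cutoff (default 1.0 — the whole pathway), and keeps
pathways present in at least `min_presence` (default 1/3) of genomes,
boundary inclusive. No external pathway database is queried; the matrix is
user-supplied. `percent_contrast` reports one group's percent excess over
the mean of the others, used for intake contrasts.

## Synthetic study generator

The generator is the package's test bed: it produces studies with the
reference design — ages (18, 28, 35, 43, 49) d (the final pre-weaning age
is configurable; 43 d is the default), diet groups (RL, LL, HH), 10
samples per cell, library sizes from a normal(48670, 11497) truncated at
1000 reads (the floor keeps rarefaction meaningful) — and known ground
truth.

**Composition model.** Each OTU belongs to a phylum (Bacteroidetes,
Firmicutes, Proteobacteria, Other). Per-age phylum masses interpolate
linearly between an 18 d profile (56/37/5/2%) and a 49 d profile
(91% Firmicutes, 6% Bacteroidetes); only the endpoints are constrained by
the study being emulated, and linear-in-age is the least-informative
interpolation. Within each phylum, a sample's composition is a Dirichlet
draw around fixed within-phylum weights (concentration 1200), multiplied
by per-OTU jitter, renormalized within the phylum, and scaled to the
phylum's mass; counts are then multinomial at the sample's library size.
Because phylum masses are exact per sample, the expected phylum
trajectory is exact by construction (tested Monte-Carlo: the age-18
Bacteroidetes fraction matches 56% within 3 standard errors).

**Planted core classes.** Four OTU sets get fixed within-phylum weights
that are exactly zero outside their active ages: persistent (12 Firmicutes
OTUs, all ages), milk-only (8 Bacteroidetes, first age only), acquired
(10 Firmicutes, every age but the first), milk∧late-shared (6
Bacteroidetes, first and last two ages). Zero base weight means zero
counts, so absences are exact; active weights are large enough that the
75% prevalence rule detects them reliably at the default depths.

**Planted correlation blocks.** Each block shares a latent standard-normal
factor per sample inside its age window; member *i*'s multiplier is
`exp(σ_b (s_i √|ρ| z_block + √(1−|ρ|) e_i))` with σ_b = 1.0 and member
signs alternating for negative ρ. Non-block OTUs instead receive
independent log-normal overdispersion (σ = 0.6). The defaults — an early
Bacteroidetes block (3 OTUs, window 18–28 d), a mid Firmicutes block
(3, 35–49 d), two late blocks (4 each, 43–49 d) and one negative pair
(43–49 d), ρ = 0.99/−0.97 — make the network densify with age the way
the emulated study reports. The parameter combination was set by a
design-stage simulation of the induced correlation structure: the latent
scale must dominate the within-member Dirichlet noise (so planted pairs
exceed the 0.7 edge threshold at n = 30), while the idiosyncratic
overdispersion of non-block OTUs must dominate the shared renormalization
shock (otherwise compositional closure creates spurious edges among
abundant bystanders, and the weaker 43→49 compositional step stops being
resolvable in the maturity curve). The recovery suite (20 seeds) requires
≥ 90% planted-edge recall at 49 d with ≤ 5% spurious edges, exact
recovery of the planted core classes, and a strictly decreasing
seed-averaged maturity curve.

**The standalone block primitive** (`simulate_correlated_counts`) emits
Poisson counts around the latent intensities *without* closing them to a
fixed depth: with only a handful of OTUs, converting to relative
abundances would cancel the shared factor (a fully shared factor leaves
the subcomposition constant) and closure would induce spurious negative
correlation. Correlation properties are therefore stated and tested on
the counts; in the full generator the blocks sit inside a 300-OTU
community where closure effects are second-order.

**What the generator does not emulate.** The real study's richness climb
with age (≈230 → ≈520 observed OTUs) — the roster of background OTUs is
fixed across ages, so alpha-diversity age trends are flat; its
litter/dam covariance structure (samples are independent given age); diet
effects (groups are exchangeable by default, so diet contrasts are null);
and read-level artefacts (chimeras, PCR bias). Passing tests therefore
validate the pipeline's statistical machinery and recovery behaviour, not
those aspects of real data.

## Numerical choices

* Ranks use average ties everywhere; edge p-values use the t
  approximation with df = n − 2.
* SMACOF runs with eps 10⁻⁹ and up to 500 iterations so exactly
  embeddable configurations reach stress < 10⁻⁶.
* Permutation p-values always use the (1 + count)/(1 + N) estimator, so
  p ∈ (0, 1].
* The generator expands one global seed into independent substreams
  (tree, depths, counts, weights), so changing one component's draw does
  not perturb the others.
* BIOM support covers the 1.0 JSON layout (dense and sparse); counts are
  validated as non-negative integers on load, with errors naming the
  offending row/column.

## Known limitations

Single-factor PERMANOVA only (no interactions or nested permutation);
unweighted UniFrac only (no weighted/generalized variants); Spearman
co-occurrence is not compositionality-aware (by design — it reproduces
the plain-correlation method); the Venn partition's named regions assume
the first age is the milk-only period and ages are cross-sectional.
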