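# Methods

`sexdevnet` re-implements, as a tested pipeline, a developmental
transcriptomics analysis of sex-biased gene regulation in a haplodiploid
insect: exon-level expression matrices are decomposed into transcription and
splicing features, a weighted co-expression network is built over all
whole-body samples, and three complementary questions are asked of its
clusters — which are differentially *expressed* between the sexes at each
stage (DE), which are differentially *correlated* (DC), and how gene age
(phylostratum) relates to each node's position in its cluster.  A synthetic
data generator with planted effects makes every stage of the pipeline
verifiable at desk scale.

## The synthetic data generator

The generator emulates a five-stage (early embryo, late embryo, larva, pupa,
adult), two-sex, three-replicate whole-body design (30 samples), plus
dissected-gonad samples for pupal males (testes) and adult females (ovaries).
Expression is simulated at the exon level on the log2 scale with additive
Gaussian noise (microarray-like log-ratio intensities), not counts.

**Baseline model.** Each gene belongs to one co-expression cluster.  A
cluster's genes share a latent per-sample factor; a gene's log2 signal is

    x_gs = mu_g + sigma * (lambda_s * f_cs + sqrt(1 - lambda_s^2) * e_gs)

with per-gene baseline `mu_g ~ N(7, 1.5)`, biological replicate scale
`sigma = 0.4` (isogenic pooled samples; total replicate SD including exon
noise is ~0.45 log2 units), and baseline loading
`lambda = sqrt(rho)` with within-cluster correlation `rho = 0.3` — a typical
mean within-module correlation for co-expression clusters.  Exon noise is
0.2 log2 units.

The shared factor `f` is by default a **two-state (on/off) co-regulation
program**, drawn uniformly from {-1, +1} per sample, rather than a Gaussian.
The two-state factor realises the *planted* correlation exactly in every
sample: a Gaussian factor's chi-square variance-of-variance at three
replicates per sex produces chance correlation differences of the same
magnitude as a planted r_M = 0.8 vs r_F = 0.1 effect, which makes any
sex-specific-correlation test at this design size powerless against its own
null.  Biologically the two-state program corresponds to switch-like
activation of a co-regulated module.  Gaussian and bounded-uniform factors
remain available (`EffectSpec.factor_kind`).

**Planted effects.**

* *DE*: a log2 shift added to one cluster's genes in one (stage, sex) cell.
* *DC*: at the stated stage, the per-sex factor loadings are set to
  `sqrt(r_M)` and `sqrt(r_F)`, so within-cluster correlation differs by sex
  at that stage only.
* *Gonad enrichment*: gonad samples copy their matched whole-body replicate's
  gene signal plus a per-gene shift for the enriched set.
* *Linkage enrichment*: a fraction of one linkage group's genes receives a
  sex-specific shift.
* *Stratum topology*: inside designated clusters, genes of named strata take
  architectural roles.  "Interactors" form dense cores — independent latent
  factors at loading 0.95 (bounded above by the CCRE-collapse threshold:
  denser cores would be merged into single features during preprocessing).
  "Hubs" are cross-core bridges loading ~0.5 on every core with random
  signs, so their neighbours span mutually-unconnected cores (low clustering
  coefficient, hence high hub score at moderate connectivity).  Everything
  else is a leaf on the cluster backbone.

A truth table records every planted effect; latent splicing fractions are
attached for recoverability checks.

**What the generator does not model**: probe-level intensities, stage-specific
expression programs (off by default; `stage_profile_sd` adds them),
count-based noise, batch effects, and (by default) the ~10% male
contamination of pre-pupal female pools (available as
`female_contamination`).  Passing tests therefore demonstrate the
*machinery* under the stated statistical structure, not performance on real
arrays.

## Preprocessing

1. **Floor**: all values below the experiment-wide 66th percentile (linear
   interpolation quantile — the cut is quantile-definition sensitive, so the
   definition is fixed here) are set to exactly 0.
2. **Detection filter**: an exon is kept if it is positive in at least two
   replicates of at least one (stage, sex, tissue) condition; genes with no
   surviving exon are dropped.
3. **Node decomposition**: per gene, one *transcription node* (mean of
   constitutive-exon log2 values) and one *splicing node* per facultative
   exon-group.  The splicing ratio is the group's linear-scale signal over
   the summed linear-scale constitutive signal, clamped to [0, 1] (0 when the
   gene total is 0).  Exons whose isoform membership is identical are merged
   into one group.
4. **CCRE collapse**: nodes with pairwise Pearson correlation above 0.95 are
   grouped (single-linkage connected components by default; an all-pairs
   clique rule is available) and replaced by one representative — the member
   with the most above-threshold links within the group, or, for pairs, the
   higher-mean member.  Collapsing is idempotent.  CCREs may span genes;
   gene-level roll-ups attribute a CCRE's calls to all member genes.

## Network construction and topology

Adjacency is unsigned soft-thresholded correlation `a_ij = |cor(x_i, x_j)|^beta`
with biweight midcorrelation as the robust default (Pearson behind a flag).
`beta` is chosen by the scale-free topology criterion: the smallest power
whose binned log-log degree distribution fits a line with negative slope and
R^2 >= 0.8 (falling back to the R^2 argmax with a warning).  Clusters come
from average-linkage hierarchical clustering of topological-overlap
dissimilarity with a fixed height cut (default 0.99 of the maximum merge
height, minimum module size 10; these knobs make no claim of reproducing any
particular published module count), or labels may be supplied.

Node statistics are computed within each node's cluster: connection density
`Kd_i = k_i / (N - 1)` (per-node degree normalised by its true maximum, so
Kd is in [0, 1]); the Zhang–Horvath weighted clustering coefficient
`CC_i = sum_{j != l} a_ij a_jl a_li / ((sum_j a_ij)^2 - sum_j a_ij^2)`;
and the hub score `Hub_i = Kd_i (1 - CC_i)`, which can never exceed Kd.
High-Kd/high-Hub nodes are regulator-like (star centres); high-Kd/low-Hub
nodes are interactor-like (clique members); low/low are marginal.

Cluster statistics: size, density (mean off-diagonal weight), centralization
`(N/(N-2)) (max Kd - density)`, heterogeneity (coefficient of variation of
degree), median CC, diameter (longest shortest path under edge length
`1 - a`; the unbounded alternative `1/a` is rejected), and the proportions of
splicing nodes and duplicated-gene nodes (paralog family of size >= 2),
normalised by their network-wide shares.

## Differential expression

Each node is fit by least squares with the cell-means model
`value ~ Stage + Stage:Sex`: the Stage factor absorbs stage-specific
expression, and each stage contributes one male-minus-female contrast.
Splicing nodes are tested on their untransformed ratio scale (a logit option
exists).  Residual variances are moderated empirical-Bayes style toward a
pooled scaled-inverse-chi-square prior fit by the method of moments on
log s^2, with moderated t on residual-plus-prior degrees of freedom.
Moderation pools **within node kind**: splicing-ratio variances (~0.01) and
log2-expression variances (~0.2) live on different scales, and pooling them
collapses the prior degrees of freedom to near zero, destroying the
moderation benefit.

P-values convert to local false discovery rates with a two-component model:
pi0 from the upper tail (`#{p > 0.75} / (0.25 n)`) and the marginal density
from the Grenander estimator (slope of the least concave majorant of the
ECDF).  Two resolutions are used, on purpose:

* node-level families (thousands of contrasts, many discoveries): the ECDF
  is thinned so each knot spans ~10 observations, which stabilises the
  estimator's inconsistent extreme-left tail — on uniform p-values the
  probability that the first-knot slope exceeds 2 is a Poisson(5) >= 10 tail,
  about 3%, so null data is essentially never called;
* small families with isolated discoveries (cluster-level DE, linkage
  enrichment; tens of contrasts): raw resolution (`block=1`), because block
  thinning averages a lone extreme p-value with its null neighbours and no
  isolated discovery could ever be made.

Gene-level bias uses the any-node rule (a gene is biased at a stage if any
of its nodes is), with `both` recorded when nodes disagree; genes ever
male- and ever female-biased are switch genes, tested for depletion with a
one-tailed Fisher test on the ever-M x ever-F table over all genes, and
excluded from linkage-group enrichment.  Gonad bias contrasts pupal male
whole bodies with testes and adult female whole bodies with ovaries in a
no-intercept model with per-sex baselines and per-sex gonad effects; a node
is flagged when both the overall gonad contrast and the testis-vs-ovary
difference pass lfdr < 0.05, the tissue taken from the difference's sign.
Cluster enrichment for gonad-biased isoforms (>= 5 flagged members) uses
one-tailed Fisher tests with Benjamini-Hochberg correction; linkage-group
enrichment uses two one-tailed Fisher tests per group against all other
groups pooled, corrected jointly by lfdr.

## Differential correlation

The targeted DC test asks whether a cluster's internal co-expression depends
on sex at a given stage.  For each stage, all C(6,3) = 20 ways of removing
three of its six samples are enumerated (one stage perturbed at a time — the
only reading that keeps a constant subnetwork size of 27 without a
combinatorial explosion), and the sex composition of the three retained
focal samples is summarised as the balance `b = (#M - #F)/3`, taking values
{-1, -1/3, +1/3, +1} with multiplicities {1, 9, 9, 1}.  Every subnetwork's
adjacency is rebuilt on its retained samples with the main network's power
and cluster assignment (never re-estimated), and each cluster's
within-cluster density is recorded, guarded into (1e-6, 1 - 1e-6) because
the logit link is undefined at the boundary.

Per cluster, a gamma-family GLM with logit link is fit by IRLS:

    Density ~ Stage + Stage:Balance + logit(NetworkDensity)

The stage-specific balance slope is the DC statistic (positive = density
rises with more males retained).  The whole-subnetwork density covariate
enters on the link scale so that a subnetwork-wide connectivity shift moves
through the intercept and covariate rather than the interactions (absorption
is exact up to the curvature of the gamma weights, empirically ~1e-4 on the
coefficients).  Gamma-with-logit is kept as specified even though beta
regression is the textbook choice for (0,1) responses; a batched IRLS with
deviance step-halving fits all clusters against the shared design at once,
which is what makes the permutation loop affordable.  Per-cluster Pearson
dispersions are squeezed toward a pooled prior before Wald tests: without
shrinkage, clusters whose densities happen to align almost perfectly with
the design produce arbitrarily extreme statistics, giving the permutation
null a polynomial tail that destroys the calibration resolution.

**Calibration.**  The raw Wald p-values are anticonservative by construction
(subnetworks share 24 of 27 samples), so inference is purely permutational:
sex labels are shuffled within stage (preserving the stage design), balances
recomputed, and the GLMs refit — densities never change, since the removal
sets are fixed.  Stage 1 refers each observed p-value to the pooled
permutation distribution of all *other* clusters (a cluster's own permuted
fits are excluded: permutations partially aligned with the true labels of a
genuinely DC cluster leak real signal into the null's left tail), and
converts the resulting exceedance to an lfdr at raw Grenander resolution —
the external permutation null supplies the calibration that block-thinning
would otherwise provide.  Stage 2 corrects each contrast against all other
clusters' stage-1 scores; it is implemented as the maximum of the stage-1
score and its empirical exceedance fraction among all contrasts.  A second
density-estimation pass was considered and rejected: chaining two Grenander
estimates multiplies the smallest score by approximately the family size
twice, so at a family of 150 contrasts no isolated discovery could ever
reach the 0.10 threshold, regardless of how extreme its statistic is.  The
max-rule keeps the stage-2 score conservative (it can only tighten stage 1)
while preserving the scale of extreme discoveries.  Calls are made at
stage-2 lfdr < 0.10, with direction from the interaction coefficient's sign.

At the shipped desk scale (30 clusters x 60 nodes, 200 permutations), null
data yields on average well under 0.5 calls per run and a planted
r_M = 0.8 / r_F = 0.1 cluster is detected in ~90% of seeds.

## Topology multivariate analysis and gene age

The eight per-cluster topology statistics are centred, scaled and decomposed
by PCA (deterministic sign: each component's largest-magnitude loading is
positive).  Cluster bias flags are regressed on PC scores with binomial GLMs
over **all predictor subsets**; models are ranked by AICc
(`AIC + 2k(k+1)/(n-k-1)`, k counting every coefficient), and each
predictor's relative importance (RI) is the sum of Akaike weights of models
containing it, with RI > 0.70 read as a significant association.
Model-averaged coefficients are full averages (absent terms contribute 0).
Complete separation triggers a Firth-penalised refit with a warning.

Stratum fold enrichment divides each bias class's stratum proportions by the
genome-wide proportions (a fold of 1.5 = 50% more genes of that age than
expected).  The gene-age models regress each node's within-cluster density
and hub score (guarded into (0,1)) on

    ClusterSize + Stratum + DE + DC + Stratum:DE + Stratum:DC

with gamma/logit GLMs, stratum as an unordered factor referenced on the
oldest level (Metazoa), cluster-level DE/DC flags propagated to member
nodes, strata with fewer than five nodes merged into the adjacent older
level, and all marginality-respecting submodels averaged by AICc
(ClusterSize forced into every model, so its RI is 1 by construction).

## Numerical choices and limitations

* Quantile definition, eps-guards (1e-6), IRLS tolerances (relative deviance
  change < 1e-8, max 50 iterations with step halving) are fixed and tested.
* The lfdr block-thinning default (10 observations per knot) trades
  single-outlier sensitivity for null robustness; both regimes are exposed.
* Problem sizes in the test-suite simulations (30 x 60-node clusters for DC,
  24 clusters for the gene-age pattern, 200 permutations, 25-50 seeds per
  check) were chosen as the smallest designs at which the planted effects are
  comfortably identifiable; all are parameters, not limits.
* The module-detection cut height and minimum size are configuration values;
  cluster counts on real data will depend on them.
* Fisher tests are exact; everything downstream of a Fisher p-value is exact
  arithmetic, verified against hypergeometric tail sums.
* The DC test's power depends strongly on the generative correlation
  structure; with Gaussian shared factors, three replicates per sex carry too
  little information about second moments for reliable detection at these
  effect sizes, which is worth remembering when interpreting DC results on
  real designs of this size.
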