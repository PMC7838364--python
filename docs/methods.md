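# Methods

`oilseednet` implements a comparative transcriptomics workflow for seed-oil
biosynthesis: it asks which genes are co-expressed with the oil pathway in
*every* species examined, and which of those also shift expression between
species with contrasting oil composition. This note records the models,
the defaults and why they are what they are, and what the bundled synthetic
data does and does not establish.

## Fatty-acid statistics

Compositions are mass fractions of total fatty acid (GC-MS-style percent
composition); molar handling is out of scope. Desaturation efficiencies
follow the product/substrate convention for the C18 cascade
18:1 → 18:2 → 18:3:

    DE_omega6 = (18:2 + 18:3) / (18:1 + 18:2 + 18:3)
    DE_omega3 =  18:3 / (18:2 + 18:3)

A zero denominator yields an explicit `None` ("undefined"), never 0 or an
infinity — undefined ratios must not silently enter downstream means. The
same convention holds for SFA:UFA and MUFA:PUFA. qPCR relative expression
is the standard 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference).

## Differential-expression screen

The screen is a label-permutation test on the log2 fold change of
pseudocounted group means (pseudocount 1 on the FPKM scale, so zeros are
finite). With triplicate designs a strictly per-gene permutation null has
only C(6,3) = 20 label assignments and cannot produce small p-values, so by
default the null statistics are pooled across genes: replicate noise on the
log scale is approximately exchangeable across genes, and the pooled null
gives p-value granularity of order 1/(B·G). Each gene is compared against
the pool of the *other* genes' permuted statistics (leave-one-out); without
this, a strongly changed gene contaminates its own null and its p-value
saturates near the fraction of label assignments that preserve the groups.
P-values use the add-one rule (never exactly 0) and are BH-adjusted;
`pooled_null=False` gives the plain per-gene permutation test. The pooled
variant assumes roughly homoscedastic log-scale noise across genes — for
data with strong mean–variance structure the per-gene mode or an external
count-model screen is more appropriate.

## Network construction

The chain is: Pearson correlation of expression profiles → signed
soft-threshold adjacency a_ij = ((1 + r_ij)/2)^β (anti-correlated pairs get
weight ≈ 0) → unsigned topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with diagonal forced to 1 → average-linkage clustering of 1 − TOM → a
static height cut with a minimum module size (label 0 = unassigned) →
module eigengenes (leading right singular vector of the gene-standardised
module submatrix, sign-anchored to the module mean profile) → transitive
merging of modules whose eigengenes correlate at ≥ `merge_correlation`.

Numerical choices that matter:

- **β selection.** The smallest β in {2, 4, …, 20} whose binned log–log
  degree regression reaches R² ≥ 0.8 (only decreasing fits count). When no
  candidate qualifies — the normal case for small planted networks, which
  are not scale-free — the selector reports its best fit with a fallback
  flag, and the pipeline then uses the conventional default power β = 6
  rather than the erratic argmax.
- **Default cut height.** The static cut is placed at the midpoint of the
  largest gap in the sorted merge heights, ignoring the lowest 5% of merges
  (near-duplicate transcripts join at tiny heights and would dominate the
  gap search). Rationale: tight branches form low in the tree and the
  diffuse background agglomerates high, so the widest height gap separates
  the two regimes; a fixed fraction of the maximum height does not, because
  module branches attach to the background cloud *below* the background's
  own merges (module–background TOM exceeds background–background TOM).
  An explicit `cut_height` always wins; this is a deterministic
  simplification of dynamic tree cut and will under-perform on nested or
  strongly unequal-density module structure.
- **Ties.** Module labels are ordered by decreasing size with the original
  cluster label as tie-break; transcript-collapse representatives are the
  longest member with lexicographic tie-break; all tie-breaks are
  deterministic so reruns are byte-identical.

## Oil-module selection and validation

Modules containing annotated pathway seed genes are candidates; those whose
eigengene correlates at ≥ `pattern_correlation` (default 0.75) with the
seed-richest module are united. Cohesion is validated by drawing
`n_permutations` (default 5,000) random equal-size gene sets and comparing
the mean off-diagonal intramodular TOM; p = (1 + #{null ≥ obs})/(n + 1),
with significance declared at 10⁻³. The permuted unit is the gene set, not
the expression values: cohesion of a *fixed* set of genes is the quantity
under test. The statistic is the mean (median available via config).
Annotation agreement uses the upper-tail hypergeometric probability
(significance 10⁻⁶); the same machinery doubles as a generic enrichment
engine over caller-supplied term→gene maps with BH correction.

## Orthology

One-to-one orthologs are reciprocal best hits: best by score, identity as
tie-break, and a residual tie disqualifies the gene — ambiguous orthology
must not seed cross-species claims. Orthogroups are connected components
of the similarity graph after normalising each hit by its query's best
score and thresholding at `score_floor` (default 0.5); singletons are kept
as their own groups. This is a deterministic stand-in for phylogeny-aware
clustering: it cannot separate recent paralogs from orthologs and will
merge families connected by strong promiscuous hits.

## Conservation and stoichiometry

A focal-species oil-module gene is *conservatively co-expressed* when its
orthogroup contains at least one oil-module member from every other species
(any-module membership, not same-module identity — the weaker, stated
reading). The conserved set intersected with interspecific DEGs gives the
candidate regulators. Desaturase neighbourhoods use a TOM weight floor at
the network's 99th percentile by default (top-k available); cross-species
consensus is computed at orthogroup resolution.

Expression stoichiometry divides each pathway gene's replicate-averaged
expression by the summed expression of the combined FA-synthesis +
TAG-assembly sets, per stage. Cross-species comparison reports the squared
Pearson correlation of the two fraction vectors per stage and a per-gene CV
of the fractions pooled over the stages of both species (pooling stages is
a documented choice; per-stage averaging was the alternative). Because
fractions are compositional, a large expression shift in one pathway gene
necessarily moves every other gene's share; the conserved-vs-diverged CV
contrast is therefore interpretable only when the diverged genes do not
dominate the pathway total.

## Synthetic data

The generator emulates the study design the analysis assumes: 2–3 species ×
five stages (0, 40, 50, 60, 100 days after flowering) × three replicates,
FPKM-like expression, a co-expressed oil module with a bell-shaped latent
profile tracking oil accumulation, interspecific DE genes with fixed log2
offsets, paralog children (optionally with a stage-shifted profile
mimicking subfunctionalised desaturase duplicates), fatty-acid trajectories
pinned to chosen desaturation efficiencies by constructive inversion
(18:3 = T·DE₆·DE₃, 18:2 = T·DE₆·(1−DE₃), 18:1 = T·(1−DE₆), interpolated
from a near-uniform start), and a similarity table whose true ortholog
pairs always out-score decoys.

Defaults, chosen once as plausible study conditions: log2-scale Gaussian
replicate noise with sd 0.3 (a typical bulk RNA-seq replicate CV of
20–25%); base expression Uniform(2, 8) in log2 FPKM; gene lengths
Uniform(500, 3000) nt; within-module correlation 0.8; final C18-unsaturate
pool 0.9 of total fatty acid; true-hit bitscores 200–250 with decoy scores
equal to base × identity × coverage (12–56% of the query's best, consistent
with the identity/coverage fields the decoy record itself reports).

The latent amplitude of a planted module is not the naive
sd·sqrt(r/(1−r)): that calibrates the *log-scale* correlation, and
exponentiation attenuates it (≈0.75 realised at a 0.8 target). The
amplitude is instead solved by bisection from the exact conditional-moment
expression for the correlation of 2^(b + a·z + e) gene pairs given the
realised latent z, so the calibration holds on the expression scale the
network is built from; the remaining small-sample estimator bias is ≈ +0.03
at 15 samples.

What the generator does **not** emulate: batch structure, mean–variance
trends, library-size variation, count discreteness, unbalanced designs,
many-to-many orthology, or sequence content (no reads, no alignments).
Passing the planted-recovery tests therefore shows the algorithms are
correct and calibrated under clean, homoscedastic, well-separated
conditions — not that they are robust to the failure modes of real
RNA-seq.

## Problem sizes

The recovery and calibration benchmarks run at desk scale, chosen so the
full suite completes in minutes on one CPU: module recovery on 630 genes ×
15 samples; conserved-gene recovery on three species × 650 gene families
with 30% decoy hits; DE detection over 20 seeds at n = 3 vs 3; null
calibrations with 200 module draws and 5,000 null genes; oracle checks on
50 random 40-gene adjacencies and 50 random score tables. The default
pipeline (three species, ~400 genes each, 5,000-permutation validation)
runs in about a second and is byte-identical under a fixed seed.

## Known limitations

- Static cut + min-size is a simplification of dynamic tree cut; deeply
  nested module structure will be merged or dropped.
- Orthogroup components are not phylogeny-aware; tandem families and
  promiscuous domains inflate groups.
- The pooled permutation null assumes exchangeable log-scale noise across
  genes.
- Headline counts from any real study (numbers of modules, module sizes,
  DEG counts) depend on the underlying sequencing data and are not
  reproduction targets of the synthetic design.
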