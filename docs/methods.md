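# Methods

This note documents the models and procedures implemented in `mirlsa`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Source transforms

**Network-based inference (NBI).** Binary miRNA–target links are re-weighted
by two rounds of equal-split mass diffusion on the bipartite graph: starting
from a miRNA's unit resource on each of its targets, every gene divides its
resource equally among the miRNAs targeting it, then every miRNA divides
what it received equally among its targets. The operation conserves each
row sum exactly; miRNAs without targets keep all-zero rows. Implemented
densely as `A D_g⁻¹ Aᵀ D_m⁻¹ A`, adequate at the matrix sizes this package
targets.

**TF-IDF.** Word blocks use the plain `count × ln(N/df)` weighting, where a
document is a miRNA with at least one token and `df` counts documents
containing the word. This is deliberately not scikit-learn's smoothed
variant (`ln((1+N)/(1+df)) + 1`): a word present in every document must be
weighted exactly zero. Tokenisation is lowercase, split on
non-alphanumerics, tokens shorter than three characters dropped; no stemming.

**Disease similarity.** The hierarchy is a parent→child DAG (MeSH-style).
Similarity between two terms is an ancestor-Dice coefficient
`2·|anc(d₁)∩anc(d₂)| / (|anc(d₁)|+|anc(d₂)|)` over self-inclusive,
root-exclusive ancestor sets. The measure is symmetric, 1 on the diagonal,
and 0 for terms sharing no non-root ancestor. It was chosen because it needs
nothing beyond the hierarchy itself and is easy to verify against
brute-force transitive closure; it is exposed behind a small function so
other measures (information-content based, Wang-style) can be substituted.
Terms absent from the hierarchy are similar only to themselves and are
skipped by inference (logged).

**Annotation inference.** Inference propagates each annotation to every
*broader* (ancestor) term. The underlying vocabulary convention could be
read in either direction; the worked convention here follows the standard
MeSH subsumption example (an annotation to "Colonic Neoplasms" implies
"Colorectal Neoplasms"). The operation is idempotent and only adds
annotations.

**Discretization.** The association strength `m` of a (miRNA, disease) pair
is the maximum similarity between the disease and any disease annotated to
the miRNA. It is expanded into overlapping upper bins: one indicator per
cutoff `c ≤ m`, plus a `no_assoc` indicator when `m` is below the smallest
cutoff. Values exactly at a cutoff go to the upper bin only (the overlapping
closed intervals of the binning description would otherwise place a boundary
value in two bins of different names). Cutoffs live on the 19-point grid
0.05…0.95.

**Genomic neighbours.** `w_ij = max(0, 1 − |start_i − start_j|/D)` when the
chromosomes match, else 0, diagonal forced to 0, with window `D = 50 000 bp`
by default. Rationale: miRNAs within a few tens of kilobases are commonly
co-transcribed as clusters, so a simple linear decay over a 50 kb window is
a reasonable first-order co-expression proxy; the window is a parameter.
Coordinates are 1-based inclusive and strand is ignored for the distance.

## Latent space and query

The selected blocks are concatenated in a fixed order (disease block first —
it is mandatory — then targets, family, neighbours, and the three text
sources), with namespaced column identifiers preventing collisions.
Transform flags whose source flag is off have no effect.

The truncated SVD uses the exact dense decomposition below 200×200 (also the
test oracle) and ARPACK (`scipy.sparse.linalg.svds`, fixed start vector)
above it. Determinism is completed by a sign convention: the
largest-magnitude component of each left singular vector is made positive.
Rows embed as `UΣ` and columns as `VΣ` — the symmetric scaling keeps both
entity types in one comparable space; asymmetric alternatives (`U`, `VΣ`)
were rejected because row–column cosines would then mix scales. A requested
dimension larger than `min(rows, cols)` is clamped down with a warning,
which necessarily happens when the 50–800 encoded grid meets a desk-scale
matrix.

A disease query takes the centroid of the disease's positive-bin feature
vectors; the `no_assoc` bin is excluded because it encodes *absence* of
association and loads with the complement population — averaging it in
would cancel the query. With query expansion the centroid also includes the
columns of descendant (more specific) diseases, mirroring the matrix-side
inference direction. The query uses the column embeddings directly rather
than folding in a pseudo-document; the fold-in alternative would only differ
by a `Σ` scaling that cosine ignores at matching rank. miRNAs are ranked by
cosine, ties broken by identifier for reproducibility.

## Parameter encoding

All tunable alternatives form a 35-bit genome: six source-inclusion bits,
five transform bits, 19 cutoff bits on the 0.05 grid, a 4-bit reflected
binary (Gray) field for the latent dimension (`dim = 50(d+1)`, bit 31 most
significant — the layout lists bits in ascending order and the field order
is fixed here for reproducibility), and a query-expansion bit. Decoding
preserves transform bits even when their source bit is off (they are simply
inert at assembly time) so that encoding and decoding are exact inverses on
all 2³⁵ genomes.

## Evaluation protocol

Per disease `d` with at least `disease_min` annotations (default 20,
matching the usual database filter; the synthetic fixtures use 5), the
annotated miRNAs are split into five seeded near-equal folds. For each fold
the held-out `(miRNA, d)` entries are removed from MD, `d` is excluded
entirely from the similarity augmentation (so its column is supported only
by cross-disease similarity and the other sources), the latent space is
rebuilt, and `d` is queried. Held-out miRNAs are scored as positives against
all miRNAs never associated with `d` in the full dataset — unlabeled pairs
are treated as negatives for lack of anything better, a standard but
acknowledged approximation. Fold (score, label) pools are concatenated
before computing per-disease metrics; per-fold AUCs over ~2 positives would
be too unstable to average. AUC uses the Mann–Whitney formulation with 0.5
credit for ties. The optimizer's fitness is the unweighted mean of the
per-disease AUCs and is deterministic given (dataset, genome, seed), which
lets the kriging surrogate run in interpolation mode.

**Invalidation.** On the full-data space, every annotated pair's cosine is
z-scored against the distribution over all annotated pairs; the invalidation
score is `−z` and pairs above a threshold (default 2.0) are flagged. A
zero-variance distribution flags nothing. **Novel predictions** are the
per-disease top-k unannotated miRNAs, globally sorted by cosine.

## Optimizer

The binary DE mutant is sampled per coordinate from the sigmoid
probability-estimation operator
`P = 1/(1 + exp(−2b[x₁ + F(x₂ − x₃) − 0.5]/(1 + 2F)))` with three distinct
partners per target, followed by binomial crossover (rate `CR`, one forced
mutant coordinate) and greedy replacement on ties-keep-target. Defaults:
λ = 50, t = 50 real generations, μ = 100 surrogate generations, F = 0.8,
CR = 0.8, b = 6, ω = −2.

The surrogate is ordinary kriging with correlation
`exp(−Σ θᵢ|xᵢ−x′ᵢ|^{pᵢ})`, constant mean estimated by generalised least
squares, and a 10⁻⁸ nugget. On the binary grid `|Δx| ∈ {0, 1}` the exponent
is inert; θ defaults to 0.1 uniformly (correlation `e^{−0.1·Hamming}`),
optionally tuned by maximising the concentrated log marginal likelihood over
a bounded grid. Duplicate genomes are merged with the mean observed fitness
before fitting, which keeps the correlation matrix non-singular (fitness is
seed-deterministic, so duplicates agree). The archive keeps every real
evaluation ever made.

One loop iteration: fit the surrogate on the archive, evolve the population
μ MBDE generations selected on the merit `f̂ − ωξ`, re-evaluate the evolved
population with the real fitness in parallel, and apply greedy replacement
against the incumbents on real fitness only (surrogate and real selections
are never mixed). With μ = 0 the surrogate phase reduces to a single plain
MBDE round (PBDE). Real evaluations total λ(t + 1) including initialisation.
Parallel evaluation is a thread pool with order-preserving semantics and
per-genome fault isolation (failures score −∞); results are identical for
any worker count because all random draws happen in the master loop. The
initial population is uniform random.

Behaviour to know about: with the published b = 6 the sigmoid leaves a ~9 %
per-bit resampling probability even on fully converged bits, so exact
convergence to a needle optimum (e.g. OneMax's all-ones genome) needs
substantially more than ~600 real evaluations — measured here, λ = 20 plain
MBDE plateaus at 29–32/35 within t = 30 generations and reliably reaches 35
only around t ≈ 100–300. The surrogate's value shows on smooth fitness
landscapes, where PGPABDE reaches target fitness levels in a small fraction
of the real evaluations PBDE needs (see the paired-seed acceptance test).

## Synthetic data

The generator plants the minimal statistical structure under which LSA
provably helps: miRNAs, diseases, genes and families are partitioned into
`n_groups` co-clusters and all sources are drawn from the same block signal
— Bernoulli(`p_in` = 0.7) links inside a group, Bernoulli(`p_out` = 0.02)
across, group-determined families, per-group genomic clusters within a
50 kb span, group-specific document vocabulary (80 % own-group words, 20 %
shared), and a hierarchy nesting each group's diseases under a broader group
term (depth 2 by default; the group terms are hierarchy-only, not MD
columns). The default fixture has 60 miRNAs, 12 diseases, 4 groups, seed 42.
One deliberately wrong cross-group association is injected (into the
strongest "pure" disease, from the strongest pure out-group miRNA, so the
inconsistency is maximally recoverable) and one genuine within-group
association is deleted; both are recorded in the ground truth.

What passing tests show: the pipeline recovers planted low-rank block
structure from redundant noisy sources, behaves at chance when the
annotation structure is destroyed, and re-finds deleted within-group links.
What they do not show: performance on real databases — real annotation
matrices are sparser and far from block-structured, their noise is not
independent Bernoulli, text is not a clean group vocabulary, and hub
miRNAs/diseases have heavy-tailed degree distributions the generator does
not model. One consequence worth noting: at `p_out = 0.02` the generator
itself creates a handful of genuinely wrong cross-group associations besides
the injected one, and these compete head-to-head with it in the invalidation
ranking — on the default fixture the injected pair ranks second among the
flagged pairs, all of which are verifiably cross-group. The injected pair is
the unambiguous top hit on a noise-free (`p_out = 0`) fixture.

Benchmark fitness functions for optimizer testing: `onemax`,
`leading_ones`, and `noisy_quadratic` — a smooth unimodal function of the
bit sum with optimum at 29 ones (away from the random-initialisation mean of
17.5, so reaching it requires actual optimization) plus a deterministic
±0.005 per-genome hash perturbation.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator` seeded explicitly;
  two runs with the same seed are bitwise identical, independent of worker
  count.
* Truncated-SVD determinism: dense path below 200×200, fixed ARPACK start
  vector and a sign convention above.
* Cosine against a zero vector is defined as 0 (such miRNAs rank last,
  ties broken by identifier).
* An all-zero assembled matrix cannot be factorised and is rejected; the
  genome fitness wrapper maps this to fitness 0 so the optimizer can
  traverse degenerate configurations.
* Diseases with fewer than five positives are skipped by cross-validation
  (logged); a filter nothing survives raises.
* Kriging: non-positive-definite correlation matrices raise with advice to
  increase the nugget; predictive variance is clipped at 0 before the square
  root.

## Known limitations

* Dense matrices throughout; tens of thousands of text columns would want a
  sparse assembly path.
* Negatives in evaluation are "not known to be associated", which
  underestimates true performance if unlabeled positives exist.
* The ancestor-Dice similarity ignores term depth and information content.
* Querying by miRNA (ranking diseases) is not implemented; the symmetric
  operation would be straightforward but is out of scope.
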