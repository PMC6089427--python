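# Methods

This note documents the models, algorithms and design choices behind
`barcodedelim`, in the order the pipeline applies them, together with the
assumptions each one makes and what the synthetic benchmarks do and do not
demonstrate.

## Distance models

All pairwise distances are computed under **pairwise deletion**: for each
sequence pair, only columns where both sequences carry an unambiguous
A/C/G/T are compared (gaps, N and all other ambiguity codes — which the
reader collapses to N — are dropped per pair, not per alignment). This
matches the convention of the common barcode-registry and MEGA-style
summaries and keeps singleton-rich datasets usable; its cost is that
different pairs are measured on slightly different site sets.

From the compared sites we keep the sufficient statistic (counts of A↔G
transitions, C↔T transitions, transversions, and pooled base counts) and
evaluate:

* **p-distance** — the raw mismatch proportion. Reported where registry
  tables use it (intra-OTU summaries, assignment similarity).
* **K2P** — `d = -½ln(1-2P-Q) - ¼ln(1-2Q)`. The default metric for
  barcode-gap discovery.
* **TN93** — splits the transition classes (P₁ = A↔G, P₂ = C↔T) and weights
  by base frequencies π estimated, by default, from the pair's pooled
  compared sites (a `global_freqs` switch uses alignment-wide frequencies
  instead). The gamma-rate-corrected form replaces each `-ln(w)` term with
  `α(w^(-1/α) - 1)`; α = 1 is the default for between-OTU matrices, a
  conventional choice for COI rate heterogeneity. At uniform π with
  P₁ = P₂ the model reduces algebraically to K2P, and α → ∞ recovers the
  uncorrected form — both identities are regression-tested.

**Saturation.** When a logarithm argument reaches zero (possible for
extremely divergent or adversarial synthetic pairs) the distance is
recorded as `+inf` and the pair is flagged on the matrix, rather than
raised: ranking places such pairs last, and tree building refuses flagged
matrices explicitly. TN93 additionally requires every base class present in
the compared sites; a missing class raises a named error, since the model
weights are undefined there.

Distances are kept in substitutions/site internally; percent appears only
in presentation-layer tables (×100).

## Barcode-gap discovery

The recursive gap finder works on the ranked list of pairwise distances:

1. `dist_limit` — the divergence below which variation is assumed
   intraspecific a priori — is taken to equal the user prior *P* directly
   (the simplest faithful estimator; it is an explicit function argument so
   alternative estimators can be plugged in).
2. The slope of the ranked-distance curve is evaluated on consecutive gaps
   `d[i+1] − d[i]`. A candidate gap must (a) end above `dist_limit`, (b) be
   a local maximum among its neighboring gaps, and (c) exceed
   `X · max(dist_limit, widest gap below dist_limit)`. Requirement (c) is
   the relative-gap-width condition; because a gap inside the prior
   intraspecific range can be as wide as *P* itself, any accepted gap is
   wider than *X*·*P* (with *X* = 1 and *P* = 0.01, the minimum detectable
   gap scale is 1%).
3. `n_bins` acts as a resolution floor: gaps narrower than
   `(d_max − d_min)/n_bins` — i.e. invisible at a 20-bin histogram
   resolution — are ignored. We evaluate the slope on raw consecutive gaps
   (the fine-binning limit) rather than on a literal 20-bin histogram
   gradient, which is ill-defined across empty bins; the bin count enters
   only through this floor.
4. The partition threshold is the midpoint of the accepted empty interval,
   clipped above `dist_limit`; sequences are grouped by **single linkage**
   below it (two sequences share a group iff a chain of sub-threshold
   distances connects them), and the search recurses inside every group of
   at least three members until no further gap is found. Fewer than three
   sequences cannot exhibit a gap, so recursion stops there.

A scan runs this over a log-spaced prior grid (defaults 0.001–0.1 in 10
steps, *X* = 1.5; the "study" configuration narrows to *P*max = 0.01,
*X* = 1). Adjacent priors yielding identical partitions are collapsed into
one row carrying the prior range. For downstream consensus a single
partition must be chosen from the scan: we take the row spanning the most
priors (ties to the higher range) — the partition least sensitive to the
prior. This stability heuristic is the package's own reading of how scan
results are conventionally condensed to "the" ABGD answer.

## Registry-style OTUs and assignment

Threshold clustering is single linkage under a fixed distance cutoff,
default 0.0112 substitutions/site — the complement of a 98.88% assignment
similarity, itself the complement of a ~1.12% minimum nearest-neighbor
distance between registry OTUs of the target group. It is a transparent
stand-in for registry clustering algorithms that are not public; it shares
their single-linkage character but none of their refinement steps.
Assignment of query sequences takes the group of the most similar reference
(p-distance similarity, `100·(1−d)`) when it reaches the threshold;
similarity ties across groups are broken by reference order with a logged
warning.

Per-OTU summaries report member count, maximum and mean intra-OTU distance
(undefined for singletons), and the nearest-neighbor OTU with its distance,
all in percent. The NN linkage is the **minimum** cross-group pairwise
distance by default (registry convention); a mean-linkage option exists
because between-group summary matrices conventionally report means. The
barcode-gap diagnostic plots, per OTU, x = max intra-OTU distance against
y = distance-to-NN − max intra; y ≤ 0 flags an OTU the gap cannot resolve,
and singletons are excluded as untestable.

## Ordination

`ClassicalMDS` is classical (Torgerson) metric MDS: eigendecomposition of
the double-centered squared-distance matrix, coordinates ordered by
eigenvalue, sign fixed so each axis's largest-magnitude coordinate is
positive — fully deterministic, and an exact isometry on
Euclidean-realizable inputs (tested to 1e-9). Genetic distance matrices are
generally only approximately Euclidean; negative eigenvalues are clipped,
and an error is raised only when no leading eigenvalue is positive. The
variant used by ordination packages in other environments (e.g. non-metric
MDS) may differ; classical MDS was chosen for determinism.

## Trees and monophyly

Neighbor joining follows the canonical Q-criterion agglomeration with the
rate-corrected branch split. Two numerical conventions make it reproducible:
Q-ties are broken by the lexicographically smallest pair of clade
representative labels (the smallest leaf name inside each clade), and
negative branch-length estimates are clamped to zero with the deficit moved
to the sibling branch, preserving path lengths. The Q search runs over one
matrix triangle only, because floating-point summation order can make
Q[i,j] and Q[j,i] differ by ulps. On additive matrices NJ recovers the
generating tree exactly (tested over random 6–10-leaf trees, topology and
branch lengths).

Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree per replicate, and score each internal edge of the reference tree
by the percentage of replicates containing the same leaf bipartition
(bipartitions are stored as unordered {side, complement} pairs, so they
survive rerooting). Replicates with an incomputable distance are dropped
and logged; more than 10% drops is an error.

Monophyly is assessed on a rooted tree: outgroup rooting when outgroup IDs
are given (with an explicit error naming intruding leaves when the outgroup
is not separable), midpoint rooting otherwise — the practical choice for
synthetic data that has no outgroup. Singletons count as trivially
monophyletic. Non-monophyletic groups also report the number of maximal
pure sub-clades their members form. Externally produced trees (e.g. from a
Bayesian run, which is out of scope here) can be substituted via Newick
import; on real data the NJ tree and a Bayesian tree may disagree, and the
report should then be read against the tree actually supplied.

## Consensus

A cluster is a **Full** OTU iff (a) the barcode-gap partition contains a
group with exactly the same membership — a strict bijective match — and
(b) the cluster is monophyletic or a singleton. Everything else is
**Partial**: a cluster split into several gap groups, merged into a larger
one, partially overlapping, non-monophyletic, or missing from a source
(e.g. members private to an external registry). A looser mode
(`strict=False`) accepts a split into whole gap groups as agreement, for
sensitivity analysis; the strict reading is the default because "agreement"
is otherwise ambiguous for partial overlaps, a case the strict rule
classifies as Partial by construction. Counting invariant:
#Full + #Partial = #clusters, always.

## Synthetic data generator

The generator emulates the divergence structure of a multi-species barcode
survey, not its genealogy. A star tree of lineages: the root sequence is
drawn from the configured composition (defaults: T 30%, C 28.4%, A 23.2%,
G 18.4% over 652 sites — typical fish-COI values); tips radiate from each
lineage ancestor with branches of `intra_target/2` expected
substitutions/site, and lineage stems are scaled so the expected
between-lineage path equals `inter_target`. Substitution is a
Kimura-two-parameter process (transition/transversion rate ratio κ,
default 4 — a typical COI value) applied with exact K80 transition
probabilities, so branch lengths are in expected substitutions/site.
Defaults are ten lineages of five sequences, intra 0.005, inter 0.08 —
clearly gapped, barcode-like data.

Deliberate simplifications: the root draw is not the K80 stationary
distribution (uniform), so composition drifts very slightly toward uniform
along branches — under 0.2 percentage points at these depths; star
topologies within and between lineages (a pure-birth option is out of
scope); no indels, no sequencing error, no coalescent population structure,
and equal rates across sites. Consequently, passing benchmarks show the
pipeline recovers *cleanly gapped* structure reliably; they do not show
robustness to rate heterogeneity, uneven sampling, or gap-free continua of
divergence, which real surveys can contain. Raising `intra_target` toward
`inter_target` erodes the gap and degrades recovery, as expected. Targets
above 0.75 expected differences/site are rejected as saturated. One seed
drives all randomness through a single generator; equal seeds give
byte-identical FASTA.

## Pipeline and problem sizes

The `run` pipeline chains distances (TN93, α = 1) → threshold clustering
(0.0112) → gap-discovery scan (K2P; study settings narrow the prior) → NJ
(+ optional bootstrap, default 1000 replicates when enabled) → monophyly →
consensus → summaries/MDS, writing every stage's TSV/Newick output and a
manifest with config, seed, versions and SHA-256 checksums of inputs and
outputs. A stage failure leaves a `FAILED` marker naming the stage and
retains completed outputs.

The test suite and the acceptance script run at desk scale — twenty seeded
replicates of 50-sequence, 652-site datasets, 100-replicate bootstraps —
sizes chosen so the full benchmark battery completes in seconds while
keeping Monte-Carlo rates (e.g. ≥18/20 recovery) stable across seeds.
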