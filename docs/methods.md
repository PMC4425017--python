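# Methods

This note documents the models, estimators, numerical conventions and design
decisions behind `barcodeval`, in the spirit of a methods appendix: enough
detail to know exactly what each reported number means and where the
package's behaviour is a choice rather than a necessity.

## Distance model

Pairwise distances use the Kimura two-parameter (K2P) substitution model,

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q),

with P and Q the observed proportions of transition (A↔G, C↔T) and
transversion differences among *compared* sites. Sites where either sequence
carries a gap, an N, or any IUPAC ambiguity code are excluded pair by pair
(**pairwise deletion**), so every pair has its own denominator. This matches
the behaviour of the species-identification tools used in barcoding studies
and preserves data in ragged alignments, at the cost of distances computed
over slightly different site sets.

Two situations make a distance undefined rather than numeric:

* **insufficient overlap** — fewer than `min_overlap` compared sites
  (default **100**, configurable; permissive for typical 230–620 bp spacer
  alignments but meaningful protection against nearly disjoint fragments);
* **saturation** — 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0, where the logarithms
  diverge. Q ≥ 0.5 is enough, so saturation is reachable on short, extremely
  divergent pairs.

Undefined pairs are carried in an explicit mask with the reason recorded,
excluded from every summary, identification candidate set and tree build,
and never imputed. Tree building refuses matrices with undefined entries
rather than guessing.

The per-dataset "overall K2P (%)" is the **unweighted (pooled) mean of all
defined off-diagonal distances** — conspecific and allospecific pooled —
expressed in percent. A species-weighted mean would be a defensible
alternative; the pooled mean is the simplest reading of an "overall"
distance and is what `alignment_stats` reports.

## Barcoding gap and the 95% threshold

Distances partition by conspecificity of the pair's species labels. The
strict gap criterion is `min_inter > max_intra`; because empirical
distributions usually overlap partially, the summary also reports the
fraction of interspecific distances at or below the intraspecific maximum
(`overlap_fraction`), letting users apply either the strict or the weaker
"distributions largely separated" reading.

The *threshold* is the 95th percentile of the intraspecific distance
multiset. Two estimators are offered:

* `linear` (default) — interpolated percentile on the sorted multiset;
* `nearest_rank` — the classic inverted-CDF rank statistic.

The estimators differ noticeably on small multisets (tens of values); the
default is documented rather than canonical, and both are exposed
everywhere the threshold is used. The threshold is computed **per dataset**,
never globally, since it is a property of that dataset's intraspecific
variation.

Histograms use half-open bins [k·w, (k+1)·w); a value exactly on an edge
falls in the upper bin. Each non-empty series is normalised to sum to 1
(relative abundance).

## Similarity identification (BM / BCM)

Both rules are **leave-one-out**: every record serves once as a query
against all other records with a defined distance to it. Records with no
defined distance at all are tallied as *uncomparable* and removed from the
denominator (this is reported, not silent).

* **Best match**: the query is identified by the species of its nearest
  candidate(s). Candidates within `tie_tolerance` (default **1e−10**, a
  floating-point guard rather than a biological parameter) of the minimum
  are pooled, which makes verdicts independent of record order. Verdicts:
  *correct* (tie set = query's species), *ambiguous* (tie set contains the
  query's species and others), *incorrect* (tie set all foreign — including
  ties among two or more foreign species).
* **Best close match**: queries whose best distance is strictly greater
  than the dataset threshold become *no match*; the rest are classified as
  BM. BCM is therefore never more permissive than BM.

Singleton species are legitimate queries (real compilations are full of
them): they can at best be *incorrect* under BM and *no match* under BCM,
which is exactly how they depress the observed identification rates of real
datasets.

**A structural property worth knowing:** the threshold is *defined* to
exclude the top ~5% of intraspecific distances. In a dataset with dozens of
queries it is therefore common — not pathological — for at least one query's
nearest conspecific to lie above it, so BCM rarely reaches a perfect score
even when the barcoding gap is ideal. Empirical studies show the same
pattern: BCM trails BM by a few points with a small persistent no-match
column.

## Tree-based identification

Neighbor joining is implemented natively (Saitou–Nei agglomeration with the
Q-criterion). Numerical conventions:

* ties in the Q matrix break to the smallest (i, j) index pair, so results
  are deterministic;
* negative branch lengths are clamped to zero with the deficit shifted to
  the sibling edge, preserving the joined path length;
* the final three nodes solve the three-point equations exactly; the output
  is an unrooted tree with a trifurcating root node.

**Bootstrap** resamples alignment columns with replacement; each replicate
gets its own NJ tree, and every internal edge of the original-data tree is
scored by the percentage of replicates containing the same bipartition
(mapping to the original tree, not a consensus). One seed governs all
replicates. A replicate whose resampled matrix contains undefined distances
is redrawn; more than `n_replicates/2` total redraws aborts, since the
alignment is then too gappy or saturated for a meaningful bootstrap.

**Monophyly** is evaluated on unrooted bipartitions — the rooting-free
formalization appropriate to NJ output: a species with ≥ 2 individuals is
monophyletic iff one edge separates exactly its individuals from everything
else, and *identified* iff that edge's support is **strictly greater** than
the cut-off (default 80 for bootstrap scale, 0.80 for posterior scale).
Edge cases: a species comprising all, or all but one, leaves is trivially
monophyletic and counted as supported (the separating edge is a pendant
edge, which bootstrapping does not score); singleton species can never be
identified by this test. Two singleton conventions are provided, since
published tables rarely state one: `count_incorrect` (default — singletons
stay in the denominator, depressing the percentage exactly as large
singleton fractions depress published tree-based scores) and `exclude`
(drop them from the denominator). Scoring is invariant to rerooting and
leaf rotation by construction.

External ML/Bayesian trees are consumed as newick with supports as internal
node labels; support bounds are validated against the declared scale
([0, 100] bootstrap, [0, 1] posterior), and unannotated internal edges warn
and score as support 0. On trees written with a bifurcating root, the two
root-child clades name the same unrooted edge; support lookup prefers the
annotation written on the queried clade's own side.

## Synthetic data

The simulator generates exactly the structure the pipeline consumes, with
known truth:

1. a root sequence drawn uniformly over {A, C, G, T};
2. species ancestors evolved from it along a **star** tree (default) with
   branch `inter_divergence/2`, or along a rescaled Yule tree whose mean
   ancestor-pair path length equals `inter_divergence`;
3. individuals evolved from their ancestor with branch
   `intra_divergence/2`;
4. optional gaps injected independently per site per sequence
   (`gap_rate`).

Substitutions follow the K2P process with transition/transversion *rate*
ratio `kappa` — the same model the distance estimator inverts, so realized
distances converge on the configured divergences as length grows (verified
to within Monte-Carlo error at L = 10⁵ in the test suite).

Divergences are **branch lengths** (expected substitutions/site), not
observed p-distances. Under the star model a conspecific pair is separated
by `intra_divergence` and an allospecific pair by
`inter_divergence + intra_divergence` (both tips plus both ancestor
branches). When a target *distance regime* is wanted — "intraspecific
distances around a, interspecific around b" — set
`intra_divergence = a, inter_divergence = b − a`. The acceptance script and
the end-to-end tests use this regime convention.

Defaults describe a clearly structured, desk-scale barcode dataset: **20
species × 3 individuals, 500 bp, intra 0.01, inter 0.15, kappa 2.0, no
gaps**. Sampling depth can instead be a per-species list or a singleton
fraction; `emulate_table1_shape` builds a configuration reproducing a real
row's individuals/species/singletons/length exactly, distributing
non-singleton individuals as evenly as possible and choosing divergences so
the pooled mean K2P lands near a target value.

What the simulator deliberately does **not** model: insertion/deletion
evolution (gaps are noise, not indels), among-site rate heterogeneity,
recombination, and concerted-evolution artefacts of multi-copy spacers.
Passing tests on simulated data therefore demonstrate correctness of the
estimators and decision rules under their own model assumptions — they do
not certify performance on loci where those omitted processes dominate.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at desk scale, chosen
to make the statistical assertions sharp while remaining quick on one CPU:
gap-recovery rates over 100 seeds of 20 species × 3 × 500 bp; best-match
oracle agreement over 200 random datasets of ≤ 30 records; NJ recovery on
100 random additive trees of ≤ 12 leaves; end-to-end identification over 50
seeds with 500 bootstrap replicates; simulator calibration at L = 10⁵ over
20 seeds.

## Known limitations

* NJ is O(n³) in pure numpy — comfortable to a few hundred records,
  not thousands.
* Only the K2P distance is implemented; JC/HKY distances and model
  selection are out of scope.
* ML and Bayesian tree *construction* are out of scope; their outputs are
  scored, not produced.
* The region-comparison table is descriptive; no significance testing is
  attached to differences between loci or methods.
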