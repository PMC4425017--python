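# barcodeval

Evaluation toolkit for DNA barcode candidate loci. Given a species-labeled,
pre-aligned set of sequences (e.g. nuclear ribosomal ITS1/ITS2 compilations,
or plastid *rbcL*/*matK* alignments), `barcodeval` answers the question every
barcoding study asks: **how well does this locus identify species?** It does
so with the three standard method families used in plant and animal
barcoding, plus a ground-truth simulator for calibrating them.

## What it computes

**Distances.** All pairwise distances use the Kimura two-parameter (K2P)
model with pairwise deletion of gaps/ambiguities:

```
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
```

where *P* and *Q* are the proportions of compared sites with a transition
(A↔G, C↔T) or a transversion. Pairs whose overlap is too short or whose
divergence saturates the logarithms are masked as undefined, never imputed.

**Barcoding gap.** Distances are partitioned into intraspecific and
interspecific multisets. A strict gap is present when the minimum
interspecific distance exceeds the maximum intraspecific distance; because
real compilations typically overlap partially, the overlap fraction is
reported too, along with relative-abundance histograms and the 95th
percentile of the intraspecific distances (the *threshold*).

**Similarity identification.** Leave-one-out "best match" (BM): each record
is identified by the species of its nearest defined neighbour; ties spanning
species are *ambiguous*, all-foreign nearest neighbours are *incorrect*.
"Best close match" (BCM) additionally declares queries *no match* when their
nearest neighbour lies above the 95% intraspecific threshold.

**Tree identification.** A native neighbor-joining implementation with
column-resampling bootstrap; a species is identified when its individuals
form a monophyletic group (an unrooted bipartition) whose edge support
exceeds 80 (bootstrap) or 0.80 (posterior). Externally built ML/Bayesian
trees are consumed as support-annotated newick and scored by the same rule.

**Simulation.** Species-structured alignments evolve under the K2P process
along a star (or Yule) species tree with configurable intraspecific and
interspecific divergence, transition/transversion ratio, gap rate, and
per-species sampling depth — including emulation of a real dataset's
individuals/species/singletons/length row.

## Worked example

```python
import barcodeval as bv

cfg = bv.SimulationConfig(n_species=6, individuals_per_species=3,
                          seq_length=400, intra_divergence=0.01,
                          inter_divergence=0.15, seed=7)
aln, truth = bv.simulate_dataset(cfg)

dm = bv.distance_matrix(aln)
print(bv.alignment_stats(aln, dm))
ps = bv.pairwise_summary(dm)
print(ps.gap_present, ps.threshold, ps.max_intra, ps.min_inter)
print(bv.best_match(dm).pct_correct, bv.best_close_match(dm, ps).pct_correct)

st = bv.bootstrap_supports(aln, n_replicates=500, seed=7)
print(bv.score_monophyly(st).pct_correct_individuals)
```

prints

```
AlignmentStats(n_individuals=18, n_species=6, n_singletons=0,
               alignment_length=400, variable_pct=40.25, pi_pct=34.75,
               overall_k2p_pct=13.45...)
True 0.0155 0.0177 0.1252
100.0 100.0
100.0
```

Eighteen simulated individuals in six species: 40.25% of sites variable,
34.75% parsimony-informative, mean pairwise K2P 13.5%. The gap is strict
(max intraspecific 0.018 « min interspecific 0.125), so both similarity
methods identify every individual, and every species forms a fully
supported clade on the bootstrapped NJ tree.

The same workflow is available from the shell:

```bash
barcodeval simulate --n-species 6 --seed 7 --out-prefix demo
barcodeval stats demo.fasta
barcodeval gap demo.fasta
barcodeval identify demo.fasta
barcodeval tree demo.fasta --bootstrap 500 --seed 7
barcodeval evaluate --region ITS1=demo.fasta --out-dir results/demo
```

`evaluate` emits the full report bundle (stats, histograms, per-query
verdicts, summary tables, NJ tree, comparison matrix) plus a JSON manifest
that reproduces the run bit-for-bit.

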