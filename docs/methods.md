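# Methods

This note documents the models, defaults and design choices behind each
pipeline stage, what the synthetic fixtures do and do not emulate, and the
package's known limitations.

## Motif scoring

A motif is an L×4 column-stochastic position weight matrix (PWM). Scoring
uses the log-odds form against a background base-composition model with an
additive, background-proportional pseudocount:

    score(p, b) = ln((probs[p, b] + c·freq[b]) / ((1 + c)·freq[b]))

with pseudocount `c = 0.01` by default (standard practice; keeps zero
probabilities finite without distorting informative columns). Natural
logarithms are used throughout. Both strands are scanned by default and each
window's score is the maximum of the forward and reverse-complement score at
that offset. Windows containing an ambiguous base (N) are excluded; a
sequence with no valid window is marked unscoreable and its feature is
imputed with the global minimum of that motif's finite features, so the
design matrix is always finite.

Per-sequence aggregation of the window scores S_w is the log-average-exp
soft-max `x = ln((1/W)·Σ_w exp(S_w))` by default, with the plain maximum as
an alternative. The soft-max is smooth, respects the bound
`max_w S_w − ln W ≤ x ≤ max_w S_w`, and degrades gracefully for sequences
with several moderate sites; the max variant emphasises a single best site.
Both are exposed because either is a defensible definition of a sequence's
motif score; results on the synthetic benchmarks are insensitive to the
choice.

## Sparse logistic regression and stability selection

"Selecting a small motif combination" is formalised as lasso-penalised
logistic regression: maximise
`Σ_i [y_i ln p_i + (1−y_i) ln(1−p_i)] − λ·Σ_m |β_m|` with an unpenalised
intercept. Features are standardised before fitting by default so the
penalty is scale-fair; coefficients are reported on both scales and
selection (|β| > 1e−8) is made on the fitted scale. The optimiser is
scikit-learn's saga solver followed by a deterministic quasi-Newton polish
on the fixed sign pattern (on which the objective is smooth), which removes
the stochastic solver's residual error; tests verify agreement with a dense
grid-search oracle of the penalised likelihood to 1e−3 on small tables.

λ defaults to the 5-fold cross-validated deviance minimiser over a
geometric grid (0.1–100, 8 points), chosen independently per stability run.
Each stability run draws a fresh background sample — the same number of
sequences as there are peaks (balanced classes), drawn without replacement
from the promoter pool after excluding promoters overlapping any peak of
the experiment by ≥ 1 bp — with a per-run seed derived deterministically
from (master seed, run index). Only motifs selected in all five runs are
retained; across datasets, motifs retained in at least 9 of 10 are kept.

PWM similarity (used to merge redundant matrices) is the maximum over all
ungapped offsets and both orientations of the mean column-wise Pearson
correlation, mapped from [−1, 1] to [0, 1], over at least 4 overlapping
columns. Two flat (uniform) columns correlate perfectly and a flat column
against a shaped one scores zero, so self-similarity is exactly 1. Motifs
are clustered by single linkage at similarity ≥ 0.9; the representative is
the member with the highest mean intra-cluster similarity, ties broken
lexicographically.

## Consensus regions and gene mapping

Intervals are BED-style 0-based half-open; overlap means ≥ 1 shared base,
so book-ended peaks do not merge. Peaks longer than 3000 bp (strictly; a
3000-bp peak is kept) are removed before grouping. Pooled peaks are grouped
per chromosome by single-linkage connected components of the overlap graph
(implemented as a sorted sweep, verified against a brute-force union-find
oracle); a group's support is its number of distinct experiments, and
groups with support ≥ 6 become consensus regions. Output ordering is
(chrom, span start) and is invariant to experiment order and within-file
shuffling.

Gene assignment is TSS proximity: a gene is a target of a region iff its
TSS lies within 10 kb of the region span (inclusive; distance 0 when the
TSS is inside the span). The 10-kb default reflects that recurrently bound
regulatory regions typically sit within a few kilobases of the promoters
they control while still allowing one region to serve several genes; it is
configurable. Gene-symbol intersections (enriched TFs, pathway components,
disease targets) match case-insensitively on exact symbols.

## Key-node analysis

The upstream search for regulators of the NF-κB components is implemented
as downstream reachability from each candidate: R(k) is the set of nodes
reachable from k in at most `radius` directed steps (default 10; the
candidate itself and self-loops excluded), and

    score(k) = (|R ∩ inputs| + w_c·|R ∩ context|) / max(|R|, 1).

Input nodes weigh 1 and context proteins weigh `w_c = 2` by default — the
simplest weighting in which disease-relevant context up-weights a candidate
without overwhelming the input set; the denominator is the total reach, so
the score rewards *specific* regulators over broad broadcasters.

Significance is an empirical permutation test: each of `n_random`
replicates draws one node permutation, takes pseudo-input and pseudo-context
sets of the observed sizes from its head (disjoint, mirroring the real
configuration), and rescores every node — reach sets are fixed per node, so
replicates reduce to matrix products. Then `z = (score − null mean)/null
sd` (population sd; a degenerate null gives z = 0),
`p = (1 + #{null ≥ obs})/(n_random + 1)`, and Benjamini–Hochberg converts p
to FDR across nodes. Controlling nodes satisfy FDR ≤ 0.05 and Z ≥ 1.0, both
inclusive.

One practical constraint: with N scored nodes the smallest attainable BH
FDR is about `N/(n_random + 1)`, so `n_random` must comfortably exceed
20·N for the 0.05 cut-off to be reachable at all. The default of 1000
replicates suits scoring and ranking; for FDR-based selection on a ~300-node
network the examples use 8000.

## Drug prioritisation

The cumulative score is the plain sum of the probabilities of being active,
`S = Σ_i P_a(i)`, over the selected activity panel; the text-book
alternative `Σ_i [P_a(i) − P_i(i)]` is available behind a flag. Activities
missing from a compound's spectrum contribute 0 (and are usable partial
spectra); a missing *required* activity is an error. A compound passes iff
`S > 3.0` strictly and the required NF-κB-inhibitor activity has `P_a > 0`
(literal reading; the conventional `P_a > P_i` rule is an alternative
mode). Ranking is by descending score with lexicographic tie-break.

## Synthetic fixtures

All generators are pure functions of a `FixtureSpec` (sizes, rates, seed);
identical spec and seed give byte-identical files. Substream seeds are
derived per generator so the stages are independent. Defaults define the
benchmark conditions:

* **Peak sequences** — 200 positives of 200 bp, a 12-bp planted motif
  (Dirichlet-concentrated columns, concentration 20) embedded at rate 0.9
  at uniform offsets, 10 decoy matrices, a 600-promoter background pool on
  a synthetic chromosome with ~10% of promoters deliberately overlapping
  peak intervals so exclusion is exercised.
* **Multi-experiment peaks** — 200 well-separated loci; half receive
  mutually overlapping peaks in ≥ 6 of 10 experiments, the rest in ≤ 5;
  four extra loci carry only > 3000-bp peaks that the length filter must
  remove. The truth lists exactly the surviving regions.
* **Network** — ~300 background nodes with Poisson(1.2) out-degree, 12
  sink input nodes, 8 context proteins, and a planted regulator reaching
  every input through two dedicated hubs (depth ≤ 2). The node universe is
  kept much larger than the seed sets, as in curated pathway databases, so
  the permutation null is informative. Noise feeders into single inputs
  and all context nodes also feed a shared wide-fan-out broadcast node, so
  no bystander can outscore the regulator on a one-edge fluke.
* **Activity matrix** — 200 drugs × 46 activities; non-hits draw
  Beta(2, 48) probabilities (mean 0.04) with rows resampled if their sum
  approaches the threshold, hits draw uniform(0.08, 0.20) plus a strong
  required-activity probability, so the planted hits are exactly the
  compounds passing the filters.

These fixtures emulate the *logic* of the real inputs, not their texture:
backgrounds are i.i.d. uniform DNA (no GC skew, repeats or phylogenetic
structure), loci never abut, the network has no complexes, modification
semantics or hub-dominated degree distribution, and activity probabilities
are independent across activities. Passing tests therefore demonstrate the
correctness and statistical behaviour of the algorithms under controlled
conditions, not performance on real genomic data.

Benchmark sizes (20 seeds for recovery rates, 200–8000 permutation
replicates, 50-node oracle digraphs) were chosen so the full suite and the
acceptance script each complete in a couple of minutes on a single CPU
while leaving binomial noise on the measured rates well below the margins
of interest.

## Known limitations

* IUPAC ambiguity codes other than N are rejected rather than scored.
* The lasso path is not warm-started; each λ is fitted independently.
* PWM similarity is a pragmatic stand-in for dedicated motif-comparison
  tools; it ignores column information content when aligning.
* The permutation null draws pseudo-inputs uniformly from all nodes, with
  no degree or compartment matching.
* Consensus support counts experiments, not peak strength; no
  signal-weighted merging is attempted.
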