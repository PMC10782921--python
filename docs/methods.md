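# Methods

This note records the model, the choices that were genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Network construction

All coordinates are 0-based half-open; any 1-based dialect must be converted
at the reader boundary. Strand is ignored throughout (elements are
re-centred, never oriented). Inter-chromosomal loop records are rejected
(strict mode) or skipped with a warning: the network is intra-chromosomal by
construction and every retained component lies on one chromosome.

Thresholds are strict inequalities: anchors are kept when *both* are
< 1000 nt; a node is labelled when element–node overlap is > 300 nt (for the
600-nt normalized elements this is the same as "more than half the
element"); components survive when they have > 100 nodes. Anchor merging is
the connected-overlap closure — the same result as repeating pairwise merges
to a fixpoint, which the suite checks against a brute-force oracle.
Abutting-but-disjoint intervals do not merge. Duplicate loops between one
merged node pair collapse to a single undirected edge.

Element windows are `[c − 300, c + 300)` with `c = floor((start + end)/2)`;
a window that would cross the chromosome origin is clamped at 0 with a
warning and later padded (N for sequence, 0 for signal) back to 600
positions so the feature tensor keeps its shape. After normalization at most
one node can normally exceed the 300-nt overlap; if abutting nodes tie the
larger overlap wins, then the leftmost.

Promoter negatives are `floor(0.10 · n_promoters)` *per component*, drawn
without replacement from a seeded generator; floor is conservative and
reproducible where a rounding rule was not otherwise fixed.

## Features

The 21 × 600 tensor is the one-hot DNA block (rows A, T, C, G; N encodes as
an all-zero column; any other IUPAC code is an error rather than a silent
guess) stacked over the 17 assay tracks in a fixed order (12 histone marks,
then RAD21, POLR2A, SMC3, ZNF143, CTCF). A missing assay may be supplied as
an empty track, which reads as zeros — the convention also used when a
dataset lacks a profile — but the name must be present so channel order can
never silently shift.

The graph branch consumes a 10-d structural descriptor per node:
`[log1p(degree), self-loop flag, log1p(anchor length), window means of CTCF,
POLR2A, RAD21, SMC3, H3K27me3, H3K27ac, H3K4me3]`. The published
architecture fixes the graph-branch input width at 10 without documenting
the content, so this package defines it: every component is computable for
unlabeled nodes (no label leakage), deterministic, and spans the two kinds
of information the branch is meant to carry (local topology and the
signal context of the anchor).

## Classifier

* CNN branch: four units of (same-padded conv, kernel 8, stride 1 →
  LeakyReLU → width-4 max pool → dropout), channels 21→100 then 100→100
  three times; positions shrink 600 → 150 → 37 → 9 → 2 and a global max over
  the remaining positions gives the 100-d summary. Kernel width, pool width
  and global pooling are package choices; channel counts and unit count are
  the published calibration. Global pooling makes the first 256-unit MLP
  layer well defined for any window length.
* Graph branch: two rounds of mean aggregation over `{v} ∪ N(v)` followed by
  a learned projection and LeakyReLU (10→100, then 100→100). Two rounds is
  the conventional GraphSAGE depth and keeps receptive fields local; the
  round count was not fixed by the calibration. A self-loop contributes its
  node once to the neighbour set (set semantics), so a self-loop on an
  otherwise isolated node is a no-op, as the aggregation rule implies.
* Head: concatenated 200-d vector → 256 → 64 → 2 with dropout 0.2 after the
  hidden layers.
* Loss: class-weighted softmax cross-entropy, weight w = 1.2 on the silencer
  class (the positive class is the slightly rarer one in the balanced
  design), normalized by the weight sum. Cross-entropy is the standard loss
  for a 2-unit softmax head with a class weight. L2 with λ = 1e-4 enters the
  gradient as λ·W on weight matrices (biases excluded).
* Optimizer: Adam (β₁ = 0.9, β₂ = 0.999) at initial learning rate 1e-4, in
  minibatches of 32 labelled nodes; the published calibration fixes the
  learning rate, decay rule, L2 and class weight but not the optimizer, and
  Adam is the de-facto default for this architecture family. After any epoch
  whose mean training loss exceeded the previous epoch's, the learning rate
  is multiplied by γ = 0.95. Early stopping watches a stratified 10%
  validation split of the labelled nodes with patience 10 (max 100 epochs);
  the best-validation weights are restored.
* Inputs are standardized per channel / per descriptor dimension using
  statistics of the training nodes only; raw signal tracks have arbitrary
  units and unscaled inputs would make the fixed learning rate meaningless.
* All backpropagation is hand-written NumPy and verified against central
  finite differences in the suite (relative tolerance 1e-4 in float64).

During cross-validation the default is transductive masking: test-node
labels are hidden (`y = -1`) but their features participate in neighbours'
aggregation, in the spirit of inductive neighbourhood sampling on a fixed
graph. `test_isolation=True` instead removes test nodes from the training
graph entirely; both modes share one code path and the aggregation operator
is rebuilt whenever prediction runs on a different graph than training.

## Evaluation machinery

* AUROC is the rank statistic with ties split evenly — it equals the
  pairwise probability P(s⁺ > s⁻) + ½P(tie) exactly, which the suite asserts
  at 1e-9 against exhaustive pair comparison (and cross-checks against
  scikit-learn). AUPR integrates precision over recall trapezoidally across
  distinct thresholds.
* Zero-denominator ratios (PPV with no predicted positives, etc.) are NaN
  with a warning, never a silent 0.
* The two-set separation index uses the population variance (divide by n),
  exactly as defined, not the unbiased form. Reported spreads across CV
  repetitions use the sample SD (n − 1), since they summarize repeated
  experiments; the default report row is the repetition mean (a flag gives
  fold-level rows instead).
* Motif scores with zero counts are infinite and omitted with a warning.
* APA consumes a provided stack of odd-sided square contact submatrices,
  aggregates by element-wise mean, and scores the central pixel against the
  c × c lower-left block (default c = max(3, side/4)); ZscoreLL uses the
  population SD of the corner. Window geometry is configurable because the
  published analysis delegates it to an external tool.
* Method comparisons use Welch's two-tailed t-test on per-repetition values
  (variances are not assumed equal).

## Synthetic data

The generator emulates the *shapes* of the real inputs: anchors whose
lengths and overlaps are configurable, loops drawn over an anchor pool,
elements centred on anchor sites, per-base signal written as binned bedGraph
with Gaussian noise, and random DNA with an optional planted motif.
Class-conditional mean shifts act on the normalized 600-nt windows — exactly
where featurization reads — with defaults of +2 SD on H3K27me3, H3K9me3 and
CTCF for silencers and active-mark shifts for enhancers/promoters, a cartoon
of the class-conditional epigenome. `silencer_degree_boost` routes a
fraction of loop endpoints to silencer anchors, planting purely structural
signal. Element-bearing sites are spaced so their windows never collide;
deliberate anchor overlap is confined to non-element sites so planted labels
are never destroyed by merging.

Default conditions: 2 chromosomes × 2 Mb, 1500 loops over 1200 anchor
sites, 150 silencers and ~150 mixed negatives (50 non-silencers, 50
enhancers, ~50 of 500 promoters), noise SD 1, 20-nt signal bins. The
chance-level control uses zero effect scale with ≥ 500 labelled nodes; the
ablation experiments plant structural signal only (effect scale 0, degree
boost 0.8) on ten single-chromosome datasets. Training lengths are scaled to
the experiment (30 epochs for planted-effect recovery, 25 for ablation, 4
for the null control, where the model only needs to exist); these sizes are
the package's study conditions and are stated in the relevant tests and in
`scripts/acceptance.py`.

What passing shows: the pipeline's rules are implemented faithfully, the
optimizer can recover planted linear and structural signal, and nothing
leaks labels (zero effects give chance AUROC measured over every labelled
node by 2-fold cross-prediction). What it does not show: performance on real
chromatin, where signal-to-noise, anchor statistics, label noise and motif
grammar are all harder than the cartoon; absolute AUROC values on synthetic
data say nothing about real-data AUROC.

## Known limitations

* The NumPy implementation is single-CPU; it is sized for networks of
  thousands of nodes, not genome-wide millions.
* bigWig reading requires the optional pyBigWig; bedGraph is the tested
  path.
* Loop significance calling, contact-matrix generation and motif scanning
  are out of scope: the package consumes their outputs (BEDPE, window
  stacks, match-count tables).
* The 10-d node descriptor is this package's definition (see above); other
  choices of graph-branch input are plausible and would change the topology
  branch's contribution.
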