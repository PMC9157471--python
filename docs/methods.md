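# Methods

## Problem and approach

`splicewindow` identifies splice sites — donor sites whose introns begin
with the dinucleotide `GT` and acceptor sites whose introns end with `AG`
— in eukaryotic genomic DNA, and uses them to delineate exon/intron
structure. The pipeline has five stages:

1. **ORF extraction.** Open reading frames are the ATG→first-in-frame-stop
   spans of length ≥ 150 nt (stop codon included). Two stop-set presets are
   available: the standard nuclear set {TAA, TAG, TGA} (default) and
   `code4` = {TAA, TAG}, the protozoan/mold mitochondrial table under which
   TGA codes tryptophan. Forward strand by default; reverse/both
   selectable.
2. **Dataset construction.** Within each ORF, every `GT` occurrence is a
   donor candidate and every `AG` an acceptor candidate. Each `GT` is
   paired with its nearest strictly-downstream unconsumed `AG`, which makes
   donor and acceptor counts equal (an intron needs one of each). One
   no-site anchor per pair is taken at the pair midpoint, shifted rightward
   past any accidental `GT`/`AG`. Around every retained position a 60-nt
   window is cut with the site dinucleotide at 1-based window positions
   30–31 (29 nt upstream + 2-nt site + 29 nt downstream). Windows that run
   off the sequence or contain `N` are skipped, never padded — the
   encoding has no padding symbol. Classes are truncated to the smallest
   class size, so counts are exactly balanced. Labels: donor = 0,
   acceptor = 1, no-site = 2; nucleotides are encoded ordinally,
   A→1, G→2, T→3, C→4.
3. **Split.** A seeded, stratified 80/20 train/test split. The train size
   is exactly `round(0.8 × N)` via largest-remainder allocation across
   classes; labels are one-hot (3 columns).
4. **Classifier.** A four-layer network: embedding (5 × 8 table; row 0 is
   a reserved padding index, rows 1–4 the nucleotide tokens) → dropout
   (rate 0.2) on the embedded sequence → bidirectional LSTM (60 units per
   direction; the two final hidden states are concatenated) → dense 3-way
   softmax. Training: categorical cross-entropy, Adam (learning rate
   1e-3), batch size 32, 10 epochs × 5 rounds = 50 epochs, with the
   held-out set evaluated after every epoch to populate the loss/accuracy
   history curves.
5. **Calling.** On new sequence, one candidate window is cut per `GT`/`AG`
   occurrence with full flanks (same geometry as training). A `GT`
   candidate becomes a donor call only if the argmax class is donor, an
   `AG` candidate an acceptor call only if the argmax is acceptor; exact
   probability ties resolve to no-site (conservative). Donors and
   acceptors are then paired greedily left-to-right, keeping only pairs
   whose intron length — first base of `GT` through last base of `AG`,
   inclusive — lies in [70, 100] nt; consumed and spanned sites are
   skipped so introns never overlap. Exons are the complementary spans of
   a gene span (k introns → k + 1 exons); gene spans default to predicted
   ORF spans and can be overridden with a GFF3 of spans.

## Numpy implementation of the classifier

The network is implemented directly in numpy: fused-gate LSTM forward
recursions for both directions run in one stacked loop (gate blocks
ordered i|f|o|g so one sigmoid and one tanh cover each step), with
hand-derived backpropagation through time and an Adam optimiser.
Correctness is pinned by a finite-difference gradient check and a
closed-form parameter-count test
(`(V+1)d + 2·4H(d+H+1) + 2HC + C` = 33,523 at the defaults). All
randomness — initialisation (Glorot uniform; forget-gate bias 1),
minibatch shuffling, dropout masks — derives from a single integer seed,
so runs are bit-reproducible on a fixed numpy version. Forward inference
uses float32 by default; probabilities are normalised in float64.

Early stopping is available (`early_stopping_patience`): training stops
once held-out accuracy has not improved for the given number of epochs,
and the best-validation weights are restored (`restore_best_weights`,
default on when patience is set). This is the conventional policy for
small datasets, where per-epoch accuracy fluctuates under dropout and
small-batch noise; without patience the model trains the full 50 epochs
and keeps its final weights.

Because the held-out 20% also serves as the per-epoch validation series
for the history curves (and for early stopping), the reported held-out
accuracy is mildly optimistic in the early-stopping regime; a disjoint
validation split can be carved by the caller when unbiased test numbers
matter.

## Synthetic genomes

The simulator plants genes — codon-aware coding sequences (ATG start, no
internal in-frame stop, terminal stop) split into exons — interrupted by
introns forced to begin `GT` and end `AG`, with lengths uniform on
[70, 100] nt by default. Background (intergenic and intron-interior) bases
are i.i.d. with a single GC-content parameter, default 30.2%, an AT-rich
protozoan-like composition. Defaults: 50 genes, exons uniform on
[100, 300] nt, 1–3 introns per gene, intergenic gaps uniform on
[100, 400] nt. Ground truth (gene/exon/intron spans, donor/acceptor
positions) is emitted alongside, and `truth_windows` builds a balanced
labelled window set directly from it.

What the simulator deliberately does *not* model: codon-usage bias,
extended splice-site consensus beyond the `GT`/`AG` dinucleotides,
branch-point or polypyrimidine signals, and any compositional difference
between exons, introns and intergenic DNA beyond the stop-codon
constraint. Spurious `GT`/`AG` occurrences arising by chance are retained.

## What passing tests do and do not show

On this synthetic data the three classes are separated by the center
dinucleotide alone, so the classifier's held-out accuracy (the ~95.5%
floor and above) demonstrates that the architecture and optimiser learn
the window-classification task — not that the features generalise to real
splice sites, whose signal lies in flanking consensus context the
simulator omits.

The same omission bounds end-to-end site recovery. Because true and
spurious `GT` flanks are statistically identical by construction, the
Bayes-optimal window classifier on this data can only read the center
dinucleotide, and the precision of whole-genome site calling is capped
near the base rate of true sites among all `GT`/`AG` occurrences (a few
percent at the default composition; on a ~106 kb simulation, 249 true
introns against ~5,900 genomic `GT` occurrences). The greedy 70–100 nt
length filter raises specificity only modestly. The end-to-end recovery
test therefore documents this measured ceiling: its structural assertions
(every called intron within [70, 100]; exon/intron tiling conservation)
hold exactly, while site-level precision/recall on the fully synthetic
background remain far below what a consensus-aware simulation or real
annotated data would support. On real genomes the practical specificity of
this method likewise comes from the intron-length filter and downstream
validation against annotation, not from the window classifier alone.

### Majority-vote aggregation

A per-site majority vote over all overlapping stride-1 windows was
considered and rejected: training windows are always site-centered, so an
off-center window's prediction is governed by its own center dinucleotide
and the vote degenerates to "no-site" everywhere. `SpliceCall.support` is
kept in the schema (fixed at 1) so that a future context-trained model
can populate it.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere, matching GFF3; BED export
  converts to 0-based half-open.
- The window is 29 + 2 + 29 nt: with a 2-nt site, symmetric flanks inside
  a 60-nt window require 29 on each side.
- ORFs are first-stop maximal; nested ATGs seed additional ORFs only with
  `all_starts`. `min_orf_length` counts nucleotides including the stop
  codon.
- `split_counts` rounds half-up, and stratified allocation uses largest
  remainder, so the train size is exact for any N.
- Greedy nearest-downstream pairing is linear-time and predictable; an
  exhaustive maximum-matching oracle bounds its cardinality in tests
  (agreement ≥ 95% on small random instances).
- Argmax ties resolve to no-site: fewer false splice calls.
- Degenerate inputs: empty FASTA, zero usable windows, fewer than 3
  examples to split, non-one-hot labels and non-finite training loss all
  raise descriptive errors rather than proceeding.

## Problem sizes used in the checked runs

The reproduction script trains on a simulated genome of 1,200 genes
(~1.5 Mb, ~3,500 introns, ≥ 3,000 windows per class; ~10,700 windows
total) — a scaled-down analogue of the 111,015-window/37,005-per-class
dataset the full-genome workflow produces — and reports held-out accuracy
after at most 50 epochs with patience 5. The learning-floor test repeats
training across 10 seeds on the same scale; the end-to-end test uses an
~106 kb genome (80 genes). These sizes were chosen so every stage of the
method is exercised end to end at desktop scale.

## Known limitations

- No GPU path and no hyperparameter search; the defaults are conventional
  and exposed in `ModelConfig`.
- The simulator's i.i.d. background makes context learning impossible by
  design (see above); it validates machinery, not biological signal.
- Real-genome workflows (NCBI downloads, external ORF tools, annotation
  benchmarks) are supported through the FASTA/GFF3 interfaces but ship
  with no bundled data.
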