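# Methods

## The problem

Single-step (retro)synthesis prediction treats reactions as text: a model
reads the SMILES of a product and writes the SMILES of plausible precursors
(retro direction), or reads precursors and writes the product (direct
direction).  Because a molecule admits many valid SMILES writings — one per
starting atom and traversal direction — the text representation itself is a
natural axis for data augmentation, for test-time ensembling, and for a
frequency-based confidence score.  `rxnaug` packages those three mechanisms
plus the evaluation measures they require.

## Augmentation protocols

Every protocol emits `n` source→target pairs per reaction (2`n` for the
mixed protocol), and — except for `xNR` — the fully canonical pair is always
emitted first, so at least one canonical copy of each reaction is present in
any training set:

| protocol | source (product side) | target (precursor side) |
|----------|----------------------|--------------------------|
| `x1`     | canonical            | canonical |
| `xN`     | randomized           | canonical |
| `xNF`    | randomized           | each fragment randomized, order kept |
| `xNS`    | randomized           | fragments randomized and order shuffled |
| `xNM`    | `xNS` retro pairs interleaved with their forward inverses; the forward source carries a leading dot |
| `xNR`    | randomized           | one fixed random writing, reused for all `n` |

Randomization permutes the atom order before writing a non-canonical SMILES,
which draws the root atom and traversal at random.  Sub-seeds derive from
`(seed, rxn_id)` so a dataset reorder does not change any reaction's
augmentations.  Duplicate random writings within one reaction's batch are
kept: tiny molecules have few distinct writings and resampling could not
terminate.  The leading-dot marker distinguishing forward from retro pairs
in `xNM` is placed on the source string; a consistent convention is all the
mechanism needs, and the source side keeps targets uncontaminated.

Test-time augmentation always uses the simplest scheme (`canonical +
(n-1) random` writings of the product) since nothing about the unknown
precursors can be used at inference.

## Aggregation and confidence

For one product, `n_aug × beam_size` sequences are decoded (beam search with
optional temperature `p^(1/t)`, renormalized per step).  Each decoded string
is canonicalized; strings that fail to parse are flagged invalid and carry
no vote.  Within one beam, later duplicates of an already-seen canonical
form are dropped (the beam tends to restate one molecule in several
writings); duplicates across different augmented inputs are kept — they are
the agreement signal.  Answers are ranked by count; the confidence of an
answer is `count / (valid retained records)`, with a Wilson score interval
at 95% quantifying its sampling uncertainty.  Ties break by best log
probability, then lexicographically, so ranking is a pure function of the
pool.  A `--no-dedup` switch reproduces the alternative analysis that keeps
all within-beam duplicates.

## Metrics

* `seq_accuracy` compares canonical fragment **multisets**, so predictions
  differing only in atom numbering or fragment order still match.
* `char_accuracy` is `100 · LCS(pred, target) / len(target)` on raw
  characters.  The longest-common-subsequence definition is fixed by the
  worked example the metric must reproduce: `CCCCN` vs `NCCCC` scores 80%
  (4 of 5 characters), whereas naive per-position matching would give 60%.
* `topn_accuracy` has a `full` mode (whole precursor set) and a `maxfrag`
  mode that compares only the largest fragment — the principal
  transformation.  MaxFrag dominates full matching by construction and is
  the more chemically meaningful score when datasets list spectator
  reagents that no model could recover from the product alone.
* `stratify` splits by stereo markers (`@`, `/`, `\`) or class labels;
  `calibration` bins top-1 confidence into deciles against accuracy;
  `invalid_rate` tracks unparsable decodes per beam position.

## Dataset hygiene

`filter_reactions` removes records that cannot be learned from: no products;
no reactants; a reactant side that is a single charged fragment of ≤2 heavy
atoms (a bare counter-ion); a largest product shorter than 5 characters of
canonical SMILES (maps stripped first — map tokens would inflate lengths);
reactants totalling fewer than 5 heavy atoms.  Rules are independent, so the
kept set does not depend on evaluation order.  `classify_reaction_role` uses
atom maps to label reactions non-reagent (product equals a precursor), one
reagent (A→P), multiple reagent (A+B→P, all contribute) or unclear reagent
(some precursor contributes no mapped atom); without maps it answers
`unknown` rather than guessing from substructure.

## Synthetic reaction grammar

The generator builds single-product condensations from four string-rewrite
templates (esterification, amide coupling, Williamson ether, halide
amination) over random acyclic alkyl scaffolds (chains of 1–6 carbons,
branch probability 0.3).  Defaults plant a spectator reagent in 10% of
reactions and a stereocenter in 20% — the spectator share reported for
large patent reaction corpora and the stereo share of a typical
retrosynthesis benchmark test set.  Atom maps are assigned from the known
atom correspondence of each template, which makes the role classifier
exactly testable; the template precursors are the unique ground-truth retro
answer, so a cheating oracle scores 100% top-1 — a fixed point that
validates the whole evaluation path.

What the grammar does **not** emulate: rings and aromatic systems, charge
chemistry beyond spectator salts, competing reactions for one product,
reaction conditions, and the long-tailed molecule-size distribution of
patent data.  Passing tests on the grammar therefore demonstrate the
correctness of the machinery (augmentation laws, aggregation arithmetic,
metric semantics) and the qualitative behavior of training, not real-data
accuracy.

## The tiny reference model

`TinySeq2Seq` is a pointer-generator transducer sized for a laptop CPU: the
decoder state concatenates the previous 4 target tokens, a source window of
radius 5 centered on the output position (a monotonic-alignment prior),
the first/last 4 source tokens, a normalized bag of source tokens, and
learned embeddings of the output position, the number of completed
fragments and the position within the current fragment.  A single
dot-product attention head over all source positions adds non-monotonic
alignment, and its weights double as a copy distribution mixed with the
generator softmax through a learned gate.  Training is plain Adam
(lr 3·10⁻³) on cross-entropy with hand-written backpropagation; gradients
were verified against finite differences.  Given a seed, initialization,
shuffling and therefore the fitted model are bit-reproducible.

The model memorizes a 50-pair training set essentially verbatim when
trained long enough, and on the grammar shows the qualitative augmentation
effect: full-reaction augmentation (`x5F`) yields held-out top-1 at least
as good as canonical-only (`x1`) training under identical budgets.  Its
absolute accuracy is far below a production transformer's, which matters
for the confidence score: with mostly-uncertain predictions the
frequency–accuracy relationship is much weaker than for a strong model.

A second, structural effect works against calibration at toy scale:
frequency confidence assumes the augmented inputs are *distinct* writings.
The grammar's products are small (a dozen heavy atoms or fewer), so the
set of distinct SMILES writings is tiny and test-time augmentation
repeatedly presents the same string; a deterministic decoder then returns
the same answer every time, producing high agreement that carries no
information.  Small products are also exactly the ones whose retro answer
is most ambiguous (several template/split combinations fit a short
string), so at this scale high confidence associates with *small* — hence
hard — inputs.  On realistic molecules (tens of heavy atoms) writings
essentially never collide and this confound disappears; the toy study
therefore exercises the confidence machinery but should not be read as a
verdict on frequency confidence itself.

## Numerical and design choices

* Canonical dotted strings order fragments by (heavy atoms ↓, string length
  ↓, lexicographic); "largest fragment" uses the same key, so it is always
  the first fragment of a canonical multi-fragment string.  Heavy-atom
  count was chosen over character length as the size measure.
* Beam scores are sums of post-temperature log probabilities with no length
  normalization by default (`length_penalty` exponent available); at equal
  scores candidates order lexicographically.  Truncated (never-terminated)
  candidates are returned, flagged, only when fewer than `beam_size`
  sequences finished.
* Temperature is applied per decoding step (`p^(1/t)`, renormalized);
  greedy decoding is therefore temperature-invariant.
* Character-level tokenization is the default (SMILES vocabularies are a
  few dozen characters); a regex mode with bracket atoms and two-letter
  elements is available for interoperability.
* Confidence denominators count valid retained records; an option counts
  the raw pool instead.
* The acceptance study trains on 2000 generated reactions with 10 epochs,
  3 seeds, and ranks with 10 augmented inputs × beam 5 per product — sizes
  chosen so the complete study runs in minutes on one CPU core.

## Known limitations

* The tiny model's absolute accuracy on the grammar (top-1 well under 50%)
  limits how sharply frequency confidence separates right from wrong
  answers; conclusions about calibration on real data require a stronger
  model.
* The role classifier trusts atom maps; wrong maps yield wrong categories.
* `largest_fragment` ties (equal atoms, equal length) are resolved
  lexicographically, which is deterministic but chemically arbitrary.
* Beam search prunes exactly; it can miss sequences whose prefixes score
  poorly, as any beam decoder does.
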