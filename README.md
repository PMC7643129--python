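# rxnaug

SMILES augmentation, beam-search aggregation and evaluation for
single-step (retro)synthesis sequence models.

Reaction prediction can be framed as translation between strings: a
sequence model reads the SMILES of a product and writes the SMILES of its
precursors (retrosynthesis), or the reverse (forward synthesis).  Because
every molecule admits many valid SMILES writings — one per starting atom
and traversal direction — the text representation is itself a lever:

* **training-set augmentation** — the `x1 / xN / xNF / xNS / xNM / xNR`
  protocols multiply each reaction into randomized writings of its
  molecules, optionally shuffling precursor order and interleaving
  forward/retro pairs (the forward source marked with a leading dot);
* **test-time augmentation and frequency ranking** — each product is
  decoded from many random writings with beam search; decoded sequences
  are canonicalized, deduplicated within a beam, and ranked by how often
  each canonical answer appears.  The frequency of the top answer is a
  confidence score, reported with a Wilson 95% interval;
* **evaluation** — exact sequence accuracy on canonical fragment
  multisets, character accuracy (longest common subsequence over target
  length), Top-n and MaxFrag Top-n (largest-fragment-only — "classical
  retro-synthesis accuracy"), stereo/class stratification, confidence
  calibration and invalid-SMILES rates;
* **dataset hygiene** for patent-style reaction corpora (multi-product
  splitting, trivial/ill-formed record filters, reaction-role census from
  atom maps);
* a **synthetic reaction grammar** (`toydata`) generating desk-scale
  datasets of template condensations with known ground truth, spectator
  reagents, stereocenters and atom maps, so the whole pipeline is testable
  without downloading anything;
* a **tiny trainable pointer-generator model** (`TinySeq2Seq`, pure NumPy)
  that plugs into the same decoding stack and exercises the pipeline end
  to end on a CPU.  Any model exposing the `SequenceModel` contract
  (a per-step `next_token_distribution`) can be used instead.

## Worked example

```python
import rxnaug as rx
from rxnaug.reactions import serialize_reaction

rxns = rx.generate(rx.ToyGrammar(), n_reactions=3, seed=7)
r = rxns[0]                      # a halide amination, class label 4
pair = rx.to_pair(r, "retro")
print(pair.source, "->", pair.target)
for p in rx.augment_xNS(r, 3, seed=0):
    print(p.aug_index, p.is_canonical_pair, p.source, "->", p.target)
print(rx.char_accuracy("CCCCN", "NCCCC"))
print(rx.seq_accuracy("NCCCC", "CCCCN"))
```

prints

```
CCCCNCCCC(C)CC -> CCC(C)CCCN.CCCCCl
0 True CCCCNCCCC(C)CC -> CCC(C)CCCN.CCCCCl
1 False C(CCCNCCCC)(C)CC -> C(Cl)CCC.C(CC(CC)C)CN
2 False CCC(CCCNCCCC)C -> C(CC(CC)C)CN.C(CCl)CC
80.0
1
```

The first augmented pair is always the canonical writing; the others are
random writings of the same molecules (here with the precursor order
shuffled as well — protocol `xNS`).  The two accuracy calls show the two
views the metrics take of the same pair of strings: as raw text, `CCCCN`
matches the recorded `NCCCC` in 4 of 5 characters (80%); as molecules,
both are n-butylamine, an exact match (1).

The same operations are available from the shell:

```bash
rxnaug simulate --n 1000 --seed 0 --out rxns.tsv
rxnaug augment rxns.tsv --protocol xNS --n 5 --out-prefix train
rxnaug train --src train.src --tgt train.tgt --out model.npz
rxnaug predict --model model.npz --products prods.txt --n-aug 20 --beam 5 --out preds.tsv
rxnaug evaluate --predictions preds.tsv --targets targets.txt
```

## Layout

| module | contents |
|--------|----------|
| `rxnaug.chem` | canonicalization, seeded randomization, fragment handling |
| `rxnaug.reactions` | reaction SMILES parsing/serialization, source→target pairs |
| `rxnaug.augment` | the augmentation protocols and test-time augmentation |
| `rxnaug.prep` | dataset filters, multi-product splitting, reaction-role census |
| `rxnaug.predictor` | tokenizers, beam search, the `SequenceModel` contract, `TinySeq2Seq` |
| `rxnaug.aggregate` | candidate pools, within-beam dedup, frequency ranking, confidence |
| `rxnaug.metrics` | sequence/character accuracy, Top-n, MaxFrag, strata, calibration |
| `rxnaug.toydata` | the synthetic reaction grammar and its ground-truth oracle |
| `rxnaug.cli` | the `rxnaug` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
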