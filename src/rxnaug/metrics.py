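"""Evaluation measures for (retro)synthesis prediction.

* **Exact sequence accuracy** — order- and notation-insensitive: predicted
  and recorded answers match iff their canonical fragment multisets are
  equal (a prediction written from a different starting atom, or with the
  reactants permuted, still counts).
* **Character-based accuracy** — per-string similarity between the raw
  predicted and target sequences, defined as the longest common subsequence
  over the target length ("CCCCN" vs "NCCCC" scores 80% even though both
  denote n-butylamine).
* **Top-n** and **MaxFrag Top-n** — fraction of test items whose answer
  appears among the n best-ranked predictions; the MaxFrag (classical
  retro-synthesis) variant compares only the largest precursor fragment,
  the principal transformation, and therefore always dominates the full
  match.
* **Stratification** by stereochemistry markers or reaction class, and
  **calibration** of the frequency-based confidence score against accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import chem
from .aggregate import CandidatePool, RankedPrediction


def _canonical_multiset(smiles: str) -> tuple[str, ...] | None:
    try:
        return tuple(sorted(chem.canonicalize(smiles).split(".")))
    except chem.SmilesParseError:
        return None


def seq_accuracy(pred: str, target: str) -> int:
    """1 iff prediction and target have equal canonical fragment multisets
    (order-insensitive); an unparsable prediction scores 0."""
    t = _canonical_multiset(target)
    if t is None:
        raise chem.SmilesParseError(f"invalid target SMILES: {target!r}")
    p = _canonical_multiset(pred)
    return int(p == t)


def _lcs_length(a: str, b: str) -> int:
    # O(len(a)*len(b)) dynamic program, one rolling row
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ca in a:
        cur = prev.copy()
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
            elif cur[j - 1] > cur[j]:
                cur[j] = cur[j - 1]
        prev = cur
    return int(prev[-1])


def char_accuracy(pred: str, target: str) -> float:
    """Percentage character-level agreement: 100 * LCS(pred, target) /
    len(target), on raw characters.

    The longest-common-subsequence definition scores insertions and
    deletions gracefully: a one-character shift of an otherwise identical
    string loses only the shifted character, so "CCCCN" against target
    "NCCCC" gives 4/5 = 80%.
    """
    if not target:
        raise ValueError("target must be non-empty")
    return 100.0 * _lcs_length(pred, target) / len(target)


def _maxfrag_or_none(smiles: str) -> str | None:
    try:
        return chem.largest_fragment(smiles)
    except chem.SmilesParseError:
        return None


def topn_accuracy(
    ranked_lists: Sequence[Sequence[RankedPrediction | str]],
    targets: Sequence[str],
    n: int = 1,
    mode: str = "full",
) -> float:
    """Percentage of test items whose recorded answer appears among the
    first ``n`` ranked predictions.

    ``full`` compares canonical fragment multisets of the whole precursor
    set; ``maxfrag`` compares only the largest fragment of prediction and
    target (classical retro-synthesis accuracy).  Ranked entries may be
    :class:`RankedPrediction` objects or plain SMILES strings; lists
    shorter than ``n`` are evaluated over what exists.
    """
    if len(ranked_lists) != len(targets):
        raise ValueError("one ranked list per target required")
    if mode not in ("full", "maxfrag"):
        raise ValueError(f"unknown mode {mode!r}")
    if not targets:
        return 0.0
    hits = 0
    for preds, target in zip(ranked_lists, targets):
        top = [p.canonical if isinstance(p, RankedPrediction) else p
               for p in list(preds)[:n]]
        if mode == "full":
            hit = any(seq_accuracy(p, target) for p in top)
        else:
            t = chem.largest_fragment(target)
            hit = any(_maxfrag_or_none(p) == t for p in top)
        hits += hit
    return 100.0 * hits / len(targets)


STEREO_MARKERS = ("@", "/", "\\")


def has_stereo(reaction_smiles: str) -> bool:
    """Any molecule in the reaction carries a stereo marker."""
    return any(m in reaction_smiles for m in STEREO_MARKERS)


@dataclass
class EvalItem:
    """One evaluated test reaction, ready for stratified summaries."""

    rxn_id: str
    target: str
    ranked: Sequence[RankedPrediction | str]
    reaction_smiles: str = ""
    rxn_class: int | None = None
    confidence: float | None = None  # top-1 frequency score


def stratify(
    items: Sequence[EvalItem],
    by: str = "stereo",
    n: int = 1,
    mode: str = "full",
) -> dict:
    """Top-n accuracy per stratum.

    ``stereo`` splits on the presence of stereo markers anywhere in the
    reaction; ``class`` uses the provided 1-10 labels.  Strata partition
    the items; with no labels present the class table is empty and flagged.
    """
    if by == "stereo":
        strata: dict[str, list[EvalItem]] = {"stereo": [], "no_stereo": []}
        for it in items:
            key = "stereo" if has_stereo(it.reaction_smiles or it.target) else "no_stereo"
            strata[key].append(it)
    elif by == "class":
        if all(it.rxn_class is None for it in items):
            return {"strata": {}, "no_labels": True}
        strata = {}
        for it in items:
            strata.setdefault(str(it.rxn_class), []).append(it)
    else:
        raise ValueError(f"unknown stratification {by!r}")
    table = {}
    for key, group in strata.items():
        table[key] = {
            "n_items": len(group),
            "topn": topn_accuracy([it.ranked for it in group],
                                  [it.target for it in group], n=n, mode=mode)
            if group else float("nan"),
        }
    return {"strata": table, "no_labels": False}


def calibration(
    items: Sequence[EvalItem],
    n_bins: int = 10,
    mode: str = "full",
) -> list[dict]:
    """Bin top-1 confidence into deciles; per bin report mean top-1
    accuracy and the fraction of test items falling in the bin (densities
    sum to 1).  Items without a confidence are excluded."""
    scored = [it for it in items if it.confidence is not None]
    if not scored:
        return []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    total = len(scored)
    for b in range(n_bins):
        lo, hi = float(edges[b]), float(edges[b + 1])
        in_bin = [it for it in scored
                  if (lo <= it.confidence < hi) or (b == n_bins - 1 and it.confidence == hi)]
        acc = (topn_accuracy([it.ranked for it in in_bin],
                             [it.target for it in in_bin], n=1, mode=mode)
               if in_bin else float("nan"))
        out.append({"lo": lo, "hi": hi, "n_items": len(in_bin),
                    "density": len(in_bin) / total, "accuracy": acc})
    return out


def invalid_rate(pools: Sequence[CandidatePool]) -> dict:
    """Fraction of decoded records that fail to parse, overall and per beam
    position."""
    by_pos: dict[int, list[int]] = {}
    n_records = 0
    n_invalid = 0
    for pool in pools:
        for rec in pool.records:
            n_records += 1
            bad = int(not rec.valid)
            n_invalid += bad
            by_pos.setdefault(rec.beam_position, []).append(bad)
    return {
        "overall": (n_invalid / n_records) if n_records else float("nan"),
        "by_beam_position": {
            pos: float(np.mean(flags)) for pos, flags in sorted(by_pos.items())
        },
        "n_records": n_records,
    }
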