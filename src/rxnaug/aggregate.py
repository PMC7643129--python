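"""Test-time augmentation inference: collect, deduplicate, rank.

A single product is decoded many times — once per augmented writing of its
SMILES, times the beam width — and every decoded sequence is canonicalized.
Different raw strings that denote the same molecule(s) collapse onto one
canonical answer, and the number of times an answer appears across the
augmented runs is the ranking signal: the frequency of the most common
canonical answer acts as a confidence score for the prediction.

Sequences that fail to parse carry no chemical vote: they are flagged
invalid and excluded from ranking (the denominator of the confidence is the
number of valid retained records, configurably the raw pool size instead).
Within one beam, later duplicates of an already-seen canonical form are
dropped by default — across different augmented inputs they are kept, being
exactly the signal the frequency ranking integrates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

from . import chem
from .augment import augment_test
from .predictor import SequenceModel, beam_search

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateRecord:
    """One raw decoded sequence for one test input."""

    raw: str
    aug_index: int
    beam_position: int
    logprob: float
    canonical: str | None  # None == invalid SMILES, excluded from ranking

    @property
    def valid(self) -> bool:
        return self.canonical is not None


@dataclass
class CandidatePool:
    """All decoded sequences for one test input."""

    records: list[CandidateRecord]
    n_aug: int = 1
    beam_size: int = 1
    source: str = ""

    @property
    def valid_records(self) -> list[CandidateRecord]:
        return [r for r in self.records if r.valid]


@dataclass(frozen=True)
class RankedPrediction:
    """A canonical answer with its appearance frequency and confidence."""

    canonical: str
    count: int
    confidence: float
    rank: int
    interval: tuple[float, float]


def _canonical_or_none(raw: str) -> str | None:
    try:
        return chem.canonicalize(raw)
    except chem.SmilesParseError:
        return None


def collect(
    model: SequenceModel,
    product: str,
    n_aug: int = 20,
    beam_size: int = 5,
    temperature: float = 1.0,
    seed: int = 0,
    max_len: int = 200,
) -> CandidatePool:
    """Decode all augmented writings of a product; pool capacity is
    ``n_aug * beam_size`` records, each tagged with its augmentation index
    and beam position.  Failure on one variant skips that variant."""
    if n_aug < 1 or beam_size < 1:
        raise ValueError("n_aug and beam_size must be >= 1")
    variants = augment_test([product], n_aug, seed=seed)[0]
    records: list[CandidateRecord] = []
    for aug_index, variant in enumerate(variants):
        try:
            candidates = beam_search(model, variant, beam_size=beam_size,
                                     temperature=temperature, max_len=max_len)
        except Exception:  # a failing variant is skipped, not fatal
            logger.warning("decoding failed for augmented variant %d of %r",
                           aug_index, product, exc_info=True)
            continue
        for cand in candidates:
            records.append(
                CandidateRecord(
                    raw=cand.text,
                    aug_index=aug_index,
                    beam_position=cand.beam_position,
                    logprob=cand.logprob,
                    canonical=_canonical_or_none(cand.text),
                )
            )
    return CandidatePool(records=records, n_aug=n_aug, beam_size=beam_size,
                         source=product)


def dedup_within_beam(pool: CandidatePool) -> CandidatePool:
    """Keep only the first occurrence (lowest beam position) of each
    canonical form within each augmented input's beam; duplicates across
    different augmentation indices are untouched.  Invalid records are kept
    (they are excluded from ranking anyway but remain countable)."""
    seen: set[tuple[int, str]] = set()
    retained = []
    for rec in sorted(pool.records, key=lambda r: (r.aug_index, r.beam_position)):
        if rec.valid:
            key = (rec.aug_index, rec.canonical)
            if key in seen:
                continue
            seen.add(key)
        retained.append(rec)
    return replace(pool, records=retained)


def rank(
    pool: CandidatePool,
    n: int | None = None,
    denominator: str = "valid",
    ci_alpha: float = 0.05,
) -> list[RankedPrediction]:
    """Group valid records by canonical form and rank by descending count.

    Ties break by best (highest) log probability then lexicographic
    canonical string, making the result independent of record order.
    Confidence is ``count / n_valid_retained`` (``denominator="pool"``
    divides by the raw pool size instead); the interval is the Wilson score
    interval at level ``1 - ci_alpha``.  An empty valid set yields an empty
    list.
    """
    valid = pool.valid_records
    if not valid:
        return []
    groups: dict[str, list[CandidateRecord]] = {}
    for rec in valid:
        groups.setdefault(rec.canonical, []).append(rec)
    total = len(valid) if denominator == "valid" else len(pool.records)
    keyed = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), -max(r.logprob for r in kv[1]), kv[0]),
    )
    if n is not None:
        keyed = keyed[:n]
    out = []
    for rank_pos, (canon, recs) in enumerate(keyed, start=1):
        count = len(recs)
        lo, hi = proportion_confint(count, total, alpha=ci_alpha, method="wilson")
        out.append(
            RankedPrediction(canonical=canon, count=count,
                             confidence=count / total, rank=rank_pos,
                             interval=(float(lo), float(hi)))
        )
    return out


def predict_ranked(
    model: SequenceModel,
    products: Sequence[str],
    n_aug: int = 20,
    beam_size: int = 5,
    temperature: float = 1.0,
    seed: int = 0,
    max_len: int = 200,
    dedup: bool = True,
    top: int | None = None,
) -> tuple[list[list[RankedPrediction]], list[CandidatePool]]:
    """End-to-end inference for a batch of products: collect, optionally
    dedup within beams, rank.  Returns the ranked lists and the raw pools
    (for invalid-rate audits)."""
    ranked, pools = [], []
    for product in products:
        pool = collect(model, product, n_aug=n_aug, beam_size=beam_size,
                       temperature=temperature, seed=seed, max_len=max_len)
        pools.append(pool)
        ranked.append(rank(dedup_within_beam(pool) if dedup else pool, n=top))
    return ranked, pools


def write_predictions_tsv(
    ranked_lists: Sequence[Sequence[RankedPrediction]],
    rxn_ids: Sequence[str],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rxn_id", "rank", "canonical_smiles", "count",
                         "confidence", "conf_lo", "conf_hi"])
        for rxn_id, preds in zip(rxn_ids, ranked_lists):
            for p in preds:
                writer.writerow([rxn_id, p.rank, p.canonical, p.count,
                                 f"{p.confidence:.6f}",
                                 f"{p.interval[0]:.6f}", f"{p.interval[1]:.6f}"])
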