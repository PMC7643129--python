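"""Training- and test-set augmentation protocols.

Each protocol multiplies every reaction into ``n`` source→target pairs built
from random SMILES writings of the molecules (random root atom and traversal
direction).  The protocols, in increasing order of perturbation:

========  ===================================================================
``x1``    canonical pair only (``xN`` with n=1)
``xN``    sources (products) randomized; target stays canonical
``xNF``   sources and every target fragment randomized (order kept)
``xNS``   as ``xNF`` plus a uniform random shuffle of target fragment order
``xNM``   each ``xNS`` retro pair followed by its forward twin (dot-marked),
          giving 2n pairs per reaction
``xNR``   target frozen to ONE random writing per reaction, reused verbatim
          in all n pairs (probes pure memorization)
========  ===================================================================

Every protocol except ``xNR`` emits the fully canonical pair first, so at
least one canonical copy of each reaction is always present.  Sub-seeds are
derived per reaction from ``(seed, rxn_id)`` so augmentation is stable under
dataset reordering.  Test-time augmentation uses only the simplest scheme:
canonical plus ``n-1`` random writings of the product.
"""

from __future__ import annotations

import csv
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import chem
from .reactions import (
    DIRECT_MARK,
    Reaction,
    RetroTarget,
    SeqPair,
    UntrainableReactionError,
    to_pair,
)

logger = logging.getLogger(__name__)

PROTOCOLS = ("x1", "xN", "xNF", "xNS", "xNM", "xNR")


@dataclass(frozen=True)
class AugProtocol:
    """An augmentation recipe: protocol name, multiplicity n, master seed."""

    name: str
    n: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.name not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.name!r}; use one of {PROTOCOLS}")
        if self.n < 1:
            raise ValueError("augmentation multiplicity n must be >= 1")


def subseed(seed: int, rxn_id: str) -> int:
    """Stable per-reaction sub-seed below 2**31."""
    return (int(seed) ^ zlib.crc32(rxn_id.encode())) % (2**31)


def _rng_for(rxn: Reaction, seed: int) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, rxn.rxn_id))


def _random_source(pair: SeqPair, rng: np.random.Generator) -> str:
    return chem.randomize(pair.source, rng)


def _random_target_fragments(pair: SeqPair, rng: np.random.Generator) -> list[str]:
    return [chem.randomize(f, rng) for f in pair.target.split(".")]


def _tag(pair: SeqPair, protocol: str, aug_index: int, canonical: bool,
         source: str | None = None, target: str | None = None) -> SeqPair:
    return SeqPair(
        source=pair.source if source is None else source,
        target=pair.target if target is None else target,
        direction=pair.direction,
        rxn_id=pair.rxn_id,
        is_canonical_pair=canonical,
        aug_index=aug_index,
        protocol=protocol,
    )


def augment_xN(rxn: Reaction, n: int, seed: int = 0,
               retro_target: RetroTarget = "all_precursors") -> list[SeqPair]:
    """Products-only augmentation: random sources, canonical target."""
    rng = _rng_for(rxn, seed)
    base = to_pair(rxn, "retro", retro_target=retro_target)
    out = [_tag(base, "xN", 0, True)]
    for i in range(1, n):
        out.append(_tag(base, "xN", i, False, source=_random_source(base, rng)))
    return out


def augment_xNF(rxn: Reaction, n: int, seed: int = 0,
                retro_target: RetroTarget = "all_precursors",
                _protocol: str = "xNF", _shuffle: bool = False) -> list[SeqPair]:
    """Full augmentation: sources and target fragments randomized
    independently; target fragment order unchanged (unless shuffling is
    layered on by :func:`augment_xNS`)."""
    rng = _rng_for(rxn, seed)
    base = to_pair(rxn, "retro", retro_target=retro_target)
    out = [_tag(base, _protocol, 0, True)]
    for i in range(1, n):
        src = _random_source(base, rng)
        frags = _random_target_fragments(base, rng)
        if _shuffle and len(frags) > 1:  # no RNG draw for 1 fragment: keeps
            frags = [frags[j] for j in rng.permutation(len(frags))]  # xNS==xNF there
        out.append(_tag(base, _protocol, i, False, source=src, target=".".join(frags)))
    return out


def augment_xNS(rxn: Reaction, n: int, seed: int = 0,
                retro_target: RetroTarget = "all_precursors") -> list[SeqPair]:
    """Full augmentation plus uniform random shuffling of target fragment
    order (reactants and reagents alike)."""
    return augment_xNF(rxn, n, seed, retro_target, _protocol="xNS", _shuffle=True)


def augment_xNM(rxn: Reaction, n: int, seed: int = 0,
                retro_target: RetroTarget = "all_precursors") -> list[SeqPair]:
    """Mixed retro/forward augmentation: every ``xNS`` retro pair is
    immediately followed by the inverse (forward) pair whose source carries
    the leading-dot marker.  2n pairs per reaction."""
    retro_pairs = augment_xNS(rxn, n, seed, retro_target)
    out = []
    for p in retro_pairs:
        out.append(_tag(p, "xNM", p.aug_index, p.is_canonical_pair))
        fwd = SeqPair(
            source=DIRECT_MARK + p.target,
            target=p.source,
            direction="direct",
            rxn_id=p.rxn_id,
            is_canonical_pair=False,
            aug_index=p.aug_index,
            protocol="xNM",
        )
        out.append(fwd)
    return out


def augment_xNR(rxn: Reaction, n: int, seed: int = 0,
                retro_target: RetroTarget = "all_precursors") -> list[SeqPair]:
    """Fixed-random-target augmentation: one random writing of the target is
    drawn per reaction and reused verbatim in all n pairs (so no canonical
    pair is guaranteed)."""
    rng = _rng_for(rxn, seed)
    base = to_pair(rxn, "retro", retro_target=retro_target)
    frozen = ".".join(_random_target_fragments(base, rng))
    out = [_tag(base, "xNR", 0, False, target=frozen)]
    for i in range(1, n):
        out.append(_tag(base, "xNR", i, False,
                        source=_random_source(base, rng), target=frozen))
    return out


_AUGMENTERS = {
    "x1": augment_xN,
    "xN": augment_xN,
    "xNF": augment_xNF,
    "xNS": augment_xNS,
    "xNM": augment_xNM,
    "xNR": augment_xNR,
}


@dataclass
class AugmentedDataset:
    """Ordered augmented pairs plus bookkeeping of skipped reactions."""

    pairs: list[SeqPair]
    protocol: AugProtocol
    n_reactions: int
    n_skipped: int = 0


def augment_dataset(
    rxns: Iterable[Reaction],
    protocol: AugProtocol,
    retro_target: RetroTarget = "all_precursors",
) -> AugmentedDataset:
    """Apply a protocol to every reaction.

    Invalid or untrainable reactions are skipped with a logged warning and
    counted, never raised.  ``|pairs| == n * R`` (``2n * R`` for xNM) over
    the R reactions kept.
    """
    n = 1 if protocol.name == "x1" else protocol.n
    fn = _AUGMENTERS[protocol.name]
    pairs: list[SeqPair] = []
    kept = 0
    skipped = 0
    for rxn in rxns:
        if not rxn.is_valid:
            logger.warning("skipping reaction %r: invalid SMILES", rxn.rxn_id)
            skipped += 1
            continue
        try:
            pairs.extend(fn(rxn, n, protocol.seed, retro_target=retro_target))
        except UntrainableReactionError as exc:
            logger.warning("skipping reaction %r: %s", rxn.rxn_id, exc)
            skipped += 1
            continue
        kept += 1
    return AugmentedDataset(pairs=pairs, protocol=protocol,
                            n_reactions=kept, n_skipped=skipped)


def augment_test(products: Sequence[str], n: int, seed: int = 0) -> list[list[str]]:
    """Test-time augmentation: per product, ``[canonical, n-1 random]``
    source strings (the simple products-only scheme)."""
    out = []
    for i, smiles in enumerate(products):
        rng = np.random.default_rng(subseed(seed, f"test-{i}-{smiles}"))
        canon = chem.canonicalize(smiles)
        variants = [canon]
        for _ in range(n - 1):
            variants.append(chem.randomize(canon, rng))
        out.append(variants)
    return out


def write_pair_files(
    dataset: AugmentedDataset,
    src_path: str | Path,
    tgt_path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write line-aligned ``src``/``tgt`` files and an optional manifest TSV
    (rxn_id, protocol, aug_index, direction, is_canonical_pair)."""
    with open(src_path, "w") as fs, open(tgt_path, "w") as ft:
        for p in dataset.pairs:
            fs.write(p.source + "\n")
            ft.write(p.target + "\n")
    if manifest_path is None:
        return
    with open(manifest_path, "w", newline="") as fm:
        writer = csv.writer(fm, delimiter="\t", lineterminator="\n")
        writer.writerow(["rxn_id", "protocol", "aug_index", "direction",
                         "is_canonical_pair"])
        for p in dataset.pairs:
            writer.writerow([p.rxn_id, p.protocol, p.aug_index, p.direction,
                             int(p.is_canonical_pair)])
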