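"""Reaction SMILES parsing, representation and sequence-pair emission.

Two textual reaction dialects are supported:

* **separated** — ``reactants>reagents>products``: reagents (catalysts,
  solvents, bases...) are kept apart from reactants by the ``>`` signs;
* **mixed** — ``precursors>>products`` with every precursor dot-joined on
  the left: the reactant/reagent distinction is erased, which reflects the
  practical setting where that separation is unknown without knowing the
  product.

A :class:`Reaction` can be turned into a source→target :class:`SeqPair` for
a sequence model in either direction.  For the retro direction the target is
either every precursor or only the largest one (the principal transformation);
for the direct direction an optional leading-dot marker distinguishes forward
pairs inside mixed training sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from . import chem
from .chem import MoleculeString, SmilesParseError

Direction = Literal["retro", "direct"]
Format = Literal["separated", "mixed"]
RetroTarget = Literal["all_precursors", "largest_only"]

DIRECT_MARK = "."


class ReactionFormatError(ValueError):
    """Malformed reaction line (wrong arrow structure)."""


@dataclass
class Reaction:
    """One reaction: reactant/reagent/product molecule lists plus metadata."""

    reactants: list[MoleculeString]
    reagents: list[MoleculeString]
    products: list[MoleculeString]
    rxn_id: str = ""
    rxn_class: int | None = None

    @property
    def precursors(self) -> list[MoleculeString]:
        return self.reactants + self.reagents

    @property
    def is_trainable(self) -> bool:
        return len(self.products) >= 1 and len(self.reactants) >= 1

    @property
    def is_valid(self) -> bool:
        return all(
            m.valid for m in self.reactants + self.reagents + self.products
        )

    def canonical_fragments(self, role: str) -> list[str]:
        """Sorted canonical fragment list for ``reactants``/``reagents``/
        ``products``/``precursors`` (multiset comparison helper)."""
        mols = getattr(self, role)
        return sorted(m.canonical for m in mols)


@dataclass(frozen=True)
class SeqPair:
    """A single source→target example for a sequence model."""

    source: str
    target: str
    direction: Direction
    rxn_id: str = ""
    is_canonical_pair: bool = False
    aug_index: int = 0
    protocol: str = ""


def _mols(chunk: str) -> list[MoleculeString]:
    if not chunk:
        return []
    return [MoleculeString.from_smiles(f) for f in chunk.split(".")]


def parse_reaction(
    line: str,
    format: Format = "separated",
    rxn_id: str = "",
    rxn_class: int | None = None,
) -> Reaction:
    """Parse one reaction SMILES line.

    Separated lines must contain exactly two ``>`` delimiters
    (``A>B>C``).  Mixed lines use ``A>>C`` with all precursors dot-joined
    in A; the parsed reaction then has an empty reagent list.
    """
    parts = line.strip().split(">")
    if len(parts) != 3:
        raise ReactionFormatError(
            f"expected 'reactants>reagents>products' with two '>' signs, "
            f"got {line!r}"
        )
    left, middle, right = parts
    if format == "mixed":
        if middle:
            raise ReactionFormatError(
                f"mixed-format line must use '>>' (empty reagent slot): {line!r}"
            )
        return Reaction(
            reactants=_mols(left), reagents=[], products=_mols(right),
            rxn_id=rxn_id, rxn_class=rxn_class,
        )
    return Reaction(
        reactants=_mols(left), reagents=_mols(middle), products=_mols(right),
        rxn_id=rxn_id, rxn_class=rxn_class,
    )


def serialize_reaction(rxn: Reaction, format: Format = "separated") -> str:
    """Deterministic reaction SMILES (canonical fragments, sorted order)."""
    prods = ".".join(rxn.canonical_fragments("products"))
    if format == "mixed":
        return f"{'.'.join(rxn.canonical_fragments('precursors'))}>>{prods}"
    return (
        f"{'.'.join(rxn.canonical_fragments('reactants'))}>"
        f"{'.'.join(rxn.canonical_fragments('reagents'))}>{prods}"
    )


class UntrainableReactionError(ValueError):
    """Reaction lacks the roles needed to form a training pair."""


def _dotted(mols: list[MoleculeString]) -> str:
    # Atom maps are stripped: the model-facing text representation carries
    # no mapping annotations.
    return ".".join(sorted(chem.strip_atom_maps(m.smiles) for m in mols))


def to_pair(
    rxn: Reaction,
    direction: Direction,
    format: Format = "mixed",
    mark_direct: bool = False,
    retro_target: RetroTarget = "all_precursors",
) -> SeqPair:
    """Canonical source→target pair for one reaction.

    retro:  source = dotted products, target = precursors (all, or the
    largest fragment only).  direct: source = precursors (``>``-separated
    or dotted per *format*), target = dotted products; ``mark_direct``
    prepends the leading-dot marker to the source so mixed forward/retro
    training sets stay distinguishable.
    """
    if not rxn.products:
        raise UntrainableReactionError(f"reaction {rxn.rxn_id!r} has no products")
    prods = _dotted(rxn.products)
    if direction == "retro":
        if not rxn.precursors:
            raise UntrainableReactionError(
                f"reaction {rxn.rxn_id!r} has no precursors"
            )
        tgt = _dotted(rxn.precursors)
        if retro_target == "largest_only":
            tgt = chem.largest_fragment(tgt)
        return SeqPair(source=prods, target=tgt, direction="retro",
                       rxn_id=rxn.rxn_id, is_canonical_pair=True)
    if not rxn.precursors:
        raise UntrainableReactionError(f"reaction {rxn.rxn_id!r} has no precursors")
    if format == "separated":
        src = f"{_dotted(rxn.reactants)}>{_dotted(rxn.reagents)}"
    else:
        src = _dotted(rxn.precursors)
    if mark_direct:
        src = DIRECT_MARK + src
    return SeqPair(source=src, target=prods, direction="direct",
                   rxn_id=rxn.rxn_id, is_canonical_pair=True)


# ---------------------------------------------------------------------------
# Reaction TSV I/O


def read_reactions_tsv(path: str | Path, format: Format = "separated") -> list[Reaction]:
    """Read a reaction table: columns ``rxn_id``, ``reaction_smiles``,
    optional ``class``."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            cls = row.get("class")
            out.append(
                parse_reaction(
                    row["reaction_smiles"],
                    format=format,
                    rxn_id=row.get("rxn_id", str(i)),
                    rxn_class=int(cls) if cls not in (None, "") else None,
                )
            )
    return out


def write_reactions_tsv(
    rxns: Iterable[Reaction], path: str | Path, format: Format = "separated"
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rxn_id", "reaction_smiles", "class"])
        for rxn in rxns:
            writer.writerow(
                [
                    rxn.rxn_id,
                    serialize_reaction(rxn, format=format),
                    "" if rxn.rxn_class is None else rxn.rxn_class,
                ]
            )
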