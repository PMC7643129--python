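"""Dataset hygiene for patent-derived reaction corpora.

Patent reaction sets (USPTO-style extractions) contain records that are not
learnable reactions: empty sides, bare counter-ions as the whole reactant
side, or trivial products a couple of characters long.  This module provides
the standard clean-up steps:

* :func:`split_multiproduct` — duplicate multi-product records into
  single-product reactions;
* :func:`filter_reactions` — drop no-product / single-ion-reactant /
  short-product / tiny-reactant-side records, each removal tagged with the
  rule that fired;
* :func:`classify_reaction_role` — categorize mapped reactions by how their
  precursors contribute atoms to the product (non-reagent, one reagent,
  multiple reagent, unclear reagent).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from . import chem
from .reactions import Reaction

# removal rule tags
NO_PRODUCTS = "no_products"
NO_REACTANTS = "no_reactants"
SINGLE_ION = "single_ion_reactants"
SHORT_PRODUCT = "short_product"
FEW_REACTANT_ATOMS = "few_reactant_atoms"


def split_multiproduct(rxns: Iterable[Reaction]) -> list[Reaction]:
    """Duplicate each multi-product reaction into one reaction per product.

    Precursor roles and metadata are copied; derived ids get a ``.k``
    suffix.  Total product count is conserved.
    """
    out = []
    for rxn in rxns:
        if len(rxn.products) <= 1:
            out.append(rxn)
            continue
        for k, prod in enumerate(rxn.products):
            out.append(replace(rxn, products=[prod],
                               rxn_id=f"{rxn.rxn_id}.{k}" if rxn.rxn_id else ""))
    return out


def _is_single_ion_side(rxn: Reaction, max_heavy_atoms: int = 2) -> bool:
    """Reactant side is one charged fragment of <= max_heavy_atoms atoms
    (e.g. ``[I-]``, ``[K+]``) — not a real starting material."""
    if len(rxn.reactants) != 1 or rxn.reagents:
        return False
    m = rxn.reactants[0]
    if not m.valid or m.heavy_atoms > max_heavy_atoms:
        return False
    mol = Chem.MolFromSmiles(m.smiles)
    return Chem.GetFormalCharge(mol) != 0


def _largest_product_length(rxn: Reaction) -> int:
    """Character length of the largest product, on the canonical mapless
    string (map tokens would inflate the length arbitrarily)."""
    valid = [m.canonical for m in rxn.products if m.valid]
    if not valid:
        return 0
    return len(chem.strip_atom_maps(chem.largest_fragment(".".join(valid))))


@dataclass
class FilterReport:
    kept: list[Reaction]
    removed: list[tuple[Reaction, str]]

    @property
    def removal_reasons(self) -> list[str]:
        return [rule for _, rule in self.removed]


def filter_reactions(
    rxns: Iterable[Reaction],
    min_product_chars: int = 5,
    min_reactant_atoms: int = 5,
    single_ion_max_atoms: int = 2,
) -> FilterReport:
    """Apply the hygiene filters; returns kept reactions and removals
    tagged with the first rule that fired.

    Rules (checked in a fixed order; the rules are mutually independent so
    the kept set does not depend on the order):

    a. no products;
    b. reactant side missing, or a single small ion;
    c. largest product's canonical SMILES shorter than ``min_product_chars``;
    d. reactants total fewer than ``min_reactant_atoms`` heavy atoms.
    """
    kept: list[Reaction] = []
    removed: list[tuple[Reaction, str]] = []
    for rxn in rxns:
        if not rxn.products:
            removed.append((rxn, NO_PRODUCTS))
        elif not rxn.reactants:
            removed.append((rxn, NO_REACTANTS))
        elif _is_single_ion_side(rxn, single_ion_max_atoms):
            removed.append((rxn, SINGLE_ION))
        elif _largest_product_length(rxn) < min_product_chars:
            removed.append((rxn, SHORT_PRODUCT))
        elif sum(m.heavy_atoms or 0 for m in rxn.reactants) < min_reactant_atoms:
            removed.append((rxn, FEW_REACTANT_ATOMS))
        else:
            kept.append(rxn)
    return FilterReport(kept=kept, removed=removed)


def write_removal_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rxn_id", "rule"])
        for rxn, rule in report.removed:
            writer.writerow([rxn.rxn_id, rule])


# ---------------------------------------------------------------------------
# Reaction-role categories

NON_REAGENT = "non_reagent"
ONE_REAGENT = "one_reagent"
MULTIPLE_REAGENT = "multiple_reagent"
UNCLEAR_REAGENT = "unclear_reagent"
UNKNOWN = "unknown"


def _map_numbers(smiles: str) -> set[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return set()
    return {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}


def classify_reaction_role(rxn: Reaction) -> str:
    """Categorize a mapped reaction by precursor participation.

    * ``non_reagent`` — a product is identical to one of the precursors
      (A + B -> A: the reaction did not happen);
    * ``one_reagent`` — a single precursor supplies all mapped product
      atoms (A -> P);
    * ``multiple_reagent`` — several precursors contribute and every one
      of them does (A + B -> P);
    * ``unclear_reagent`` — at least one precursor contributes no mapped
      atom to the product (A + B + N -> P: N is conditions/solvent/salt).

    Requires atom maps on both sides; without them returns ``unknown``
    rather than guessing from substructure.
    """
    precursors = rxn.precursors
    if not precursors or not rxn.products:
        return UNKNOWN
    prod_canon = {chem.strip_atom_maps(m.smiles) for m in rxn.products if m.valid}
    if any(m.valid and chem.strip_atom_maps(m.smiles) in prod_canon
           for m in precursors):
        return NON_REAGENT

    prod_maps: set[int] = set()
    for m in rxn.products:
        prod_maps |= _map_numbers(m.smiles)
    if not prod_maps:
        return UNKNOWN
    contrib = [bool(_map_numbers(m.smiles) & prod_maps) for m in precursors]
    if not any(contrib):
        return UNKNOWN
    if not all(contrib):
        return UNCLEAR_REAGENT
    return ONE_REAGENT if len(precursors) == 1 else MULTIPLE_REAGENT


def role_census(rxns: Sequence[Reaction]) -> dict[str, int]:
    """Counts of each reaction-role category over a dataset."""
    counts = {k: 0 for k in
              (NON_REAGENT, ONE_REAGENT, MULTIPLE_REAGENT, UNCLEAR_REAGENT, UNKNOWN)}
    for rxn in rxns:
        counts[classify_reaction_role(rxn)] += 1
    return counts
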