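"""Molecule-level SMILES operations.

Canonicalization, seeded randomization (random root atom and traversal
direction) and fragment handling.  All chemistry goes through RDKit; this
module only fixes the conventions the rest of the toolkit relies on:

* multi-fragment (dot-separated) strings are canonicalized fragment-wise and
  re-joined in a deterministic order (descending heavy-atom count, then
  lexicographic), so that downstream comparisons are insensitive to the
  order reactants were written in;
* "largest fragment" means most heavy atoms, ties broken by longer canonical
  string then lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

# RDKit warns loudly on every unparsable candidate SMILES; decoded model
# output is routinely invalid, so keep the error log quiet.
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not parse to a chemical graph."""


@dataclass(frozen=True)
class MoleculeString:
    """A SMILES string together with its parse status.

    Attributes
    ----------
    smiles : str
        The string as given.
    valid : bool
        Whether it parses under RDKit sanitization.
    canonical : str | None
        Canonical SMILES (fragment-ordered for dotted input); ``None`` when
        invalid.
    heavy_atoms : int | None
        Number of non-hydrogen atoms; ``None`` when invalid.
    """

    smiles: str
    valid: bool
    canonical: str | None
    heavy_atoms: int | None

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeString":
        try:
            canon = canonicalize(smiles)
        except SmilesParseError:
            return cls(smiles=smiles, valid=False, canonical=None, heavy_atoms=None)
        n = sum(heavy_atom_count(f) for f in canon.split("."))
        return cls(smiles=smiles, valid=True, canonical=canon, heavy_atoms=n)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in a (single- or multi-fragment) SMILES."""
    return _mol_from_smiles(smiles).GetNumHeavyAtoms()


def strip_atom_maps(smiles: str) -> str:
    """Remove atom-map annotations, returning the canonical mapless SMILES."""
    mol = _mol_from_smiles(smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _fragment_sort_key(canonical_fragment: str) -> tuple:
    n = heavy_atom_count(canonical_fragment)
    return (-n, -len(canonical_fragment), canonical_fragment)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES of a molecule or dotted fragment list.

    Fragments are canonicalized individually and re-joined sorted by
    (descending heavy-atom count, descending string length, lexicographic),
    making the result independent of the order fragments were written in.

    Raises
    ------
    SmilesParseError
        If the input is empty or any fragment fails to parse.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    frags = smiles.split(".")
    canon = []
    for i, frag in enumerate(frags):
        try:
            canon.append(Chem.MolToSmiles(_mol_from_smiles(frag)))
        except SmilesParseError:
            raise SmilesParseError(
                f"unparsable fragment {i} ({frag!r}) in {smiles!r}"
            ) from None
    if len(canon) == 1:
        return canon[0]
    return ".".join(sorted(canon, key=_fragment_sort_key))


def is_valid(smiles: str) -> bool:
    """True if every dot-separated fragment parses under sanitization."""
    try:
        canonicalize(smiles)
        return True
    except SmilesParseError:
        return False


def randomize(smiles: str, rng: np.random.Generator | int) -> str:
    """A random, valid SMILES of the same molecule.

    The atom order is permuted uniformly at random before writing a
    non-canonical SMILES, which randomizes both the root atom and the
    traversal direction.  Dotted inputs are randomized fragment-wise with
    fragment order preserved.  Deterministic given the generator state; no
    global random state is touched.

    Parameters
    ----------
    rng : numpy.random.Generator or int
        Seeded generator (or a seed to build one from).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    parts = []
    for frag in smiles.split("."):
        mol = _mol_from_smiles(frag)
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        shuffled = Chem.RenumberAtoms(mol, perm)
        parts.append(Chem.MolToSmiles(shuffled, canonical=False))
    return ".".join(parts)


def largest_fragment(dotted_smiles: str) -> str:
    """Canonical SMILES of the fragment with the most heavy atoms.

    Ties are broken toward the longer canonical string, then
    lexicographically — the same key that orders fragments in
    :func:`canonicalize`, so ``largest_fragment(canonicalize(s))`` is the
    first fragment of the canonical form.
    """
    if not dotted_smiles:
        raise SmilesParseError("empty SMILES string")
    best = None
    for i, frag in enumerate(dotted_smiles.split(".")):
        try:
            canon = Chem.MolToSmiles(_mol_from_smiles(frag))
        except SmilesParseError:
            raise SmilesParseError(
                f"unparsable fragment {i} ({frag!r}) in {dotted_smiles!r}"
            ) from None
        key = _fragment_sort_key(canon)
        if best is None or key < best[0]:
            best = (key, canon)
    return best[1]


def enumerate_rooted_smiles(smiles: str) -> set[str]:
    """All atom-rooted non-canonical writings of a molecule.

    Brute-force enumeration over every root atom and both traversal
    directions (via atom-order reversal).  Used as an oracle for
    :func:`randomize`; feasible only for small molecules.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    out: set[str] = set()
    orders = [list(range(n)), list(reversed(range(n)))]
    for order in orders:
        m = Chem.RenumberAtoms(mol, order)
        for root in range(n):
            out.add(Chem.MolToSmiles(m, canonical=False, rootedAtAtom=root))
    return out
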