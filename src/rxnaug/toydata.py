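"""Synthetic reaction grammar for desk-scale, ground-truth-known datasets.

Reactions are generated from four string-rewrite condensation templates on
randomly built acyclic alkyl scaffolds:

=====  ==============================  =================================
class  template                        product
=====  ==============================  =================================
1      esterification                  ``R1-C(=O)O`` + ``O-R2`` → ester
2      amide coupling                  ``R1-C(=O)O`` + ``N-R2`` → amide
3      Williamson ether                ``R1-Br`` + ``O-R2`` → ether
4      halide amination                ``R1-Cl`` + ``N-R2`` → amine
=====  ==============================  =================================

Because the scaffolds contain only carbon skeletons, each product is
reachable from its precursors by exactly one template, and the template's
precursors are the unique ground-truth retro answer.  Optional features
emulate the statistical structure of patent-derived sets: spectator
molecules (salts/solvents contributing no atoms, i.e. "unclear reagent"
records), a stereocenter subset, per-template class labels, and atom maps
derived from the known atom correspondence of each template.

The grammar trades chemical realism for constructive validity: templates
are string rewrites on scaffolds built to concatenate into valid SMILES,
so every generated reaction parses and the generator can serve as an exact
oracle for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import chem
from .reactions import Reaction, MoleculeString


class CapacityError(ValueError):
    """The fragment alphabet cannot supply the requested diversity."""


@dataclass(frozen=True)
class Template:
    name: str
    class_label: int
    a_group: str   # functional suffix of reactant A (appended to R1)
    b_head: str    # heteroatom head of reactant B (prepended to R2)
    joiner: str    # text between R1 and R2 in the product
    a_drop_last: bool   # A's last atom leaves (OH of acid / halide)
    b_drop_first: bool  # B's first atom leaves (alcohol O in esterification)


TEMPLATES = (
    Template("esterification", 1, "C(=O)O", "O", "C(=O)O", False, True),
    Template("amide_coupling", 2, "C(=O)O", "N", "C(=O)N", True, False),
    Template("williamson_ether", 3, "Br", "O", "O", True, False),
    Template("halide_amination", 4, "Cl", "N", "N", True, False),
)

SPECTATORS = ("[Na+]", "[Cl-]", "CC#N", "CS(C)=O", "CCOCC")

STEREO_UNIT = "[C@@H](OC)"  # inserted after R1; methoxy branch keeps the
                            # four substituents distinct in every template


@dataclass
class ToyGrammar:
    """Generation parameters: scaffold sizes, spectator and stereo rates.

    ``spectator_p`` is the probability that a reaction carries one
    non-participating reagent (default 0.1, the "unclear reagent" share
    reported for large patent corpora); ``stereo_p`` the probability of a
    stereocenter on the acid/halide scaffold (default 0.2, the stereo share
    of a typical retrosynthesis benchmark test set).
    """

    min_chain: int = 1
    max_chain: int = 6
    branch_p: float = 0.3
    spectator_p: float = 0.1
    stereo_p: float = 0.2
    with_atom_maps: bool = True
    spectator_pool: tuple[str, ...] = SPECTATORS
    seed: int = 0


def _random_scaffold(rng: np.random.Generator, g: ToyGrammar) -> str:
    """Random acyclic alkyl string valid both as prefix and suffix."""
    n = int(rng.integers(g.min_chain, g.max_chain + 1))
    parts = []
    for i in range(n):
        parts.append("C")
        if 0 < i < n - 1 and rng.random() < g.branch_p:
            parts.append("(C)")
    return "".join(parts)


def _mapped(smiles: str, maps: list[int]) -> str:
    """SMILES with per-atom map numbers (0 = unmapped) set by parse order."""
    mol = Chem.MolFromSmiles(smiles)
    for atom, m in zip(mol.GetAtoms(), maps):
        atom.SetAtomMapNum(m)
    return Chem.MolToSmiles(mol)


def _build_reaction(
    tpl: Template, r1: str, r2: str, stereo: bool,
    spectators: tuple[str, ...], rxn_id: str, with_maps: bool,
) -> Reaction | None:
    r1s = r1 + STEREO_UNIT if stereo else r1
    a = r1s + tpl.a_group
    b = tpl.b_head + r2
    product = r1s + tpl.joiner + r2
    if stereo and "@" not in chem.canonicalize(product):
        return None  # degenerate stereocenter (symmetric substituents)
    if with_maps:
        n_a = chem.heavy_atom_count(a)
        n_b = chem.heavy_atom_count(b)
        k_a = n_a - 1 if tpl.a_drop_last else n_a   # A atoms kept in product
        b0 = 1 if tpl.b_drop_first else 0           # first kept B atom
        a_maps = [i + 1 for i in range(k_a)] + [0] * (n_a - k_a)
        b_maps = [0] * b0 + [k_a + 1 + j for j in range(n_b - b0)]
        p_maps = list(range(1, k_a + (n_b - b0) + 1))
        a, b = _mapped(a, a_maps), _mapped(b, b_maps)
        product = _mapped(product, p_maps)
    return Reaction(
        reactants=[MoleculeString.from_smiles(a), MoleculeString.from_smiles(b)],
        reagents=[MoleculeString.from_smiles(s) for s in spectators],
        products=[MoleculeString.from_smiles(product)],
        rxn_id=rxn_id,
        rxn_class=tpl.class_label,
    )


def generate(
    grammar: ToyGrammar | None = None,
    n_reactions: int = 100,
    seed: int | None = None,
) -> list[Reaction]:
    """Generate ``n_reactions`` distinct reactions, reproducibly.

    Distinctness is by (template, scaffolds, stereo); raises
    :class:`CapacityError` when the alphabet cannot supply the requested
    diversity within a bounded number of draws.
    """
    g = grammar or ToyGrammar()
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    rng = np.random.default_rng(g.seed if seed is None else seed)
    out: list[Reaction] = []
    seen: set[tuple] = set()
    attempts = 0
    max_attempts = 200 * n_reactions + 1000
    while len(out) < n_reactions:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not draw {n_reactions} distinct reactions in "
                f"{max_attempts} attempts; enlarge the scaffold alphabet"
            )
        tpl = TEMPLATES[int(rng.integers(len(TEMPLATES)))]
        r1 = _random_scaffold(rng, g)
        r2 = _random_scaffold(rng, g)
        stereo = bool(rng.random() < g.stereo_p)
        key = (tpl.name, r1, r2, stereo)
        if key in seen:
            continue
        spectators = ()
        if rng.random() < g.spectator_p:
            spectators = (g.spectator_pool[int(rng.integers(len(g.spectator_pool)))],)
        rxn = _build_reaction(tpl, r1, r2, stereo, spectators,
                              rxn_id=f"toy-{len(out):06d}", with_maps=g.with_atom_maps)
        if rxn is None:
            continue
        seen.add(key)
        out.append(rxn)
    return out


def train_test_split(
    rxns: list[Reaction], test_fraction: float = 0.1, seed: int = 0
) -> tuple[list[Reaction], list[Reaction]]:
    """Split with train and test disjoint by canonical product."""
    groups: dict[str, list[Reaction]] = {}
    for rxn in rxns:
        key = ".".join(rxn.canonical_fragments("products"))
        groups.setdefault(key, []).append(rxn)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_test = max(1, int(round(test_fraction * len(keys))))
    test_keys = set(keys[:n_test])
    train = [r for k in keys[n_test:] for r in groups[k]]
    test = [r for k in test_keys for r in groups[k]]
    return train, test


def ground_truth_answer(rxn: Reaction) -> str:
    """Canonical dotted precursor string — the known retro answer."""
    return ".".join(sorted(chem.strip_atom_maps(m.smiles)
                           for m in rxn.precursors))


def oracle_predictions(rxns: list[Reaction]) -> list[list[str]]:
    """A cheating predictor built from the generator's ground truth: one
    correct answer per reaction.  Fixed point for the metrics suite (100%
    top-1 by construction)."""
    return [[ground_truth_answer(r)] for r in rxns]
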