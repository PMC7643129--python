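import pytest

from rxnaug import chem
from rxnaug.toydata import ToyGrammar, generate


@pytest.fixture(scope="session")
def toy_reactions():
    """200 synthetic reactions with atom maps, spectators and stereo."""
    return generate(ToyGrammar(), n_reactions=200, seed=123)


@pytest.fixture(scope="session")
def toy_molecules(toy_reactions):
    """Deduplicated mapless SMILES of every molecule in the toy set."""
    smiles = set()
    for rxn in toy_reactions:
        for m in rxn.reactants + rxn.reagents + rxn.products:
            smiles.add(chem.strip_atom_maps(m.smiles))
    return sorted(smiles)
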