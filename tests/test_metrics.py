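import itertools

import numpy as np
import pytest

from rxnaug import chem
from rxnaug.aggregate import CandidatePool, CandidateRecord
from rxnaug.metrics import (
    EvalItem,
    _lcs_length,
    calibration,
    char_accuracy,
    has_stereo,
    invalid_rate,
    seq_accuracy,
    stratify,
    topn_accuracy,
)
from rxnaug.toydata import ground_truth_answer, oracle_predictions


class TestSeqAccuracy:
    def test_same_molecule_different_writing_matches(self):
        assert seq_accuracy("NCCCC", "CCCCN") == 1

    def test_fragment_order_insensitive(self):
        assert seq_accuracy("CCO.CCN", "CCN.CCO") == 1

    def test_different_molecule_fails(self):
        assert seq_accuracy("CCO", "CCN") == 0

    def test_invalid_prediction_scores_zero(self):
        assert seq_accuracy("C((C", "CCO") == 0

    def test_invalid_target_raises(self):
        with pytest.raises(chem.SmilesParseError):
            seq_accuracy("CCO", "C((C")

    def test_agrees_with_fragment_multiset_oracle(self, toy_molecules):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            frags = [toy_molecules[int(rng.integers(12))] for _ in range(k)]
            pred_frags = [frags[i] for i in rng.permutation(k)]
            if rng.random() < 0.5:  # corrupt: swap one fragment for another
                pred_frags[0] = toy_molecules[int(rng.integers(12, 24))]
            pred = ".".join(chem.randomize(f, int(rng.integers(2**31)))
                            for f in pred_frags)
            target = ".".join(frags)
            expected = int(sorted(chem.canonicalize(f) for f in pred_frags)
                           == sorted(chem.canonicalize(f) for f in frags))
            assert seq_accuracy(pred, target) == expected


class TestCharAccuracy:
    def test_shifted_string_example(self):
        assert char_accuracy("CCCCN", "NCCCC") == pytest.approx(80.0)

    def test_identical_strings_are_perfect(self):
        assert char_accuracy("CC(=O)OCC", "CC(=O)OCC") == 100.0

    def test_disjoint_characters_zero(self):
        assert char_accuracy("C", "N") == 0.0

    def test_bounds_and_self_identity(self, toy_molecules):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = toy_molecules[int(rng.integers(len(toy_molecules)))]
            b = toy_molecules[int(rng.integers(len(toy_molecules)))]
            v = char_accuracy(a, b)
            assert 0.0 <= v <= 100.0
            assert char_accuracy(a, a) == 100.0

    def test_lcs_against_exhaustive_subsequence_oracle(self):
        # brute force: longest string that is a subsequence of both
        rng = np.random.default_rng(2)
        alphabet = "CNO()="
        for _ in range(200):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 8)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 8)))
            best = 0
            for r in range(len(a), 0, -1):
                for sub in itertools.combinations(a, r):
                    it = iter(b)
                    if all(c in it for c in sub):
                        best = r
                        break
                if best:
                    break
            assert _lcs_length(a, b) == best


class TestTopN:
    def test_perfect_predictor_scores_100(self, toy_reactions):
        sub = toy_reactions[:30]
        ranked = oracle_predictions(sub)
        targets = [ground_truth_answer(r) for r in sub]
        assert topn_accuracy(ranked, targets, n=1) == 100.0
        assert topn_accuracy(ranked, targets, n=1, mode="maxfrag") == 100.0

    def test_missing_coreactant_full_fails_maxfrag_hits(self):
        target = "CC(C)CC(=O)O.CCO"
        pred = [chem.largest_fragment(target)]  # dropped the small alcohol
        assert topn_accuracy([pred], [target], n=1) == 0.0
        assert topn_accuracy([pred], [target], n=1, mode="maxfrag") == 100.0

    def test_maxfrag_dominates_full(self, toy_reactions):
        # over 100 random degraded evaluation sets
        rng = np.random.default_rng(3)
        sub = toy_reactions[:25]
        targets = [ground_truth_answer(r) for r in sub]
        for _ in range(100):
            ranked = []
            for t in targets:
                frags = t.split(".")
                u = rng.random()
                if u < 0.3:
                    pred = t                               # exact
                elif u < 0.6:
                    pred = chem.largest_fragment(t)        # largest only
                elif u < 0.8:
                    pred = ".".join(frags[:-1]) or "CCO"   # truncated
                else:
                    pred = "CCCCCCCC"                      # wrong
                ranked.append([pred])
            for n in (1, 3):
                full = topn_accuracy(ranked, targets, n=n)
                maxfrag = topn_accuracy(ranked, targets, n=n, mode="maxfrag")
                assert maxfrag >= full

    def test_monotone_in_n(self, toy_reactions):
        rng = np.random.default_rng(4)
        sub = toy_reactions[:25]
        targets = [ground_truth_answer(r) for r in sub]
        ranked = []
        for t in targets:
            wrongs = ["CCCCCCCC", "CCCCCCN", "CCCCCCO"]
            pos = int(rng.integers(0, 4))
            preds = wrongs[:pos] + [t] + wrongs[pos:]
            ranked.append(preds[:4])
        accs = [topn_accuracy(ranked, targets, n=n) for n in (1, 2, 3, 4)]
        assert accs == sorted(accs)
        assert accs[-1] == 100.0

    def test_short_ranked_lists_evaluated_over_what_exists(self):
        assert topn_accuracy([["CCO"]], ["CCO"], n=5) == 100.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            topn_accuracy([["C"]], ["C", "N"], n=1)


class TestStratify:
    def test_stereo_marker_routes_to_stereo_stratum(self):
        items = [
            EvalItem("a", "C[C@H](N)O", ["C[C@H](N)O"],
                     reaction_smiles="CC(N)=O>>C[C@H](N)O"),
            EvalItem("b", "CCO", ["CCO"], reaction_smiles="CC=O>>CCO"),
        ]
        out = stratify(items, by="stereo", n=1)
        assert out["strata"]["stereo"]["n_items"] == 1
        assert out["strata"]["no_stereo"]["n_items"] == 1

    def test_strata_partition_items(self, toy_reactions):
        from rxnaug.reactions import serialize_reaction
        items = [EvalItem(r.rxn_id, ground_truth_answer(r),
                          [ground_truth_answer(r)],
                          reaction_smiles=serialize_reaction(r),
                          rxn_class=r.rxn_class)
                 for r in toy_reactions[:60]]
        for by in ("stereo", "class"):
            out = stratify(items, by=by, n=1)
            assert sum(s["n_items"] for s in out["strata"].values()) == 60

    def test_no_class_labels_flagged(self):
        items = [EvalItem("a", "CCO", ["CCO"])]
        out = stratify(items, by="class")
        assert out["no_labels"] and out["strata"] == {}


class TestCalibration:
    def test_confident_correct_predictor_single_bin(self):
        items = [EvalItem(str(i), "CCO", ["CCO"], confidence=0.95)
                 for i in range(10)]
        bins = calibration(items)
        populated = [b for b in bins if b["n_items"]]
        assert len(populated) == 1
        assert populated[0]["accuracy"] == 100.0
        assert populated[0]["density"] == 1.0

    def test_densities_sum_to_one(self, toy_reactions):
        rng = np.random.default_rng(5)
        items = [EvalItem(r.rxn_id, ground_truth_answer(r),
                          [ground_truth_answer(r)],
                          confidence=float(rng.random()))
                 for r in toy_reactions[:50]]
        bins = calibration(items)
        assert sum(b["density"] for b in bins) == pytest.approx(1.0, abs=1e-12)


class TestInvalidRate:
    def _pool(self, raws):
        records = []
        for i, raw in enumerate(raws):
            try:
                canon = chem.canonicalize(raw)
            except chem.SmilesParseError:
                canon = None
            records.append(CandidateRecord(raw=raw, aug_index=0,
                                           beam_position=i + 1, logprob=0.0,
                                           canonical=canon))
        return CandidatePool(records=records)

    def test_all_valid_is_zero(self):
        out = invalid_rate([self._pool(["CCO", "CCN"])])
        assert out["overall"] == 0.0

    def test_all_garbage_is_one(self):
        out = invalid_rate([self._pool(["x(", ")y"])])
        assert out["overall"] == 1.0

    def test_matches_direct_recount(self):
        pools = [self._pool(["CCO", "x(", "CCN"]), self._pool(["y)", "CCC"])]
        out = invalid_rate(pools)
        assert out["overall"] == pytest.approx(2 / 5)
        # position 1 holds CCO (valid) and y) (invalid); position 3 only CCN
        assert out["by_beam_position"][1] == pytest.approx(1 / 2)
        assert out["by_beam_position"][2] == pytest.approx(1 / 2)
        assert out["by_beam_position"][3] == 0.0
        assert out["n_records"] == 5


def test_has_stereo_markers():
    assert has_stereo("C[C@H](N)C(=O)O")
    assert has_stereo("C/C=C/C")
    assert not has_stereo("CCOC(C)=O")


# -- hypothesis property: character accuracy is a bounded similarity --------

from hypothesis import given, settings, strategies as st

_ALPHABET = "CNOc1()=[]@/\\."


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet=_ALPHABET, min_size=1, max_size=20),
       st.text(alphabet=_ALPHABET, min_size=1, max_size=20))
def test_char_accuracy_bounded_and_symmetric_on_equal_strings(a, b):
    v = char_accuracy(a, b)
    assert 0.0 <= v <= 100.0
    assert char_accuracy(b, b) == 100.0
    # LCS is symmetric up to the normalizing length
    assert _lcs_length(a, b) == _lcs_length(b, a)
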