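import math

import numpy as np
import pytest

from rxnaug import chem
from rxnaug.aggregate import (
    CandidatePool,
    CandidateRecord,
    collect,
    dedup_within_beam,
    predict_ranked,
    rank,
)
from rxnaug.predictor import BOS, EOS, Vocabulary


class EchoModel:
    """Mock sequence model that deterministically echoes its source."""

    def __init__(self, texts):
        self.vocab = Vocabulary.from_texts(texts)
        self.tokenizer_mode = "char"

    def next_token_distribution(self, source, prefix):
        out = np.zeros(len(self.vocab))
        target = list(source)
        tok = target[len(prefix)] if len(prefix) < len(target) else EOS
        out[self.vocab.index[tok]] = 1.0
        return out


def record(raw, aug, beam, logprob=0.0, canonical="auto"):
    canon = None
    if canonical == "auto":
        try:
            canon = chem.canonicalize(raw)
        except chem.SmilesParseError:
            canon = None
    elif canonical is not None:
        canon = canonical
    return CandidateRecord(raw=raw, aug_index=aug, beam_position=beam,
                           logprob=logprob, canonical=canon)


def pool_of(records):
    return CandidatePool(records=list(records))


class TestCollect:
    def test_single_variant_single_beam_is_one_record(self):
        model = EchoModel(["CCO"])
        pool = collect(model, "CCO", n_aug=1, beam_size=1, seed=0)
        assert len(pool.records) == 1
        assert pool.records[0].canonical == chem.canonicalize("CCO")

    def test_pool_capacity_is_naug_times_beam(self):
        model = EchoModel(["CC(C)CO", "OCC(C)C", "C(O)C(C)C"])
        pool = collect(model, "CC(C)CO", n_aug=4, beam_size=2, seed=1)
        assert len(pool.records) <= 4 * 2
        # independent recount: per-variant beams sum to the pool size
        per_variant = {}
        for r in pool.records:
            per_variant[r.aug_index] = per_variant.get(r.aug_index, 0) + 1
        assert sum(per_variant.values()) == len(pool.records)
        assert set(per_variant) == set(range(4))

    def test_echo_model_records_all_valid(self):
        model = EchoModel(["CC(C)CO", "OCC(C)C", "C(O)C(C)C", "C(C)(C)CO"])
        pool = collect(model, "CC(C)CO", n_aug=5, beam_size=1, seed=3)
        assert all(r.valid for r in pool.records)


class TestDedup:
    def test_first_occurrence_kept_within_beam(self):
        pool = pool_of([
            record("OCC", 0, 1), record("C(C)O", 0, 2), record("CCN", 0, 3),
        ])
        kept = dedup_within_beam(pool).records
        assert [(r.raw, r.beam_position) for r in kept] == \
               [("OCC", 1), ("CCN", 3)]

    def test_duplicates_across_variants_kept(self):
        pool = pool_of([record("CCO", 0, 1), record("CCO", 1, 1)])
        assert len(dedup_within_beam(pool).records) == 2

    def test_distinct_canonicals_preserved(self):
        pool = pool_of([record("CCO", 0, 1), record("OCC", 0, 2),
                        record("CCN", 0, 3), record("NCC", 1, 1)])
        before = {r.canonical for r in pool.records}
        after = {r.canonical for r in dedup_within_beam(pool).records}
        assert before == after  # dedup never loses a distinct answer

    def test_matches_brute_force_first_scan(self, toy_molecules):
        rng = np.random.default_rng(4)
        for _ in range(200):
            records = []
            for aug in range(rng.integers(1, 4)):
                for beam in range(1, rng.integers(2, 6)):
                    s = toy_molecules[int(rng.integers(len(toy_molecules)))]
                    records.append(record(s, aug, beam))
            got = dedup_within_beam(pool_of(records)).records
            seen, expected = set(), []
            for r in sorted(records, key=lambda r: (r.aug_index, r.beam_position)):
                key = (r.aug_index, r.canonical)
                if key in seen:
                    continue
                seen.add(key)
                expected.append(r)
            assert got == expected


def wilson(count, total, z=1.959963984540054):
    """Closed-form Wilson score interval (oracle, written independently)."""
    phat = count / total
    denom = 1 + z**2 / total
    center = (phat + z**2 / (2 * total)) / denom
    half = z * math.sqrt(phat * (1 - phat) / total + z**2 / (4 * total**2)) / denom
    return center - half, center + half


class TestRank:
    def test_simple_counts(self):
        records = ([record("CCO", a, 1) for a in range(7)]
                   + [record("CCN", a, 2) for a in range(2)]
                   + [record("CCC", 0, 3)])
        out = rank(pool_of(records))
        assert out[0].canonical == chem.canonicalize("CCO")
        assert out[0].count == 7
        assert out[0].confidence == pytest.approx(0.7)
        assert [p.rank for p in out] == [1, 2, 3]

    def test_all_distinct_confidence_is_one_over_k(self):
        records = [record(s, i, 1) for i, s in enumerate(["CCO", "CCN", "CCC", "CCCC"])]
        out = rank(pool_of(records))
        assert all(p.confidence == pytest.approx(1 / 4) for p in out)

    def test_invalid_records_excluded_from_ranking(self):
        records = [record("CCO", 0, 1), record("xxx", 0, 2), record("CCO", 1, 1)]
        out = rank(pool_of(records))
        assert len(out) == 1
        assert out[0].count == 2
        assert out[0].confidence == pytest.approx(1.0)  # denominator = valid

    def test_pool_denominator_option(self):
        records = [record("CCO", 0, 1), record("xxx", 0, 2)]
        out = rank(pool_of(records), denominator="pool")
        assert out[0].confidence == pytest.approx(0.5)

    def test_zero_valid_records_empty_result(self):
        assert rank(pool_of([record("xxx", 0, 1)])) == []

    def test_wilson_interval_matches_closed_form(self):
        records = [record("CCO", a, 1) for a in range(7)] + \
                  [record("CCN", a, 2) for a in range(3)]
        out = rank(pool_of(records))
        lo, hi = wilson(7, 10)
        assert out[0].interval[0] == pytest.approx(lo, abs=1e-9)
        assert out[0].interval[1] == pytest.approx(hi, abs=1e-9)

    def test_counts_conserved(self, toy_molecules):
        rng = np.random.default_rng(5)
        for _ in range(50):
            records = [record(toy_molecules[int(rng.integers(20))],
                              int(rng.integers(5)), int(rng.integers(1, 6)),
                              float(rng.normal()))
                       for _ in range(int(rng.integers(1, 30)))]
            out = rank(pool_of(records))
            assert sum(p.count for p in out) == sum(r.valid for r in records)

    def test_matches_brute_force_count_sort_slice(self, toy_molecules):
        # 1000 random pools incl. ties, vs an independent count/sort oracle
        rng = np.random.default_rng(6)
        for _ in range(1000):
            size = int(rng.integers(1, 25))
            records = [record(toy_molecules[int(rng.integers(8))],
                              int(rng.integers(4)), int(rng.integers(1, 6)),
                              float(rng.integers(-3, 0)))
                       for _ in range(size)]
            n = int(rng.integers(1, 6))
            got = rank(pool_of(records), n=n)
            groups = {}
            for r in records:
                if r.canonical is not None:
                    groups.setdefault(r.canonical, []).append(r)
            order = sorted(groups,
                           key=lambda c: (-len(groups[c]),
                                          -max(x.logprob for x in groups[c]), c))
            assert [p.canonical for p in got] == order[:n]
            assert [p.count for p in got] == [len(groups[c]) for c in order[:n]]

    def test_permutation_invariant(self):
        records = [record("CCO", 0, 1, -1.0), record("CCN", 1, 1, -0.5),
                   record("OCC", 2, 2, -2.0), record("NCC", 0, 3, -0.1)]
        a = rank(pool_of(records))
        b = rank(pool_of(list(reversed(records))))
        assert a == b

    def test_adding_record_never_lowers_its_rank(self):
        records = [record("CCO", 0, 1), record("CCN", 1, 1), record("CCN", 2, 1)]
        before = {p.canonical: p.rank for p in rank(pool_of(records))}
        more = records + [record("OCC", 3, 1)]
        after = {p.canonical: p.rank for p in rank(pool_of(more))}
        ccodc = chem.canonicalize("CCO")
        assert after[ccodc] <= before[ccodc]


class TestEndToEnd:
    def test_predict_ranked_echo_model_is_perfect(self):
        products = ["CC(C)CO", "CCOC(C)C"]
        texts = []
        from rxnaug.augment import augment_test
        for var in augment_test(products, 10, seed=0):
            texts.extend(var)
        model = EchoModel(texts)
        ranked, pools = predict_ranked(model, products, n_aug=10, beam_size=1,
                                       seed=0)
        for preds, product in zip(ranked, products):
            assert preds[0].canonical == chem.canonicalize(product)
            assert preds[0].confidence == pytest.approx(1.0)
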