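"""Tandem duplication–random loss: application, enumeration, minimality.

The brute-force oracle here is deliberately independent of the package
implementation: it materializes the duplicated block as a plain list,
applies the loss mask positionally, and compares all rotations.
"""

import random
from itertools import permutations, product

import pytest
from hypothesis import given, strategies as st

from mitocomp.gene_order import GROUND_PATTERN, GeneOrder, GeneOrderError, \
    orders_equal
from mitocomp.tdrl import (TdrlScenario, apply_tdrl, enumerate_single_tdrl,
                           make_scenario, minimal_tdrl)


def _order(spec: str) -> GeneOrder:
    return GeneOrder.from_string(spec, normalize=False)


# ------------------------------------------------------------- the oracle

def oracle_apply(elements, start, keep):
    """Independent TDRL: rotate, double the block, drop unkept copies."""
    n, k = len(elements), len(keep)
    rot = [elements[(start + i) % n] for i in range(n)]
    block, rest = rot[:k], rot[k:]
    doubled = block + block
    survivors = [doubled[i if choice == "first" else k + i]
                 for i, choice in enumerate(keep)]
    ordered = [doubled[p] for p in sorted(
        i if choice == "first" else k + i for i, choice in enumerate(keep))]
    assert sorted(map(tuple, survivors)) == sorted(map(tuple, ordered))
    return ordered + rest

def oracle_equal(a, b):
    return any(list(a[i:]) + list(a[:i]) == list(b) for i in range(len(a)))

def oracle_enumerate(source, target, max_interval):
    found = []
    n = len(source.elements)
    for start in range(n):
        for k in range(1, min(max_interval, n) + 1):
            for keep in product(("first", "second"), repeat=k):
                result = oracle_apply(list(source.elements), start, keep)
                if oracle_equal(result, list(target.elements)):
                    found.append((start, keep))
    return found


# ------------------------------------------------------- published events

class TestPublishedScenarios:
    def test_trnh_translocation_block(self):
        """Duplicating trnF-nad5-trnH and losing the first trnF, first
        nad5 and second trnH yields trnH-trnF-nad5."""
        src = _order("-trnF,-nad5,-trnH")
        s = TdrlScenario(start=0, keep=("second", "second", "first"))
        out = apply_tdrl(src, s)
        assert [l for l, _ in out.elements] == ["trnH", "trnF", "nad5"]
        assert all(o == -1 for _, o in out.elements)

    def test_trnq_trni_swap_block(self):
        src = _order("trnI,-trnQ,trnM")
        s = TdrlScenario(start=0, keep=("second", "first", "second"))
        out = apply_tdrl(src, s)
        assert out.elements == (("trnQ", -1), ("trnI", 1), ("trnM", 1))

    def test_ground_segment_reachable_by_enumeration(self):
        src = _order("trnE,-trnF,-nad5,-trnH,-nad4")
        tgt = _order("trnE,-trnH,-trnF,-nad5,-nad4")
        scenarios = enumerate_single_tdrl(src, tgt, max_interval=5)
        assert scenarios
        intervals = {s.interval_labels(src) for s in scenarios}
        assert ("trnF", "nad5", "trnH") in intervals


class TestApply:
    @pytest.mark.parametrize("keep", [("first",) * 3, ("second",) * 3])
    def test_uniform_masks_are_identity(self, keep):
        src = _order("a,b,-c,d,e")
        s = TdrlScenario(start=1, keep=keep)
        assert orders_equal(apply_tdrl(src, s), src)

    def test_malformed_mask_rejected(self):
        with pytest.raises(GeneOrderError):
            TdrlScenario(start=0, keep=("first", "both"))
        with pytest.raises(GeneOrderError):
            TdrlScenario(start=0, keep=())

    def test_wrapping_interval(self):
        src = _order("a,b,c,d")
        s = TdrlScenario(start=3, keep=("second", "first"))  # block (d, a)
        out = apply_tdrl(src, s)
        assert orders_equal(out, _order("a,d,b,c"))

    @given(st.integers(0, 10_000))
    def test_multiset_conservation_for_random_scenarios(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 9)
        src = GeneOrder(tuple((f"g{i}", rng.choice((1, -1)))
                              for i in range(n)))
        k = rng.randint(1, n)
        s = TdrlScenario(start=rng.randrange(n),
                         keep=tuple(rng.choice(("first", "second"))
                                    for _ in range(k)))
        out = apply_tdrl(src, s)
        assert sorted(out.elements) == sorted(src.elements)

    def test_matches_oracle_on_random_scenarios(self):
        rng = random.Random(123)
        for _ in range(200):
            n = rng.randint(3, 8)
            src = GeneOrder(tuple((f"g{i}", rng.choice((1, -1)))
                                  for i in range(n)))
            k = rng.randint(1, n)
            s = TdrlScenario(start=rng.randrange(n),
                             keep=tuple(rng.choice(("first", "second"))
                                        for _ in range(k)))
            assert list(apply_tdrl(src, s).elements) == \
                oracle_apply(list(src.elements), s.start, s.keep)


class TestEnumeration:
    def test_agrees_with_oracle_for_all_four_element_targets(self):
        src = _order("a,b,c,d")
        for perm in permutations("abcd"):
            tgt = GeneOrder(tuple((l, 1) for l in perm))
            ours = {(s.start, s.keep)
                    for s in enumerate_single_tdrl(src, tgt, 4)}
            assert ours == set(oracle_enumerate(src, tgt, 4)), perm

    def test_agrees_with_oracle_for_signed_six_element_samples(self):
        rng = random.Random(99)
        src = GeneOrder(tuple((f"g{i}", rng.choice((1, -1)))
                              for i in range(6)))
        for _ in range(12):
            labels = [l for l, _ in src.elements]
            rng.shuffle(labels)
            orient = dict(src.elements)
            tgt = GeneOrder(tuple((l, orient[l]) for l in labels))
            ours = {(s.start, s.keep)
                    for s in enumerate_single_tdrl(src, tgt, 6)}
            assert ours == set(oracle_enumerate(src, tgt, 6))

    def test_every_returned_scenario_reproduces_the_target(self, pbidens_order):
        scenarios = enumerate_single_tdrl(GROUND_PATTERN, GROUND_PATTERN,
                                          max_interval=3)
        for s in scenarios[:50]:
            assert orders_equal(apply_tdrl(GROUND_PATTERN, s), GROUND_PATTERN)

    def test_nontrivial_only_excludes_identity_scenarios(self):
        src = _order("a,b,c")
        all_scen = enumerate_single_tdrl(src, src, 3)
        nontrivial = enumerate_single_tdrl(src, src, 3, nontrivial_only=True)
        assert all_scen and not nontrivial

    def test_deterministic_ordering(self):
        src, tgt = _order("a,b,c,d"), _order("a,c,b,d")
        scenarios = enumerate_single_tdrl(src, tgt, 4)
        keys = [(s.start, s.length, s.mask_int) for s in scenarios]
        assert keys == sorted(keys)

    @given(st.integers(0, 2_000))
    def test_round_trip_recovery(self, seed):
        """Any applied scenario is rediscovered by enumeration."""
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        src = GeneOrder(tuple((f"g{i}", rng.choice((1, -1)))
                              for i in range(n)))
        k = rng.randint(1, min(4, n))
        s = TdrlScenario(start=rng.randrange(n),
                         keep=tuple(rng.choice(("first", "second"))
                                    for _ in range(k)))
        tgt = apply_tdrl(src, s)
        found = enumerate_single_tdrl(src, tgt, max_interval=4)
        assert any(orders_equal(apply_tdrl(src, f), tgt) for f in found)


class TestMinimal:
    def test_iqm_swap_needs_only_two_gene_duplication(self):
        src, tgt = _order("I,Q,M"), _order("Q,I,M")
        s = minimal_tdrl(src, tgt, nontrivial_only=True)
        assert s is not None and s.length == 2
        assert set(s.interval_labels(src)) == {"I", "Q"}

    def test_identical_orders_have_no_nontrivial_scenario(self):
        src = _order("a,b,c,d")
        assert minimal_tdrl(src, src, nontrivial_only=True) is None
        trivial = minimal_tdrl(src, src)
        assert trivial is not None and trivial.length == 1

    def test_unreachable_rearrangement_returns_none(self):
        """A 3-cycle of distant elements cannot be one short TDRL."""
        src = _order("a,b,c,d,e,f")
        tgt = _order("e,b,a,d,c,f")   # a->c slot, c->e slot, e->a slot
        assert minimal_tdrl(src, tgt, max_interval=2) is None
        assert not oracle_enumerate(src, tgt, 2)

    def test_label_set_mismatch_rejected(self):
        with pytest.raises(GeneOrderError):
            minimal_tdrl(_order("a,b"), _order("a,c"))


def test_make_scenario_locates_circular_interval():
    s = make_scenario(GROUND_PATTERN, ("trnF", "nad5", "trnH"),
                      ("second", "second", "first"))
    assert s.interval_labels(GROUND_PATTERN) == ("trnF", "nad5", "trnH")
    with pytest.raises(GeneOrderError):
        make_scenario(GROUND_PATTERN, ("trnF", "trnH"), ("first", "first"))
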