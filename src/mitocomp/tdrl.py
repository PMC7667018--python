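"""Tandem duplication–random loss (TDRL) rearrangement model.

A TDRL event duplicates a contiguous block of genes in tandem and then
loses exactly one copy of each duplicated gene; the surviving copies,
read in position, reorder the block.  TDRL is the standard mechanism
invoked for mitochondrial gene-order changes such as the sesarmid trnH
translocation (duplicate trnF–nad5–trnH, lose the first trnF, first nad5
and second trnH → trnH–trnF–nad5) and the trnI/trnQ swap next to the
control region.

The model operates on the order alone: orientations are carried through
unchanged (TDRL never inverts), the control region may sit inside a
duplicated block, and "random loss" is treated as enumeration of loss
patterns rather than stochastic sampling — a seeded sampler lives in the
synthetic-data module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional, Sequence

from .gene_order import GeneOrder, GeneOrderError, orders_equal

__all__ = [
    "TdrlScenario", "apply_tdrl", "enumerate_single_tdrl", "minimal_tdrl",
    "make_scenario",
]

KEEP_FIRST = "first"
KEEP_SECOND = "second"


@dataclass(frozen=True)
class TdrlScenario:
    """One tandem duplication + loss pattern.

    ``start`` indexes the first duplicated element in the source order,
    ``keep`` records, per duplicated gene, which tandem copy survives.
    ``mask_int`` encodes ``keep`` as a binary number, first gene as the
    most significant bit, 'second' = 1 — the deterministic enumeration
    order of :func:`enumerate_single_tdrl`.
    """

    start: int
    keep: tuple[str, ...]

    def __post_init__(self):
        if not self.keep:
            raise GeneOrderError("empty keep mask")
        if any(k not in (KEEP_FIRST, KEEP_SECOND) for k in self.keep):
            raise GeneOrderError(f"malformed keep mask: {self.keep}")

    @property
    def length(self) -> int:
        return len(self.keep)

    @property
    def mask_int(self) -> int:
        return int("".join("1" if k == KEEP_SECOND else "0"
                           for k in self.keep), 2)

    def interval_labels(self, source: GeneOrder) -> tuple[str, ...]:
        n = len(source)
        return tuple(source.elements[(self.start + i) % n][0]
                     for i in range(self.length))

    @property
    def is_trivial_mask(self) -> bool:
        """All-first or all-second masks always reproduce the source."""
        return len(set(self.keep)) == 1


def apply_tdrl(source: GeneOrder, s: TdrlScenario) -> GeneOrder:
    """Apply one TDRL event and return the resulting order.

    The block ``source[start : start+k]`` (circular span) is duplicated in
    tandem; for each duplicated gene the copy named in ``keep`` survives.
    The multiset of (label, orientation) pairs is conserved by
    construction.
    """
    n = len(source)
    k = s.length
    if not (1 <= k <= n):
        raise GeneOrderError(f"interval length {k} outside 1..{n}")
    rotated = source.rotate(s.start)  # block now occupies positions 0..k-1
    block = rotated.elements[:k]
    # positions of survivors inside the tandem duplication block..block
    survivor_pos = sorted(
        i if keep == KEEP_FIRST else k + i
        for i, keep in enumerate(s.keep))
    new_block = tuple(block[p % k] for p in survivor_pos)
    return GeneOrder(new_block + rotated.elements[k:], taxon=source.taxon)


def _scenarios(n: int, max_interval: int) -> Iterator[TdrlScenario]:
    """All scenarios in deterministic order: start, then interval length,
    then keep mask as a binary number."""
    for start in range(n):
        for k in range(1, min(max_interval, n) + 1):
            for keep in product((KEEP_FIRST, KEEP_SECOND), repeat=k):
                yield TdrlScenario(start=start, keep=keep)


def enumerate_single_tdrl(source: GeneOrder, target: GeneOrder,
                          max_interval: int = 6, *,
                          nontrivial_only: bool = False
                          ) -> list[TdrlScenario]:
    """Every single-TDRL scenario with interval length ≤ ``max_interval``
    that transforms ``source`` into ``target`` (up to rotation).

    ``nontrivial_only`` drops scenarios whose result equals the source
    (always present when source and target are identical).
    """
    if source.labels() != target.labels():
        raise GeneOrderError("enumeration needs equal label sets")
    out = []
    for s in _scenarios(len(source), max_interval):
        result = apply_tdrl(source, s)
        if nontrivial_only and orders_equal(result, source):
            continue
        if orders_equal(result, target):
            out.append(s)
    return out


def minimal_tdrl(source: GeneOrder, target: GeneOrder,
                 max_interval: int = 6, *,
                 nontrivial_only: bool = False) -> Optional[TdrlScenario]:
    """First matching scenario under (interval length, start, mask)
    ordering, or None when no single TDRL suffices."""
    if source.labels() != target.labels():
        raise GeneOrderError("search needs equal label sets")
    n = len(source)
    for k in range(1, min(max_interval, n) + 1):
        for start in range(n):
            for keep in product((KEEP_FIRST, KEEP_SECOND), repeat=k):
                s = TdrlScenario(start=start, keep=keep)
                result = apply_tdrl(source, s)
                if nontrivial_only and orders_equal(result, source):
                    continue
                if orders_equal(result, target):
                    return s
    return None


def make_scenario(source: GeneOrder, interval_labels: Sequence[str],
                  keep: Sequence[str]) -> TdrlScenario:
    """Build a scenario from gene labels: locate the contiguous run of
    ``interval_labels`` in the source order and attach the keep mask."""
    labels = [l for l, _ in source.elements]
    n = len(labels)
    k = len(interval_labels)
    if len(keep) != k:
        raise GeneOrderError("keep mask length must match the interval")
    for start in range(n):
        if all(labels[(start + i) % n] == interval_labels[i]
               for i in range(k)):
            return TdrlScenario(start=start, keep=tuple(keep))
    raise GeneOrderError(
        f"interval {list(interval_labels)} is not contiguous in the source")
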