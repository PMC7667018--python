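"""Circular signed gene orders and their comparison.

A mitochondrial gene order is a circular list of signed gene labels read
along the majority strand: '+' for majority-strand genes, '−' for
minority-strand genes, and the control region as an unsigned element.
Two orders are identical when some rotation matches element-for-element
(label and orientation); reflection and global strand flips are *not*
identities, because published orders are reported on a fixed majority
strand.

The module ships the pancrustacean ground pattern (the inferred ancestral
arrangement used as the comparison baseline) and the shared sesarmid crab
order, which differs from it by a translocated trnH and a swapped
trnI/trnQ pair next to the control region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import MitoAnnotation
from .genes import normalize_gene_name, UnknownGeneError

__all__ = [
    "Element", "GeneOrder", "GROUND_PATTERN", "SESARMID_ORDER",
    "order_from_annotation", "orders_equal", "breakpoint_distance",
    "diff_orders", "group_identical_orders", "OrderDiff", "DisplacedRegion",
]

#: orientation values: +1 majority strand, −1 minority strand, 0 unsigned
Element = tuple[str, int]

_ORIENT_CHAR = {1: "+", -1: "-", 0: ""}


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrder:
    """A circular order of uniquely labelled, signed elements."""

    elements: tuple[Element, ...]
    taxon: str = ""

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(
            (str(l), int(o)) for l, o in self.elements))
        labels = [l for l, _ in self.elements]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise GeneOrderError(f"duplicate labels in order: {dupes}")
        if any(o not in (-1, 0, 1) for _, o in self.elements):
            raise GeneOrderError("orientations must be +1, -1 or 0")

    # -------------------------------------------------------- construction
    @classmethod
    def from_string(cls, text: str, taxon: str = "",
                    normalize: bool = True) -> "GeneOrder":
        """Parse 'cox1,+trnL2,...,-trnY': '-' prefix = minority strand,
        optional '+' = majority, CR is unsigned."""
        elements: list[Element] = []
        for token in text.strip().split(","):
            token = token.strip()
            if not token:
                continue
            orient = 1
            if token[0] in "+-−":
                orient = -1 if token[0] in "-−" else 1
                token = token[1:].strip()
            if normalize:
                try:
                    token = normalize_gene_name(token)
                except UnknownGeneError:
                    pass
            if token == "CR":
                orient = 0
            elements.append((token, orient))
        if not elements:
            raise GeneOrderError("empty gene order")
        return cls(tuple(elements), taxon=taxon)

    def to_string(self) -> str:
        return ",".join(f"{_ORIENT_CHAR[o]}{l}" for l, o in self.elements)

    # ------------------------------------------------------------ algebra
    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def labels(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.elements)

    def rotate(self, k: int) -> "GeneOrder":
        """Rotation moving element k to the front (circular identity)."""
        k %= len(self.elements)
        return GeneOrder(self.elements[k:] + self.elements[:k],
                         taxon=self.taxon)

    def canonical(self) -> tuple[Element, ...]:
        """Rotation-invariant key: rotate the unique smallest label first."""
        labels = [l for l, _ in self.elements]
        k = labels.index(min(labels))
        return self.rotate(k).elements

    def display(self, anchor: str = "cox1") -> "GeneOrder":
        """Canonical display rotation starting at ``anchor`` when present."""
        labels = [l for l, _ in self.elements]
        return self.rotate(labels.index(anchor)) if anchor in labels else self

    def index(self, label: str) -> int:
        for i, (l, _) in enumerate(self.elements):
            if l == label:
                return i
        raise KeyError(label)

    def neighbors(self, label: str) -> tuple[Element, Element]:
        """(predecessor, successor) of a label on the circle."""
        i = self.index(label)
        n = len(self.elements)
        return self.elements[(i - 1) % n], self.elements[(i + 1) % n]

    def adjacencies(self) -> frozenset[tuple[Element, Element]]:
        """Ordered, oriented neighbor pairs around the circle."""
        n = len(self.elements)
        return frozenset(
            (self.elements[i], self.elements[(i + 1) % n])
            for i in range(n))

    def equals(self, other: "GeneOrder") -> bool:
        return orders_equal(self, other)


def orders_equal(x: GeneOrder, y: GeneOrder) -> bool:
    """True iff some rotation of x equals y element-for-element.

    Orientation is part of identity; reflection is not an equivalence.
    """
    if len(x) != len(y) or x.labels() != y.labels():
        return False
    return x.canonical() == y.canonical()


#: the pancrustacean ground pattern — the ancestral arrangement against
#: which brachyuran rearrangements are scored
GROUND_PATTERN = GeneOrder.from_string(
    "cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,"
    "trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,"
    "-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY",
    taxon="Pancrustacea ground pattern")

#: the arrangement shared by sesarmid crabs (e.g. Perisesarma bidens):
#: trnH translocated to the trnE|trnF junction and trnI/trnQ swapped
SESARMID_ORDER = GeneOrder.from_string(
    "cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,"
    "trnS1,trnE,-trnH,-trnF,-nad5,-nad4,-nad4L,trnT,-trnP,nad6,cob,trnS2,"
    "-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,-trnQ,trnI,trnM,nad2,trnW,-trnC,-trnY",
    taxon="Sesarmidae")


def order_from_annotation(a: MitoAnnotation) -> GeneOrder:
    """Gene order in majority-strand positional order, orientations from
    the strand column (F → +, R → −, CR → unsigned)."""
    orient = {"F": 1, "R": -1, None: 0}
    elements = tuple((f.name, orient[f.strand]) for f in a.sorted_features())
    return GeneOrder(elements, taxon=a.source_id)


def breakpoint_distance(x: GeneOrder, y: GeneOrder) -> int:
    """Number of oriented adjacencies of x absent from y.

    Symmetric for equal label sets; zero iff the orders are identical
    under rotation.
    """
    if x.labels() != y.labels():
        raise GeneOrderError("breakpoint distance needs equal label sets")
    return len(x.adjacencies() - y.adjacencies())


@dataclass(frozen=True)
class DisplacedRegion:
    """A contiguous run of displaced genes.

    ``kind`` is 'translocation' for a single gene whose old junction healed,
    'swap' when the block reappears reversed at the same junction, and
    'rearrangement' otherwise.  Junctions are (predecessor, successor)
    element pairs.
    """

    genes: tuple[Element, ...]
    from_junction: tuple[Element, Element]
    to_junction: Optional[tuple[Element, Element]]
    kind: str


@dataclass(frozen=True)
class OrderDiff:
    """Breakpoint-level difference report between two circular orders."""

    breakpoints: frozenset[tuple[Element, Element]]
    regions: tuple[DisplacedRegion, ...]

    @property
    def is_empty(self) -> bool:
        return not self.breakpoints

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def region_labels(self) -> list[tuple[str, ...]]:
        return [tuple(l for l, _ in r.genes) for r in self.regions]


def diff_orders(x: GeneOrder, y: GeneOrder) -> OrderDiff:
    """Describe where two orders with the same label set disagree.

    A gene is *displaced* when its two x-neighbors are directly adjacent
    in y (its old slot healed — the signature of a clean excision).
    Displaced genes contiguous in x are merged into one region: a single
    translocated gene reports its source and destination junctions; a
    block that reappears reversed in place reports a swap.  Genes involved
    in rearrangements without a healed slot remain visible through the
    breakpoint set.
    """
    if x.labels() != y.labels():
        raise GeneOrderError("diff needs equal label sets")
    n = len(x)
    adjy = y.adjacencies()
    breakpoints = x.adjacencies() - adjy

    displaced = []
    for i in range(n):
        pred, succ = x.elements[(i - 1) % n], x.elements[(i + 1) % n]
        if n >= 3 and (pred, succ) in adjy:
            displaced.append(i)

    # merge circularly contiguous displaced positions
    runs: list[list[int]] = []
    for i in displaced:
        if runs and runs[-1][-1] == i - 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs[-1] + runs[0]
        runs.pop()

    regions = []
    for run in runs:
        block = tuple(x.elements[i % n] for i in run)
        from_junction = (x.elements[(run[0] - 1) % n],
                         x.elements[(run[-1] + 1) % n])
        # locate the block in y
        y_pos = sorted(y.index(l) for l, _ in block)
        contiguous = all((b - a) % len(y) == 1
                         for a, b in zip(y_pos, y_pos[1:]))
        to_junction = None
        kind = "rearrangement"
        if contiguous:
            y_block = tuple(y.elements[p] for p in y_pos)
            to_junction = (y.elements[(y_pos[0] - 1) % len(y)],
                           y.elements[(y_pos[-1] + 1) % len(y)])
            if len(block) == 1:
                kind = "translocation"
            elif y_block == tuple(reversed(block)):
                kind = "swap"
        regions.append(DisplacedRegion(
            genes=block, from_junction=from_junction,
            to_junction=to_junction, kind=kind))
    return OrderDiff(breakpoints=breakpoints, regions=tuple(regions))


def group_identical_orders(orders: Sequence[GeneOrder]) -> list[list[str]]:
    """Partition taxa into classes of identical (rotation-equivalent)
    orders; clusters and members sorted by taxon name, clusters ordered
    by first member."""
    if not orders:
        raise GeneOrderError("need at least one order")
    clusters: dict[tuple, list[str]] = {}
    for i, order in enumerate(orders):
        key = order.canonical()
        clusters.setdefault(key, []).append(order.taxon or f"taxon_{i}")
    groups = [sorted(members) for members in clusters.values()]
    return sorted(groups, key=lambda g: g[0])
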