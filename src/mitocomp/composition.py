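"""Base composition, A+T content and AT/GC strand-skew statistics.

Metazoan mitogenomes are strongly A+T biased and show characteristic
strand asymmetries summarized by two dimensionless skews computed on the
reported (majority) strand:

    AT skew = (A − T) / (A + T)        GC skew = (G − C) / (G + C)

Both lie in [−1, 1] and are antisymmetric under reverse complementation.
Genome-level statistics are computed on the deposited strand, matching the
convention of mitogenome papers; per-feature statistics use the annotated
(coding) strand.  Reports round percentages to 2 decimals and skews to 3,
full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .annotation import MitoAnnotation, extract_feature_seq

__all__ = [
    "CompositionSummary", "base_composition",
    "at_skew_from_percent", "gc_skew_from_percent",
    "per_feature_composition",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CompositionSummary:
    """Counts and derived composition statistics for one sequence.

    Ambiguity codes are excluded from the denominator (counted in
    ``n_ambiguous``) rather than fractionally allocated.
    """

    a: int
    c: int
    g: int
    t: int
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def count(self, base: str) -> int:
        return getattr(self, base.lower())

    def pct(self, base: str) -> float:
        return 100.0 * self.count(base) / self.total

    @property
    def at_content(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def at_skew(self) -> float:
        """(A − T)/(A + T); NaN when the sequence has no A or T."""
        if self.a + self.t == 0:
            return float("nan")
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        """(G − C)/(G + C); NaN when the sequence has no G or C."""
        if self.g + self.c == 0:
            return float("nan")
        return (self.g - self.c) / (self.g + self.c)

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.n_ambiguous + other.n_ambiguous)

    def report(self) -> dict:
        """Rounded report dict (percentages 2 dp, skews 3 dp)."""
        return {
            **{f"pct_{b}": round(self.pct(b), 2) for b in _BASES},
            "at_content": round(self.at_content, 2),
            "at_skew": round(self.at_skew, 3) if self.a + self.t else None,
            "gc_skew": round(self.gc_skew, 3) if self.g + self.c else None,
            "n_bases": self.total,
            "n_ambiguous": self.n_ambiguous,
        }


def base_composition(seq: str) -> CompositionSummary:
    """Count ACGT over a sequence (case-insensitive, U → T).

    Raises ``ValueError`` on an empty sequence or one without any
    unambiguous base.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous ACGT bases")
    return CompositionSummary(
        a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"],
        n_ambiguous=len(s) - total)


def at_skew_from_percent(pct_a: float, pct_t: float) -> float:
    """AT skew from printed percentages: (A% − T%) / (A% + T%)."""
    if pct_a + pct_t <= 0:
        raise ValueError("A% + T% must be positive")
    return (pct_a - pct_t) / (pct_a + pct_t)


def gc_skew_from_percent(pct_g: float, pct_c: float) -> float:
    """GC skew from printed percentages: (G% − C%) / (G% + C%)."""
    if pct_g + pct_c <= 0:
        raise ValueError("G% + C% must be positive")
    return (pct_g - pct_c) / (pct_g + pct_c)


def per_feature_composition(genome: str, a: MitoAnnotation, *,
                            include_classes: bool = True) -> pd.DataFrame:
    """Composition of every feature (on its annotated strand) plus
    per-class aggregates.

    Returns a DataFrame with one row per feature and, when
    ``include_classes`` is set, one aggregate row per gene class (level
    column 'class') built by summing strand-aware counts.
    """
    rows = []
    by_class: dict[str, Optional[CompositionSummary]] = {}
    for f in a.features:
        summary = base_composition(extract_feature_seq(genome, f))
        prev = by_class.get(f.gene_class)
        by_class[f.gene_class] = summary if prev is None else prev + summary
        rows.append({"name": f.name, "level": "feature",
                     "gene_class": f.gene_class,
                     "strand": f.strand or "-", **summary.report()})
    if include_classes:
        for cls, summary in sorted(by_class.items()):
            rows.append({"name": cls, "level": "class", "gene_class": cls,
                         "strand": "*", **summary.report()})
    return pd.DataFrame(rows)
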