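"""Codon usage under the invertebrate mitochondrial genetic code.

Protein-coding genes are translated with NCBI translation table 5
(invertebrate mitochondrial: AGA/AGG → Ser, ATA → Met, TGA → Trp).  Codon
counts are tallied over complete codons only; arthropod mitochondrial PCGs
frequently end on an incomplete stop (a trailing T or TA completed to TAA
by polyadenylation), and such trailing nucleotides are trimmed and
counted, never imputed as codons.

Relative synonymous codon usage is computed within synonymous families,
with leucine and serine split the way mitogenome papers plot them:
Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN.  For codon c in a family
of size k with family total N:

    RSCU(c) = count(c) * k / N

so RSCU sums to k over each observed family and averages 1 under uniform
usage.  Stop codons are excluded from RSCU families and reported apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CODONS", "CODON_TO_AA", "FAMILY_OF", "FAMILY_SIZE", "FAMILY_CODONS",
    "translate_mito", "codon_counts", "rscu", "amino_acid_composition",
    "CodonUsageTable", "plot_rscu",
]

GENETIC_CODE_ID = 5  # NCBI invertebrate mitochondrial

_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]

CODONS: tuple[str, ...] = tuple("".join(c) for c in product("TCAG", repeat=3))

#: codon → one-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = {
    c: _TABLE.forward_table.get(c, "*") for c in CODONS}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _family_label(codon: str) -> str:
    aa = CODON_TO_AA[codon]
    if aa == "*":
        return "Stop"
    if aa == "L":
        return "Leu2" if codon.startswith("TT") else "Leu1"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    return _AA3[aa]


#: codon → synonymous family label (Leu/Ser split; stops labelled 'Stop')
FAMILY_OF: dict[str, str] = {c: _family_label(c) for c in CODONS}

#: family label → tuple of member codons (fixed TCAG order)
FAMILY_CODONS: dict[str, tuple[str, ...]] = {}
for _c in CODONS:
    FAMILY_CODONS.setdefault(FAMILY_OF[_c], tuple())
    FAMILY_CODONS[FAMILY_OF[_c]] += (_c,)

FAMILY_SIZE: dict[str, int] = {f: len(cs) for f, cs in FAMILY_CODONS.items()}

#: amino-acid families, stops excluded
AA_FAMILIES: tuple[str, ...] = tuple(
    f for f in FAMILY_CODONS if f != "Stop")


def translate_mito(cds: str) -> str:
    """Translate a coding sequence under the invertebrate mitochondrial
    code; stop codons appear as '*'.

    Complete codons only — trailing 1–2 nt beyond the last full codon are
    ignored (the incomplete-stop convention).  Internal stops are not
    fatal; :func:`internal_stop_positions` locates them.  Raises
    ``ValueError`` for input shorter than one codon.
    """
    s = cds.upper().replace("U", "T")
    if len(s) < 3:
        raise ValueError("coding sequence shorter than one codon")
    return "".join(CODON_TO_AA.get(s[i:i + 3], "X")
                   for i in range(0, len(s) - len(s) % 3, 3))


def internal_stop_positions(cds: str) -> list[int]:
    """0-based codon indices of stop codons before the final codon."""
    protein = translate_mito(cds)
    return [i for i, aa in enumerate(protein[:-1]) if aa == "*"]


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts with optional RSCU values.

    ``n_incomplete_stops`` counts input sequences whose length was not a
    multiple of 3 (trailing incomplete stop trimmed).  Families with zero
    observations are listed in ``unobserved_families`` and carry RSCU 0.
    """

    counts: dict[str, int]
    n_incomplete_stops: int = 0
    rscu_values: Optional[dict[str, float]] = None
    unobserved_families: frozenset[str] = frozenset()

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def family_total(self, family: str) -> int:
        return sum(self.counts[c] for c in FAMILY_CODONS[family])

    def compute_rscu(self) -> "CodonUsageTable":
        """Return a copy with RSCU filled in (stop codons excluded)."""
        values: dict[str, float] = {}
        unobserved: set[str] = set()
        for family in AA_FAMILIES:
            total = self.family_total(family)
            k = FAMILY_SIZE[family]
            if total == 0:
                unobserved.add(family)
                for c in FAMILY_CODONS[family]:
                    values[c] = 0.0
            else:
                for c in FAMILY_CODONS[family]:
                    values[c] = self.counts[c] * k / total
        return replace(self, rscu_values=values,
                       unobserved_families=frozenset(unobserved))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: codon, aa, family, count, rscu (2 dp)."""
        rows = []
        for c in CODONS:
            fam = FAMILY_OF[c]
            rows.append({
                "codon": c, "aa": CODON_TO_AA[c], "family": fam,
                "count": self.counts[c],
                "rscu": (round(self.rscu_values[c], 2)
                         if self.rscu_values and fam != "Stop" else None),
            })
        return pd.DataFrame(rows)


def codon_counts(cds_list: Iterable[str]) -> CodonUsageTable:
    """Tally complete codons over a collection of coding sequences.

    Each sequence must be oriented 5'→3' on its coding strand.  A sequence
    of length not divisible by 3 contributes ⌊len/3⌋ codons and increments
    ``n_incomplete_stops``.  Codons containing ambiguity symbols are
    skipped.
    """
    counts = {c: 0 for c in CODONS}
    n_incomplete = 0
    n_seqs = 0
    for cds in cds_list:
        n_seqs += 1
        s = cds.upper().replace("U", "T")
        if len(s) % 3:
            n_incomplete += 1
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    if n_seqs == 0:
        raise ValueError("no coding sequences given")
    return CodonUsageTable(counts=counts, n_incomplete_stops=n_incomplete)


def rscu(t: CodonUsageTable) -> CodonUsageTable:
    """Functional alias for :meth:`CodonUsageTable.compute_rscu`."""
    return t.compute_rscu()


def amino_acid_composition(t: CodonUsageTable) -> pd.DataFrame:
    """Per-family codon totals ranked by usage (stop codons excluded).

    Columns: family, count, pct (of all non-stop codons), rank.  Ties are
    broken by family name for determinism.
    """
    totals = {f: t.family_total(f) for f in AA_FAMILIES}
    grand = sum(totals.values())
    rows = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame([
        {"family": f, "count": n,
         "pct": 100.0 * n / grand if grand else 0.0,
         "rank": i + 1}
        for i, (f, n) in enumerate(rows)
    ])


def plot_rscu(t: CodonUsageTable, ax=None):
    """Stacked-by-family RSCU bar chart in the style mitogenome papers
    use; returns the matplotlib Axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = t if t.rscu_values is not None else t.compute_rscu()
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    x = 0.0
    ticks, labels = [], []
    for family in sorted(AA_FAMILIES):
        bottom = 0.0
        for codon in FAMILY_CODONS[family]:
            ax.bar(x, table.rscu_values[codon], bottom=bottom, width=0.8)
            bottom += table.rscu_values[codon]
        ticks.append(x)
        labels.append(family)
        x += 1.0
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90)
    ax.set_ylabel("RSCU")
    return ax
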