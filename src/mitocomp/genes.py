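"""Canonical metazoan mitochondrial gene names, classes, and aliases.

The standard bilaterian mitogenome carries 13 protein-coding genes (PCGs),
22 tRNAs, 2 rRNAs and one non-coding control region (CR).  Gene labels in
the literature vary (COI vs cox1, 12S vs rrnS, tRNA-Leu(UUR) vs trnL2);
this module maps them onto one canonical vocabulary so that annotation
tables from different sources compare cleanly.
"""

from __future__ import annotations

import re

PCG_NAMES = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)

TRNA_NAMES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")

CONTROL_REGION = "CR"

#: every canonical label of the standard 37-gene + CR complement
STANDARD_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + (CONTROL_REGION,)

#: expected per-class counts for a complete genome
STANDARD_COUNTS = {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}

_CANONICAL_LOWER = {n.lower(): n for n in STANDARD_NAMES}

# commonly seen synonyms, lower-cased
_ALIASES = {
    "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cyt b": "cob", "cytochrome b": "cob",
    "atpase6": "atp6", "atpase 6": "atp6",
    "atpase8": "atp8", "atpase 8": "atp8",
    "12s": "rrnS", "12s rrna": "rrnS", "srrna": "rrnS", "s-rrna": "rrnS",
    "rrns": "rrnS", "12s ribosomal rna": "rrnS",
    "16s": "rrnL", "16s rrna": "rrnL", "lrrna": "rrnL", "l-rrna": "rrnL",
    "rrnl": "rrnL", "16s ribosomal rna": "rrnL",
    "cr": "CR", "d-loop": "CR", "dloop": "CR", "control region": "CR",
    "at-rich region": "CR", "putative control region": "CR",
    "trnl(uur)": "trnL2", "trnl (uur)": "trnL2", "trnl-uur": "trnL2",
    "trnl(cun)": "trnL1", "trnl (cun)": "trnL1", "trnl-cun": "trnL1",
    "trns(agn)": "trnS1", "trns (agn)": "trnS1", "trns-agn": "trnS1",
    "trns(ucn)": "trnS2", "trns (ucn)": "trnS2", "trns-ucn": "trnS2",
}

for i in range(1, 7):
    _ALIASES[f"nd{i}"] = f"nad{i}"
_ALIASES["nd4l"] = "nad4L"

_TRN_RE = re.compile(r"^trn\s*([a-z])\s*([12])?$")


class UnknownGeneError(ValueError):
    """Raised when a gene label cannot be mapped onto the canonical set."""


def normalize_gene_name(name: str) -> str:
    """Map a free-text gene label to its canonical name.

    Case-insensitive; accepts the common COI/ND/12S style synonyms and the
    anticodon-disambiguated Leu/Ser forms.  Raises :class:`UnknownGeneError`
    for labels outside the standard complement.
    """
    key = name.strip()
    low = key.lower()
    if low in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[low]
    if low in _ALIASES:
        return _ALIASES[low]
    m = _TRN_RE.match(low)
    if m:
        letter, digit = m.group(1).upper(), m.group(2)
        cand = f"trn{letter}{digit or ''}"
        if cand in STANDARD_NAMES:
            return cand
        if cand in ("trnL", "trnS"):
            raise UnknownGeneError(
                f"{name!r} is ambiguous: use {cand}1/{cand}2 or the "
                f"anticodon form, e.g. {cand}(UUR)"
            )
    raise UnknownGeneError(f"unknown mitochondrial gene label: {name!r}")


def gene_class(name: str) -> str:
    """Gene class ('PCG', 'tRNA', 'rRNA' or 'CR') of a canonical name.

    The mapping is fixed: cox*/nad*/atp*/cob are PCGs, trn* are tRNAs,
    rrn* are rRNAs, CR is the control region.
    """
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_REGION:
        return "CR"
    # best-effort for user-supplied non-standard complements
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if low.startswith(("cox", "nad", "atp", "cob", "nd", "co")):
        return "PCG"
    raise UnknownGeneError(f"cannot derive a gene class for {name!r}")
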