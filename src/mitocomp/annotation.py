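"""Mitochondrial genome annotation tables: model, I/O, and validation.

The central objects are :class:`GeneFeature` (one annotated gene or region
with 1-based inclusive circular coordinates) and :class:`MitoAnnotation`
(the ordered feature set of one circular genome).  Annotation summaries in
mitogenome papers print, per gene: direction (F = majority strand,
R = minority strand), location, size in bp, and the intergenic spacer to
the next gene (negative = overlap).  Printed size/spacer columns are kept
verbatim so :func:`validate_annotation` can cross-check them against the
coordinates — published tables do occasionally contain internally
inconsistent rows, and finding them is the point of the validator.

Coordinates are 1-based inclusive throughout; conversion to 0-based
half-open happens only at the I/O boundary (:func:`to_bed`).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from . import genes
from .genes import gene_class, normalize_gene_name, UnknownGeneError

__all__ = [
    "GeneFeature", "MitoAnnotation", "ValidationIssue", "ValidationReport",
    "AnnotationError", "parse_feature_table", "write_feature_table",
    "feature_length", "intergenic_spacers", "validate_annotation",
    "extract_feature_seq", "reverse_complement", "to_bed",
    "read_genbank", "read_fasta", "load_perisesarma_bidens",
]


class AnnotationError(ValueError):
    """Malformed annotation input."""


# all dash-like characters that appear in published tables: ASCII hyphen,
# en dash, em dash, Unicode minus
_DASHES = "‐‒–—−"
_DASH_TRANS = str.maketrans({c: "-" for c in _DASHES})

_COMPLEMENT = str.maketrans("ACGTUacgtuRYKMBDHVrykmbdhv",
                            "TGCAAtgcaaYRMKVHDByrmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_int(text: str) -> Optional[int]:
    """Parse an integer cell accepting thousands separators and any dash
    variant as the minus sign; a bare dash or empty cell means 'not given'."""
    s = text.strip().translate(_DASH_TRANS).replace(",", "").replace(" ", "")
    if s in ("", "-", "--", "."):
        return None
    try:
        return int(s)
    except ValueError:
        raise AnnotationError(f"unparseable number: {text!r}") from None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a circular genome.

    ``strand`` is 'F' (majority), 'R' (minority) or ``None`` (the control
    region, which has no coding strand).  ``declared_size`` and
    ``declared_spacer`` hold the values printed in the source table, if
    any, for cross-checking; they are never used in computations.
    """

    name: str
    strand: Optional[str]
    start: int
    end: int
    gene_class: str = ""
    declared_size: Optional[int] = None
    declared_spacer: Optional[int] = None

    def __post_init__(self):
        if not self.gene_class:
            object.__setattr__(self, "gene_class", gene_class(self.name))
        if self.start < 1 or self.end < 1:
            raise AnnotationError(
                f"{self.name}: coordinates are 1-based, got "
                f"{self.start}-{self.end}")
        if self.gene_class == "CR":
            if self.strand is not None:
                object.__setattr__(self, "strand", None)
        elif self.strand not in ("F", "R"):
            raise AnnotationError(
                f"{self.name}: strand must be F or R, got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        """True when the feature spans the origin of the circle."""
        return self.end < self.start


def feature_length(f: GeneFeature, genome_length: Optional[int] = None) -> int:
    """Length in bp of a feature; wrapping features need ``genome_length``."""
    if not f.wraps:
        return f.end - f.start + 1
    if genome_length is None:
        raise AnnotationError(
            f"{f.name}: wrapping feature needs a genome length")
    return (genome_length - f.start + 1) + f.end


@dataclass(frozen=True)
class MitoAnnotation:
    """Ordered feature collection of one circular mitochondrial genome.

    ``features`` are stored in the order given (for a published table this
    equals majority-strand positional order); ``genome_length`` defaults to
    the maximum end coordinate when not supplied.
    """

    features: tuple[GeneFeature, ...]
    genome_length: int = 0
    circular: bool = True
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        if not self.features:
            raise AnnotationError("empty table: annotation needs features")
        if self.genome_length <= 0:
            object.__setattr__(
                self, "genome_length",
                max(max(f.end, f.start) for f in self.features))

    def sorted_features(self) -> tuple[GeneFeature, ...]:
        """Features in positional order (by start; wrap-around last)."""
        return tuple(sorted(self.features, key=lambda f: f.start))

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, cls: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.gene_class == cls)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.gene_class] = counts.get(f.gene_class, 0) + 1
        return counts


_LOCATION_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_feature_table(text: str, *, genome_length: Optional[int] = None,
                        allow_nonstandard: bool = False,
                        source_id: str = "") -> MitoAnnotation:
    """Parse a TSV annotation table into a :class:`MitoAnnotation`.

    Expected columns (header required, case-insensitive): ``gene``,
    ``direction`` (or ``strand``), then either ``location`` ("start–end")
    or separate ``start``/``end``, and optional ``size`` and
    ``intergenic`` (or ``spacer``).  Thousands separators and every common
    dash/minus variant are accepted; a bare dash means "not declared".

    ``allow_nonstandard=True`` admits gene labels outside the standard
    37+CR complement and duplicate labels (multi-copy genes).
    """
    rows = [line.rstrip("\n") for line in io.StringIO(text)
            if line.strip() and not line.lstrip().startswith("#")]
    if not rows:
        raise AnnotationError("empty table: no rows")
    header = [h.strip().lower() for h in rows[0].split("\t")]
    col = {name: i for i, name in enumerate(header)}
    if "strand" in col and "direction" not in col:
        col["direction"] = col["strand"]
    if "spacer" in col and "intergenic" not in col:
        col["intergenic"] = col["spacer"]
    if "gene" not in col:
        raise AnnotationError("missing 'gene' column")
    if rows[1:] == []:
        raise AnnotationError("empty table: header only")

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for line in rows[1:]:
        cells = line.split("\t")

        def cell(name: str) -> str:
            i = col.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        raw_name = cell("gene")
        try:
            name = normalize_gene_name(raw_name)
        except UnknownGeneError:
            if not allow_nonstandard:
                raise
            name = raw_name.strip()
        if name in seen and not allow_nonstandard:
            raise AnnotationError(f"duplicate gene name: {name}")
        seen.add(name)

        if "location" in col and cell("location"):
            loc = cell("location").translate(_DASH_TRANS)
            loc = loc.replace(",", "").replace(" ", "")
            m = _LOCATION_RE.match(loc)
            if not m:
                raise AnnotationError(
                    f"{name}: unparseable location {cell('location')!r}")
            start, end = int(m.group(1)), int(m.group(2))
        else:
            start, end = _clean_int(cell("start")), _clean_int(cell("end"))
            if start is None or end is None:
                raise AnnotationError(f"{name}: missing coordinates")

        d = cell("direction").translate(_DASH_TRANS).strip().lower()
        if d in ("f", "+", "h", "heavy", "majority"):
            strand: Optional[str] = "F"
        elif d in ("r", "l", "light", "minority"):
            strand = "R"
        elif d in ("", "-", ".", "none", "na"):
            strand = None
        else:
            raise AnnotationError(f"{name}: unknown direction {d!r}")
        try:
            cls = gene_class(name)
        except UnknownGeneError:
            # non-standard label admitted by the flag; class from strand
            cls = "CR" if strand is None else "PCG"
        if strand is None and cls != "CR":
            # non-CR rows must carry a direction
            raise AnnotationError(f"{name}: missing direction")

        features.append(GeneFeature(
            name=name, strand=strand, start=start, end=end, gene_class=cls,
            declared_size=_clean_int(cell("size")),
            declared_spacer=_clean_int(cell("intergenic")),
        ))
    return MitoAnnotation(features=tuple(features),
                          genome_length=genome_length or 0,
                          source_id=source_id)


def write_feature_table(a: MitoAnnotation) -> str:
    """Serialize an annotation back to normalized TSV.

    Declared size/spacer columns are written verbatim (blank when absent),
    so ``parse ∘ write`` is the identity field-for-field.
    """
    out = ["gene\tdirection\tstart\tend\tsize\tintergenic"]
    for f in a.features:
        out.append("\t".join([
            f.name,
            f.strand or "-",
            str(f.start), str(f.end),
            "" if f.declared_size is None else str(f.declared_size),
            "" if f.declared_spacer is None else str(f.declared_spacer),
        ]))
    return "\n".join(out) + "\n"


def to_bed(a: MitoAnnotation, chrom: Optional[str] = None) -> str:
    """Export features as BED (0-based half-open).  Features wrapping the
    origin are split into two blocks."""
    chrom = chrom or a.source_id or "mitogenome"
    lines = []
    for f in a.features:
        strand = {"F": "+", "R": "-", None: "."}[f.strand]
        if not f.wraps:
            lines.append(f"{chrom}\t{f.start - 1}\t{f.end}\t{f.name}\t0\t{strand}")
        else:
            lines.append(f"{chrom}\t{f.start - 1}\t{a.genome_length}\t{f.name}\t0\t{strand}")
            lines.append(f"{chrom}\t0\t{f.end}\t{f.name}\t0\t{strand}")
    return "\n".join(lines) + "\n"


def intergenic_spacers(a: MitoAnnotation) -> list[tuple[str, int]]:
    """Spacer after each feature, in positional order, wrap included.

    spacer(i) = start(i+1) − end(i) − 1; negative values denote overlap.
    The last feature's spacer wraps the origin:
    start(first) + genome_length − end(last) − 1.
    """
    feats = a.sorted_features()
    if len(feats) < 2:
        raise AnnotationError("need at least 2 features for spacers")
    out = []
    for f, g in zip(feats, feats[1:]):
        out.append((f.name, g.start - f.end - 1))
    last, first = feats[-1], feats[0]
    out.append((last.name, first.start + a.genome_length - last.end - 1))
    return out


@dataclass(frozen=True)
class ValidationIssue:
    feature: str
    code: str  # SIZE_MISMATCH | SPACER_MISMATCH | COUNT_ANOMALY | COORD_OUT_OF_RANGE | OVERLAP_NOTE
    detail: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_annotation`.

    ``issues`` are genuine internal inconsistencies — an empty list means
    the annotation is internally consistent.  ``notes`` hold informational
    OVERLAP_NOTE entries (same-strand PCG overlaps are common and real).
    """

    issues: list[ValidationIssue] = field(default_factory=list)
    notes: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def flagged_features(self) -> list[str]:
        return sorted({i.feature for i in self.issues})


def validate_annotation(a: MitoAnnotation, *,
                        genome_seq: Optional[str] = None,
                        expect_complete: Optional[bool] = None
                        ) -> ValidationReport:
    """Cross-check declared sizes/spacers against coordinates.

    Flags SIZE_MISMATCH / SPACER_MISMATCH where a printed value disagrees
    with the coordinate arithmetic, COORD_OUT_OF_RANGE for coordinates off
    the genome, and COUNT_ANOMALY when the per-class gene counts of a
    complete genome deviate from 13 PCG / 22 tRNA / 2 rRNA / 1 CR.  The
    completeness check applies when the annotation contains a control
    region (or ``expect_complete=True``), so partial toy tables validate
    clean.  Same-strand PCG overlaps are recorded as notes, not issues.
    """
    report = ValidationReport()
    L = a.genome_length
    if genome_seq is not None and len(genome_seq) != L:
        # with a sequence in hand the sequence length wins
        report.issues.append(ValidationIssue(
            "genome", "COORD_OUT_OF_RANGE",
            f"annotation genome_length {L} != sequence length {len(genome_seq)}"))
        L = len(genome_seq)

    for f in a.features:
        if f.start > L or f.end > L:
            report.issues.append(ValidationIssue(
                f.name, "COORD_OUT_OF_RANGE",
                f"{f.start}-{f.end} exceeds genome length {L}"))
            continue
        if f.declared_size is not None:
            computed = feature_length(f, L)
            if computed != f.declared_size:
                report.issues.append(ValidationIssue(
                    f.name, "SIZE_MISMATCH",
                    f"declared {f.declared_size} != computed {computed}"))

    spacers = dict_spacers = None
    if len(a.features) >= 2:
        dict_spacers = dict(intergenic_spacers(a))
        for f in a.features:
            if f.declared_spacer is None:
                continue
            computed = dict_spacers.get(f.name)
            if computed is not None and computed != f.declared_spacer:
                report.issues.append(ValidationIssue(
                    f.name, "SPACER_MISMATCH",
                    f"declared {f.declared_spacer} != computed {computed}"))

    if expect_complete is None:
        expect_complete = any(f.gene_class == "CR" for f in a.features)
    if expect_complete:
        counts = a.class_counts()
        for cls, want in genes.STANDARD_COUNTS.items():
            got = counts.get(cls, 0)
            if got != want:
                report.issues.append(ValidationIssue(
                    "genome", "COUNT_ANOMALY",
                    f"{got} {cls} features (expected {want})"))

    # informational: same-strand PCG overlaps
    feats = a.sorted_features()
    for f, g in zip(feats, feats[1:]):
        if (g.start <= f.end and f.gene_class == g.gene_class == "PCG"
                and f.strand == g.strand):
            report.notes.append(ValidationIssue(
                f.name, "OVERLAP_NOTE",
                f"{f.name}/{g.name} overlap by {f.end - g.start + 1} bp "
                f"on strand {f.strand}"))
    return report


def extract_feature_seq(genome: str, f: GeneFeature, *,
                        circular: bool = True) -> str:
    """Subsequence on [start, end], reverse-complemented for R-strand
    features; wrapping features concatenate tail + head of the circle."""
    L = len(genome)
    if f.wraps:
        if not circular:
            raise AnnotationError(f"{f.name}: wrapping feature on linear sequence")
        if f.start > L or f.end > L:
            raise AnnotationError(f"{f.name}: coordinates exceed sequence length")
        sub = genome[f.start - 1:] + genome[:f.end]
    else:
        if f.end > L:
            raise AnnotationError(f"{f.name}: coordinates exceed sequence length")
        sub = genome[f.start - 1:f.end]
    return reverse_complement(sub) if f.strand == "R" else sub


# ---------------------------------------------------------------- file I/O

def read_fasta(path) -> str:
    """First sequence of a FASTA file, as an upper-case string."""
    from Bio import SeqIO
    record = next(SeqIO.parse(path, "fasta"))
    return str(record.seq).upper()


_GB_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def read_genbank(path) -> tuple[MitoAnnotation, str]:
    """Parse a GenBank flat file into an annotation plus its sequence.

    CDS/tRNA/rRNA/D-loop features are mapped to :class:`GeneFeature`
    via their gene/product qualifiers; unrecognized labels are skipped.
    """
    from Bio import SeqIO
    record = SeqIO.read(path, "genbank")
    seq = str(record.seq).upper()
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in _GB_TYPES:
            continue
        label = (feat.qualifiers.get("gene") or
                 feat.qualifiers.get("product") or [""])[0]
        if feat.type == "D-loop" and not label:
            label = "CR"
        try:
            name = normalize_gene_name(label)
        except UnknownGeneError:
            continue
        if name in seen:
            continue
        seen.add(name)
        start = int(feat.location.start) + 1  # biopython is 0-based
        end = int(feat.location.end)
        strand = None if name == "CR" else ("R" if feat.location.strand == -1 else "F")
        feats.append(GeneFeature(name=name, strand=strand, start=start, end=end))
    if not feats:
        raise AnnotationError("no recognizable features in GenBank record")
    feats.sort(key=lambda f: f.start)
    return (MitoAnnotation(features=tuple(feats), genome_length=len(seq),
                           source_id=record.id), seq)


def load_perisesarma_bidens() -> MitoAnnotation:
    """The packaged annotation summary of the *Perisesarma bidens*
    mitogenome (GenBank KY808394, 15,641 bp), as published — including one
    internally inconsistent nad4 row that the validator flags."""
    text = (resources.files("mitocomp.data") /
            "perisesarma_bidens_annotation.tsv").read_text(encoding="utf-8")
    return parse_feature_table(text, source_id="KY808394")
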