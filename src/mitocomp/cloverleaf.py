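"""Heuristic tRNA cloverleaf detection.

Mitochondrial tRNAs (65–73 nt in brachyurans) fold into a cloverleaf of
four elements: the acceptor stem (7 bp, closing the two ends), the DHU
(dihydrouridine) arm, the anticodon arm (stem plus a 7-nt loop whose
central triplet is the anticodon), and the T arm.  In many arthropod
mitogenomes trnS1 (AGN) lacks a stable DHU arm; detecting that variant is
the purpose of this module.

This is an arm detector, not a thermodynamic folder: it runs a
deterministic constrained search over stem placements and reports the
highest-scoring consistent assignment.  The search respects cloverleaf
geometry: the DHU stem starts within a short connector of the acceptor
stem, and the T stem ends hard against the acceptor 3' side.  Scoring
counts Watson–Crick pairs as 1 and G·U wobble pairs as 0.5.  A stem is
accepted only when every stem position pairs (WC or wobble) and at least
two pairs are canonical.
Ties are broken deterministically: higher total score, then stronger
acceptor pairing, then 5'-most DHU placement, then 5'-most anticodon and
T placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import pandas as pd

from .annotation import MitoAnnotation, extract_feature_seq

__all__ = [
    "CloverleafConfig", "Arm", "AcceptorStem", "CloverleafReport",
    "fold_cloverleaf", "classify_trnas", "TrnaClassification",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_score(x: str, y: str, wc_weight: float, wobble_weight: float) -> float:
    if (x, y) in _WC:
        return wc_weight
    if (x, y) in _WOBBLE:
        return wobble_weight
    return 0.0


@dataclass(frozen=True)
class CloverleafConfig:
    """Tunable stem-length bounds and scoring weights (field defaults)."""

    acceptor_len: int = 7
    acceptor_min_pairs: int = 5          # of the 7 positions, WC or wobble
    acceptor_overhangs: tuple[int, ...] = (1, 0, 2)  # 3' unpaired tail tried
    ac_stem_lengths: tuple[int, ...] = (5, 4)
    ac_loop_len: int = 7                 # anticodon centred in a 7-nt loop
    dhu_stem_lengths: tuple[int, ...] = (3, 4)
    dhu_loop_range: tuple[int, int] = (4, 12)
    dhu_connector_max: int = 3    # DHU stem starts ≤3 nt after the acceptor
    t_stem_lengths: tuple[int, ...] = (3, 4, 5)
    t_loop_range: tuple[int, int] = (3, 9)
    t_tail_max: int = 1           # T stem ends ≤1 nt before the 3' acceptor
    wc_weight: float = 1.0
    wobble_weight: float = 0.5
    min_wc_pairs: int = 2                # minimum canonical evidence per stem
    min_len: int = 40
    max_len: int = 120


DEFAULT_CONFIG = CloverleafConfig()


@dataclass(frozen=True)
class Arm:
    """One stem-loop: 0-based start of the 5' stem strand, stem and loop
    lengths, and its pairing score."""

    start: int
    stem_len: int
    loop_len: int
    score: float


@dataclass(frozen=True)
class AcceptorStem:
    length: int
    n_pairs: int          # positions paired (WC or wobble)
    n_wobble: int
    score: float
    overhang: int         # unpaired 3' nucleotides beyond the stem
    ok: bool


@dataclass(frozen=True)
class CloverleafReport:
    """Arm assignment for one tRNA sequence.

    ``classification`` is 'cloverleaf' (all four elements found),
    'dhu_missing' (all but the DHU arm) or 'non_canonical'.
    """

    length: int
    acceptor: AcceptorStem
    dhu: Optional[Arm]
    anticodon_arm: Optional[Arm]
    t_arm: Optional[Arm]
    anticodon: Optional[str]
    anticodon_loop: Optional[str]
    classification: str
    score: float

    @property
    def is_cloverleaf(self) -> bool:
        return self.classification == "cloverleaf"

    @property
    def dhu_present(self) -> bool:
        return self.dhu is not None

    def dot_bracket(self) -> str:
        """Dot-bracket string of the assigned stems."""
        s = ["."] * self.length
        def mark(start: int, stem: int, loop: int) -> None:
            for i in range(stem):
                s[start + i] = "("
                s[start + 2 * stem + loop - 1 - i] = ")"
        if self.acceptor.ok:
            k = self.acceptor.length
            for i in range(k):
                s[i] = "("
                s[self.length - self.acceptor.overhang - 1 - i] = ")"
        for arm in (self.dhu, self.anticodon_arm, self.t_arm):
            if arm is not None:
                mark(arm.start, arm.stem_len, arm.loop_len)
        return "".join(s)


def _stem_score(seq: str, start: int, stem: int, loop: int,
                cfg: CloverleafConfig) -> Optional[float]:
    """Score a candidate hairpin; None when it fails the pairing rules."""
    score = 0.0
    n_wc = 0
    for i in range(stem):
        x = seq[start + i]
        y = seq[start + 2 * stem + loop - 1 - i]
        p = _pair_score(x, y, cfg.wc_weight, cfg.wobble_weight)
        if p == 0.0:
            return None
        if (x, y) in _WC:
            n_wc += 1
        score += p
    if n_wc < cfg.min_wc_pairs:
        return None
    return score


def _hairpins(seq: str, lo: int, hi: int, stem_lengths: tuple[int, ...],
              loop_range: tuple[int, int], cfg: CloverleafConfig,
              max_start: Optional[int] = None,
              min_end: Optional[int] = None) -> Iterator[Arm]:
    """Acceptable hairpins fully inside [lo, hi), optionally pinned to
    start by ``max_start`` or to end at/after ``min_end``."""
    for stem in stem_lengths:
        for loop in range(loop_range[0], loop_range[1] + 1):
            span = 2 * stem + loop
            first = lo
            last = hi - span  # inclusive bound for start
            if max_start is not None:
                last = min(last, max_start)
            if min_end is not None:
                first = max(first, min_end - span)
            for start in range(first, last + 1):
                score = _stem_score(seq, start, stem, loop, cfg)
                if score is not None:
                    yield Arm(start=start, stem_len=stem, loop_len=loop,
                              score=score)


def _best_arm(candidates: Iterator[Arm]) -> Optional[Arm]:
    best: Optional[Arm] = None
    for arm in candidates:
        if best is None or (arm.score, -arm.start, arm.stem_len) > \
                (best.score, -best.start, best.stem_len):
            best = arm
    return best


def _acceptor(seq: str, overhang: int, cfg: CloverleafConfig) -> AcceptorStem:
    L = len(seq)
    k = cfg.acceptor_len
    n_pairs = n_wobble = 0
    score = 0.0
    for i in range(k):
        x, y = seq[i], seq[L - overhang - 1 - i]
        p = _pair_score(x, y, cfg.wc_weight, cfg.wobble_weight)
        if p > 0:
            n_pairs += 1
            score += p
            if (x, y) in _WOBBLE:
                n_wobble += 1
    return AcceptorStem(length=k, n_pairs=n_pairs, n_wobble=n_wobble,
                        score=score, overhang=overhang,
                        ok=n_pairs >= cfg.acceptor_min_pairs)


def fold_cloverleaf(seq: str,
                    config: CloverleafConfig = DEFAULT_CONFIG
                    ) -> CloverleafReport:
    """Fold a tRNA gene sequence (5'→3' on its coding strand) into the
    best-scoring cloverleaf assignment.

    Deterministic: identical input yields an identical report.  Raises
    ``ValueError`` when the length is outside the configured bounds.
    """
    s = seq.upper().replace("U", "T")
    L = len(s)
    if not (config.min_len <= L <= config.max_len):
        raise ValueError(
            f"sequence length {L} outside tRNA bounds "
            f"[{config.min_len}, {config.max_len}]")

    best: Optional[tuple] = None  # (score, acc.score, keys..., parts)
    for overhang in config.acceptor_overhangs:
        acc = _acceptor(s, overhang, config)
        lo, hi = config.acceptor_len, L - overhang - config.acceptor_len
        # anticodon arm candidates inside the interior
        ac_candidates = list(_hairpins(
            s, lo, hi, config.ac_stem_lengths,
            (config.ac_loop_len, config.ac_loop_len), config))
        if not ac_candidates:
            ac_candidates = [None]
        dhu_max_start = lo + config.dhu_connector_max
        t_min_end = hi - config.t_tail_max
        for ac in ac_candidates:
            if ac is None:
                dhu = _best_arm(_hairpins(
                    s, lo, hi, config.dhu_stem_lengths,
                    config.dhu_loop_range, config,
                    max_start=dhu_max_start))
                t_arm = None
            else:
                dhu = _best_arm(_hairpins(
                    s, lo, ac.start, config.dhu_stem_lengths,
                    config.dhu_loop_range, config,
                    max_start=dhu_max_start))
                t_arm = _best_arm(_hairpins(
                    s, ac.start + 2 * ac.stem_len + ac.loop_len, hi,
                    config.t_stem_lengths, config.t_loop_range, config,
                    min_end=t_min_end))
            total = (acc.score if acc.ok else 0.0) \
                + sum(a.score for a in (ac, dhu, t_arm) if a is not None)
            n_arms = sum(a is not None for a in (ac, dhu, t_arm)) + acc.ok
            key = (
                total,
                n_arms,
                acc.score,
                -(dhu.start if dhu is not None else L),
                -(ac.start if ac is not None else L),
                -(t_arm.start if t_arm is not None else L),
            )
            if best is None or key > best[0]:
                best = (key, acc, ac, dhu, t_arm, total)

    _, acc, ac, dhu, t_arm, total = best
    anticodon = loop_seq = None
    if ac is not None:
        loop_start = ac.start + ac.stem_len
        loop_seq = s[loop_start:loop_start + ac.loop_len]
        centre = (ac.loop_len - 3) // 2
        anticodon = loop_seq[centre:centre + 3]
    if acc.ok and ac is not None and t_arm is not None:
        classification = "cloverleaf" if dhu is not None else "dhu_missing"
    else:
        classification = "non_canonical"
    return CloverleafReport(
        length=L, acceptor=acc, dhu=dhu, anticodon_arm=ac, t_arm=t_arm,
        anticodon=anticodon, anticodon_loop=loop_seq,
        classification=classification, score=total)


@dataclass
class TrnaClassification:
    """Cloverleaf reports for every tRNA of an annotated genome."""

    table: pd.DataFrame
    reports: dict[str, CloverleafReport]

    @property
    def n_cloverleaf(self) -> int:
        return int((self.table["classification"] == "cloverleaf").sum())

    @property
    def n_dhu_missing(self) -> int:
        return int((self.table["classification"] == "dhu_missing").sum())

    @property
    def dhu_missing(self) -> list[str]:
        return sorted(
            self.table.loc[self.table["classification"] == "dhu_missing",
                           "name"])


def classify_trnas(genome: str, a: MitoAnnotation,
                   config: CloverleafConfig = DEFAULT_CONFIG
                   ) -> TrnaClassification:
    """Fold every annotated tRNA (extracted strand-aware) and tabulate
    cloverleaf vs DHU-missing calls."""
    rows = []
    reports: dict[str, CloverleafReport] = {}
    for f in a.by_class("tRNA"):
        trna_seq = extract_feature_seq(genome, f)
        try:
            rep = fold_cloverleaf(trna_seq, config)
        except ValueError:
            rows.append({"name": f.name, "strand": f.strand or "-",
                         "length": len(trna_seq),
                         "classification": "length_out_of_bounds",
                         "anticodon": None, "score": 0.0})
            continue
        reports[f.name] = rep
        rows.append({"name": f.name, "strand": f.strand or "-",
                     "length": rep.length,
                     "classification": rep.classification,
                     "anticodon": rep.anticodon, "score": rep.score})
    columns = ["name", "strand", "length", "classification", "anticodon",
               "score"]
    return TrnaClassification(
        table=pd.DataFrame(rows, columns=columns), reports=reports)
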