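"""Combined-TE detection: fragment assembly, nesting, and TPRT hallmarks.

The central observation this module operationalises: when a young TE
(guest) retrotransposes into an older TE (host), the repeat annotator
reports the host as two or more fragments that share one linkage ``id``
(``frag_id``), flanking the guest.  Re-linking those fragments and
scanning for guests inside fragmented hosts recovers combined ("together")
TE pairs genome-wide; flanking target-site duplications (TSDs) and poly-A
tails are the hallmarks of target-primed reverse transcription (TPRT).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .io_formats import RepeatFeature, SequenceRecord

__all__ = [
    "RepeatElement",
    "TECombination",
    "TPRTHallmarks",
    "RepeatClassCounts",
    "UnknownRepeatError",
    "InsufficientFlankError",
    "count_repeat_classes",
    "assemble_elements",
    "find_combinations",
    "orientation_summary",
    "detect_tsd",
]

TSD_MIN_LEN = 2
TSD_MAX_LEN = 20
#: TSDs shorter than this are reported but flagged low-confidence
TSD_CONFIDENCE_LEN = 5
POLYA_MIN_LEN = 8
POLYA_PURITY = 1.0


class UnknownRepeatError(KeyError):
    """A query repeat name/family matches nothing in the table."""


class InsufficientFlankError(ValueError):
    """An element sits too close to a sequence end for TSD detection."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RepeatElement:
    """An assembled repeat: all fragments sharing one linkage id."""

    fragments: list[RepeatFeature]

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("element needs at least one fragment")
        first = self.fragments[0]
        for f in self.fragments:
            if (f.chrom, f.strand, f.rep_name, f.frag_id) != (
                    first.chrom, first.strand, first.rep_name, first.frag_id):
                raise ValueError("fragments disagree on chrom/strand/name/id")
        self.fragments.sort(key=lambda f: f.start)
        for a, b in zip(self.fragments, self.fragments[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"overlapping fragments for {first.rep_name} "
                    f"id={first.frag_id} on {first.chrom}; keeping merged span")

    @property
    def chrom(self) -> str:
        return self.fragments[0].chrom

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def end(self) -> int:
        return self.fragments[-1].end

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def strand(self) -> str:
        return self.fragments[0].strand

    @property
    def rep_name(self) -> str:
        return self.fragments[0].rep_name

    @property
    def rep_family(self) -> str:
        return self.fragments[0].rep_family

    @property
    def rep_class(self) -> str:
        return self.fragments[0].rep_class

    @property
    def frag_id(self) -> int:
        return self.fragments[0].frag_id

    @property
    def is_fragmented(self) -> bool:
        return len(self.fragments) > 1

    def fragment_length(self) -> int:
        """Total annotated length (sum of fragment lengths, gaps excluded)."""
        return sum(len(f) for f in self.fragments)


@dataclass
class TECombination:
    """A host/guest TE pair found together: nested or adjacent."""

    host: RepeatElement
    guest: RepeatElement
    relation: str              # "nested" | "adjacent"
    gap: int = 0               # bp between the elements (0 for nested)
    context: Optional[object] = None  # filled in by genomic_context

    def __post_init__(self):
        if self.relation not in ("nested", "adjacent"):
            raise ValueError(f"bad relation {self.relation!r}")
        if self.relation == "nested":
            if not self.host.is_fragmented:
                raise ValueError("nested relation requires a fragmented host")
            if not (self.host.start < self.guest.start
                    and self.guest.end < self.host.end):
                raise ValueError("nested guest must lie strictly inside host")

    @property
    def same_orientation(self) -> bool:
        return self.host.strand == self.guest.strand

    @property
    def chrom(self) -> str:
        return self.host.chrom

    @property
    def start(self) -> int:
        return min(self.host.start, self.guest.start)

    @property
    def end(self) -> int:
        return max(self.host.end, self.guest.end)


@dataclass
class TPRTHallmarks:
    """TPRT insertion hallmarks detected around one element."""

    tsd: Optional[str]
    tsd_mismatches: int
    polya_len: int
    low_confidence: bool = False

    def __post_init__(self):
        if self.tsd is not None and not (
                TSD_MIN_LEN <= len(self.tsd) <= TSD_MAX_LEN):
            raise ValueError("TSD length outside [2, 20]")


@dataclass
class RepeatClassCounts:
    """Counts of repeat categories, per assembled element and per raw row."""

    elements: dict[str, int]
    rows: dict[str, int]


# ---------------------------------------------------------------------------
# Assembly and counting
# ---------------------------------------------------------------------------

def assemble_elements(repeats: Iterable[RepeatFeature]) -> list[RepeatElement]:
    """Group annotation rows into elements by (chrom, frag_id, name, strand).

    Fragments of one original insertion share the rmsk linkage id; an
    element with more than one row is flagged ``is_fragmented`` — the
    signature of a disrupted (e.g. nested-into) insertion.
    """
    groups: dict[tuple, list[RepeatFeature]] = defaultdict(list)
    for f in repeats:
        groups[(f.chrom, f.frag_id, f.rep_name, f.strand)].append(f)
    elements = [RepeatElement(fragments=rows) for rows in groups.values()]
    elements.sort(key=lambda e: (e.chrom, e.start, e.end))
    return elements


def count_repeat_classes(repeats: Iterable[RepeatFeature]) -> RepeatClassCounts:
    """Count total TEs, SINEs, AluSp and MIR, per element and per raw row."""
    repeats = list(repeats)
    elements = assemble_elements(repeats)

    def tally(items, name_of, class_of) -> dict[str, int]:
        c = Counter()
        for it in items:
            c["total_te"] += 1
            if class_of(it) == "SINE":
                c["SINE"] += 1
            if name_of(it) == "AluSp":
                c["AluSp"] += 1
            if name_of(it) == "MIR":
                c["MIR"] += 1
        return {k: c.get(k, 0) for k in ("total_te", "SINE", "AluSp", "MIR")}

    return RepeatClassCounts(
        elements=tally(elements, lambda e: e.rep_name, lambda e: e.rep_class),
        rows=tally(repeats, lambda f: f.rep_name, lambda f: f.rep_class),
    )


# ---------------------------------------------------------------------------
# Combination detection
# ---------------------------------------------------------------------------

def _matches(element: RepeatElement, query: str) -> bool:
    # exact, case-sensitive match on rep_name or rep_family (rmsk style)
    return query in (element.rep_name, element.rep_family)


def find_combinations(
    elements: list[RepeatElement],
    query_host: str,
    query_guest: str,
    max_gap: int = 0,
) -> list[TECombination]:
    """Find every host/guest pair that occurs "together".

    Two relations are reported:

    * **nested** — the guest lies strictly inside the outer span of a
      fragmented host (fragments linked by ``frag_id``); this is the
      biological configuration of sequential integration.
    * **adjacent** — host and guest are consecutive elements on the
      chromosome with ``0 <= gap <= max_gap`` between their spans.

    A pair is reported at most once; nesting takes precedence.  Queries
    match ``rep_name`` or ``rep_family`` exactly (case-sensitive).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    known = {e.rep_name for e in elements} | {e.rep_family for e in elements}
    for q in (query_host, query_guest):
        if q not in known:
            raise UnknownRepeatError(
                f"{q!r} matches no rep_name/rep_family; available: "
                f"{sorted(known)}")

    combos: list[TECombination] = []
    seen: set[tuple] = set()
    by_chrom: dict[str, list[RepeatElement]] = defaultdict(list)
    for e in elements:
        by_chrom[e.chrom].append(e)

    for chrom, elems in sorted(by_chrom.items()):
        elems = sorted(elems, key=lambda e: (e.start, e.end))
        hosts = [e for e in elems if _matches(e, query_host)]
        guests = [e for e in elems if _matches(e, query_guest)]
        # nested: guest strictly inside a fragmented host's outer span
        for h in hosts:
            if not h.is_fragmented:
                continue
            for g in guests:
                if g is h:
                    continue
                if h.start < g.start and g.end < h.end:
                    key = (chrom, h.frag_id, h.rep_name, g.frag_id, g.rep_name)
                    if key not in seen:
                        seen.add(key)
                        combos.append(TECombination(
                            host=h, guest=g, relation="nested", gap=0))
        # adjacent: consecutive elements with a small (<= max_gap) gap
        for prev, nxt in zip(elems, elems[1:]):
            for h, g in ((prev, nxt), (nxt, prev)):
                if not (_matches(h, query_host) and _matches(g, query_guest)):
                    continue
                if h is g:
                    continue
                gap = max(nxt.start - prev.end, 0)
                if gap > max_gap:
                    continue
                key = (chrom, h.frag_id, h.rep_name, g.frag_id, g.rep_name)
                if key in seen:
                    continue
                seen.add(key)
                combos.append(TECombination(
                    host=h, guest=g, relation="adjacent", gap=gap))
    combos.sort(key=lambda c: (c.chrom, c.start, c.end, c.relation))
    return combos


def orientation_summary(combos: Iterable[TECombination]) -> dict:
    """Totals and the percentage of pairs in the same orientation.

    ``percent_same`` is rounded to the nearest integer percent; an empty
    input reports ``None`` (NA).
    """
    combos = list(combos)
    total = len(combos)
    same = sum(1 for c in combos if c.same_orientation)
    return {
        "total": total,
        "same_orientation": same,
        "percent_same": round(100 * same / total) if total else None,
    }


# ---------------------------------------------------------------------------
# TPRT hallmarks
# ---------------------------------------------------------------------------

def _polya_run(seq: str, start: int, step: int, base: str,
               purity: float) -> int:
    """Length of the A/T tract extending from ``start`` in direction ``step``.

    A position extends the tract while the tract's overall ``base``
    fraction stays >= ``purity`` and the tract still ends on ``base``
    (default purity 1.0: a pure homopolymer run).
    """
    n = len(seq)
    i, matched, length, best = start, 0, 0, 0
    while 0 <= i < n:
        length += 1
        if seq[i] == base:
            matched += 1
            if matched / length >= purity:
                best = length
        elif matched / length < purity:
            break
        i += step
    return best


def detect_tsd(
    genome: Union[str, SequenceRecord],
    element: RepeatElement,
    max_len: int = TSD_MAX_LEN,
    min_len: int = TSD_MIN_LEN,
    max_mismatch: int = 0,
    polya_min_len: int = POLYA_MIN_LEN,
    polya_purity: float = POLYA_PURITY,
) -> TPRTHallmarks:
    """Detect the TSD and poly-A tail around an assembled element.

    The poly-A tract is measured just outside the element's 3' end
    (strand-aware: an A-run after the end on +, a T-run before the start
    on −).  The TSD is then the longest duplication (``min_len`` to
    ``max_len`` bp, at most ``max_mismatch`` mismatches) between the
    sequence immediately 5' of the element and the sequence immediately
    past the poly-A tail.  TSDs shorter than 5 bp are flagged
    low-confidence — terminal matches that short arise easily by chance.
    """
    seq = genome.seq if isinstance(genome, SequenceRecord) else genome
    s, e = element.start, element.end
    if e > len(seq):
        raise InsufficientFlankError("element extends past the sequence end")

    if element.strand == "+":
        pa = _polya_run(seq, e, +1, "A", polya_purity)
        left_end, right_start = s, e + pa
    else:
        pa = _polya_run(seq, s - 1, -1, "T", polya_purity)
        left_end, right_start = s - pa, e

    if left_end < max_len or len(seq) - right_start < max_len:
        raise InsufficientFlankError(
            f"need {max_len} bp of flank beyond the poly-A on both sides")

    tsd, mism = None, 0
    for l in range(max_len, min_len - 1, -1):
        a = seq[left_end - l:left_end]
        b = seq[right_start:right_start + l]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch:
            tsd, mism = a, mm
            break
    polya_len = pa if pa >= polya_min_len else 0
    return TPRTHallmarks(
        tsd=tsd,
        tsd_mismatches=mism,
        polya_len=polya_len,
        low_confidence=tsd is not None and len(tsd) < TSD_CONFIDENCE_LEN,
    )
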