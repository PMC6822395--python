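"""Readers and writers for the annotation and sequence formats used throughout.

All genomic intervals are 0-based, half-open (the native start convention of
the UCSC ``rmsk`` and ``refGene`` table dumps and of BED).  Conversion to
1-based closed coordinates happens only at report boundaries, via
:func:`to_one_based` / :func:`from_one_based`.

Gzip-compressed inputs are accepted transparently (files ending in ``.gz``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed line in an annotation table."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RepeatFeature:
    """One row of a repeat-annotation table: a possibly fragmentary TE hit.

    ``frag_id`` is the integer linkage identifier (the rmsk ``id`` column)
    grouping fragments that RepeatMasker attributes to one original
    insertion — the signature by which a host split by a nested guest is
    recognised.  ``milli_div`` is divergence from the repeat consensus in
    per-mil.
    """

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str
    rep_start: int = 0
    rep_end: int = 0
    rep_left: int = 0
    frag_id: int = 0
    milli_div: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.rep_name}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A transcript model in the refGene dialect (0-based, half-open)."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    exon_ends: list[int]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(
                f"{self.name}: exonStarts has {len(self.exon_starts)} entries but "
                f"exonEnds has {len(self.exon_ends)}"
            )
        if not self.exon_starts:
            raise ValueError(f"{self.name}: at least one exon required")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.name}: exon [{s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: exons unsorted or overlapping")
            prev_end = e
        if not (self.cds_start <= self.cds_end):
            raise ValueError(f"{self.name}: cdsStart > cdsEnd")

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Coordinate conversion (report boundaries only)
# ---------------------------------------------------------------------------

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# rmsk tables
# ---------------------------------------------------------------------------

# Full UCSC rmsk.txt column order (17 columns); tables without the leading
# "bin" column (16) are auto-detected by count.
_RMSK_NCOLS = (16, 17)


def read_repeat_table(path: PathLike) -> list[RepeatFeature]:
    """Read a UCSC ``rmsk.txt``-dialect repeat table.

    Accepts 17-column tables (with the leading ``bin``) and 16-column
    tables (without), detected per line.  Strand ``C`` (RepeatMasker's
    complement notation) is normalised to ``-``.
    """
    features: list[RepeatFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in _RMSK_NCOLS:
                raise ParseError(
                    path, lineno,
                    f"expected 16 or 17 tab-separated columns, found {len(cols)}",
                )
            if len(cols) == 17:
                cols = cols[1:]  # drop bin
            (_sw, milli_div, _md, _mi, chrom, start, end, _left, strand,
             rep_name, rep_class, rep_family, rep_start, rep_end, rep_left,
             frag_id) = cols
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
            try:
                feat = RepeatFeature(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rep_name=rep_name,
                    rep_class=rep_class,
                    rep_family=rep_family,
                    rep_start=int(rep_start),
                    rep_end=int(rep_end),
                    rep_left=int(rep_left),
                    frag_id=int(frag_id),
                    milli_div=int(milli_div),
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            features.append(feat)
    return features


def write_repeat_table(features: Iterable[RepeatFeature], path: PathLike) -> None:
    """Write features as a 17-column rmsk.txt-dialect table."""
    with _open_text(path, "wt") as fh:
        for f in features:
            row = [
                "0",                       # bin
                "0",                       # swScore
                str(f.milli_div),
                "0", "0",                  # milliDel, milliIns
                f.chrom, str(f.start), str(f.end),
                "0",                       # genoLeft
                f.strand,
                f.rep_name, f.rep_class, f.rep_family,
                str(f.rep_start), str(f.rep_end), str(f.rep_left),
                str(f.frag_id),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# refGene tables
# ---------------------------------------------------------------------------

_REFGENE_NCOLS = (15, 16)


def _parse_coord_list(text: str, path, lineno: int) -> list[int]:
    # refGene exon lists are comma-terminated: "10,50,"
    items = [t for t in text.split(",") if t]
    try:
        return [int(t) for t in items]
    except ValueError as exc:
        raise ParseError(path, lineno, f"bad coordinate list {text!r}") from exc


def read_gene_table(path: PathLike) -> list[GeneModel]:
    """Read a UCSC ``refGene.txt``-dialect gene table (with or without bin)."""
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in _REFGENE_NCOLS:
                raise ParseError(
                    path, lineno,
                    f"expected 15 or 16 tab-separated columns, found {len(cols)}",
                )
            if len(cols) == 16:
                cols = cols[1:]
            (name, chrom, strand, tx_start, tx_end, cds_start, cds_end,
             exon_count, exon_starts, exon_ends, *_rest) = cols
            starts = _parse_coord_list(exon_starts, path, lineno)
            ends = _parse_coord_list(exon_ends, path, lineno)
            if len(starts) != len(ends):
                raise ParseError(
                    path, lineno,
                    f"exonStarts has {len(starts)} entries, exonEnds {len(ends)}",
                )
            if int(exon_count) != len(starts):
                raise ParseError(
                    path, lineno,
                    f"exonCount={exon_count} but {len(starts)} exon coordinates",
                )
            try:
                gene = GeneModel(
                    name=name, chrom=chrom, strand=strand,
                    tx_start=int(tx_start), tx_end=int(tx_end),
                    cds_start=int(cds_start), cds_end=int(cds_end),
                    exon_starts=starts, exon_ends=ends,
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as a 16-column refGene.txt-dialect table."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            row = [
                "0",  # bin
                g.name, g.chrom, g.strand,
                str(g.tx_start), str(g.tx_end),
                str(g.cds_start), str(g.cds_end),
                str(g.n_exons),
                "".join(f"{s}," for s in g.exon_starts),
                "".join(f"{e}," for e in g.exon_ends),
                "0", g.name, "cmpl", "cmpl",
                "".join("-1," for _ in g.exon_starts),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA and BED
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, on_invalid: str = "error") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    on_invalid:
        ``"error"`` rejects characters outside {A,C,G,T,N}; ``"mask"``
        maps them to N.
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            bad = set(seq) - VALID_BASES
            if bad:
                if on_invalid == "error":
                    raise ValueError(
                        f"record {rec.id!r} contains invalid characters {sorted(bad)}"
                    )
                seq = "".join(c if c in VALID_BASES else "N" for c in seq)
            records.append(SequenceRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike,
                width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_bed(features: Iterable[RepeatFeature], path: PathLike) -> None:
    """Write repeat features as BED6 (0-based half-open, strand in column 6)."""
    with _open_text(path, "wt") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.rep_name}\t"
                f"{f.milli_div}\t{f.strand}\n"
            )
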