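"""Synthetic genomes with planted, manifest-recorded ground truth.

The generator emulates the genomic configuration studied throughout this
package: an old, highly diverged SINE (MIR-like "host") split into two
annotation fragments by a younger SINE (Alu-like "guest") that integrated
inside it by target-primed reverse transcription (TPRT), leaving a
target-site duplication (TSD) and a poly-A tail.  Antisense nested pairs
planted inside gene introns additionally carry an AG splice acceptor in the
guest, a downstream GT donor in the host, and a branch-point heptamer with
a polypyrimidine tract 21–25 nt upstream of the AG — the raw material for
intronic exonization.

Everything is deterministic given the configuration seed, and every planted
event is recorded in a :class:`SyntheticTruth` manifest so downstream
detection can be scored exactly.

The host and guest consensus sequences are fixed synthetic toy consensi of
realistic SINE lengths (262 and 300 nt); they are random sequences, not
Repbase extracts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .io_formats import GeneModel, RepeatFeature, SequenceRecord, _open_text

__all__ = [
    "SimulationConfig",
    "PlantedInsertion",
    "PlantedExon",
    "SyntheticTruth",
    "PackingError",
    "simulate",
    "apply_divergence",
    "make_v1_v2_locus",
    "V1V2Locus",
    "write_truth_manifest",
    "read_truth_manifest",
    "HOST_CONSENSUS",
    "GUEST_CONSENSUS",
    "BP_HEPTAMER",
]

# Fixed synthetic toy consensi (not Repbase extracts).
HOST_CONSENSUS = (  # 262 nt, MIR-like host
    "ATGCCCACTGCTATCCGGTAACGGACGAGGCCTGGTACCTAGGTTTTCATAGAAACTCAA"
    "CACTTCCTCTCAGCAAGGCTTACTACCATGTTAGTCGGGTGACTCAGGAAGCCCTGCGAA"
    "CAGTGGCTAAAGATTGTTACGTCCCAGAAATGACCGCTGACTCAGAAGACCGACCAACCC"
    "TTCGTCCCCCGACGATAATTAGTGTGGTGCGCGGCTACTCCGATCGGAGAGTTCTAAGTC"
    "TGGCCTACCTTTGCAAATCCTA"
)
GUEST_CONSENSUS = (  # 300 nt, Alu-like guest
    "TAGTGACTCCGCAGCAGCATGAGAACATTTATAGCCGAAGGTTTCCACTTTGATTGACAT"
    "AGTGTCCATCACCAACCACTCAAGAATGCATCAGTCCTGGCGACATACTTGCAAAACAGA"
    "CATTAGATCGTGAAGGGTCCAACCGTGAGTCACCACAACGTCGCTATGTACCGGCCACTG"
    "AGCGCTGTATGAGTAGTGCCACACGATAGGAATCAGACGTTCTTAGGTCGTGAAAGCTGG"
    "TCCTGTGGATAACCTTTCCGTCATGGACCATCACAGAAGAGCGATGTCGCCGTCAGAGTC"
)

HOST_NAME, HOST_CLASS, HOST_FAMILY = "MIR", "SINE", "MIR"
GUEST_NAME, GUEST_CLASS, GUEST_FAMILY = "AluSp", "SINE", "Alu"

# Per-column argmax of the default branch-point PWM (see branchpoint module);
# planted as the branch-point motif, with its adenosine at position 6.
BP_HEPTAMER = "TTTTAAC"
# Stop codons in all three reading frames; planted inside candidate exons so
# that exonized variants terminate prematurely.  Contains no AG or GT.
_TRIFRAME_STOP = "TTAATTAATTAA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

_MIN_GAP = 100  # background spacer between planted blocks, bp


class PackingError(ValueError):
    """Planted elements cannot fit on the configured chromosome length."""


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Divergence defaults follow the configuration the package models: the
    ancient host at 30% substitution from consensus (mid MIR range of
    25–35%), the young guest at 10%.  TSD lengths are drawn from 4–16 bp
    (within the 2–20 bp definition of a TSD) and poly-A tails from
    8–30 nt.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 200_000
    n_genes: int = 2
    exons_per_gene: int = 5
    n_host_te: int = 20
    n_guest_te: int = 20
    p_nested: float = 0.4
    tsd_len_range: tuple[int, int] = (4, 16)
    polya_len_range: tuple[int, int] = (8, 30)
    host_divergence: float = 0.30
    guest_divergence: float = 0.10
    plant_splice_signals: bool = True

    def __post_init__(self):
        for name in ("n_chroms", "chrom_len", "n_genes", "exons_per_gene",
                     "n_host_te", "n_guest_te"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_nested", "host_divergence", "guest_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.tsd_len_range
        if not (2 <= lo <= hi <= 20):
            raise ValueError("tsd_len_range must lie within [2, 20]")
        lo, hi = self.polya_len_range
        if not (1 <= lo <= hi):
            raise ValueError("polya_len_range must be a positive range")


@dataclass
class PlantedInsertion:
    """One planted insertion event (a nested pair or a solo element).

    Coordinates are 0-based half-open element spans excluding the TSD and
    poly-A tail.  For nested events ``host_start``/``host_end`` is the
    outer span of the fragmented host (first fragment start to last
    fragment end, guest included).  ``branch`` is the species-tree node
    label under which the insertion is present (phyletic truth).
    """

    chrom: str
    relation: str  # nested | solo_host | solo_guest
    host_start: Optional[int] = None
    host_end: Optional[int] = None
    host_strand: Optional[str] = None
    host_frag_id: Optional[int] = None
    host_tsd: Optional[str] = None
    host_polya_len: Optional[int] = None
    guest_start: Optional[int] = None
    guest_end: Optional[int] = None
    guest_strand: Optional[str] = None
    guest_frag_id: Optional[int] = None
    guest_tsd: Optional[str] = None
    guest_polya_len: Optional[int] = None
    branch: Optional[str] = None


@dataclass
class PlantedExon:
    """A planted exonization signal inside a gene intron.

    Positions are genomic (0-based) starts of the AG acceptor and GT donor
    dinucleotides and of the branch-point adenosine.
    """

    gene: str
    chrom: str
    intron_index: int  # 1-based, transcription order
    acceptor_pos: int
    donor_pos: int
    branchpoint_pos: int


@dataclass
class SyntheticTruth:
    planted_insertions: list[PlantedInsertion] = field(default_factory=list)
    planted_exons: list[PlantedExon] = field(default_factory=list)

    @property
    def nested(self) -> list[PlantedInsertion]:
        return [p for p in self.planted_insertions if p.relation == "nested"]

    def relation_counts(self) -> dict[str, int]:
        counts = {"nested": 0, "solo_host": 0, "solo_guest": 0}
        for p in self.planted_insertions:
            counts[p.relation] = counts.get(p.relation, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def apply_divergence(seq: str, rate: float, seed: int,
                     indel_rate: float = 0.0) -> str:
    """Diverge a sequence from its consensus by random substitutions.

    Each site is substituted with probability ``rate``, always to a
    *different* base (so ``rate=1`` leaves no site unchanged and the
    expected observed divergence equals ``rate``).  Length is preserved
    unless ``indel_rate`` > 0, in which case single-base insertions and
    deletions are additionally applied at that per-site rate (coordinates
    are then no longer reconcilable with a truth manifest; the simulator
    itself never uses indels).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    hit = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, len(seq))
    idx[hit] = (idx[hit] + shift[hit]) % 4
    out = _BASES[idx].tobytes().decode()
    if indel_rate > 0.0:
        chars = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            chars.append(c)
            if indel_rate / 2 <= r < indel_rate:
                chars.append(_random_seq(rng, 1))  # insertion
        out = "".join(chars) or out[:1]
    return out


def _make_tsd(rng: np.random.Generator, lo: int, hi: int,
              forbid_first: str | None = None,
              forbid_last: str | None = None) -> str:
    """A random target-site duplication sequence.

    The base adjacent to the poly-A (or poly-T) tail is constrained away
    from A (or T) so that the planted tail length is unambiguous — the
    homopolymer run in the emitted genome is exactly the planted length.
    """
    n = int(rng.integers(lo, hi + 1))
    tsd = list(_random_seq(rng, n))

    def pick(exclude: set[str]) -> str:
        pool = [b for b in "ACGT" if b not in exclude]
        return pool[int(rng.integers(0, len(pool)))]

    if forbid_first and tsd[0] == forbid_first:
        tsd[0] = pick({forbid_first})
    if forbid_last and tsd[-1] == forbid_last:
        tsd[-1] = pick({forbid_last, tsd[0] if n <= 4 else ""})
    # break short periodicities so the duplication's length is unambiguous
    # (a flanking duplication of length n+k would require period-k content)
    for i in (1, 2, 3):
        if i < n and tsd[i] == tsd[0]:
            exclude = {tsd[0]}
            if forbid_last and i == n - 1:
                exclude.add(forbid_last)
            tsd[i] = pick(exclude)
    return "".join(tsd)


# ---------------------------------------------------------------------------
# Block builders (coordinates relative to the block; chrom filled in later)
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    seq: str
    features: list[RepeatFeature] = field(default_factory=list)
    gene: Optional[GeneModel] = None
    insertion: Optional[PlantedInsertion] = None
    exon: Optional[PlantedExon] = None


def _oriented(element_seq: str, strand: str) -> str:
    return element_seq if strand == "+" else reverse_complement(element_seq)


def _feature(start: int, end: int, strand: str, which: str, frag_id: int,
             milli_div: int, rep_start: int = 1, rep_end: int = 0,
             rep_left: int = 0) -> RepeatFeature:
    name, klass, family = (
        (HOST_NAME, HOST_CLASS, HOST_FAMILY) if which == "host"
        else (GUEST_NAME, GUEST_CLASS, GUEST_FAMILY)
    )
    return RepeatFeature(
        chrom="*", start=start, end=end, strand=strand,
        rep_name=name, rep_class=klass, rep_family=family,
        rep_start=rep_start, rep_end=rep_end or (end - start),
        rep_left=rep_left, frag_id=frag_id, milli_div=milli_div,
    )


def _solo_block(rng, cfg: SimulationConfig, which: str, strand: str,
                frag_id: int) -> _Block:
    consensus = HOST_CONSENSUS if which == "host" else GUEST_CONSENSUS
    rate = cfg.host_divergence if which == "host" else cfg.guest_divergence
    elt = _oriented(apply_divergence(consensus, rate, int(rng.integers(2**31))),
                    strand)
    pa = int(rng.integers(*cfg.polya_len_range))
    tsd = _make_tsd(rng, *cfg.tsd_len_range,
                    forbid_first="A" if strand == "+" else None,
                    forbid_last="T" if strand == "-" else None)
    if strand == "+":
        seq = tsd + elt + "A" * pa + tsd
        span = (len(tsd), len(tsd) + len(elt))
    else:
        seq = tsd + "T" * pa + elt + tsd
        span = (len(tsd) + pa, len(tsd) + pa + len(elt))
    feat = _feature(span[0], span[1], strand, which, frag_id,
                    int(rate * 1000))
    ins = PlantedInsertion(
        chrom="*", relation=f"solo_{which}",
        **{f"{which}_start": span[0], f"{which}_end": span[1],
           f"{which}_strand": strand, f"{which}_frag_id": frag_id,
           f"{which}_tsd": tsd, f"{which}_polya_len": pa},
    )
    return _Block(seq=seq, features=[feat], insertion=ins)


def _nested_core(rng, cfg: SimulationConfig, host_strand: str,
                 guest_strand: str, host_frag_id: int, guest_frag_id: int,
                 scrub: bool = False):
    """Host split by a guest: returns (inner_seq, features, spans, tsds).

    Layout (host '+', guest '+'):
        hostL | tsd_g guest polyA tsd_g | hostR
    The two host fragments share ``host_frag_id`` — the annotation
    signature of nesting.
    """
    host = _oriented(
        apply_divergence(HOST_CONSENSUS, cfg.host_divergence,
                         int(rng.integers(2**31))),
        host_strand)
    guest = _oriented(
        apply_divergence(GUEST_CONSENSUS, cfg.guest_divergence,
                         int(rng.integers(2**31))),
        guest_strand)
    split = int(rng.integers(60, len(host) - 60))
    pa_g = int(rng.integers(*cfg.polya_len_range))
    tsd_g = _make_tsd(rng, *cfg.tsd_len_range,
                      forbid_first="A" if guest_strand == "+" else None,
                      forbid_last="T" if guest_strand == "-" else None)
    host_l, host_r = host[:split], host[split:]
    if guest_strand == "+":
        g_block = tsd_g + guest + "A" * pa_g + tsd_g
        g_off = len(tsd_g)
    else:
        g_block = tsd_g + "T" * pa_g + guest + tsd_g
        g_off = len(tsd_g) + pa_g
    inner = host_l + g_block + host_r
    if scrub:
        inner = _scrub_splice_motifs(inner)
    guest_span = (len(host_l) + g_off, len(host_l) + g_off + len(guest))
    frag1_span = (0, len(host_l))
    frag2_span = (len(inner) - len(host_r), len(inner))
    host_div = int(cfg.host_divergence * 1000)
    guest_div = int(cfg.guest_divergence * 1000)
    L = len(HOST_CONSENSUS)
    feats = [
        _feature(*frag1_span, host_strand, "host", host_frag_id, host_div,
                 rep_start=1, rep_end=split, rep_left=-(L - split)),
        _feature(*guest_span, guest_strand, "guest", guest_frag_id, guest_div),
        _feature(*frag2_span, host_strand, "host", host_frag_id, host_div,
                 rep_start=split + 1, rep_end=L, rep_left=0),
    ]
    return inner, feats, frag2_span, guest_span, tsd_g, pa_g


def _nested_block(rng, cfg: SimulationConfig, host_strand: str,
                  guest_strand: str, host_frag_id: int, guest_frag_id: int,
                  scrub: bool = False, plant_signal: bool = False) -> _Block:
    inner, feats, frag2_span, guest_span, tsd_g, pa_g = _nested_core(
        rng, cfg, host_strand, guest_strand, host_frag_id, guest_frag_id,
        scrub=scrub)
    signal = None
    if plant_signal:
        inner, signal = _plant_signal(rng, inner, guest_span, frag2_span)
    pa_h = int(rng.integers(*cfg.polya_len_range))
    tsd_h = _make_tsd(rng, *cfg.tsd_len_range,
                      forbid_first="A" if host_strand == "+" else None,
                      forbid_last="T" if host_strand == "-" else None)
    if host_strand == "+":
        seq = tsd_h + inner + "A" * pa_h + tsd_h
        off = len(tsd_h)
    else:
        seq = tsd_h + "T" * pa_h + inner + tsd_h
        off = len(tsd_h) + pa_h
    feats = [replace(f, start=f.start + off, end=f.end + off) for f in feats]
    ins = PlantedInsertion(
        chrom="*", relation="nested",
        host_start=off, host_end=off + len(inner),
        host_strand=host_strand, host_frag_id=host_frag_id,
        host_tsd=tsd_h, host_polya_len=pa_h,
        guest_start=guest_span[0] + off, guest_end=guest_span[1] + off,
        guest_strand=guest_strand, guest_frag_id=guest_frag_id,
        guest_tsd=tsd_g, guest_polya_len=pa_g,
    )
    block = _Block(seq=seq, features=feats, insertion=ins)
    if signal is not None:
        # positions still relative to the block
        block.exon = PlantedExon(
            gene="*", chrom="*", intron_index=0,
            acceptor_pos=signal[0] + off, donor_pos=signal[1] + off,
            branchpoint_pos=signal[2] + off,
        )
    return block


def _scrub_splice_motifs(seq: str) -> str:
    """Remove every AG and GT dinucleotide (for fully controlled loci)."""
    chars = list(seq)
    for i in range(len(chars) - 1):
        pair = chars[i] + chars[i + 1]
        if pair in ("AG", "GT"):
            chars[i + 1] = "C"
    return "".join(chars)


def _plant_signal(rng, inner: str, guest_span: tuple[int, int],
                  hostr_span: tuple[int, int],
                  exon_len_range: tuple[int, int] = (60, 150)):
    """Overwrite an AG/GT exonization signal into a nested pair.

    AG acceptor inside the guest, GT donor inside the downstream host
    fragment, branch-point heptamer with its adenosine 21–25 nt upstream of
    the AG, and a pyrimidine-rich tract between branch point and acceptor.
    Returns (new_seq, (acceptor_pos, donor_pos, bp_pos)) relative to inner.
    """
    chars = list(inner)
    g0, g1 = guest_span
    h0, h1 = hostr_span
    # acceptor needs >= 35 nt of guest upstream for BP heptamer + tract
    d_lo, d_hi = h0 + 5, h1 - 5
    lo, hi = exon_len_range
    # exon runs from a+2 to d; restrict a to positions with a feasible donor
    a_lo = max(g0 + 35, d_lo - 2 - hi)
    a_hi = min(g1 - 2, d_hi - 2 - lo)
    if a_lo >= a_hi:
        raise ValueError("nested pair too short to host a splice signal")
    a = int(rng.integers(a_lo, a_hi))
    d = int(rng.integers(max(d_lo, a + 2 + lo), min(d_hi, a + 2 + hi) + 1))
    chars[a:a + 2] = "AG"
    chars[d:d + 2] = "GT"
    dist = int(rng.integers(21, 26))  # BP adenosine offset from intron 3' end
    bp = a + 2 - dist
    chars[bp - 5:bp + 2] = BP_HEPTAMER
    py = "CT"
    for i in range(bp + 2, a):
        chars[i] = py[int(rng.integers(0, 2))]
    return "".join(chars), (a, d, bp)


def _gene_block(rng, cfg: SimulationConfig, name: str,
                nested: Optional[_Block]) -> _Block:
    """A gene model, optionally hosting a nested TE pair in one intron.

    Signal-bearing genes are emitted on the + strand with the TE pair in
    the 4th intron when the exon count allows (the configuration this
    package models); fewer exons fall back to the last intron.
    """
    n_ex = max(cfg.exons_per_gene, 2 if nested is not None else 1)
    exon_lens = rng.integers(80, 201, n_ex)
    intron_lens = rng.integers(400, 1200, max(n_ex - 1, 0))
    te_intron = 0
    if nested is not None:
        te_intron = min(4, n_ex - 1)  # 1-based intron ordinal
    parts: list[str] = []
    exon_starts, exon_ends = [], []
    cursor = 0
    feats: list[RepeatFeature] = []
    ins = None
    exon_truth = None
    for i in range(n_ex):
        exon_starts.append(cursor)
        parts.append(_random_seq(rng, int(exon_lens[i])))
        cursor += int(exon_lens[i])
        exon_ends.append(cursor)
        if i < n_ex - 1:
            if nested is not None and (i + 1) == te_intron:
                pad_up = int(rng.integers(150, 400))
                pad_dn = int(rng.integers(150, 400))
                parts.append(_random_seq(rng, pad_up))
                cursor += pad_up
                off = cursor
                parts.append(nested.seq)
                feats.extend(
                    replace(f, start=f.start + off, end=f.end + off)
                    for f in nested.features)
                ins = replace(nested.insertion,
                              host_start=nested.insertion.host_start + off,
                              host_end=nested.insertion.host_end + off,
                              guest_start=nested.insertion.guest_start + off,
                              guest_end=nested.insertion.guest_end + off)
                if nested.exon is not None:
                    exon_truth = replace(
                        nested.exon, gene=name, intron_index=te_intron,
                        acceptor_pos=nested.exon.acceptor_pos + off,
                        donor_pos=nested.exon.donor_pos + off,
                        branchpoint_pos=nested.exon.branchpoint_pos + off)
                cursor += len(nested.seq)
                parts.append(_random_seq(rng, pad_dn))
                cursor += pad_dn
            else:
                parts.append(_random_seq(rng, int(intron_lens[i])))
                cursor += int(intron_lens[i])
    strand = "+" if nested is not None else ("+", "-")[int(rng.integers(0, 2))]
    cds_start = exon_starts[0] + 19
    cds_end = max(cds_start, exon_ends[-1] - 60)
    gene = GeneModel(
        name=name, chrom="*", strand=strand,
        tx_start=0, tx_end=cursor,
        cds_start=cds_start, cds_end=cds_end,
        exon_starts=exon_starts, exon_ends=exon_ends,
    )
    return _Block(seq="".join(parts), features=feats, gene=gene,
                  insertion=ins, exon=exon_truth)


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig):
    """Generate a genome with planted TE insertions, genes and ground truth.

    Returns ``(genome, repeats, genes, truth)`` where ``genome`` is a list
    of :class:`SequenceRecord`, ``repeats`` a list of rmsk-style
    :class:`RepeatFeature` rows (nested hosts emitted as two fragments
    sharing one ``frag_id``), ``genes`` a list of :class:`GeneModel`, and
    ``truth`` the :class:`SyntheticTruth` manifest.  Deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    frag_counter = 0

    def next_frag() -> int:
        nonlocal frag_counter
        frag_counter += 1
        return frag_counter

    n_nested = min(cfg.n_host_te,
                   int(np.sum(rng.random(cfg.n_guest_te) < cfg.p_nested)))
    n_solo_host = cfg.n_host_te - n_nested
    n_solo_guest = cfg.n_guest_te - n_nested
    n_signal = min(cfg.n_genes, n_nested) if cfg.plant_splice_signals else 0

    blocks: list[_Block] = []
    # genes first (some carrying a signal-bearing nested pair)
    nested_left = n_nested
    for gi in range(cfg.n_genes):
        nested = None
        if gi < n_signal and cfg.exons_per_gene >= 2:
            nested = _nested_block(rng, cfg, "-", "-", next_frag(),
                                   next_frag(), plant_signal=True)
            nested_left -= 1
        blocks.append(_gene_block(rng, cfg, f"gene{gi + 1}", nested))
    for _ in range(nested_left):
        hs = "+-"[int(rng.integers(0, 2))]
        gs = "+-"[int(rng.integers(0, 2))]
        blocks.append(_nested_block(rng, cfg, hs, gs, next_frag(), next_frag()))
    for _ in range(n_solo_host):
        blocks.append(_solo_block(rng, cfg, "host",
                                  "+-"[int(rng.integers(0, 2))], next_frag()))
    for _ in range(n_solo_guest):
        blocks.append(_solo_block(rng, cfg, "guest",
                                  "+-"[int(rng.integers(0, 2))], next_frag()))

    order = rng.permutation(len(blocks))
    per_chrom: list[list[_Block]] = [[] for _ in range(cfg.n_chroms)]
    for k, bi in enumerate(order):
        per_chrom[k % cfg.n_chroms].append(blocks[bi])

    genome: list[SequenceRecord] = []
    repeats: list[RepeatFeature] = []
    genes: list[GeneModel] = []
    truth = SyntheticTruth()

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        cblocks = per_chrom[ci]
        used = sum(len(b.seq) for b in cblocks)
        n_gaps = len(cblocks) + 1
        budget = cfg.chrom_len - used - n_gaps * _MIN_GAP
        if budget < 0:
            raise PackingError(
                f"{chrom}: planted blocks need {used + n_gaps * _MIN_GAP} bp "
                f"but chrom_len is {cfg.chrom_len}")
        extra = rng.multinomial(budget, np.full(n_gaps, 1.0 / n_gaps))
        gaps = [int(g) + _MIN_GAP for g in extra]
        parts: list[str] = []
        cursor = 0
        for gap, block in zip(gaps, cblocks):
            parts.append(_random_seq(rng, gap))
            cursor += gap
            parts.append(block.seq)
            for f in block.features:
                repeats.append(replace(f, chrom=chrom, start=f.start + cursor,
                                       end=f.end + cursor))
            if block.gene is not None:
                g = block.gene
                genes.append(GeneModel(
                    name=g.name, chrom=chrom, strand=g.strand,
                    tx_start=g.tx_start + cursor, tx_end=g.tx_end + cursor,
                    cds_start=g.cds_start + cursor, cds_end=g.cds_end + cursor,
                    exon_starts=[s + cursor for s in g.exon_starts],
                    exon_ends=[e + cursor for e in g.exon_ends],
                ))
            if block.insertion is not None:
                ins = block.insertion
                shifted = replace(ins, chrom=chrom)
                for fld in ("host_start", "host_end", "guest_start",
                            "guest_end"):
                    v = getattr(shifted, fld)
                    if v is not None:
                        setattr(shifted, fld, v + cursor)
                truth.planted_insertions.append(shifted)
            if block.exon is not None:
                ex = block.exon
                truth.planted_exons.append(replace(
                    ex, chrom=chrom,
                    acceptor_pos=ex.acceptor_pos + cursor,
                    donor_pos=ex.donor_pos + cursor,
                    branchpoint_pos=ex.branchpoint_pos + cursor))
            cursor += len(block.seq)
        parts.append(_random_seq(rng, gaps[-1]))
        genome.append(SequenceRecord(id=chrom, seq="".join(parts)))

    # phyletic truth: each insertion arose on a branch of the fixture tree
    from .phylodating import primate_fixture_tree
    tree = primate_fixture_tree()
    node_labels = tree.internal_labels() + tree.leaf_names
    for ins in truth.planted_insertions:
        ins.branch = node_labels[int(rng.integers(0, len(node_labels)))]

    repeats.sort(key=lambda f: (f.chrom, f.start))
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genome, repeats, genes, truth


# ---------------------------------------------------------------------------
# The controlled V1/V2 locus
# ---------------------------------------------------------------------------

@dataclass
class V1V2Locus:
    """A fully controlled exonization locus with two alternative acceptors.

    A 5-exon + strand gene whose 4th intron carries an antisense nested TE
    pair.  The TE region is scrubbed of all AG/GT dinucleotides and then
    given exactly two AG acceptors (sharing one downstream GT donor), each
    with a branch-point heptamer and pyrimidine tract at canonical
    distance.  The reference mRNA is 1208 nt: a 19-nt 5'UTR, a 429-nt CDS
    (142 codons + stop) and a 760-nt 3'UTR, with the CDS ending inside the
    last exon so that exonization disrupts the reading frame.  Candidate
    exons carry stop codons in all three frames, so spliced-in variants
    always terminate prematurely.
    """

    chrom: SequenceRecord
    gene: GeneModel
    repeats: list[RepeatFeature]
    te_region: tuple[int, int]       # nested-pair outer span (genomic)
    intron_index: int                # 1-based; the TE-bearing intron
    acceptor_positions: list[int]    # genomic AG starts, upstream first
    donor_position: int              # genomic GT start
    branchpoint_positions: list[int]  # genomic BP adenosine, per acceptor
    reference_mrna: str


# codons free of stop codons, ATG and of AG/GT dinucleotides (also across
# codon boundaries: none starts with G/T and none ends with A/G)
_SAFE_CODONS = ("CAT", "CCT", "CTT", "ACT", "CAC", "TCC", "TTC", "CCC")


def _safe_cds(rng: np.random.Generator, n_codons: int) -> str:
    picks = rng.integers(0, len(_SAFE_CODONS), n_codons)
    return "".join(_SAFE_CODONS[int(i)] for i in picks)


def make_v1_v2_locus(seed: int = 0) -> V1V2Locus:
    """Build the controlled two-acceptor exonization locus (see V1V2Locus)."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(seed=seed)

    # --- reference mRNA: 19 + 429 + 760 = 1208 nt over 5 exons -------------
    utr5 = _scrub_splice_motifs(_random_seq(rng, 19).replace("ATG", "ACG"))
    cds = "ATG" + _safe_cds(rng, 141) + "TAA"
    utr3 = _random_seq(rng, 760)
    mrna = utr5 + cds + utr3
    exon_lens = [100, 90, 90, 100, 828]  # cumsum 380 < 448 = CDS end
    assert sum(exon_lens) == len(mrna) == 1208

    # --- the TE-bearing intron -------------------------------------------
    inner, feats, frag2_span, guest_span, _tsd, _pa = _nested_core(
        rng, cfg, "-", "-", 1, 2, scrub=True)
    chars = list(inner)
    g0, g1 = guest_span
    h0, h1 = frag2_span
    # donor in the downstream host fragment, placed so that both acceptors
    # (120-nt and 180-nt exons) fall inside the guest with BP headroom
    d_lo = h0 + 5
    d_hi = min(h1 - 5, (g1 - 1) + 2 + 120)
    d = int(rng.integers(d_lo, d_hi + 1))
    a1 = d - 2 - 120            # downstream acceptor: 120-nt exon
    a2 = a1 - 60                # upstream acceptor: 180-nt exon
    assert g0 + 35 <= a2 < a1 < g1, "acceptors must fall inside the guest"
    bps = []
    for a in (a2, a1):
        chars[a:a + 2] = "AG"
        dist = 23
        bp = a + 2 - dist
        chars[bp - 5:bp + 2] = BP_HEPTAMER
        for i in range(bp + 2, a):
            chars[i] = "CT"[int(rng.integers(0, 2))]
        bps.append(bp)
    chars[d:d + 2] = "GT"
    # tri-frame stops inside the shared 3' part of both candidate exons
    stop_at = a1 + 30
    chars[stop_at:stop_at + len(_TRIFRAME_STOP)] = _TRIFRAME_STOP
    # boundary guards: the writes above must not create stray AG/GT pairs
    for a in (a2, a1):
        if chars[a + 2] == "T":        # G|T after the acceptor's G
            chars[a + 2] = "C"
    for bp in (a2 + 2 - 23, a1 + 2 - 23):
        if chars[bp - 6] == "G":       # G|T before the heptamer's leading T
            chars[bp - 6] = "C"
    if chars[d - 1] == "A":            # A|G before the donor's G
        chars[d - 1] = "C"
    if chars[stop_at + len(_TRIFRAME_STOP)] == "G":  # A|G after the stops
        chars[stop_at + len(_TRIFRAME_STOP)] = "C"
    inner = "".join(chars)
    # the controlled region must now contain exactly the planted sites
    n_ag = sum(1 for i in range(len(inner) - 1) if inner[i:i + 2] == "AG")
    n_gt = sum(1 for i in range(len(inner) - 1) if inner[i:i + 2] == "GT")
    assert (n_ag, n_gt) == (2, 1), "locus construction left stray splice motifs"

    # --- assemble the chromosome ------------------------------------------
    pad = 500
    intron_lens = [400, 450, 500]  # introns 1-3
    pad_up, pad_dn = 300, 300
    parts = [_random_seq(rng, pad)]
    cursor = pad
    exon_starts, exon_ends = [], []
    m = 0  # cursor in mRNA
    te_off = None
    for i, elen in enumerate(exon_lens):
        exon_starts.append(cursor)
        parts.append(mrna[m:m + elen])
        m += elen
        cursor += elen
        exon_ends.append(cursor)
        if i < 4:
            if i == 3:  # the 4th intron
                parts.append(_random_seq(rng, pad_up))
                cursor += pad_up
                te_off = cursor
                parts.append(inner)
                cursor += len(inner)
                parts.append(_random_seq(rng, pad_dn))
                cursor += pad_dn
            else:
                parts.append(_random_seq(rng, intron_lens[i]))
                cursor += intron_lens[i]
    parts.append(_random_seq(rng, pad))
    seq = "".join(parts)

    # map the mRNA-coordinate CDS end (19 + 429 = 448) into the genome
    cds_end_mrna = 19 + 429
    cum = 0
    cds_end_genomic = None
    for s, e, elen in zip(exon_starts, exon_ends, exon_lens):
        if cum + elen >= cds_end_mrna:
            cds_end_genomic = s + (cds_end_mrna - cum)
            break
        cum += elen
    gene = GeneModel(
        name="BLOC-like", chrom="chrV", strand="+",
        tx_start=exon_starts[0], tx_end=exon_ends[-1],
        cds_start=exon_starts[0] + 19, cds_end=cds_end_genomic,
        exon_starts=exon_starts, exon_ends=exon_ends,
    )
    repeats = [replace(f, chrom="chrV", start=f.start + te_off,
                       end=f.end + te_off) for f in feats]
    return V1V2Locus(
        chrom=SequenceRecord(id="chrV", seq=seq),
        gene=gene,
        repeats=repeats,
        te_region=(te_off, te_off + len(inner)),
        intron_index=4,
        acceptor_positions=[a2 + te_off, a1 + te_off],
        donor_position=d + te_off,
        branchpoint_positions=[bp + te_off for bp in bps],
        reference_mrna=mrna,
    )


# ---------------------------------------------------------------------------
# Truth manifest I/O (tab-separated)
# ---------------------------------------------------------------------------

_INSERTION_COLS = [f.name for f in dataclasses.fields(PlantedInsertion)]
_EXON_COLS = [f.name for f in dataclasses.fields(PlantedExon)]
_STR_INSERTION_COLS = frozenset(
    c for c in _INSERTION_COLS
    if c in ("chrom", "relation", "branch") or c.endswith(("strand", "tsd")))


def write_truth_manifest(truth: SyntheticTruth, path) -> None:
    """Write the truth manifest as a single TSV.

    One row per record; the first column is the record type (``insertion``
    or ``exon``), followed by the insertion-record schema and then the
    exon-record schema (columns prefixed ``exon.``), with ``.`` for fields
    that do not apply to the row's record type.
    """
    cols = (["record_type"] + _INSERTION_COLS
            + [f"exon.{c}" for c in _EXON_COLS])
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for ins in truth.planted_insertions:
            vals = ["insertion"] + [
                "." if getattr(ins, c) is None else str(getattr(ins, c))
                for c in _INSERTION_COLS] + ["."] * len(_EXON_COLS)
            fh.write("\t".join(vals) + "\n")
        for ex in truth.planted_exons:
            vals = (["exon"] + ["."] * len(_INSERTION_COLS)
                    + [str(getattr(ex, c)) for c in _EXON_COLS])
            fh.write("\t".join(vals) + "\n")


def read_truth_manifest(path) -> SyntheticTruth:
    truth = SyntheticTruth()
    with _open_text(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            if vals["record_type"] == "insertion":
                kwargs = {}
                for c in _INSERTION_COLS:
                    v = vals[c]
                    if v == ".":
                        kwargs[c] = None
                    elif c in _STR_INSERTION_COLS:
                        kwargs[c] = v
                    else:
                        kwargs[c] = int(v)
                truth.planted_insertions.append(PlantedInsertion(**kwargs))
            else:
                truth.planted_exons.append(PlantedExon(
                    gene=vals["exon.gene"], chrom=vals["exon.chrom"],
                    intron_index=int(vals["exon.intron_index"]),
                    acceptor_pos=int(vals["exon.acceptor_pos"]),
                    donor_pos=int(vals["exon.donor_pos"]),
                    branchpoint_pos=int(vals["exon.branchpoint_pos"])))
    return truth
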