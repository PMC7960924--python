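"""Reference sequences, transcript models and splice-aware coordinate arithmetic.

Internal coordinates are 0-based half-open throughout; FASTA/GFF3/GTF/VCF
input and all report output use the 1-based inclusive conventions of those
formats.  cDNA ("c.") numbering follows HGVS: c.1 is the first base of the
annotated CDS, and intronic positions are anchored to the nearest exon edge
as ``c.N+M`` (M bases downstream of the donor at cDNA position N, transcript
sense) or ``c.N-M`` (M bases upstream of the acceptor at cDNA position N).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "IntronicOffset",
    "HgvsParseError",
    "DONOR_DOWNSTREAM",
    "ACCEPTOR_UPSTREAM",
    "read_fasta",
    "read_gene_models",
    "junction_distance",
    "parse_intronic_hgvs",
    "format_intronic_hgvs",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: side tag for HGVS "+M" offsets (downstream of a donor, transcript sense)
DONOR_DOWNSTREAM = "+"
#: side tag for HGVS "-M" offsets (upstream of an acceptor, transcript sense)
ACCEPTOR_UPSTREAM = "-"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A toy reference genome: contig name -> uppercase ACGTN string."""

    contigs: dict

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if not re.fullmatch(r"[ACGTN]+", seq):
                raise ValueError(f"contig {name!r} contains non-ACGTN characters")

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class IntronicOffset:
    """A parsed cDNA-relative position, HGVS style.

    ``offset == 0`` denotes an exonic (plain ``c.N``) position; intronic
    positions carry ``side`` ``"+"`` (donor_downstream) or ``"-"``
    (acceptor_upstream).  ``ref``/``alt`` are transcript-sense bases for
    substitutions and ``None`` for del/dup edits, whose raw text is kept
    in ``edit``.
    """

    anchor_cdna_pos: int
    offset: int
    side: Optional[str] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    edit: str = ""

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.offset > 0 and self.side not in (DONOR_DOWNSTREAM, ACCEPTOR_UPSTREAM):
            raise ValueError("intronic offset requires side '+' or '-'")
        if self.offset == 0 and self.side is not None:
            raise ValueError("exonic position must not carry a side")

    @property
    def is_intronic(self) -> bool:
        return self.offset > 0


@dataclass
class TranscriptModel:
    """Strand-aware exon chain with optional CDS bounds on a named contig.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order regardless of strand; transcript (5'->3') order is the reverse of
    genomic order for minus-strand models.  ``cds_start``/``cds_end`` bound
    the CDS on the genome (half-open over the exon union) or are ``None``
    for non-coding transcripts.
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: list
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
        if self.exons != sorted(self.exons):
            raise ValueError(f"{self.transcript_id}: exons not in ascending order")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            if s2 - e1 < 4:
                raise ValueError(
                    f"{self.transcript_id}: intron [{e1}, {s2}) shorter than 4 bp"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self._exonic(self.cds_start) and self._exonic(self.cds_end - 1)):
                raise ValueError(
                    f"{self.transcript_id}: CDS bounds outside the exon union"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list:
        """Genomic intron intervals, ascending order."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def cdna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def _exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def locate(self, pos: int):
        """Classify ``pos``: ('exonic', genomic exon index),
        ('intronic', genomic intron index) or ('outside', None)."""
        if pos < self.start or pos >= self.end:
            return ("outside", None)
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return ("exonic", i)
        for i, (s, e) in enumerate(self.introns):
            if s <= pos < e:
                return ("intronic", i)
        raise AssertionError("unreachable")

    def intron_number(self, genomic_intron_index: int) -> int:
        """1-based transcript-sense intron number (intron k follows exon k)."""
        n = len(self.exons) - 1
        if not 0 <= genomic_intron_index < n:
            raise IndexError("intron index out of range")
        if self.strand == "+":
            return genomic_intron_index + 1
        return n - genomic_intron_index

    # -- cDNA arithmetic ------------------------------------------------

    def genomic_to_cdna(self, pos: int) -> int:
        """0-based transcript-sense offset of an exonic genomic position."""
        loc, idx = self.locate(pos)
        if loc != "exonic":
            raise ValueError(f"position {pos} is not exonic in {self.transcript_id}")
        if self.strand == "+":
            before = sum(e - s for s, e in self.exons[:idx])
            return before + (pos - self.exons[idx][0])
        before = sum(e - s for s, e in self.exons[idx + 1 :])
        return before + (self.exons[idx][1] - 1 - pos)

    def cdna_to_genomic(self, offset: int) -> int:
        if not 0 <= offset < self.cdna_length:
            raise ValueError(f"cDNA offset {offset} out of range")
        order = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in order:
            n = e - s
            if offset < n:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= n
        raise AssertionError("unreachable")

    @property
    def _cds_first_cdna(self) -> int:
        """cDNA offset of c.1 (first coding base)."""
        if not self.is_coding:
            return 0
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        return self.genomic_to_cdna(g)

    def cds_position(self, pos: int) -> int:
        """1-based HGVS c. coordinate of an exonic genomic position.

        Falls back to 1-based cDNA numbering for non-coding transcripts.
        """
        return self.genomic_to_cdna(pos) - self._cds_first_cdna + 1

    def cds_to_genomic(self, c: int) -> int:
        return self.cdna_to_genomic(c - 1 + self._cds_first_cdna)

    def genomic_position(self, off: IntronicOffset) -> int:
        """Genomic position of a parsed c. label on this transcript."""
        anchor_g = self.cds_to_genomic(off.anchor_cdna_pos)
        if not off.is_intronic:
            return anchor_g
        step = off.offset if self.strand == "+" else -off.offset
        if off.side == DONOR_DOWNSTREAM:
            pos = anchor_g + step
        else:
            pos = anchor_g - step
        loc, _ = self.locate(pos)
        if loc != "intronic":
            raise ValueError(
                f"{self.transcript_id}: c.{off.anchor_cdna_pos}{off.side}{off.offset} "
                "does not land in an intron (anchor is not the matching exon edge?)"
            )
        return pos

    def spliced_sequence(self, genome: GenomeSequence, exons=None) -> str:
        """Transcript-sense mRNA of ``exons`` (default: this model's chain)."""
        chain = self.exons if exons is None else sorted(exons)
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in chain)
        return seq if self.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# readers


def _as_handle(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source)


def read_fasta(source: Union[str, TextIO]) -> GenomeSequence:
    """Read a FASTA stream or path into a :class:`GenomeSequence`.

    Contigs are keyed by the first whitespace-delimited header token and
    uppercased.  Duplicate contig names and empty input are errors.
    """
    handle = _as_handle(source)
    contigs: dict = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError("no FASTA records found")
    return GenomeSequence(contigs)


def read_gene_models(
    source: Union[str, TextIO],
    dialect: str = "gff3",
    genome: Optional[GenomeSequence] = None,
) -> list:
    """Read exon/CDS features from GFF3 or GTF into transcript models.

    Exons are grouped by ``Parent`` (GFF3) or ``transcript_id`` (GTF);
    the gene symbol comes from ``gene``/``gene_name``/``gene_id``
    attributes.  1-based inclusive file coordinates become 0-based
    half-open.  With ``genome`` given, exon bounds are checked against
    contig lengths.
    """
    import gffutils.iterators

    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(source, "read"):
        data, from_string = source.read(), True
    else:
        data, from_string = str(source), False
    feats = list(gffutils.iterators.DataIterator(data, from_string=from_string))

    by_tx: dict = {}
    for f in feats:
        if f.featuretype not in ("exon", "CDS"):
            continue
        if dialect == "gff3":
            parents = f.attributes.get("Parent", [])
        else:
            parents = f.attributes.get("transcript_id", [])
        if not parents:
            raise ValueError(f"{f.featuretype} feature without a transcript id")
        gene = (
            f.attributes.get("gene", [])
            or f.attributes.get("gene_name", [])
            or f.attributes.get("gene_id", [""])
        )[0]
        for tx_id in parents:
            entry = by_tx.setdefault(
                tx_id,
                {"gene": gene, "contig": f.seqid, "strand": f.strand,
                 "exons": [], "cds": []},
            )
            iv = (f.start - 1, f.end)  # 1-based inclusive -> half-open
            entry[f.featuretype == "CDS" and "cds" or "exons"].append(iv)

    models = []
    for tx_id, entry in by_tx.items():
        exons = sorted(entry["exons"])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {tx_id}: overlapping exons")
        cds_start = cds_end = None
        if entry["cds"]:
            cds_start = min(s for s, _ in entry["cds"])
            cds_end = max(e for _, e in entry["cds"])
        if genome is not None:
            if entry["contig"] not in genome:
                raise ValueError(
                    f"transcript {tx_id}: contig {entry['contig']!r} not in genome"
                )
            clen = len(genome.contigs[entry["contig"]])
            if exons and (exons[0][0] < 0 or exons[-1][1] > clen):
                raise ValueError(
                    f"transcript {tx_id}: exon outside contig {entry['contig']!r}"
                )
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene=entry["gene"],
                contig=entry["contig"],
                strand=entry["strand"],
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    models.sort(key=lambda t: (t.contig, t.start, t.transcript_id))
    return models


# ---------------------------------------------------------------------------
# junction distance


def junction_distance(pos: int, tx: TranscriptModel):
    """Distance (in bases) from ``pos`` to the nearest exon-intron junction.

    Returns ``(distance, location)`` with location one of ``exonic``,
    ``intronic``, ``outside``.  The first intronic base adjacent to an exon
    has distance 1, matching HGVS "+1"/"-1"; exonic positions have
    distance 0; positions outside the transcript span report the distance
    to the nearest transcript end.
    """
    loc, idx = tx.locate(pos)
    if loc == "exonic":
        return 0, "exonic"
    if loc == "outside":
        d = tx.start - pos if pos < tx.start else pos - (tx.end - 1)
        return d, "outside"
    s, e = tx.introns[idx]
    return min(pos - s + 1, e - pos), "intronic"


# ---------------------------------------------------------------------------
# HGVS intronic grammar


class HgvsParseError(ValueError):
    """Raised on malformed c. labels; carries the 0-based failure position."""

    def __init__(self, text: str, position: int, message: str):
        super().__init__(f"cannot parse {text!r} at position {position}: {message}")
        self.text = text
        self.position = position


_HGVS_HEAD = re.compile(r"c\.(\d+)(?:\s*([+-])\s*([\d,]+))?\s*")
_SUBST = re.compile(r"([ACGTN]+)>([ACGTN]+)$")
_DELDUP = re.compile(r"(del|dup|ins)([ACGTN]*)$")


def parse_intronic_hgvs(text: str) -> IntronicOffset:
    """Parse a cDNA substitution/del/dup label, e.g. ``c.2367+82A>G``.

    Supports the grammar ``c.N[+|-]M<ref>><alt>`` and exonic
    ``c.N<ref>><alt>`` / ``c.Ndel<seq>`` / ``c.Ndup<seq>``; commas and
    stray spaces inside the offset are tolerated (``c.3998+3,023 T>G``).
    """
    stripped = text.strip()
    m = _HGVS_HEAD.match(stripped)
    if not m:
        raise HgvsParseError(text, 0, "expected 'c.<number>'")
    anchor = int(m.group(1))
    side = m.group(2)
    offset = int(m.group(3).replace(",", "")) if m.group(3) else 0
    if side and offset == 0:
        raise HgvsParseError(text, m.start(3), "offset must be >= 1")
    rest = stripped[m.end() :]
    sub = _SUBST.match(rest)
    if sub:
        return IntronicOffset(
            anchor_cdna_pos=anchor,
            offset=offset,
            side=side if offset else None,
            ref=sub.group(1),
            alt=sub.group(2),
            edit=rest,
        )
    dd = _DELDUP.match(rest)
    if dd:
        if offset:
            raise HgvsParseError(
                text, m.end(), f"intronic {dd.group(1)} edits are not supported"
            )
        return IntronicOffset(
            anchor_cdna_pos=anchor, offset=0, side=None, ref=None, alt=None, edit=rest
        )
    raise HgvsParseError(text, m.end(), "expected '<ref>><alt>', 'del...' or 'dup...'")


def format_intronic_hgvs(tx: TranscriptModel, pos: int, ref: str, alt: str) -> str:
    """HGVS c. substitution label for a genomic SNV on ``tx``.

    ``ref``/``alt`` are reference-strand bases and are complemented for
    minus-strand transcripts.  Intronic positions anchor to the nearest
    exon edge (ties resolved to the donor side, "+"), so the result
    round-trips through :func:`parse_intronic_hgvs` and
    :meth:`TranscriptModel.genomic_position`.
    """
    if tx.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    loc, idx = tx.locate(pos)
    if loc == "outside":
        raise ValueError(f"position {pos} outside transcript {tx.transcript_id}")
    if loc == "exonic":
        return f"c.{tx.cds_position(pos)}{ref}>{alt}"
    s, e = tx.introns[idx]
    left_exon_end = tx.exons[idx][1]      # genomic-left exon, last base + 1
    right_exon_start = tx.exons[idx + 1][0]
    d_left = pos - left_exon_end + 1
    d_right = right_exon_start - pos
    if tx.strand == "+":
        d_donor, d_acc = d_left, d_right
        donor_anchor_g, acc_anchor_g = left_exon_end - 1, right_exon_start
    else:
        d_donor, d_acc = d_right, d_left
        donor_anchor_g, acc_anchor_g = right_exon_start, left_exon_end - 1
    if d_donor <= d_acc:
        n = tx.cds_position(donor_anchor_g)
        return f"c.{n}+{d_donor}{ref}>{alt}"
    n = tx.cds_position(acc_anchor_g)
    return f"c.{n}-{d_acc}{ref}>{alt}"
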