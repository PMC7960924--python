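"""Design of minigene splicing-reporter inserts and RT-PCR size prediction.

The insert for a candidate event spans the test exon (the canonical exon
closest to the variant), the predicted cryptic exon when there is one, and
a symmetric intronic flank (default 150 bp) on both outer edges.  The
insert is cloned between two vector exons; RT-PCR primers sit inside those
vector exons and contribute a fixed 92 bp per side to every product, so
the wild-type product is ``2*92 + test-exon length`` and each
variant-specific product exceeds it by exactly the inserted length.
Because partial splicing can never be excluded, the variant construct is
always predicted to yield both the wild-type-size and the variant-size
bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .gene_models import GenomeSequence, TranscriptModel, reverse_complement
from .splice_reconstruction import SpliceEvent

__all__ = [
    "MinigeneConstruct",
    "RtpcrPrediction",
    "design_construct",
    "predict_rtpcr_products",
    "splice_insert_in_silico",
    "apply_variants_to_insert",
]

DEFAULT_FLANK = 150
DEFAULT_VECTOR_EXON_BP = 92


@dataclass
class MinigeneConstruct:
    """A designed insert: genomic region, member exons and extracted sequence.

    ``region``/``test_exon``/``cryptic_exon`` are 0-based half-open genomic
    intervals; ``sequence`` is the insert in transcript sense (reverse-
    complemented for minus-strand genes).
    """

    contig: str
    strand: str
    region: Tuple[int, int]
    test_exon: Tuple[int, int]
    cryptic_exon: Optional[Tuple[int, int]]
    flank: int
    vector_exon_bp: int
    sequence: str

    def __post_init__(self) -> None:
        s, e = self.region
        if len(self.sequence) != e - s:
            raise ValueError("sequence length does not match region length")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        for iv in filter(None, (self.test_exon, self.cryptic_exon)):
            if not (s <= iv[0] and iv[1] <= e):
                raise ValueError("insert region does not cover its exons")

    @property
    def test_exon_length(self) -> int:
        return self.test_exon[1] - self.test_exon[0]


@dataclass
class RtpcrPrediction:
    """Predicted RT-PCR band sizes for the WT and variant constructs."""

    wt_product: int
    variant_products: List[int]
    labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.variant_products):
            raise ValueError("one label per predicted product")


def _included_exons(tx: TranscriptModel, event: SpliceEvent):
    """(test exon, cryptic exon or None) for the event, genomic intervals."""
    host = event.host_intron_index
    left, right = tx.exons[host], tx.exons[host + 1]
    if event.kind == "pseudo_exon":
        lo = min(event.gained_acceptor, event.gained_donor)
        hi = max(event.gained_acceptor, event.gained_donor) + 1
        cryptic = (lo, hi)
        # test exon: the flanking exon nearer the cryptic exon
        d_left = lo - left[1]
        d_right = right[0] - hi
        test = left if d_left <= d_right else right
        return test, cryptic
    if event.kind == "exon_elongation":
        exon = left if tx.strand == "+" else right
        if tx.strand == "+":
            return (exon[0], event.gained_donor + 1), None
        return (event.gained_donor, exon[1]), None
    if event.kind == "acceptor_shift":
        exon = right if tx.strand == "+" else left
        if tx.strand == "+":
            return (event.gained_acceptor, exon[1]), None
        return (exon[0], event.gained_acceptor + 1), None
    raise ValueError("cannot design a construct for an event of kind 'none'")


def design_construct(
    tx: TranscriptModel,
    event: SpliceEvent,
    genome: GenomeSequence,
    flank: int = DEFAULT_FLANK,
    vector_exon_bp: int = DEFAULT_VECTOR_EXON_BP,
) -> MinigeneConstruct:
    """PCR-amplifiable insert covering test exon, cryptic exon and flanks.

    The region runs from ``flank`` bases 5' of the 5'-most included exon
    edge to ``flank`` bases 3' of the 3'-most edge (transcript sense); a
    region that would overrun the contig is clipped with a warning.  For
    elongation/acceptor-shift events the extended exon itself is the test
    exon.
    """
    test, cryptic = _included_exons(tx, event)
    lo = min(iv[0] for iv in filter(None, (test, cryptic)))
    hi = max(iv[1] for iv in filter(None, (test, cryptic)))
    start, end = lo - flank, hi + flank
    contig_len = len(genome.contigs[tx.contig])
    if start < 0 or end > contig_len:
        warnings.warn(
            f"minigene region [{start}, {end}) clipped to contig bounds "
            f"[0, {contig_len})"
        )
        start, end = max(0, start), min(contig_len, end)
    seq = genome.fetch(tx.contig, start, end)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return MinigeneConstruct(
        contig=tx.contig,
        strand=tx.strand,
        region=(start, end),
        test_exon=test,
        cryptic_exon=cryptic,
        flank=flank,
        vector_exon_bp=vector_exon_bp,
        sequence=seq,
    )


def predict_rtpcr_products(
    construct: MinigeneConstruct, event: SpliceEvent
) -> RtpcrPrediction:
    """Band sizes for the WT and variant minigene constructs.

    For elongation/acceptor-shift events the designed test exon already
    contains the inserted bases, so the *canonical* exon length
    (test exon minus inserted length) defines the WT band.
    """
    v = construct.vector_exon_bp
    if event.kind == "pseudo_exon":
        canonical_len = construct.test_exon_length
        extra = construct.cryptic_exon[1] - construct.cryptic_exon[0]
    else:
        canonical_len = construct.test_exon_length - event.inserted_length
        extra = event.inserted_length
    wt = 2 * v + canonical_len
    return RtpcrPrediction(
        wt_product=wt,
        variant_products=[wt, wt + extra],
        labels=["canonical splicing", f"aberrant (+{extra} bp)"],
    )


def splice_insert_in_silico(
    construct: MinigeneConstruct, event: SpliceEvent
) -> List[int]:
    """Exonic lengths obtained by splicing the insert at its exon intervals.

    Internal consistency check for the size arithmetic: returns the total
    exonic content of the canonical and the aberrant isoform of the insert
    (without the vector-exon contribution).
    """
    def _len(iv):
        return iv[1] - iv[0]

    if event.kind == "pseudo_exon":
        canonical = _len(construct.test_exon)
        aberrant = canonical + _len(construct.cryptic_exon)
    else:
        canonical = _len(construct.test_exon) - event.inserted_length
        aberrant = _len(construct.test_exon)
    return [canonical, aberrant]


def apply_variants_to_insert(
    construct: MinigeneConstruct, variants
) -> str:
    """Insert sequence with a list of SNVs applied (site-directed mutagenesis).

    ``variants`` provide reference-strand ``pos``/``ref``/``alt``; edits are
    applied in coordinate-descending order so earlier edits cannot
    invalidate later coordinates.
    """
    start, end = construct.region
    seq = construct.sequence
    if construct.strand == "-":
        seq = reverse_complement(seq)  # work on the reference strand
    chars = list(seq)
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if not (start <= v.pos < end):
            raise ValueError(f"variant at {v.pos} outside the insert region")
        i = v.pos - start
        if "".join(chars[i : i + len(v.ref)]) != v.ref:
            raise ValueError(
                f"reference mismatch at {v.pos}: insert has "
                f"{''.join(chars[i:i + len(v.ref)])!r}, variant says {v.ref!r}"
            )
        chars[i : i + len(v.ref)] = list(v.alt)
    out = "".join(chars)
    return reverse_complement(out) if construct.strand == "-" else out
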