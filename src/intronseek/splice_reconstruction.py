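"""Cryptic-splicing event inference and mutant-transcript consequences.

Given a variant's SpliceAI delta scores/positions and the canonical
transcript model, classify the predicted mechanism (pseudo-exon inclusion,
exon elongation to a gained donor, or acceptor shift), rebuild the mutant
exon chain, and derive reading-frame class, premature-termination-codon
(PTC) position and a nonsense-mediated-decay (NMD) call under the standard
50-nt last-junction heuristic.

Conventions
-----------
* SpliceAI DP positions are reference-strand offsets from the variant
  (gained site = variant position + DP).
* Gained-site positions denote *included* exonic boundary bases: the
  gained acceptor is the first base of the new/extended exon and the
  gained donor its last base (transcript sense), so a pseudo-exon's
  inserted length is ``|donor - acceptor| + 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .gene_models import GenomeSequence, TranscriptModel
from .variant_io import AnnotatedVariant, SpliceAIRecord

__all__ = [
    "SpliceEvent",
    "TranscriptConsequence",
    "infer_splice_event",
    "apply_event",
    "frame_consequence",
    "find_ptc",
    "predict_nmd",
    "reconstruct_consequence",
    "summarize_consequence",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SpliceEvent:
    """A classified cryptic-splicing mechanism in genomic coordinates.

    ``gained_acceptor``/``gained_donor`` are the first/last included exonic
    bases of the new or extended exon (transcript sense); ``lost_site`` is
    the canonical site predicted lost, when any.  ``host_intron_index`` is
    the genomic index of the intron containing the variant;
    ``min_gained_score`` is the smaller delta score among the event's
    gained sites, reported so prediction confidence can be compared with
    assay completeness.
    """

    kind: str  # pseudo_exon | exon_elongation | acceptor_shift | none
    gained_acceptor: Optional[int] = None
    gained_donor: Optional[int] = None
    lost_site: Optional[int] = None
    host_intron_index: int = 0
    inserted_length: int = 0
    min_gained_score: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("pseudo_exon", "exon_elongation", "acceptor_shift", "none"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind != "none" and self.inserted_length < 1:
            raise ValueError("non-none event must insert at least 1 base")


@dataclass
class TranscriptConsequence:
    """Predicted effect of a splice event on the mature transcript."""

    mutant_exons: List[Tuple[int, int]]
    inserted_length: int
    frame_class: str  # in_frame | frameshift
    ptc: Optional[int] = None  # 1-based codon index in the mutant CDS
    ptc_offset_aa: Optional[int] = None  # codons downstream of the event junction
    nmd_predicted: bool = False
    protein_effect: str = "none"  # insertion | truncation | none

    def __post_init__(self) -> None:
        if self.frame_class not in ("in_frame", "frameshift"):
            raise ValueError(f"bad frame_class {self.frame_class!r}")
        if (self.frame_class == "in_frame") != (self.inserted_length % 3 == 0):
            raise ValueError("frame_class inconsistent with inserted_length mod 3")
        if self.nmd_predicted and self.ptc is None:
            raise ValueError("NMD predicted without a PTC")


def infer_splice_event(
    variant: AnnotatedVariant,
    rec: SpliceAIRecord,
    tx: TranscriptModel,
    cutoff: float = 0.5,
) -> SpliceEvent:
    """Classify the cryptic-splicing mechanism predicted for ``variant``.

    Acceptor gain + donor gain above ``cutoff`` with the acceptor 5' of the
    donor inside the variant's intron -> ``pseudo_exon``; acceptor gain +
    acceptor loss -> ``acceptor_shift``; a donor gain alone (with or
    without donor loss) -> ``exon_elongation`` of the transcript-upstream
    exon.  The most specific mechanism wins when several patterns pass.  A
    gained acceptor/donor pair in the wrong orientation cannot form an
    exon and yields ``none`` with a warning; gained sites in different
    introns raise ``ValueError`` ("non-local event").
    """
    loc, host = tx.locate(variant.pos)
    if loc != "intronic":
        raise ValueError(
            f"variant {variant.contig}:{variant.pos + 1} is not intronic "
            f"in {tx.transcript_id}"
        )
    acc_g = variant.pos + rec.dp_ag
    don_g = variant.pos + rec.dp_dg
    ag, al = rec.ds_ag >= cutoff, rec.ds_al >= cutoff
    dg, dl = rec.ds_dg >= cutoff, rec.ds_dl >= cutoff

    if ag and dg:
        acc_loc, acc_intron = tx.locate(acc_g)
        don_loc, don_intron = tx.locate(don_g)
        if acc_loc == "intronic" and don_loc == "intronic":
            if acc_intron != don_intron:
                raise ValueError(
                    "non-local event: gained acceptor and donor fall in "
                    f"different introns of {tx.transcript_id}"
                )
            upstream = acc_g <= don_g if tx.strand == "+" else acc_g >= don_g
            if not upstream:
                warnings.warn(
                    "gained acceptor lies 3' of the gained donor; "
                    "no exon can form — classifying as none"
                )
                return SpliceEvent(kind="none", host_intron_index=host)
            return SpliceEvent(
                kind="pseudo_exon",
                gained_acceptor=acc_g,
                gained_donor=don_g,
                host_intron_index=acc_intron,
                inserted_length=abs(don_g - acc_g) + 1,
                min_gained_score=min(rec.ds_ag, rec.ds_dg),
            )

    if ag and al:
        # canonical acceptor of the exon following the host intron
        if tx.strand == "+":
            canonical = tx.exons[host + 1][0]
            inserted = canonical - acc_g
        else:
            canonical = tx.exons[host][1] - 1
            inserted = acc_g - canonical
        if inserted >= 1:
            return SpliceEvent(
                kind="acceptor_shift",
                gained_acceptor=acc_g,
                lost_site=variant.pos + rec.dp_al,
                host_intron_index=host,
                inserted_length=inserted,
                min_gained_score=rec.ds_ag,
            )

    if dg:
        if tx.strand == "+":
            upstream_exon_end = tx.exons[host][1]  # half-open
            inserted = don_g - upstream_exon_end + 1
        else:
            upstream_exon_start = tx.exons[host + 1][0]
            inserted = upstream_exon_start - don_g
        if inserted >= 1:
            return SpliceEvent(
                kind="exon_elongation",
                gained_donor=don_g,
                lost_site=variant.pos + rec.dp_dl if dl else None,
                host_intron_index=host,
                inserted_length=inserted,
                min_gained_score=rec.ds_dg,
            )

    return SpliceEvent(kind="none", host_intron_index=host)


def apply_event(tx: TranscriptModel, event: SpliceEvent) -> List[Tuple[int, int]]:
    """Build the mutant exon chain (ascending genomic intervals).

    pseudo_exon inserts a new exon inside the host intron; exon_elongation
    extends the transcript-upstream exon's 3' edge to the gained donor;
    acceptor_shift moves the downstream exon's 5' edge to the gained
    acceptor.  Only pseudo_exon changes the exon count.
    """
    if event.kind == "none":
        raise ValueError("cannot apply an event of kind 'none'")
    exons = list(tx.exons)
    host = event.host_intron_index
    intron = tx.introns[host]

    if event.kind == "pseudo_exon":
        lo = min(event.gained_acceptor, event.gained_donor)
        hi = max(event.gained_acceptor, event.gained_donor) + 1
        if not (intron[0] <= lo and hi <= intron[1]):
            raise ValueError("pseudo-exon outside the host intron")
        exons.insert(host + 1, (lo, hi))
    elif event.kind == "exon_elongation":
        if tx.strand == "+":
            s, e = exons[host]
            new = (s, event.gained_donor + 1)
            if new[1] > intron[1]:
                raise ValueError("gained donor outside the host intron")
            exons[host] = new
        else:
            s, e = exons[host + 1]
            new = (event.gained_donor, e)
            if new[0] < intron[0]:
                raise ValueError("gained donor outside the host intron")
            exons[host + 1] = new
    elif event.kind == "acceptor_shift":
        if tx.strand == "+":
            s, e = exons[host + 1]
            new = (event.gained_acceptor, e)
            if new[0] < intron[0]:
                raise ValueError("gained acceptor outside the host intron")
            exons[host + 1] = new
        else:
            s, e = exons[host]
            new = (s, event.gained_acceptor + 1)
            if new[1] > intron[1]:
                raise ValueError("gained acceptor outside the host intron")
            exons[host] = new
    return exons


def frame_consequence(inserted_length: int) -> str:
    """``in_frame`` iff the inserted length is a multiple of 3."""
    if inserted_length < 1:
        raise ValueError("inserted_length must be >= 1")
    return "in_frame" if inserted_length % 3 == 0 else "frameshift"


def _mutant_model(tx: TranscriptModel, chain) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tx.transcript_id + "|mut",
        gene=tx.gene,
        contig=tx.contig,
        strand=tx.strand,
        exons=list(chain),
        cds_start=tx.cds_start,
        cds_end=tx.cds_end,
    )


def find_ptc(
    mutant_chain,
    genome: GenomeSequence,
    tx: TranscriptModel,
) -> Optional[int]:
    """First in-frame stop strictly 5' of the original stop, or ``None``.

    Splices ``mutant_chain`` against the genome, locates the CDS start in
    the mutant mRNA and scans codons; a TAA/TAG/TGA whose first base lies
    strictly 5' of the (remapped) first base of the wild-type stop codon is
    a PTC and its 1-based codon index is returned.
    """
    if not tx.is_coding:
        raise ValueError(f"{tx.transcript_id} has no CDS")
    mt = _mutant_model(tx, mutant_chain)
    cds_first_g = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    try:
        start_off = mt.genomic_to_cdna(cds_first_g)
    except ValueError as exc:
        raise ValueError("CDS start is not inside the mutant chain") from exc
    mrna = mt.spliced_sequence(genome)
    # first base of the wild-type stop codon, remapped into mutant coordinates
    cds_len = tx.cds_position(tx.cds_end - 1 if tx.strand == "+" else tx.cds_start)
    orig_stop_g = tx.cds_to_genomic(cds_len - 2)
    orig_stop_off = mt.genomic_to_cdna(orig_stop_g)
    for k, i in enumerate(range(start_off, len(mrna) - 2, 3)):
        if mrna[i : i + 3] in STOP_CODONS:
            if i < orig_stop_off:
                return k + 1
            return None
    return None


def predict_nmd(
    ptc: Optional[int],
    mutant_chain,
    tx: TranscriptModel,
    boundary: int = 50,
) -> bool:
    """NMD call under the last-junction rule.

    True iff the first base of the PTC's stop codon lies strictly more than
    ``boundary`` nucleotides upstream of the final exon-exon junction of
    the mutant transcript; single-exon chains never trigger NMD.
    """
    if ptc is None:
        raise ValueError("predict_nmd requires a PTC")
    chain = sorted(mutant_chain)
    if len(chain) < 2:
        return False
    mt = _mutant_model(tx, chain)
    cds_first_g = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    start_off = mt.genomic_to_cdna(cds_first_g)
    ptc_off = start_off + 3 * (ptc - 1)
    last_exon = chain[-1] if tx.strand == "+" else chain[0]
    junction_off = mt.cdna_length - (last_exon[1] - last_exon[0])
    return junction_off - ptc_off > boundary


def reconstruct_consequence(
    variant: AnnotatedVariant,
    tx: TranscriptModel,
    genome: GenomeSequence,
    cutoff: float = 0.5,
    nmd_boundary: int = 50,
) -> Tuple[SpliceEvent, Optional[TranscriptConsequence]]:
    """Full event -> mutant chain -> frame/PTC/NMD analysis for one variant."""
    if variant.spliceai is None:
        raise ValueError("variant has no SpliceAI record")
    event = infer_splice_event(variant, variant.spliceai, tx, cutoff=cutoff)
    if event.kind == "none":
        return event, None
    chain = apply_event(tx, event)
    frame = frame_consequence(event.inserted_length)
    ptc = ptc_offset = None
    nmd = False
    protein_effect = "insertion" if frame == "in_frame" else "none"
    if tx.is_coding:
        ptc = find_ptc(chain, genome, tx)
        if ptc is not None:
            # landmark: the codon at the event's upstream junction
            host = event.host_intron_index
            if tx.strand == "+":
                anchor_g = tx.exons[host][1] - 1
            else:
                anchor_g = tx.exons[host + 1][0]
            anchor_aa = math.ceil(tx.cds_position(anchor_g) / 3)
            ptc_offset = ptc - anchor_aa
            nmd = predict_nmd(ptc, chain, tx, boundary=nmd_boundary)
            protein_effect = "truncation"
    return event, TranscriptConsequence(
        mutant_exons=chain,
        inserted_length=event.inserted_length,
        frame_class=frame,
        ptc=ptc,
        ptc_offset_aa=ptc_offset,
        nmd_predicted=nmd,
        protein_effect=protein_effect,
    )


def summarize_consequence(
    variant: AnnotatedVariant,
    event: SpliceEvent,
    consequence: Optional[TranscriptConsequence],
    hgvs: Optional[str] = None,
) -> dict:
    """One deterministic report row for the consequence TSV."""
    row = {
        "proband": variant.proband,
        "gene": variant.gene,
        "contig": variant.contig,
        "position": variant.pos + 1,
        "ref": variant.ref,
        "alt": variant.alt,
        "cdna_variant": hgvs,
        "zygosity": variant.zygosity,
        "event_kind": event.kind,
        "inserted_length": event.inserted_length if event.kind != "none" else None,
        "frame_class": None,
        "ptc_codon": None,
        "ptc_offset_aa": None,
        "nmd_predicted": None,
        "protein_effect": None,
        "min_gained_score": (
            event.min_gained_score if event.kind != "none" else None
        ),
        "description": "no predicted effect",
    }
    if consequence is not None:
        row.update(
            frame_class=consequence.frame_class,
            ptc_codon=consequence.ptc,
            ptc_offset_aa=consequence.ptc_offset_aa,
            nmd_predicted=consequence.nmd_predicted,
            protein_effect=consequence.protein_effect,
        )
        bits = [
            event.kind,
            f"{event.inserted_length} bp",
            consequence.frame_class,
        ]
        if consequence.ptc is not None:
            bits.append(f"PTC at codon {consequence.ptc}")
            bits.append("NMD" if consequence.nmd_predicted else "no NMD")
        if variant.zygosity == "hom":
            bits.append("homozygous")
        row["description"] = ", ".join(bits)
    return row
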