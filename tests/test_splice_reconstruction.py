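"""Event inference, mutant-chain construction, frame/PTC/NMD logic."""

import numpy as np
import pytest

from intronseek.gene_models import GenomeSequence, TranscriptModel, reverse_complement
from intronseek.splice_reconstruction import (
    SpliceEvent,
    apply_event,
    find_ptc,
    frame_consequence,
    infer_splice_event,
    predict_nmd,
    reconstruct_consequence,
)
from intronseek.synthetic_data import GeneBuilder
from intronseek.variant_io import AnnotatedVariant, SpliceAIRecord


def _variant(tx, pos, rec):
    ref = "A"
    return AnnotatedVariant(
        contig=tx.contig, pos=pos, ref=ref, alt="G", proband="P",
        gene=tx.gene, spliceai=rec,
    )


def _rec(alt="G", gene="G", ag=0.0, al=0.0, dg=0.0, dl=0.0,
         dp_ag=0, dp_al=0, dp_dg=0, dp_dl=0):
    return SpliceAIRecord(alt, gene, ag, al, dg, dl, dp_ag, dp_al, dp_dg, dp_dl)


@pytest.fixture
def plus_tx():
    return TranscriptModel(
        "p1", "G", "c", "+",
        exons=[(100, 200), (600, 700), (1100, 1200)],
        cds_start=100, cds_end=1200,
    )


# ---------------------------------------------------------------------------
# event inference


def test_pseudo_exon_129(plus_tx):
    """Acceptor gain at g and donor gain at g+128 span a 129-bp exon."""
    pos = 300
    rec = _rec(ag=0.7, dg=0.9, dp_ag=0, dp_dg=128)
    ev = infer_splice_event(_variant(plus_tx, pos, rec), rec, plus_tx)
    assert ev.kind == "pseudo_exon"
    assert ev.inserted_length == 129
    assert ev.min_gained_score == pytest.approx(0.7)


def test_pseudo_exon_29(plus_tx):
    """Acceptor at the variant plus donor 28 bases downstream -> 29 bp."""
    pos = 300
    rec = _rec(ag=0.96, dg=0.98, dp_ag=0, dp_dg=28)
    ev = infer_splice_event(_variant(plus_tx, pos, rec), rec, plus_tx)
    assert (ev.kind, ev.inserted_length) == ("pseudo_exon", 29)


def test_exon_elongation_81(plus_tx):
    """A gained donor 81 bases past the canonical donor elongates the exon."""
    pos = 281  # intronic offset +82
    rec = _rec(dg=0.88, dp_dg=-1)  # gained donor at offset +81
    ev = infer_splice_event(_variant(plus_tx, pos, rec), rec, plus_tx)
    assert (ev.kind, ev.inserted_length) == ("exon_elongation", 81)
    assert ev.gained_donor == 280


def test_acceptor_shift(plus_tx):
    pos = 550
    rec = _rec(ag=0.8, al=0.7, dp_ag=0, dp_al=50)
    ev = infer_splice_event(_variant(plus_tx, pos, rec), rec, plus_tx)
    assert ev.kind == "acceptor_shift"
    assert ev.inserted_length == 600 - 550


def test_all_scores_below_cutoff_is_none(plus_tx):
    rec = _rec(ag=0.4, dg=0.45)
    ev = infer_splice_event(_variant(plus_tx, 300, rec), rec, plus_tx)
    assert ev.kind == "none"


def test_wrong_orientation_warns_and_is_none(plus_tx):
    rec = _rec(ag=0.9, dg=0.9, dp_ag=50, dp_dg=0)  # acceptor 3' of donor
    with pytest.warns(UserWarning, match="no exon"):
        ev = infer_splice_event(_variant(plus_tx, 300, rec), rec, plus_tx)
    assert ev.kind == "none"


def test_gained_sites_in_different_introns_error(plus_tx):
    rec = _rec(ag=0.9, dg=0.9, dp_ag=0, dp_dg=500)  # donor in intron 2
    with pytest.raises(ValueError, match="non-local"):
        infer_splice_event(_variant(plus_tx, 300, rec), rec, plus_tx)


def test_exonic_variant_rejected(plus_tx):
    rec = _rec(ag=0.9, dg=0.9)
    with pytest.raises(ValueError, match="not intronic"):
        infer_splice_event(_variant(plus_tx, 150, rec), rec, plus_tx)


# ---------------------------------------------------------------------------
# chain construction


def test_apply_pseudo_exon_conserves_length(plus_tx):
    ev = SpliceEvent("pseudo_exon", gained_acceptor=300, gained_donor=400,
                     host_intron_index=0, inserted_length=101)
    chain = apply_event(plus_tx, ev)
    assert len(chain) == 4
    assert sum(e - s for s, e in chain) == plus_tx.cdna_length + 101


def test_apply_elongation_keeps_exon_count(plus_tx):
    ev = SpliceEvent("exon_elongation", gained_donor=250, host_intron_index=0,
                     inserted_length=51)
    chain = apply_event(plus_tx, ev)
    assert len(chain) == 3
    assert sum(e - s for s, e in chain) == plus_tx.cdna_length + 51


def test_apply_then_remove_restores_chain(plus_tx):
    ev = SpliceEvent("pseudo_exon", gained_acceptor=300, gained_donor=400,
                     host_intron_index=0, inserted_length=101)
    chain = apply_event(plus_tx, ev)
    restored = [iv for iv in chain if iv != (300, 401)]
    assert restored == plus_tx.exons


def test_apply_none_event_is_an_error(plus_tx):
    with pytest.raises(ValueError):
        apply_event(plus_tx, SpliceEvent("none"))


# ---------------------------------------------------------------------------
# frame / PTC / NMD


def test_frame_consequence_exhaustive():
    for n in range(1, 301):
        expected = "in_frame" if n % 3 == 0 else "frameshift"
        assert frame_consequence(n) == expected


@pytest.mark.parametrize("n, expected", [(129, "in_frame"), (54, "in_frame"),
                                         (29, "frameshift"), (3, "in_frame")])
def test_frame_consequence_reported_lengths(n, expected):
    assert frame_consequence(n) == expected


def _toy_world(insert_seq):
    """Two-exon coding gene plus an insert placed in the intron."""
    exon1 = "ATG" + "GGC" * 9          # 30 bases
    exon2 = "GCT" * 9 + "TAA"          # 30, ends with the real stop
    intron = "GT" + "C" * 20 + insert_seq + "C" * 20 + "AG"
    contig = "C" * 10 + exon1 + intron + exon2 + "C" * 10
    s1 = 10
    e1 = s1 + 30
    ins_s = e1 + 22
    ins_e = ins_s + len(insert_seq)
    s2 = e1 + len(intron)
    tx = TranscriptModel("t", "G", "c", "+", [(s1, e1), (s2, s2 + 30)],
                         cds_start=s1, cds_end=s2 + 30)
    genome = GenomeSequence({"c": contig})
    chain = [(s1, e1), (ins_s, ins_e), (s2, s2 + 30)]
    return tx, genome, chain


def test_find_ptc_early_stop():
    """An in-frame TAA right after the start codon is codon 2."""
    tx, genome, chain = _toy_world("TAAGGC")
    assert find_ptc(chain, genome, tx) == 11  # 10 exon1 codons + TAA
    # and with the insert as the very first codons after ATG:
    tx2, genome2, _ = _toy_world("")
    exon1_chain = [(10, 16)]  # ATG TAA ... needs a custom mini world
    mini = GenomeSequence({"c": "ATGTAAGGGGGG" + "C" * 20})
    mini_tx = TranscriptModel("m", "G", "c", "+", [(0, 6), (12, 18)],
                              cds_start=0, cds_end=18)
    assert find_ptc([(0, 6), (12, 18)], mini, mini_tx) == 2


def test_find_ptc_no_stop_in_frame_insert():
    tx, genome, chain = _toy_world("GGCGGC")
    assert find_ptc(chain, genome, tx) is None


def test_find_ptc_against_brute_force_oracle():
    """200 random coding transcripts with random intronic inserts."""
    rng = np.random.default_rng(17)
    for trial in range(200):
        n_ex = int(rng.integers(2, 5))
        exon_lengths = [int(x) for x in rng.integers(30, 90, n_ex)]
        exon_lengths[-1] += (3 - sum(exon_lengths) % 3) % 3
        intron_lengths = [int(x) for x in rng.integers(80, 200, n_ex - 1)]
        strand = "+" if trial % 2 == 0 else "-"
        b = GeneBuilder(f"T{trial}", strand, exon_lengths, intron_lengths,
                        rng, pad=20)
        contig_seq, tx = b.finalize()
        genome = GenomeSequence({b.contig: contig_seq})
        # random pseudo-exon inside a random intron
        gi = int(rng.integers(0, n_ex - 1))
        s, e = tx.introns[gi]
        span = int(rng.integers(10, 60))
        lo = int(rng.integers(s + 5, e - 5 - span))
        chain = sorted(tx.exons + [(lo, lo + span)])

        ptc = find_ptc(chain, genome, tx)

        # oracle: splice by plain string slicing; first stop before the
        # final codon is the PTC
        mrna = "".join(contig_seq[a:b_] for a, b_ in chain)
        if strand == "-":
            mrna = reverse_complement(mrna)
        expected = None
        for k, i in enumerate(range(0, len(mrna) - 2, 3)):
            codon = mrna[i : i + 3]
            if codon in {"TAA", "TAG", "TGA"}:
                expected = k + 1 if i < len(mrna) - 3 else None
                break
        assert ptc == expected, f"trial {trial}"


def test_predict_nmd_boundary_enumeration():
    """Distance to the last junction decides, with a strict 50-nt rule."""
    exon1 = 300
    tx = TranscriptModel("t", "G", "c", "+", [(0, exon1), (400, 460)],
                         cds_start=0, cds_end=460)
    chain = tx.exons
    junction = exon1  # cDNA offset of the last junction
    for ptc_codon in range(60, 101):
        ptc_off = 3 * (ptc_codon - 1)
        expected = junction - ptc_off > 50
        assert predict_nmd(ptc_codon, chain, tx) is expected


def test_predict_nmd_single_exon_false():
    tx = TranscriptModel("t", "G", "c", "+", [(0, 300)], cds_start=0,
                         cds_end=300)
    assert predict_nmd(5, [(0, 300)], tx) is False


def test_predict_nmd_ptc_in_last_exon_false():
    tx = TranscriptModel("t", "G", "c", "+", [(0, 90), (200, 500)],
                         cds_start=0, cds_end=500)
    assert predict_nmd(40, tx.exons, tx) is False  # cDNA offset 117 > junction


# ---------------------------------------------------------------------------
# strand invariance and conservation


def _twin_worlds(seed=23):
    """The same transcript-space gene realized on both strands."""
    out = []
    for strand in "+-":
        rng = np.random.default_rng(seed)
        b = GeneBuilder("TWIN", strand, [60, 60, 63], [120, 120], rng, pad=30)
        contig_seq, tx = b.finalize()
        out.append((b, GenomeSequence({b.contig: contig_seq}), tx))
    return out


def test_strand_invariance_of_events_and_consequences():
    """A minus-strand twin yields identical kind/length/frame/PTC."""
    results = []
    for b, genome, tx in _twin_worlds():
        var_t = b.intron_t(1, 40, "+")
        don_t = b.intron_t(1, 69, "+")
        g = b.t_to_genomic(var_t)
        rec = SpliceAIRecord("N", "TWIN", 0.9, 0.0, 0.9, 0.0,
                             0, 0, b.t_to_genomic(don_t) - g, 0)
        ref = genome.fetch(tx.contig, g, g + 1)
        alt = "G" if ref != "G" else "A"
        v = AnnotatedVariant(tx.contig, g, ref, alt, "P", gene="TWIN",
                             spliceai=rec)
        event, cons = reconstruct_consequence(v, tx, genome)
        results.append(
            (event.kind, event.inserted_length, cons.frame_class, cons.ptc,
             cons.nmd_predicted)
        )
    assert results[0] == results[1]
    assert results[0][0] == "pseudo_exon" and results[0][1] == 30


def test_mutant_mrna_length_conservation(tx_by_gene, bundle):
    """Spliced mutant mRNA length = WT length + inserted length."""
    from intronseek.synthetic_data import annotated_cohort

    cohort = annotated_cohort(bundle.cohort)
    for proband, variants in cohort.items():
        for v in variants:
            if v.spliceai is None:
                continue
            tx = tx_by_gene[v.gene]
            event, cons = reconstruct_consequence(v, tx, bundle.genome)
            wt = len(tx.spliced_sequence(bundle.genome))
            mutant = len(tx.spliced_sequence(bundle.genome, cons.mutant_exons))
            assert mutant == wt + event.inserted_length
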