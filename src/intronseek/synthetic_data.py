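"""Self-contained synthetic test worlds for the pipeline.

Two generators live here:

* a randomized cohort simulator (:func:`simulate_genome_and_models` /
  :func:`plant_cohort`) producing toy multi-gene genomes with canonical
  GT/AG introns, ATG-initiated CDSs and per-proband VCFs carrying planted
  causal configurations and decoy variants, together with a truth table;
* :func:`table1_fixture`, a hand-laid-out six-gene world that realizes the
  published IRD case series (8 probands, 6 distinct deep-intronic splice
  variants, 5 of them novel) with synthetic coordinates chosen so every
  printed cDNA label (e.g. ``c.8682-654C>G``) is literally realizable on
  the fixture transcripts.

Everything is generated at run time; no data files ship with the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .gene_models import GenomeSequence, TranscriptModel, reverse_complement
from .prioritization import GenePanelEntry
from .variant_io import AnnotatedVariant, SpliceAIRecord, format_spliceai_field

__all__ = [
    "CohortSpec",
    "TruthRecord",
    "PlannedVariant",
    "GeneBuilder",
    "simulate_genome_and_models",
    "plant_cohort",
    "table1_fixture",
    "write_fasta",
    "write_gff3",
    "write_panel",
    "write_vcf",
    "write_manifest",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _random_bases(n: int, rng) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _random_codons(n: int, rng) -> str:
    """``n`` random codons, none of them a stop."""
    out = []
    while len(out) < n:
        codon = _random_bases(3, rng)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def nonstop_frame(
    length: int,
    phase: int,
    rng,
    stop_at_codon: Optional[int] = None,
    pins: Optional[Dict[int, str]] = None,
) -> str:
    """A sequence whose in-frame codons avoid stops, given the reading phase.

    ``phase`` is the number of coding bases carried over from upstream
    (0-2); the first full codon of the returned sequence starts at offset
    ``(3 - phase) % 3``.  ``pins`` fixes particular 0-based offsets to
    given bases.  With ``stop_at_codon`` = k, the k-th full codon is TGA
    and every other full codon is stop-free (repairs never touch a pinned
    base).
    """
    lead = (3 - phase) % 3
    seq = list(_random_bases(length, rng))
    pins = dict(pins or {})
    if lead and lead - 1 not in pins:
        # never complete an upstream codon into a stop: no stop contains C
        seq[lead - 1] = "C"
    for i, base in pins.items():
        seq[i] = base
    i = lead
    codon_index = 0
    while i + 3 <= length:
        codon_index += 1
        if stop_at_codon is not None and codon_index == stop_at_codon:
            if any(j in pins for j in (i, i + 1, i + 2)):
                raise ValueError("pinned base collides with the planted stop")
            seq[i : i + 3] = list("TGA")
        elif "".join(seq[i : i + 3]) in _STOPS:
            for j in (i + 2, i + 1, i):
                if j not in pins:
                    seq[j] = "C"
                    break
            else:
                raise ValueError("cannot repair a stop codon of pinned bases")
        i += 3
    if stop_at_codon is not None and codon_index < stop_at_codon:
        raise ValueError("sequence too short to host the requested stop codon")
    return "".join(seq)


class GeneBuilder:
    """Assemble one synthetic gene in transcript space, then realize it.

    The gene is laid out 5'->3' as ``pad . exon1 . intron1 ... exonN . pad``
    with every intron ``GT...AG`` and the CDS spanning all exons (ATG
    first codon, stop last).  Base-level patches pin particular coding or
    intronic bases (repairing any stop codon a patch would create) before
    :meth:`finalize` emits the plus-strand contig and the transcript model;
    minus-strand genes are reverse-complemented wholesale, with all
    coordinate converters strand-aware.
    """

    def __init__(
        self,
        name: str,
        strand: str,
        exon_lengths: Sequence[int],
        intron_lengths: Sequence[int],
        rng,
        pad: int = 200,
        contig: Optional[str] = None,
        transcript_id: Optional[str] = None,
    ):
        if len(intron_lengths) != len(exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if any(l < 4 for l in intron_lengths):
            raise ValueError("introns must be at least 4 bp (GT..AG)")
        total = sum(exon_lengths)
        if total % 3:
            raise ValueError("total coding length must be a multiple of 3")
        self.name = name
        self.strand = strand
        self.exon_lengths = list(exon_lengths)
        self.intron_lengths = list(intron_lengths)
        self.pad = pad
        self.contig = contig or f"chr_{name}"
        self.transcript_id = transcript_id or f"{name}-tx1"
        coding = "ATG" + _random_codons(total // 3 - 2, rng) + "TAA"
        self.coding = list(coding)
        self.introns = [
            list("GT" + _random_bases(l - 4, rng) + "AG") for l in intron_lengths
        ]
        self.pad5 = _random_bases(pad, rng)
        self.pad3 = _random_bases(pad, rng)
        self._pinned: set = set()

    # -- patches (transcript space) ------------------------------------

    def _fix_codon(self, codon_index: int) -> None:
        i = 3 * codon_index
        if "".join(self.coding[i : i + 3]) in _STOPS and codon_index != len(
            self.coding
        ) // 3 - 1:
            for j in (i + 2, i + 1, i):
                if j not in self._pinned:
                    self.coding[j] = "C"
                    return
            raise ValueError(f"cannot unpin stop codon at index {codon_index}")

    def set_coding_base(self, c: int, base: str) -> None:
        """Pin the base at cDNA position ``c`` (1-based, transcript sense)."""
        self.coding[c - 1] = base
        self._pinned.add(c - 1)
        self._fix_codon((c - 1) // 3)

    def set_coding_codon(self, aa: int, codon: str) -> None:
        """Pin the codon for amino acid ``aa`` (1-based)."""
        for k, b in enumerate(codon):
            self.coding[3 * (aa - 1) + k] = b
            self._pinned.add(3 * (aa - 1) + k)

    def set_intron_base(self, intron: int, offset: int, base: str,
                        side: str = "+") -> None:
        """Pin one intronic base; offset 1 is adjacent to the exon edge.

        ``side`` '+' counts from the donor (5') end, '-' from the acceptor
        (3') end, matching HGVS offsets.  The GT/AG dinucleotides cannot be
        overwritten.
        """
        seq = self.introns[intron - 1]
        i = offset - 1 if side == "+" else len(seq) - offset
        if i < 2 or i >= len(seq) - 2:
            raise ValueError("refusing to overwrite the GT/AG splice dinucleotides")
        seq[i] = base

    def set_intron_segment(self, intron: int, offset: int, segment: str,
                           side: str = "+") -> None:
        """Write ``segment`` into intron ``intron`` starting at ``offset``."""
        for k, b in enumerate(segment):
            if side == "+":
                self.set_intron_base(intron, offset + k, b, side="+")
            else:
                self.set_intron_base(intron, offset - k, b, side="-")

    # -- coordinates ----------------------------------------------------

    def _exon_t_start(self, i: int) -> int:
        """Transcript-space start of exon ``i`` (1-based)."""
        return (
            self.pad
            + sum(self.exon_lengths[: i - 1])
            + sum(self.intron_lengths[: i - 1])
        )

    def cdna_t(self, c: int) -> int:
        """Transcript-space offset of cDNA position ``c`` (1-based)."""
        rem = c - 1
        for i, n in enumerate(self.exon_lengths, start=1):
            if rem < n:
                return self._exon_t_start(i) + rem
            rem -= n
        raise ValueError(f"cDNA position {c} beyond transcript")

    def intron_t(self, intron: int, offset: int, side: str = "+") -> int:
        """Transcript-space offset of an intronic position.

        ``side`` '+': ``offset`` bases past the donor of intron ``intron``;
        '-': ``offset`` bases before its acceptor (offset 1 adjacent).
        """
        start = self._exon_t_start(intron) + self.exon_lengths[intron - 1]
        n = self.intron_lengths[intron - 1]
        if not 1 <= offset <= n:
            raise ValueError(f"offset {offset} outside intron of length {n}")
        return start + (offset - 1) if side == "+" else start + n - offset

    @property
    def length(self) -> int:
        return (
            2 * self.pad + sum(self.exon_lengths) + sum(self.intron_lengths)
        )

    def t_to_genomic(self, t: int) -> int:
        return t if self.strand == "+" else self.length - 1 - t

    def t_base(self, t: int) -> str:
        return self._assembled[t]

    # -- realization ----------------------------------------------------

    def finalize(self) -> Tuple[str, TranscriptModel]:
        """Return (plus-strand contig sequence, transcript model)."""
        parts = [self.pad5]
        ci = 0
        for i, n in enumerate(self.exon_lengths):
            parts.append("".join(self.coding[ci : ci + n]))
            ci += n
            if i < len(self.introns):
                parts.append("".join(self.introns[i]))
        parts.append(self.pad3)
        self._assembled = "".join(parts)
        contig_seq = (
            self._assembled if self.strand == "+" else reverse_complement(self._assembled)
        )
        t_exons = [
            (self._exon_t_start(i + 1), self._exon_t_start(i + 1) + n)
            for i, n in enumerate(self.exon_lengths)
        ]
        if self.strand == "+":
            g_exons = t_exons
        else:
            g_exons = sorted((self.length - e, self.length - s) for s, e in t_exons)
        tx = TranscriptModel(
            transcript_id=self.transcript_id,
            gene=self.name,
            contig=self.contig,
            strand=self.strand,
            exons=g_exons,
            cds_start=g_exons[0][0],
            cds_end=g_exons[-1][1],
        )
        return contig_seq, tx

    def snv(self, t: int, ref_tsense: str, alt_tsense: str):
        """(genomic pos, plus-strand ref, plus-strand alt) for a tsense SNV."""
        if self.t_base(t) != ref_tsense:
            raise ValueError(
                f"{self.name}: transcript-sense base at {t} is "
                f"{self.t_base(t)!r}, expected {ref_tsense!r}"
            )
        g = self.t_to_genomic(t)
        if self.strand == "+":
            return g, ref_tsense, alt_tsense
        comp = str.maketrans("ACGT", "TGCA")
        return g, ref_tsense.translate(comp), alt_tsense.translate(comp)


# ---------------------------------------------------------------------------
# planned variants and file writers


@dataclass
class PlannedVariant:
    """A VCF row to be emitted for one proband."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str = "het"
    af: Optional[float] = None
    spliceai: Optional[SpliceAIRecord] = None
    coding_class: Optional[str] = None
    gene: Optional[str] = None
    novel: bool = False


def planned_to_annotated(v: PlannedVariant, proband: str) -> AnnotatedVariant:
    """View a planned VCF row as the pipeline's variant data model."""
    return AnnotatedVariant(
        contig=v.contig,
        pos=v.pos,
        ref=v.ref,
        alt=v.alt,
        proband=proband,
        gene=v.gene,
        zygosity=v.zygosity,
        allele_frequency=v.af,
        coding_class=v.coding_class or "none",
        spliceai=v.spliceai,
        novel=v.novel or None,
    )


def annotated_cohort(cohort: Dict[str, List[PlannedVariant]]
                     ) -> Dict[str, List[AnnotatedVariant]]:
    return {
        proband: [planned_to_annotated(v, proband) for v in variants]
        for proband, variants in cohort.items()
    }


@dataclass
class TruthRecord:
    """Ground truth for one planted configuration."""

    proband: str
    gene: str
    variant_keys: List[tuple]
    intended_status: str
    event_kind: Optional[str] = None
    inserted_length: Optional[int] = None


@dataclass
class CohortSpec:
    """Parameters of a randomized toy cohort.

    ``proband_configs`` names one planted configuration per proband from
    {AD_single, AR_splice_plus_coding, AR_hom_splice, XL_hemi, unsolved};
    decoy counts apply per proband.  ``seed`` fixes every downstream draw.
    """

    n_genes: int = 6
    exons_per_gene: int = 4
    intron_length_range: Tuple[int, int] = (300, 800)
    proband_configs: Sequence[str] = (
        "AD_single",
        "AR_splice_plus_coding",
        "AR_hom_splice",
        "XL_hemi",
        "unsolved",
    )
    n_common_decoys: int = 1
    n_low_score_decoys: int = 1
    n_near_junction_decoys: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes (one per inheritance mode)")
        if self.exons_per_gene < 2:
            raise ValueError("need at least 2 exons per gene")
        if self.intron_length_range[0] < 60:
            raise ValueError("introns must be long enough to host deep variants")
        bad = set(self.proband_configs) - {
            "AD_single",
            "AR_splice_plus_coding",
            "AR_hom_splice",
            "XL_hemi",
            "unsolved",
        }
        if bad:
            raise ValueError(f"unknown planted configurations: {sorted(bad)}")


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: Sequence[TranscriptModel], genome: GenomeSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for tx in models:
            fh.write(
                f"{tx.contig}\tintronseek\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\tID={tx.transcript_id};gene={tx.gene}\n"
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.contig}\tintronseek\texon\t{s + 1}\t{e}\t.\t{tx.strand}"
                    f"\t.\tParent={tx.transcript_id};gene={tx.gene}\n"
                )
            if tx.is_coding:
                for s, e in tx.exons:
                    cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{tx.contig}\tintronseek\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{tx.strand}\t.\tParent={tx.transcript_id};gene={tx.gene}\n"
                        )


def write_panel(panel: Dict[str, GenePanelEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tinheritance\ttranscript_id\n")
        for gene in sorted(panel):
            e = panel[gene]
            fh.write(f"{e.gene}\t{e.inheritance}\t{e.transcript_id}\n")


_GT = {"het": (0, 1), "hom": (1, 1), "hemi": (1,)}


def write_vcf(
    path,
    variants: Sequence[PlannedVariant],
    sample: str,
    genome: GenomeSequence,
) -> None:
    """Emit one proband's VCF (plain text, VCF 4.2) via pysam."""
    header = pysam.VariantHeader()
    for name, seq in genome.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("AF", "A", "Float", "Population allele frequency")
    header.info.add("SpliceAI", ".", "String",
                    "SpliceAI annotation ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|"
                    "DP_AG|DP_AL|DP_DG|DP_DL")
    header.info.add("CODING_CLASS", "1", "String", "Coding consequence class")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("NOVEL", "0", "Flag", "Absent from population databases")
    header.formats.add("GT", "1", "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            rec = out.new_record(
                contig=v.contig, start=v.pos, alleles=(v.ref, v.alt)
            )
            if v.af is not None:
                rec.info["AF"] = (v.af,)
            if v.spliceai is not None:
                rec.info["SpliceAI"] = format_spliceai_field([v.spliceai])
            if v.coding_class:
                rec.info["CODING_CLASS"] = v.coding_class
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.novel:
                rec.info["NOVEL"] = True
            rec.samples[sample]["GT"] = _GT[v.zygosity]
            out.write(rec)


def write_manifest(manifest: Dict[str, str], path) -> None:
    """Write proband -> VCF rows; paths are stored relative to the manifest."""
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    with open(path, "w") as fh:
        fh.write("#proband\tvcf\n")
        for proband in sorted(manifest):
            rel = os.path.relpath(os.path.abspath(manifest[proband]), base)
            fh.write(f"{proband}\t{rel}\n")


def read_manifest(path) -> Dict[str, str]:
    manifest = {}
    base = os.path.dirname(os.fspath(path))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            proband, vcf = line.split("\t")[:2]
            if not os.path.isabs(vcf):
                vcf = os.path.join(base, vcf)
            manifest[proband] = vcf
    return manifest


# ---------------------------------------------------------------------------
# randomized cohort simulator


def simulate_genome_and_models(spec: CohortSpec):
    """Toy genome + transcript models + panel for a :class:`CohortSpec`.

    Genes alternate strand and cycle through AR/AD/XL inheritance; every
    intron is GT..AG, every CDS starts ATG and ends in a stop, and the
    whole world is a pure function of the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    genome_contigs: Dict[str, str] = {}
    models: List[TranscriptModel] = []
    panel: Dict[str, GenePanelEntry] = {}
    modes = ["AR", "AD", "XL"]
    for gi in range(spec.n_genes):
        name = f"GENE{gi + 1}"
        exon_lengths = [int(x) for x in rng.integers(120, 300, spec.exons_per_gene)]
        excess = sum(exon_lengths) % 3
        exon_lengths[-1] += (3 - excess) % 3
        lo, hi = spec.intron_length_range
        intron_lengths = [int(x) for x in rng.integers(lo, hi, spec.exons_per_gene - 1)]
        strand = "+" if gi % 2 == 0 else "-"
        b = GeneBuilder(name, strand, exon_lengths, intron_lengths, rng)
        contig_seq, tx = b.finalize()
        genome_contigs[b.contig] = contig_seq
        models.append(tx)
        panel[name] = GenePanelEntry(name, modes[gi % 3], tx.transcript_id)
    return GenomeSequence(genome_contigs), models, panel


def _plant_splice(
    tx: TranscriptModel,
    genome: GenomeSequence,
    rng,
    kind: str,
    zygosity: str = "het",
    min_distance: int = 10,
) -> Tuple[PlannedVariant, str, int]:
    """Plant one causal splice variant on ``tx`` with consistent DP geometry."""
    introns = tx.introns
    idx = int(rng.integers(0, len(introns)))
    s, e = introns[idx]
    n = e - s
    margin = min_distance + 2
    if kind == "pseudo_exon":
        span = int(rng.integers(15, min(90, n - 2 * margin - 1)))
        lo = int(rng.integers(s + margin, e - margin - span))
        acc_g, don_g = (lo, lo + span - 1) if tx.strand == "+" else (lo + span - 1, lo)
        var_g = acc_g
        ds_ag = float(rng.uniform(0.5, 1.0))
        ds_dg = float(rng.uniform(0.5, 1.0))
        rec_scores = dict(ds_ag=ds_ag, ds_al=float(rng.uniform(0, 0.3)),
                          ds_dg=ds_dg, ds_dl=float(rng.uniform(0, 0.3)),
                          dp_ag=acc_g - var_g, dp_al=0,
                          dp_dg=don_g - var_g, dp_dl=0)
        inserted = span
    elif kind == "exon_elongation":
        k = int(rng.integers(margin, n - margin))  # gained-donor intronic offset
        if tx.strand == "+":
            don_g = s + k - 1
            var_g = don_g + 1
        else:
            don_g = e - k
            var_g = don_g - 1
        rec_scores = dict(ds_ag=float(rng.uniform(0, 0.3)),
                          ds_al=float(rng.uniform(0, 0.3)),
                          ds_dg=float(rng.uniform(0.5, 1.0)),
                          ds_dl=float(rng.uniform(0, 0.3)),
                          dp_ag=0, dp_al=0, dp_dg=don_g - var_g, dp_dl=0)
        inserted = k
    else:
        raise ValueError(f"unknown planted event kind {kind!r}")
    ref = genome.fetch(tx.contig, var_g, var_g + 1)
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    rec = SpliceAIRecord(allele=alt, gene=tx.gene, **rec_scores)
    return (
        PlannedVariant(
            contig=tx.contig, pos=var_g, ref=ref, alt=alt, zygosity=zygosity,
            af=None, spliceai=rec, gene=tx.gene, novel=True,
        ),
        kind,
        inserted,
    )


def _plant_coding(tx: TranscriptModel, genome: GenomeSequence, rng
                  ) -> PlannedVariant:
    s, e = tx.exons[0]
    pos = int(rng.integers(s + 3, e - 3))
    ref = genome.fetch(tx.contig, pos, pos + 1)
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return PlannedVariant(
        contig=tx.contig, pos=pos, ref=ref, alt=alt, zygosity="het",
        af=None, coding_class="nonsense", gene=tx.gene, novel=True,
    )


def _plant_decoy(tx, genome, rng, flavor: str) -> PlannedVariant:
    introns = tx.introns
    s, e = introns[int(rng.integers(0, len(introns)))]
    if flavor == "near_junction":
        off = int(rng.integers(1, 11))
        pos = s + off - 1 if rng.random() < 0.5 else e - off
    else:
        pos = int(rng.integers(s + 15, e - 15))
    ref = genome.fetch(tx.contig, pos, pos + 1)
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    if flavor == "low_score":
        hi = float(rng.uniform(0.05, 0.49))
        rec = SpliceAIRecord(alt, tx.gene, hi, 0.0, float(rng.uniform(0, hi)), 0.0,
                             0, 0, 10, 0)
        af = None
    else:
        rec = SpliceAIRecord(alt, tx.gene, float(rng.uniform(0.6, 1.0)), 0.0,
                             float(rng.uniform(0.6, 1.0)), 0.0, 0, 0, 25, 0)
        af = float(rng.uniform(0.01, 0.1)) if flavor == "common" else None
    return PlannedVariant(
        contig=tx.contig, pos=pos, ref=ref, alt=alt, zygosity="het",
        af=af, spliceai=rec, gene=tx.gene,
    )


def plant_cohort(
    spec: CohortSpec,
    genome: GenomeSequence,
    models: Sequence[TranscriptModel],
    panel: Dict[str, GenePanelEntry],
    out_dir: Optional[str] = None,
):
    """Plant causal configurations and decoys; optionally write VCFs.

    Returns ``(cohort, truth)`` where ``cohort`` maps proband id to a list
    of :class:`PlannedVariant` (and, with ``out_dir``, VCFs are written and
    a path manifest is returned instead) and ``truth`` lists the intended
    outcome per proband.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_mode: Dict[str, List[TranscriptModel]] = {"AD": [], "AR": [], "XL": []}
    for tx in models:
        by_mode[panel[tx.gene].inheritance].append(tx)
    for mode, needed in (("AD", "AD_single"), ("AR", "AR_splice_plus_coding"),
                         ("XL", "XL_hemi")):
        if not by_mode[mode] and any(c.startswith(needed[:2]) for c in
                                     spec.proband_configs):
            raise ValueError(f"no {mode} gene available for planted configurations")

    cohort: Dict[str, List[PlannedVariant]] = {}
    truth: List[TruthRecord] = []
    for pi, config in enumerate(spec.proband_configs):
        proband = f"P{pi + 1:03d}"
        variants: List[PlannedVariant] = []
        if config == "unsolved":
            truth.append(TruthRecord(proband, "", [], "unsolved"))
        else:
            mode = {"AD_single": "AD", "AR_splice_plus_coding": "AR",
                    "AR_hom_splice": "AR", "XL_hemi": "XL"}[config]
            tx = by_mode[mode][pi % len(by_mode[mode])]
            kind = "pseudo_exon" if rng.random() < 0.7 else "exon_elongation"
            zyg = {"AR_hom_splice": "hom", "XL_hemi": "hemi"}.get(config, "het")
            sv, ekind, inserted = _plant_splice(tx, genome, rng, kind, zygosity=zyg)
            variants.append(sv)
            keys = [(sv.contig, sv.pos, sv.ref, sv.alt)]
            if config == "AR_splice_plus_coding":
                cv = _plant_coding(tx, genome, rng)
                variants.append(cv)
                keys.append((cv.contig, cv.pos, cv.ref, cv.alt))
            truth.append(
                TruthRecord(proband, tx.gene, keys, "solved_candidate",
                            event_kind=ekind, inserted_length=inserted)
            )
        decoy_genes = [tx for tx in models]
        planted_pos = {(v.contig, v.pos) for v in variants}
        for flavor, count in (("common", spec.n_common_decoys),
                              ("low_score", spec.n_low_score_decoys),
                              ("near_junction", spec.n_near_junction_decoys)):
            for _ in range(count):
                for _attempt in range(20):
                    tx = decoy_genes[int(rng.integers(0, len(decoy_genes)))]
                    d = _plant_decoy(tx, genome, rng, flavor)
                    if (d.contig, d.pos) not in planted_pos:
                        planted_pos.add((d.contig, d.pos))
                        variants.append(d)
                        break
        cohort[proband] = variants

    if out_dir is None:
        return cohort, truth
    os.makedirs(out_dir, exist_ok=True)
    manifest: Dict[str, str] = {}
    for proband, variants in cohort.items():
        path = os.path.join(out_dir, f"{proband}.vcf")
        write_vcf(path, variants, proband, genome)
        manifest[proband] = path
    return manifest, truth


# ---------------------------------------------------------------------------
# the published case-series fixture


@dataclass
class FixtureBundle:
    """The realized case-series world: objects, file paths, expectations."""

    genome: GenomeSequence
    models: List[TranscriptModel]
    panel: Dict[str, GenePanelEntry]
    cohort: Dict[str, List[PlannedVariant]]
    table: List[dict]
    expected_counts: Dict[str, int]
    truth_events: Dict[str, dict]
    manifest: Optional[Dict[str, str]] = None
    paths: Dict[str, str] = field(default_factory=dict)


def _comp(b: str) -> str:
    return b.translate(str.maketrans("ACGT", "TGCA"))


def table1_fixture(out_dir: Optional[str] = None, seed: int = 73) -> FixtureBundle:
    """Build the six-gene, eight-proband case-series world.

    Encodes, with synthetic coordinates, the published per-patient variant
    table: seven compound-heterozygous recessive cases plus one dominant
    single-hit case, six distinct deep-intronic splice variants (five
    novel), and the per-variant event geometry reported for each gene
    (pseudo-exon lengths 129/54/84/34/29 bp, one 81-bp exon elongation).
    ``seed`` only randomizes the neutral sequence background; the layout,
    labels and counts are fixed by construction.
    """
    rng = np.random.default_rng(seed)
    genome_contigs: Dict[str, str] = {}
    models: List[TranscriptModel] = []
    panel: Dict[str, GenePanelEntry] = {}
    splice_vars: Dict[str, PlannedVariant] = {}
    coding_vars: Dict[str, PlannedVariant] = {}
    truth_events: Dict[str, dict] = {}

    def register(b: GeneBuilder, mode: str):
        contig_seq, tx = b.finalize()
        genome_contigs[b.contig] = contig_seq
        models.append(tx)
        panel[b.name] = GenePanelEntry(b.name, mode, tx.transcript_id)
        return tx

    def sai(alt, gene, ds, dp):
        return SpliceAIRecord(alt, gene,
                              ds.get("ag", 0.02), ds.get("al", 0.01),
                              ds.get("dg", 0.02), ds.get("dl", 0.01),
                              dp.get("ag", 0), dp.get("al", 0),
                              dp.get("dg", 0), dp.get("dl", 0))

    # --- ADGRV1 analog (+, AR): c.14661+717A>G, 84-bp pseudo-exon,
    #     PTC 17 codons past the cryptic acceptor; second allele c.5965dupA.
    b = GeneBuilder("ADGRV1", "+", [5000, 5000, 4661, 1000, 1001],
                    [400, 400, 1500, 400], rng)
    # phase 0 at the insertion point (14661 % 3 == 0); the acceptor base is
    # the variant itself and must read A on the transcript strand
    b.set_intron_segment(
        3, 717, nonstop_frame(84, 0, rng, stop_at_codon=17, pins={0: "A"})
    )
    b.set_coding_base(5965, "A")  # duplicated base of the c.5965dupA allele
    tx = register(b, "AR")
    var_t = b.intron_t(3, 717, "+")
    don_t = b.intron_t(3, 800, "+")
    g, ref, alt = b.snv(var_t, "A", "G")
    splice_vars["ADGRV1"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True, gene="ADGRV1",
        spliceai=sai(alt, "ADGRV1", {"ag": 0.55, "dg": 0.92},
                     {"ag": 0, "dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["ADGRV1"] = {
        "kind": "pseudo_exon", "inserted_length": 84, "frame_class": "in_frame",
        "ptc_offset_aa": 17, "cdna": "c.14661+717A>G",
    }
    dup_t = b.cdna_t(5964)
    dup_ref = b.t_base(dup_t)
    coding_vars["ADGRV1"] = PlannedVariant(
        b.contig, b.t_to_genomic(dup_t), dup_ref, dup_ref + "A", af=1.43e-5,
        coding_class="frameshift", gene="ADGRV1",
    )

    # --- USH2A analog (-, AR): c.8682-654C>G, 129-bp pseudo-exon with a
    #     stop just past the cryptic acceptor (downstream of codon 2894).
    b = GeneBuilder("USH2A", "-", [4000, 4681, 1500, 1687], [400, 1400, 500], rng)
    # insert interrupts codon 2894 (phase 8681 % 3 == 2); acceptor base = C
    b.set_intron_segment(
        2, 654,
        nonstop_frame(129, 8681 % 3, rng, stop_at_codon=2, pins={0: "C"}),
        side="-",
    )
    b.set_coding_base(10073, "C")
    b.set_coding_codon(3955, "TGG")  # Trp: G>A at c.11864 makes a stop
    tx = register(b, "AR")
    var_t = b.intron_t(2, 654, "-")
    don_t = b.intron_t(2, 654 - 128, "-")
    g, ref, alt = b.snv(var_t, "C", "G")
    splice_vars["USH2A"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True, gene="USH2A",
        spliceai=sai(alt, "USH2A", {"ag": 0.61, "dg": 0.95},
                     {"ag": 0, "dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["USH2A"] = {
        "kind": "pseudo_exon", "inserted_length": 129, "frame_class": "in_frame",
        "cdna": "c.8682-654C>G", "anchor_aa": 2894,
    }
    g, ref, alt = b.snv(b.cdna_t(10073), "C", "T")
    coding_vars["USH2A:DGB289"] = PlannedVariant(
        b.contig, g, ref, alt, af=1e-4, coding_class="missense", gene="USH2A",
    )
    g, ref, alt = b.snv(b.cdna_t(11864), "G", "A")
    coding_vars["USH2A:MEP337"] = PlannedVariant(
        b.contig, g, ref, alt, af=5e-5, coding_class="nonsense", gene="USH2A",
    )

    # --- OPA1 analog (-, AD): c.1608+622A>G, 54-bp in-frame pseudo-exon,
    #     no stop inside the insert (pure 18-aa insertion).
    b = GeneBuilder("OPA1", "-", [1000, 608, 1200], [400, 1300], rng)
    # phase 0 (1608 % 3 == 0); the variant sits inside the cryptic exon at
    # segment offset 22 and must read A on the transcript strand
    b.set_intron_segment(2, 600, nonstop_frame(54, 0, rng, pins={22: "A"}))
    tx = register(b, "AD")
    var_t = b.intron_t(2, 622, "+")
    acc_t = b.intron_t(2, 600, "+")
    don_t = b.intron_t(2, 653, "+")
    g, ref, alt = b.snv(var_t, "A", "G")
    splice_vars["OPA1"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True, gene="OPA1",
        spliceai=sai(alt, "OPA1", {"ag": 0.93, "dg": 0.97},
                     {"ag": b.t_to_genomic(acc_t) - g,
                      "dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["OPA1"] = {
        "kind": "pseudo_exon", "inserted_length": 54, "frame_class": "in_frame",
        "ptc": None, "cdna": "c.1608+622A>G",
    }

    # --- RPGRIP1 analog (+, AR): c.2367+82A>G, gained donor 81 bp into the
    #     intron -> exon elongation, PTC 19 codons past the canonical donor.
    b = GeneBuilder("RPGRIP1", "+", [1200, 1167, 900, 300], [300, 400, 400], rng)
    # the retained 81 bp start with the canonical GT (intron bases 1-2);
    # bases 3-81 carry phase 2, and the segment's 18th full codon (intron
    # bases 55-57, insert codon 19) is the planted stop
    b.set_intron_segment(2, 3, nonstop_frame(79, 2, rng, stop_at_codon=18))
    b.set_intron_base(2, 82, "A")
    b.set_coding_codon(705, "CAA")  # Gln: A>C at c.2114 makes Pro
    tx = register(b, "AR")
    var_t = b.intron_t(2, 82, "+")
    don_t = b.intron_t(2, 81, "+")
    g, ref, alt = b.snv(var_t, "A", "G")
    splice_vars["RPGRIP1"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True, gene="RPGRIP1",
        spliceai=sai(alt, "RPGRIP1", {"dg": 0.88, "dl": 0.45},
                     {"dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["RPGRIP1"] = {
        "kind": "exon_elongation", "inserted_length": 81,
        "frame_class": "in_frame", "ptc_offset_aa": 19, "cdna": "c.2367+82A>G",
    }
    g, ref, alt = b.snv(b.cdna_t(2114), "A", "C")
    coding_vars["RPGRIP1"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True,
        coding_class="missense", gene="RPGRIP1",
    )

    # --- CNGB3 analog (+, AR): c.1663-1205G>A, 34-bp pseudo-exon
    #     (frameshift); this is the one previously reported splice variant.
    b = GeneBuilder("CNGB3", "+", [900, 762, 900], [400, 2500], rng)
    b.set_intron_base(2, 1205, "G", side="-")
    b.set_coding_codon(383, "ACC")  # Thr; c.1148 is its middle C
    tx = register(b, "AR")
    var_t = b.intron_t(2, 1205, "-")
    don_t = b.intron_t(2, 1205 - 33, "-")
    g, ref, alt = b.snv(var_t, "G", "A")
    splice_vars["CNGB3"] = PlannedVariant(
        b.contig, g, ref, alt, af=2e-4, novel=False, gene="CNGB3",
        spliceai=sai(alt, "CNGB3", {"ag": 0.85, "dg": 0.80},
                     {"ag": 0, "dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["CNGB3"] = {
        "kind": "pseudo_exon", "inserted_length": 34, "frame_class": "frameshift",
        "cdna": "c.1663-1205G>A",
    }
    del_t = b.cdna_t(1147)
    coding_vars["CNGB3"] = PlannedVariant(
        b.contig, b.t_to_genomic(del_t), b.t_base(del_t) + "C", b.t_base(del_t),
        af=2e-4, coding_class="frameshift", gene="CNGB3",
    )

    # --- PCDH15 analog (+, AR): c.3998+3023T>G, gained acceptor at the
    #     variant and donor 28 bp downstream -> 29-bp pseudo-exon, frameshift.
    b = GeneBuilder("PCDH15", "+", [2000, 1998, 600, 601], [300, 6200, 400], rng)
    b.set_intron_base(2, 3023, "T")  # variant ref base = cryptic acceptor base
    b.set_coding_base(1163, "G")
    tx = register(b, "AR")
    var_t = b.intron_t(2, 3023, "+")
    don_t = b.intron_t(2, 3051, "+")
    g, ref, alt = b.snv(var_t, "T", "G")
    splice_vars["PCDH15"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True, gene="PCDH15",
        spliceai=sai(alt, "PCDH15", {"ag": 0.96, "dg": 0.98},
                     {"ag": 0, "dg": b.t_to_genomic(don_t) - g}),
    )
    truth_events["PCDH15"] = {
        "kind": "pseudo_exon", "inserted_length": 29, "frame_class": "frameshift",
        "cdna": "c.3998+3,023 T>G",
    }
    g, ref, alt = b.snv(b.cdna_t(1163), "G", "T")
    coding_vars["PCDH15"] = PlannedVariant(
        b.contig, g, ref, alt, af=None, novel=True,
        coding_class="missense", gene="PCDH15",
    )

    genome = GenomeSequence(genome_contigs)

    cohort = {
        "DGB288": [splice_vars["ADGRV1"], coding_vars["ADGRV1"]],
        "DGB289": [splice_vars["USH2A"], coding_vars["USH2A:DGB289"]],
        "MEP337": [splice_vars["USH2A"], coding_vars["USH2A:MEP337"]],
        "MEP344": [splice_vars["OPA1"]],
        "NEI4320": [splice_vars["RPGRIP1"], coding_vars["RPGRIP1"]],
        "MEP129": [splice_vars["CNGB3"], coding_vars["CNGB3"]],
        "MEP130": [splice_vars["CNGB3"], coding_vars["CNGB3"]],
        "MEP105": [splice_vars["PCDH15"], coding_vars["PCDH15"]],
    }

    table = [
        dict(patient="DGB288", gene="ADGRV1", cdna="c.5965dupA",
             zygosity="heterozygous", variant_type="frameshift", novel=False),
        dict(patient="DGB288", gene="ADGRV1", cdna="c.14661+717A>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
        dict(patient="DGB289", gene="USH2A", cdna="c.10073C>T",
             zygosity="heterozygous", variant_type="nonsynonymous", novel=False),
        dict(patient="DGB289", gene="USH2A", cdna="c.8682-654C>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
        dict(patient="MEP337", gene="USH2A", cdna="c.11864G>A",
             zygosity="heterozygous", variant_type="nonsense", novel=False),
        dict(patient="MEP337", gene="USH2A", cdna="c.8682-654C>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
        dict(patient="MEP344", gene="OPA1", cdna="c.1608+622A>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
        dict(patient="NEI4320", gene="RPGRIP1", cdna="c.2114A>C",
             zygosity="heterozygous", variant_type="nonsynonymous", novel=True),
        dict(patient="NEI4320", gene="RPGRIP1", cdna="c.2367+82A>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
        dict(patient="MEP129", gene="CNGB3", cdna="c.1148delC",
             zygosity="heterozygous", variant_type="frameshift", novel=False),
        dict(patient="MEP129", gene="CNGB3", cdna="c.1663-1205G>A",
             zygosity="heterozygous", variant_type="splicing", novel=False),
        dict(patient="MEP130", gene="CNGB3", cdna="c.1148delC",
             zygosity="heterozygous", variant_type="frameshift", novel=False),
        dict(patient="MEP130", gene="CNGB3", cdna="c.1663-1205G>A",
             zygosity="heterozygous", variant_type="splicing", novel=False),
        dict(patient="MEP105", gene="PCDH15", cdna="c.1163G>T",
             zygosity="heterozygous", variant_type="nonsynonymous", novel=True),
        dict(patient="MEP105", gene="PCDH15", cdna="c.3998+3,023 T>G",
             zygosity="heterozygous", variant_type="splicing", novel=True),
    ]

    expected_counts = {
        "distinct_splice_variants": 6,
        "solved_probands": 8,
        "novel_splice_variants": 5,
    }

    bundle = FixtureBundle(
        genome=genome,
        models=models,
        panel=panel,
        cohort=cohort,
        table=table,
        expected_counts=expected_counts,
        truth_events=truth_events,
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "genome.fa"),
            "gff3": os.path.join(out_dir, "models.gff3"),
            "panel": os.path.join(out_dir, "panel.tsv"),
            "manifest": os.path.join(out_dir, "manifest.tsv"),
        }
        write_fasta(genome, paths["fasta"])
        write_gff3(models, genome, paths["gff3"])
        write_panel(panel, paths["panel"])
        manifest = {}
        for proband, variants in cohort.items():
            vcf_path = os.path.join(out_dir, f"{proband}.vcf")
            write_vcf(vcf_path, variants, proband, genome)
            manifest[proband] = vcf_path
        write_manifest(manifest, paths["manifest"])
        bundle.manifest = manifest
        bundle.paths = paths
    return bundle
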