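"""The candidate-selection cascade and inheritance-aware allele pairing.

The cascade keeps rare variants (population AF < 0.5% or unobserved),
requires a SpliceAI maximum delta score >= 0.5, restricts to a curated
disease-gene panel, discards candidates within 10 bp of an exon-intron
junction (those remain eligible only as coding second alleles), and then
pairs alleles per gene under the gene's inheritance mode: one hit suffices
for dominant genes and X-linked hemizygotes, while recessive genes need a
second allele (a rare coding hit, a second qualifying splice variant, or
homozygosity).

Filter tags: ``common``, ``low_score``, ``not_in_panel``, ``near_junction``,
``unpaired``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .gene_models import (
    GenomeSequence,
    TranscriptModel,
    format_intronic_hgvs,
    junction_distance,
)
from .variant_io import AnnotatedVariant, SpliceAIRecord, read_annotated_vcf

__all__ = [
    "GenePanelEntry",
    "CandidateStatus",
    "ProbandReport",
    "read_panel",
    "frequency_filter",
    "max_delta",
    "splice_score_filter",
    "deep_intronic_filter",
    "panel_restrict",
    "inheritance_pairing",
    "prioritize_cohort",
]

INHERITANCE_MODES = ("AD", "AR", "XL")


@dataclass(frozen=True)
class GenePanelEntry:
    """A disease-gene panel row: symbol, inheritance mode, canonical transcript."""

    gene: str
    inheritance: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(
                f"{self.gene}: inheritance must be one of {INHERITANCE_MODES}"
            )


@dataclass
class CandidateStatus:
    """Per-gene decision: solved_candidate, needs_second_allele or rejected."""

    status: str
    reasons: List[str] = field(default_factory=list)
    paired: List[AnnotatedVariant] = field(default_factory=list)
    phase: Optional[str] = None  # unconfirmed | trans_confirmed | de_novo

    def __post_init__(self) -> None:
        if self.status not in ("solved_candidate", "needs_second_allele", "rejected"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "rejected" and not self.reasons:
            raise ValueError("rejected status requires at least one reason")


@dataclass
class ProbandReport:
    """Per-proband outcome: gene statuses plus the surviving splice variants."""

    proband: str
    statuses: Dict[str, CandidateStatus] = field(default_factory=dict)
    splice_variants: List[dict] = field(default_factory=list)

    @property
    def solved(self) -> bool:
        return any(s.status == "solved_candidate" for s in self.statuses.values())


def read_panel(source) -> Dict[str, GenePanelEntry]:
    """Read a panel TSV (gene, inheritance, transcript id); '#' comments allowed."""
    close = False
    if not hasattr(source, "read"):
        source = open(source)
        close = True
    try:
        panel: Dict[str, GenePanelEntry] = {}
        for line in source:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"panel row needs 3 columns: {line!r}")
            gene, mode, tx_id = parts[:3]
            if gene in panel:
                raise ValueError(f"duplicate panel entry for gene {gene!r}")
            panel[gene] = GenePanelEntry(gene, mode, tx_id)
        return panel
    finally:
        if close:
            source.close()


# ---------------------------------------------------------------------------
# pure filters: each returns (survivors, tagged) where tagged maps a removed
# variant's allele key to its reason tag.


def frequency_filter(
    variants: Sequence[AnnotatedVariant], af_max: float = 0.005
) -> Tuple[List[AnnotatedVariant], List[AnnotatedVariant]]:
    """Keep variants with AF strictly below ``af_max`` or with no AF record.

    An absent frequency means the allele is unobserved in the population
    database, hence rare; removed variants are tagged ``common``.
    """
    kept, removed = [], []
    for v in variants:
        if v.allele_frequency is None or v.allele_frequency < af_max:
            kept.append(v)
        else:
            removed.append(v)
    return kept, removed


def max_delta(rec: Optional[SpliceAIRecord]) -> float:
    """Maximum of the four delta scores; 0 for a missing record."""
    return 0.0 if rec is None else rec.max_delta


def splice_score_filter(
    variants: Sequence[AnnotatedVariant], cutoff: float = 0.5
) -> Tuple[List[AnnotatedVariant], List[AnnotatedVariant]]:
    """Keep variants whose maximum delta score is >= ``cutoff`` (inclusive).

    Variants without a SpliceAI record fail; removed ones are tagged
    ``low_score``.
    """
    kept, removed = [], []
    for v in variants:
        (kept if max_delta(v.spliceai) >= cutoff else removed).append(v)
    return kept, removed


def panel_restrict(
    variants: Sequence[AnnotatedVariant], panel: Mapping[str, GenePanelEntry]
) -> Tuple[List[AnnotatedVariant], List[AnnotatedVariant]]:
    """Keep variants on panel genes (case-sensitive symbol match)."""
    kept, removed = [], []
    for v in variants:
        (kept if v.gene in panel else removed).append(v)
    return kept, removed


def deep_intronic_filter(
    variants: Sequence[AnnotatedVariant],
    transcripts: Mapping[str, TranscriptModel],
    min_distance: int = 10,
) -> Tuple[List[AnnotatedVariant], List[AnnotatedVariant]]:
    """Keep intronic variants strictly more than ``min_distance`` bp from a junction.

    ``transcripts`` maps gene symbol to its canonical model.  Exonic and
    near-junction variants are tagged ``near_junction``; they stay eligible
    as coding second alleles but not as splice candidates.
    """
    kept, removed = [], []
    for v in variants:
        tx = transcripts.get(v.gene)
        if tx is None:
            raise ValueError(f"no canonical transcript for gene {v.gene!r}")
        d, loc = junction_distance(v.pos, tx)
        if loc == "intronic" and d > min_distance:
            kept.append(v)
        else:
            removed.append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# inheritance pairing


def _phase(
    splice_v: AnnotatedVariant,
    partner: Optional[AnnotatedVariant],
    parental_genotypes: Optional[Mapping],
) -> str:
    """Phase call for a compound-het pair from optional parental genotypes.

    ``parental_genotypes`` maps an allele key to ``{"father": n, "mother": n}``
    carrier counts.  Alleles on different parental haplotypes confirm trans;
    a splice allele carried by neither parent is flagged de novo.
    """
    if parental_genotypes is None:
        return "unconfirmed"
    sp = parental_genotypes.get(splice_v.key)
    if sp is not None and not sp.get("father") and not sp.get("mother"):
        return "de_novo"
    if partner is None or sp is None:
        return "unconfirmed"
    pa = parental_genotypes.get(partner.key)
    if pa is None:
        return "unconfirmed"
    sp_parents = {p for p in ("father", "mother") if sp.get(p)}
    pa_parents = {p for p in ("father", "mother") if pa.get(p)}
    if sp_parents and pa_parents and not (sp_parents & pa_parents):
        return "trans_confirmed"
    return "unconfirmed"


def inheritance_pairing(
    splice_candidates: Sequence[AnnotatedVariant],
    coding_hits: Sequence[AnnotatedVariant],
    mode: str,
    parental_genotypes: Optional[Mapping] = None,
) -> CandidateStatus:
    """Pair a gene's qualifying alleles under its inheritance mode.

    AD (or an XL hemizygote): one qualifying splice variant suffices.  AR:
    a splice variant plus a second allele — homozygosity, a second splice
    variant, or a rare coding hit — solves; a lone heterozygous splice
    variant is ``needs_second_allele``.  Heterozygous XL carriers are also
    reported ``needs_second_allele``.
    """
    if mode not in INHERITANCE_MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    if not splice_candidates:
        return CandidateStatus(status="rejected", reasons=["unpaired"])
    sv = list(splice_candidates)
    if mode == "AD":
        return CandidateStatus(
            status="solved_candidate", paired=[sv[0]], phase="unconfirmed"
        )
    if mode == "XL":
        hemi = [v for v in sv if v.zygosity in ("hemi", "hom")]
        if hemi:
            return CandidateStatus(
                status="solved_candidate", paired=[hemi[0]], phase="unconfirmed"
            )
        return CandidateStatus(
            status="needs_second_allele", reasons=["unpaired"], paired=[sv[0]]
        )
    # AR
    hom = [v for v in sv if v.zygosity == "hom"]
    if hom:
        return CandidateStatus(
            status="solved_candidate", paired=[hom[0]], phase="unconfirmed"
        )
    if len(sv) >= 2:
        return CandidateStatus(
            status="solved_candidate",
            paired=sv[:2],
            phase=_phase(sv[0], sv[1], parental_genotypes),
        )
    if coding_hits:
        partner = coding_hits[0]
        return CandidateStatus(
            status="solved_candidate",
            paired=[sv[0]] + list(coding_hits),
            phase=_phase(sv[0], partner, parental_genotypes),
        )
    return CandidateStatus(
        status="needs_second_allele", reasons=["unpaired"], paired=[sv[0]]
    )


# ---------------------------------------------------------------------------
# cohort driver


def prioritize_cohort(
    manifest: Mapping[str, object],
    panel: Mapping[str, GenePanelEntry],
    transcripts: Mapping[str, TranscriptModel],
    af_max: float = 0.005,
    score_cutoff: float = 0.5,
    min_junction_distance: int = 10,
    af_key: str = "AF",
    parental_genotypes: Optional[Mapping] = None,
    log=None,
) -> Tuple[List[ProbandReport], dict]:
    """Run the full cascade over a cohort and tally the headline counts.

    ``manifest`` maps proband id to a VCF path (or an already-loaded list
    of :class:`AnnotatedVariant`).  Filters run in the narrated order —
    frequency, splice score, panel, junction distance — and the surviving
    splice candidates are then paired per gene under the panel's
    inheritance mode.  Returns deterministic per-proband reports plus a
    summary with the distinct-variant / solved-proband / novel-variant
    counts and the per-stage funnel.
    """
    reports: List[ProbandReport] = []
    funnel = {"input": 0, "rare": 0, "high_score": 0, "in_panel": 0, "deep_intronic": 0}
    candidate_keys = {}
    for proband in sorted(manifest):
        source = manifest[proband]
        if isinstance(source, (list, tuple)):
            variants = list(source)
        else:
            import os

            if not os.path.exists(os.fspath(source)):
                raise FileNotFoundError(
                    f"VCF for proband {proband!r} not found: {source}"
                )
            variants = read_annotated_vcf(source, proband, af_key=af_key)
        funnel["input"] += len(variants)

        rare, common = frequency_filter(variants, af_max=af_max)
        funnel["rare"] += len(rare)
        scored, low = splice_score_filter(rare, cutoff=score_cutoff)
        funnel["high_score"] += len(scored)
        in_panel, off_panel = panel_restrict(scored, panel)
        funnel["in_panel"] += len(in_panel)
        deep, near = deep_intronic_filter(
            in_panel, transcripts, min_distance=min_junction_distance
        )
        funnel["deep_intronic"] += len(deep)

        # rare coding hits pair as second alleles under AR
        coding = [
            v
            for v in rare
            if v.coding_class != "none" and v.gene in panel
        ]

        tags: Dict[Tuple, List[str]] = {}
        for vs, tag in ((common, "common"), (low, "low_score"),
                        (off_panel, "not_in_panel"), (near, "near_junction")):
            for v in vs:
                tags.setdefault((v.gene, v.key), []).append(tag)

        report = ProbandReport(proband=proband)
        genes = sorted(
            {v.gene for v in variants if v.gene is not None and v.spliceai is not None}
        )
        for gene in genes:
            if gene not in panel:
                report.statuses[gene] = CandidateStatus(
                    status="rejected", reasons=["not_in_panel"]
                )
                continue
            gene_splice = [v for v in deep if v.gene == gene]
            gene_coding = [
                v for v in coding if v.gene == gene and v not in gene_splice
            ]
            status = inheritance_pairing(
                gene_splice,
                gene_coding,
                panel[gene].inheritance,
                parental_genotypes=(parental_genotypes or {}).get(proband),
            )
            if status.status == "rejected":
                reasons = sorted(
                    {t for (g, _), ts in tags.items() if g == gene for t in ts}
                ) or ["unpaired"]
                status = CandidateStatus(status="rejected", reasons=reasons)
            report.statuses[gene] = status
            if status.status == "solved_candidate":
                for v in gene_splice:
                    candidate_keys.setdefault(v.key, v)
            tx = transcripts[gene]
            for v in gene_splice:
                d, _ = junction_distance(v.pos, tx)
                report.splice_variants.append(
                    {
                        "variant": v,
                        "gene": gene,
                        "max_delta": max_delta(v.spliceai),
                        "junction_distance": d,
                        "cdna_variant": format_intronic_hgvs(tx, v.pos, v.ref, v.alt)
                        if v.is_snv
                        else None,
                        "status": status.status,
                    }
                )
        reports.append(report)
        if log is not None:
            log.info(
                "proband %s: %d variants in, %d splice candidates, status %s",
                proband,
                len(variants),
                len(report.splice_variants),
                "solved" if report.solved else "unsolved",
            )

    summary = {
        "probands": len(reports),
        "solved_probands": sum(1 for r in reports if r.solved),
        "distinct_splice_variants": len(candidate_keys),
        "novel_splice_variants": sum(
            1 for v in candidate_keys.values() if v.novel
        ),
        "funnel": funnel,
    }
    return reports, summary
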