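"""VCF input and report output for SpliceAI-annotated cohort variants.

Reads per-proband VCFs (pysam) into :class:`AnnotatedVariant` records,
decomposing multi-allelic sites, and parses the standard SpliceAI INFO
layout ``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``.
Allele frequency, coding consequence class and deleteriousness rank scores
are pass-through annotations: this package consumes them, it never computes
them.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Union

import pysam

__all__ = [
    "SpliceAIRecord",
    "AnnotatedVariant",
    "parse_spliceai_field",
    "format_spliceai_field",
    "read_annotated_vcf",
    "write_candidate_tsv",
    "CANDIDATE_TSV_COLUMNS",
]

CODING_CLASSES = ("none", "missense", "nonsense", "frameshift", "other")


@dataclass(frozen=True)
class SpliceAIRecord:
    """One SpliceAI gene annotation: four delta scores and their positions.

    ``ds_*`` are probabilities in [0, 1] for acceptor gain/loss and donor
    gain/loss; ``dp_*`` are signed positions of the affected site relative
    to the variant, on the reference strand (positive = increasing genomic
    coordinate).
    """

    allele: str
    gene: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def max_delta(self) -> float:
        return max(self.ds_ag, self.ds_al, self.ds_dg, self.ds_dl)


@dataclass
class AnnotatedVariant:
    """One decomposed VCF record with the annotations the cascade consumes.

    ``pos`` is 0-based genomic; ``zygosity`` one of het/hom/hemi;
    ``allele_frequency`` is ``None`` when the population database has no
    entry (treated downstream as rare).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    proband: str
    gene: Optional[str] = None
    zygosity: str = "het"
    allele_frequency: Optional[float] = None
    coding_class: str = "none"
    rank_scores: Dict[str, float] = field(default_factory=dict)
    spliceai: Optional[SpliceAIRecord] = None
    novel: Optional[bool] = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACGTN]+", self.ref) or not re.fullmatch(
            r"[ACGTN]+", self.alt
        ):
            raise ValueError(
                f"{self.contig}:{self.pos + 1} {self.ref}>{self.alt}: "
                "ref/alt must be plain ACGTN sequences (symbolic alleles rejected)"
            )
        if self.zygosity not in ("het", "hom", "hemi"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if self.coding_class not in CODING_CLASSES:
            raise ValueError(f"bad coding_class {self.coding_class!r}")
        if self.allele_frequency is not None and not 0 <= self.allele_frequency <= 1:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def key(self):
        """Identity of the allele, shared across probands."""
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def parse_spliceai_field(text: str) -> List[SpliceAIRecord]:
    """Parse a SpliceAI INFO value into one record per annotated gene.

    Groups are comma-separated; each group has exactly ten pipe-delimited
    tokens.  Missing ("." ) scores and positions map to 0.
    """
    records = []
    for group in text.split(","):
        tokens = group.split("|")
        if len(tokens) != 10:
            raise ValueError(
                f"malformed SpliceAI group {group!r}: "
                f"expected 10 pipe-delimited tokens, got {len(tokens)}"
            )
        def _f(tok: str) -> float:
            return 0.0 if tok in (".", "") else float(tok)

        def _i(tok: str) -> int:
            return 0 if tok in (".", "") else int(tok)

        records.append(
            SpliceAIRecord(
                allele=tokens[0],
                gene=tokens[1],
                ds_ag=_f(tokens[2]),
                ds_al=_f(tokens[3]),
                ds_dg=_f(tokens[4]),
                ds_dl=_f(tokens[5]),
                dp_ag=_i(tokens[6]),
                dp_al=_i(tokens[7]),
                dp_dg=_i(tokens[8]),
                dp_dl=_i(tokens[9]),
            )
        )
    return records


def format_spliceai_field(records: Sequence[SpliceAIRecord]) -> str:
    """Inverse of :func:`parse_spliceai_field` (used by the simulator)."""
    return ",".join(
        "|".join(
            [
                r.allele,
                r.gene,
                f"{r.ds_ag:.2f}",
                f"{r.ds_al:.2f}",
                f"{r.ds_dg:.2f}",
                f"{r.ds_dl:.2f}",
                str(r.dp_ag),
                str(r.dp_al),
                str(r.dp_dg),
                str(r.dp_dl),
            ]
        )
        for r in records
    )


def _zygosity_from_gt(gt, allele_index: int) -> Optional[str]:
    calls = [a for a in gt if a is not None]
    if not calls:
        return None
    hits = sum(1 for a in calls if a == allele_index)
    if hits == 0:
        return None
    if len(calls) == 1:
        return "hemi"
    return "hom" if hits == len(calls) else "het"


def read_annotated_vcf(
    source: Union[str, os.PathLike, TextIO],
    proband: str,
    af_key: str = "AF",
) -> List[AnnotatedVariant]:
    """Read one proband's VCF into annotated variants, one per ALT allele.

    GT is required (0/1 -> het, 1/1 -> hom, haploid 1 -> hemi; records where
    the sample carries no copy of an ALT allele contribute nothing for that
    allele).  Multi-allelic records are decomposed, never dropped.  INFO
    keys: ``af_key`` (population allele frequency), ``SpliceAI``,
    ``CODING_CLASS``, ``NOVEL`` flag and any ``RANK_*`` scores are picked up
    when present.
    """
    tmp_path = None
    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            tmp_path = tmp.name
        path = tmp_path
    else:
        path = os.fspath(source)
    try:
        variants: List[AnnotatedVariant] = []
        with pysam.VariantFile(path) as vcf:
            samples = list(vcf.header.samples)
            if not samples:
                raise ValueError(f"VCF for proband {proband!r} has no sample column")
            sample = samples[0]
            for rec in vcf:
                if "GT" not in rec.samples[sample]:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: missing GT for sample {sample!r}"
                    )
                gt = rec.samples[sample]["GT"]
                if gt is None or all(a is None for a in gt):
                    raise ValueError(f"{rec.chrom}:{rec.pos}: missing GT call")
                info = dict(rec.info)
                spliceai_groups = []
                if "SpliceAI" in info:
                    raw = info["SpliceAI"]
                    raw = ",".join(raw) if isinstance(raw, tuple) else str(raw)
                    spliceai_groups = parse_spliceai_field(raw)
                af_values = info.get(af_key)
                if af_values is not None and not isinstance(af_values, tuple):
                    af_values = (af_values,)
                coding = info.get("CODING_CLASS")
                if isinstance(coding, tuple):
                    coding = coding[0]
                gene_info = info.get("GENE")
                if isinstance(gene_info, tuple):
                    gene_info = gene_info[0]
                rank_scores = {
                    k[len("RANK_") :]: float(
                        v[0] if isinstance(v, tuple) else v
                    )
                    for k, v in info.items()
                    if k.startswith("RANK_")
                }
                for ai, alt in enumerate(rec.alts or (), start=1):
                    zyg = _zygosity_from_gt(gt, ai)
                    if zyg is None:
                        continue
                    sai = next(
                        (g for g in spliceai_groups if g.allele == alt),
                        spliceai_groups[0] if len(spliceai_groups) == 1 else None,
                    )
                    af = None
                    if af_values is not None and len(af_values) >= ai:
                        af = float(af_values[ai - 1])
                    variants.append(
                        AnnotatedVariant(
                            contig=rec.chrom,
                            pos=rec.pos - 1,
                            ref=rec.ref,
                            alt=alt,
                            proband=proband,
                            gene=gene_info or (sai.gene if sai else None),
                            zygosity=zyg,
                            allele_frequency=af,
                            coding_class=coding or "none",
                            rank_scores=rank_scores,
                            spliceai=sai,
                            novel="NOVEL" in info or None,
                        )
                    )
        return variants
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


CANDIDATE_TSV_COLUMNS = [
    "proband",
    "gene",
    "contig",
    "position",
    "ref",
    "alt",
    "cdna_variant",
    "zygosity",
    "variant_type",
    "novel",
    "max_delta",
    "junction_distance",
    "status",
    "phase",
]


def write_candidate_tsv(rows: Sequence[dict], stream: TextIO) -> None:
    """Write candidate report rows as TSV with deterministic order.

    Rows are sorted by proband, then contig, then 1-based genomic position;
    missing fields print as '.'; byte-identical for identical input.
    """
    stream.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
    def sort_key(r):
        return (str(r.get("proband", "")), str(r.get("contig", "")),
                int(r.get("position", 0)))

    for row in sorted(rows, key=sort_key):
        cells = []
        for col in CANDIDATE_TSV_COLUMNS:
            v = row.get(col)
            if v is None:
                cells.append(".")
            elif isinstance(v, bool):
                cells.append("yes" if v else "no")
            elif isinstance(v, float):
                cells.append(f"{v:.4g}")
            else:
                cells.append(str(v))
        stream.write("\t".join(cells) + "\n")
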