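# Methods

## Scope and model

`intronseek` operationalizes a prioritization-and-interpretation procedure
for deep-intronic splice-disrupting SNVs. It does not call variants, does
not compute splice-impact scores (SpliceAI deltas are consumed as VCF
annotations), and does not classify coding deleteriousness (CADD-style
rank scores pass through untouched). Its contributions are the filtering
cascade, the inheritance-aware allele pairing, the mechanistic transcript
reconstruction, and the minigene/RT-PCR design arithmetic.

## Coordinates and conventions

* Internally, all intervals are 0-based half-open; FASTA/GFF3/GTF/VCF I/O
  and all report output use 1-based inclusive conventions.
* HGVS c. numbering anchors intronic positions at the nearest exon edge:
  the first intronic base adjacent to an exon has offset 1 (`+1`/`-1`), so
  the ">10 bp from a junction" filter excludes offsets 1–10 exactly. Ties
  at an intron midpoint resolve to the donor (`+`) side. `format ∘ parse`
  is the identity on every intronic position of a valid transcript
  (property-tested on enumerated positions, both strands).
* SpliceAI DP positions are interpreted as reference-strand offsets from
  the variant (gained site = variant position + DP), then converted to
  transcript sense. This is one fixed, tested convention; annotations
  produced under a different convention must be converted upstream.
* Gained splice-site positions denote *included* boundary bases: the
  gained acceptor is the first and the gained donor the last base of the
  new or extended exon, hence a pseudo-exon's length is
  `|donor − acceptor| + 1`. This inclusive-span convention is what makes
  the fixture reproduce the printed exon lengths (129, 84, 54, 34, 29 bp).
* One canonical transcript per gene (named in the panel file) is used for
  all coordinate arithmetic and reporting.

## Thresholds (defaults, units, rationale)

| parameter | default | meaning |
|---|---|---|
| `af_max` | 0.005 | population AF must be strictly below; absent AF counts as rare (an allele unseen by the population database cannot be common) |
| `score_cutoff` | 0.5 | applied inclusively (≥) to the maximum of the four delta scores; max-of-four is the community convention and is configurable |
| `min_junction_distance` | 10 bp | candidates must be strictly farther from any junction |
| `nmd_boundary` | 50 nt | last-junction rule (below) |
| `flank` | 150 bp | symmetric intronic flank of the minigene insert |
| `vector_exon_bp` | 92 bp | per-side vector-exon contribution to every RT-PCR product |

Filter order is frequency → splice score → panel → junction distance,
then inheritance pairing. The individual filters are pure and commute on
the final survivor set (tested under all permutations); only the reason
tags attached to removed variants depend on order. Junction distance is
applied *before* pairing because near-junction and exonic variants must be
excluded from the qualifying splice-candidate set while remaining eligible
as coding second alleles.

## Event classification

Given a deep-intronic variant with scores ≥ cutoff:

* acceptor gain AND donor gain, acceptor 5' of donor (transcript sense),
  both inside the variant's intron → `pseudo_exon`;
* acceptor gain AND acceptor loss → `acceptor_shift` (downstream exon's 5'
  edge moves into the intron);
* donor gain (with or without donor loss) → `exon_elongation` of the
  transcript-upstream exon.

When several patterns pass, the most specific mechanism wins
(pseudo_exon > acceptor_shift > exon_elongation). A gained acceptor lying
3' of the gained donor cannot form an exon: the event is reported as
`none` with a warning rather than guessed. Gained sites in different
introns raise an error ("non-local event"). An acceptor gain alone, with
no acceptor loss, is not classified — no mechanism in scope explains it.

Every classified event carries `min_gained_score`, the smaller delta among
its gained sites. It is emitted (consequences TSV, summary JSON) because
prediction confidence at the weaker site tracks how completely the
aberrant isoform replaces the normal one in reporter assays; the package
reports the number and asserts nothing about the correlation.

## Frame, PTC and NMD

The mutant chain is spliced against the reference genome. Frame class is
`in_frame` iff the inserted length is a multiple of 3. The PTC scan starts
at the CDS start in mutant-mRNA coordinates and reports the first
TAA/TAG/TGA whose first base lies strictly 5' of the wild-type stop codon
(remapped into mutant coordinates); its 1-based codon index and its offset
in amino acids downstream of the event's upstream junction codon are both
reported. NMD is predicted iff the PTC's first base is strictly more than
`nmd_boundary` nucleotides upstream of the last exon–exon junction of the
mutant chain; single-exon chains never trigger NMD. The 50-nt rule is the
standard heuristic, not a measured quantity; the boundary is configurable.
`find_ptc` is checked against an independent splice-by-slicing codon
scanner on hundreds of random transcripts, and the whole chain (event →
frame → PTC) is strand-mirror invariant by construction and by test.

## Minigene design

The insert runs from `flank` bases 5' of the 5'-most included exon edge to
`flank` bases 3' of the 3'-most edge: for a pseudo-exon, the included
exons are the cryptic exon and the nearer flanking canonical exon (the
test exon); for elongation/acceptor-shift events the extended exon is
itself the test exon. The flank is a single symmetric parameter because no
per-side values are established. Regions overrunning the contig are
clipped with a warning. Predicted products: WT = 2×92 + canonical test
exon length; the variant construct lists both the WT-size and the
variant-size band (partial splicing can never be excluded when any gained
site scores < 1), and the variant band exceeds WT by exactly the inserted
length. Observed isoform ratios are an assay result, not a prediction, and
are out of scope, as are primer thermodynamics and the vector backbone
beyond its two 92-bp exon contributions.

## Synthetic worlds

The simulator builds genes as `pad·exon1·intron1·…·exonN·pad` in
transcript space — every intron GT..AG, every CDS ATG-initiated with a
single terminal stop — then realizes minus-strand genes by
reverse-complementing the contig. Planted splice variants receive SpliceAI
records whose DP geometry is exactly consistent with the intended event;
decoys fail exactly one filter each (common: AF 0.01–0.1; low-score: max
delta < 0.5; near-junction: offset ≤ 10). Default cohort shape: 6 genes ×
4 exons (120–300 bp exons, 300–800 bp introns), five probands covering the
planted configurations {AD_single, AR_splice_plus_coding, AR_hom_splice,
XL_hemi, unsolved}, three decoys per proband. Everything is a pure
function of the spec and its seed (byte-identical outputs, tested).

The case-series fixture is laid out by hand so that each printed cDNA
label is literally realizable: exon lengths are chosen to put the anchor
cDNA position at the correct exon edge (e.g. cumulative coding length 8681
before the exon whose acceptor anchors `c.8682-654`), intron lengths host
the printed offsets on the donor-proximal side, and insert sequences are
built codon-aware (reading phase carried across the junction) with stops
planted at — and only at — the reported positions (e.g. 17 codons past the
ADGRV1-analog cryptic acceptor, 19 codons past the RPGRIP1-analog donor).
The generator seed varies only the neutral background; layout, labels and
counts are fixed by construction. The one previously reported splice
variant (the CNGB3 analog) carries a small nonzero AF and no novelty flag;
the other five are novel with AF absent.

What the fixture does *not* emulate: real hg19 coordinates and transcript
accessions (anchors are reproduced by construction, not lifted from the
genome), realistic allele-frequency spectra, sequencing noise, structural
variants, and SpliceAI's actual score distribution (planted scores are
chosen to respect the pass/fail contract, which is all the cascade
observes). Passing tests therefore demonstrate the correctness of the
cascade, arithmetic and reconstructions under the stated conventions — not
the sensitivity of SpliceAI on real genomes.

## Numerical and degenerate-input choices

* Cutoff comparisons: score ≥ cutoff passes; AF < af_max passes; junction
  distance > threshold passes (all read literally from the stated rules).
* Multi-allelic VCF records are decomposed per ALT allele, never dropped;
  records without a usable GT are a hard error.
* Variants without a SpliceAI record fail the score filter (tag
  `low_score`); genes without a panel transcript are a hard error at the
  distance filter.
* Heterozygous females on XL genes are reported `needs_second_allele`
  rather than solved — the conservative reading where the mode of action
  is hemizygous exposure.
* A splice variant shared by several probands counts once in the
  distinct-variant tally.
* Report ordering is fully deterministic (proband, contig, position), and
  pipeline outputs are byte-identical across runs on identical inputs.

## Problem sizes used in the test suite

Property suites run on deliberately small worlds: ≤ 5-exon transcripts for
exhaustive junction-distance scans; 200 random transcripts for the PTC
oracle; 20 seeded cohorts (default shape above) for recovery/leakage; the
fixture genome is ~60 kb across six contigs. These sizes exercise every
code path while keeping the whole suite in a few seconds.

## Known limitations

* Only SNVs are interpreted mechanistically; indel splice candidates pass
  the cascade but get no HGVS label from the formatter.
* One event per variant: combinations (e.g. simultaneous donor loss and
  distal acceptor gain spanning introns) are rejected rather than modeled.
* Isoform ratios, splice-site strength from sequence, and liftover between
  assemblies are out of scope.
* The acceptor-shift branch is exercised synthetically; the case-series
  fixture encodes the donor-gain/elongation reading for the one variant
  whose mechanism is described both ways in the source material.
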