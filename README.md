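# intronseek

Prioritization of deep-intronic splice-disrupting variants in Mendelian
disease cohorts, with in-silico reconstruction of the aberrant transcript
and automated design of the minigene assay that would validate each
candidate.

About 30% of patients with a clinical diagnosis of an inherited retinal
disease (IRD) remain molecularly unsolved after panel or exome testing.
Part of the gap is deep-intronic variation: single-nucleotide changes far
(>10 bp, often hundreds to thousands of bases) from any exon–intron
junction that create cryptic splice sites, splicing a pseudo-exon into the
mRNA or elongating a canonical exon. `intronseek` is for genome analysts
working such cohorts: it consumes whole-genome VCFs annotated with SpliceAI
delta scores and turns them into a short, inheritance-consistent candidate
list plus everything needed to plan the wet-lab follow-up.

## The cascade

For each proband, variants pass through:

1. **Frequency** — keep alleles with population AF < 0.5% (or absent from
   the population database);
2. **Splice score** — keep variants with max(ΔAG, ΔAL, ΔDG, ΔDL) ≥ 0.5,
   the four SpliceAI delta scores for acceptor/donor gain/loss;
3. **Gene panel** — restrict to curated disease genes, each with an
   inheritance mode (AD/AR/XL) and a canonical transcript;
4. **Junction distance** — keep intronic variants strictly more than 10 bp
   from any exon–intron junction (HGVS offsets ±1..±10 are excluded);
   near-junction and exonic variants stay eligible only as second alleles;
5. **Inheritance pairing** — one hit suffices on a dominant gene or in an
   X-linked hemizygote; a recessive gene needs a second allele (a rare
   coding hit, a second qualifying splice variant, or homozygosity), with
   compound hets assumed in trans (phase flagged, optionally confirmed or
   called de novo from parental genotypes).

Each surviving candidate is then interpreted mechanistically from the
SpliceAI positions: acceptor gain + donor gain inside one intron →
**pseudo-exon** of length `|donor − acceptor| + 1`; donor gain alone →
**exon elongation**; acceptor gain + acceptor loss → **acceptor shift**.
The mutant exon chain is spliced against the reference to classify the
reading frame (in-frame iff insert length ≡ 0 mod 3), locate a premature
termination codon (PTC), and predict nonsense-mediated decay under the
50-nt last-junction rule. Finally a minigene insert is designed — test
exon, cryptic exon and ~150 bp intronic flanks — and RT-PCR band sizes are
predicted with the standard 92 bp vector-exon contribution per side, so a
gel photo can be read against expectation.

## Worked example

The package ships a generator for a synthetic eight-proband case series
(six genes, six distinct deep-intronic splice variants, five novel) whose
cDNA labels, zygosities and event geometry mirror a published IRD cohort;
coordinates are synthetic but every HGVS label is literally realizable on
the fixture transcripts.

```bash
intronseek fixture table1 --out fx/
intronseek prioritize --fasta fx/genome.fa --gff fx/models.gff3 \
    --panel fx/panel.tsv --vcf-manifest fx/manifest.tsv --out report.tsv
```

prints

```
6 distinct splice variants, 8 solved probands
```

and `report.tsv` lists all 15 alleles, e.g.

```
proband  gene     cdna_variant     zygosity  variant_type  max_delta  junction_distance  status
MEP344   OPA1     c.1608+622A>G    het       splicing      0.97       622                solved_candidate
NEI4320  RPGRIP1  c.2367+82A>G     het       splicing      0.88       82                 solved_candidate
MEP105   PCDH15   c.3998+3023T>G   het       splicing      0.98       3023               solved_candidate
```

The full run (`intronseek run --config cfg.yaml`) also writes
`consequences.tsv` (event kind, insert length, frame, PTC, NMD call and the
minimum gained-site score, which tracks how completely the aberrant isoform
is expected to replace the normal one), `minigene_inserts.fa`, and
`rtpcr_products.tsv` with rows like

```
construct                    test_exon_length  wt_product  variant_products
USH2A_chr_USH2A_4541_G_C     1500              1684        1684,1813
RPGRIP1_chr_RPGRIP1_2949_A_G 1248              1351        1351,1432
```

— the variant band always exceeds the wild-type band by exactly the
inserted length (129 bp pseudo-exon for the USH2A analog, 81 bp elongation
for RPGRIP1).

A randomized simulator (`intronseek simulate`) builds toy cohorts with
planted causal configurations and decoy variants plus a truth table, for
benchmarking recall and filter leakage.

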