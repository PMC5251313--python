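# isoclean

A toolkit for refining reference-free transcriptome assemblies and
comparing transcript annotations, aimed at researchers who build genome
annotations for under-characterised species from deep multi-tissue
RNA-seq.  Raw assemblies from tools like Cufflinks or StringTie are
heavily inflated by unspliced pre-mRNA fragments, assembly artifacts and
noise; `isoclean` turns such an assembly into a refined annotation,
quantifies how it differs from existing annotations, and profiles
isoform usage across tissues.

## What it computes

**Class codes.** Every query transcript is assigned a one-character
relationship to a reference annotation, in the style of gffcompare:
`=` (identical intron chain, terminal exons ignored), `c` (contained
sub-chain), `j` (≥1 shared splice junction), `e` (single-exon fragment
intruding into a reference intron), `o` (other same-strand exonic
overlap), `i` (fully intronic), `x` (opposite-strand overlap only),
`u` (intergenic).  Transcripts coded `=` are *matching*, `j` are
*similar*, `u` are *novel*.

**Filtration cascade.** Four successive filters refine a raw assembly:

1. *pre-mRNA* — remove single-exon transcripts classified `i`/`e`/`o`
   against the multi-exon subset of the same assembly;
2. *low abundance* — remove transcripts with pooled TPM below 5% of their
   locus total (single pass, strict inequality);
3. *evidence* — keep only transcripts with an ORF or exonic-overlap
   support (codes `=`,`j`,`o`,`x`,`c`) from an evidence annotation;
4. *erroneous* — remove mitochondrial-contig transcripts and transcripts
   shorter than 201 bp (summed exon length).

A merged version (refined set + reference annotations, redundant
intron chains and contained single-exon transcripts collapsed) is also
available.  A *locus* ("gene") is a single-linkage cluster of
exon-overlapping, strand-compatible transcripts, recomputed at every
stage.

**Comparison statistics.** Matching/similar/novel tallies, *complex
loci* (a locus in one annotation overlapping ≥2 loci in the other), and
Burset–Guigó sensitivity/specificity, Sn = TP/(TP+FN) and
Sp = TP/(TP+FP), at the base, intron and locus levels.

**Structure accounting.** UTR change measured as the summed-exon-length
difference between coding transcripts and reference transcripts sharing
an identical intron chain; novel transcripts triaged into category I
(supported by another same-species annotation), II (cross-species or
ab initio support only), III (ORF only) or excluded (neither).

**Tissue profiles.** A transcript is *present* in a tissue when its mean
TPM there exceeds 5% of its locus total within that tissue; derived
per-tissue statistics include uniquely-present and solely-absent isoform
sets, mitochondrial transcription load, the splicing rate
(transcripts/locus), variable-gene selection (cross-tissue sum and SD
both > 200), and two-axis average-linkage clustering (genes by
1 − Pearson r, tissues by 1 − Spearman ρ).

**Synthetic fixtures.** A deterministic generator plants known counts of
every artifact class (pre-mRNA fragments, sub-5% isoforms, unsupported
transcripts, mitochondrial/short transcripts, three novelty categories,
per-tissue presence patterns) with a truth table, so the whole pipeline
is testable without external data.

## Worked example

Generate a fixture, refine it, and compare the refined set to the
bundled public-style reference:

```bash
isoclean simulate --seed 7 --out demo/fixtures
isoclean refine --gtf demo/fixtures/assembly.gtf --tpm demo/fixtures/tpm.tsv \
    --orfs demo/fixtures/orfs.tsv \
    --evidence demo/fixtures/ncbi.gtf,demo/fixtures/ensembl.gtf,demo/fixtures/xeno.gtf \
    --out demo/refined
cat demo/refined/summary.tsv
```

```
version    genes  transcripts  n50   total_bp  mean_length
initial    70     118          1113  107146    908.0
filtered1  62     102          1145  102286    1002.8
filtered2  62     96           1145  95712     997.0
filtered3  57     91           1151  91327     1003.6
filtered4  48     82           1164  87954     1072.6
```

Each row is one transcriptome version: the pre-mRNA filter removes the 16
planted single-exon fragments (118 → 102), the abundance filter the 6
planted sub-5% isoforms, the evidence filter the 5 unsupported
transcripts, and the erroneous filter the 4 mitochondrial plus 5 short
transcripts, leaving the 82-transcript refined set.

```bash
isoclean compare --query demo/refined/filtered4.gtf --ref demo/fixtures/ncbi.gtf \
    --out demo/cmp
cat demo/cmp/summary.tsv
```

```
metric                  value
matching                64
similar                 0
novel                   18
other                   0
complex_loci_query      0
complex_loci_reference  0
sensitivity_base        0.9308
specificity_base        0.524
sensitivity_intron      1.0
specificity_intron      0.8438
sensitivity_locus       1.0
specificity_locus       0.625
```

The 64 matching transcripts are the gene isoforms sharing intron chains
with the reference; the 18 novel ones are the planted intergenic and
novel-category transcripts.  Base-level sensitivity is below 1 because
reference terminal exons extend beyond some assembled isoforms, and
specificity reflects the refined set's extra isoforms and novel loci.

`isoclean utr`, `isoclean novel` and `isoclean tissues` expose the UTR
accounting, novelty triage and tissue profiling the same way; every
subcommand writes TSV reports plus a `manifest.json`.

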