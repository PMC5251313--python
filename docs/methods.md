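# Methods

This note documents the models and procedures implemented by `isoclean`,
the parameters that matter, the design choices made where the published
protocol leaves the behaviour open, and what the synthetic fixtures do
and do not demonstrate.

## Coordinates and domain model

GTF files are 1-based inclusive; internally every coordinate is 0-based
half-open, with conversion confined to the I/O layer.  A transcript is an
ordered set of disjoint exons on one contig and strand; its *length* is
the summed exon length (RNA space), never the genomic span.  The *intron
chain* is the ordered list of (donor, acceptor) junction coordinates;
two multi-exon transcripts with identical chains are structurally the
same gene model regardless of terminal exon boundaries.

A *locus* is the unit reported as a "gene" and the denominator of every
per-locus expression fraction.  Because assemblers and merged annotations
disagree on `gene_id`, loci are always recomputed: single-linkage
clusters of transcripts sharing ≥1 bp of exonic sequence on compatible
strands.  Unknown-strand transcripts link to either strand and can
bridge the two; bridged loci are reported with unknown strand and a
warning.  Input `gene_id` values are preserved as attributes but never
trusted for grouping; gene counts may therefore differ from
`gene_id`-based tallies of the same file.

## Classification (class codes)

A query transcript takes the most informative code over all reference
transcripts, precedence `= > c > j > e > o > i > x > u`; the reported
partner is the transcript achieving that code (longest first, then
lexicographic id).  Decisions the code definitions leave open:

* **Single-exon `=`.**  Intron chains do not exist for single-exon
  transcripts; a single-exon pair is called `=` when each transcript
  covers ≥ 80% of the other (configurable `single_exon_match_frac`).
* **`e` intrusion.**  A single-exon fragment must reach ≥ 10 bp into a
  reference intron (`e_intrusion_bp`) to be called pre-mRNA-like,
  separating genuine unspliced fragments from exon-boundary jitter.
* **Strands.**  Unknown-strand transcripts are compared against both
  strands and keep the best code; `x` is assigned only when both strands
  are known, so it never swallows ambiguous overlaps.
* **`c`.**  Requires the query's chain to be a contiguous sub-chain of
  the reference chain *and* the query span to lie within the reference
  span; a sub-chain hanging over the reference end is `j`.

## Comparison statistics

Matching/similar/novel tallies count codes `=`/`j`/`u`; every other code
(including opposite-strand overlap) is *other*.  Complex loci are
directional: a locus of A is flagged when its exons overlap ≥ 2 distinct
loci of B.

Sensitivity and specificity follow the gene-prediction convention
(Sn = TP/(TP+FN), Sp = TP/(TP+FP)) at three levels:

* **base** — exonic bases, deduplicated through per-annotation exon
  union, counted once per strand with unknown-strand exons contributing
  to both strands.  Swapping query and reference exchanges Sn and Sp
  exactly.
* **intron** — distinct (contig, strand, donor, acceptor) units, with
  unknown strand matching either.
* **locus** — a reference locus scores when one of its transcripts is
  the `=` partner of some query transcript.  This is the strictest
  defensible reading of "gene level" for loci; an annotation pair with
  many near-matches but no exact chains scores 0 here by design.
  Empty denominators (e.g. no introns anywhere) report 1.0, treating an
  absent category as trivially recovered.

## Filtration cascade

The four filters run in a fixed order, each on the previous stage's
output, loci rebuilt after every stage (so a locus can *split* when
isoforms are removed, and per-stage gene counts can rise even as
transcript counts fall).

1. **pre-mRNA** — single-exon transcripts classified `i`, `e` or `o`
   against the multi-exon subset of the same assembly are removed.
2. **low abundance** — pooled TPM (a matrix is pooled by summing library
   columns) below `locus_fraction` (default 0.05) of the locus total,
   strict inequality, single pass: totals are not re-derived after
   removals, so one filtering event cannot cascade.  Zero-TPM loci keep
   all transcripts.  Transcripts absent from the table count as zero and
   are logged.
3. **evidence** — a transcript survives with an ORF call or a support
   code against ≥ 1 evidence annotation.  The support set is
   `{=, j, o, x, c}`: the published protocol lists `{j, o, x, c}`, and an
   exact match is strictly stronger evidence than a shared junction, so
   `=` is included by default; `literal_support=True` restores the
   four-code list.
4. **erroneous** — transcripts on mitochondrial contigs (default
   `chrM`, `MT`) and transcripts with summed exon length < `min_length`
   (default 201 bp; genomic span would spare short multi-exon
   fragments).

Assembly summary statistics (N50, total bp, mean length) are computed on
summed exon lengths.  `merge_dedup` unions annotations, collapsing
multi-exon transcripts by exact chain key (longest representative,
primary annotation wins ties) and dropping single-exon transcripts
contained in a longer strand-compatible single-exon transcript.  The
merged version deliberately sacrifices terminal-exon isoform diversity
for non-redundancy.

## UTR accounting and novelty triage

UTR change is measured only where it is well defined: coding multi-exon
query transcripts whose chain exactly matches ≥ 1 reference transcript.
With identical internal structure, any length difference is terminal
(UTR) sequence.  When several references share the chain the longest is
used — the most conservative extension estimate and one record per query
transcript.  Single-exon transcripts are excluded (no chain to anchor
"same gene"), and "coding" comes from the same ORF table as the evidence
filter (a single source of coding truth).

A transcript is *novel* when coded `u` against at least one of the two
primary same-species annotations.  Category I requires exonic-overlap
support (`{=, j, o, x, c}`) from any same-species annotation; II requires
`u` against all same-species annotations plus cross-species/ab initio
support; III requires `u` everywhere, no support, and an ORF.  The
*excluded* bucket is the catch-all remainder so that the four categories
partition the novel set; this includes the corner case of a transcript
novel to one primary annotation but overlapping the other without exonic
support (e.g. intronic), for which the published rules give no category.

## Tissue profiles

Per-tissue transcript TPM is the arithmetic mean over the tissue's
libraries: TPM is already depth-normalised, so summing would weight
tissues by library count.  Presence requires tissue TPM strictly above
5% of the locus total in that tissue; a zero-expression locus has no
present transcripts.  Uniquely-present (present in exactly one tissue)
and solely-absent (absent from exactly one) sets need ≥ 2 tissues.
Mitochondrial load is the TPM share of mitochondrial-contig transcripts
and is only meaningful on an annotation version that still contains
them (the stage-3 annotation in our pipeline).  The per-tissue splicing
rate is transcripts ÷ loci over the present subset with loci rebuilt per
tissue, reported to one decimal.

Variable genes require cross-tissue TPM sum and sample standard
deviation (n−1 denominator) both strictly above 200.  Clustering is
agglomerative average linkage; gene distance is 1 − Pearson r across
tissues and tissue distance 1 − Spearman ρ across selected genes,
with Spearman computed as Pearson on average ranks.  Constant vectors
have undefined correlation; their distance to everything is set to the
maximum (2.0) with a warning — the SD filter normally prevents this, but
synthetic inputs may not.  Dendrograms are returned as linkage matrices,
leaf orders and Newick text; ties follow scipy's input-index convention.

## Synthetic fixtures

The generator emulates, at desk scale, the structure that makes raw
multi-tissue assemblies hard: a small genome (two nuclear contigs plus a
mitochondrial contig), 30 multi-exon genes of 3–6 exons with 1–3
isoforms differing in terminal exons, and planted artifacts with exact
bookkeeping — 8 intronic and 8 exon-overlapping single-exon fragments,
6 isoforms at 1% of locus TPM (against a 70/15/12 TPM share for real
isoforms), 5 unsupported transcripts, 4 mitochondrial and 5 sub-201 bp
transcripts, 4 novel transcripts per category, and 4 uniquely-present
plus 4 solely-absent isoforms across 4 tissues × 2 libraries with ±2%
multiplicative library noise.  Reference annotations are derived from
the same genes with terminal exons shifted by 100–600 bp, giving known
UTR deltas.  Every transcript appears in exactly one truth row, and the
same seed reproduces byte-identical files.

What the fixtures do *not* emulate: sequence content, read-level noise,
fractional-ambiguity in quantification, incomplete assemblies of real
isoforms, or the scale of a real assembly (hundreds of thousands of
transcripts).  Passing the recovery tests therefore demonstrates that
the rules are implemented exactly as stated, not that the thresholds are
optimal for any particular real data set.  Published headline counts
(tens of thousands of genes from hundreds of gigabases of RNA-seq)
depend on the full data and external annotations and are out of reach at
this scale; the acceptance checks instead verify the arithmetic
identities those publications print (splicing rates from per-tissue
counts, percent gene reduction, mean UTR change, single-exon share)
and exact oracle equivalence on randomized fixtures.

## Numerical and procedural choices

* Strict inequalities at every threshold (5% locus fraction, presence
  rule, variable-gene cutoffs); boundary values survive.
* Filters are idempotent and the cascade is monotone in transcript
  count; both are asserted by tests.
* Oracle-equivalence tests run 100 random annotation pairs of up to ~35
  transcripts against brute-force per-base/all-pairs enumerations, and
  planted-recovery tests run 5 generator seeds — sizes chosen to keep
  the default suite in the tens of seconds while exercising every code
  path.
* Ties in best-reference selection break by longest reference, then
  lexicographic id; locus ids order by (contig, span start, span end).

## Known limitations

* The locus-level Sn/Sp criterion (exact chain match) is one defensible
  choice among several; overlap-based criteria would score higher.
* `compare` reports the precedence-best code per transcript; a
  transcript equal to one reference and intronic to another reports `=`
  only.
* The merged annotation keeps a single representative per intron chain
  and therefore under-represents UTR diversity by construction.
* GFF3 input, FASTA sequence extraction and read-level processing are
  out of scope.
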