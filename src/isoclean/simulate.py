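"""Deterministic synthetic fixtures with planted, countable structure.

The generator emulates the statistical structure of a raw multi-tissue
RNA-seq assembly on a small synthetic genome (two nuclear contigs plus one
mitochondrial contig): multi-exon genes with isoform and UTR variants,
single-exon pre-mRNA fragments (intronic and exon-overlapping),
low-abundance isoforms below the 5% locus fraction, mitochondrial and
sub-201 bp transcripts, unsupported transcripts, three classes of novel
transcripts, and per-tissue expression with planted unique-presence and
sole-absence patterns.  Every planted transcript is listed in a truth
table with its expected fate, so filters and classifiers can be checked by
exact count recovery.  The same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gtf import write_gtf
from .models import TranscriptModel, TranscriptomeAnnotation, make_transcript
from .tissues import ExpressionTable

NUCLEAR_CONTIGS = ("chr1", "chr2")
MITO_CONTIG = "chrM"


@dataclass(frozen=True)
class FixtureSpec:
    """Plant counts and study conditions for one synthetic fixture."""

    seed: int = 0
    n_loci: int = 30
    isoform_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.35, 3: 0.25}
    )
    n_pre_mrna_intronic: int = 8
    n_pre_mrna_exonic: int = 8
    n_clean_singletons: int = 6
    n_low_abundance: int = 6
    n_no_evidence: int = 5
    n_mito: int = 4
    n_short: int = 5
    n_novel_1: int = 4
    n_novel_2: int = 4
    n_novel_3: int = 4
    tissues: tuple[str, ...] = ("brainstem", "cerebellum", "retina", "muscle")
    samples_per_tissue: int = 2
    n_unique_present: int = 4
    n_sole_absent: int = 4
    n_utr_reduced: int = 3
    n_utr_unchanged: int = 2
    utr_jitter: tuple[int, int] = (100, 600)
    mito_contig: str = MITO_CONTIG

    def __post_init__(self) -> None:
        counts = {
            k: getattr(self, k)
            for k in (
                "n_loci", "n_pre_mrna_intronic", "n_pre_mrna_exonic",
                "n_clean_singletons", "n_low_abundance", "n_no_evidence",
                "n_mito", "n_short", "n_novel_1", "n_novel_2", "n_novel_3",
                "n_unique_present", "n_sole_absent", "n_utr_reduced",
                "n_utr_unchanged", "samples_per_tissue",
            )
        }
        for k, v in counts.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for k in ("n_pre_mrna_intronic", "n_pre_mrna_exonic"):
            if counts[k] > self.n_loci:
                raise ValueError(f"{k} may not exceed n_loci (one fragment per gene)")
        if self.n_low_abundance + self.n_unique_present + self.n_sole_absent > self.n_loci:
            raise ValueError(
                "n_low_abundance + n_unique_present + n_sole_absent may not exceed n_loci"
            )
        if self.n_utr_reduced + self.n_utr_unchanged > self.n_loci:
            raise ValueError("n_utr_reduced + n_utr_unchanged may not exceed n_loci")
        if self.n_mito > 0 and not self.mito_contig:
            raise ValueError("n_mito > 0 requires a mitochondrial contig name")
        if self.n_unique_present or self.n_sole_absent:
            if len(self.tissues) < 2:
                raise ValueError("presence plants require at least two tissues")
        total = sum(self.isoform_weights.values())
        if not total > 0:
            raise ValueError("isoform_weights must have positive total weight")


@dataclass
class Fixture:
    spec: FixtureSpec
    assembly: TranscriptomeAnnotation
    ncbi: TranscriptomeAnnotation
    ensembl: TranscriptomeAnnotation
    xeno: TranscriptomeAnnotation
    expr: ExpressionTable
    orf_calls: dict[str, bool]
    truth: pd.DataFrame

    @property
    def equine_refs(self) -> dict[str, TranscriptomeAnnotation]:
        return {"ncbi": self.ncbi, "ensembl": self.ensembl}

    @property
    def evidence(self) -> list[TranscriptomeAnnotation]:
        """Evidence tracks for support filtering (public + cross-species)."""
        return [self.ncbi, self.ensembl, self.xeno]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.assembly, outdir / "assembly.gtf")
        write_gtf(self.ncbi, outdir / "ncbi.gtf")
        write_gtf(self.ensembl, outdir / "ensembl.gtf")
        write_gtf(self.xeno, outdir / "xeno.gtf")
        self.expr.tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="transcript_id")
        pd.Series(self.expr.sample_tissue, name="tissue").rename_axis("sample").to_csv(
            outdir / "samples.tsv", sep="\t"
        )
        pd.Series(
            {k: int(v) for k, v in self.orf_calls.items()}, name="has_orf"
        ).rename_axis("transcript_id").to_csv(outdir / "orfs.tsv", sep="\t")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


class _Builder:
    def __init__(self, spec: FixtureSpec) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.assembly: list[TranscriptModel] = []
        self.ncbi: list[TranscriptModel] = []
        self.ensembl: list[TranscriptModel] = []
        self.xeno: list[TranscriptModel] = []
        self.orf: dict[str, bool] = {}
        self.base_tpm: dict[str, dict[str, float]] = {}  # tid -> tissue -> TPM
        self.truth_rows: list[dict] = []

    # -- helpers ------------------------------------------------------------

    def _record(self, tid: str, kind: str, **extra) -> None:
        row = {
            "transcript_id": tid,
            "kind": kind,
            "removal_stage": "",
            "removal_reason": "",
            "code_vs_ncbi": "",
            "novel_category": "",
            "unique_tissue": "",
            "absent_tissue": "",
            "utr_delta": "",
        }
        row.update(extra)
        self.truth_rows.append(row)

    def _flat_tpm(self, value: float) -> dict[str, float]:
        return {t: value for t in self.spec.tissues}

    def _add(self, t: TranscriptModel, tpm: dict[str, float], orf: bool) -> None:
        self.assembly.append(t)
        self.base_tpm[t.transcript_id] = tpm
        self.orf[t.transcript_id] = orf

    # -- gene territory -----------------------------------------------------

    def build_genes(self) -> None:
        spec, rng = self.spec, self.rng
        n_iso_choices = sorted(spec.isoform_weights)
        weights = np.array([spec.isoform_weights[k] for k in n_iso_choices], dtype=float)
        weights /= weights.sum()

        low_hosts = set(range(spec.n_low_abundance))
        uniq_hosts = {
            spec.n_low_abundance + i: spec.tissues[i % len(spec.tissues)]
            for i in range(spec.n_unique_present)
        }
        abs_hosts = {
            spec.n_low_abundance + spec.n_unique_present + i:
            spec.tissues[i % len(spec.tissues)]
            for i in range(spec.n_sole_absent)
        }
        utr_unchanged = set(
            range(spec.n_loci - spec.n_utr_reduced - spec.n_utr_unchanged,
                  spec.n_loci - spec.n_utr_reduced)
        )
        utr_reduced = set(range(spec.n_loci - spec.n_utr_reduced, spec.n_loci))

        self.genes: list[dict] = []
        cursor = 2000
        for g in range(spec.n_loci):
            strand = "+" if g % 2 == 0 else "-"
            n_exons = int(rng.integers(3, 7))
            exons: list[tuple[int, int]] = []
            pos = cursor
            for _ in range(n_exons):
                length = int(rng.integers(100, 400))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(300, 1200))
            cursor = exons[-1][1] + 8000
            primary = tuple(exons)

            n_iso = int(rng.choice(n_iso_choices, p=weights))
            iso_exons = [primary]
            for _ in range(n_iso - 1):
                iso_exons.append(self._jitter_terminals(primary))

            # reference model: same chain, terminal exons shifted
            if g in utr_unchanged:
                ref_exons = primary
            elif g in utr_reduced:
                ref_exons = self._shift_terminals(primary, outward=True)
            else:
                ref_exons = self._shift_terminals(primary, outward=False)

            gene = {
                "idx": g,
                "contig": "chr1",
                "strand": strand,
                "primary": primary,
                "isoforms": iso_exons,
                "ref_exons": ref_exons,
                "low": g in low_hosts,
                "unique_tissue": uniq_hosts.get(g),
                "absent_tissue": abs_hosts.get(g),
            }
            self.genes.append(gene)
            self._emit_gene(gene)

        self.chr1_end = cursor

    def _jitter_terminals(self, exons: tuple[tuple[int, int], ...]) -> tuple:
        """New isoform exons: same chain, first/last exon boundaries moved."""
        rng = self.rng
        exons = [list(e) for e in exons]
        for which in (0, -1):
            shift = int(rng.integers(20, 150))
            s, e = exons[which]
            if which == 0:
                exons[0][0] = s - shift if rng.random() < 0.5 else min(s + shift, e - 50)
            else:
                exons[-1][1] = e + shift if rng.random() < 0.5 else max(e - shift, s + 50)
        return tuple(tuple(e) for e in exons)

    def _shift_terminals(self, exons, outward: bool) -> tuple:
        rng = self.rng
        lo, hi = self.spec.utr_jitter
        exons = [list(e) for e in exons]
        first = int(rng.integers(lo, hi + 1))
        last = int(rng.integers(lo, hi + 1))
        if outward:
            exons[0][0] -= first
            exons[-1][1] += last
        else:
            s, e = exons[0]
            exons[0][0] = min(s + first, e - 50)
            s, e = exons[-1]
            exons[-1][1] = max(e - last, s + 50)
        return tuple(tuple(e) for e in exons)

    def _emit_gene(self, gene: dict) -> None:
        g = gene["idx"]
        contig, strand = gene["contig"], gene["strand"]
        ref_len = sum(e - s for s, e in gene["ref_exons"])
        tpm_shares = [70.0, 15.0, 12.0]
        for k, exons in enumerate(gene["isoforms"]):
            tid = f"G{g:03d}.{k + 1}"
            t = make_transcript(tid, contig, strand, exons, gene_id=f"G{g:03d}")
            self._add(t, self._flat_tpm(tpm_shares[k]), orf=True)
            self._record(
                tid, "gene_isoform", code_vs_ncbi="=", utr_delta=t.length - ref_len
            )
        if gene["low"]:
            tid = f"G{g:03d}.low"
            exons = self._jitter_terminals(gene["primary"])
            t = make_transcript(tid, contig, strand, exons, gene_id=f"G{g:03d}")
            self._add(t, self._flat_tpm(1.0), orf=True)
            self._record(
                tid, "low_abundance", removal_stage="low_abundance",
                removal_reason="below locus fraction", code_vs_ncbi="=",
                utr_delta=t.length - ref_len,
            )
        if gene["unique_tissue"]:
            tissue = gene["unique_tissue"]
            tid = f"G{g:03d}.unq"
            exons = self._jitter_terminals(gene["primary"])
            t = make_transcript(tid, contig, strand, exons, gene_id=f"G{g:03d}")
            tpm = {tt: 0.0 for tt in self.spec.tissues}
            tpm[tissue] = 100.0
            self._add(t, tpm, orf=True)
            self._record(
                tid, "unique_present", code_vs_ncbi="=", unique_tissue=tissue,
                utr_delta=t.length - sum(e - s for s, e in gene["ref_exons"]),
            )
        if gene["absent_tissue"]:
            tissue = gene["absent_tissue"]
            tid = f"G{g:03d}.abs"
            exons = self._jitter_terminals(gene["primary"])
            t = make_transcript(tid, contig, strand, exons, gene_id=f"G{g:03d}")
            tpm = {tt: 40.0 for tt in self.spec.tissues}
            tpm[tissue] = 0.0
            self._add(t, tpm, orf=True)
            self._record(
                tid, "sole_absent", code_vs_ncbi="=", absent_tissue=tissue,
                utr_delta=t.length - sum(e - s for s, e in gene["ref_exons"]),
            )
        # public reference models
        self.ncbi.append(
            make_transcript(f"NCBI_G{g:03d}", contig, strand, gene["ref_exons"])
        )
        self.ensembl.append(
            make_transcript(f"ENS_G{g:03d}", contig, strand, gene["ref_exons"])
        )

    # -- planted artifacts on chr1 ------------------------------------------

    def build_fragments(self) -> None:
        spec = self.spec
        for i in range(spec.n_pre_mrna_intronic):
            gene = self.genes[i % spec.n_loci]
            primary = make_transcript("tmp", "chr1", gene["strand"], gene["primary"])
            d, a = primary.introns[0]
            end = min(a - 20, d + 20 + 400)
            tid = f"PMI{i:03d}"
            t = make_transcript(tid, "chr1", gene["strand"], [(d + 20, end)])
            self._add(t, self._flat_tpm(8.0), orf=False)
            self._record(tid, "pre_mrna_intronic", removal_stage="pre_mrna",
                         removal_reason="i", code_vs_ncbi="i")
        for i in range(spec.n_pre_mrna_exonic):
            gene = self.genes[i % spec.n_loci]
            exon1 = gene["primary"][1]
            tid = f"PME{i:03d}"
            t = make_transcript(
                tid, "chr1", gene["strand"], [(exon1[1] - 100, exon1[1] + 120)]
            )
            self._add(t, self._flat_tpm(3.0), orf=False)
            self._record(tid, "pre_mrna_exonic", removal_stage="pre_mrna",
                         removal_reason="e", code_vs_ncbi="e")

    def build_intergenic(self) -> None:
        spec, rng = self.spec, self.rng
        cursor = self.chr1_end + 5000
        for i in range(spec.n_clean_singletons):
            length = int(rng.integers(300, 800))
            tid = f"SGL{i:03d}"
            strand = "+" if i % 2 == 0 else "-"
            t = make_transcript(tid, "chr1", strand, [(cursor, cursor + length)])
            cursor += length + 3000
            self._add(t, self._flat_tpm(10.0), orf=True)
            self._record(tid, "clean_singleton", code_vs_ncbi="u",
                         novel_category="III")
        for i in range(spec.n_short):
            length = int(rng.integers(80, 200))
            tid = f"SHORT{i:03d}"
            t = make_transcript(tid, "chr1", "+", [(cursor, cursor + length)])
            cursor += length + 3000
            self._add(t, self._flat_tpm(6.0), orf=True)
            self._record(tid, "short", removal_stage="erroneous",
                         removal_reason="short", code_vs_ncbi="u",
                         novel_category="III")

    def build_mito(self) -> None:
        spec, rng = self.spec, self.rng
        cursor = 100
        for i in range(spec.n_mito):
            length = int(rng.integers(400, 1200))
            tid = f"MITO{i:03d}"
            t = make_transcript(tid, spec.mito_contig, "+", [(cursor, cursor + length)])
            cursor += length + 500
            self._add(t, self._flat_tpm(300.0), orf=True)
            self._record(tid, "mito", removal_stage="erroneous",
                         removal_reason="mito", code_vs_ncbi="u",
                         novel_category="III")

    # -- novelty territory on chr2 ------------------------------------------

    def _random_multiexon(self, contig: str, strand: str, start: int,
                          n_exons: int) -> tuple[tuple[int, int], ...]:
        rng = self.rng
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(150, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(300, 900))
        return tuple(exons)

    def build_novels(self) -> None:
        spec, rng = self.spec, self.rng
        cursor = 2000
        for i in range(spec.n_novel_1):
            strand = "+" if i % 2 == 0 else "-"
            exons = self._random_multiexon("chr2", strand, cursor, int(rng.integers(3, 5)))
            cursor = exons[-1][1] + 6000
            tid = f"NOV1_{i:03d}"
            t = make_transcript(tid, "chr2", strand, exons)
            self._add(t, self._flat_tpm(12.0), orf=False)
            self._record(tid, "novel_I", code_vs_ncbi="u", novel_category="I")
            if i % 2 == 0:  # exact chain in the second public annotation
                self.ensembl.append(make_transcript(f"ENS_{tid}", "chr2", strand, exons))
            else:  # shared-junction support only
                self.ensembl.append(
                    make_transcript(f"ENS_{tid}", "chr2", strand, exons[:-1])
                )
        for i in range(spec.n_novel_2):
            strand = "+" if i % 2 == 0 else "-"
            exons = self._random_multiexon("chr2", strand, cursor, int(rng.integers(2, 4)))
            cursor = exons[-1][1] + 6000
            tid = f"NOV2_{i:03d}"
            t = make_transcript(tid, "chr2", strand, exons)
            self._add(t, self._flat_tpm(9.0), orf=False)
            self._record(tid, "novel_II", code_vs_ncbi="u", novel_category="II")
            s, e = exons[0]
            self.xeno.append(
                make_transcript(f"XENO_{tid}", "chr2", strand, [(s - 30, e + 30)])
            )
        for i in range(spec.n_novel_3):
            strand = "+" if i % 2 == 0 else "-"
            exons = self._random_multiexon("chr2", strand, cursor, int(rng.integers(2, 4)))
            cursor = exons[-1][1] + 6000
            tid = f"NOV3_{i:03d}"
            t = make_transcript(tid, "chr2", strand, exons)
            self._add(t, self._flat_tpm(7.0), orf=True)
            self._record(tid, "novel_III", code_vs_ncbi="u", novel_category="III")
        for i in range(spec.n_no_evidence):
            strand = "+" if i % 2 == 0 else "-"
            exons = self._random_multiexon("chr2", strand, cursor, int(rng.integers(2, 4)))
            cursor = exons[-1][1] + 6000
            tid = f"NOEV{i:03d}"
            t = make_transcript(tid, "chr2", strand, exons)
            self._add(t, self._flat_tpm(10.0), orf=False)
            self._record(tid, "no_evidence", removal_stage="evidence",
                         removal_reason="no ORF, no evidence overlap",
                         code_vs_ncbi="u", novel_category="excluded")

    # -- expression matrix ---------------------------------------------------

    def build_expression(self) -> ExpressionTable:
        spec, rng = self.spec, self.rng
        samples: list[str] = []
        sample_tissue: dict[str, str] = {}
        for tissue in spec.tissues:
            for s in range(spec.samples_per_tissue):
                name = f"{tissue}_s{s + 1}"
                samples.append(name)
                sample_tissue[name] = tissue
        tids = [t.transcript_id for t in self.assembly]
        data = np.zeros((len(tids), len(samples)))
        for i, tid in enumerate(tids):
            for j, sample in enumerate(samples):
                base = self.base_tpm[tid][sample_tissue[sample]]
                if base > 0:
                    data[i, j] = base * (1.0 + 0.02 * rng.uniform(-1.0, 1.0))
        tpm = pd.DataFrame(np.round(data, 4), index=pd.Index(tids, name="transcript_id"),
                           columns=samples)
        return ExpressionTable(tpm, sample_tissue)

    def build(self) -> Fixture:
        self.build_genes()
        self.build_fragments()
        self.build_intergenic()
        self.build_mito()
        self.build_novels()
        expr = self.build_expression()
        truth = pd.DataFrame(self.truth_rows)
        return Fixture(
            spec=self.spec,
            assembly=TranscriptomeAnnotation.from_transcripts("assembly", self.assembly),
            ncbi=TranscriptomeAnnotation.from_transcripts("ncbi", self.ncbi),
            ensembl=TranscriptomeAnnotation.from_transcripts("ensembl", self.ensembl),
            xeno=TranscriptomeAnnotation.from_transcripts("xeno", self.xeno),
            expr=expr,
            orf_calls=self.orf,
            truth=truth,
        )


def generate(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Build one fixture; optionally write its files to ``outdir``."""
    fixture = _Builder(spec).build()
    if outdir is not None:
        fixture.write(outdir)
    return fixture
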