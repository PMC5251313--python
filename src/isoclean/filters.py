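"""The four-stage refinement cascade and the merge-with-dedup step.

Stage 1 (``pre_mrna``)       removes single-exon fragments that look like
                             unspliced pre-mRNA: classified ``i``, ``e`` or
                             ``o`` against the multi-exon subset of the same
                             assembly.
Stage 2 (``low_abundance``)  removes transcripts carrying less than 5% of
                             their locus' pooled TPM (single pass).
Stage 3 (``evidence``)       keeps a transcript only if it has an ORF or
                             exonic-overlap support from at least one
                             evidence annotation.
Stage 4 (``erroneous``)      removes transcripts on mitochondrial contigs
                             and transcripts shorter than 201 bp.

Loci are rebuilt after every stage, so gene counts always reflect the
surviving transcripts (a locus can split when isoforms are removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .compare import ReferenceIndex, classify_transcript
from .config import DEFAULT_CONFIG, RunConfig
from .models import (
    TranscriptModel,
    TranscriptomeAnnotation,
    strands_compatible,
)

logger = logging.getLogger(__name__)

STAGES = ("pre_mrna", "low_abundance", "evidence", "erroneous")


@dataclass
class FilterReport:
    stage: str
    removed: dict[str, str]  # transcript_id -> reason
    genes_before: int
    genes_after: int
    transcripts_before: int
    transcripts_after: int

    def __post_init__(self) -> None:
        assert self.transcripts_after == self.transcripts_before - len(self.removed)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.removed.items()), columns=["transcript_id", "reason"]
        )


def _finish(
    stage: str,
    assembly: TranscriptomeAnnotation,
    removed: dict[str, str],
    name: str,
) -> tuple[TranscriptomeAnnotation, FilterReport]:
    kept = [t for t in assembly.transcripts() if t.transcript_id not in removed]
    out = TranscriptomeAnnotation.from_transcripts(name, kept)
    report = FilterReport(
        stage=stage,
        removed=removed,
        genes_before=assembly.n_loci,
        genes_after=out.n_loci,
        transcripts_before=len(assembly),
        transcripts_after=len(out),
    )
    return out, report


# ---------------------------------------------------------------------------
# stage 1: pre-mRNA fragments
# ---------------------------------------------------------------------------

def filter_pre_mrna(
    assembly: TranscriptomeAnnotation, config: RunConfig = DEFAULT_CONFIG
) -> tuple[TranscriptomeAnnotation, FilterReport]:
    """Drop single-exon transcripts classified i/e/o vs the multi-exon subset."""
    multi = [t for t in assembly.transcripts() if t.is_multi_exon]
    subset = TranscriptomeAnnotation.from_transcripts(f"{assembly.name}_multiexon", multi)
    index = ReferenceIndex(subset)
    removed: dict[str, str] = {}
    for t in assembly.transcripts():
        if t.is_multi_exon:
            continue
        code, _ = classify_transcript(t, index, config)
        if code in ("i", "e", "o"):
            removed[t.transcript_id] = code
    return _finish("pre_mrna", assembly, removed, f"{assembly.name}_f1")


# ---------------------------------------------------------------------------
# stage 2: low-abundance isoforms
# ---------------------------------------------------------------------------

def pooled_tpm(expr, transcript_ids: Iterable[str] | None = None) -> pd.Series:
    """One pooled TPM per transcript from a Series, DataFrame or mapping.

    A DataFrame (transcript x library) is pooled by summing its numeric
    columns, matching a quantification run over all libraries together.
    """
    if isinstance(expr, pd.DataFrame):
        pooled = expr.select_dtypes("number").sum(axis=1)
        if expr.shape[1] > 1:
            logger.info("pooling %d TPM columns by summation", expr.shape[1])
    elif isinstance(expr, pd.Series):
        pooled = expr.astype(float)
    else:
        pooled = pd.Series(dict(expr), dtype=float)
    if (pooled < 0).any():
        bad = pooled[pooled < 0].index[0]
        raise ValueError(f"negative TPM for transcript {bad}")
    if transcript_ids is not None:
        ids = list(transcript_ids)
        missing = [i for i in ids if i not in pooled.index]
        if missing:
            logger.warning("%d transcripts missing from TPM table, set to 0", len(missing))
        pooled = pooled.reindex(ids, fill_value=0.0)
    return pooled


def filter_low_abundance(
    assembly: TranscriptomeAnnotation,
    expr,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[TranscriptomeAnnotation, FilterReport]:
    """Drop transcripts with pooled TPM below the locus-fraction threshold.

    Single pass: locus totals are computed once from the input annotation
    and not re-derived after removals.  A zero-TPM locus keeps everything
    (nothing is strictly below 5% of zero).
    """
    tpm = pooled_tpm(expr, assembly.transcript_ids)
    removed: dict[str, str] = {}
    for locus in assembly.loci:
        total = float(sum(tpm[t.transcript_id] for t in locus.transcripts))
        cutoff = config.locus_fraction * total
        for t in locus.transcripts:
            if float(tpm[t.transcript_id]) < cutoff:
                removed[t.transcript_id] = (
                    f"tpm {tpm[t.transcript_id]:.4g} < {config.locus_fraction:.0%}"
                    f" of locus total {total:.4g}"
                )
    return _finish("low_abundance", assembly, removed, f"{assembly.name}_f2")


# ---------------------------------------------------------------------------
# stage 3: ORF / evidence support
# ---------------------------------------------------------------------------

def filter_evidence(
    assembly: TranscriptomeAnnotation,
    orf_calls: Mapping[str, bool],
    evidence: Sequence[TranscriptomeAnnotation],
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[TranscriptomeAnnotation, FilterReport]:
    """Keep transcripts with an ORF or exonic-overlap support from evidence.

    Support means a class code in ``config.effective_support_codes``
    (default {=, j, o, x, c}) against at least one evidence annotation.
    Transcripts absent from ``orf_calls`` are treated as ORF-less.
    """
    missing = [t for t in assembly.transcript_ids if t not in orf_calls]
    if missing:
        logger.warning("%d transcripts missing from ORF table, treated as no-ORF", len(missing))
    indexes = [ReferenceIndex(ev) for ev in evidence]
    support = set(config.effective_support_codes)
    removed: dict[str, str] = {}
    for t in assembly.transcripts():
        if orf_calls.get(t.transcript_id, False):
            continue
        supported = False
        for index in indexes:
            code, _ = classify_transcript(t, index, config)
            if code in support:
                supported = True
                break
        if not supported:
            removed[t.transcript_id] = "no ORF, no evidence overlap"
    return _finish("evidence", assembly, removed, f"{assembly.name}_f3")


# ---------------------------------------------------------------------------
# stage 4: erroneous transcripts
# ---------------------------------------------------------------------------

def filter_erroneous(
    assembly: TranscriptomeAnnotation,
    mito_contigs: Iterable[str] | None = None,
    min_length: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[TranscriptomeAnnotation, FilterReport]:
    """Drop mitochondrial-contig transcripts and transcripts < min_length bp."""
    mito = set(mito_contigs if mito_contigs is not None else config.mito_contigs)
    cutoff = min_length if min_length is not None else config.min_length
    removed: dict[str, str] = {}
    for t in assembly.transcripts():
        if t.contig in mito:
            removed[t.transcript_id] = "mitochondrial contig"
        elif t.length < cutoff:
            removed[t.transcript_id] = f"short transcript ({t.length} bp < {cutoff})"
    return _finish("erroneous", assembly, removed, f"{assembly.name}_f4")


# ---------------------------------------------------------------------------
# merge with deduplication
# ---------------------------------------------------------------------------

def merge_dedup(
    primary: TranscriptomeAnnotation,
    others: Sequence[TranscriptomeAnnotation],
    name: str | None = None,
) -> TranscriptomeAnnotation:
    """Union of annotations with redundant transcripts removed.

    Multi-exon transcripts sharing an identical intron-chain key collapse to
    the longest representative (the primary annotation wins ties); a
    single-exon transcript contained within another strand-compatible
    single-exon transcript is dropped in favour of the longer one.
    """
    pool: list[tuple[int, TranscriptModel]] = [(0, t) for t in primary.transcripts()]
    for rank, ann in enumerate(others, start=1):
        pool.extend((rank, t) for t in ann.transcripts())

    survivors: list[TranscriptModel] = []
    by_chain: dict[object, tuple[int, TranscriptModel]] = {}
    for rank, t in pool:
        if not t.is_multi_exon:
            continue
        key = t.chain_key()
        held = by_chain.get(key)
        if held is None or _merge_priority(rank, t) > _merge_priority(*held):
            by_chain[key] = (rank, t)
    survivors.extend(t for _, t in by_chain.values())

    singles = sorted(
        ((rank, t) for rank, t in pool if not t.is_multi_exon),
        key=lambda rt: (-rt[1].length, rt[0], rt[1].transcript_id),
    )
    kept_singles: list[TranscriptModel] = []
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for rank, t in singles:
        tree = trees.setdefault(t.contig, IntervalTree())
        contained = any(
            hit.begin <= t.start and t.end <= hit.end
            and strands_compatible(t.strand, hit.data)
            for hit in tree.overlap(t.start, t.end)
        )
        if contained:
            continue
        tree[t.start : t.end] = t.strand
        kept_singles.append(t)
    survivors.extend(kept_singles)

    seen: dict[str, int] = {}
    unique: list[TranscriptModel] = []
    for t in sorted(survivors, key=lambda t: (t.contig, t.start, t.end, t.transcript_id)):
        if t.transcript_id in seen:
            n = seen[t.transcript_id] = seen[t.transcript_id] + 1
            t = TranscriptModel(
                transcript_id=f"{t.transcript_id}.dup{n}",
                gene_id=t.gene_id,
                contig=t.contig,
                strand=t.strand,
                exons=t.exons,
                attributes=dict(t.attributes),
            )
        else:
            seen[t.transcript_id] = 0
        unique.append(t)
    return TranscriptomeAnnotation.from_transcripts(name or f"{primary.name}_merged", unique)


def _merge_priority(rank: int, t: TranscriptModel) -> tuple:
    # longer wins; then lower annotation rank (primary first); then stable id
    return (t.length, -rank, _rev(t.transcript_id))


class _rev(str):
    def __lt__(self, other):  # type: ignore[override]
        return str(self) > str(other)


# ---------------------------------------------------------------------------
# cascade driver and summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    stages: dict[str, TranscriptomeAnnotation]  # initial, filtered1..4, merged?
    reports: list[FilterReport]

    @property
    def refined(self) -> TranscriptomeAnnotation:
        return self.stages["filtered4"]

    def summary(self) -> pd.DataFrame:
        rows = [summarize(ann, label) for label, ann in self.stages.items()]
        return pd.DataFrame(rows).set_index("version")


def run_cascade(
    assembly: TranscriptomeAnnotation,
    expr,
    orf_calls: Mapping[str, bool],
    evidence: Sequence[TranscriptomeAnnotation],
    config: RunConfig = DEFAULT_CONFIG,
    merge_refs: Sequence[TranscriptomeAnnotation] | None = None,
) -> CascadeResult:
    """Apply the four filters in order; optionally add the merged version."""
    stages = {"initial": assembly}
    reports: list[FilterReport] = []
    f1, r1 = filter_pre_mrna(assembly, config)
    stages["filtered1"] = f1
    reports.append(r1)
    f2, r2 = filter_low_abundance(f1, expr, config)
    stages["filtered2"] = f2
    reports.append(r2)
    f3, r3 = filter_evidence(f2, orf_calls, evidence, config)
    stages["filtered3"] = f3
    reports.append(r3)
    f4, r4 = filter_erroneous(f3, config=config)
    stages["filtered4"] = f4
    reports.append(r4)
    if merge_refs:
        stages["merged"] = merge_dedup(f4, merge_refs)
    return CascadeResult(stages=stages, reports=reports)


def n50(lengths: Sequence[int]) -> int:
    """Classic N50 of a length distribution (0 for empty input)."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for ln in ordered:
        running += ln
        if running >= half:
            return ln
    return ordered[-1]


def summarize(annotation: TranscriptomeAnnotation, label: str | None = None) -> dict:
    """Assembly summary in RNA space: genes, transcripts, N50, size, mean length."""
    lengths = [t.length for t in annotation.transcripts()]
    return {
        "version": label or annotation.name,
        "genes": annotation.n_loci,
        "transcripts": len(lengths),
        "n50": n50(lengths),
        "total_bp": sum(lengths),
        "mean_length": round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
    }


def percent_reduction(before: int, after: int) -> float:
    """Percent decrease from ``before`` to ``after`` (e.g. gene inflation)."""
    if before <= 0:
        raise ValueError("before must be positive")
    return 100.0 * (before - after) / before
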