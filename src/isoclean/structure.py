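"""UTR-extension accounting and novel-transcript categorisation.

UTR change is measured indirectly: a coding multi-exon query transcript
whose intron chain exactly matches a reference transcript has, by
construction, the same internal structure, so any difference in summed exon
length is terminal (UTR) sequence.  Novel transcripts — code ``u`` against
at least one of the two primary public annotations — are triaged by the
strength of their supporting evidence into categories I (supported by some
other same-species annotation), II (supported only by cross-species or ab
initio gene models), III (no support but an ORF) and an excluded bucket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .compare import ReferenceIndex, classify_transcript
from .config import DEFAULT_CONFIG, RunConfig
from .models import TranscriptModel, TranscriptomeAnnotation, strands_compatible

CATEGORIES = ("I", "II", "III", "excluded")


# ---------------------------------------------------------------------------
# UTR extension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtrDeltaRecord:
    query_id: str
    reference_id: str
    delta: int  # query summed exon length - reference summed exon length
    direction: str  # extended / reduced / unchanged

    def __post_init__(self) -> None:
        expect = "extended" if self.delta > 0 else "reduced" if self.delta < 0 else "unchanged"
        assert self.direction == expect


def utr_extension(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    coding: Mapping[str, bool],
) -> tuple[list[UtrDeltaRecord], pd.DataFrame]:
    """Length deltas for coding query transcripts chain-matched to the reference.

    One record per coding multi-exon query transcript whose intron chain
    exactly matches at least one reference transcript; when several
    reference transcripts share the chain the longest is used (ties by id),
    giving the most conservative extension estimate.  The summary frame has
    one row per direction with isoform/gene counts, total bp moved and the
    mean per-isoform change.
    """
    index = ReferenceIndex(reference)
    records: list[UtrDeltaRecord] = []
    for t in query.transcripts():
        if not t.is_multi_exon or not coding.get(t.transcript_id, False):
            continue
        partners = index.exact_chain_matches(t)
        if not partners:
            continue
        best = max(
            (reference[p] for p in partners), key=lambda r: (r.length, r.transcript_id)
        )
        delta = t.length - best.length
        direction = "extended" if delta > 0 else "reduced" if delta < 0 else "unchanged"
        records.append(
            UtrDeltaRecord(
                query_id=t.transcript_id,
                reference_id=best.transcript_id,
                delta=delta,
                direction=direction,
            )
        )
    rows = []
    for direction in ("extended", "reduced", "unchanged"):
        sub = [r for r in records if r.direction == direction]
        genes = {query.locus_of(r.query_id) for r in sub}
        total = sum(abs(r.delta) for r in sub)
        rows.append(
            {
                "direction": direction,
                "isoforms": len(sub),
                "genes": len(genes),
                "total_bp": total,
                "mean_bp": round(total / len(sub), 1) if sub else 0.0,
            }
        )
    return records, pd.DataFrame(rows).set_index("direction")


# ---------------------------------------------------------------------------
# novel-transcript categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NovelCategory:
    category: str  # I / II / III / excluded
    support: frozenset[str]  # names of supporting annotations

    def __post_init__(self) -> None:
        assert self.category in CATEGORIES


def classify_novel(
    refined: TranscriptomeAnnotation,
    equine_refs: Mapping[str, TranscriptomeAnnotation],
    nonhorse_evidence: Mapping[str, TranscriptomeAnnotation] | Sequence[TranscriptomeAnnotation],
    orf_calls: Mapping[str, bool],
    config: RunConfig = DEFAULT_CONFIG,
    primary: tuple[str, str] | None = None,
) -> dict[str, NovelCategory]:
    """Categorise novel transcripts by supporting evidence.

    A transcript is *novel* when its class code is ``u`` against at least
    one of the two primary same-species annotations (by default the first
    two entries of ``equine_refs``).  Categories:

    - I:   exonic-overlap support (codes {=, j, o, x, c}) from any
           same-species annotation;
    - II:  ``u`` against every same-species annotation but supported by a
           cross-species / ab initio evidence track;
    - III: ``u`` against every same-species annotation, no support at all,
           but an ORF;
    - excluded: every remaining novel transcript (in particular those with
           neither ORF nor support).

    Non-novel transcripts do not appear in the result.
    """
    if len(equine_refs) < 2:
        raise ValueError("need at least two same-species reference annotations")
    if primary is None:
        primary = tuple(list(equine_refs)[:2])  # type: ignore[assignment]
    if isinstance(nonhorse_evidence, Mapping):
        evidence_items = list(nonhorse_evidence.items())
    else:
        evidence_items = [(ann.name, ann) for ann in nonhorse_evidence]
    support_set = set(config.support_codes)

    equine_index = {name: ReferenceIndex(ann) for name, ann in equine_refs.items()}
    evidence_index = [(name, ReferenceIndex(ann)) for name, ann in evidence_items]

    out: dict[str, NovelCategory] = {}
    for t in refined.transcripts():
        codes = {
            name: classify_transcript(t, idx, config)[0]
            for name, idx in equine_index.items()
        }
        if not any(codes[p] == "u" for p in primary):
            continue
        equine_support = frozenset(n for n, c in codes.items() if c in support_set)
        u_vs_all = all(c == "u" for c in codes.values())
        if equine_support:
            out[t.transcript_id] = NovelCategory("I", equine_support)
            continue
        nonhorse_support = frozenset(
            name
            for name, idx in evidence_index
            if classify_transcript(t, idx, config)[0] in support_set
        )
        if u_vs_all and nonhorse_support:
            out[t.transcript_id] = NovelCategory("II", nonhorse_support)
        elif u_vs_all and not nonhorse_support and orf_calls.get(t.transcript_id, False):
            out[t.transcript_id] = NovelCategory("III", frozenset())
        else:
            out[t.transcript_id] = NovelCategory("excluded", nonhorse_support)
    return out


def novel_summary(
    categories: Mapping[str, NovelCategory],
    annotation: TranscriptomeAnnotation,
    tissue_tpm: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-category transcript counts, exon-count histograms and tissue TPM.

    ``tissue_tpm`` is an optional transcript x tissue TPM frame; cumulative
    expression is summed over the transcripts of each category.
    """
    counts = pd.DataFrame(
        [
            {
                "category": cat,
                "transcripts": sum(1 for c in categories.values() if c.category == cat),
            }
            for cat in CATEGORIES
        ]
    ).set_index("category")

    hist_rows = []
    for tid, cat in categories.items():
        if tid in annotation:
            hist_rows.append({"category": cat.category, "n_exons": annotation[tid].n_exons})
    if hist_rows:
        hist = (
            pd.DataFrame(hist_rows)
            .groupby(["category", "n_exons"])
            .size()
            .rename("transcripts")
            .reset_index()
        )
    else:
        hist = pd.DataFrame(columns=["category", "n_exons", "transcripts"])

    out = {"counts": counts, "exon_histogram": hist}
    if tissue_tpm is not None:
        rows = []
        for cat in CATEGORIES:
            tids = [
                tid
                for tid, c in categories.items()
                if c.category == cat and tid in tissue_tpm.index
            ]
            sums = tissue_tpm.loc[tids].sum(axis=0) if tids else tissue_tpm.iloc[0:0].sum(axis=0)
            row = {"category": cat}
            row.update({tissue: float(v) for tissue, v in sums.items()})
            rows.append(row)
        out["tissue_tpm"] = pd.DataFrame(rows).set_index("category")
    return out
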