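"""Pairwise transcript classification and annotation comparison statistics.

Each query transcript is assigned a one-character class code describing its
strongest relationship to a reference annotation:

``=``  identical intron chain (terminal exon boundaries ignored); for
       single-exon pairs, reciprocal exonic overlap above a threshold
``c``  contained: the query's intron chain is a contiguous sub-chain of a
       reference chain and the query lies within the reference span
``j``  at least one shared splice junction, but not ``=``/``c``
``e``  single-exon query overlapping a reference exon and intruding into a
       reference intron (pre-mRNA-like fragment)
``o``  any other same-strand exonic overlap
``i``  query entirely inside a reference intron, no exonic overlap
``x``  exonic overlap only with opposite-strand references
``u``  no exonic overlap with any reference transcript on either strand

When several reference transcripts yield different codes the most
informative one wins, with precedence ``= > c > j > e > o > i > x > u``.

The module also computes the derived comparison statistics: matching /
similar / novel tallies, complex loci, and Burset–Guigó-style sensitivity
and specificity at the base, intron and locus levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .config import DEFAULT_CONFIG, RunConfig
from .models import (
    Locus,
    TranscriptModel,
    TranscriptomeAnnotation,
    UNKNOWN_STRAND,
    strands_compatible,
)

CLASS_CODES = ("=", "c", "j", "e", "o", "i", "x", "u")
_PRECEDENCE = {code: rank for rank, code in enumerate(CLASS_CODES)}


# ---------------------------------------------------------------------------
# interval-set arithmetic (for exonic overlap and base-level Sn/Sp)
# ---------------------------------------------------------------------------

def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged

def _intersect_len(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total

def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Shared exonic bases between two transcripts (0 if different contigs)."""
    if a.contig != b.contig:
        return 0
    return _intersect_len(a.exon_spans, b.exon_spans)


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------

def _is_contiguous_subchain(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    n, m = len(sub), len(chain)
    if n > m:
        return False
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def classify_pair(
    q: TranscriptModel, r: TranscriptModel, config: RunConfig = DEFAULT_CONFIG
) -> str | None:
    """Class code of query ``q`` relative to the single reference ``r``.

    Returns ``None`` when the pair has no classifiable relationship (the
    caller then falls through to ``u`` once all references are exhausted).
    """
    if q.contig != r.contig:
        return None
    overlap = exonic_overlap_bp(q, r)
    compatible = strands_compatible(q.strand, r.strand)
    if compatible:
        if q.is_multi_exon and r.is_multi_exon:
            if q.introns == r.introns:
                return "="
            if (
                _is_contiguous_subchain(q.introns, r.introns)
                and q.start >= r.start
                and q.end <= r.end
            ):
                return "c"
            if set(q.introns) & set(r.introns):
                return "j"
        elif not q.is_multi_exon and not r.is_multi_exon and overlap > 0:
            f = config.single_exon_match_frac
            if overlap >= f * q.length and overlap >= f * r.length:
                return "="
        if not q.is_multi_exon and r.is_multi_exon and overlap > 0:
            for ds, de in r.introns:
                lo, hi = max(q.start, ds), min(q.end, de)
                if hi - lo >= config.e_intrusion_bp:
                    return "e"
        if overlap > 0:
            return "o"
        # fully intronic, no exonic overlap
        for ds, de in r.introns:
            if q.start >= ds and q.end <= de:
                return "i"
        return None
    # opposite, both strands known
    if overlap > 0:
        return "x"
    return None


class ReferenceIndex:
    """Interval/junction/chain indexes over a reference annotation."""

    def __init__(self, reference: TranscriptomeAnnotation) -> None:
        self.reference = reference
        self.exon_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        self.chains: dict[tuple[str, tuple[tuple[int, int], ...]], list[str]] = {}
        for t in reference.transcripts():
            etree = self.exon_trees.setdefault(t.contig, IntervalTree())
            for s, e in t.exon_spans:
                etree[s:e] = t.transcript_id
            stree = self.span_trees.setdefault(t.contig, IntervalTree())
            stree[t.start : t.end] = t.transcript_id
            if t.is_multi_exon:
                self.chains.setdefault((t.contig, t.introns), []).append(
                    t.transcript_id
                )

    def candidates(self, q: TranscriptModel) -> set[str]:
        """Reference transcripts whose span overlaps the query span."""
        tree = self.span_trees.get(q.contig)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(q.start, q.end)}

    def exact_chain_matches(self, q: TranscriptModel) -> list[str]:
        """References sharing the query's full intron chain (strand-compatible)."""
        if not q.is_multi_exon:
            return []
        out = []
        for tid in self.chains.get((q.contig, q.introns), []):
            if strands_compatible(q.strand, self.reference[tid].strand):
                out.append(tid)
        return out


def classify_transcript(
    q: TranscriptModel,
    reference: TranscriptomeAnnotation | ReferenceIndex,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[str, str | None]:
    """Best class code of ``q`` over all reference transcripts.

    Returns ``(code, best_reference_transcript_id)``; the best reference is
    the transcript achieving the winning code, ties broken by longest
    reference then lexicographic id.  An empty reference yields ``("u",
    None)``.
    """
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference)
    )
    ref = index.reference
    best_code: str | None = None
    best_ref: TranscriptModel | None = None
    for tid in index.candidates(q):
        r = ref[tid]
        code = classify_pair(q, r, config)
        if code is None:
            continue
        if (
            best_code is None
            or _PRECEDENCE[code] < _PRECEDENCE[best_code]
            or (
                code == best_code
                and (r.length, _neg_id(r)) > (best_ref.length, _neg_id(best_ref))
            )
        ):
            best_code, best_ref = code, r
    if best_code is None:
        return "u", None
    return best_code, best_ref.transcript_id


class _neg_id(str):
    """Reversed lexicographic ordering helper: larger means earlier id."""

    def __new__(cls, t: TranscriptModel):
        return super().__new__(cls, t.transcript_id)

    def __lt__(self, other):  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other):  # type: ignore[override]
        return str(self) < str(other)


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    query_name: str
    reference_name: str
    codes: dict[str, tuple[str, str | None]]  # transcript_id -> (code, best ref id)
    tallies: dict[str, int]  # matching / similar / novel / other
    complex_loci: dict[str, int]  # direction ("query"/"reference") -> count
    sensitivity_specificity: dict[str, tuple[float, float]]  # level -> (Sn, Sp)

    def code_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for code, _ in self.codes.values():
            counts[code] = counts.get(code, 0) + 1
        return counts


def classify_all(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, tuple[str, str | None]]:
    index = ReferenceIndex(reference)
    return {
        t.transcript_id: classify_transcript(t, index, config)
        for t in query.transcripts()
    }


def compare(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    config: RunConfig = DEFAULT_CONFIG,
) -> ComparisonReport:
    """Full comparison: class codes, tallies, complex loci, Sn/Sp."""
    codes = classify_all(query, reference, config)
    tallies = {"matching": 0, "similar": 0, "novel": 0, "other": 0}
    for code, _ in codes.values():
        if code == "=":
            tallies["matching"] += 1
        elif code == "j":
            tallies["similar"] += 1
        elif code == "u":
            tallies["novel"] += 1
        else:
            tallies["other"] += 1
    n_q, _ = complex_loci(query, reference)
    n_r, _ = complex_loci(reference, query)
    snsp = sensitivity_specificity(query, reference, config)
    return ComparisonReport(
        query_name=query.name,
        reference_name=reference.name,
        codes=codes,
        tallies=tallies,
        complex_loci={"query": n_q, "reference": n_r},
        sensitivity_specificity=snsp,
    )


# ---------------------------------------------------------------------------
# complex loci
# ---------------------------------------------------------------------------

def complex_loci(
    a: TranscriptomeAnnotation, b: TranscriptomeAnnotation
) -> tuple[int, list[tuple[str, tuple[str, ...]]]]:
    """Loci of ``a`` whose exons overlap two or more distinct loci of ``b``.

    Overlap is exonic (>= 1 bp) and strand-compatible.  Returns the count of
    flagged a-loci and the (a_locus, sorted b_loci) pairs.
    """
    trees: dict[str, IntervalTree] = {}
    for locus in b.loci:
        for t in locus.transcripts:
            tree = trees.setdefault(t.contig, IntervalTree())
            for s, e in t.exon_spans:
                tree[s:e] = (locus.locus_id, t.strand)
    flagged = []
    for locus in a.loci:
        partners: set[str] = set()
        tree = trees.get(locus.contig)
        if tree is None:
            continue
        for t in locus.transcripts:
            for s, e in t.exon_spans:
                for hit in tree.overlap(s, e):
                    b_locus, b_strand = hit.data
                    if strands_compatible(t.strand, b_strand):
                        partners.add(b_locus)
        if len(partners) >= 2:
            flagged.append((locus.locus_id, tuple(sorted(partners))))
    return len(flagged), flagged


# ---------------------------------------------------------------------------
# sensitivity / specificity (base, intron, locus)
# ---------------------------------------------------------------------------

def _stranded_exon_union(
    ann: TranscriptomeAnnotation, strand: str
) -> dict[str, list[tuple[int, int]]]:
    """Per-contig exon union of transcripts compatible with ``strand``."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in ann.transcripts():
        if strands_compatible(t.strand, strand):
            spans.setdefault(t.contig, []).extend(t.exon_spans)
    return {contig: merge_intervals(s) for contig, s in spans.items()}


def _total_len(unions: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for spans in unions.values() for s, e in spans)


def _ratio(tp: int, denom: int) -> float:
    return tp / denom if denom else 1.0


def _base_level(
    query: TranscriptomeAnnotation, reference: TranscriptomeAnnotation
) -> tuple[float, float]:
    tp = q_total = r_total = 0
    for strand in ("+", "-"):
        qu = _stranded_exon_union(query, strand)
        ru = _stranded_exon_union(reference, strand)
        q_total += _total_len(qu)
        r_total += _total_len(ru)
        for contig, q_spans in qu.items():
            tp += _intersect_len(q_spans, ru.get(contig, []))
    return _ratio(tp, r_total), _ratio(tp, q_total)


def _intron_units(ann: TranscriptomeAnnotation) -> set[tuple[str, str, int, int]]:
    return {
        (t.contig, t.strand, d, a)
        for t in ann.transcripts()
        if t.is_multi_exon
        for d, a in t.introns
    }


def _intron_level(
    query: TranscriptomeAnnotation, reference: TranscriptomeAnnotation
) -> tuple[float, float]:
    q_units = _intron_units(query)
    r_units = _intron_units(reference)

    def matched(units, against):
        by_coord: dict[tuple[str, int, int], set[str]] = {}
        for contig, strand, d, a in against:
            by_coord.setdefault((contig, d, a), set()).add(strand)
        n = 0
        for contig, strand, d, a in units:
            strands = by_coord.get((contig, d, a), ())
            if any(strands_compatible(strand, s) for s in strands):
                n += 1
        return n

    return _ratio(matched(r_units, q_units), len(r_units)), _ratio(
        matched(q_units, r_units), len(q_units)
    )


def _locus_level(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    config: RunConfig,
) -> tuple[float, float]:
    """Locus-level Sn/Sp: a locus scores when it holds an exact ("=") match.

    A reference locus is a true positive if any of its transcripts is the
    ``=`` partner of some query transcript; a query locus counts toward
    specificity if it contains a transcript with an ``=`` partner.
    """
    ref_index = ReferenceIndex(reference)
    matched_ref: set[str] = set()
    matched_query: set[str] = set()
    for t in query.transcripts():
        partners = _equal_partners(t, ref_index, config)
        if partners:
            matched_query.add(query.locus_of(t.transcript_id))
            for tid in partners:
                matched_ref.add(reference.locus_of(tid))
    return _ratio(len(matched_ref), reference.n_loci), _ratio(
        len(matched_query), query.n_loci
    )


def _equal_partners(
    q: TranscriptModel, index: ReferenceIndex, config: RunConfig
) -> list[str]:
    """All reference transcripts related to ``q`` by code ``=``."""
    if q.is_multi_exon:
        return index.exact_chain_matches(q)
    out = []
    for tid in index.candidates(q):
        r = index.reference[tid]
        if not r.is_multi_exon and classify_pair(q, r, config) == "=":
            out.append(tid)
    return out


def sensitivity_specificity(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, tuple[float, float]]:
    """(Sn, Sp) at base, intron and locus level.

    Sn = TP/(TP+FN) against the reference, Sp = TP/(TP+FP) against the
    query.  Base level counts deduplicated exonic bases per strand (unknown
    strand matches either); intron level counts distinct (contig, strand,
    donor, acceptor) units; locus level requires an exact-match transcript.
    """
    return {
        "base": _base_level(query, reference),
        "intron": _intron_level(query, reference),
        "locus": _locus_level(query, reference, config),
    }
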