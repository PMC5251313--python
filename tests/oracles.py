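"""Brute-force reference implementations used as test oracles.

Everything here works by literal enumeration — per-base position sets,
all-pairs scans, naive sub-chain search — and shares no code with the
package's indexed implementations.
"""

from __future__ import annotations

from itertools import combinations

from isoclean.config import RunConfig
from isoclean.models import TranscriptModel, TranscriptomeAnnotation

PRECEDENCE = ["=", "c", "j", "e", "o", "i", "x", "u"]


def compat(a: str, b: str) -> bool:
    return a == b or "." in (a, b)


_BASE_CACHE: dict[int, tuple[TranscriptModel, set]] = {}


def base_set(t: TranscriptModel) -> set[tuple[str, int]]:
    hit = _BASE_CACHE.get(id(t))
    if hit is not None and hit[0] is t:
        return hit[1]
    bases = {(t.contig, p) for s, e in t.exon_spans for p in range(s, e)}
    _BASE_CACHE[id(t)] = (t, bases)
    return bases


# ---------------------------------------------------------------------------
# locus partition
# ---------------------------------------------------------------------------

def oracle_loci(transcripts) -> set[frozenset[str]]:
    """Connected components of the all-pairs exon-overlap graph."""
    transcripts = list(transcripts)
    bases = {t.transcript_id: base_set(t) for t in transcripts}
    parent = {t.transcript_id: t.transcript_id for t in transcripts}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in combinations(transcripts, 2):
        if compat(a.strand, b.strand) and bases[a.transcript_id] & bases[b.transcript_id]:
            parent[find(a.transcript_id)] = find(b.transcript_id)
    groups: dict[str, set[str]] = {}
    for t in transcripts:
        groups.setdefault(find(t.transcript_id), set()).add(t.transcript_id)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------

def oracle_pair_code(q: TranscriptModel, r: TranscriptModel, config: RunConfig) -> str | None:
    """Literal application of the class-code definitions to one pair."""
    overlap = len(base_set(q) & base_set(r))
    if not compat(q.strand, r.strand):
        return "x" if overlap > 0 else None
    if q.contig != r.contig:
        return None
    qi, ri = list(q.introns), list(r.introns)
    if qi and ri and qi == ri:
        return "="
    if not qi and not ri and overlap > 0:
        f = config.single_exon_match_frac
        if overlap >= f * q.length and overlap >= f * r.length:
            return "="
    if qi and ri:
        is_sub = any(ri[k : k + len(qi)] == qi for k in range(len(ri) - len(qi) + 1))
        if is_sub and q.start >= r.start and q.end <= r.end:
            return "c"
        if set(qi) & set(ri):
            return "j"
    if not qi and ri and overlap > 0:
        for d, a in ri:
            intrusion = len({p for p in range(q.start, q.end)} & set(range(d, a)))
            if intrusion >= config.e_intrusion_bp:
                return "e"
    if overlap > 0:
        return "o"
    for d, a in ri:
        if d <= q.start and q.end <= a:
            return "i"
    return None


def oracle_classify(
    q: TranscriptModel, reference: TranscriptomeAnnotation, config: RunConfig
) -> tuple[str, str | None]:
    best = None  # (precedence rank, -length, id, tid)
    for r in reference.transcripts():
        code = oracle_pair_code(q, r, config)
        if code is None:
            continue
        key = (PRECEDENCE.index(code), -r.length, r.transcript_id)
        if best is None or key < best[0]:
            best = (key, code, r.transcript_id)
    if best is None:
        return "u", None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# complex loci
# ---------------------------------------------------------------------------

def oracle_complex(a: TranscriptomeAnnotation, b: TranscriptomeAnnotation) -> int:
    count = 0
    for la in a.loci:
        partners = set()
        for ta in la.transcripts:
            for lb in b.loci:
                for tb in lb.transcripts:
                    if compat(ta.strand, tb.strand) and base_set(ta) & base_set(tb):
                        partners.add(lb.locus_id)
        if len(partners) >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# sensitivity / specificity
# ---------------------------------------------------------------------------

def _strand_bases(ann: TranscriptomeAnnotation, strand: str) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for t in ann.transcripts():
        if compat(t.strand, strand):
            out |= base_set(t)
    return out


def oracle_snsp(
    query: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    config: RunConfig,
) -> dict[str, tuple[float, float]]:
    def ratio(tp, denom):
        return tp / denom if denom else 1.0

    tp = qt = rt = 0
    for strand in ("+", "-"):
        qb = _strand_bases(query, strand)
        rb = _strand_bases(reference, strand)
        tp += len(qb & rb)
        qt += len(qb)
        rt += len(rb)
    base = (ratio(tp, rt), ratio(tp, qt))

    q_introns = {
        (t.contig, t.strand, d, a) for t in query.transcripts() for d, a in t.introns
    }
    r_introns = {
        (t.contig, t.strand, d, a) for t in reference.transcripts() for d, a in t.introns
    }

    def n_matched(units, others):
        return sum(
            1
            for (c, s, d, a) in units
            if any(c == c2 and d == d2 and a == a2 and compat(s, s2)
                   for (c2, s2, d2, a2) in others)
        )

    intron = (
        ratio(n_matched(r_introns, q_introns), len(r_introns)),
        ratio(n_matched(q_introns, r_introns), len(q_introns)),
    )

    matched_ref_loci, matched_query_loci = set(), set()
    for tq in query.transcripts():
        for tr in reference.transcripts():
            if oracle_pair_code(tq, tr, config) == "=":
                matched_ref_loci.add(reference.locus_of(tr.transcript_id))
                matched_query_loci.add(query.locus_of(tq.transcript_id))
    locus = (
        ratio(len(matched_ref_loci), reference.n_loci),
        ratio(len(matched_query_loci), query.n_loci),
    )
    return {"base": base, "intron": intron, "locus": locus}
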