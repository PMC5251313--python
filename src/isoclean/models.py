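"""Domain types for transcript annotations.

Internally every coordinate is 0-based half-open; the GTF layer
(:mod:`isoclean.gtf`) converts to and from the 1-based inclusive file
convention.  A *locus* is a single-linkage cluster of exon-overlapping,
strand-compatible transcripts and is the unit used for "gene" counts and
for every per-locus expression-fraction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
#: the GTF symbol used for transcripts of unknown strand
UNKNOWN_STRAND = "."


def strands_compatible(a: str, b: str) -> bool:
    """True when two strand symbols may describe the same molecule.

    Unknown strand (``.``) is compatible with either known strand.
    """
    return a == b or a == UNKNOWN_STRAND or b == UNKNOWN_STRAND


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = UNKNOWN_STRAND

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class IntronChainKey(NamedTuple):
    """Identity of a multi-exon transcript up to its terminal exon boundaries.

    Two multi-exon transcripts share a key iff they have the exact same
    ordered (donor, acceptor) junction coordinates on the same contig and
    strand; terminal exon ends play no part.
    """

    contig: str
    strand: str
    junctions: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, disjoint set of exons on one contig/strand."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.contig != self.contig:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {ex.contig}, "
                    f"transcript on {self.contig}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    # ---- derived geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_spans(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs between consecutive exons; empty if single-exon."""
        return tuple(
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        """Summed exon length in bp (RNA space, not genomic span)."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def chain_key(self) -> IntronChainKey | None:
        """Intron-chain identity; ``None`` for single-exon transcripts."""
        if not self.is_multi_exon:
            return None
        return IntronChainKey(self.contig, self.strand, self.introns)


def transcript_length(t: TranscriptModel) -> int:
    """Summed exon length of a transcript in bp."""
    return t.length


def make_transcript(
    transcript_id: str,
    contig: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    gene_id: str = "",
    attributes: Mapping[str, str] | None = None,
) -> TranscriptModel:
    """Convenience constructor from plain (start, end) pairs (0-based half-open)."""
    ivs = tuple(
        GenomicInterval(contig, s, e, strand) for s, e in sorted(exons)
    )
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id,
        contig=contig,
        strand=strand,
        exons=ivs,
        attributes=dict(attributes or {}),
    )


@dataclass
class Locus:
    """A single-linkage cluster of exon-overlapping transcripts ("gene")."""

    locus_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_loci(transcripts: Sequence[TranscriptModel]) -> list[Locus]:
    """Partition transcripts into loci.

    Two transcripts belong to the same locus when a chain of pairwise
    exonic overlaps (>= 1 bp of shared exonic sequence, strand-compatible)
    connects them.  Unknown-strand transcripts may link to either strand and
    can therefore bridge strands; bridged loci get strand ``.`` and a logged
    warning.  Locus ids are deterministic, ordered by (contig, span start,
    span end).
    """
    if not transcripts:
        return []
    uf = _UnionFind(len(transcripts))
    by_contig: dict[str, list[int]] = {}
    for i, t in enumerate(transcripts):
        by_contig.setdefault(t.contig, []).append(i)
    for contig, idxs in by_contig.items():
        tree = IntervalTree()
        for i in idxs:
            t = transcripts[i]
            for s, e in t.exon_spans:
                tree[s:e] = i
        for i in idxs:
            t = transcripts[i]
            for s, e in t.exon_spans:
                for hit in tree.overlap(s, e):
                    j = hit.data
                    if j != i and strands_compatible(t.strand, transcripts[j].strand):
                        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = sorted(
        groups.values(),
        key=lambda g: (
            transcripts[g[0]].contig,
            min(transcripts[i].start for i in g),
            max(transcripts[i].end for i in g),
            min(transcripts[i].transcript_id for i in g),
        ),
    )
    loci = []
    for n, group in enumerate(clusters, start=1):
        members = sorted(
            (transcripts[i] for i in group), key=lambda t: (t.start, t.end, t.transcript_id)
        )
        known = {t.strand for t in members if t.strand != UNKNOWN_STRAND}
        if len(known) > 1:
            logger.warning(
                "locus on %s:%d spans both strands via unknown-strand transcripts",
                members[0].contig,
                members[0].start,
            )
            strand = UNKNOWN_STRAND
        else:
            strand = known.pop() if known else UNKNOWN_STRAND
        loci.append(
            Locus(
                locus_id=f"LOC{n:06d}",
                contig=members[0].contig,
                strand=strand,
                transcripts=members,
            )
        )
    return loci


@dataclass
class TranscriptomeAnnotation:
    """A named set of transcripts partitioned into loci."""

    name: str
    loci: list[Locus]

    def __post_init__(self) -> None:
        self._by_id: dict[str, TranscriptModel] = {}
        self._locus_of: dict[str, str] = {}
        for locus in self.loci:
            for t in locus.transcripts:
                if t.transcript_id in self._by_id:
                    raise ValueError(f"duplicate transcript_id {t.transcript_id}")
                self._by_id[t.transcript_id] = t
                self._locus_of[t.transcript_id] = locus.locus_id

    @classmethod
    def from_transcripts(
        cls, name: str, transcripts: Sequence[TranscriptModel]
    ) -> "TranscriptomeAnnotation":
        return cls(name=name, loci=build_loci(transcripts))

    # ---- access -----------------------------------------------------------

    def transcripts(self) -> Iterator[TranscriptModel]:
        for locus in self.loci:
            yield from locus.transcripts

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_of(self, transcript_id: str) -> str:
        return self._locus_of[transcript_id]

    def locus(self, locus_id: str) -> Locus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def subset(self, name: str, transcript_ids: Iterable[str]) -> "TranscriptomeAnnotation":
        """New annotation with the given transcripts; loci are rebuilt."""
        wanted = set(transcript_ids)
        kept = [t for t in self.transcripts() if t.transcript_id in wanted]
        return TranscriptomeAnnotation.from_transcripts(name, kept)
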