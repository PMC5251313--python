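"""GTF reading and writing.

The file convention is 1-based inclusive coordinates; everything internal
is 0-based half-open.  Only ``exon`` features are consumed — transcript and
gene rows are recomputed from exon structure on output.  Per-record parsing
(the attribute column in particular) is delegated to :mod:`gffutils`.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Union

from gffutils.feature import feature_from_line

from .models import (
    GenomicInterval,
    TranscriptModel,
    TranscriptomeAnnotation,
    UNKNOWN_STRAND,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class GtfParseError(ValueError):
    """A malformed GTF record, reported with its line number."""


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path: PathLike, name: str | None = None) -> TranscriptomeAnnotation:
    """Read an exon-level GTF into an annotation with recomputed loci.

    Any ``gene_id`` found in the file is preserved on the transcript but is
    not trusted for grouping: locus membership is always recomputed from
    exonic overlap.  Duplicate (transcript_id, exon span) records are
    collapsed with a warning; exons that overlap *within* one transcript
    are an error.
    """
    name = name or Path(path).stem
    exons: dict[str, dict[tuple[int, int], None]] = {}
    meta: dict[str, tuple[str, str, str, dict[str, str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise GtfParseError(
                    f"{path}:{lineno}: exon end {feat.end} < start {feat.start}"
                )
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(f"{path}:{lineno}: exon without transcript_id")
            strand = feat.strand if feat.strand in ("+", "-") else UNKNOWN_STRAND
            span = (feat.start - 1, feat.end)  # to 0-based half-open
            if tid not in meta:
                meta[tid] = (feat.seqid, strand, attrs.get("gene_id", tid), attrs)
                exons[tid] = {}
            else:
                contig, known_strand, _, _ = meta[tid]
                if contig != feat.seqid:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {tid} spans contigs "
                        f"{contig} and {feat.seqid}"
                    )
                if known_strand != strand:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {tid} has inconsistent strand"
                    )
            if span in exons[tid]:
                logger.warning(
                    "%s:%d: duplicate exon %s for transcript %s collapsed",
                    path,
                    lineno,
                    span,
                    tid,
                )
            exons[tid][span] = None
    transcripts = []
    for tid, spans in exons.items():
        contig, strand, gene_id, attrs = meta[tid]
        ordered = sorted(spans)
        ivs = tuple(GenomicInterval(contig, s, e, strand) for s, e in ordered)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=ivs,
                attributes={k: v for k, v in attrs.items() if k not in ("transcript_id",)},
            )
        )
    return TranscriptomeAnnotation.from_transcripts(name, transcripts)


def write_gtf(annotation: TranscriptomeAnnotation, path: PathLike) -> None:
    """Write an annotation as 1-based inclusive GTF (transcript + exon rows).

    ``gene_id`` is the recomputed locus id, so a read/write round trip
    reproduces both coordinates and grouping exactly.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for locus in annotation.loci:
            for t in locus.transcripts:
                attrs = f'gene_id "{locus.locus_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        (
                            t.contig,
                            "isoclean",
                            "transcript",
                            str(t.start + 1),
                            str(t.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )
                for ex in t.exons:
                    fh.write(
                        "\t".join(
                            (
                                t.contig,
                                "isoclean",
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            )
                        )
                        + "\n"
                    )
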