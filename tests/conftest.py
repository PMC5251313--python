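"""Shared fixtures: hand-built annotations and a random-annotation generator.

The random generator mixes independent transcripts with variants derived
from a shared gene pool (terminal jitter, sub-chains, intronic and
exon-edge fragments) so that every class code actually occurs in the
sampled pairs.
"""

from __future__ import annotations

import numpy as np
import pytest

from isoclean.models import TranscriptomeAnnotation, make_transcript
from isoclean.simulate import FixtureSpec, generate


def random_annotation(rng: np.random.Generator, n: int, name: str = "rand",
                      contig: str = "c1") -> TranscriptomeAnnotation:
    transcripts = []
    pool: list[list[tuple[int, int]]] = []
    for i in range(n):
        strand = rng.choice(["+", "-", "."], p=[0.45, 0.45, 0.1])
        if pool and rng.random() < 0.5:
            exons = _variant(rng, pool[int(rng.integers(len(pool)))])
        else:
            exons = _random_exons(rng, int(rng.integers(0, 4000)),
                                  int(rng.integers(1, 5)))
            pool.append(exons)
        transcripts.append(
            make_transcript(f"{name}_t{i:03d}", contig, str(strand), exons)
        )
    return TranscriptomeAnnotation.from_transcripts(name, transcripts)


def _random_exons(rng, start: int, n_exons: int) -> list[tuple[int, int]]:
    exons, pos = [], start
    for _ in range(n_exons):
        length = int(rng.integers(30, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(40, 150))
    return exons


def _variant(rng, base: list[tuple[int, int]]) -> list[tuple[int, int]]:
    kind = rng.integers(0, 4)
    if kind == 0:  # terminal jitter, same chain
        exons = [list(e) for e in base]
        exons[0][0] = max(0, exons[0][0] + int(rng.integers(-60, 60)))
        if exons[0][0] >= exons[0][1]:
            exons[0][0] = exons[0][1] - 10
        exons[-1][1] += int(rng.integers(-min(60, exons[-1][1] - exons[-1][0] - 5), 60))
        return [tuple(e) for e in exons]
    if kind == 1 and len(base) > 1:  # contiguous sub-structure
        i = int(rng.integers(0, len(base) - 1))
        j = int(rng.integers(i + 1, len(base) + 1))
        return [tuple(e) for e in base[i:j]]
    if kind == 2 and len(base) > 1:  # single exon around a junction or intron
        k = int(rng.integers(0, len(base) - 1))
        donor, acceptor = base[k][1], base[k + 1][0]
        if rng.random() < 0.5 and acceptor - donor > 20:  # intronic
            return [(donor + 5, acceptor - 5)]
        return [(base[k][1] - 20, base[k][1] + 25)]  # exon edge, intron intrusion
    shift = max(int(rng.integers(-200, 200)), -base[0][0])  # keep intron spacing
    return [(s + shift, e + shift) for s, e in base]


@pytest.fixture(scope="session")
def fixture_seed1():
    return generate(FixtureSpec(seed=1))


@pytest.fixture
def simple_annotation():
    """Two overlapping + one isolated transcript on one contig."""
    return TranscriptomeAnnotation.from_transcripts(
        "simple",
        [
            make_transcript("tA", "chr1", "+", [(0, 100), (200, 300), (400, 520)]),
            make_transcript("tB", "chr1", "+", [(250, 300), (400, 700)]),
            make_transcript("tC", "chr1", "+", [(5000, 5400)]),
        ],
    )
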