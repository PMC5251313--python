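"""Run configuration: every numeric threshold used by the pipeline.

Defaults reflect the published refinement protocol: a transcript must
carry at least 5% of its locus' TPM to survive abundance filtering (and to
be called present in a tissue), transcripts shorter than 201 bp are
discarded, single-exon transcripts match when they reciprocally overlap by
80%, and a single-exon fragment must intrude at least 10 bp into a
reference intron to be called pre-mRNA-like (code ``e``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_MITO_CONTIGS = ("chrM", "MT")

#: class codes counted as exonic-overlap support for evidence filtering and
#: novelty categories.  The literal published list is {j, o, x, c}; an exact
#: match ("=") is strictly stronger evidence and is included by default.
SUPPORT_CODES = ("=", "j", "o", "x", "c")
LITERAL_SUPPORT_CODES = ("j", "o", "x", "c")


@dataclass(frozen=True)
class RunConfig:
    locus_fraction: float = 0.05
    min_length: int = 201
    single_exon_match_frac: float = 0.80
    e_intrusion_bp: int = 10
    mito_contigs: tuple[str, ...] = DEFAULT_MITO_CONTIGS
    support_codes: tuple[str, ...] = SUPPORT_CODES
    literal_support: bool = False  # drop "=" from evidence-support codes

    def __post_init__(self) -> None:
        if not 0.0 <= self.locus_fraction < 1.0:
            raise ValueError(f"locus_fraction must be in [0, 1): {self.locus_fraction}")
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1: {self.min_length}")
        if not 0.0 < self.single_exon_match_frac <= 1.0:
            raise ValueError(
                f"single_exon_match_frac must be in (0, 1]: {self.single_exon_match_frac}"
            )
        if self.e_intrusion_bp < 1:
            raise ValueError(f"e_intrusion_bp must be >= 1: {self.e_intrusion_bp}")

    @property
    def effective_support_codes(self) -> tuple[str, ...]:
        if self.literal_support:
            return tuple(c for c in self.support_codes if c != "=")
        return self.support_codes

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mito_contigs"] = list(self.mito_contigs)
        d["support_codes"] = list(self.support_codes)
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key in ("mito_contigs", "support_codes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)


DEFAULT_CONFIG = RunConfig()
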