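"""Tissue-level expression profiling.

A transcript is *present* in a tissue when its tissue TPM exceeds 5% of
the total TPM of its locus computed from that tissue alone; per-tissue
TPM is the arithmetic mean over the tissue's libraries (TPM is already
depth-normalised, so summation would weight tissues by library count).
On top of the presence matrix the module derives uniquely-present and
solely-absent isoform sets, the mitochondrial share of transcription, the
per-tissue splicing rate (transcripts per locus), a variable-gene
selection, and two-axis average-linkage hierarchical clustering with
correlation-based dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .config import DEFAULT_CONFIG, RunConfig
from .models import TranscriptomeAnnotation

logger = logging.getLogger(__name__)


class ExpressionTable:
    """Transcript x sample TPM matrix with a sample -> tissue grouping."""

    def __init__(self, tpm: pd.DataFrame, sample_tissue: Mapping[str, str]) -> None:
        if (tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = [s for s in tpm.columns if s not in sample_tissue]
        if missing:
            raise ValueError(f"samples without a tissue assignment: {missing}")
        self.tpm = tpm.astype(float)
        self.sample_tissue = dict(sample_tissue)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.tpm.columns:
            seen.setdefault(self.sample_tissue[s], None)
        return list(seen)

    def tissue_means(self) -> pd.DataFrame:
        """Transcript x tissue TPM: mean over each tissue's sample columns."""
        groups = pd.Series({s: self.sample_tissue[s] for s in self.tpm.columns})
        return self.tpm.T.groupby(groups).mean().T[self.tissues]

    def pooled(self) -> pd.Series:
        return self.tpm.sum(axis=1)

    @classmethod
    def from_files(cls, tpm_path, samples_path) -> "ExpressionTable":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(tpm, samples.iloc[:, 0].to_dict())


# ---------------------------------------------------------------------------
# presence calls and derived sets
# ---------------------------------------------------------------------------

def presence_calls(
    annotation: TranscriptomeAnnotation,
    expr: ExpressionTable,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, set[str]]:
    """Per tissue, the set of present transcript ids.

    Present means tissue TPM strictly greater than ``locus_fraction`` of the
    locus total in that tissue; a zero-total locus has no present
    transcripts.  Transcripts missing from the table count as zero.
    """
    means = expr.tissue_means().reindex(annotation.transcript_ids, fill_value=0.0)
    present: dict[str, set[str]] = {t: set() for t in expr.tissues}
    for tissue in expr.tissues:
        col = means[tissue]
        for locus in annotation.loci:
            tids = [t.transcript_id for t in locus.transcripts]
            total = float(col[tids].sum())
            cutoff = config.locus_fraction * total
            for tid in tids:
                if float(col[tid]) > cutoff:
                    present[tissue].add(tid)
    return present


def unique_presence(
    presence: Mapping[str, set[str]],
    tissues: Sequence[str] | None = None,
    expr: ExpressionTable | None = None,
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, float]]:
    """Uniquely-present and solely-absent isoforms per tissue.

    A transcript is uniquely present in tissue T when T is the only tissue
    calling it present, and solely absent from T when every other tissue
    (but not T) calls it present.  When ``expr`` is given, also returns the
    cumulative tissue TPM of each tissue's uniquely present transcripts.
    """
    tissues = list(tissues if tissues is not None else presence)
    if len(tissues) < 2:
        raise ValueError("unique presence needs at least two tissues")
    uniquely: dict[str, set[str]] = {}
    solely_absent: dict[str, set[str]] = {}
    for tissue in tissues:
        others = [t for t in tissues if t != tissue]
        here = presence[tissue]
        elsewhere = set().union(*(presence[t] for t in others))
        uniquely[tissue] = here - elsewhere
        everywhere_else = set(presence[others[0]])
        for t in others[1:]:
            everywhere_else &= presence[t]
        solely_absent[tissue] = everywhere_else - here
    cum_tpm: dict[str, float] = {}
    if expr is not None:
        means = expr.tissue_means()
        for tissue in tissues:
            tids = [t for t in uniquely[tissue] if t in means.index]
            cum_tpm[tissue] = float(means.loc[tids, tissue].sum()) if tids else 0.0
    return uniquely, solely_absent, cum_tpm


def mito_fraction(
    annotation: TranscriptomeAnnotation,
    expr: ExpressionTable,
    mito_contigs: Iterable[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Fraction of each tissue's TPM carried by mitochondrial-contig transcripts."""
    mito = set(mito_contigs if mito_contigs is not None else config.mito_contigs)
    means = expr.tissue_means().reindex(annotation.transcript_ids, fill_value=0.0)
    mito_ids = [t.transcript_id for t in annotation.transcripts() if t.contig in mito]
    out: dict[str, float] = {}
    for tissue in expr.tissues:
        total = float(means[tissue].sum())
        out[tissue] = float(means.loc[mito_ids, tissue].sum()) / total if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# per-tissue profile and splicing rate
# ---------------------------------------------------------------------------

@dataclass
class TissueProfile:
    tissue: str
    present: set[str]
    genes: int
    transcripts: int
    multi_exon_transcripts: int
    multi_transcript_loci: int
    splicing_rate: float | None
    mito_fraction: float = 0.0


def splicing_rate(n_transcripts: int, n_loci: int) -> float | None:
    """Transcripts per gene locus, reported to one decimal (None if no loci)."""
    if n_loci <= 0:
        return None
    return round(n_transcripts / n_loci, 1)


def tissue_profile(
    annotation: TranscriptomeAnnotation,
    tissue: str,
    present_ids: set[str],
    mito_frac: float = 0.0,
) -> TissueProfile:
    """Counts over the tissue's present-transcript subset with loci rebuilt."""
    sub = annotation.subset(f"{annotation.name}_{tissue}", present_ids)
    n_multi = sum(1 for t in sub.transcripts() if t.is_multi_exon)
    n_multi_loci = sum(1 for locus in sub.loci if locus.n_transcripts > 1)
    return TissueProfile(
        tissue=tissue,
        present=set(present_ids),
        genes=sub.n_loci,
        transcripts=len(sub),
        multi_exon_transcripts=n_multi,
        multi_transcript_loci=n_multi_loci,
        splicing_rate=splicing_rate(len(sub), sub.n_loci),
        mito_fraction=mito_frac,
    )


def tissue_summary(
    annotation: TranscriptomeAnnotation,
    expr: ExpressionTable,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, dict[str, TissueProfile]]:
    """Per-tissue profile table (genes, transcripts, splicing rate, mito load)."""
    presence = presence_calls(annotation, expr, config)
    mito = mito_fraction(annotation, expr, config=config)
    profiles = {
        tissue: tissue_profile(annotation, tissue, present, mito.get(tissue, 0.0))
        for tissue, present in presence.items()
    }
    frame = pd.DataFrame(
        [
            {
                "tissue": p.tissue,
                "genes": p.genes,
                "transcripts": p.transcripts,
                "multi_exon_transcripts": p.multi_exon_transcripts,
                "multi_transcript_loci": p.multi_transcript_loci,
                "splicing_rate": p.splicing_rate,
                "mito_fraction": round(p.mito_fraction, 4),
            }
            for p in profiles.values()
        ]
    ).set_index("tissue")
    return frame, profiles


# ---------------------------------------------------------------------------
# variable genes and clustering
# ---------------------------------------------------------------------------

def gene_level_tpm(
    annotation: TranscriptomeAnnotation, expr: ExpressionTable
) -> pd.DataFrame:
    """Gene (locus) x tissue TPM: sum of member-transcript tissue TPM."""
    means = expr.tissue_means().reindex(annotation.transcript_ids, fill_value=0.0)
    locus_ids = pd.Series(
        {tid: annotation.locus_of(tid) for tid in annotation.transcript_ids}
    )
    return means.groupby(locus_ids).sum()


def select_variable_genes(
    gene_tpm: pd.DataFrame, min_sum: float = 200.0, min_sd: float = 200.0
) -> list[str]:
    """Genes with cross-tissue TPM sum and sample SD both strictly above cutoffs."""
    sums = gene_tpm.sum(axis=1)
    sds = gene_tpm.std(axis=1, ddof=1)
    mask = (sums > min_sum) & (sds > min_sd)
    return list(gene_tpm.index[mask])


@dataclass
class ClusteringResult:
    gene_linkage: np.ndarray
    tissue_linkage: np.ndarray
    gene_order: list[str]
    tissue_order: list[str]
    gene_newick: str
    tissue_newick: str


def _correlation_distance(matrix: np.ndarray, method: str) -> np.ndarray:
    """1 - correlation among rows; undefined (constant-row) pairs get 2.0.

    Spearman is computed as Pearson on per-row average ranks, the standard
    definition, which keeps the output square for any input shape.
    """
    if method == "spearman":
        matrix = rankdata(matrix, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.atleast_2d(np.corrcoef(matrix))
    constant = np.isclose(matrix.std(axis=1), 0.0)
    if constant.any():
        logger.warning("%d constant vectors: correlation undefined, distance set to 2.0",
                       int(constant.sum()))
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    bad = constant[:, None] | constant[None, :]
    dist[bad] = 2.0
    np.fill_diagonal(dist, 0.0)
    # numerical symmetry for squareform
    return (dist + dist.T) / 2.0


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_heatmap(gene_tpm: pd.DataFrame) -> ClusteringResult:
    """Two-axis average-linkage clustering of a gene x tissue matrix.

    Gene distance is 1 - Pearson r across tissues; tissue distance is
    1 - Spearman rho across genes.  Returns linkage matrices, leaf orders
    and Newick renderings of both dendrograms.
    """
    if gene_tpm.shape[0] < 2 or gene_tpm.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 tissues")
    genes = gene_tpm.to_numpy(dtype=float)
    gene_dist = _correlation_distance(genes, "pearson")
    tissue_dist = _correlation_distance(genes.T, "spearman")
    gene_link = hierarchy.linkage(squareform(gene_dist, checks=False), method="average")
    tissue_link = hierarchy.linkage(squareform(tissue_dist, checks=False), method="average")
    gene_order = [gene_tpm.index[i] for i in hierarchy.leaves_list(gene_link)]
    tissue_order = [gene_tpm.columns[i] for i in hierarchy.leaves_list(tissue_link)]
    return ClusteringResult(
        gene_linkage=gene_link,
        tissue_linkage=tissue_link,
        gene_order=gene_order,
        tissue_order=tissue_order,
        gene_newick=_to_newick(gene_link, list(gene_tpm.index)),
        tissue_newick=_to_newick(tissue_link, list(gene_tpm.columns)),
    )
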