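"""Presence calls, unique/absent isoforms, mito load, splicing rate, clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from isoclean.models import TranscriptomeAnnotation, make_transcript
from isoclean.tissues import (
    ExpressionTable,
    cluster_heatmap,
    gene_level_tpm,
    mito_fraction,
    presence_calls,
    select_variable_genes,
    splicing_rate,
    tissue_profile,
    tissue_summary,
    unique_presence,
)


def expr_table(values: dict[str, dict[str, float]], samples_per_tissue=1):
    """Build an ExpressionTable from transcript -> tissue -> TPM."""
    tissues = list(next(iter(values.values())))
    columns, mapping = [], {}
    for tissue in tissues:
        for k in range(samples_per_tissue):
            s = f"{tissue}_s{k}"
            columns.append(s)
            mapping[s] = tissue
    frame = pd.DataFrame(
        {s: {tid: row[mapping[s]] for tid, row in values.items()} for s in columns}
    )
    return ExpressionTable(frame, mapping)


def two_isoform_locus():
    return TranscriptomeAnnotation.from_transcripts(
        "a",
        [
            make_transcript("big", "c", "+", [(0, 100), (200, 300)]),
            make_transcript("small", "c", "+", [(0, 100), (200, 320)]),
        ],
    )


class TestPresence:
    def test_lone_transcript_present(self):
        ann = TranscriptomeAnnotation.from_transcripts(
            "a", [make_transcript("t", "c", "+", [(0, 300)])]
        )
        expr = expr_table({"t": {"T1": 10.0, "T2": 0.0}})
        present = presence_calls(ann, expr)
        assert present == {"T1": {"t"}, "T2": set()}

    def test_boundary_is_strict(self):
        expr = expr_table({"big": {"T": 95.0}, "small": {"T": 5.0}})
        present = presence_calls(two_isoform_locus(), expr)
        assert present["T"] == {"big"}  # 5 > 5 is false

    def test_tissue_mean_over_samples(self):
        frame = pd.DataFrame({"T_s0": {"t": 0.0}, "T_s1": {"t": 20.0}})
        expr = ExpressionTable(frame, {"T_s0": "T", "T_s1": "T"})
        ann = TranscriptomeAnnotation.from_transcripts(
            "a", [make_transcript("t", "c", "+", [(0, 300)])]
        )
        assert presence_calls(ann, expr)["T"] == {"t"}  # mean 10 > 0.5

    def test_presence_monotone_in_tpm(self, fixture_seed1):
        fx = fixture_seed1
        ann = fx.assembly
        present = presence_calls(ann, fx.expr)
        tid = "G000.1"
        boosted = fx.expr.tpm.copy()
        boosted.loc[tid] *= 10
        present2 = presence_calls(ann, ExpressionTable(boosted, fx.expr.sample_tissue))
        for tissue in present:
            if tid in present[tissue]:
                assert tid in present2[tissue]


class TestUniquePresence:
    def test_planted_patterns(self):
        presence = {
            "retina": {"u1", "shared"},
            "brain": {"shared", "a1"},
            "skin": {"shared", "a1"},
        }
        uniq, sole, _ = unique_presence(presence)
        assert uniq["retina"] == {"u1"}
        assert sole["retina"] == {"a1"}
        assert uniq["brain"] == set() and sole["brain"] == set()

    def test_uniquely_present_sets_disjoint(self, fixture_seed1):
        fx = fixture_seed1
        presence = presence_calls(fx.assembly, fx.expr)
        uniq, _, _ = unique_presence(presence)
        tissues = list(uniq)
        for i, a in enumerate(tissues):
            for b in tissues[i + 1 :]:
                assert not uniq[a] & uniq[b]

    def test_cumulative_tpm_of_unique(self):
        expr = expr_table({"u1": {"T1": 30.0, "T2": 0.0}, "c": {"T1": 5.0, "T2": 5.0}})
        presence = {"T1": {"u1", "c"}, "T2": {"c"}}
        _, _, cum = unique_presence(presence, expr=expr)
        assert cum["T1"] == 30.0 and cum["T2"] == 0.0

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            unique_presence({"only": set()})


class TestMitoFraction:
    def test_planted_ratio(self):
        ann = TranscriptomeAnnotation.from_transcripts(
            "a",
            [
                make_transcript("mt", "chrM", "+", [(0, 500)]),
                make_transcript("nuc", "c", "+", [(0, 500)]),
            ],
        )
        expr = expr_table({"mt": {"T": 200.0}, "nuc": {"T": 800.0}})
        assert mito_fraction(ann, expr) == {"T": 0.2}

    def test_no_mito_and_zero_total(self):
        ann = TranscriptomeAnnotation.from_transcripts(
            "a", [make_transcript("nuc", "c", "+", [(0, 500)])]
        )
        assert mito_fraction(ann, expr_table({"nuc": {"T": 10.0}})) == {"T": 0.0}
        assert mito_fraction(ann, expr_table({"nuc": {"T": 0.0}})) == {"T": 0.0}

    def test_fraction_bounds(self, fixture_seed1):
        fx = fixture_seed1
        fracs = mito_fraction(fx.assembly, fx.expr)
        assert all(0.0 <= f <= 1.0 for f in fracs.values())


class TestSplicingRate:
    def test_one_isoform_per_locus_is_one(self):
        assert splicing_rate(10, 10) == 1.0

    def test_zero_loci_undefined(self):
        assert splicing_rate(0, 0) is None

    def test_profile_counts(self):
        ann = two_isoform_locus()
        profile = tissue_profile(ann, "T", {"big", "small"})
        assert profile.genes == 1 and profile.transcripts == 2
        assert profile.multi_exon_transcripts == 2
        assert profile.multi_transcript_loci == 1
        assert profile.splicing_rate == 2.0

    def test_summary_frame(self, fixture_seed1):
        fx = fixture_seed1
        frame, profiles = tissue_summary(fx.assembly, fx.expr)
        assert set(frame.index) == set(fx.expr.tissues)
        assert (frame["splicing_rate"] >= 1.0).all()


class TestVariableGenes:
    def test_flat_expression_excluded(self):
        tpm = pd.DataFrame([[100.0] * 8], index=["flat"])
        assert select_variable_genes(tpm) == []

    def test_single_tissue_spike_included(self):
        row = [1000.0] + [0.0] * 7
        tpm = pd.DataFrame([row], index=["spike"])
        assert np.isclose(tpm.std(axis=1, ddof=1).iloc[0], 353.55, atol=0.01)
        assert select_variable_genes(tpm) == ["spike"]

    def test_all_zero_excluded(self):
        tpm = pd.DataFrame([[0.0] * 8], index=["zero"])
        assert select_variable_genes(tpm) == []

    def test_gene_level_sums_member_transcripts(self):
        ann = two_isoform_locus()
        expr = expr_table({"big": {"T1": 10.0, "T2": 2.0}, "small": {"T1": 5.0, "T2": 1.0}})
        gene = gene_level_tpm(ann, expr)
        assert gene.shape == (1, 2)
        assert gene.iloc[0].tolist() == [15.0, 3.0]


class TestClustering:
    def test_identical_vectors_merge_first_at_zero(self):
        tpm = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
            index=["a", "b", "c"],
        )
        result = cluster_heatmap(tpm)
        first = result.gene_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_is_two(self):
        tpm = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        result = cluster_heatmap(tpm)
        assert result.gene_linkage[0][2] == pytest.approx(2.0)

    def test_planted_tissue_groups_cluster_together(self):
        rng = np.random.default_rng(0)
        # three tissue blocks with shared within-block gene programs
        blocks = {"cnsA": 0, "cnsB": 0, "embA": 1, "embB": 1, "out": 2}
        programs = rng.uniform(10, 1000, size=(3, 40))
        data = {
            tissue: programs[b] + rng.uniform(0, 20, size=40)
            for tissue, b in blocks.items()
        }
        tpm = pd.DataFrame(data, index=[f"g{i}" for i in range(40)])
        result = cluster_heatmap(tpm)
        order = result.tissue_order
        assert abs(order.index("cnsA") - order.index("cnsB")) == 1
        assert abs(order.index("embA") - order.index("embB")) == 1

    def test_constant_row_gets_max_distance(self, caplog):
        tpm = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["const", "var"])
        with caplog.at_level("WARNING"):
            result = cluster_heatmap(tpm)
        assert result.gene_linkage[0][2] == pytest.approx(2.0)
        assert any("constant" in m for m in caplog.messages)

    def test_linkage_heights_bounded(self, fixture_seed1):
        fx = fixture_seed1
        gene = gene_level_tpm(fx.assembly, fx.expr)
        result = cluster_heatmap(gene.head(30))
        assert (result.gene_linkage[:, 2] >= -1e-9).all()
        assert (result.gene_linkage[:, 2] <= 2.0 + 1e-9).all()

    def test_newick_output_is_parseable(self):
        tpm = pd.DataFrame(
            np.arange(12.0).reshape(4, 3) ** 2, index=list("abcd"),
            columns=["t1", "t2", "t3"],
        )
        result = cluster_heatmap(tpm)
        tree = Phylo.read(io.StringIO(result.gene_newick), "newick")
        assert sorted(leaf.name for leaf in tree.get_terminals()) == list("abcd")

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_heatmap(pd.DataFrame([[1.0, 2.0]], index=["a"]))


def test_negative_tpm_rejected():
    frame = pd.DataFrame({"s": {"t": -1.0}})
    with pytest.raises(ValueError):
        ExpressionTable(frame, {"s": "T"})
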