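"""The four filtration stages, the cascade, and merge-with-dedup."""

import numpy as np
import pandas as pd
import pytest

from isoclean.config import RunConfig
from isoclean.filters import (
    filter_erroneous,
    filter_evidence,
    filter_low_abundance,
    filter_pre_mrna,
    merge_dedup,
    n50,
    percent_reduction,
    run_cascade,
)
from isoclean.models import TranscriptomeAnnotation, make_transcript

CFG = RunConfig()


def ann(name, *transcripts):
    return TranscriptomeAnnotation.from_transcripts(name, list(transcripts))


MULTI = make_transcript("multi", "c", "+", [(0, 300), (800, 1100)])


class TestPreMrna:
    def test_intronic_singleton_removed(self):
        frag = make_transcript("frag", "c", "+", [(400, 700)])
        out, report = filter_pre_mrna(ann("a", MULTI, frag))
        assert report.removed == {"frag": "i"}
        assert "multi" in out and "frag" not in out

    def test_exon_overlap_singleton_removed(self):
        frag = make_transcript("frag", "c", "+", [(100, 500)])  # exon + intron
        _, report = filter_pre_mrna(ann("a", MULTI, frag))
        assert report.removed == {"frag": "e"}

    def test_isolated_singleton_kept(self):
        lone = make_transcript("lone", "c2", "+", [(0, 500)])
        out, report = filter_pre_mrna(ann("a", MULTI, lone))
        assert report.removed == {} and "lone" in out

    def test_multi_exon_always_kept(self):
        nested = make_transcript("nested", "c", "+", [(400, 500), (600, 700)])
        out, _ = filter_pre_mrna(ann("a", MULTI, nested))
        assert "nested" in out


class TestLowAbundance:
    def _locus(self):
        return [
            make_transcript("big", "c", "+", [(0, 100), (200, 300)]),
            make_transcript("mid", "c", "+", [(0, 100), (200, 320)]),
            make_transcript("tiny", "c", "+", [(0, 100), (200, 340)]),
        ]

    def test_threshold_arithmetic(self):
        a = ann("a", *self._locus())
        tpm = pd.Series({"big": 95.0, "mid": 4.9, "tiny": 0.1})
        out, report = filter_low_abundance(a, tpm)
        assert set(report.removed) == {"mid", "tiny"}
        assert len(out) == 1

    def test_boundary_is_strict(self):
        a = ann("a", *self._locus()[:2])
        out, report = filter_low_abundance(a, pd.Series({"big": 95.0, "mid": 5.0}))
        assert report.removed == {}  # 5.0 is exactly 5% of 100, not below

    def test_zero_total_locus_keeps_all(self):
        a = ann("a", *self._locus())
        _, report = filter_low_abundance(a, pd.Series(0.0, index=["big", "mid", "tiny"]))
        assert report.removed == {}

    def test_negative_tpm_rejected(self):
        a = ann("a", *self._locus()[:1])
        with pytest.raises(ValueError, match="negative TPM"):
            filter_low_abundance(a, pd.Series({"big": -1.0}))

    def test_missing_transcript_counts_as_zero(self):
        a = ann("a", *self._locus()[:2])
        _, report = filter_low_abundance(a, pd.Series({"big": 100.0}))
        assert set(report.removed) == {"mid"}

    def test_matrix_columns_are_pooled(self):
        a = ann("a", *self._locus()[:2])
        frame = pd.DataFrame({"s1": {"big": 50.0, "mid": 1.0}, "s2": {"big": 50.0, "mid": 1.0}})
        _, report = filter_low_abundance(a, frame)
        assert set(report.removed) == {"mid"}  # pooled 2 < 5% of 102


class TestEvidence:
    def test_orf_branch_keeps_unsupported(self):
        lone = make_transcript("lone", "c9", "+", [(0, 400)])
        out, _ = filter_evidence(ann("a", lone), {"lone": True}, [])
        assert "lone" in out

    def test_opposite_strand_overlap_is_support(self):
        t = make_transcript("t", "c", "-", [(0, 300)])
        evidence = ann("ev", make_transcript("e1", "c", "+", [(100, 500)]))
        out, report = filter_evidence(ann("a", t), {"t": False}, [evidence])
        assert report.removed == {} and "t" in out

    def test_no_orf_no_overlap_removed(self):
        t = make_transcript("t", "c9", "+", [(0, 400)])
        _, report = filter_evidence(ann("a", t), {}, [])
        assert set(report.removed) == {"t"}

    def test_literal_mode_drops_exact_match_support(self):
        t = make_transcript("t", "c", "+", [(0, 100), (200, 300)])
        same = ann("ev", make_transcript("e1", "c", "+", [(0, 100), (200, 300)]))
        keep_cfg = RunConfig()
        out, _ = filter_evidence(ann("a", t), {"t": False}, [same], keep_cfg)
        assert "t" in out  # "=" counts as support by default
        literal = RunConfig(literal_support=True)
        # an exact match is still a shared junction, so build a match with no
        # shared junction: single-exon reciprocal overlap
        s = make_transcript("s", "c2", "+", [(0, 100)])
        ev = ann("ev2", make_transcript("e2", "c2", "+", [(2, 102)]))
        _, report = filter_evidence(ann("b", s), {"s": False}, [ev], literal)
        assert set(report.removed) == {"s"}


class TestErroneous:
    def test_mito_removed_regardless_of_length(self):
        t = make_transcript("mt", "chrM", "+", [(0, 1500)])
        _, report = filter_erroneous(ann("a", t))
        assert report.removed == {"mt": "mitochondrial contig"}

    def test_length_boundary(self):
        t200 = make_transcript("t200", "c", "+", [(0, 200)])
        t201 = make_transcript("t201", "c", "+", [(500, 701)])
        out, report = filter_erroneous(ann("a", t200, t201))
        assert set(report.removed) == {"t200"}
        assert "t201" in out

    def test_length_is_exonic_not_genomic_span(self):
        spread = make_transcript("spread", "c", "+", [(0, 100), (5000, 5100)])
        _, report = filter_erroneous(ann("a", spread))
        assert "spread" in report.removed  # 200 exonic bp despite 5.1 kb span


class TestCascade:
    def test_planted_counts_recovered(self, fixture_seed1):
        fx = fixture_seed1
        result = run_cascade(fx.assembly, fx.expr.tpm, fx.orf_calls, fx.evidence)
        truth = fx.truth.set_index("transcript_id")
        for report in result.reports:
            expected = set(truth.index[truth.removal_stage == report.stage])
            assert set(report.removed) == expected, report.stage

    def test_clean_fixture_is_fixed_point(self):
        from isoclean.simulate import FixtureSpec, generate

        spec = FixtureSpec(
            seed=3, n_loci=10, n_pre_mrna_intronic=0, n_pre_mrna_exonic=0,
            n_clean_singletons=0, n_low_abundance=0, n_no_evidence=0, n_mito=0,
            n_short=0, n_novel_1=0, n_novel_2=0, n_novel_3=0,
            n_unique_present=0, n_sole_absent=0,
        )
        fx = generate(spec)
        result = run_cascade(fx.assembly, fx.expr.tpm, fx.orf_calls, fx.evidence)
        assert all(r.n_removed == 0 for r in result.reports)

    def test_counts_never_increase(self, fixture_seed1):
        fx = fixture_seed1
        result = run_cascade(fx.assembly, fx.expr.tpm, fx.orf_calls, fx.evidence)
        labels = ["initial", "filtered1", "filtered2", "filtered3", "filtered4"]
        sizes = [len(result.stages[l]) for l in labels]
        assert sizes == sorted(sizes, reverse=True)

    def test_filters_idempotent(self, fixture_seed1):
        fx = fixture_seed1
        f1, _ = filter_pre_mrna(fx.assembly)
        assert filter_pre_mrna(f1)[1].n_removed == 0
        f2, _ = filter_low_abundance(f1, fx.expr.tpm)
        assert filter_low_abundance(f2, fx.expr.tpm)[1].n_removed == 0
        f3, _ = filter_evidence(f2, fx.orf_calls, fx.evidence)
        assert filter_evidence(f3, fx.orf_calls, fx.evidence)[1].n_removed == 0
        f4, _ = filter_erroneous(f3)
        assert filter_erroneous(f4)[1].n_removed == 0

    def test_removed_plus_survivors_conserved(self, fixture_seed1):
        fx = fixture_seed1
        result = run_cascade(fx.assembly, fx.expr.tpm, fx.orf_calls, fx.evidence)
        removed = set()
        for r in result.reports:
            assert not removed & set(r.removed)  # one reason per transcript
            removed |= set(r.removed)
        survivors = set(result.refined.transcript_ids)
        assert removed | survivors == set(fx.assembly.transcript_ids)
        assert not removed & survivors


class TestMergeDedup:
    def test_self_merge_is_idempotent(self, simple_annotation):
        merged = merge_dedup(simple_annotation, [simple_annotation])
        assert sorted(merged.transcript_ids) == sorted(simple_annotation.transcript_ids)

    def test_longer_chain_twin_survives(self):
        short = make_transcript("short", "c", "+", [(10, 100), (200, 290)])
        long = make_transcript("long", "c", "+", [(0, 100), (200, 400)])
        merged = merge_dedup(ann("a", short), [ann("b", long)])
        assert merged.transcript_ids == ["long"]

    def test_contained_single_exon_collapses(self):
        outer = make_transcript("outer", "c", "+", [(0, 500)])
        inner = make_transcript("inner", "c", "+", [(100, 300)])
        merged = merge_dedup(ann("a", inner), [ann("b", outer)])
        assert merged.transcript_ids == ["outer"]

    def test_no_surviving_chain_duplicates(self, fixture_seed1):
        fx = fixture_seed1
        merged = merge_dedup(fx.assembly, [fx.ncbi, fx.ensembl])
        keys = [t.chain_key() for t in merged.transcripts() if t.is_multi_exon]
        assert len(keys) == len(set(keys))


def test_n50_and_percent_reduction():
    assert n50([]) == 0
    assert n50([2, 2, 2, 10]) == 10  # half of 16 reached by the 10
    assert n50([5, 4, 3, 2, 1]) == 4
    assert percent_reduction(200, 50) == 75.0
    with pytest.raises(ValueError):
        percent_reduction(0, 1)
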