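"""Feature assembly: binarization, TP53 classes, copy-number collapse and
thresholds, expression normalization, signature scoring, and the sparse /
perfect-correlation filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbcprog.features import (
    assemble_features,
    binarize_mutations,
    call_gain_loss,
    classify_tp53_variant,
    collapse_segments,
    dedup_perfect_correlation,
    filter_sparse,
    hrd_status,
    log2_ratio,
    normalize_expression,
    score_signatures,
    zscale_gene,
)


def _mut(records):
    return pd.DataFrame(
        records,
        columns=["patient", "gene", "variant_classification", "protein_change", "origin",
                 "pathogenicity"],
    )


PATIENTS = ["P1", "P2", "P3"]


class TestBinarize:
    def test_any_record_rule_and_tp53_variant_columns(self):
        mut = _mut(
            [
                ("P1", "TP53", "Missense_Mutation", "p.R175H", "somatic", ""),
                ("P1", "TP53", "Nonsense_Mutation", "p.R213*", "somatic", ""),
                ("P2", "GATA3", "Missense_Mutation", "p.A1B", "somatic", ""),
            ]
        )
        mm = binarize_mutations(mut, ["TP53", "GATA3"], patients=PATIENTS)
        assert mm.gene.loc["P1", "TP53"] == 1
        assert mm.gene.loc["P3"].sum() == 0  # no records -> all-zero row
        assert mm.tp53_variant.loc["P1", "R175H"] == 1
        assert mm.tp53_variant.loc["P1", "R213*"] == 1

    def test_excluded_passenger_gene_contributes_nothing(self):
        mut = _mut([("P1", "MUC16", "Missense_Mutation", "", "somatic", "")])
        mm = binarize_mutations(
            mut, ["TP53", "MUC16"], exclusion_list=["MUC16"], patients=PATIENTS
        )
        assert "MUC16" not in mm.gene.columns
        assert mm.gene.to_numpy().sum() == 0

    def test_unknown_patient_and_empty_catalog_error(self):
        mut = _mut([("PX", "TP53", "", "", "somatic", "")])
        with pytest.raises(ValueError, match="unknown patient"):
            binarize_mutations(mut, ["TP53"], patients=PATIENTS)
        with pytest.raises(ValueError, match="catalog"):
            binarize_mutations(_mut([]), ["TP53"], exclusion_list=["TP53"],
                               patients=PATIENTS)

    def test_germline_records_do_not_binarize(self):
        mut = _mut([("P1", "BRCA1", "Missense_Mutation", "", "germline", "pathogenic")])
        mm = binarize_mutations(mut, ["BRCA1"], patients=PATIENTS)
        assert mm.gene.loc["P1", "BRCA1"] == 0


@pytest.mark.parametrize(
    "change,classification,expected",
    [
        ("p.R175H", "", "missense"),
        ("p.R213*", "", "nonsense"),
        ("p.K120fs", "", "frameshift"),
        ("p.I255del", "", "in-frame"),
        ("p.X307_splice", "", "splice site"),
        ("", "Splice_Site", "splice site"),
        ("", "Missense_Mutation", "missense"),
    ],
)
def test_tp53_variant_classification(change, classification, expected):
    assert classify_tp53_variant(change, classification) == expected


def test_unparseable_tp53_variant_warns_other():
    with pytest.warns(UserWarning, match="unclassifiable"):
        assert classify_tp53_variant("p.???", "") == "other"


class TestHRD:
    def test_qualifying_and_non_qualifying_calls(self):
        calls = _mut(
            [
                ("P1", "BRCA1", "", "", "germline", "pathogenic"),
                ("P2", "PALB2", "", "", "somatic", "likely_oncogenic"),
                ("P3", "BRCA1", "", "", "somatic", "uncertain_significance"),
            ]
        )
        flags = hrd_status(calls, patients=PATIENTS)
        assert flags.tolist() == [1, 1, 0]

    def test_other_genes_ignored_with_warning(self):
        calls = _mut([("P1", "ATM", "", "", "germline", "pathogenic")])
        with pytest.warns(UserWarning, match="non-HRD"):
            flags = hrd_status(calls, patients=PATIENTS)
        assert flags.sum() == 0


def test_log2_ratio_closed_forms_and_errors():
    assert log2_ratio(1, 1, 2) == 0.0
    assert log2_ratio(3, 1, 2) == 1.0
    assert log2_ratio(2, 1, 2) == pytest.approx(np.log2(1.5))
    with pytest.raises(ValueError):
        log2_ratio(0, 0, 2)
    with pytest.raises(ValueError):
        log2_ratio(1, 1, 0)


@pytest.mark.parametrize(
    "score,call", [(0.31, "gain"), (-0.31, "loss"), (0.30, "neutral"), (-0.30, "neutral"),
                   (0.0, "neutral")]
)
def test_gain_loss_threshold_is_strict(score, call):
    assert call_gain_loss(score) == call


class TestCollapseSegments:
    def test_mean_and_single_gene_and_constant(self):
        scores = pd.DataFrame(
            {"g1": [0.2, 1.0], "g2": [0.4, 1.0], "g3": [-0.5, 0.7]}, index=["P1", "P2"]
        )
        calls = collapse_segments(scores, {"s12": ["g1", "g2"], "s3": ["g3"]})
        assert calls.scores.loc["P1", "s12"] == pytest.approx(0.3)
        assert calls.scores.loc["P1", "s3"] == pytest.approx(-0.5)
        assert calls.scores.loc["P2", "s12"] == pytest.approx(1.0)
        assert calls.gain.loc["P2", "s12"] == 1 and calls.loss.loc["P1", "s3"] == 1

    def test_absent_genes_skipped_and_empty_segment_flagged(self):
        scores = pd.DataFrame({"g1": [0.2]}, index=["P1"])
        with pytest.warns(UserWarning, match="dropped"):
            calls = collapse_segments(scores, {"a": ["g1", "missing"], "b": ["gone"]})
        assert calls.missing_segments == ("b",)
        assert calls.scores.loc["P1", "a"] == pytest.approx(0.2)
        cov = calls.coverage.set_index("segment")
        assert cov.loc["a", "genes_present"] == 1 and cov.loc["b", "genes_present"] == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_bruteforce_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(
            rng.normal(size=(20, 50)), columns=[f"g{i}" for i in range(50)]
        )
        segs = {}
        start = 0
        k = 0
        while start < 50:
            width = int(rng.integers(1, 6))
            segs[f"s{k}"] = [f"g{i}" for i in range(start, min(start + width, 50))]
            start += width
            k += 1
        calls = collapse_segments(scores, segs)
        for sid, genes in segs.items():
            expect = np.array([np.mean([scores.loc[i, g] for g in genes])
                               for i in scores.index])
            np.testing.assert_allclose(calls.scores[sid].to_numpy(), expect, atol=1e-12)

    def test_gain_and_loss_mutually_exclusive(self, small_cohort):
        calls = collapse_segments(
            small_cohort.cn_genes,
            {s.segment_id: list(s.genes) for s in small_cohort.segment_catalog},
        )
        assert ((calls.gain.to_numpy() + calls.loss.to_numpy()) <= 1).all()


class TestNormalizeExpression:
    def test_scale_invariance_and_zero_preservation(self):
        raw = pd.DataFrame({"s1": [0.0, 10.0, 20.0, 40.0], "s2": [5.0, 10.0, 15.0, 0.0]})
        norm = normalize_expression(raw)
        doubled = normalize_expression(raw.assign(s1=raw["s1"] * 2))
        pd.testing.assert_frame_equal(norm, doubled)
        assert norm.loc[0, "s1"] == 0.0

    def test_sample_at_target_quartile_gets_only_log_transform(self):
        raw = pd.DataFrame({"s1": [500.0, 1000.0, 2000.0]})
        norm = normalize_expression(raw, target_quartile=np.percentile([500, 1000, 2000], 75))
        np.testing.assert_allclose(norm["s1"], np.log2(raw["s1"] + 1))

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all zeros"):
            normalize_expression(pd.DataFrame({"s1": [0.0, 0.0]}))


class TestSignatures:
    def test_median_scoring_and_centering(self):
        expr = pd.DataFrame(
            {"p1": [1.0, 2.0, 3.0], "p2": [4.0, 6.0, 8.0]}, index=["a", "b", "c"]
        )
        raw = score_signatures(expr, {"s": ["a", "b", "c"]}, center=False)
        assert raw.loc["p1", "s"] == 2.0 and raw.loc["p2", "s"] == 6.0
        centered = score_signatures(expr, {"s": ["a", "b", "c"]})
        assert centered.median(axis=0)["s"] == 0.0

    def test_identical_patients_get_identical_rows(self):
        expr = pd.DataFrame({"p1": [1.0, 5.0], "p2": [1.0, 5.0]}, index=["a", "b"])
        mat = score_signatures(expr, {"s": ["a", "b"]})
        assert mat.loc["p1", "s"] == mat.loc["p2", "s"]

    def test_signature_without_genes_dropped_with_warning(self):
        expr = pd.DataFrame({"p1": [1.0]}, index=["a"])
        with pytest.warns(UserWarning, match="dropped"):
            mat = score_signatures(expr, {"ok": ["a"], "empty": ["zz"]})
        assert list(mat.columns) == ["ok"]


def test_zscale_gene_properties():
    combined = zscale_gene({"d1": [1.0, 2.0, 3.0], "d2": [10.0, 20.0, 30.0, 40.0]})
    assert combined[:3].mean() == pytest.approx(0.0)
    assert combined[3:].mean() == pytest.approx(0.0)
    shifted = zscale_gene({"d1": [101.0, 102.0, 103.0], "d2": [10.0, 20.0, 30.0, 40.0]})
    np.testing.assert_allclose(combined.to_numpy(), shifted.to_numpy())
    with pytest.raises(ValueError, match="zero variance"):
        zscale_gene({"d1": [1.0, 1.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        zscale_gene({"d1": [1.0]})


class TestAssemble:
    def test_column_count_is_sum_of_catalog_sizes(self, small_cohort):
        from conftest import SMALL_COHORT_KW

        mm = binarize_mutations(
            small_cohort.mutations,
            small_cohort.mutation_genes,
            patients=small_cohort.clinical.index,
            tp53_variant_catalog=small_cohort.tp53_variants,
        )
        calls = collapse_segments(
            small_cohort.cn_genes,
            {s.segment_id: list(s.genes) for s in small_cohort.segment_catalog},
        )
        sigs = score_signatures(small_cohort.expression, small_cohort.signature_catalog)
        fm = assemble_features(small_cohort.clinical, mm, calls, sigs)
        expected = (
            1
            + SMALL_COHORT_KW["n_signatures"]
            + SMALL_COHORT_KW["n_mutation_genes"]
            + SMALL_COHORT_KW["n_tp53_variants"]
            + 2 * SMALL_COHORT_KW["n_segments"]
        )
        assert fm.values.shape[1] == expected
        assert not fm.values.isna().any().any()
        assert fm.values.columns.is_unique

    def test_patients_missing_a_platform_are_excluded_and_counted(self, small_cohort):
        mm = binarize_mutations(
            small_cohort.mutations,
            small_cohort.mutation_genes,
            patients=small_cohort.clinical.index,
        )
        calls = collapse_segments(
            small_cohort.cn_genes.iloc[5:],  # drop 5 patients from one platform
            {s.segment_id: list(s.genes) for s in small_cohort.segment_catalog},
        )
        sigs = score_signatures(small_cohort.expression, small_cohort.signature_catalog)
        fm = assemble_features(small_cohort.clinical, mm, calls, sigs)
        assert fm.n_excluded_patients == 5
        assert fm.values.shape[0] == len(small_cohort.clinical) - 5


class TestFilters:
    def test_sparse_threshold_boundary_is_inclusive(self):
        n = 100
        mat = pd.DataFrame(
            {
                "five": [1.0] * 5 + [0.0] * 95,
                "six": [1.0] * 6 + [0.0] * 94,
                "dense": np.linspace(-1, 1, n),
            }
        )
        out = filter_sparse(mat, threshold=0.05)
        assert list(out.columns) == ["six", "dense"]

    def test_all_removed_errors(self):
        mat = pd.DataFrame({"a": [1.0] + [0.0] * 99})
        with pytest.raises(ValueError, match="every feature"):
            filter_sparse(mat)

    def test_dedup_keeps_first_of_perfect_group(self, rng):
        x = rng.normal(size=50)
        mat = pd.DataFrame(
            {"x": x, "noise": rng.normal(size=50), "x2": 2 * x, "negx": -x,
             "const": np.ones(50)}
        )
        out = dedup_perfect_correlation(mat)
        assert list(out.columns) == ["x", "noise"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_filter_then_dedup_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.binomial(1, 0.15, size=(40, 15)).astype(float))
        mat.columns = [f"f{i}" for i in range(15)]
        mat["dup"] = mat["f0"]
        try:
            once = dedup_perfect_correlation(filter_sparse(mat))
        except ValueError:
            return  # everything sparse: nothing to be idempotent about
        twice = dedup_perfect_correlation(filter_sparse(once))
        pd.testing.assert_frame_equal(once, twice)
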