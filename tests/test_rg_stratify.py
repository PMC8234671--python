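import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatratio import (
    NormalizedMatrix,
    RGProfile,
    class_fractions,
    cut_interval,
    inter_patient_table,
    parse_feature_id,
    rg_profiles,
    rg_ratio,
    stratify_cohort,
    zscore,
)

from conftest import make_table


def matrix_from_medians(repeat_values, gene_values) -> NormalizedMatrix:
    """Single-sample normalized matrix with given repeat/gene log2 values."""
    features = [
        parse_feature_id(f"R{i}:Alu:SINE") for i in range(len(repeat_values))
    ] + [parse_feature_id(f"G{i}") for i in range(len(gene_values))]
    values = np.array([list(repeat_values) + list(gene_values)], dtype=float).T
    return NormalizedMatrix(
        features=features, samples=["P1"], values=values,
        transform="log2-sizefactor", pseudocount=1.0,
    )


class TestRGRatio:
    def test_published_worked_example(self):
        """Median repeat 7.83 over median gene 9.57 reports as 0.82 (2 dp)."""
        norm = matrix_from_medians([7.0, 7.83, 8.6], [9.0, 9.57, 10.4])
        prof = rg_ratio(norm, "P1")
        assert prof.median_repeat_expr == pytest.approx(7.83)
        assert prof.median_gene_expr == pytest.approx(9.57)
        assert round(prof.rg_ratio, 2) == 0.82

    def test_identical_compartments_give_unity(self):
        norm = matrix_from_medians([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rg_ratio(norm, "P1").rg_ratio == pytest.approx(1.0)

    def test_even_length_median_is_mean_of_central_pair(self):
        norm = matrix_from_medians([1, 2, 3, 4, 5], [2, 2, 4, 4])
        prof = rg_ratio(norm, "P1")
        assert prof.median_repeat_expr == 3.0
        assert prof.median_gene_expr == 3.0
        assert prof.rg_ratio == pytest.approx(1.0)

    def test_zero_gene_median_errors(self):
        norm = matrix_from_medians([1.0], [0.0])
        with pytest.raises(ValueError, match="median gene expression is zero"):
            rg_ratio(norm, "P1")

    def test_scaling_matrix_leaves_ratio_unchanged(self):
        norm = matrix_from_medians([2.0, 4.0, 6.0], [3.0, 5.0, 9.0])
        base = rg_ratio(norm, "P1").rg_ratio
        scaled = NormalizedMatrix(
            features=norm.features, samples=norm.samples,
            values=3.7 * norm.values, transform=norm.transform,
            pseudocount=norm.pseudocount,
        )
        assert rg_ratio(scaled, "P1").rg_ratio == pytest.approx(base)

    def test_unknown_sample_errors(self):
        norm = matrix_from_medians([1.0], [2.0])
        with pytest.raises(KeyError):
            rg_ratio(norm, "nope")


class TestZScore:
    def test_simple_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, 2.2, 5.0, 9.1])
        np.testing.assert_allclose(zscore(a * x + b), zscore(x), atol=1e-7)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            zscore([5.0, 5.0])

    def test_output_standardized(self):
        z = zscore([2.0, 4.0, 7.0, 11.0])
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)


class TestCutInterval:
    def test_hand_evaluated_edges(self):
        labels = cut_interval([0, 0.5, 1, 1.5, 2, 2.5, 3], n=3)
        assert labels == ["low", "low", "low", "mid", "mid", "high", "high"]

    def test_exact_edge_value_goes_to_lower_bin(self):
        # range [0, 3]: interior edges at 1 and 2, right-closed
        assert cut_interval([0.0, 1.0, 3.0], n=3) == ["low", "low", "high"]

    def test_degenerate_range_all_mid(self):
        assert cut_interval([4.2, 4.2, 4.2], n=3) == ["mid"] * 3

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cut_interval([], n=3)

    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40).filter(
            lambda v: max(v) > min(v)
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_bins_partition_the_range(self, values):
        """Bins cover [min,max], are disjoint, and have equal width."""
        x = np.asarray(values)
        labels = np.array(cut_interval(values, n=3))
        lo, hi = x.min(), x.max()
        w = (hi - lo) / 3
        for val, lab in zip(x, labels):
            k = {"low": 0, "mid": 1, "high": 2}[lab]
            left, right = lo + k * w, lo + (k + 1) * w
            assert val <= right + 1e-9 * max(1, abs(right))
            if k > 0:
                assert val > left - 1e-9 * max(1, abs(left))
        assert "low" in labels and "high" in labels


class TestStratifyCohort:
    def _profiles(self, ratios):
        return [
            RGProfile(sample=f"s{i}", median_repeat_expr=np.nan,
                      median_gene_expr=np.nan, rg_ratio=r)
            for i, r in enumerate(ratios)
        ]

    def test_extreme_outlier_occupies_bin_alone(self):
        out = stratify_cohort(self._profiles([1.0, 1.01, 1.02, 1.03, 9.0]))
        assert [p.stratum for p in out] == ["low"] * 4 + ["high"]

    def test_zscore_does_not_change_strata(self):
        ratios = [0.7, 0.8, 0.9, 1.0, 1.1, 1.35]
        via_z = stratify_cohort(self._profiles(ratios))
        raw = cut_interval(ratios, n=3)
        assert [p.stratum for p in via_z] == raw

    def test_duplicated_sample_gets_same_stratum(self):
        ratios = [0.6, 0.8, 1.0, 1.2, 1.4]
        base = stratify_cohort(self._profiles(ratios))
        dup = stratify_cohort(self._profiles(ratios + [1.0]))
        assert dup[-1].stratum == base[2].stratum

    def test_all_equal_ratios_labelled_mid(self):
        out = stratify_cohort(self._profiles([1.0, 1.0, 1.0]))
        assert [p.stratum for p in out] == ["mid"] * 3


class TestClassFractions:
    def test_direct_arithmetic(self):
        import numpy as np
        from repeatratio import CountTable, parse_feature_id

        features = [
            parse_feature_id("g1"),
            parse_feature_id("a:Alu:SINE"),
            parse_feature_id("b:L1:LINE"),
            parse_feature_id("c:ERVL:LTR"),
            parse_feature_id("d:centr:Satellite"),
            parse_feature_id("e:hAT:DNA"),
        ]
        counts = np.array([[100], [40], [30], [9], [1], [20]], dtype=np.int64)
        table = CountTable(features, ["P1"], counts)
        prof = class_fractions(table, "P1")
        assert prof.class_fractions == pytest.approx(
            {"SINE": 0.40, "LINE": 0.30, "LTR": 0.09, "Satellite": 0.01,
             "DNA": 0.20}
        )
        assert prof.repeat_fraction_of_all == pytest.approx(0.5)
        assert sum(prof.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_class_is_total(self):
        table = make_table(np.array([[10], [7]]), n_repeats=1)
        prof = class_fractions(table, "s0")
        assert prof.class_fractions == {"SINE": 1.0}

    def test_zero_repeat_total_errors(self):
        table = make_table(np.array([[10], [0]]), n_repeats=1)
        with pytest.raises(ValueError, match="zero repeat reads"):
            class_fractions(table, "s0")


class TestInterPatientTable:
    def test_median_line(self):
        table = make_table(np.array([[1, 2, 9], [1, 1, 1]]))
        from repeatratio import normalize_log

        norm = NormalizedMatrix(
            features=table.features, samples=table.samples,
            values=table.counts.astype(float), transform="identity",
            pseudocount=1.0,
        )
        df, med = inter_patient_table(norm, "GENE00000")
        assert med == 2.0
        assert list(df["value"]) == [1, 2, 9]

    def test_even_cohort_median_mean_of_central_two(self):
        norm = NormalizedMatrix(
            features=[parse_feature_id("g")],
            samples=["a", "b", "c", "d"],
            values=np.array([[1.0, 2.0, 5.0, 10.0]]),
            transform="identity", pseudocount=1.0,
        )
        _, med = inter_patient_table(norm, "g")
        assert med == 3.5

    def test_unknown_feature_errors(self):
        norm = matrix_from_medians([1.0], [2.0])
        with pytest.raises(KeyError):
            inter_patient_table(norm, "missing")
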