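"""Unit and property tests for trait tables, transforms and covariance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divmat.trait_data as td
from divmat import (
    TRAITS,
    CovarianceMatrix,
    DegenerateTraitError,
    InsufficientDataError,
    LineageMeans,
    ParseError,
    SchemaError,
    TransformError,
    apply_transforms,
    cov_to_corr,
    lineage_means,
    read_trait_table,
    sample_covariance,
    standardize,
    write_trait_table,
)


def _make_table(rows):
    df = pd.DataFrame(
        rows, columns=["lineage_id", "treatment", "replicate_id", *TRAITS, "MGR"]
    )
    return td.TraitTable(df)


def _simple_table():
    rows = []
    for lin, tr in [("L1", "small"), ("L2", "large")]:
        for j in range(3):
            rows.append((lin, tr, f"r{j}", 1.0 + j, 2.0, 3.0, 4.0, 5.0))
    return _make_table(rows)


class TestReadWrite:
    def test_well_formed_file_roundtrip(self, tmp_path):
        table = _simple_table()
        path = tmp_path / "t.csv"
        write_trait_table(table, path, header_comment="roundtrip test")
        back = read_trait_table(path)
        assert back.n_lineages == 2
        assert len(back.data) == 6
        pd.testing.assert_frame_equal(back.data, table.data)

    def test_unknown_treatment_rejected(self, tmp_path):
        df = _simple_table().data.copy()
        df.loc[0, "treatment"] = "medium"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="medium"):
            read_trait_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        df = _simple_table().data.drop(columns=["DPL"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="DPL"):
            read_trait_table(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        df = _simple_table().data.copy().astype(object)
        df.loc[2, "CFU"] = "oops"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 2"):
            read_trait_table(path)

    def test_long_layout_matches_wide(self, tmp_path):
        table = _simple_table()
        long = table.data.melt(
            id_vars=["lineage_id", "treatment", "replicate_id"],
            var_name="variable", value_name="value",
        )
        path = tmp_path / "long.csv"
        long.to_csv(path, index=False)
        back = read_trait_table(path, td.TableLayout(layout="long"))
        a = back.data.sort_values(["lineage_id", "replicate_id"]).reset_index(drop=True)
        b = table.data.sort_values(["lineage_id", "replicate_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_replicate_rejected(self):
        rows = [("L1", "small", "r1", 1, 1, 1, 1, 1),
                ("L1", "small", "r1", 2, 2, 2, 2, 2)]
        with pytest.raises(SchemaError, match="duplicate"):
            _make_table(rows)


class TestTransforms:
    def test_default_spec_logs_all_but_biomass(self):
        rows = [("L1", "small", "r1", 7.46, math.e, math.e, math.e, 5.0),
                ("L2", "large", "r1", 1.0, 1.0, 1.0, 1.0, 5.0)]
        out = apply_transforms(_make_table(rows))
        first = out.data.iloc[0]
        assert first["BM"] == pytest.approx(7.46)   # biomass stays raw
        assert first["CFU"] == pytest.approx(1.0)   # ln(e) = 1
        assert first["DPL"] == pytest.approx(1.0)
        assert first["SFB"] == pytest.approx(1.0)
        assert ("CFU", "ln") in out.transform_log

    def test_nonpositive_value_names_lineage_and_trait(self):
        rows = [("L9", "small", "r1", 1.0, 1.0, 0.0, 1.0, 5.0)]
        with pytest.raises(td.DivmatError, match="DPL.*L9"):
            apply_transforms(_make_table(rows))

    def test_double_transform_refused(self):
        out = apply_transforms(_simple_table())
        with pytest.raises(TransformError, match="already"):
            apply_transforms(out)

    def test_transform_before_averaging_is_the_pipeline_order(self):
        # ln of means differs from mean of lns; the pipeline applies the
        # transform at replicate level, before averaging
        rows = [("L1", "small", "r1", 1.0, 1.0, 1.0, 1.0, 5.0),
                ("L1", "small", "r2", 1.0, math.e ** 2, 1.0, 1.0, 5.0),
                ("L2", "large", "r1", 1.0, 2.0, 2.0, 2.0, 5.0)]
        means = lineage_means(apply_transforms(_make_table(rows)))
        cfu = means.values[list(means.lineage_ids).index("L1"),
                           list(TRAITS).index("CFU")]
        assert cfu == pytest.approx(1.0)  # (0 + 2)/2, not ln((1+e^2)/2)


class TestStandardize:
    def _means(self, col):
        vals = np.column_stack([col, col, col, col]).astype(float)
        return LineageMeans(
            tuple(f"L{i}" for i in range(len(col))),
            tuple("small" for _ in col), vals,
        )

    def test_variance_mode_symmetric_zscores(self):
        out = standardize(self._means([1.0, 2.0, 3.0]), mode="variance")
        assert out.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_mode_divides_by_mean(self):
        out = standardize(self._means([2.0, 4.0, 6.0]), mode="mean")
        assert out.values[:, 0] == pytest.approx([0.5, 1.0, 1.5])

    def test_variance_mode_recomputation_property(self):
        rng = np.random.default_rng(1)
        m = LineageMeans(
            tuple(f"L{i}" for i in range(20)), tuple(["small"] * 20),
            rng.normal(size=(20, 4)) * [1, 5, 0.2, 3] + [0, 10, -4, 2],
        )
        out = standardize(m, mode="variance")
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12
        assert np.abs(out.values.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateTraitError):
            standardize(self._means([2.0, 2.0, 2.0]), mode="variance")

    def test_zero_mean_is_degenerate(self):
        with pytest.raises(DegenerateTraitError):
            standardize(self._means([-1.0, 0.0, 1.0]), mode="mean")


class TestLineageMeans:
    def test_groupby_oracle_on_synthetic_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            for j in range(3):
                rows.append((f"L{i}", "small" if i < 10 else "large", f"r{j}",
                             *rng.uniform(1, 5, size=5)))
        table = _make_table(rows)
        means = lineage_means(table)
        oracle = table.data.groupby("lineage_id", sort=False)[list(TRAITS)].mean()
        assert np.allclose(means.values, oracle.to_numpy())

    def test_single_replicate_identity(self):
        rows = [("L1", "small", "r1", 1.5, 2.5, 3.5, 4.5, 5.5)]
        means = lineage_means(_make_table(rows))
        assert means.values[0] == pytest.approx([1.5, 2.5, 3.5, 4.5])

    def test_replicate_mean(self):
        rows = [("L1", "small", f"r{j}", float(j + 1), 1, 1, 1, 1) for j in range(3)]
        means = lineage_means(_make_table(rows))
        assert means.values[0, 0] == pytest.approx(2.0)


class TestSampleCovariance:
    def test_identical_rows_give_zero_matrix(self):
        m = LineageMeans(("a", "b"), ("small", "small"),
                         np.ones((2, 4)) * [1, 2, 3, 4])
        assert np.allclose(sample_covariance(m).values, 0.0)

    def test_hand_computed_two_trait_case(self):
        m = LineageMeans(
            ("a", "b", "c"), ("small",) * 3,
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
            traits=("BM", "CFU"),
        )
        cov = sample_covariance(m)
        assert np.allclose(cov.values, 1.0)  # divisor n-1 = 2

    def test_single_row_insufficient(self):
        m = LineageMeans(("a",), ("small",), np.ones((1, 4)))
        with pytest.raises(InsufficientDataError):
            sample_covariance(m)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetric_psd_on_random_means(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        m = LineageMeans(
            tuple(f"L{i}" for i in range(n)), tuple(["small"] * n),
            rng.normal(size=(n, 4)),
        )
        cov = sample_covariance(m)
        assert np.abs(cov.values - cov.values.T).max() < 1e-12
        assert np.linalg.eigvalsh(cov.values).min() > -1e-10

    def test_standardized_means_have_unit_diagonal(self):
        rng = np.random.default_rng(5)
        m = LineageMeans(
            tuple(f"L{i}" for i in range(15)), tuple(["small"] * 15),
            rng.normal(size=(15, 4)) * [2, 0.5, 7, 1],
        )
        std = standardize(m, mode="variance", reference="with_ancestor")
        assert np.allclose(np.diag(sample_covariance(std).values), 1.0, atol=1e-10)


class TestCovToCorr:
    def test_published_cells(self, pooled_D):
        corr = cov_to_corr(pooled_D).values
        # self-consistent printed correlations of the pooled D matrix
        assert corr[2, 3] == pytest.approx(-0.367, abs=5e-4)
        assert corr[0, 2] == pytest.approx(0.180, abs=5e-4)
        assert corr[1, 2] == pytest.approx(0.257, abs=5e-4)
        assert corr[1, 3] == pytest.approx(-0.035, abs=5e-4)
        assert corr[0, 3] == pytest.approx(-0.001, abs=5e-4)

    def test_diagonal_input_gives_identity(self):
        cov = CovarianceMatrix(TRAITS, np.diag([1.0, 2.0, 3.0, 4.0]), 10,
                               "sample_of_means")
        assert np.allclose(cov_to_corr(cov).values, np.eye(4))

    def test_bounds_and_unit_diagonal(self, pooled_D):
        corr = cov_to_corr(pooled_D).values
        assert np.allclose(np.diag(corr), 1.0)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) <= 1.0)

    def test_zero_variance_rejected(self):
        v = np.zeros((4, 4))
        cov = CovarianceMatrix(TRAITS, v, 10, "sample_of_means")
        with pytest.raises(DegenerateTraitError):
            cov_to_corr(cov)
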