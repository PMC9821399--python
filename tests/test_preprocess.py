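"""Preprocessing stages: filters, log2/missing handling, imputation."""

import numpy as np
import pandas as pd
import pytest

from layerstrata import ExpressionMatrix
from layerstrata.preprocess import (PreprocessConfig, filter_min_total_counts,
                                    filter_valid_fraction, filter_zero_fraction,
                                    impute_downshifted_normal, log2_transform,
                                    merge_duplicate_symbols, select_top_variable)

from conftest import make_matrix


def table(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples:
        df.columns = samples
    return df.astype(float)


class TestMergeDuplicates:
    def test_duplicate_rows_are_summed(self):
        raw = pd.DataFrame([[3.0, 1.0], [5.0, 2.0]], index=["X", "X"],
                           columns=["s1", "s2"])
        out = merge_duplicate_symbols(raw)
        assert out.loc["X"].tolist() == [8.0, 3.0]

    def test_triplicate(self):
        raw = pd.DataFrame([[1.0], [1.0], [1.0]], index=["X"] * 3, columns=["s1"])
        assert merge_duplicate_symbols(raw).loc["X", "s1"] == 3.0

    def test_no_duplicates_identity(self):
        raw = table({"A": [1, 2], "B": [3, 4]}, ["s1", "s2"])
        pd.testing.assert_frame_equal(merge_duplicate_symbols(raw), raw)

    def test_non_numeric_rejected_with_gene_name(self):
        raw = pd.DataFrame([["x", 1]], index=["BAD"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="BAD"):
            merge_duplicate_symbols(raw)


class TestCountFilters:
    def test_min_total_counts_boundary_inclusive(self):
        raw = table({"a": [399], "b": [400], "c": [401]}, ["s1"])
        out = filter_min_total_counts(raw, 400)
        assert sorted(out.index) == ["b", "c"]

    def test_threshold_zero_keeps_all(self):
        raw = table({"a": [0], "b": [5]}, ["s1"])
        assert len(filter_min_total_counts(raw, 0)) == 2

    def test_empty_table(self):
        out = filter_min_total_counts(pd.DataFrame(), 400)
        assert out.empty

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            filter_min_total_counts(table({"a": [-1]}, ["s1"]), 0)


class TestLog2:
    def test_values_and_zero_to_missing(self):
        raw = table({"a": [8, 0, 1]}, ["s1", "s2", "s3"])
        m = log2_transform(raw)
        row = m.values.loc["a"]
        assert row["s1"] == 3.0 and row["s3"] == 0.0
        assert np.isnan(row["s2"])
        assert np.isfinite(m.values.to_numpy()[~m.missing_mask.to_numpy()]).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(table({"a": [-2]}, ["s1"]))


class TestMissingnessFilters:
    def test_zero_fraction_strictly_above_removed(self):
        arr = np.ones((2, 40))
        arr[0, :21] = np.nan  # 52.5% missing -> removed
        arr[1, :20] = np.nan  # exactly 50% -> kept
        m = make_matrix(arr)
        out = filter_zero_fraction(m, 0.5)
        assert out.genes == ["g001"]

    def test_valid_fraction_boundary(self):
        arr = np.ones((2, 10))
        arr[0, :2] = np.nan  # 80% valid -> kept at 0.75
        arr[1, :3] = np.nan  # 70% valid -> removed
        out = filter_valid_fraction(make_matrix(arr), 0.75)
        assert out.genes == ["g000"]

    def test_valid_fraction_one_keeps_only_complete(self):
        arr = np.ones((2, 4))
        arr[1, 0] = np.nan
        out = filter_valid_fraction(make_matrix(arr), 1.0)
        assert out.genes == ["g000"]

    def test_raising_valid_fraction_shrinks_gene_set(self, rng):
        arr = rng.normal(size=(30, 20))
        arr[rng.random(arr.shape) < 0.3] = np.nan
        m = make_matrix(arr)
        kept = None
        for vf in (0.5, 0.7, 0.9):
            genes = set(filter_valid_fraction(m, vf).genes)
            if kept is not None:
                assert genes <= kept
            kept = genes


class TestImputation:
    def test_width_zero_is_degenerate_at_downshifted_mean(self):
        arr = np.array([[9.0], [11.0], [np.nan], [np.nan]])
        m = make_matrix(arr)
        out = impute_downshifted_normal(m, impute_width=0.0, impute_downshift=1.8,
                                        seed=0)
        target = 10.0 - 1.8 * np.std([9.0, 11.0], ddof=1)
        assert np.allclose(out.values.to_numpy()[2:, 0], target)

    def test_no_missing_identity(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        out = impute_downshifted_normal(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_observed_cells_bit_unchanged(self, rng):
        arr = rng.normal(8, 2, size=(50, 6))
        mask = rng.random(arr.shape) < 0.2
        arr[mask] = np.nan
        m = make_matrix(arr)
        out = impute_downshifted_normal(m, seed=2)
        assert out.is_complete()
        observed = ~mask
        assert (out.values.to_numpy()[observed] == arr[observed]).all()

    def test_column_with_too_few_observed_rejected(self):
        arr = np.full((3, 2), np.nan)
        arr[:, 0] = 1.0
        arr[0, 1] = 1.0
        with pytest.raises(ValueError, match="s001"):
            impute_downshifted_normal(make_matrix(arr), seed=0)


class TestTopVariable:
    def test_selects_by_sd_and_preserves_order(self, rng):
        arr = rng.normal(size=(10, 30)) * np.arange(1, 11)[:, None]
        m = make_matrix(arr)
        out = select_top_variable(m, 3)
        assert out.genes == ["g007", "g008", "g009"]

    def test_top_n_at_least_gene_count_is_identity(self, rng):
        m = make_matrix(rng.normal(size=(5, 10)))
        pd.testing.assert_frame_equal(select_top_variable(m, 100).values, m.values)

    def test_zero_sd_gene_loses(self):
        arr = np.vstack([np.zeros(10), np.arange(10.0)])
        out = select_top_variable(make_matrix(arr), 1)
        assert out.genes == ["g001"]


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(valid_fraction=1.5)
    with pytest.raises(ValueError):
        PreprocessConfig(top_n=1)
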