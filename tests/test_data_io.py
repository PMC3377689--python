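import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdmrnet import (
    DataTable,
    NoiseConfig,
    add_noise,
    load_table,
    make_pairwise,
    normalize_unit_interval,
    resample,
    split_train_test,
    write_table,
)
from hdmrnet.data_io import ParseError, apply_transform, denormalize_column

SIGNALING_NODES = ["Akt", "Jnk", "Raf", "Erk", "p38", "Mek", "PKA", "PLCg", "PKC", "PIP2", "PIP3"]


class TestLoadTable:
    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_table(p)

    def test_header_without_body_is_parse_error(self, tmp_path):
        p = tmp_path / "hdr.csv"
        p.write_text("a,b\n")
        with pytest.raises(ParseError):
            load_table(p)

    def test_non_numeric_cell_names_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n3,oops\n")
        with pytest.raises(ParseError, match="b"):
            load_table(p)

    def test_duplicate_node_name_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("a,a\n1,2\n3,4\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_table(p)

    def test_round_trip_identity(self, tmp_path, tiny_table):
        p = tmp_path / "t.csv"
        write_table(tiny_table, p)
        back = load_table(p, condition_id="tiny")
        pd.testing.assert_frame_equal(back.values, tiny_table.values)
        assert back.node_names == tiny_table.node_names

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("a\tb\n1\t2\n3\t4\n")
        t = load_table(p)
        assert t.node_names == ["a", "b"] and t.n_samples == 2

    def test_eleven_node_signaling_panel(self, tmp_path, rng):
        """A cytometry-style table of 11 phosphoprotein/phospholipid nodes."""
        df = pd.DataFrame(rng.uniform(10, 500, size=(20, 11)), columns=SIGNALING_NODES)
        p = tmp_path / "cells.csv"
        df.to_csv(p, index=False)
        t = load_table(p, condition_id="d1")
        assert t.n_nodes == 11 and t.node_names == SIGNALING_NODES


class TestNormalize:
    def test_linear_rescale(self):
        t = DataTable(values=pd.DataFrame({"a": [0.0, 5.0, 10.0]}))
        out = normalize_unit_interval(t)
        assert np.allclose(out.values["a"], [0.0, 0.5, 1.0])
        assert out.transforms["a"] == (0.0, 10.0)

    def test_already_unit_interval_unchanged(self):
        t = DataTable(values=pd.DataFrame({"a": [0.0, 0.25, 1.0]}))
        out = normalize_unit_interval(t)
        assert np.allclose(out.values["a"], [0.0, 0.25, 1.0])

    def test_constant_column_error_names_node(self):
        t = DataTable(values=pd.DataFrame({"Raf": [3.0, 3.0, 3.0], "b": [0.0, 1.0, 2.0]}))
        with pytest.raises(ValueError, match="Raf"):
            normalize_unit_interval(t)

    def test_double_normalization_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="already"):
            normalize_unit_interval(normalize_unit_interval(tiny_table))

    def test_out_of_range_points_clamped_with_warning(self, tiny_table):
        out = normalize_unit_interval(tiny_table)
        with pytest.warns(UserWarning, match="clamped"):
            z = apply_transform(np.array([-5.0, 20.0]), out.transforms["a"], node="a")
        assert z.min() == 0.0 and z.max() == 1.0

    @given(
        vals=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=3, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_transform_is_invertible(self, vals):
        x = np.asarray(vals)
        if np.ptp(x) < 1e-9:
            return
        t = normalize_unit_interval(DataTable(values=pd.DataFrame({"a": x})))
        back = denormalize_column(t.values["a"].to_numpy(), t.transforms["a"])
        assert np.allclose(back, x, atol=1e-6 * max(1.0, np.abs(x).max()))


class TestPairwise:
    def _pair(self, rng, n_ctrl=6, n_pert=4):
        cols = ["PKA", "Erk"]
        c = DataTable(pd.DataFrame(rng.uniform(0, 1, (n_ctrl, 2)), columns=cols), "ctrl")
        p = DataTable(pd.DataFrame(rng.uniform(0, 1, (n_pert, 2)), columns=cols), "act")
        return c, p

    def test_activated_overwrites_control_low_perturbed_high(self, rng):
        c, p = self._pair(rng)
        pw = make_pairwise(c, p, "PKA", "activated")
        col = pw.values["PKA"].to_numpy()
        assert np.all(col[:6] == 0.0) and np.all(col[6:] == 1.0)
        assert np.array_equal(pw.class_labels, col)

    def test_inhibited_swaps_roles(self, rng):
        c, p = self._pair(rng)
        pw = make_pairwise(c, p, "PKA", "inhibited")
        col = pw.values["PKA"].to_numpy()
        assert np.all(col[:6] == 1.0) and np.all(col[6:] == 0.0)

    def test_class_counts_match_input_row_counts(self, rng):
        c, _ = self._pair(rng)
        pw = make_pairwise(c, c, "Erk", "activated")
        assert pw.n_samples == 12
        assert int(pw.class_labels.sum()) == 6

    def test_missing_node_and_mismatched_names_error(self, rng):
        c, p = self._pair(rng)
        with pytest.raises(ValueError, match="XYZ"):
            make_pairwise(c, p, "XYZ")
        other = DataTable(pd.DataFrame(rng.uniform(0, 1, (4, 2)), columns=["A", "B"]), "x")
        with pytest.raises(ValueError, match="node names"):
            make_pairwise(c, other, "PKA")


class TestSplit:
    def test_disjoint_partition_counts(self, rng):
        t = DataTable(pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2}))
        tr, te = split_train_test(t, 0.7, seed=5)
        assert tr.n_samples == 7 and te.n_samples == 3
        union = set(tr.values["a"]) | set(te.values["a"])
        assert union == set(t.values["a"])
        assert not set(tr.values["a"]) & set(te.values["a"])

    def test_same_seed_same_partition(self):
        t = DataTable(pd.DataFrame({"a": np.arange(20.0), "b": np.arange(20.0)}))
        a = split_train_test(t, 0.5, seed=9)
        b = split_train_test(t, 0.5, seed=9)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_degenerate_fraction_rejected(self, fraction):
        t = DataTable(pd.DataFrame({"a": np.arange(10.0)}))
        with pytest.raises(ValueError):
            split_train_test(t, fraction, seed=0)


class TestNoise:
    def test_zero_scale_is_identity(self, tiny_table):
        out = add_noise(tiny_table, NoiseConfig("additive", 0.0, seed=3))
        pd.testing.assert_frame_equal(out.values, tiny_table.values)

    def test_additive_noise_scales_with_column_sd(self, rng):
        n = 100_000
        df = pd.DataFrame({"a": rng.normal(50, 4.0, n), "b": rng.normal(0, 20.0, n)})
        t = DataTable(df)
        out = add_noise(t, NoiseConfig("additive", 0.1, seed=7))
        for col in df.columns:
            delta = out.values[col] - df[col]
            target = 0.1 * df[col].std(ddof=0)
            assert abs(delta.std(ddof=0) - target) < 0.05 * target

    def test_multiplicative_noise_is_proportional(self, rng):
        n = 100_000
        df = pd.DataFrame({"a": np.full(n, 10.0) + rng.uniform(0, 1e-9, n)})
        out = add_noise(DataTable(df), NoiseConfig("multiplicative", 0.05, seed=2))
        ratio = out.values["a"] / df["a"] - 1.0
        assert abs(ratio.std(ddof=0) - 0.05) < 0.05 * 0.05

    def test_reproducible_under_seed(self, tiny_table):
        a = add_noise(tiny_table, NoiseConfig("additive", 0.3, seed=11))
        b = add_noise(tiny_table, NoiseConfig("additive", 0.3, seed=11))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_bad_mode_and_scale_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig("weird", 0.1)
        with pytest.raises(ValueError):
            NoiseConfig("additive", -0.1)


class TestResample:
    def test_quarter_subsample(self, rng):
        t = DataTable(pd.DataFrame({"a": np.arange(400.0), "b": np.arange(400.0)}))
        out = resample(t, "subsample", 0.25, seed=5)
        assert out.n_samples == 100
        assert set(out.values["a"]).issubset(set(t.values["a"]))

    def test_tenfold_oversample(self, rng):
        t = DataTable(pd.DataFrame(rng.uniform(0, 1, (95, 3)), columns=list("abc")))
        out = resample(t, "oversample", 10, jitter_sd=0.05, seed=5)
        assert out.n_samples == 950

    def test_oversample_centroid_is_original_row(self, rng):
        t = DataTable(pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 6.0]}))
        out = resample(t, "oversample", 5000, jitter_sd=0.1, seed=5)
        first = out.values.iloc[:5000]
        assert np.allclose(first.mean(), [1.0, 5.0], atol=0.01)

    def test_unit_oversample_no_jitter_is_identity(self, tiny_table):
        out = resample(tiny_table, "oversample", 1, jitter_sd=0.0, seed=0)
        assert np.allclose(out.values.to_numpy(), tiny_table.values.to_numpy())

    def test_invalid_factor_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            resample(tiny_table, "subsample", 1.5)
        with pytest.raises(ValueError):
            resample(tiny_table, "oversample", 2.5)
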