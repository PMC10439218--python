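"""Grid lattice, resampling and collinearity screening."""

import numpy as np
import pytest

from aquamap.grid import (
    CATEGORICAL, NUMERICAL, FeatureLayer, FeatureStack, GridSpec,
    build_cell_table, correlation_screen, cramers_v, eta_squared,
    load_stack, resample_layer, save_stack,
)


def _grid(n, cell=1.0, mask=None):
    return GridSpec(n, n, cell, mask)


class TestResample:
    @pytest.mark.parametrize("dst_n", [2, 3, 8])
    def test_constant_layer_stays_constant(self, dst_n):
        src = _grid(4)
        layer = FeatureLayer("c", NUMERICAL, np.full(16, 7.0))
        out = resample_layer(layer, src, _grid(dst_n, cell=4.0 / dst_n))
        assert np.allclose(out.values, 7.0)

    def test_bilinear_matches_bruteforce_oracle(self):
        # 2x2 layer [[0,2],[0,2]] upsampled to 4x4: the value depends only on
        # the x coordinate; a hand bilinear evaluation over the 4 corners with
        # edge clamping gives [0, 0.5, 1.5, 2] in every row.
        src = GridSpec(2, 2, 1.0)
        dst = GridSpec(4, 4, 0.5)
        layer = FeatureLayer("v", NUMERICAL, [0.0, 2.0, 0.0, 2.0])
        out = resample_layer(layer, src, dst).values.reshape(4, 4)
        xs = np.clip(np.array([0.25, 0.75, 1.25, 1.75]), 0.5, 1.5)
        expected_row = (xs - 0.5) / 1.0 * 2.0
        assert np.allclose(out, np.tile(expected_row, (4, 1)))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_categorical_upsampling_invents_no_codes(self, seed):
        rng = np.random.default_rng(seed)
        src = _grid(5)
        layer = FeatureLayer("k", CATEGORICAL, rng.integers(0, 4, 25))
        out = resample_layer(layer, src, _grid(20, cell=0.25))
        assert set(out.values) <= set(layer.values)

    @pytest.mark.parametrize("kind", [NUMERICAL, CATEGORICAL])
    def test_identity_resampling(self, kind):
        rng = np.random.default_rng(3)
        src = _grid(7)
        vals = rng.normal(size=49) if kind == NUMERICAL else rng.integers(0, 3, 49)
        out = resample_layer(FeatureLayer("x", kind, vals), src, src)
        if kind == NUMERICAL:
            assert np.allclose(out.values, vals, atol=1e-12)
        else:
            assert np.array_equal(out.values, vals)

    def test_extent_mismatch_and_degenerate_grid(self):
        layer = FeatureLayer("x", NUMERICAL, np.zeros(16))
        with pytest.raises(ValueError, match="extent"):
            resample_layer(layer, _grid(4), _grid(5))
        with pytest.raises(ValueError):
            GridSpec(0, 4)


class TestAssociationStatistics:
    def test_cramers_v_from_hand_computed_chi_square(self):
        # joint 2x2 table [[30,10],[10,30]]: chi2 = 20, n = 80, V = 0.5
        a = np.repeat([0, 0, 1, 1], [40, 0, 40, 0])
        b = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        assert cramers_v(a, b) == pytest.approx(0.5)

    def test_cramers_v_of_layer_with_itself_is_one(self):
        a = np.random.default_rng(0).integers(0, 3, 200)
        assert cramers_v(a, a) == pytest.approx(1.0)

    def test_eta_squared_of_deterministic_binning_refines_to_one(self):
        x = np.random.default_rng(1).normal(size=500)
        coarse = np.digitize(x, np.quantile(x, [0.5]))
        fine = np.digitize(x, np.quantile(x, np.linspace(0, 1, 40)[1:-1]))
        e_coarse, e_fine = eta_squared(x, coarse), eta_squared(x, fine)
        assert e_coarse < e_fine
        assert e_fine > 0.99


class TestCorrelationScreen:
    def _stack(self, layers):
        n = layers[0].values.size
        side = int(np.sqrt(n))
        return FeatureStack(GridSpec(side, side), layers)

    def test_duplicated_layer_detected_and_one_copy_dropped(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=100)
        stack = self._stack([
            FeatureLayer("a", NUMERICAL, v),
            FeatureLayer("b", NUMERICAL, v.copy()),
            FeatureLayer("c", NUMERICAL, rng.normal(size=100)),
        ])
        out, report = correlation_screen(stack)
        rec = [r for r in report.pairs if {r["layer_a"], r["layer_b"]} == {"a", "b"}][0]
        assert rec["value"] == pytest.approx(1.0)
        assert rec["dropped_layer"] in ("a", "b")
        assert len(out.layers) == 2 and "c" in out.names

    def test_independent_normals_not_dropped(self):
        rng = np.random.default_rng(7)
        stack = self._stack([
            FeatureLayer("a", NUMERICAL, rng.standard_normal(10000)),
            FeatureLayer("b", NUMERICAL, rng.standard_normal(10000)),
        ])
        out, report = correlation_screen(stack)
        assert abs(report.pairs[0]["value"]) < 0.05
        assert len(out.layers) == 2

    def test_screening_is_idempotent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=400)
        stack = self._stack([
            FeatureLayer("a", NUMERICAL, base),
            FeatureLayer("b", NUMERICAL, base + 0.1 * rng.normal(size=400)),
            FeatureLayer("c", NUMERICAL, rng.normal(size=400)),
            FeatureLayer("d", CATEGORICAL, rng.integers(0, 3, 400)),
        ])
        survived, _ = correlation_screen(stack)
        again, report = correlation_screen(survived)
        assert again.names == survived.names
        assert all(r["dropped_layer"] is None for r in report.pairs)

    def test_constant_layer_pair_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        stack = self._stack([
            FeatureLayer("const", NUMERICAL, np.full(100, 3.0)),
            FeatureLayer("x", NUMERICAL, rng.normal(size=100)),
        ])
        with pytest.warns(UserWarning, match="skipping pair"):
            out, report = correlation_screen(stack)
        assert len(out.layers) == 2
        assert report.pairs == []


class TestCellTable:
    def test_one_hot_encoding_width(self):
        grid = GridSpec(2, 2)
        stack = FeatureStack(grid, [
            FeatureLayer("num", NUMERICAL, [0.1, 0.2, 0.3, 0.4]),
            FeatureLayer("cat", CATEGORICAL, [0, 1, 2, 1]),
        ])
        pop = FeatureLayer("population", NUMERICAL, np.ones(4))
        strata = FeatureLayer("stratum", CATEGORICAL, [1, 1, 0, 0])
        table = build_cell_table(stack, pop, strata)
        assert len(table.feature_cols) == 4  # 1 numeric + 3 one-hot
        assert table.groups["cat"] == ["cat=0", "cat=1", "cat=2"]

    def test_empty_mask_is_an_error(self):
        grid = GridSpec(2, 2, mask=np.zeros(4, dtype=bool))
        stack = FeatureStack(grid, [FeatureLayer("x", NUMERICAL, np.zeros(4))])
        with pytest.raises(ValueError, match="empty mask"):
            build_cell_table(stack, FeatureLayer("p", NUMERICAL, np.zeros(4)),
                             FeatureLayer("s", CATEGORICAL, np.zeros(4, dtype=int)))

    def test_all_urban_strata_and_unknown_code(self):
        grid = GridSpec(2, 2)
        stack = FeatureStack(grid, [FeatureLayer("x", NUMERICAL, np.arange(4.0))])
        pop = FeatureLayer("population", NUMERICAL, np.ones(4))
        table = build_cell_table(stack, pop, FeatureLayer("s", CATEGORICAL, [1] * 4))
        assert (table.df["stratum"] == "urban").all()
        with pytest.raises(ValueError, match="unknown stratum"):
            build_cell_table(stack, pop, FeatureLayer("s", CATEGORICAL, [1, 2, 1, 1]))

    def test_drop_feature_removes_column_group(self, tiny_table):
        dropped = tiny_table.drop_feature("f")
        assert "f" not in dropped.feature_cols
        assert "f" in tiny_table.feature_cols  # original untouched


def test_stack_round_trips_through_csv(tmp_path):
    rng = np.random.default_rng(9)
    mask = rng.random(36) > 0.2
    grid = GridSpec(6, 6, mask=mask)
    stack = FeatureStack(grid, [
        FeatureLayer("n0", NUMERICAL, rng.normal(size=36)),
        FeatureLayer("c0", CATEGORICAL, rng.integers(0, 3, 36)),
    ])
    save_stack(stack, tmp_path / "stack")
    loaded = load_stack(tmp_path / "stack")
    assert loaded.names == stack.names
    assert np.array_equal(loaded.grid.mask, mask)
    assert np.allclose(loaded["n0"].values, stack["n0"].values)
    assert np.array_equal(loaded["c0"].values, stack["c0"].values)
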