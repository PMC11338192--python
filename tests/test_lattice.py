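import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spotzone import (
    BarcodeGrid,
    Grid,
    ZonationParams,
    annotate_spots_with_zones,
    assign_zones,
    build_label_grids,
    composite_score,
    moving_average,
    zonate,
    zonate_sample,
)
from spotzone.lattice import delta_sweep

from conftest import (
    brute_force_moving_average,
    full_grid_spots,
    half_plane_spots,
    random_class_grid,
    spots_from_class_grid,
)

PARAMS = ZonationParams()
ORDINAL = {name: i for i, name in enumerate(PARAMS.zone_names)}


class TestBuildLabelGrids:
    def test_single_tumor_spot_maps_to_all_three_grids(self):
        spots = pd.DataFrame(
            {"barcode": ["bc1"], "array_row": [5], "array_col": [7], "tissue_class": [1]}
        )
        tumor, parenchyma, barcodes = build_label_grids(spots)
        assert tumor.values[0, 0] == 1
        assert parenchyma.values[0, 0] == 0
        assert barcodes.values[0, 0] == "bc1"
        assert (tumor.row_offset, tumor.col_offset) == (5, 7)

    def test_three_spot_toy_matches_hand_enumeration(self):
        spots = pd.DataFrame(
            {
                "barcode": ["a", "b", "c"],
                "array_row": [1, 1, 2],
                "array_col": [1, 3, 2],
                "tissue_class": [1, 0, 1],
            }
        )
        tumor, parenchyma, barcodes = build_label_grids(spots)
        expected_tumor = np.array([[1.0, np.nan, 0.0], [np.nan, 1.0, np.nan]])
        np.testing.assert_array_equal(tumor.values, expected_tumor)
        np.testing.assert_array_equal(parenchyma.values, 1 - expected_tumor)
        assert int(tumor.occupied.sum()) == 3
        assert barcodes.values[0, 0] == "a"
        assert barcodes.values[0, 2] == "b"
        assert barcodes.values[1, 1] == "c"

    def test_unoccupied_positions_missing_everywhere(self):
        spots = spots_from_class_grid([[1, np.nan], [np.nan, 0]])
        tumor, parenchyma, barcodes = build_label_grids(spots)
        assert np.isnan(tumor.values[0, 1]) and np.isnan(parenchyma.values[0, 1])
        assert barcodes.values[0, 1] is None

    def test_duplicate_coordinates_error_names_barcodes(self):
        spots = pd.DataFrame(
            {
                "barcode": ["x", "y"],
                "array_row": [1, 1],
                "array_col": [2, 2],
                "tissue_class": [0, 1],
            }
        )
        with pytest.raises(ValueError, match="x.*y"):
            build_label_grids(spots)

    def test_non_integer_coordinates_rejected(self):
        spots = pd.DataFrame(
            {"barcode": ["a"], "array_row": [1.5], "array_col": [2], "tissue_class": [1]}
        )
        with pytest.raises(ValueError, match="non-integer"):
            build_label_grids(spots)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_complement_symmetry_under_class_flip(self, seed):
        cg = random_class_grid(np.random.default_rng(seed))
        spots = spots_from_class_grid(cg)
        tumor, parenchyma, _ = build_label_grids(spots)
        flipped = spots.assign(tissue_class=1 - spots["tissue_class"])
        tumor_f, parenchyma_f, _ = build_label_grids(flipped)
        np.testing.assert_array_equal(tumor.values, parenchyma_f.values)
        np.testing.assert_array_equal(parenchyma.values, tumor_f.values)


class TestMovingAverage:
    def test_all_ones_grid_stays_one_even_at_clipped_edges(self, grid_factory):
        out = moving_average(grid_factory(np.ones((7, 7))), delta=2)
        np.testing.assert_allclose(out.values, 1.0)

    def test_corner_impulse_delta_one(self, grid_factory):
        v = np.zeros((3, 3))
        v[0, 0] = 1.0
        out = moving_average(grid_factory(v), delta=1)
        assert out.values[0, 0] == pytest.approx(1 / 4)
        assert out.values[1, 1] == pytest.approx(1 / 9)
        assert out.values[2, 2] == pytest.approx(0.0)

    def test_missing_cells_are_skipped_not_counted(self, grid_factory):
        out = moving_average(grid_factory([[1.0, np.nan, 0.0]]), delta=1)
        np.testing.assert_allclose(out.values, [[1.0, 0.5, 0.0]])

    def test_all_missing_window_stays_missing(self, grid_factory):
        v = np.full((5, 5), np.nan)
        v[0, 0] = 1.0
        out = moving_average(grid_factory(v), delta=1)
        assert np.isnan(out.values[3:, 3:]).all()

    def test_edge_policy_missing_blanks_the_border(self, grid_factory):
        out = moving_average(grid_factory(np.ones((5, 5))), delta=1, edge_policy="missing")
        assert np.isnan(out.values[0]).all() and np.isnan(out.values[:, -1]).all()
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 1.0)

    @pytest.mark.parametrize("delta", [0, -1])
    def test_invalid_delta_rejected(self, grid_factory, delta):
        with pytest.raises(ValueError):
            moving_average(grid_factory(np.ones((3, 3))), delta=delta)

    def test_empty_grid_rejected(self, grid_factory):
        with pytest.raises(ValueError):
            moving_average(grid_factory(np.empty((0, 0))), delta=1)

    @pytest.mark.parametrize("edge_policy", ["clip", "missing"])
    def test_matches_brute_force_oracle_on_random_grids(self, grid_factory, edge_policy):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cg = random_class_grid(rng)
            delta = int(rng.integers(1, 4))
            ours = moving_average(grid_factory(cg), delta, edge_policy).values
            oracle = brute_force_moving_average(cg, delta, edge_policy)
            np.testing.assert_allclose(ours, oracle, atol=1e-12, equal_nan=True)


class TestCompositeScore:
    def test_all_tumor_grid_scores_three_everywhere(self):
        tumor, _, _ = build_label_grids(full_grid_spots(20, 20, 1))
        comp = composite_score(tumor, tumor, (2, 1), (2, 3))
        np.testing.assert_allclose(comp.values, 3.0)

    def test_all_parenchyma_grid_scores_two_point_one(self):
        _, parenchyma, _ = build_label_grids(full_grid_spots(20, 20, 0))
        comp = composite_score(parenchyma, parenchyma, (2, 0.1), (2, 3))
        np.testing.assert_allclose(comp.values, 2.1)

    def test_straight_boundary_column_values(self):
        spots = half_plane_spots(n=40, cut=20)
        tumor, parenchyma, _ = build_label_grids(spots)
        ts = composite_score(tumor, tumor, (2, 1), (2, 3))
        ps = composite_score(parenchyma, parenchyma, (2, 0.1), (2, 3))
        # boundary-most tumor column: 2*(3/5) + 1*(4/7); parenchyma: 2*(3/5) + 0.1*(4/7)
        assert ts.values[20, 19] == pytest.approx(62 / 35)
        assert ps.values[20, 20] == pytest.approx(2 * 3 / 5 + 0.1 * 4 / 7)
        assert ts.values[20, 20] == 0.0  # masked to tumor
        assert ps.values[20, 19] == 0.0  # masked to parenchyma

    def test_shape_mismatch_rejected(self, grid_factory):
        with pytest.raises(ValueError, match="shape"):
            composite_score(grid_factory(np.ones((3, 3))), grid_factory(np.ones((4, 3))))


def _score_grids(tumor_scores, parenchyma_scores):
    ts = np.asarray(tumor_scores, dtype=float)
    ps = np.asarray(parenchyma_scores, dtype=float)
    barcodes = np.empty(ts.shape, dtype=object)
    occ = np.isfinite(ts)
    barcodes[occ] = [f"b{i}" for i in range(int(occ.sum()))]
    return Grid(ts), Grid(ps), BarcodeGrid(barcodes)


class TestAssignZones:
    def test_threshold_examples(self):
        ts, ps, bc = _score_grids([[2.97, 0.0, 62 / 35]], [[0.0, 2.1, 0.0]])
        _, table = assign_zones(ts, ps, bc)
        assert list(table["zone"]) == ["Zone_A", "Zone_H", "Zone_D"]

    def test_unoccupied_cells_yield_no_rows(self):
        ts, ps, bc = _score_grids([[3.0, np.nan]], [[0.0, np.nan]])
        zone_grid, table = assign_zones(ts, ps, bc)
        assert len(table) == 1
        assert zone_grid[0, 1] is None

    def test_both_scores_positive_is_a_mask_violation(self):
        ts, ps, bc = _score_grids([[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="mask"):
            assign_zones(ts, ps, bc)

    def test_table_rows_carry_array_coordinates(self):
        ts, ps, bc = _score_grids([[3.0]], [[0.0]])
        ts.row_offset = ps.row_offset = bc.row_offset = 10
        ts.col_offset = ps.col_offset = bc.col_offset = 20
        _, table = assign_zones(ts, ps, bc)
        assert (table.loc[0, "row"], table.loc[0, "col"]) == (10, 20)

    def test_matches_sequential_threshold_overwrite_script(self):
        """Interval assignment equals the in-place overwrite sequence."""
        M1, M2, M3 = PARAMS.tumor_cuts
        L1, L2, L3 = PARAMS.parenchyma_cuts
        rng = np.random.default_rng(7)
        for _ in range(1000):
            shape = (rng.integers(2, 9), rng.integers(2, 9))
            is_tumor = rng.random(shape) < 0.5
            occupied = rng.random(shape) < 0.8
            ts = np.where(occupied & is_tumor, rng.uniform(1e-9, 3.0, shape), 0.0)
            ps = np.where(occupied & ~is_tumor, rng.uniform(1e-9, 2.1, shape), 0.0)
            ts[~occupied] = np.nan
            ps[~occupied] = np.nan

            t = ts.copy()
            t[t > M1] = -4
            t[(t <= M1) & (t > M2)] = -3
            t[(t <= M2) & (t > M3)] = -2
            t[(t <= M3) & (t > 0)] = -1
            p = ps.copy()
            p[(p <= L3) & (p > 0)] = 0
            p[(p <= L2) & (p > L3)] = 1
            p[(p <= L1) & (p > L2)] = 2
            p[p > L1] = 3
            combined = t + p
            names = np.asarray(PARAMS.zone_names, dtype=object)
            expected = np.full(shape, None, dtype=object)
            expected[occupied] = names[(combined[occupied] + 4).astype(int)]

            grid_ts, grid_ps, bc = _score_grids(ts, ps)
            zone_grid, _ = assign_zones(grid_ts, grid_ps, bc)
            np.testing.assert_array_equal(zone_grid, expected)

    def test_more_cuts_give_more_zones(self):
        params = ZonationParams(
            tumor_cuts=(2.96, 2.7, 2.5, 2.3),
            zone_names=tuple("Zone_" + c for c in "ABCDEFGHI"),
        )
        ts, ps, bc = _score_grids([[2.97, 2.6, 2.4]], [[0.0, 0.0, 0.0]])
        _, table = assign_zones(ts, ps, bc, params)
        assert list(table["zone"]) == ["Zone_A", "Zone_C", "Zone_D"]


class TestZonationPipeline:
    def test_conservation_tumor_spots_fill_zones_a_to_d(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cg = random_class_grid(rng, max_side=12)
            spots = spots_from_class_grid(cg)
            table, _ = zonate_sample(spots)
            tumor_zones = set(PARAMS.zone_names[:4])
            n_tumor_assigned = table["zone"].isin(tumor_zones).sum()
            assert n_tumor_assigned == spots["tissue_class"].sum()
            assert len(table) == len(spots)

    def test_degenerate_all_tumor_is_all_zone_a(self):
        table, _ = zonate_sample(full_grid_spots(10, 10, 1))
        assert (table["zone"] == "Zone_A").all()

    def test_degenerate_all_parenchyma_is_all_zone_h(self):
        table, _ = zonate_sample(full_grid_spots(10, 10, 0))
        assert (table["zone"] == "Zone_H").all()

    def test_zone_ordinal_monotone_across_straight_boundary(self):
        spots = half_plane_spots(n=40, cut=20)
        table, _ = zonate_sample(spots)
        for row in range(10, 30):
            line = table[table["row"] == row].sort_values("col")
            ordinals = [ORDINAL[z] for z in line["zone"]]
            assert ordinals == sorted(ordinals)

    def test_translation_invariance_of_zone_assignment(self):
        spots = half_plane_spots(n=15, cut=7)
        table, _ = zonate_sample(spots)
        shifted = spots.assign(
            array_row=spots["array_row"] + 13, array_col=spots["array_col"] + 5
        )
        table_shifted, _ = zonate_sample(shifted)
        merged = table.merge(table_shifted, on="barcode", suffixes=("", "_s"))
        assert (merged["zone"] == merged["zone_s"]).all()

    def test_padding_with_missing_rows_changes_nothing(self):
        spots = half_plane_spots(n=12, cut=6)
        tumor, parenchyma, barcodes = build_label_grids(spots)
        pad = 4
        shape = (tumor.shape[0] + 2 * pad, tumor.shape[1] + 2 * pad)

        def padded(values, fill):
            out = np.full(shape, fill, dtype=values.dtype)
            out[pad:-pad, pad:-pad] = values
            return out

        tumor_p = Grid(padded(tumor.values, np.nan), -pad, -pad)
        parenchyma_p = Grid(padded(parenchyma.values, np.nan), -pad, -pad)
        barcodes_p = BarcodeGrid(padded(barcodes.values, None), -pad, -pad)

        def run(t, p, b):
            ts = composite_score(t, t, PARAMS.tumor_weights, (2, 3))
            ps = composite_score(p, p, PARAMS.parenchyma_weights, (2, 3))
            return assign_zones(ts, ps, b)[1]

        base = run(tumor, parenchyma, barcodes)
        padded_table = run(tumor_p, parenchyma_p, barcodes_p)
        merged = base.merge(padded_table, on="barcode", suffixes=("", "_p"))
        assert (merged["zone"] == merged["zone_p"]).all()
        assert (merged["row"] == merged["row_p"]).all()

    def test_hex_lattice_checkerboard_positions_are_missing(self):
        spots = full_grid_spots(8, 8, 1)
        hexed = spots[(spots["array_row"] + spots["array_col"]) % 2 == 0]
        tumor, _, _ = build_label_grids(hexed)
        assert int(tumor.occupied.sum()) == len(hexed)
        table, _ = zonate_sample(hexed)
        assert len(table) == len(hexed)

    def test_delta_sweep_returns_unmasked_grid_per_delta(self):
        tumor, _, _ = build_label_grids(half_plane_spots(n=20, cut=10))
        sweep = delta_sweep(tumor, deltas=(1, 2))
        assert set(sweep) == {1, 2}
        # unmasked: parenchyma-side cells still carry smoothed tumor signal
        assert sweep[1].values[10, 10] > 0


class TestAnnotate:
    def _spots(self):
        return pd.DataFrame(
            {
                "barcode": ["a", "b", "a"],
                "sample_id": ["s1", "s1", "s2"],
                "group": "Ctrl",
            }
        )

    def test_zone_joined_by_sample_and_barcode(self):
        tables = {
            "s1": pd.DataFrame({"barcode": ["a", "b"], "zone": ["Zone_C", "Zone_E"]}),
            "s2": pd.DataFrame({"barcode": ["a"], "zone": ["Zone_H"]}),
        }
        out = annotate_spots_with_zones(self._spots(), tables)
        assert list(out["zone"]) == ["Zone_C", "Zone_E", "Zone_H"]

    def test_row_order_of_tables_is_irrelevant(self):
        tables = {
            "s1": pd.DataFrame({"barcode": ["b", "a"], "zone": ["Zone_E", "Zone_C"]}),
            "s2": pd.DataFrame({"barcode": ["a"], "zone": ["Zone_H"]}),
        }
        out = annotate_spots_with_zones(self._spots(), tables)
        assert list(out["zone"]) == ["Zone_C", "Zone_E", "Zone_H"]

    def test_missing_barcode_is_an_error_not_a_default_zone(self):
        tables = {
            "s1": pd.DataFrame({"barcode": ["a"], "zone": ["Zone_C"]}),
            "s2": pd.DataFrame({"barcode": ["a"], "zone": ["Zone_H"]}),
        }
        with pytest.raises(KeyError, match="'b'"):
            annotate_spots_with_zones(self._spots(), tables)

    def test_multi_sample_zonate_never_crosses_samples(self):
        s1 = half_plane_spots(n=8, cut=4, sample_id="s1")
        s2 = full_grid_spots(8, 8, 1, sample_id="s2")
        s2 = s2.assign(barcode=s1["barcode"].values)  # colliding barcode strings
        annotated, tables = zonate(pd.concat([s1, s2], ignore_index=True))
        assert set(tables) == {"s1", "s2"}
        z2 = annotated[annotated["sample_id"] == "s2"]["zone"]
        assert (z2 == "Zone_A").all()
        z1 = annotated[annotated["sample_id"] == "s1"]["zone"]
        assert z1.nunique() > 1


class TestZonationParams:
    def test_defaults_match_protocol_constants(self):
        p = ZonationParams()
        assert (p.delta_small, p.delta_large) == (2, 3)
        assert p.tumor_cuts == (2.96, 2.7, 2.3)
        assert p.parenchyma_cuts == (2.095, 1.91, 1.7)
        assert p.tumor_score_max == 3.0
        assert p.parenchyma_score_max == pytest.approx(2.1)
        assert len(p.zone_names) == 8

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta_small": 0},
            {"tumor_cuts": (2.3, 2.7)},
            {"tumor_cuts": (2.96, 2.7)},  # name count mismatch
            {"zone_names": ("Z",) * 8, "tumor_cuts": (1.0,)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ZonationParams(**kwargs)
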