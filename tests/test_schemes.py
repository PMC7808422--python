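"""Sampling-scheme layouts: hand-enumerated fixtures and grid invariants."""

import numpy as np
import pytest

import pollenflow as pf


def test_transect_columns_follow_even_spacing_rule():
    geo = pf.FieldGeometry(n_rows=10, n_cols=10, plot_depth_m=2.5, plot_width_m=0.75)
    assert pf.layout_transects(geo, 2).params["transect_cols"] == (2, 7)


def test_requested_distance_maps_to_nearest_row():
    geo = pf.FieldGeometry(n_rows=10, n_cols=10, plot_depth_m=2.5, plot_width_m=0.75)
    # |3 - 2.5| < |3 - 5| -> row 1
    assert pf.layout_transects(geo, 1, (3,)).positions == ((1, 5),)
    # exact tie 1.25 m between rows 0 and 1 -> smaller row
    assert pf.layout_transects(geo, 1, (1.25,)).positions == ((0, 5),)


def test_single_transect_at_zero_distance_is_one_edge_plot():
    geo = pf.FieldGeometry(n_rows=4, n_cols=10, plot_depth_m=2.5, plot_width_m=0.75)
    layout = pf.layout_transects(geo, 1, (0,))
    assert layout.positions == ((0, 5),)


def test_two_transect_fixture_on_6x6(geo6):
    layout = pf.layout_transects(geo6, 2, (0, 3))
    assert layout.positions == ((0, 1), (1, 1), (0, 4), (1, 4))


def test_four_transect_columns_on_6x6(geo6):
    assert pf.layout_transects(geo6, 4).params["transect_cols"] == (1, 2, 4, 5)


def test_duplicate_distances_collapse(geo6):
    layout = pf.layout_transects(geo6, 2, (0, 0.5, 3))  # 0 and 0.5 both -> row 0
    assert layout.n == 4


def test_cross_fixture_on_5x5():
    geo = pf.FieldGeometry(n_rows=5, n_cols=5, plot_depth_m=1.0, plot_width_m=1.0)
    layout = pf.layout_cross(geo, sample_distances_m=(0, 1, 2, 3, 4), lateral_col_step=1)
    expected = {(r, 2) for r in range(5)} | {(2, c) for c in range(5)}
    assert set(layout.positions) == expected
    assert layout.n == 9  # shared centre counted once


def test_cross_on_single_plot_grid():
    geo = pf.FieldGeometry(n_rows=1, n_cols=1, plot_depth_m=1.0, plot_width_m=1.0)
    assert pf.layout_cross(geo, (0,), 1).positions == ((0, 0),)


def test_cross_centre_column_uses_lower_median():
    geo = pf.FieldGeometry(n_rows=5, n_cols=40, plot_depth_m=1.0, plot_width_m=1.0)
    assert pf.layout_cross(geo).params["center_col"] == 19


def test_v_fixture_on_3x3():
    geo = pf.FieldGeometry(n_rows=3, n_cols=3, plot_depth_m=2.5, plot_width_m=0.75)
    layout = pf.layout_v(geo, n_per_arm=3)
    assert set(layout.positions) == {(0, 0), (1, 1), (2, 1), (0, 2)}


def test_v_fixture_on_5x5():
    geo = pf.FieldGeometry(n_rows=5, n_cols=5, plot_depth_m=1.0, plot_width_m=1.0)
    layout = pf.layout_v(geo, n_per_arm=4)
    assert set(layout.positions) == {
        (0, 0), (1, 1), (3, 1), (4, 2), (0, 4), (1, 3), (3, 3),
    }


def test_v_arms_meet_on_far_row():
    geo = pf.preset("2009-1").geometry
    layout = pf.layout_v(geo, n_per_arm=10)
    rows = [r for r, _ in layout.positions]
    assert max(rows) == geo.n_rows - 1
    assert layout.n <= 20


def test_v_rejects_single_row_grid():
    geo = pf.FieldGeometry(n_rows=1, n_cols=5, plot_depth_m=1.0, plot_width_m=1.0)
    with pytest.raises(ValueError, match="single-row"):
        pf.layout_v(geo, 3)


def test_jm_fixture_on_6x6(geo6):
    # trisection cols/rows {2, 4}; offsets 0 m -> index 0/5, 3 m -> index 1/4
    layout = pf.layout_jm(geo6, "low")
    expected = (
        {(r, c) for c in (2, 4) for r in (0, 1, 4, 5)}
        | {(r, c) for r in (2, 4) for c in (0, 1, 4, 5)}
        | {(2, 2), (2, 4), (4, 2), (4, 4)}
    )
    assert set(layout.positions) == expected
    assert layout.n == 16


def test_jm_trisection_on_2009_1_grid():
    layout = pf.layout_jm(pf.preset("2009-1").geometry, "low")
    assert layout.params["trisection_cols"] == (13, 27)
    assert layout.params["trisection_rows"] == (14, 27)


def test_jm_junctions_are_the_four_transect_crossings():
    layout = pf.layout_jm(pf.preset("2009-1").geometry, "low")
    for junction in [(14, 13), (14, 27), (27, 13), (27, 27)]:
        assert junction in layout.positions


@pytest.mark.parametrize("preset_name", ["2009-1", "2009-2", "2010-1"])
def test_jm_low_is_subset_of_jm_high(preset_name):
    geo = pf.preset(preset_name).geometry
    low = pf.layout_jm(geo, "low")
    high = pf.layout_jm(geo, "high")
    assert set(low.positions) <= set(high.positions)


def test_jm_clamps_offsets_on_shallow_fields(geo6):
    with pytest.warns(UserWarning, match="clamped"):
        high = pf.layout_jm(geo6, "high")  # 10 m exceeds the 4.5 m width
    assert set(pf.layout_jm(geo6, "low").positions) <= set(high.positions)


def test_sys_step_one_covers_whole_field():
    geo = pf.FieldGeometry(n_rows=4, n_cols=5, plot_depth_m=1.0, plot_width_m=1.0)
    layout = pf.layout_sys(geo, 1, 1, seed=99)
    assert layout.n == geo.n_plots


def test_sys_lattice_count_on_2009_1():
    geo = pf.preset("2009-1").geometry
    layout = pf.layout_sys(geo, 6, 7, start=(0, 0))
    assert layout.n == int(np.ceil(41 / 6) * np.ceil(40 / 7)) == 42


def test_sys_same_seed_same_layout():
    geo = pf.preset("2009-1").geometry
    assert pf.layout_sys(geo, 6, 7, seed=5).positions == pf.layout_sys(geo, 6, 7, seed=5).positions


def test_srs_full_population_returns_whole_field():
    geo = pf.FieldGeometry(n_rows=3, n_cols=3, plot_depth_m=1.0, plot_width_m=1.0)
    layout = pf.layout_srs(geo, 9, seed=0)
    assert set(layout.positions) == {(r, c) for r in range(3) for c in range(3)}


def test_srs_default_size_on_2009_1():
    layout = pf.layout_srs(pf.preset("2009-1").geometry, 322, seed=1)
    assert layout.n == 322 == len(set(layout.positions))


def test_srs_draws_each_cell_uniformly():
    # 10,000 seeded single-plot draws from a 4-cell grid: each cell
    # 2500 +/- 150 (about 3 binomial SD).
    geo = pf.FieldGeometry(n_rows=2, n_cols=2, plot_depth_m=1.0, plot_width_m=1.0)
    counts = {}
    for s in range(10_000):
        (pos,) = pf.layout_srs(geo, 1, seed=s).positions
        counts[pos] = counts.get(pos, 0) + 1
    assert set(counts) == {(0, 0), (0, 1), (1, 0), (1, 1)}
    for v in counts.values():
        assert abs(v - 2500) <= 150


def test_srs_rejects_oversized_sample():
    geo = pf.FieldGeometry(n_rows=2, n_cols=2, plot_depth_m=1.0, plot_width_m=1.0)
    with pytest.raises(ValueError, match="sample size"):
        pf.layout_srs(geo, 5, seed=0)


@pytest.mark.parametrize("preset_name", ["2009-1", "2009-2", "2010-1"])
@pytest.mark.parametrize("scheme", pf.SCHEME_NAMES)
def test_layouts_are_on_grid_and_duplicate_free(preset_name, scheme):
    geo = pf.preset(preset_name).geometry
    params = dict(dict(pf.default_scheme_specs(preset_name))[scheme])
    layout = pf.build_scheme(scheme, geo, params, seed=7)
    layout.validate_on(geo)  # raises if off-grid
    assert len(set(layout.positions)) == layout.n >= 1


@pytest.mark.parametrize("scheme", ["T_two", "T_four", "T_six", "T_cross", "T_V", "JM_L", "JM_H"])
def test_fixed_layouts_are_deterministic(scheme):
    geo = pf.preset("2009-1").geometry
    l1 = pf.build_scheme(scheme, geo)
    l2 = pf.build_scheme(scheme, geo)
    assert l1.positions == l2.positions  # order included


def test_default_sample_sizes_approximate_the_surveys():
    geo = pf.preset("2009-1").geometry
    specs = dict(pf.default_scheme_specs("2009-1"))
    n = {s: pf.build_scheme(s, geo, dict(specs[s]), seed=0).n for s in specs}
    assert n["T_six"] == 42
    assert n["SRS"] == 322
    assert n["T_two"] in range(12, 17)
    assert n["T_four"] in range(22, 30)


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown scheme"):
        pf.build_scheme("T_seven", pf.preset("2009-1").geometry)
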