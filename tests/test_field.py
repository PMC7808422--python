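"""Synthetic field generator: presets, noise layers, reproducibility."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import pollenflow as pf


@pytest.mark.parametrize(
    "name,n_plots,depth,fb_widths",
    [
        ("2009-1", 1640, 2.5, {0.0}),
        ("2009-2", 3120, 1.25, {0.0, 6.75}),
        ("2010-1", 3640, 1.25, {0.0, 7.5}),
    ],
)
def test_preset_geometries_match_survey_designs(name, n_plots, depth, fb_widths):
    cfg = pf.preset(name)
    geo = cfg.geometry
    assert geo.n_plots == n_plots
    assert geo.plot_depth_m == depth
    assert set(np.unique(geo.fb_by_col())) == fb_widths
    assert cfg.a == 0.6261 and cfg.b == -0.6784


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        pf.preset("2011-9")


def test_geometry_validation():
    with pytest.raises(ValueError):
        pf.FieldGeometry(n_rows=0, n_cols=4, plot_depth_m=1, plot_width_m=1)
    with pytest.raises(ValueError, match="partition"):
        pf.FieldGeometry(
            n_rows=2, n_cols=4, plot_depth_m=1, plot_width_m=1,
            border_segments=(((0, 2), 0.0),),  # columns 2-3 uncovered
        )
    with pytest.raises(ValueError, match="FB"):
        pf.FieldGeometry(
            n_rows=2, n_cols=4, plot_depth_m=1, plot_width_m=1,
            border_segments=(((0, None), -1.0),),
        )


def test_distance_includes_border_width():
    # D runs from the pollen-source edge, so a bordered strip starts at FB.
    geo = pf.preset("2009-2").geometry
    assert geo.d_for(0, 0) == 0.0
    assert geo.d_for(0, 39) == 6.75
    assert geo.d_for(4, 39) == 6.75 + 4 * 1.25


def test_same_seed_reproduces_field_exactly():
    cfg = pf.preset("2009-1", seed=3)
    f1 = pf.generate_field(cfg)
    f2 = pf.generate_field(cfg)
    pd.testing.assert_frame_equal(f1.plots, f2.plots)
    f3 = pf.generate_field(replace(cfg, seed=4))
    assert not f3.plots["purple_grains"].equals(f1.plots["purple_grains"])


def test_true_p_monotone_decreasing_with_distance():
    cfg = pf.preset("2009-1")
    p = pf.true_cp_grid(cfg)
    assert np.all(np.diff(p, axis=0) < 0)  # b < 0, a irrelevant at FB=0


def test_realized_cp_declines_with_distance_at_large_avk():
    geo = pf.FieldGeometry(n_rows=3, n_cols=50, plot_depth_m=2.5, plot_width_m=0.75,
                           plants_per_plot=10, avk=2000)
    cfg = pf.GeneratorConfig(geometry=geo, p0=0.3, a=0.0, b=-0.2, seed=5)
    f = pf.generate_field(cfg)
    row_means = f.plots.groupby("row")["actual_cp"].mean()
    assert row_means.is_monotonic_decreasing


def test_border_effect_sign_at_fixed_distance():
    # a > 0: at equal D, plots behind a wider border see more pollen.
    cfg = pf.preset("2009-1")
    p_no_border = cfg.p0 * 10.0 ** (cfg.a * 0.0 + cfg.b * 10.0)
    p_border = cfg.p0 * 10.0 ** (cfg.a * 6.75 + cfg.b * 10.0)
    assert p_border > p_no_border


def test_grain_totals_never_exceed_capacity():
    for noise, rho in [("binomial", 0.0), ("beta_binomial", 0.2)]:
        geo = pf.FieldGeometry(n_rows=4, n_cols=8, plot_depth_m=1.0, plot_width_m=0.75,
                               plants_per_plot=3, avk=50)
        cfg = pf.GeneratorConfig(geometry=geo, p0=1.0, a=0.0, b=-0.01,
                                 noise_model=noise, overdispersion_rho=rho, seed=1)
        f = pf.generate_field(cfg)
        cap = f.plots["n_ears"] * f.plots["avk"]
        assert (f.plots["purple_grains"] <= cap).all()
        assert (f.plots["purple_grains"] >= 0).all()


def test_actual_cp_is_unbiased_for_true_p():
    # >= 1000 replicate plots at the same true rate: the purple-grain
    # fraction averages to p within 3 Monte-Carlo SE.
    geo = pf.FieldGeometry(n_rows=1, n_cols=1200, plot_depth_m=1.0, plot_width_m=0.75,
                           plants_per_plot=5, avk=100)
    p = 0.13
    cfg = pf.GeneratorConfig(geometry=geo, p0=p, a=0.0, b=0.0, seed=9)
    f = pf.generate_field(cfg)
    se = np.sqrt(p * (1 - p) / (5 * 100) / 1200)
    assert abs(f.plots["actual_cp"].mean() - p) < 3 * se


def test_generated_counts_match_independent_rng_replay():
    # Oracle: replay the documented draw order (single stream, row-major
    # binomial draws) with a fresh generator and identical seed.
    geo = pf.FieldGeometry(n_rows=2, n_cols=2, plot_depth_m=2.0, plot_width_m=0.75,
                           plants_per_plot=1, avk=100)
    cfg = pf.GeneratorConfig(geometry=geo, p0=0.1, a=0.0, b=-0.5, seed=21)
    f = pf.generate_field(cfg)
    true_by_row = f.plots.groupby("row")["true_p"].first()
    assert true_by_row[0] == pytest.approx(0.1)
    assert true_by_row[1] == pytest.approx(0.01)
    p = np.array([[0.1, 0.1], [0.01, 0.01]])
    expected = np.random.default_rng(21).binomial(100, p).astype(float)
    assert np.array_equal(
        f.plots["purple_grains"].to_numpy().reshape(2, 2), expected
    )


def test_beta_binomial_is_overdispersed_relative_to_binomial():
    geo = pf.FieldGeometry(n_rows=1, n_cols=2000, plot_depth_m=1.0, plot_width_m=0.75,
                           plants_per_plot=5, avk=100)
    base = pf.GeneratorConfig(geometry=geo, p0=0.2, a=0.0, b=0.0, seed=2)
    var_bin = pf.generate_field(base).plots["purple_grains"].var()
    over = replace(base, noise_model="beta_binomial", overdispersion_rho=0.3)
    var_bb = pf.generate_field(over).plots["purple_grains"].var()
    assert var_bb > 2 * var_bin


def test_noise_free_mode_reproduces_true_p_exactly():
    cfg = replace(pf.preset("2009-1"), noise_model="none")
    f = pf.generate_field(cfg)
    assert np.array_equal(f.plots["actual_cp"].to_numpy(), f.plots["true_p"].to_numpy())


def test_truncation_of_cp_above_one_warns():
    geo = pf.FieldGeometry(n_rows=2, n_cols=2, plot_depth_m=1.0, plot_width_m=0.75,
                           border_segments=(((0, 1), 0.0), ((1, None), 5.0)))
    cfg = pf.GeneratorConfig(geometry=geo, p0=0.9, a=1.0, b=0.0, seed=0)
    with pytest.warns(UserWarning, match="truncated"):
        f = pf.generate_field(cfg)
    assert f.plots["true_p"].max() == 1.0


def test_generator_config_validation():
    geo = pf.FieldGeometry(n_rows=2, n_cols=2, plot_depth_m=1.0, plot_width_m=1.0)
    with pytest.raises(ValueError):
        pf.GeneratorConfig(geometry=geo, p0=0.0)
    with pytest.raises(ValueError):
        pf.GeneratorConfig(geometry=geo, noise_model="gaussian")
    with pytest.raises(ValueError):
        pf.GeneratorConfig(geometry=geo, overdispersion_rho=1.0)


def test_planting_density_from_row_and_plant_spacing():
    assert pf.plant_density_per_ha(0.75, 0.25) == pytest.approx(53333.333, abs=0.01)


def test_field_grid_rejects_capacity_violations_and_duplicates():
    geo = pf.FieldGeometry(n_rows=1, n_cols=2, plot_depth_m=1.0, plot_width_m=1.0)
    good = pf.generate_field(pf.GeneratorConfig(geometry=geo, p0=0.5, seed=0)).plots
    bad = good.copy()
    bad.loc[0, "purple_grains"] = bad.loc[0, "n_ears"] * bad.loc[0, "avk"] + 1
    with pytest.raises(ValueError, match="purple_grains"):
        pf.FieldGrid(geo, bad)
    dup = pd.concat([good, good.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        pf.FieldGrid(geo, dup)
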