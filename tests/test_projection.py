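"""Raster projection: transformed stacks, PCA-RGB, vulnerability, seed sourcing."""

import numpy as np
import pytest
from shapely.geometry import box

import yellowbox as yb
from yellowbox.gdm import GEO
from yellowbox.projection import (
    genomic_vulnerability,
    pca_rgb,
    seed_source_map,
    transform_environment,
)
from yellowbox.rasters import (
    NODATA,
    EnvRasterStack,
    RegionMask,
    read_ascii_grid,
    write_ascii_grid,
)


@pytest.fixture(scope="module")
def fitted():
    cfg = yb.small_config(seed=21)
    current, future = yb.generate_environment(cfg)
    sites = yb.place_sites(cfg, current)
    gm, _ = yb.generate_genotypes(cfg, sites)
    scaled = yb.scale_unit_interval(yb.pairwise_fst_wc(gm))
    geo = yb.geographic_distance(sites)
    model = yb.fit_gdm(yb.make_pair_table(sites, cfg.layer_names, scaled, geo))
    return {"cfg": cfg, "current": current, "future": future, "model": model}


def zero_model(model):
    clone = yb.GDMModel.from_json(model.to_json())
    clone.intercept = 0.0
    clone.coefficients = {p: np.zeros_like(c) for p, c in clone.coefficients.items()}
    return clone


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path, rng):
        arr = rng.normal(size=(5, 7))
        p = tmp_path / "g.asc"
        write_ascii_grid(p, arr, 10.0, 20.0, 2.5)
        back, x0, y0, cs, nodata = read_ascii_grid(p)
        assert np.allclose(back, arr, atol=1e-9)
        assert (x0, y0, cs) == (10.0, 20.0, 2.5)

    def test_stack_round_trip(self, fitted, tmp_path):
        stack = fitted["current"]
        stack.write_dir(tmp_path / "stack")
        back = EnvRasterStack.read_dir(tmp_path / "stack")
        assert back.names == stack.names
        for n in stack.names:
            assert np.allclose(back.layers[n], stack.layers[n], atol=1e-9)
        assert back.scenario == stack.scenario


class TestTransformEnvironment:
    def test_zero_model_gives_zero_layers(self, fitted):
        res = transform_environment(zero_model(fitted["model"]), fitted["current"])
        for p in fitted["model"].predictors:
            assert np.all(res.transformed.layers[p] == 0)

    def test_constant_layer_maps_to_constant(self, fitted):
        model = fitted["model"]
        stack = fitted["current"]
        const = {n: np.full(stack.shape, 0.37) for n in stack.names}
        cstack = EnvRasterStack(const, stack.x_origin, stack.y_origin,
                                stack.cell_size, stack.crs, "current")
        res = transform_environment(model, cstack, include_geo=False)
        for p in model.predictors:
            expected = float(model.bases[p].evaluate(0.37) @ model.coefficients[p])
            vals = res.transformed.layers[p]
            assert np.allclose(vals, expected)

    def test_cellwise_values_equal_spline_evaluation(self, fitted):
        model = fitted["model"]
        stack = fitted["current"]
        res = transform_environment(model, stack)
        p = model.predictors[0]
        basis = model.bases[p]
        cells = stack.layers[p]
        expected = basis.evaluate(cells) @ model.coefficients[p]
        assert np.allclose(res.transformed.layers[p], expected, atol=1e-9)

    def test_missing_layer_named_in_error(self, fitted):
        model = fitted["model"]
        stack = fitted["current"]
        partial = EnvRasterStack(
            {n: stack.layers[n] for n in stack.names[1:]},
            stack.x_origin, stack.y_origin, stack.cell_size, stack.crs,
        )
        with pytest.raises(ValueError, match=stack.names[0]):
            transform_environment(model, partial)

    def test_mask_respected(self, fitted):
        stack = fitted["current"]
        half = box(0, 0, stack.cell_size * stack.shape[1], stack.cell_size * 10)
        mask = RegionMask.from_polygon(half, stack)
        res = transform_environment(fitted["model"], stack, mask)
        p = fitted["model"].predictors[0]
        out = res.transformed.layers[p]
        assert np.all(out[~mask.grid] == NODATA)
        assert np.all(np.isfinite(out[mask.grid]))


class TestPcaRgb:
    def test_channels_span_0_255(self, fitted):
        res = pca_rgb(transform_environment(fitted["model"], fitted["current"]))
        valid = res.mask.grid
        for k in range(3):
            ch = res.rgb[..., k][valid]
            assert ch.min() == 0 and ch.max() == 255

    def test_identical_cells_same_color(self, fitted):
        model = fitted["model"]
        stack = fitted["current"]
        # force two cells to identical environments
        for n in stack.names:
            stack.layers[n][0, 0] = stack.layers[n][1, 1]
        res = pca_rgb(transform_environment(model, stack))
        assert np.array_equal(res.rgb[0, 0], res.rgb[1, 1])

    def test_reconstruction_from_all_pcs(self, fitted):
        res = transform_environment(fitted["model"], fitted["current"])
        stack = res.transformed
        valid = res.mask.grid & stack.valid_mask()
        data = np.column_stack([stack.layers[n][valid] for n in stack.names])
        centered = data - data.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        assert np.allclose((u * s) @ vt, centered, atol=1e-8)

    def test_too_few_variable_layers_rejected(self, fitted):
        stack = fitted["current"]
        res = transform_environment(zero_model(fitted["model"]), stack)
        with pytest.raises(ValueError, match="3"):
            pca_rgb(res)


class TestGenomicVulnerability:
    def test_identical_scenarios_zero(self, fitted):
        model = fitted["model"]
        cur = fitted["current"]
        with pytest.warns(UserWarning, match="current"):
            v = genomic_vulnerability(model, cur, cur)
        assert np.allclose(v, 0.0)

    def test_unused_layer_perturbation_is_invisible(self, fitted):
        model = zero_model(fitted["model"])
        # give one predictor real weight, leave the rest at zero
        p_used = model.predictors[0]
        model.coefficients[p_used] = np.array([0.2, 0.2, 0.2])
        cur = fitted["current"]
        fut_layers = {n: a.copy() for n, a in cur.layers.items()}
        p_unused = model.predictors[1]
        fut_layers[p_unused] += 5.0
        fut = EnvRasterStack(fut_layers, cur.x_origin, cur.y_origin,
                             cur.cell_size, cur.crs, "future")
        v = genomic_vulnerability(model, cur, fut)
        assert np.allclose(v, 0.0)

    def test_uniform_shift_closed_form(self, fitted):
        model = fitted["model"]
        cur = fitted["current"]
        p0 = model.predictors[0]
        delta = 0.6
        fut_layers = {n: a.copy() for n, a in cur.layers.items()}
        fut_layers[p0] = fut_layers[p0] + delta
        fut = EnvRasterStack(fut_layers, cur.x_origin, cur.y_origin,
                             cur.cell_size, cur.crs, "future")
        v = genomic_vulnerability(model, cur, fut)
        basis, beta = model.bases[p0], model.coefficients[p0]
        x = cur.layers[p0]
        expected = 1 - np.exp(-np.abs(basis.evaluate(x + delta) @ beta
                                      - basis.evaluate(x) @ beta))
        assert np.allclose(v, expected, atol=1e-12)

    def test_symmetric_in_scenarios(self, fitted):
        model = fitted["model"]
        cur, fut = fitted["current"], fitted["future"]
        v1 = genomic_vulnerability(model, cur, fut)
        fut2 = EnvRasterStack(fut.layers, fut.x_origin, fut.y_origin,
                              fut.cell_size, fut.crs, "current")
        cur2 = EnvRasterStack(cur.layers, cur.x_origin, cur.y_origin,
                              cur.cell_size, cur.crs, "future")
        v2 = genomic_vulnerability(model, fut2, cur2)
        assert np.allclose(v1, v2, atol=1e-12)

    def test_range_and_mask(self, fitted):
        stack = fitted["current"]
        half = box(0, 0, stack.cell_size * stack.shape[1], stack.cell_size * 15)
        mask = RegionMask.from_polygon(half, stack)
        v = genomic_vulnerability(fitted["model"], stack, fitted["future"], mask)
        assert np.all(v[~mask.grid] == NODATA)
        inside = v[mask.grid]
        assert np.all((inside >= 0) & (inside < 1))


class TestSeedSourceMap:
    def test_perfectly_matched_target_cell_is_zero(self, fitted):
        model = fitted["model"]
        cur = fitted["current"]
        tx = ty = cur.cell_size * (cur.shape[0] // 2) + cur.cell_size / 2
        fut_env = {p: float(cur.sample(p, tx, ty)) for p in model.predictors}
        m = seed_source_map(model, (tx, ty), fut_env, cur)
        row = int(ty / cur.cell_size)
        col = int(tx / cur.cell_size)
        assert m[row, col] == pytest.approx(0.0, abs=1e-9)

    def test_geography_only_model_is_monotone_in_distance(self, fitted):
        model = zero_model(fitted["model"])
        model.coefficients[GEO] = np.array([0.1, 0.2, 0.3])
        cur = fitted["current"]
        tx = ty = cur.cell_size * 5
        fut_env = {p: 0.0 for p in model.predictors}
        m = seed_source_map(model, (tx, ty), fut_env, cur)
        xs, ys = cur.cell_centers()
        dist = np.hypot(xs - tx, ys - ty)
        basis, beta = model.bases[GEO], model.coefficients[GEO]
        expected = 1 - np.exp(-(basis.evaluate(dist) @ beta))
        assert np.allclose(m, expected, atol=1e-12)
        order = np.argsort(dist.ravel())
        assert np.all(np.diff(m.ravel()[order]) >= -1e-12)

    def test_unused_layer_shift_invariance(self, fitted):
        model = zero_model(fitted["model"])
        p_used, p_unused = model.predictors[0], model.predictors[1]
        model.coefficients[p_used] = np.array([0.3, 0.1, 0.1])
        cur = fitted["current"]
        tx = ty = cur.cell_size * 10
        fut_env = {p: 0.5 for p in model.predictors}
        m1 = seed_source_map(model, (tx, ty), fut_env, cur)
        shifted_layers = {n: a.copy() for n, a in cur.layers.items()}
        shifted_layers[p_unused] += 7.0
        shifted = EnvRasterStack(shifted_layers, cur.x_origin, cur.y_origin,
                                 cur.cell_size, cur.crs, "current")
        m2 = seed_source_map(model, (tx, ty), fut_env, shifted)
        assert np.allclose(m1, m2, atol=1e-12)

    def test_target_outside_mask_rejected(self, fitted):
        cur = fitted["current"]
        half = box(0, 0, cur.cell_size * cur.shape[1], cur.cell_size * 5)
        mask = RegionMask.from_polygon(half, cur)
        far_y = cur.cell_size * 20
        fut_env = {p: 0.0 for p in fitted["model"].predictors}
        with pytest.raises(ValueError, match="outside"):
            seed_source_map(fitted["model"], (100.0, far_y), fut_env, cur, mask)
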