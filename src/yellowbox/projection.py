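"""Project a fitted GDM onto raster landscapes.

Capabilities: spline-transformed environmental stacks, PCA red-green-blue
genomic-composition maps, genomic vulnerability (predicted dissimilarity
between each cell's current and future environments), and seed-source
matching maps for a restoration target.

Vulnerability and seed-source dissimilarities exclude the fitted
intercept by default: the intercept encodes the baseline dissimilarity of
any two distinct samples, which would put a constant floor under
same-location comparisons.  Pass ``include_intercept=True`` to keep it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import EARTH_RADIUS_KM
from .gdm import GEO, GDMModel
from .rasters import NODATA, EnvRasterStack, RegionMask


@dataclass
class ProjectionResult:
    transformed: EnvRasterStack
    mask: RegionMask
    clamp_counts: dict[str, int]
    rgb: np.ndarray | None = None  # (n_rows, n_cols, 3) uint8 where valid
    pca_loadings: np.ndarray | None = None
    pca_percent_variance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _check_layers(model: GDMModel, stack: EnvRasterStack) -> None:
    missing = [p for p in model.predictors if p not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing predictor layer(s): {missing}")


def _partial_grid(model: GDMModel, predictor: str, values: np.ndarray,
                  valid: np.ndarray) -> tuple[np.ndarray, int]:
    """Apply a fitted partial spline cellwise; returns (layer, n_clamped)."""
    basis = model.bases[predictor]
    v = values[valid]
    n_clamped = basis.n_clamped(v)
    out = np.full(values.shape, NODATA)
    out[valid] = basis.evaluate(v) @ model.coefficients[predictor]
    return out, n_clamped


def transform_environment(
    model: GDMModel, stack: EnvRasterStack, mask: RegionMask | None = None,
    include_geo: bool = True,
) -> ProjectionResult:
    """Map each predictor layer through its fitted partial spline.

    Two geographic layers (``geo_x``/``geo_y``) evaluate the fitted
    geographic spline on each cell's easting/northing offset, in km, from
    the mask's west/south edge — a per-axis approximation of the
    distance-based geographic term, mirroring coordinate-transform
    practice for GDM map projection.
    """
    _check_layers(model, stack)
    mask = mask or RegionMask.full(stack)
    valid = mask.grid & stack.valid_mask()
    layers: dict[str, np.ndarray] = {}
    clamps: dict[str, int] = {}
    for p in model.predictors:
        layers[p], clamps[p] = _partial_grid(model, p, stack.layers[p], valid)
    if include_geo:
        xs, ys = stack.cell_centers()
        rows, cols = np.where(valid)
        west_x = xs[valid].min()
        south_y = ys[valid].min()
        if stack.crs == "EPSG:4326":
            mean_lat = np.deg2rad(ys[valid].mean())
            km_per_deg = np.pi * EARTH_RADIUS_KM / 180.0
            off_x = (xs - west_x) * km_per_deg * np.cos(mean_lat)
            off_y = (ys - south_y) * km_per_deg
        else:
            off_x = xs - west_x
            off_y = ys - south_y
        geo_basis = model.bases[GEO]
        for nm, off in (("geo_x", off_x), ("geo_y", off_y)):
            out = np.full(stack.shape, NODATA)
            out[valid] = geo_basis.evaluate(off[valid]) @ model.coefficients[GEO]
            layers[nm] = out
            clamps[nm] = geo_basis.n_clamped(off[valid])
    transformed = EnvRasterStack(
        layers=layers, x_origin=stack.x_origin, y_origin=stack.y_origin,
        cell_size=stack.cell_size, crs=stack.crs, scenario=stack.scenario,
    )
    return ProjectionResult(
        transformed=transformed, mask=mask, clamp_counts=clamps,
        metadata={"scenario": stack.scenario},
    )


def pca_rgb(result: ProjectionResult) -> ProjectionResult:
    """PCA over in-mask cells of the transformed layers; PCs 1-3 are
    rescaled min->0, max->255 and assigned to R, G, B."""
    stack = result.transformed
    valid = result.mask.grid & stack.valid_mask()
    names = stack.names
    data = np.column_stack([stack.layers[n][valid] for n in names])
    variable = data.std(axis=0) > 0
    if variable.sum() < 3:
        raise ValueError(
            "need >= 3 transformed layers with variance inside the mask; "
            "consider an environment-only transform or fewer channels"
        )
    centered = data - data.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :3] * s[:3]
    var = s**2
    pct = 100.0 * var / var.sum()
    rgb_valid = np.empty((scores.shape[0], 3))
    for k in range(3):
        col = scores[:, k]
        rng = col.max() - col.min()
        rgb_valid[:, k] = 0.0 if rng == 0 else (col - col.min()) / rng * 255.0
    rgb = np.zeros(stack.shape + (3,), dtype=np.uint8)
    rgb[valid] = np.round(rgb_valid).astype(np.uint8)
    result.rgb = rgb
    result.pca_loadings = vt
    result.pca_percent_variance = pct
    return result


def _dissimilarity_from_partial_sums(model: GDMModel, abs_sum: np.ndarray,
                                     include_intercept: bool) -> np.ndarray:
    eta = abs_sum + (model.intercept if include_intercept else 0.0)
    return 1.0 - np.exp(-eta)


def genomic_vulnerability(
    model: GDMModel, current: EnvRasterStack, future: EnvRasterStack,
    mask: RegionMask | None = None, include_intercept: bool = False,
) -> np.ndarray:
    """Per-cell predicted dissimilarity between current and future
    environments at zero geographic distance — the genomic change implied
    by tracking the environmental shift in place.  Returns a grid in
    [0, 1) with NODATA outside the mask.
    """
    _check_layers(model, current)
    _check_layers(model, future)
    if current.shape != future.shape or current.cell_size != future.cell_size:
        raise ValueError("current and future stacks are not co-registered")
    import warnings

    if current.scenario == future.scenario == "current":
        warnings.warn("both stacks are tagged 'current'", stacklevel=2)
    mask = mask or RegionMask.full(current)
    valid = mask.grid & current.valid_mask() & future.valid_mask()
    abs_sum = np.zeros(valid.sum())
    for p in model.predictors:
        basis = model.bases[p]
        beta = model.coefficients[p]
        fc = basis.evaluate(current.layers[p][valid]) @ beta
        ff = basis.evaluate(future.layers[p][valid]) @ beta
        abs_sum += np.abs(fc - ff)
    out = np.full(current.shape, NODATA)
    out[valid] = _dissimilarity_from_partial_sums(model, abs_sum, include_intercept)
    return out


def seed_source_map(
    model: GDMModel, target_xy: tuple[float, float], future_env_at_target: dict,
    current: EnvRasterStack, mask: RegionMask | None = None,
    include_intercept: bool = False,
) -> np.ndarray:
    """Predicted dissimilarity between the target site under its FUTURE
    environment and every landscape cell under the CURRENT environment,
    including the geographic spline at the target-cell distance.  Low
    values mark good seed sources.  ``target_xy`` is (x, y) in the stack
    CRS — (lon, lat) for EPSG:4326 grids.
    """
    _check_layers(model, current)
    missing = [p for p in model.predictors if p not in future_env_at_target]
    if missing:
        raise ValueError(f"future env at target missing predictor(s): {missing}")
    mask = mask or RegionMask.full(current)
    tx, ty = target_xy
    if not mask.contains_point(current, tx, ty):
        raise ValueError(f"target {target_xy} is outside the mask")
    valid = mask.grid & current.valid_mask()
    abs_sum = np.zeros(valid.sum())
    for p in model.predictors:
        basis = model.bases[p]
        beta = model.coefficients[p]
        fc = basis.evaluate(current.layers[p][valid]) @ beta
        ft = float(basis.evaluate(np.asarray(future_env_at_target[p], float)) @ beta)
        abs_sum += np.abs(fc - ft)
    xs, ys = current.cell_centers()
    cx, cy = xs[valid], ys[valid]
    if current.crs == "EPSG:4326":
        dist = _haversine_km(ty, tx, cy, cx)
    else:
        dist = np.hypot(cx - tx, cy - ty)
    abs_sum += model.bases[GEO].evaluate(dist) @ model.coefficients[GEO]
    out = np.full(current.shape, NODATA)
    out[valid] = _dissimilarity_from_partial_sums(model, abs_sum, include_intercept)
    return out


def _haversine_km(lat1, lon1, lat2, lon2):
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def write_rgb_png(result: ProjectionResult, path) -> None:
    """Export the RGB composition map as PNG (north-up) with a world file."""
    from PIL import Image

    if result.rgb is None:
        raise ValueError("run pca_rgb first")
    img = np.flipud(result.rgb)  # row 0 = south internally; PNG is north-first
    Image.fromarray(img, mode="RGB").save(path)
    stack = result.transformed
    cs = stack.cell_size
    top_y = stack.y_origin + stack.shape[0] * cs - cs / 2
    world = f"{cs}\n0.0\n0.0\n{-cs}\n{stack.x_origin + cs / 2}\n{top_y}\n"
    from pathlib import Path as _P

    _P(str(path) + "w").write_text(world)
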